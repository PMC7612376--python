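"""Small-angle X-ray scattering analysis for rod-like assemblies.

Forward scattering from bead models (Debye sum) and analytic cylinders, and
the standard 1-D analyses for rod-like particles:

* Guinier fit, ln I vs q^2 over a self-consistent low-q window with
  q*Rg below a configurable limit (default 1.3), giving Rg = sqrt(-3*slope);
* cross-sectional Guinier fit, ln(q*I) vs q^2 over an intermediate-q window
  (above ~1.3/Rg, with q*Rc below the same limit), giving Rc = sqrt(-2*slope)
  — for a uniform cylinder Rg^2 = L^2/12 + R^2/2 and Rc = R/sqrt(2);
* regularized indirect Fourier inversion of I(q) to the pair-distance
  distribution P(r) with Dmax selection;
* least-squares chi^2 model-vs-data fitting;
* per-frame analysis of an SEC elution series, with the Shannon-limit flag
  (Dmax beyond ~pi/qmin is not determined by the sampled q-range).

Momentum transfer q is stored in 1/Å (the `.dat` convention); all lengths
are nm, so q is converted to 1/nm inside the fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.special import j1
from scipy.spatial.distance import pdist

from .beads import BeadModel, model_dmax

Q_A_TO_NM = 10.0  # 1/A -> 1/nm


class NoGuinierRegionError(RuntimeError):
    """The low-q data admit no decreasing Guinier window."""


class InsufficientDataError(RuntimeError):
    pass


class InversionFailedError(RuntimeError):
    """No (Dmax, alpha) candidate fits the curve below the chi^2 ceiling."""


@dataclass
class SAXSCurve:
    """One-dimensional scattering curve: q (1/Å), I, optional sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.I = np.asarray(self.I, dtype=float).ravel()
        if len(self.q) != len(self.I):
            raise ValueError("q and I must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float).ravel()
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class GuinierFit:
    Rg: float  # nm
    I0: float
    q_window: tuple[float, float]  # 1/A
    max_qRg: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class CrossSectionFit:
    Rc: float  # nm
    I0_cross: float
    q_window: tuple[float, float]
    max_qRc: float
    r2: float
    n_points: int


@dataclass
class PofR:
    """Pair-distance distribution on [0, Dmax]; p(0) = p(Dmax) = 0, p >= 0."""

    r: np.ndarray  # nm
    p: np.ndarray
    dmax: float  # nm
    rg: float  # nm, from the second moment of p(r)
    chi2: float | None = None
    alpha: float | None = None


def _pr_rg(r: np.ndarray, p: np.ndarray) -> float:
    denom = 2.0 * np.trapezoid(p, r)
    if denom <= 0:
        return float("nan")
    return float(np.sqrt(np.trapezoid(p * r**2, r) / denom))


# ---------------------------------------------------------------------------
# forward models

def debye_intensity(
    model: BeadModel, q_grid: np.ndarray, dr: float | None = None
) -> SAXSCurve:
    """Debye-sum intensity of a bead model on q_grid (1/Å).

    I(q) = sum_ij w_i w_j sin(q r_ij)/(q r_ij); I(0) = (sum w)^2 exactly.
    With ``dr`` set, pair distances are accumulated into bins of that width
    (nm) before the sum — a large speed-up at negligible cost for q well
    below 1/dr.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    w = model.weights
    self_term = float(np.sum(w * w))
    n = len(model)
    if n == 1:
        return SAXSCurve(q, np.full_like(q, self_term))
    d = pdist(model.coords)
    iu, ju = np.triu_indices(n, 1)
    ww = w[iu] * w[ju]
    if dr is not None:
        nbins = int(np.ceil(d.max() / dr)) + 1
        edges = np.arange(nbins + 1) * dr
        wsum, _ = np.histogram(d, bins=edges, weights=ww)
        centres = 0.5 * (edges[:-1] + edges[1:])
        keep = wsum > 0
        d, ww = centres[keep], wsum[keep]
    q_nm = q * Q_A_TO_NM
    out = np.empty_like(q)
    for k, qk in enumerate(q_nm):
        out[k] = self_term + 2.0 * float(np.sum(ww * np.sinc(qk * d / np.pi)))
    return SAXSCurve(q, out)


def cylinder_intensity(
    length: float, radius: float, q_grid: np.ndarray, n_quad: int = 400
) -> SAXSCurve:
    """Orientationally averaged uniform-cylinder form factor, I(0) = 1.

    Quadrature over the tilt angle between the cylinder axis and q uses
    fixed-order Gauss-Legendre nodes (deterministic).
    """
    if length <= 0 or radius <= 0:
        raise ValueError("length and radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    q_nm = q * Q_A_TO_NM
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    alpha = 0.5 * (nodes + 1.0) * (np.pi / 2.0)  # (0, pi/2)
    wq = weights * (np.pi / 4.0)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)

    qa = np.outer(q_nm, cos_a) * (length / 2.0)
    rod = np.sinc(qa / np.pi)
    qr = np.outer(q_nm, sin_a) * radius
    disc = np.where(qr > 1e-12, 2.0 * j1(np.maximum(qr, 1e-12)) / np.maximum(qr, 1e-12), 1.0)
    amp2 = (rod * disc) ** 2
    intensity = amp2 @ (wq * sin_a)
    norm = float(np.sum(wq * sin_a))  # = 1 analytically; normalise numerically
    if not np.isfinite(norm) or norm <= 0:
        raise ArithmeticError("cylinder quadrature failed to converge")
    return SAXSCurve(q, intensity / norm)


# ---------------------------------------------------------------------------
# Guinier analyses

def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def guinier_fit(
    curve: SAXSCurve,
    qRg_limit: float = 1.3,
    window_qRg: float = 0.8,
    min_points: int = 5,
    max_iter: int = 30,
) -> GuinierFit:
    """Self-consistent Guinier fit of ln I vs q^2 at low q.

    Starting from the lowest usable points, the window is re-fitted and its
    upper bound moved to window_qRg/Rg until stable; Rg = sqrt(-3 slope).
    ``qRg_limit`` is the hard validity cap on the window (the classical
    q*Rg < 1.3 criterion); ``window_qRg`` is the extension target actually
    used, set conservatively because the Guinier expansion departs early for
    elongated particles (q*Rg <= 0.8 is the standard rod guidance).
    """
    window_qRg = min(window_qRg, qRg_limit)
    usable = curve.I > 0
    q = curve.q[usable] * Q_A_TO_NM
    lnI = np.log(curve.I[usable])
    if len(q) < min_points:
        raise InsufficientDataError("need at least %d usable low-q points" % min_points)
    n_window = min_points
    for _ in range(max_iter):
        x, y = q[:n_window] ** 2, lnI[:n_window]
        slope, intercept, r2 = _linfit(x, y)
        if slope >= 0:
            # a few low-q points can be noise-flat; widen before giving up
            if n_window < len(q):
                n_window = min(len(q), 2 * n_window)
                continue
            raise NoGuinierRegionError("intensity does not decrease at low q")
        rg = float(np.sqrt(-3.0 * slope))
        qmax = window_qRg / rg
        new_n = int(np.searchsorted(q, qmax, side="right"))
        new_n = max(min_points, min(new_n, len(q)))
        if new_n == n_window:
            break
        n_window = new_n
    max_qrg = float(q[n_window - 1] * rg)
    return GuinierFit(
        Rg=rg,
        I0=float(np.exp(intercept)),
        q_window=(float(q[0] / Q_A_TO_NM), float(q[n_window - 1] / Q_A_TO_NM)),
        max_qRg=max_qrg,
        r2=r2,
        n_points=n_window,
    )


def cross_section_fit(
    curve: SAXSCurve,
    qRc_limit: float = 1.3,
    window_qRc: float = 1.3,
    plateau_factor: float = 1.6,
    rg_hint: float | None = None,
    min_points: int = 5,
    max_iter: int = 30,
) -> CrossSectionFit:
    """Cross-sectional Guinier fit of ln(q I) vs q^2 for rod-like particles.

    The window must exclude both the overall-size regime (q below ~1.3/Rg;
    Rg comes from ``guinier_fit`` unless ``rg_hint`` is given) and the
    finite-length transition around the q*I maximum, so it starts at
    ``plateau_factor`` times the q of that maximum and extends while
    q*Rc < window_qRc under self-consistent re-fitting, capped by
    ``qRc_limit``; Rc = sqrt(-2 slope).  A curve with I exactly
    proportional to 1/q has zero slope and returns Rc = 0.
    """
    window_qRc = min(window_qRc, qRc_limit)
    if rg_hint is None:
        rg_hint = guinier_fit(curve, qRg_limit=qRc_limit, min_points=min_points).Rg
    usable = curve.I > 0
    q = curve.q[usable] * Q_A_TO_NM
    lnqi = np.log(q / Q_A_TO_NM * curve.I[usable])  # ln(qI), q in 1/A (offset only)
    lo = int(np.searchsorted(q, 1.3 / rg_hint, side="left"))
    if len(q) - lo < min_points:
        raise InsufficientDataError("too few points above the overall-size regime")
    # anchor above the q*I maximum: the thin-rod plateau onset
    q_peak = q[lo + int(np.argmax(lnqi[lo:]))]
    lo = int(np.searchsorted(q, plateau_factor * q_peak, side="left"))
    if len(q) - lo < min_points:
        lo = len(q) - min_points
    # skip any residual rising flank (secondary q*I maxima of short rods)
    while len(q) - lo > min_points and _linfit(q[lo : lo + min_points] ** 2, lnqi[lo : lo + min_points])[0] > 0:
        lo += 1
    n_window = min_points
    for _ in range(max_iter):
        x = q[lo : lo + n_window] ** 2
        y = lnqi[lo : lo + n_window]
        slope, intercept, r2 = _linfit(x, y)
        if np.ptp(y) <= 1e-9 * max(1.0, float(np.max(np.abs(y)))):
            slope = 0.0  # numerically flat ln(qI): an exact 1/q rod, Rc = 0
        if slope > 0:
            if lo + n_window < len(q):
                n_window = min(len(q) - lo, 2 * n_window)
                continue
            raise NoGuinierRegionError("q*I rises over the cross-section window")
        rc = float(np.sqrt(-2.0 * slope))
        if rc > 0:
            qmax = window_qRc / rc
            new_n = int(np.searchsorted(q, qmax, side="right")) - lo
        else:
            new_n = len(q) - lo
        new_n = max(min_points, min(new_n, len(q) - lo))
        if new_n == n_window:
            break
        n_window = new_n
    max_qrc = float(q[lo + n_window - 1] * rc)
    return CrossSectionFit(
        Rc=rc,
        I0_cross=float(np.exp(intercept)),
        q_window=(float(q[lo] / Q_A_TO_NM), float(q[lo + n_window - 1] / Q_A_TO_NM)),
        max_qRc=max_qrc,
        r2=r2,
        n_points=n_window,
    )


# ---------------------------------------------------------------------------
# P(r)

def pofr_from_beads(model: BeadModel, dr: float = 0.1) -> PofR:
    """Weighted pair-distance histogram of a bead model, unit area."""
    if dr <= 0:
        raise ValueError("dr must be positive")
    dmax = model_dmax(model)
    if len(model) == 1:
        r = np.array([0.0, dmax / 2.0, dmax])
        return PofR(r, np.array([0.0, 1.0, 0.0]), dmax, 0.0)
    d = pdist(model.coords)
    w = model.weights
    iu, ju = np.triu_indices(len(model), 1)
    ww = w[iu] * w[ju]
    edges = np.arange(0.0, dmax + dr, dr)
    hist, edges = np.histogram(d, bins=edges, weights=ww)
    centres = 0.5 * (edges[:-1] + edges[1:])
    r = np.concatenate([[0.0], centres, [dmax]])
    p = np.concatenate([[0.0], hist, [0.0]])
    area = np.trapezoid(p, r)
    if area > 0:
        p = p / area
    return PofR(r, p, dmax, _pr_rg(r, p))


def _second_difference(n: int) -> np.ndarray:
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2


def _pr_grid(dmax: float, sol: np.ndarray, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Expand an interior NNLS solution to the full r grid with pinned ends."""
    r = np.linspace(0.0, dmax, len(sol) + 2)
    p = np.zeros(len(sol) + 2)
    p[1:-1] = sol * scale
    return r, p

def _flank_dmax(r: np.ndarray, p: np.ndarray, hi: float = 0.45, lo: float = 0.08) -> float:
    """Zero-crossing of a line fitted to the descending flank of p(r).

    A rod-like p(r) decays roughly linearly to zero at Dmax, so the
    x-intercept of the flank between ``hi`` and ``lo`` of the maximum is a
    support estimate that is insensitive to the thin tail being lost in
    noise.  Returns NaN when no usable flank exists.
    """
    pm = float(p.max())
    if pm <= 0:
        return float("nan")
    i_hi = int(np.where(p >= hi * pm)[0][-1])
    below = np.where(p[i_hi:] <= lo * pm)[0]
    i_lo = int(below[0]) + i_hi if len(below) else len(p) - 1
    if i_lo - i_hi < 3:
        return float("nan")
    slope, intercept = np.polyfit(r[i_hi : i_lo + 1], p[i_hi : i_lo + 1], 1)
    if slope >= 0:
        return float("nan")
    return float(-intercept / slope)

def ift_pofr(
    curve: SAXSCurve,
    dmax_candidates,
    alpha_grid=None,
    n_r: int = 40,
    chi2_ceiling: float = 25.0,
    knee_factor: float = 1.1,
    dmax_slack: float = 1.25,
) -> PofR:
    """Regularized indirect Fourier inversion of I(q) to P(r).

    For each candidate Dmax, p(r) on an n_r grid (endpoints pinned to zero,
    p >= 0) is solved by non-negative least squares on the Fourier kernel
    with a second-difference smoothness penalty alpha.  alpha is picked by
    a knee criterion on chi^2(alpha) — the largest alpha whose chi^2 is
    within ``knee_factor`` of the minimum.  Dmax selection combines fit
    feasibility with a support estimate: candidates whose knee chi^2 is
    within ``dmax_slack`` of the global best are all consistent with the
    data (truncating a thin p(r) tail costs less than the noise), so among
    them the one closest to a support estimate is chosen: the median, over
    the most generous candidate's knee-feasible alpha solutions, of the
    zero-crossing of a straight line fitted to the descending flank of
    p(r).  If no flank estimate is available the smallest feasible
    candidate wins (parsimony).

    ``n_r`` is a floor: the r grid is refined so its step stays below a
    quarter period of the highest-frequency Fourier kernel, otherwise the
    under-sampled kernel inflates chi^2 at large Dmax.
    """
    if curve.sigma is None:
        raise ValueError("indirect inversion requires sigma")
    if len(curve) < 30:
        raise InsufficientDataError("need at least 30 points for inversion")
    dmax_candidates = np.asarray(sorted(dmax_candidates), dtype=float)
    if alpha_grid is None:
        alpha_grid = np.logspace(-6.0, 6.0, 13)
    q_nm = curve.q * Q_A_TO_NM
    scale = float(np.max(curve.I))
    iw = curve.I / curve.sigma
    results = []
    qmax_nm = float(q_nm[-1])
    for dmax in dmax_candidates:
        n_r_d = max(n_r, int(np.ceil(4.0 * qmax_nm * dmax / np.pi)) + 1)
        r = np.linspace(0.0, dmax, n_r_d)
        dr_step = r[1] - r[0]
        kernel = np.sinc(np.outer(q_nm, r) / np.pi) * dr_step  # (nq, n_r_d)
        kw = (kernel / curve.sigma[:, None])[:, 1:-1]  # endpoints pinned to 0
        # rows encode integral(p''^2 dr) (second difference / dr^1.5),
        # normalized against the data block so alpha is dimensionless and
        # independent of the intensity scale and of the candidate grid
        d2 = _second_difference(n_r_d)[:, 1:-1] / dr_step**1.5
        d2 *= np.linalg.norm(kw) / max(np.linalg.norm(d2), 1e-300)
        b_vec = np.concatenate([iw, np.zeros(n_r_d - 2)])
        trials = []
        for alpha in alpha_grid:
            a_mat = np.vstack([kw * scale, np.sqrt(alpha) * d2 * scale])
            sol, _ = nnls(a_mat, b_vec)
            resid = kw * scale @ sol - iw
            chi2 = float(np.sum(resid**2) / max(len(curve) - 1, 1))
            trials.append((chi2, alpha, sol))
        chi_min = min(t[0] for t in trials)
        # knee: largest alpha within knee_factor of the chi2 minimum
        knee = max(
            (t for t in trials if t[0] <= chi_min * knee_factor + 1e-12),
            key=lambda t: t[1],
        )
        results.append((dmax, *knee))
        if dmax == dmax_candidates[-1]:
            last_trials, last_chi_min = trials, chi_min
    global_best = min(res[1] for res in results)
    # any reduced chi^2 <= 1 fits within the noise; without this floor the
    # relative slack compares meaningless ratios of near-zero chi^2 when the
    # data are (nearly) noiseless
    thresh = max(global_best * dmax_slack, 1.0)
    feasible = [res for res in results if res[1] <= thresh + 1e-12]
    if not feasible or global_best > chi2_ceiling:
        raise InversionFailedError(
            f"best reduced chi^2 {global_best:.3g} exceeds ceiling {chi2_ceiling}"
        )
    flanks = [
        _flank_dmax(*_pr_grid(float(dmax_candidates[-1]), t[2], scale))
        for t in last_trials
        if t[0] <= last_chi_min * knee_factor + 1e-12
    ]
    flanks = [f for f in flanks if np.isfinite(f)]
    d_est = float(np.median(flanks)) if flanks else float("nan")
    if np.isfinite(d_est):
        chosen = min(feasible, key=lambda res: abs(res[0] - d_est))
    else:
        chosen = feasible[0]
    dmax, chi2, alpha, sol = chosen
    r, p = _pr_grid(dmax, sol, scale)
    area = np.trapezoid(p, r)
    if area > 0:
        p = p / area
    return PofR(r, p, float(dmax), _pr_rg(r, p), chi2=chi2, alpha=float(alpha))


def shannon_channels(qmin: float, qmax: float, dmax: float) -> tuple[float, bool]:
    """Shannon channel count for a q-range (1/Å) and Dmax (nm), plus a
    reliability flag: Dmax at or beyond pi/qmin leaves the first channel
    unsampled and is therefore not determined by the data."""
    if qmax <= qmin or qmin < 0:
        raise ValueError("require qmax > qmin >= 0")
    channels = dmax * (qmax - qmin) * Q_A_TO_NM / np.pi
    if qmin == 0:
        reliable = True
    else:
        reliable = dmax < np.pi / (qmin * Q_A_TO_NM)
    return float(channels), bool(reliable)


# ---------------------------------------------------------------------------
# model-vs-data fitting and SEC series

def chi2_fit(model_curve: SAXSCurve, data_curve: SAXSCurve) -> tuple[float, float]:
    """Optimal scale and reduced chi^2 of a model curve against data.

    The scale c minimises sum(((c*Im - Id)/sigma)^2); chi^2 is that minimum
    divided by (N - 1).  The model is linearly interpolated onto the data
    grid and must cover it.
    """
    if data_curve.sigma is None:
        raise ValueError("data curve requires sigma")
    if np.all(data_curve.sigma == data_curve.sigma[0]) and data_curve.sigma[0] == 0:
        raise ValueError("zero-variance sigma")
    if data_curve.q[0] < model_curve.q[0] - 1e-12 or data_curve.q[-1] > model_curve.q[-1] + 1e-12:
        raise ValueError("model q-grid does not cover the data")
    im = np.interp(data_curve.q, model_curve.q, model_curve.I)
    iv = data_curve.sigma**2
    denom = float(np.sum(im * im / iv))
    if denom == 0:
        raise ValueError("degenerate model curve")
    c = float(np.sum(im * data_curve.I / iv)) / denom
    chi2 = float(np.sum((c * im - data_curve.I) ** 2 / iv) / max(len(data_curve) - 1, 1))
    return c, chi2


def analyze_sec_series(
    frames,
    dmax_candidates=None,
    qRg_limit: float = 1.3,
    qRc_limit: float = 1.3,
    **ift_kwargs,
):
    """Per-frame Guinier / cross-section / P(r) analysis of an elution series.

    Returns a pandas DataFrame ordered as the input, one row per frame with
    I0, Rg, Rc, Dmax (NaN when the Shannon limit makes it undetermined) and
    a status column; per-frame failures are recorded, never raised.
    """
    import pandas as pd

    if len(frames) < 1:
        raise ValueError("need at least one frame")
    if dmax_candidates is None:
        dmax_candidates = np.arange(10.0, 85.0, 2.5)
    rows = []
    for i, frame in enumerate(frames):
        row = {
            "frame": i,
            "I0": np.nan,
            "Rg_nm": np.nan,
            "Rc_nm": np.nan,
            "Dmax_nm": np.nan,
            "shannon_channels": np.nan,
            "shannon_reliable": False,
            "status": "ok",
        }
        problems = []
        rg = None
        try:
            g = guinier_fit(frame, qRg_limit=qRg_limit)
            row["I0"], row["Rg_nm"], rg = g.I0, g.Rg, g.Rg
        except (NoGuinierRegionError, InsufficientDataError) as exc:
            problems.append(f"guinier: {exc}")
        try:
            c = cross_section_fit(frame, qRc_limit=qRc_limit, rg_hint=rg)
            row["Rc_nm"] = c.Rc
        except (NoGuinierRegionError, InsufficientDataError) as exc:
            problems.append(f"cross-section: {exc}")
        try:
            pr = ift_pofr(frame, dmax_candidates, **ift_kwargs)
            channels, reliable = shannon_channels(frame.q[0], frame.q[-1], pr.dmax)
            row["shannon_channels"] = channels
            row["shannon_reliable"] = reliable
            row["Dmax_nm"] = pr.dmax if reliable else np.nan
        except (InversionFailedError, InsufficientDataError, ValueError) as exc:
            problems.append(f"pofr: {exc}")
        if problems:
            row["status"] = "; ".join(problems)
        rows.append(row)
    return pd.DataFrame(rows)
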