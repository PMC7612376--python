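"""Quantification of curvilinear fibres in negative-stain-like micrographs.

The measurement chain mirrors standard practice for filament micrographs:
background correction plus an FFT bandpass, Hessian-based (Steger-style)
ridge detection with sub-pixel centreline localisation, per-point width from
the two gradient extrema along the local normal, conversion to physical
units, and width-population statistics (histogram and 1-D Gaussian-mixture
fitting).

Image convention: row-major arrays, origin top-left, y increases downward;
sub-pixel coordinates are (column, row) = (x, y) floats.  Negative staining
can render fibres dark (stain accumulation) or bright, so ridge polarity is
an explicit parameter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize


class Polarity(enum.Enum):
    DARK_RIDGES = "dark"
    BRIGHT_RIDGES = "bright"


class DegenerateFitError(RuntimeError):
    """The width sample cannot support the requested mixture."""


@dataclass
class Micrograph:
    pixels: np.ndarray  # 2-D float intensities
    pixel_size: float  # nm per pixel
    polarity: Polarity = Polarity.DARK_RIDGES

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D intensity array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FibreTrace:
    """One detected fibre: ordered sub-pixel centreline with per-point widths."""

    id: int
    points: np.ndarray  # (N, 2) sub-pixel (x, y)
    widths_px: np.ndarray  # (N,) may contain NaN where edges were not found
    length_nm: float
    mean_width_nm: float

    @property
    def length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass(frozen=True)
class WidthPopulation:
    label: str
    mean: float  # nm
    sd: float  # nm
    n: int


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    image: Micrograph,
    bg_scale: float = 40.0,
    band_small: float = 2.0,
    band_large: float = 40.0,
) -> Micrograph:
    """Background correction and radial FFT bandpass; output zero mean, unit sd.

    A Gaussian estimate at ``bg_scale`` px removes the slowly varying
    background (stain gradients, illumination); the bandpass then keeps
    structure with spatial periods between ``band_small`` and ``band_large``
    pixels, with smooth Gaussian roll-offs.
    """
    if not band_small < band_large < min(image.pixels.shape):
        raise ValueError("require band_small < band_large < image size")
    img = image.pixels
    background = ndi.gaussian_filter(img, bg_scale, mode="nearest")
    flat = img - background
    f = np.fft.rfft2(flat)
    fy = np.fft.fftfreq(flat.shape[0])[:, None]
    fx = np.fft.rfftfreq(flat.shape[1])[None, :]
    radius = np.hypot(fy, fx)  # cycles / px
    f_hi, f_lo = 1.0 / band_small, 1.0 / band_large
    # smooth band edges: Gaussian roll-off with width 25% of each cut-off
    keep = np.exp(-0.5 * (radius / f_hi) ** 4) * (1.0 - np.exp(-0.5 * (radius / f_lo) ** 4))
    out = np.fft.irfft2(f * keep, s=flat.shape)
    out -= out.mean()
    sd = out.std()
    if sd > 1e-12:
        out /= sd
    else:
        out = np.zeros_like(out)
    return Micrograph(out, image.pixel_size, image.polarity)


# ---------------------------------------------------------------------------
# ridge detection

def _hessian_fields(s: np.ndarray, sigma: float):
    gx = ndi.gaussian_filter(s, sigma, order=(0, 1), mode="nearest")
    gy = ndi.gaussian_filter(s, sigma, order=(1, 0), mode="nearest")
    hxx = ndi.gaussian_filter(s, sigma, order=(0, 2), mode="nearest")
    hyy = ndi.gaussian_filter(s, sigma, order=(2, 0), mode="nearest")
    hxy = ndi.gaussian_filter(s, sigma, order=(1, 1), mode="nearest")
    return gx, gy, hxx, hxy, hyy


def _principal_eigen(hxx, hxy, hyy):
    """Eigenvalue of largest magnitude of the 2x2 Hessian, and its eigenvector."""
    tr = hxx + hyy
    det_half = np.sqrt(((hxx - hyy) / 2.0) ** 2 + hxy**2)
    lam1 = tr / 2.0 + det_half
    lam2 = tr / 2.0 - det_half
    take2 = np.abs(lam2) > np.abs(lam1)
    lam = np.where(take2, lam2, lam1)
    # eigenvector for lam: (hxy, lam - hxx) and (lam - hyy, hxy) are both
    # valid; either degenerates when the Hessian is (near-)diagonal, so take
    # the better-conditioned of the two per pixel
    v1x, v1y = hxy, lam - hxx
    v2x, v2y = lam - hyy, hxy
    use2 = np.hypot(v2x, v2y) > np.hypot(v1x, v1y)
    vx = np.where(use2, v2x, v1x)
    vy = np.where(use2, v2y, v1y)
    norm = np.hypot(vx, vy)
    ok = norm > 1e-12
    vx = np.where(ok, vx / np.where(ok, norm, 1.0), 1.0)
    vy = np.where(ok, vy / np.where(ok, norm, 1.0), 0.0)
    return lam, vx, vy


def _trace_components(mask: np.ndarray):
    """Split a thin binary mask at junctions and return ordered pixel chains."""
    skel = skeletonize(mask)
    neigh = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant") - skel
    junctions = skel & (neigh >= 3)
    pruned = skel & ~junctions
    labels, n_lab = ndi.label(pruned, structure=np.ones((3, 3), int))
    chains = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < 2:
            continue
        pixels = set(zip(ys.tolist(), xs.tolist()))
        # adjacency by 8-connectivity
        def neighbours(p):
            y, x = p
            return [
                (y + dy, x + dx)
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy or dx) and (y + dy, x + dx) in pixels
            ]

        degree = {p: len(neighbours(p)) for p in pixels}
        endpoints = [p for p, d in degree.items() if d == 1]
        start = min(endpoints) if endpoints else min(pixels)
        chain = [start]
        visited = {start}
        current = start
        while True:
            nxt = [p for p in neighbours(current) if p not in visited]
            if not nxt:
                break
            # prefer 4-connected steps to keep the path tight
            nxt.sort(key=lambda p: (abs(p[0] - current[0]) + abs(p[1] - current[1])))
            current = nxt[0]
            visited.add(current)
            chain.append(current)
        if len(chain) >= 2:
            chains.append(np.array(chain))  # rows of (y, x)
    return chains


def _widths_along_normals(
    smoothed: np.ndarray, points_xy: np.ndarray, normals_xy: np.ndarray, search: float
) -> np.ndarray:
    """Width at each centreline point from the two gradient extrema along the normal."""
    step = 0.25
    offsets = np.arange(-search, search + step / 2, step)
    # sample coordinates: (n_pts, n_off)
    xs = points_xy[:, 0][:, None] + offsets[None, :] * normals_xy[:, 0][:, None]
    ys = points_xy[:, 1][:, None] + offsets[None, :] * normals_xy[:, 1][:, None]
    prof = ndi.map_coordinates(smoothed, [ys.ravel(), xs.ravel()], order=3, mode="nearest")
    prof = prof.reshape(xs.shape)
    grad = np.gradient(prof, step, axis=1)
    centre = len(offsets) // 2
    guard = int(round(0.5 / step))  # ignore +-0.5 px around the centre
    widths = np.full(len(points_xy), np.nan)
    left = grad[:, : centre - guard]
    right = grad[:, centre + guard + 1 :]
    if left.shape[1] == 0 or right.shape[1] == 0:
        return widths

    def _refine(block, idx):
        # parabolic sub-sample refinement of the extremum position
        shift = np.zeros(len(idx))
        interior = (idx > 0) & (idx < block.shape[1] - 1)
        rows = np.arange(len(idx))[interior]
        i = idx[interior]
        y0, y1, y2 = block[rows, i - 1], block[rows, i], block[rows, i + 1]
        denom = y0 - 2 * y1 + y2
        ok = np.abs(denom) > 1e-12
        shift[rows[ok]] = np.clip(0.5 * (y0 - y2)[ok] / denom[ok], -0.5, 0.5)
        return shift

    il = np.argmax(left, axis=1)  # rising edge on the negative side
    ir = np.argmin(right, axis=1)  # falling edge on the positive side
    o_left = offsets[: centre - guard][il] + _refine(left, il) * step
    o_right = offsets[centre + guard + 1 :][ir] + _refine(right, ir) * step
    good = (left[np.arange(len(il)), il] > 0) & (right[np.arange(len(ir)), ir] < 0)
    widths[good] = (o_right - o_left)[good]
    return widths


def _extend_ends(points: np.ndarray, smoothed: np.ndarray, sigma: float) -> np.ndarray:
    """Extend a centreline along its end tangents while the ridge persists.

    Hessian-based tracing loses roughly one smoothing scale at each fibre
    end (the second derivative flips before the intensity does), so each end
    is marched forward while the smoothed intensity stays above the midpoint
    between the trace's median amplitude and the image background, for at
    most 3 sigma.
    """
    if len(points) < 2:
        return points
    h, w = smoothed.shape
    bg = float(np.median(smoothed))
    amp = float(
        np.median(ndi.map_coordinates(smoothed, [points[:, 1], points[:, 0]], order=1, mode="nearest"))
    )
    thresh = bg + 0.5 * (amp - bg)
    if amp <= bg:
        return points
    step = 0.5
    n_max = int(np.ceil(3.0 * sigma / step))
    out = points
    for end, inward in ((0, 1), (-1, -2)):
        tangent = out[end] - out[inward]
        norm = np.linalg.norm(tangent)
        if norm < 1e-9:
            continue
        tangent = tangent / norm
        added = []
        pos = out[end]
        for _ in range(n_max):
            cand = pos + step * tangent
            if not (1 <= cand[0] < w - 1 and 1 <= cand[1] < h - 1):
                break
            val = float(ndi.map_coordinates(smoothed, [[cand[1]], [cand[0]]], order=1, mode="nearest")[0])
            if val < thresh:
                break
            added.append(cand)
            pos = cand
        if added:
            ext = np.array(added)
            out = np.vstack([ext[::-1], out]) if end == 0 else np.vstack([out, ext])
    return out


def detect_ridges(
    image: Micrograph,
    sigma: float = 2.0,
    high_thresh: float = 0.3,
    low_thresh: float = 0.1,
    min_length: float = 10.0,
) -> list[FibreTrace]:
    """Steger-style ridge detection with sub-pixel centrelines and widths.

    The image is analysed at Gaussian-derivative scale ``sigma`` (px);
    candidate line points are pixels whose scale-normalised principal
    second derivative across the line exceeds the thresholds (hysteresis
    linking) and whose sub-pixel ridge position falls inside the pixel.
    ``sigma`` should be about expected_width / (2*sqrt(3)); widths are the
    distance between the two gradient-magnitude extrema along the local
    normal.  ``min_length`` is in pixels.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not high_thresh >= low_thresh >= 0:
        raise ValueError("require high_thresh >= low_thresh >= 0")
    if 6 * sigma >= min(image.pixels.shape):
        raise ValueError("sigma too large for the image")
    s = image.pixels if image.polarity is Polarity.BRIGHT_RIDGES else -image.pixels
    gx, gy, hxx, hxy, hyy = _hessian_fields(s, sigma)
    lam, nx, ny = _principal_eigen(hxx, hxy, hyy)
    strength = np.where(lam < 0, sigma**2 * (-lam), 0.0)  # gamma-normalised
    # sub-pixel offset along the normal to the zero of the directional derivative
    second = hxx * nx**2 + 2 * hxy * nx * ny + hyy * ny**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(gx * nx + gy * ny) / second
    t = np.where(np.isfinite(t), t, np.inf)
    with np.errstate(invalid="ignore"):  # inf * 0 -> nan compares False, as intended
        inside = (np.abs(t * nx) <= 0.55) & (np.abs(t * ny) <= 0.55)
    candidate = strength * (inside & (strength > 0))
    if not np.any(candidate > low_thresh) or not np.any(candidate >= high_thresh):
        return []
    mask = apply_hysteresis_threshold(candidate, low_thresh, high_thresh)
    chains = _trace_components(mask)
    smoothed = ndi.gaussian_filter(s, sigma, mode="nearest")
    search = max(2.0 * np.sqrt(3.0) * sigma + 2.0, 4.0)
    traces: list[FibreTrace] = []
    fid = 0
    for chain in chains:
        ys, xs = chain[:, 0], chain[:, 1]
        tc = np.clip(t[ys, xs], -0.75, 0.75)
        px = xs + tc * nx[ys, xs]
        py = ys + tc * ny[ys, xs]
        core = np.column_stack([px, py])
        # length gate on the un-extended chain so end extension cannot
        # promote skeleton spurs past the threshold
        if float(np.linalg.norm(np.diff(core, axis=0), axis=1).sum()) < min_length:
            continue
        points = _extend_ends(core, smoothed, sigma)
        seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
        length_px = float(seglen.sum())
        normals = np.column_stack([nx[ys, xs], ny[ys, xs]])
        core_widths = _widths_along_normals(smoothed, core, normals, search)
        widths = np.full(len(points), np.nan)
        start = int(np.where((points == core[0]).all(axis=1))[0][0])
        widths[start : start + len(core)] = core_widths
        valid = widths[np.isfinite(widths)]
        mean_w_px = float(np.mean(valid)) if len(valid) else float("nan")
        traces.append(
            FibreTrace(
                id=fid,
                points=points,
                widths_px=widths,
                length_nm=length_px * image.pixel_size,
                mean_width_nm=mean_w_px * image.pixel_size,
            )
        )
        fid += 1
    return traces


def measure_fibres(traces, pixel_size: float, min_length_nm: float = 0.0) -> pd.DataFrame:
    """Per-fibre physical measurements as an id-sorted table."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rows = []
    for tr in traces:
        length_nm = tr.length_px * pixel_size
        if length_nm < min_length_nm:
            continue
        valid = tr.widths_px[np.isfinite(tr.widths_px)]
        mean_w = float(np.mean(valid)) * pixel_size if len(valid) else np.nan
        rows.append({"id": tr.id, "length_nm": length_nm, "mean_width_nm": mean_w})
    df = pd.DataFrame(rows, columns=["id", "length_nm", "mean_width_nm"])
    return df.sort_values("id").reset_index(drop=True)


def width_histogram(widths, bin: float = 0.5):
    """Left-closed right-open histogram of widths from 0; conserves total n."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    widths = np.asarray(list(widths), dtype=float)
    if len(widths) == 0:
        return np.array([0.0]), np.array([], dtype=int)
    idx = np.floor(widths / bin).astype(int)
    nbins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nbins)
    edges = np.arange(nbins + 1) * bin
    return edges, counts


def fit_width_populations(widths, k: int, seed: int = 0) -> list[WidthPopulation]:
    """1-D Gaussian mixture of fibre widths by EM, deterministic quantile init.

    Returns per-component mean, sd and hard-assigned count (summing to the
    sample size), sorted by mean.  With k = 1 this is the sample mean and
    (population) standard deviation.
    """
    from sklearn.mixture import GaussianMixture

    w = np.asarray(list(widths), dtype=float)
    if len(w) < 2 * k:
        raise DegenerateFitError(f"need at least {2 * k} widths for k={k}")
    if len(np.unique(w)) < max(k, 2):
        raise DegenerateFitError("width sample is degenerate (too few distinct values)")
    quantiles = np.quantile(w, (np.arange(k) + 0.5) / k)
    var0 = max(float(np.var(w)) / max(k, 1), 1e-6)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="spherical",
        means_init=quantiles.reshape(-1, 1),
        weights_init=np.full(k, 1.0 / k),
        precisions_init=np.full(k, 1.0 / var0),
        random_state=seed,
        n_init=1,
        max_iter=500,
        reg_covar=1e-8,
    )
    x = w.reshape(-1, 1)
    gm.fit(x)
    labels = gm.predict(x)
    order = np.argsort(gm.means_.ravel())
    pops = []
    for rank, comp in enumerate(order):
        n = int(np.sum(labels == comp))
        pops.append(
            WidthPopulation(
                label=f"population-{rank + 1}",
                mean=float(gm.means_.ravel()[comp]),
                sd=float(np.sqrt(gm.covariances_.ravel()[comp])),
                n=n,
            )
        )
    return pops
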