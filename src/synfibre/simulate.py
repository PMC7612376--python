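"""Synthetic data generators: noisy SAXS curves, negative-stain-like
micrographs with ground truth, and SEC elution series of assembly mixtures.

These generators provide every input the analysis modules consume, with the
statistical structure those analyses assume: Gaussian intensity noise with
an intensity-proportional standard deviation for SAXS (counting statistics
are not modelled), persistent-random-walk fibres rendered as rectangular
cross-profiles blurred by a Gaussian PSF on a slowly varying noisy
background for EM, and convex mixtures of cached species curves for SEC
frames.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .assembly import FOUR_FOUR, TWO_TWO, AssemblyRule
from .beads import FibreModelSpec, build_fibre_beads
from .emquant import Micrograph, Polarity
from .saxs import SAXSCurve, debye_intensity


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian SAXS noise: sigma(q) = relative_sd * I(q) + floor_sd."""

    relative_sd: float = 0.02
    floor_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.floor_sd <= 0:
            raise ValueError("floor_sd must be positive")


def simulate_saxs(model_curve: SAXSCurve, noise: NoiseModel) -> SAXSCurve:
    """Add Gaussian noise to a model curve; the sigma column records sigma(q)."""
    sigma = noise.relative_sd * np.abs(model_curve.I) + noise.floor_sd
    rng = np.random.default_rng(noise.seed)
    observed = model_curve.I + rng.normal(0.0, sigma)
    return SAXSCurve(model_curve.q, observed, sigma)


# ---------------------------------------------------------------------------
# micrographs

@dataclass(frozen=True)
class FibreClassRecipe:
    """One fibre width class to draw: true widths ~ N(mean, sd), clipped > 0."""

    label: str
    count: int
    width_mean_nm: float
    width_sd_nm: float
    length_range_nm: tuple[float, float] = (40.0, 120.0)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.width_mean_nm <= 0 or self.width_sd_nm < 0:
            raise ValueError("widths must be positive")
        if self.length_range_nm[0] <= 0 or self.length_range_nm[0] > self.length_range_nm[1]:
            raise ValueError("invalid length range")


@dataclass(frozen=True)
class MicrographRecipe:
    """Synthetic negative-stain field: curvilinear fibres on a noisy background.

    Fibres are persistent random walks (step 2 px, turning angle set by the
    persistence length); each is rendered as a rectangular cross-profile of
    its true width and blurred by a Gaussian PSF.  The published small-
    assembly fields motivate the defaults: 2-nm-class and 4-nm-class fibres
    with the printed population dispersions, molecule lengths spanning
    roughly 20-110 nm.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # nm / px
    classes: tuple[FibreClassRecipe, ...] = (
        FibreClassRecipe("2:2-fibre", 8, 2.3, 0.4, (20.0, 110.0)),
        FibreClassRecipe("4:4-fibre", 4, 3.6, 1.0, (20.0, 110.0)),
    )
    persistence_nm: float = 400.0
    contrast: float = 1.0
    gradient_amplitude: float = 0.3
    noise_sd: float = 0.05
    polarity: Polarity = Polarity.DARK_RIDGES
    psf_sigma_px: float = 1.0
    min_separation_px: float = 14.0
    margin_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.persistence_nm <= 0:
            raise ValueError("pixel_size and persistence must be positive")
        if self.noise_sd < 0 or self.contrast <= 0:
            raise ValueError("invalid contrast/noise")


def _walk_polyline(rng, start, theta0, n_steps, step, turn_sd, shape, margin):
    pts = [np.asarray(start, dtype=float)]
    theta = theta0
    for _ in range(n_steps):
        theta = theta + rng.normal(0.0, turn_sd)
        nxt = pts[-1] + step * np.array([np.cos(theta), np.sin(theta)])
        if not (margin <= nxt[0] < shape[1] - margin and margin <= nxt[1] < shape[0] - margin):
            break
        pts.append(nxt)
    return np.array(pts)  # (n, 2) as (x, y)


def sample_fibre_truth(recipe: MicrographRecipe) -> pd.DataFrame:
    """Draw the ground-truth fibres (polylines, widths, lengths) for a recipe."""
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.shape
    margin = recipe.margin_px
    if margin * 2 + 8 >= min(h, w):
        raise ValueError("image too small for the requested margins")
    step = 2.0  # px
    accepted_pts: list[np.ndarray] = []
    rows = []
    fid = 0
    for cls in recipe.classes:
        for _ in range(cls.count):
            width_nm = 0.0
            while width_nm <= 0.2:
                width_nm = rng.normal(cls.width_mean_nm, cls.width_sd_nm)
            target_nm = rng.uniform(*cls.length_range_nm)
            n_steps = max(2, int(round(target_nm / recipe.pixel_size / step)))
            turn_sd = np.sqrt(step * recipe.pixel_size / recipe.persistence_nm)
            placed = None
            for _attempt in range(200):
                start = rng.uniform(
                    [margin, margin], [w - margin, h - margin]
                )
                theta0 = rng.uniform(0, 2 * np.pi)
                poly = _walk_polyline(
                    rng, start, theta0, n_steps, step, turn_sd, recipe.shape, margin
                )
                if len(poly) < max(3, n_steps // 2):
                    continue
                if accepted_pts:
                    tree = cKDTree(np.vstack(accepted_pts))
                    if tree.query(poly, k=1)[0].min() < recipe.min_separation_px:
                        continue
                placed = poly
                break
            if placed is None:
                raise ValueError(
                    "could not place all requested fibres; image too small or too crowded"
                )
            accepted_pts.append(placed)
            length_px = float(np.sum(np.linalg.norm(np.diff(placed, axis=0), axis=1)))
            rows.append(
                {
                    "id": fid,
                    "label": cls.label,
                    "width_nm": float(width_nm),
                    "width_px": float(width_nm / recipe.pixel_size),
                    "length_nm": length_px * recipe.pixel_size,
                    "polyline": placed,
                }
            )
            fid += 1
    return pd.DataFrame(rows, columns=["id", "label", "width_nm", "width_px", "length_nm", "polyline"])


def _rasterize_polyline(dist: np.ndarray, poly: np.ndarray, pad: float) -> None:
    """Min-accumulate the distance to a polyline into ``dist`` (in place)."""
    h, w = dist.shape
    for a, b in zip(poly[:-1], poly[1:]):
        x0 = int(max(0, np.floor(min(a[0], b[0]) - pad)))
        x1 = int(min(w, np.ceil(max(a[0], b[0]) + pad) + 1))
        y0 = int(max(0, np.floor(min(a[1], b[1]) - pad)))
        y1 = int(min(h, np.ceil(max(a[1], b[1]) + pad) + 1))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-12:
            d = np.hypot(xx - a[0], yy - a[1])
        else:
            t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
            tc = np.clip(t, 0.0, 1.0)
            d = np.hypot(xx - (a[0] + tc * ab[0]), yy - (a[1] + tc * ab[1]))
            # flat fibre ends: beyond the segment span contributes nothing
            # (interior joints are covered by the neighbouring segment)
            d = np.where((t >= 0.0) & (t <= 1.0), d, np.inf)
        np.minimum(dist[y0:y1, x0:x1], d, out=dist[y0:y1, x0:x1])


def render_micrograph(truth: pd.DataFrame, recipe: MicrographRecipe) -> np.ndarray:
    """Noise-free fibre layer: rectangular profiles blurred by the PSF."""
    h, w = recipe.shape
    layer = np.zeros((h, w))
    for _, row in truth.iterrows():
        dist = np.full((h, w), np.inf)
        half = row["width_px"] / 2.0
        _rasterize_polyline(dist, row["polyline"], pad=half + 3.0)
        # area-coverage anti-aliasing: the 50% contour sits at exactly
        # width/2 regardless of fibre orientation
        layer += recipe.contrast * np.clip(half + 0.5 - dist, 0.0, 1.0)
    if recipe.psf_sigma_px > 0:
        layer = ndi.gaussian_filter(layer, recipe.psf_sigma_px, mode="nearest")
    return layer


def simulate_micrograph(recipe: MicrographRecipe) -> tuple[Micrograph, pd.DataFrame]:
    """Full synthetic micrograph plus its ground-truth table."""
    truth = sample_fibre_truth(recipe)
    layer = render_micrograph(truth, recipe)
    h, w = recipe.shape
    rng = np.random.default_rng(recipe.seed + 1_000_003)
    yy, xx = np.mgrid[0:h, 0:w]
    gx, gy = rng.uniform(-1, 1, 2)
    gradient = recipe.gradient_amplitude * (gx * xx / w + gy * yy / h)
    background = 0.5 + gradient + rng.normal(0.0, recipe.noise_sd, (h, w))
    sign = -1.0 if recipe.polarity is Polarity.DARK_RIDGES else 1.0
    pixels = background + sign * layer
    return Micrograph(pixels, recipe.pixel_size, recipe.polarity), truth


# ---------------------------------------------------------------------------
# SEC elution series

@dataclass(frozen=True)
class SECSeriesRecipe:
    """Per-frame species mixtures on a common q grid.

    ``frames`` is a list of frames; each frame is a list of
    (FibreModelSpec, weight fraction) with fractions summing to one.
    """

    frames: tuple
    q: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)
    debye_dr: float = 0.05  # nm; distance-binning for the Debye sums

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("need at least one frame")
        for frame in self.frames:
            total = sum(frac for _, frac in frame)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("species fractions must sum to 1 in every frame")
            if any(frac < 0 for _, frac in frame):
                raise ValueError("fractions must be non-negative")


def simulate_sec_series(recipe: SECSeriesRecipe) -> list[SAXSCurve]:
    """Noisy frame curves: convex mixtures of cached species Debye curves."""
    q = np.asarray(recipe.q, dtype=float)
    cache: dict = {}
    curves = []
    rng_seed = recipe.noise.seed
    for i, frame in enumerate(recipe.frames):
        total = np.zeros_like(q)
        for spec, frac in frame:
            key = (spec.subunit.kind, spec.n_subunits, spec.lateral_copies)
            if key not in cache:
                model = build_fibre_beads(spec)
                cache[key] = debye_intensity(model, q, dr=recipe.debye_dr).I
            total = total + frac * cache[key]
        noise_i = NoiseModel(recipe.noise.relative_sd, recipe.noise.floor_sd, rng_seed + i)
        curves.append(simulate_saxs(SAXSCurve(q, total), noise_i))
    return curves


def default_elution_sweep(
    q: np.ndarray | None = None, seed: int = 0, relative_sd: float = 0.02
) -> SECSeriesRecipe:
    """A four-frame sweep from long thin 2:2 fibres to the single 4:4 particle.

    Frame compositions move from a pure four-subunit 2:2 fibre (65 nm)
    through mixtures with progressively shorter dominant species to the pure
    single 4:4 subunit (20 nm) — the direction of a size-exclusion elution
    of a self-assembling rod system.
    """
    if q is None:
        q = np.geomspace(0.0015, 0.25, 200)
    rule = AssemblyRule()
    s22 = lambda n: FibreModelSpec(TWO_TWO, n_subunits=n, rule=rule)
    s44 = lambda n: FibreModelSpec(FOUR_FOUR, n_subunits=n, rule=rule)
    frames = (
        ((s22(4), 1.0),),
        ((s22(3), 0.6), (s44(1), 0.4)),
        ((s22(2), 0.3), (s44(1), 0.7)),
        ((s44(1), 1.0),),
    )
    noise = NoiseModel(relative_sd=relative_sd, seed=seed)
    return SECSeriesRecipe(frames=frames, q=q, noise=noise)
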