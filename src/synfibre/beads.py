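"""Coarse-grained bead models of subunits and fibres.

Subunits are represented as rods of rectangular cross-section (width x
thickness) filled with equal-weight beads on a regular grid — a deliberate
coarse-graining of the true molecular envelope that is sufficient for
forward scattering and maximum-dimension arithmetic.  Coordinates are
right-handed with the fibre axis along +z; lengths are nm internally and
Å in PDB output (1 nm = 10 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .assembly import AssemblyRule, SubunitSpec, predict_fibre_length

DEFAULT_BEAD_RADIUS = 0.25  # nm; fine enough for Debye convergence at q <= 0.4 1/A


@dataclass
class BeadModel:
    """Bead coordinates (nm), radii (nm) and scattering weights."""

    coords: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)
    weights: np.ndarray  # (N,)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.coords.shape[0] < 1 or self.coords.shape[1] != 3:
            raise ValueError("a bead model needs at least one (x, y, z) bead")
        if len(self.radii) != len(self.coords) or len(self.weights) != len(self.coords):
            raise ValueError("radii and weights must match the bead count")
        if np.any(self.radii <= 0) or np.any(self.weights <= 0):
            raise ValueError("bead radii and weights must be positive")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FibreModelSpec:
    """A fibre: n_subunits end-to-end copies, optionally replicated laterally."""

    subunit: SubunitSpec
    n_subunits: int = 1
    lateral_copies: int = 1
    rule: AssemblyRule = field(default_factory=AssemblyRule)

    def __post_init__(self) -> None:
        if self.n_subunits < 1 or self.lateral_copies < 1:
            raise ValueError("n_subunits and lateral_copies must be >= 1")


def _axis_centres(extent: float, spacing: float) -> np.ndarray:
    n = max(1, int(round(extent / spacing)))
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def _rod_grid(length: float, width: float, thickness: float, radius: float) -> np.ndarray:
    spacing = 2.0 * radius
    xs = _axis_centres(width, spacing)
    ys = _axis_centres(thickness, spacing)
    zs = _axis_centres(length, spacing)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def build_subunit_beads(
    spec: SubunitSpec,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    use_extended: bool = False,
) -> BeadModel:
    """Fill one subunit rod with beads on a grid of spacing 2*bead_radius."""
    if bead_radius <= 0:
        raise ValueError("bead_radius must be positive")
    if bead_radius > min(spec.width, spec.thickness) / 2.0:
        raise ValueError("bead_radius must not exceed half the cross-section")
    length = spec.extended_length if use_extended else spec.core_length
    coords = _rod_grid(length, spec.width, spec.thickness, bead_radius)
    n = len(coords)
    return BeadModel(
        coords,
        np.full(n, bead_radius),
        np.ones(n),
        label=f"{spec.kind.value} subunit ({length:g} nm)",
    )


def build_fibre_beads(
    spec: FibreModelSpec, bead_radius: float = DEFAULT_BEAD_RADIUS
) -> BeadModel:
    """End-to-end (and optionally lateral) fibre of subunit rods.

    Each subunit is a rod of the rule's initial length placed at axial
    offsets 0, increment, 2*increment, ...; consecutive rods therefore
    overlap by (initial_length - increment) at the junctions and duplicate
    grid sites are merged so the junction is not artificially dense.  The
    total axial extent equals ``predict_fibre_length(n_subunits)``.
    """
    if bead_radius <= 0:
        raise ValueError("bead_radius must be positive")
    sub = spec.subunit
    rule = spec.rule
    if bead_radius > min(sub.width, sub.thickness) / 2.0:
        raise ValueError("bead_radius must not exceed half the cross-section")
    spacing = 2.0 * bead_radius
    base = _rod_grid(rule.initial_length, sub.width, sub.thickness, bead_radius)
    pieces = []
    for i in range(spec.n_subunits):
        shift = np.array([0.0, 0.0, i * rule.increment])
        for k in range(spec.lateral_copies):
            lat = np.array([k * rule.lateral_spacing, 0.0, 0.0])
            pieces.append(base + shift + lat)
    coords = np.vstack(pieces)
    # merge duplicate grid sites (axial offsets need not be grid-commensurate,
    # so round to a fine fraction of the spacing)
    keys = np.round(coords / (spacing / 2.0)).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    coords = coords[np.sort(idx)]
    n = len(coords)
    label = (
        f"{sub.kind.value} fibre n={spec.n_subunits}"
        + (f" x{spec.lateral_copies} lateral" if spec.lateral_copies > 1 else "")
    )
    return BeadModel(coords, np.full(n, bead_radius), np.ones(n), label=label)


def model_dmax(model: BeadModel) -> float:
    """Maximum particle dimension (nm): max centre-centre distance + bead diameter."""
    if len(model) == 1:
        return 2.0 * float(model.radii[0])
    d = pdist(model.coords)
    return float(d.max() + 2.0 * model.radii.max())


# ---------------------------------------------------------------------------
# fixed-column PDB plumbing for bead models (dummy-atom records; weight is
# stored in the occupancy field and the bead radius, in Å, in the B column)

def write_beads_pdb(model: BeadModel, path) -> None:
    lines = [f"REMARK   bead model: {model.label}\n"]
    for i, (xyz, r, w) in enumerate(zip(model.coords, model.radii, model.weights), 1):
        x, y, z = xyz * 10.0  # nm -> A
        lines.append(
            f"HETATM{i % 100000:5d}  C   BEA A{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{w:6.2f}{r * 10.0:6.2f}           C\n"
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_beads_pdb(path) -> BeadModel:
    coords, radii, weights = [], [], []
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK   bead model:"):
                label = line.split(":", 1)[1].strip()
            elif line.startswith(("HETATM", "ATOM  ")):
                coords.append(
                    (
                        float(line[30:38]) / 10.0,
                        float(line[38:46]) / 10.0,
                        float(line[46:54]) / 10.0,
                    )
                )
                weights.append(float(line[54:60]))
                radii.append(float(line[60:66]) / 10.0)
    if not coords:
        raise ValueError(f"no atom records found in {path}")
    return BeadModel(np.array(coords), np.array(radii), np.array(weights), label=label)
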