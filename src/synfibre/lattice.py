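"""Unit-cell d-spacings and fibre-diffraction helpers.

The fibrous crystal lattice of the 4:4 assembly has a long-axis translation
of 156 Å (the end-to-end repeat) and lateral repeats near 5 nm; its
diffraction shows the k-m-e-f signature of alpha-fibrous proteins
(~5.1 Å meridional arc from the supercoiled helical repeat, ~12 Å
equatorial reflections from inter-helix spacings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell axes must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")


#: published cells of the two crystal forms (Å, degrees)
CELL_2TO2 = UnitCell(88.52, 24.19, 88.48, 90.0, 115.737, 90.0, label="2:2 form, P21")
CELL_4TO4 = UnitCell(42.67, 59.68, 156.49, label="4:4 form, P21212")


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Direct-space metric tensor G (Å^2)."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    a, b, c = cell.a, cell.b, cell.c
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


def dspacing(cell: UnitCell, h: int, k: int, l: int) -> float:
    """d-spacing (Å) of reflection (h, k, l) from the triclinic metric.

    1/d^2 = h^T G* h with G* the reciprocal metric (inverse of the direct
    metric tensor); orthorhombic and monoclinic cells are special cases.
    """
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(0,0,0) has no d-spacing")
    hkl = np.array([h, k, l], dtype=float)
    g_star = np.linalg.inv(metric_tensor(cell))
    inv_d2 = float(hkl @ g_star @ hkl)
    return 1.0 / math.sqrt(inv_d2)


def kmef_meridional(helix_pitch: float, tilt: float = 0.0) -> float:
    """Axial period (Å) projected by a supercoiled helical repeat.

    A coiled-coil helix of axial ``helix_pitch`` per turn tilted by
    ``tilt`` degrees from the fibre axis projects a meridional spacing of
    pitch * cos(tilt) — e.g. 5.4 Å at ~19 degrees gives the 5.1 Å arc
    typical of alpha-fibrous (k-m-e-f) proteins.
    """
    if helix_pitch <= 0:
        raise ValueError("pitch must be positive")
    if not 0.0 <= tilt < 90.0:
        raise ValueError("tilt must be within [0, 90) degrees")
    return helix_pitch * math.cos(math.radians(tilt))


def lattice_repeats(cell: UnitCell, long_axis: str = "c") -> tuple[float, list[float]]:
    """(longitudinal repeat nm, lateral repeats nm) of a fibrous lattice."""
    axes = {"a": cell.a, "b": cell.b, "c": cell.c}
    if long_axis not in axes:
        raise ValueError("long_axis must be one of 'a', 'b', 'c'")
    longitudinal = axes.pop(long_axis) / 10.0
    lateral = [v / 10.0 for v in axes.values()]
    return longitudinal, lateral
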