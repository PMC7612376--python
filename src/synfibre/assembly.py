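"""Hierarchical assembly model for SYCE2-TEX12-like coiled-coil fibres.

The synaptonemal complex (SC) central element is built on SYCE2-TEX12, which
assembles hierarchically: obligate 2:2 coiled-coil building blocks tessellate
laterally into 4:4 complexes, which associate end-to-end into 2-nm and 4-nm
fibres of discrete lengths; 4-nm fibres thicken laterally into 10-nm fibres
that intertwine within bundles of up to 40 nm.  This module encodes that
taxonomy quantitatively: the calibrated subunit dimensions, the discrete
fibre-length rule (an initial subunit length plus an integer number of
repeat increments), the width classes, a mass-per-length model for the
assembled SC, and the heptad-register logic used to classify the interface
residues that drive assembly.

Lengths are nanometres unless a name says otherwise; residue indices are
1-based as in the human SYCE2/TEX12 numbering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from scipy.constants import atomic_mass

#: grams per dalton (unified atomic mass constant)
DALTON_G = atomic_mass * 1e3

HEPTAD_LETTERS = "abcdefg"
#: heptad positions forming the hydrophobic core of a canonical coiled-coil
CORE_POSITIONS = frozenset("ad")

# Interface residue sets of the assembly motifs (TEX12 C-terminal tip and
# the SYCE2 C-terminal helix), 1-based residue indices.
LFIL_RESIDUES = (110, 114, 117, 121)   # TEX12 Ctip hydrophobic core
FFV_RESIDUES = (102, 109, 116)         # TEX12 Ctip solvent-exposed surface
S2C_CORE_RESIDUES = (149, 153, 156, 160)  # SYCE2 C-terminal hydrophobic core
#: SYCE2 S2C motif boundaries as annotated (amino acids 155-165).  Note that
#: the hydrophobic-core set above partly precedes this window; both are kept
#: verbatim and the discrepancy is not resolved here.
S2C_RANGE = (155, 165)


class SubunitKind(enum.Enum):
    TWO_TWO = "2:2"
    FOUR_FOUR = "4:4"


@dataclass(frozen=True)
class SubunitSpec:
    """Calibrated dimensions of a 2:2 or 4:4 building block.

    ``core_length`` is the folded-core rod length; ``extended_length`` the
    length once the C-terminal helices are appended.  ``width`` doubles from
    the 2:2 to the 4:4 because the latter is two laterally tessellated 2:2
    complexes of the same length.
    """

    kind: SubunitKind
    core_length: float = 14.0
    extended_length: float = 19.0
    width: float = 2.0
    thickness: float = 2.0
    chain_stoichiometry: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.core_length > self.extended_length:
            raise ValueError("core_length must not exceed extended_length")
        if self.width <= 0 or self.thickness <= 0:
            raise ValueError("width and thickness must be positive")
        if any(c < 0 for c in self.chain_stoichiometry):
            raise ValueError("chain stoichiometry must be non-negative")


TWO_TWO = SubunitSpec(kind=SubunitKind.TWO_TWO)
FOUR_FOUR = SubunitSpec(
    kind=SubunitKind.FOUR_FOUR, width=4.0, chain_stoichiometry=(4, 4)
)


def subunit_for(kind: SubunitKind) -> SubunitSpec:
    return TWO_TWO if kind is SubunitKind.TWO_TWO else FOUR_FOUR


@dataclass(frozen=True)
class AssemblyRule:
    """End-to-end / lateral assembly constants of the fibre lattice.

    ``initial_length`` is the length of a single (C-terminally extended plus
    terminal bundle) subunit; each further subunit overlaps the previous one
    at the end-to-end junction and adds ``increment``.  The crystallographic
    translation along the fibre axis is 156 Å, which the length arithmetic
    uses rounded to 15 nm; both values are exposed, deliberately
    unreconciled (they agree to the nearest nanometre).
    """

    initial_length: float = 20.0
    increment: float = 15.0
    lattice_translation: float = 156.0  # Å
    lateral_spacing: float = 5.0
    ten_nm_fibre_nominal: float = 10.0
    bundle_max: float = 40.0

    def __post_init__(self) -> None:
        if self.increment <= 0 or self.initial_length <= 0:
            raise ValueError("lengths must be positive")
        if self.increment > self.initial_length:
            raise ValueError("increment must not exceed initial_length")
        if abs(self.lattice_translation / 10.0 - self.increment) >= 1.0:
            raise ValueError(
                "lattice_translation (Å) must agree with increment (nm) "
                "to the nearest nanometre"
            )


@dataclass(frozen=True)
class WidthClass:
    label: str
    nominal: float
    lower: float
    upper: float


@dataclass(frozen=True)
class WidthTaxonomy:
    """Ordered width classes with non-overlapping ascending [lower, upper) bounds.

    Nominal widths follow the hierarchy (2, 4, 10, up-to-40 nm); the class
    boundaries are a design choice (geometric midpoints between nominal
    widths) because only population means, not gates, are published.
    """

    classes: tuple[WidthClass, ...] = (
        WidthClass("2:2-fibre", 2.0, 0.0, 3.0),
        WidthClass("4:4-fibre", 4.0, 3.0, 7.0),
        WidthClass("10-nm fibre", 10.0, 7.0, 20.0),
        WidthClass("bundled fibre", 40.0, 20.0, 40.0),
    )

    def __post_init__(self) -> None:
        prev_upper = 0.0
        prev_nominal = 0.0
        for i, c in enumerate(self.classes):
            if c.lower >= c.upper:
                raise ValueError(f"class {c.label}: lower must be < upper")
            if i and c.lower < prev_upper:
                raise ValueError("width class bounds must be non-overlapping")
            if c.nominal <= prev_nominal:
                raise ValueError("nominal widths must be ascending")
            prev_upper, prev_nominal = c.upper, c.nominal


UNASSIGNED = "UNASSIGNED"


def predict_fibre_length(n: int, rule: AssemblyRule | None = None) -> float:
    """Length (nm) of an end-to-end fibre of ``n`` subunits.

    A single subunit measures ``rule.initial_length``; every additional
    subunit adds one ``rule.increment`` (subunits overlap at the terminal
    bundles, so the increment is shorter than the subunit itself).
    """
    rule = rule or AssemblyRule()
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
        raise ValueError("subunit count n must be an integer >= 1")
    return rule.initial_length + rule.increment * (n - 1)


def enumerate_allowed_lengths(
    rule: AssemblyRule | None = None, n_max: int = 4
) -> list[float]:
    """The discrete fibre lengths for 1..n_max subunits (strictly increasing)."""
    rule = rule or AssemblyRule()
    if not isinstance(n_max, int) or isinstance(n_max, bool) or n_max < 1:
        raise ValueError("n_max must be an integer >= 1")
    return [predict_fibre_length(n, rule) for n in range(1, n_max + 1)]


def classify_fibre_width(width: float, taxonomy: WidthTaxonomy | None = None) -> str:
    """Assign a measured fibre width (nm) to its taxonomy class.

    Intervals are [lower, upper); the final (bundle) class additionally
    accepts its upper bound since bundles run *up to* that width.
    Returns ``UNASSIGNED`` when no class contains the width.
    """
    taxonomy = taxonomy or WidthTaxonomy()
    if width <= 0:
        raise ValueError("width must be positive")
    last = taxonomy.classes[-1]
    for c in taxonomy.classes:
        if c.lower <= width < c.upper:
            return c.label
    if width == last.upper:
        return last.label
    return UNASSIGNED


@dataclass(frozen=True)
class MassModel:
    """Mass-per-length model of the assembled SC.

    The SC is approximated as a square prism of ``cross_section_side`` nm
    sides containing protein of ``protein_density`` at a solvent (void)
    fraction ``solvent_fraction``.
    """

    cross_section_side: float = 100.0  # nm
    solvent_fraction: float = 0.5
    protein_density: float = 1.33  # g/cm^3

    def __post_init__(self) -> None:
        if self.cross_section_side <= 0 or self.protein_density <= 0:
            raise ValueError("side and density must be positive")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError("solvent_fraction must be within [0, 1]")


def sc_mass_per_micron(model: MassModel | None = None) -> float:
    """Dry protein mass per micrometre of SC length, in GDa/μm."""
    model = model or MassModel()
    volume_nm3 = model.cross_section_side**2 * 1000.0  # 1 μm slab
    grams = volume_nm3 * 1e-21 * model.protein_density  # 1 nm^3 = 1e-21 cm^3
    daltons = grams * (1.0 - model.solvent_fraction) / DALTON_G
    return daltons / 1e9


def sc_total_mass(model: MassModel | None = None, length_um: float = 1.0) -> float:
    """Total SC mass (GDa) for a chromosome axis of ``length_um`` micrometres."""
    if length_um <= 0:
        raise ValueError("length must be positive")
    return sc_mass_per_micron(model) * length_um


@dataclass(frozen=True)
class HeptadAssignment:
    """Heptad-register map: residue index -> position letter a-g.

    Positions a and d form the hydrophobic core of a canonical coiled-coil;
    only that {a, d} core property is semantically load-bearing here — the
    absolute letter labels depend on the register convention
    (letter = HEPTAD_LETTERS[(index + offset) % 7]).
    """

    register_offset: int
    positions: dict[int, str] = field(default_factory=dict)

    def core_flag(self, index: int) -> bool:
        return self.positions[index] in CORE_POSITIONS

    def records(self) -> list[tuple[int, str, bool]]:
        return [(i, p, p in CORE_POSITIONS) for i, p in sorted(self.positions.items())]


def _letters_for(indices, offset: int) -> dict[int, str]:
    return {i: HEPTAD_LETTERS[(i + offset) % 7] for i in indices}


def heptad_register(residue_indices, offset: int | None = None) -> HeptadAssignment:
    """Assign heptad positions to residues.

    With an explicit ``offset`` (0-6) the letters follow
    ``(index + offset) mod 7``.  Without one, the offset maximising the
    number of supplied residues landing on core positions {a, d} is chosen
    (ties broken toward the smallest offset) — the register search used to
    decide whether a motif is core-compatible.
    """
    indices = list(residue_indices)
    if not indices:
        raise ValueError("residue index list must be non-empty")
    if offset is not None:
        if not 0 <= offset <= 6:
            raise ValueError("offset must be within 0..6")
        return HeptadAssignment(offset, _letters_for(indices, offset))
    best_offset, best_count = 0, -1
    for cand in range(7):
        count = sum(
            1 for letter in _letters_for(indices, cand).values()
            if letter in CORE_POSITIONS
        )
        if count > best_count:
            best_offset, best_count = cand, count
    return HeptadAssignment(best_offset, _letters_for(indices, best_offset))


def classify_interface_residues(assignment: HeptadAssignment, indices):
    """Per-residue (index, position letter, core flag) records.

    Raises ``KeyError`` for residues absent from the assignment.
    """
    out = []
    for i in indices:
        if i not in assignment.positions:
            raise KeyError(f"residue {i} not present in the heptad assignment")
        letter = assignment.positions[i]
        out.append((i, letter, letter in CORE_POSITIONS))
    return out


def congruence_classes(indices) -> set[int]:
    """Distinct residue classes modulo 7 (register-independent)."""
    return {i % 7 for i in indices}
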