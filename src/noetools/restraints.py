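"""NOE, hydrogen-bond, and dihedral restraint model.

Distance restraints carry a lower and an upper bound in Å.  NOE restraints
enter in four intensity classes — strong, medium, weak, very weak — mapped
to the fixed bounds 1.8–2.8, 1.8–3.5, 1.8–5.0 and 1.8–6.0 Å.  Backbone
hydrogen bonds contribute two restraints per bond: H/O at 1.7–2.5 Å and
N/O at 2.7–3.5 Å.  Backbone φ/ψ restraints derived from chemical-shift
(TALOS-style) predictions use a half-width of max(20°, 1.5·sd).

Wildcard atom patterns (``HD1*``, ``HM*``) stand in for groups of
degenerate protons (pseudoatoms); their multiplicity is resolved at
evaluation time by r⁻⁶ averaging in :mod:`noetools.geometry`, not by bound
corrections here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSelector",
    "IntensityClass",
    "DistanceRestraint",
    "DihedralRestraint",
    "TalosRecord",
    "RestraintCategory",
    "RestraintSet",
    "RestraintParseError",
    "INTENSITY_BOUNDS",
    "NOE_LOWER_BOUND",
    "HBOND_HO_BOUNDS",
    "HBOND_NO_BOUNDS",
    "classify_intensity",
    "class_for_distance",
    "parse_distance_table",
    "write_distance_table",
    "parse_talos_table",
    "talos_to_dihedrals",
    "make_hbond_restraints",
    "categorize",
    "accounting",
    "totals_from_counts",
    "ONE_TO_THREE",
]

#: One-letter → three-letter residue codes (standard amino acids).
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Universal NOE lower bound (van der Waals contact), Å.
NOE_LOWER_BOUND = 1.8
#: Hydrogen-bond restraint bounds, Å.
HBOND_HO_BOUNDS = (1.7, 2.5)
HBOND_NO_BOUNDS = (2.7, 3.5)


class RestraintParseError(ValueError):
    """Raised for malformed restraint-table input (carries the row number)."""


class IntensityClass(str, Enum):
    strong = "strong"
    medium = "medium"
    weak = "weak"
    very_weak = "very_weak"
    unset = "unset"


#: NOE intensity class → (lower, upper) bounds in Å.
INTENSITY_BOUNDS: dict[IntensityClass, tuple[float, float]] = {
    IntensityClass.strong: (1.8, 2.8),
    IntensityClass.medium: (1.8, 3.5),
    IntensityClass.weak: (1.8, 5.0),
    IntensityClass.very_weak: (1.8, 6.0),
}


class RestraintCategory(str, Enum):
    intra_residue = "intra_residue"
    sequential = "sequential"
    medium_range = "medium_range"
    long_range = "long_range"
    intermolecular = "intermolecular"
    hydrogen_bond = "hydrogen_bond"


#: The five NOE categories counted into the NOE total.
NOE_CATEGORIES = (
    RestraintCategory.intra_residue,
    RestraintCategory.sequential,
    RestraintCategory.medium_range,
    RestraintCategory.long_range,
    RestraintCategory.intermolecular,
)


@dataclass(frozen=True)
class AtomSelector:
    """Chain/residue-qualified atom name or trailing-wildcard pattern."""

    chain_id: str
    residue_number: int
    atom_pattern: str
    residue_name: str | None = None

    def __post_init__(self) -> None:
        if not self.atom_pattern:
            raise ValueError("empty atom pattern")
        stars = self.atom_pattern.count("*")
        if stars > 1 or (stars == 1 and not self.atom_pattern.endswith("*")):
            raise ValueError(
                f"at most one terminal wildcard allowed: {self.atom_pattern!r}"
            )
        if self.residue_number < 1:
            raise ValueError("residue numbers are 1-based")

    def __str__(self) -> str:  # pragma: no cover - repr aid
        rn = self.residue_name or "?"
        return f"{self.chain_id}:{rn}{self.residue_number}:{self.atom_pattern}"


@dataclass(frozen=True)
class DistanceRestraint:
    selector_i: AtomSelector
    selector_j: AtomSelector
    lower_bound: float
    upper_bound: float
    origin: Literal["noe", "hbond"] = "noe"
    intensity_class: IntensityClass = IntensityClass.unset

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_bound < self.upper_bound):
            raise ValueError(
                f"bounds must satisfy 0 < lower < upper, got "
                f"({self.lower_bound}, {self.upper_bound})"
            )


@dataclass(frozen=True)
class DihedralRestraint:
    selectors: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]
    target_deg: float
    half_width_deg: float
    angle_name: Literal["phi", "psi", "other"] = "other"

    def __post_init__(self) -> None:
        if not (-180.0 < self.target_deg <= 180.0):
            raise ValueError("target angle must lie in (-180, 180]")
        if self.half_width_deg <= 0:
            raise ValueError("half width must be positive")


@dataclass(frozen=True)
class TalosRecord:
    """One residue's chemical-shift-based φ/ψ prediction."""

    residue_number: int
    phi_deg: float
    psi_deg: float
    phi_sd_deg: float
    psi_sd_deg: float
    usable: bool = True

    def __post_init__(self) -> None:
        for a in (self.phi_deg, self.psi_deg):
            if not (-180.0 < a <= 180.0):
                raise ValueError("angles must lie in (-180, 180]")
        if self.phi_sd_deg < 0 or self.psi_sd_deg < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class RestraintSet:
    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    dihedral_restraints: list[DihedralRestraint] = field(default_factory=list)
    provenance: str = ""
    category_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.distance_restraints) + len(self.dihedral_restraints)


# ---------------------------------------------------------------------------
# Intensity classes
# ---------------------------------------------------------------------------

def classify_intensity(intensity: IntensityClass | str) -> tuple[float, float]:
    """Bounds (lower, upper) in Å for an NOE intensity class."""
    try:
        cls = IntensityClass(intensity)
        return INTENSITY_BOUNDS[cls]
    except (ValueError, KeyError):
        raise ValueError(f"unknown intensity class: {intensity!r}") from None


def class_for_distance(distance: float) -> IntensityClass:
    """Tightest intensity class whose upper bound covers ``distance``."""
    for cls in (
        IntensityClass.strong,
        IntensityClass.medium,
        IntensityClass.weak,
        IntensityClass.very_weak,
    ):
        if distance <= INTENSITY_BOUNDS[cls][1]:
            return cls
    raise ValueError(f"distance {distance:.2f} Å exceeds the very-weak bound 6.0 Å")


# ---------------------------------------------------------------------------
# Distance-table parsing and writing
# ---------------------------------------------------------------------------

_RESIDUE_TOKEN = re.compile(r"^([A-Z])(\d+)$")

# Single supported CNS-style assign statement:
#   assign (segid A and resid 71 and name HE*) (segid L and resid 1 and name HM*) 3.15 1.35 1.35
_CNS_SEL = (
    r"\(\s*segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)"
)
_CNS_ASSIGN = re.compile(
    r"^assign\s*" + _CNS_SEL + r"\s*" + _CNS_SEL +
    r"\s+([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)\s*$",
    re.IGNORECASE,
)


def parse_distance_table(
    text: str,
    dialect: Literal["tsv_simple", "cns_tbl"] = "tsv_simple",
    protein_chain: str = "A",
    ligand_chain: str = "L",
    ligand_residue: int = 1,
    methyl_bonus: float = 0.0,
) -> RestraintSet:
    """Parse a distance-restraint table.

    ``tsv_simple``: whitespace/tab separated columns
    ``residue_token protein_hydrogen ligand_hydrogen upper_Å`` with ``#``
    comments, e.g. ``F71  HE*  HM*  4.5``; the residue-token letter is the
    one-letter residue code, checked for consistency; the lower bound is
    the 1.8 Å NOE floor.

    ``cns_tbl``: ``assign (segid/resid/name ...) (...) d dminus dplus``
    statements; bounds reconstructed as (d − dminus, d + dplus).

    ``methyl_bonus`` (Å) widens the upper bound of restraints with a
    pseudoatom (wildcard) on either side, for protocols that scale
    methyl-involving NOEs separately; published bound tables normally
    fold such corrections in already, hence the 0 default.
    """
    restraints: list[DistanceRestraint] = []
    rows = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if dialect == "tsv_simple":
            parts = line.split()
            if len(parts) != 4:
                raise RestraintParseError(
                    f"row {lineno}: expected 4 columns, got {len(parts)}"
                )
            token, prot_h, lig_h, upper_txt = parts
            m = _RESIDUE_TOKEN.match(token)
            if not m:
                raise RestraintParseError(
                    f"row {lineno}: bad residue token {token!r}"
                )
            letter, resnum = m.group(1), int(m.group(2))
            resname = ONE_TO_THREE.get(letter)
            if resname is None:
                raise RestraintParseError(
                    f"row {lineno}: unknown residue letter {letter!r}"
                )
            try:
                upper = float(upper_txt)
            except ValueError:
                raise RestraintParseError(
                    f"row {lineno}: bad upper bound {upper_txt!r}"
                ) from None
            if upper <= NOE_LOWER_BOUND:
                raise RestraintParseError(
                    f"row {lineno}: upper bound {upper} ≤ {NOE_LOWER_BOUND}"
                )
            restraints.append(
                DistanceRestraint(
                    selector_i=AtomSelector(
                        protein_chain, resnum, prot_h, residue_name=resname
                    ),
                    selector_j=AtomSelector(ligand_chain, ligand_residue, lig_h),
                    lower_bound=NOE_LOWER_BOUND,
                    upper_bound=upper,
                )
            )
        elif dialect == "cns_tbl":
            m = _CNS_ASSIGN.match(line)
            if m is None:
                raise RestraintParseError(
                    f"row {lineno}: unsupported assign statement"
                )
            seg_i, res_i, name_i, seg_j, res_j, name_j, d, dminus, dplus = m.groups()
            d, dminus, dplus = float(d), float(dminus), float(dplus)
            lower, upper = d - dminus, d + dplus
            if not (0 < lower < upper):
                raise RestraintParseError(
                    f"row {lineno}: reconstructed bounds ({lower}, {upper}) invalid"
                )
            restraints.append(
                DistanceRestraint(
                    selector_i=AtomSelector(seg_i, int(res_i), name_i),
                    selector_j=AtomSelector(seg_j, int(res_j), name_j),
                    lower_bound=lower,
                    upper_bound=upper,
                )
            )
        else:
            raise ValueError(f"unsupported dialect: {dialect!r}")
        rows += 1
    if methyl_bonus:
        restraints = [
            replace(r, upper_bound=r.upper_bound + methyl_bonus)
            if (r.selector_i.atom_pattern.endswith("*")
                or r.selector_j.atom_pattern.endswith("*"))
            else r
            for r in restraints
        ]
    return RestraintSet(
        distance_restraints=restraints,
        provenance=f"parsed {rows} rows ({dialect})",
    )


def write_distance_table(
    rset: RestraintSet,
    dialect: Literal["tsv_simple", "cns_tbl"] = "tsv_simple",
) -> str:
    """Serialize distance restraints in a parseable dialect (round-trip safe)."""
    lines: list[str] = []
    if dialect == "tsv_simple":
        lines.append("# residue_token protein_hydrogen ligand_hydrogen upper_A")
        for r in rset.distance_restraints:
            letter = THREE_TO_ONE.get(r.selector_i.residue_name or "", "X")
            lines.append(
                f"{letter}{r.selector_i.residue_number}\t"
                f"{r.selector_i.atom_pattern}\t{r.selector_j.atom_pattern}\t"
                f"{r.upper_bound:g}"
            )
    elif dialect == "cns_tbl":
        for r in rset.distance_restraints:
            d = (r.lower_bound + r.upper_bound) / 2.0
            half = (r.upper_bound - r.lower_bound) / 2.0
            lines.append(
                f"assign (segid {r.selector_i.chain_id} and resid "
                f"{r.selector_i.residue_number} and name {r.selector_i.atom_pattern}) "
                f"(segid {r.selector_j.chain_id} and resid "
                f"{r.selector_j.residue_number} and name {r.selector_j.atom_pattern}) "
                f"{d:.3f} {half:.3f} {half:.3f}"
            )
    else:
        raise ValueError(f"unsupported dialect: {dialect!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# TALOS-style dihedral restraints
# ---------------------------------------------------------------------------

def parse_talos_table(text: str) -> list[TalosRecord]:
    """Parse a whitespace table ``RESID PHI PSI DPHI DPSI CLASS``.

    ``CLASS`` values of ``Good``/``Strong`` (case-insensitive) are usable;
    anything else marks the record unusable.
    """
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.upper().startswith(("RESID", "FORMAT", "VARS", "DATA")):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise RestraintParseError(
                f"row {lineno}: expected 6 columns, got {len(parts)}"
            )
        records.append(
            TalosRecord(
                residue_number=int(parts[0]),
                phi_deg=float(parts[1]),
                psi_deg=float(parts[2]),
                phi_sd_deg=float(parts[3]),
                psi_sd_deg=float(parts[4]),
                usable=parts[5].lower() in ("good", "strong"),
            )
        )
    return records


def talos_to_dihedrals(
    records: Sequence[TalosRecord],
    chain_id: str = "A",
    first_residue: int | None = None,
    last_residue: int | None = None,
    min_half_width: float = 20.0,
    sd_factor: float = 1.5,
) -> list[DihedralRestraint]:
    """Convert φ/ψ predictions into restraints with half-width
    max(min_half_width, sd_factor·sd).

    ``first_residue``/``last_residue`` give the chain termini so that a φ
    restraint at the first residue (no preceding C′) or a ψ restraint at
    the last (no following N) is skipped with a logged reason.  Unusable
    records emit nothing.
    """
    if first_residue is None:
        first_residue = min((r.residue_number for r in records), default=1)
    if last_residue is None:
        last_residue = max((r.residue_number for r in records), default=1)
    out: list[DihedralRestraint] = []
    for rec in records:
        if not rec.usable:
            continue
        i = rec.residue_number
        if i > first_residue:
            out.append(
                DihedralRestraint(
                    selectors=(
                        AtomSelector(chain_id, i - 1, "C"),
                        AtomSelector(chain_id, i, "N"),
                        AtomSelector(chain_id, i, "CA"),
                        AtomSelector(chain_id, i, "C"),
                    ),
                    target_deg=rec.phi_deg,
                    half_width_deg=max(min_half_width, sd_factor * rec.phi_sd_deg),
                    angle_name="phi",
                )
            )
        else:
            logger.info("skipping phi restraint at N-terminal residue %d", i)
        if i < last_residue:
            out.append(
                DihedralRestraint(
                    selectors=(
                        AtomSelector(chain_id, i, "N"),
                        AtomSelector(chain_id, i, "CA"),
                        AtomSelector(chain_id, i, "C"),
                        AtomSelector(chain_id, i + 1, "N"),
                    ),
                    target_deg=rec.psi_deg,
                    half_width_deg=max(min_half_width, sd_factor * rec.psi_sd_deg),
                    angle_name="psi",
                )
            )
        else:
            logger.info("skipping psi restraint at C-terminal residue %d", i)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def make_hbond_restraints(
    pairs: Iterable[tuple[AtomSelector, AtomSelector, AtomSelector]],
) -> list[DistanceRestraint]:
    """Two restraints per (N, H, O) donor/acceptor triple:
    H/O at 1.7–2.5 Å and N/O at 2.7–3.5 Å."""
    out = []
    for n_sel, h_sel, o_sel in pairs:
        for sel in (n_sel, h_sel, o_sel):
            if sel.atom_pattern.endswith("*"):
                raise ValueError(
                    f"hydrogen-bond selectors must be atom-specific: {sel}"
                )
        out.append(
            DistanceRestraint(
                selector_i=h_sel, selector_j=o_sel,
                lower_bound=HBOND_HO_BOUNDS[0], upper_bound=HBOND_HO_BOUNDS[1],
                origin="hbond",
            )
        )
        out.append(
            DistanceRestraint(
                selector_i=n_sel, selector_j=o_sel,
                lower_bound=HBOND_NO_BOUNDS[0], upper_bound=HBOND_NO_BOUNDS[1],
                origin="hbond",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Categorisation and accounting
# ---------------------------------------------------------------------------

def categorize(restraint: DistanceRestraint, ligand_chain: str) -> RestraintCategory:
    """Assign the structure-statistics category of a distance restraint.

    Hydrogen bonds are their own category; exactly one side on the ligand
    chain is intermolecular; otherwise the sequence separation |i−j|
    decides: 0 intra-residue, 1 sequential, 2–4 medium-range, >4 long-range.
    """
    if restraint.origin == "hbond":
        return RestraintCategory.hydrogen_bond
    on_lig_i = restraint.selector_i.chain_id == ligand_chain
    on_lig_j = restraint.selector_j.chain_id == ligand_chain
    if on_lig_i and on_lig_j:
        raise ValueError("intra-ligand restraints are not categorised")
    if on_lig_i or on_lig_j:
        return RestraintCategory.intermolecular
    sep = abs(restraint.selector_i.residue_number - restraint.selector_j.residue_number)
    if sep == 0:
        return RestraintCategory.intra_residue
    if sep == 1:
        return RestraintCategory.sequential
    if sep <= 4:
        return RestraintCategory.medium_range
    return RestraintCategory.long_range


def accounting(rset: RestraintSet, ligand_chain: str = "L") -> dict[str, int]:
    """Count restraints per category plus the derived totals.

    Returns category counts, ``noe_total`` (the five NOE categories),
    ``inter_residue`` (sequential + medium + long), ``phi``/``psi``/
    ``dihedral_total``, and ``grand_total`` = NOE + dihedral + H-bond.
    """
    counts = {c.value: 0 for c in RestraintCategory}
    for r in rset.distance_restraints:
        counts[categorize(r, ligand_chain).value] += 1
    phi = sum(1 for d in rset.dihedral_restraints if d.angle_name == "phi")
    psi = sum(1 for d in rset.dihedral_restraints if d.angle_name == "psi")
    counts["phi"] = phi
    counts["psi"] = psi
    rset.category_counts = dict(counts)
    counts["dihedral_total"] = len(rset.dihedral_restraints)
    return totals_from_counts(counts)


def totals_from_counts(counts: dict[str, int]) -> dict[str, int]:
    """Derive totals from raw per-category counts (a manifest).

    Accepts the six distance categories plus ``phi``/``psi`` (or a
    pre-summed ``dihedral_total``) and fills in ``noe_total``,
    ``inter_residue``, ``dihedral_total`` and ``grand_total``.
    """
    out = dict(counts)
    for c in RestraintCategory:
        out.setdefault(c.value, 0)
    out["noe_total"] = sum(out[c.value] for c in NOE_CATEGORIES)
    out["inter_residue"] = (
        out["sequential"] + out["medium_range"] + out["long_range"]
    )
    if "dihedral_total" not in out:
        out["dihedral_total"] = out.get("phi", 0) + out.get("psi", 0)
    out["grand_total"] = (
        out["noe_total"] + out["dihedral_total"] + out["hydrogen_bond"]
    )
    return out
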