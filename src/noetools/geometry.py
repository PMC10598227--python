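"""Coordinate-level primitives for restraint evaluation.

Everything downstream (energies, violation reports, ensemble statistics)
reduces to a handful of geometric operations on a :class:`Structure`:

* wildcard atom-selector expansion (pseudoatoms such as ``HD1*``),
* effective interproton distances under the two conventions used for
  ambiguous/pseudoatom restraints — r⁻⁶ averaging and r⁻⁶ summation,
* signed torsion angles (IUPAC convention, cis = 0°),
* a triple-product chirality sign for tetrahedral centers,
* least-squares rigid superposition (Kabsch) and ensemble pairwise RMSD.

Units are Å and degrees throughout; residue numbers are 1-based and
chain-qualified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .restraints import AtomSelector, DihedralRestraint, DistanceRestraint

__all__ = [
    "Structure",
    "Ensemble",
    "ChiralCenter",
    "Selection",
    "BACKBONE_ATOMS",
    "BACKBONE_ATOMS_NO_O",
    "GeometryError",
    "SelectorError",
    "expand_pair",
    "effective_distance",
    "distance_violation",
    "dihedral_angle",
    "dihedral_violation",
    "chirality_sign",
    "superpose",
    "mean_pairwise_rmsd",
    "wrap_angle",
]

#: Default backbone atom set for RMSD selections.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Alternative three-atom backbone definition.
BACKBONE_ATOMS_NO_O = ("N", "CA", "C")

#: Atom-name equivalences across restraint/coordinate dialects
#: (restraint tables often call the amide proton HN; PDB files use H).
EQUIVALENT_NAMES = {"HN": "H", "H": "HN"}

#: |triple product| below this (Å³) is treated as planar/indeterminate.
CHIRALITY_TOLERANCE = 1e-6


class GeometryError(ValueError):
    """Raised for degenerate geometry (coincident atoms, collinearity...)."""


class SelectorError(KeyError):
    """Raised when an atom selector matches no atoms."""


# ---------------------------------------------------------------------------
# Structures and ensembles
# ---------------------------------------------------------------------------

ATOM_COLUMNS = ["chain_id", "residue_number", "residue_name", "atom_name", "element"]


@dataclass
class Structure:
    """A single conformer: an ordered atom table plus Cartesian coordinates.

    ``atoms`` is a DataFrame with columns ``chain_id, residue_number,
    residue_name, atom_name, element`` (one row per atom, file order);
    ``coords`` is the matching (N, 3) float array in Å.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._index: dict[tuple[str, int, str], int] | None = None

    # -- lookup helpers ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _key_index(self) -> dict[tuple[str, int, str], int]:
        if self._index is None:
            keys = zip(
                self.atoms["chain_id"].tolist(),
                self.atoms["residue_number"].tolist(),
                self.atoms["atom_name"].tolist(),
            )
            self._index = {k: i for i, k in enumerate(keys)}
        return self._index

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Index of a uniquely named atom; raises SelectorError if absent."""
        idx = self._key_index().get((chain_id, residue_number, atom_name))
        if idx is None:
            alias = EQUIVALENT_NAMES.get(atom_name)
            if alias is not None:
                idx = self._key_index().get((chain_id, residue_number, alias))
        if idx is None:
            raise SelectorError(
                f"no atom {chain_id}:{residue_number}:{atom_name}"
            )
        return idx

    def select(self, selector: AtomSelector) -> list[int]:
        """All atom indices matched by ``selector``, in file order.

        Exact names match directly (with the HN/H dialect alias); a
        trailing-wildcard pattern like ``HD1*`` prefix-matches within the
        selected residue.
        """
        pattern = selector.atom_pattern
        if not pattern.endswith("*"):
            try:
                return [self.atom_index(selector.chain_id, selector.residue_number, pattern)]
            except SelectorError:
                return []
        prefix = pattern[:-1]
        mask = (
            (self.atoms["chain_id"] == selector.chain_id)
            & (self.atoms["residue_number"] == selector.residue_number)
            & self.atoms["atom_name"].str.startswith(prefix)
        )
        return list(np.flatnonzero(mask.to_numpy()))

    def identity(self) -> list[tuple[str, int, str, str]]:
        """Per-atom identity tuples, used to check ensemble consistency."""
        return list(
            zip(
                self.atoms["chain_id"],
                self.atoms["residue_number"],
                self.atoms["residue_name"],
                self.atoms["atom_name"],
            )
        )

    def copy_with(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        return Structure(
            atoms=self.atoms,
            coords=np.array(coords, dtype=float),
            model_id=self.model_id if model_id is None else model_id,
        )


@dataclass
class Ensemble:
    """An ordered list of conformers sharing one atom-identity sequence."""

    models: list[Structure]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        ref = self.models[0].identity()
        for m in self.models[1:]:
            if m.identity() != ref:
                raise ValueError(
                    f"model {m.model_id} atom identities differ from model "
                    f"{self.models[0].model_id}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> Structure:
        return self.models[i]


@dataclass
class ChiralCenter:
    """A tetrahedral center with four substituents in priority order
    (highest priority first — supplied by the caller, not inferred)."""

    center: AtomSelector
    substituents: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]


@dataclass
class Selection:
    """Residue ranges per chain plus an atom-name filter.

    ``ranges`` maps chain id to a list of inclusive (lo, hi) residue-number
    ranges.  ``atom_names`` restricts to the named atoms (None = all atoms,
    "heavy" = all non-hydrogen atoms).
    """

    ranges: dict[str, list[tuple[int, int]]]
    atom_names: tuple[str, ...] | Literal["heavy"] | None = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        for chain, rngs in self.ranges.items():
            srt = sorted(rngs)
            for (a1, b1), (a2, _) in zip(srt, srt[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping ranges on chain {chain}")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``"A:10-31,47-176@backbone"`` style selection strings."""
        atom_names: tuple[str, ...] | Literal["heavy"] | None = BACKBONE_ATOMS
        if "@" in text:
            text, atom_part = text.split("@", 1)
            if atom_part == "backbone":
                atom_names = BACKBONE_ATOMS
            elif atom_part == "heavy":
                atom_names = "heavy"
            elif atom_part in ("all", "*"):
                atom_names = None
            else:
                atom_names = tuple(atom_part.split("+"))
        ranges: dict[str, list[tuple[int, int]]] = {}
        for chain_block in text.split(";"):
            chain, _, rng_text = chain_block.partition(":")
            rngs = []
            for token in rng_text.split(","):
                lo, _, hi = token.partition("-")
                rngs.append((int(lo), int(hi) if hi else int(lo)))
            ranges[chain] = rngs
        return cls(ranges=ranges, atom_names=atom_names)

    def resolve(self, structure: Structure) -> list[int]:
        """Atom indices covered by this selection, in file order."""
        at = structure.atoms
        res_mask = np.zeros(len(at), dtype=bool)
        for chain, rngs in self.ranges.items():
            cmask = (at["chain_id"] == chain).to_numpy()
            resnum = at["residue_number"].to_numpy()
            for lo, hi in rngs:
                res_mask |= cmask & (resnum >= lo) & (resnum <= hi)
        if self.atom_names is None:
            mask = res_mask
        elif self.atom_names == "heavy":
            mask = res_mask & (at["element"] != "H").to_numpy()
        else:
            mask = res_mask & at["atom_name"].isin(self.atom_names).to_numpy()
        return list(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Selector expansion and effective distances
# ---------------------------------------------------------------------------

def expand_pair(
    sel_i: AtomSelector, sel_j: AtomSelector, structure: Structure
) -> list[tuple[int, int]]:
    """Cartesian product of the atoms matched by two selectors.

    Order is deterministic (file order on each side).  Raises
    :class:`SelectorError` naming the selector if either side matches
    nothing.
    """
    mi = structure.select(sel_i)
    if not mi:
        raise SelectorError(f"selector matches no atoms: {sel_i}")
    mj = structure.select(sel_j)
    if not mj:
        raise SelectorError(f"selector matches no atoms: {sel_j}")
    return list(itertools.product(mi, mj))


def effective_distance(
    pairs: Sequence[tuple[int, int]],
    structure: Structure,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> float:
    """Collapse a pair list into one effective distance.

    ``r6_average`` returns (mean_p d_p⁻⁶)^(−1/6); ``r6_sum`` returns
    (Σ_p d_p⁻⁶)^(−1/6).  For a single pair both equal the plain distance;
    in general r6_sum = N^(−1/6) · r6_average ≤ min_p d_p.
    """
    if not pairs:
        raise ValueError("effective_distance needs at least one pair")
    idx = np.asarray(pairs, dtype=int)
    diff = structure.coords[idx[:, 0]] - structure.coords[idx[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d < 1e-8):
        raise GeometryError("coincident atoms in pair list (d = 0)")
    s = np.sum(d**-6.0)
    if method == "r6_average":
        s /= len(d)
    elif method != "r6_sum":
        raise ValueError(f"unknown averaging method: {method!r}")
    return float(s ** (-1.0 / 6.0))


def distance_violation(
    restraint: DistanceRestraint,
    structure: Structure,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> float:
    """Bound violation in Å: max(0, d_eff − upper, lower − d_eff)."""
    pairs = expand_pair(restraint.selector_i, restraint.selector_j, structure)
    d_eff = effective_distance(pairs, structure, method)
    return max(0.0, d_eff - restraint.upper_bound, restraint.lower_bound - d_eff)


# ---------------------------------------------------------------------------
# Torsions and chirality
# ---------------------------------------------------------------------------

def wrap_angle(deg: float) -> float:
    """Map an angle in degrees to (−180, 180]."""
    d = (deg + 180.0) % 360.0 - 180.0
    if d <= -180.0:
        d += 360.0
    return d


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion in degrees, IUPAC convention (cis = 0°), in (−180, 180].

    Sign is positive for a clockwise rotation of the far bond viewed from
    p2 towards p3; mirroring all four points negates the angle.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or nb2 < 1e-9:
        raise GeometryError("collinear points in dihedral")
    m1 = np.cross(n1, b2 / nb2)
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return wrap_angle(float(ang))


def dihedral_violation(restraint: DihedralRestraint, structure: Structure) -> float:
    """Excess over the allowed band, in degrees (0 inside the band)."""
    pts = []
    for sel in restraint.selectors:
        matches = structure.select(sel)
        if len(matches) != 1:
            raise SelectorError(
                f"dihedral selector must match exactly one atom: {sel}"
            )
        pts.append(structure.coords[matches[0]])
    observed = dihedral_angle(*pts)
    delta = abs(wrap_angle(observed - restraint.target_deg))
    return max(0.0, delta - restraint.half_width_deg)


def chirality_sign(center: ChiralCenter, structure: Structure) -> str:
    """Label a tetrahedral center ``"R_like"`` or ``"S_like"``.

    With substituent positions r1..r4 in caller-supplied priority order
    (highest first), the signed volume t = (r1−r4)·[(r2−r4)×(r3−r4)] is
    evaluated: t < 0 → R_like, t > 0 → S_like.  This is a fixed documented
    convention on user priorities, not CIP inference.  |t| below
    ``CHIRALITY_TOLERANCE`` raises (planar/indeterminate).
    """
    pos = []
    for sel in center.substituents:
        matches = structure.select(sel)
        if len(matches) != 1:
            raise SelectorError(f"chiral substituent not unique: {sel}")
        pos.append(structure.coords[matches[0]])
    r1, r2, r3, r4 = pos
    t = float(np.dot(r1 - r4, np.cross(r2 - r4, r3 - r4)))
    if abs(t) < CHIRALITY_TOLERANCE:
        raise GeometryError("planar/indeterminate chiral center")
    return "S_like" if t > 0 else "R_like"


# ---------------------------------------------------------------------------
# Superposition and ensemble RMSD
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R and translation t with R·p + t ≈ q."""
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: Structure, reference: Structure, selection: Selection
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where the rotation is a
    proper rotation (det +1) and rmsd is the post-fit value over the
    selection.  The selection must resolve to the same ordered atom list in
    both structures.
    """
    mi = selection.resolve(mobile)
    ri = selection.resolve(reference)
    mid = [mobile.identity()[i] for i in mi]
    rid = [reference.identity()[i] for i in ri]
    if mid != rid:
        for a, b in itertools.zip_longest(mid, rid):
            if a != b:
                raise ValueError(f"selection atom mismatch: {a} vs {b}")
    if len(mi) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    P = mobile.coords[mi]
    Q = reference.coords[ri]
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-8) < 2:
        raise GeometryError("selection atoms are collinear")
    return _kabsch(P, Q)


def mean_pairwise_rmsd(ensemble: Ensemble, selection: Selection) -> float:
    """Mean RMSD over all C(M, 2) model pairs, each pair independently
    superposed on the selection (the convention behind "average pairwise
    r.m.s. deviation" ensemble statistics)."""
    if len(ensemble) < 2:
        raise ValueError("pairwise RMSD needs at least 2 models")
    vals = []
    for a, b in itertools.combinations(range(len(ensemble)), 2):
        _, _, rmsd = superpose(ensemble[a], ensemble[b], selection)
        vals.append(rmsd)
    return float(np.mean(vals))
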