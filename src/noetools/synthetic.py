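"""Synthetic complex generator: the fixture behind every downstream test.

Emulates the statistical structure the restraint analysis assumes:

* an ideal α-helical protein fragment (default 30 residues, φ/ψ −57/−47)
  with backbone N/H/CA/HA/C/O, a Cβ per non-glycine residue and a labelled
  pseudo-methyl (Cγ + HG1–3) for methyl-bearing residue types,
* a small rigid chiral toy ligand (six heavy atoms around one tetrahedral
  center; every substituent direction carries protons) docked at known
  contacts on the helix face,
* NOE restraints derived from the true coordinates using the four
  intensity-class bounds (tightest class covering the true effective
  distance; optional noise widens bounds only), helical i→i+4 hydrogen-bond
  restraints, and φ/ψ restraints with a 20° half-width,
* a covalent topology whose equilibrium values are *measured* from the true
  structure, so the truth has exactly zero total energy,
* reproducibly perturbed starting structures.

Restraints whose r⁻⁶-sum effective distance would fall below the 1.8 Å
class floor are not emitted: such a restraint would flag a spurious
short-contact violation under the summing convention, and the generator's
contract is that the truth is violation-free under both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .energy import (
    AngleTerm,
    BondTerm,
    CovalentTopology,
    ImproperTerm,
    mirror_topology,
)
from .geometry import ChiralCenter, Structure, dihedral_angle, effective_distance
from .restraints import (
    NOE_LOWER_BOUND,
    AtomSelector,
    DihedralRestraint,
    DistanceRestraint,
    IntensityClass,
    INTENSITY_BOUNDS,
    ONE_TO_THREE,
    RestraintSet,
    accounting,
    class_for_distance,
    make_hbond_restraints,
)

__all__ = [
    "FixtureConfig",
    "Fixture",
    "make_ideal_helix",
    "make_toy_ligand",
    "derive_restraints",
    "make_fixture",
    "make_screen_problem",
    "DEFAULT_SEQUENCE",
]

#: Default 30-residue fragment: helix-forming, methyl-rich, two glycines.
DEFAULT_SEQUENCE = "ADKLVEAMTRLFGESAVKLMQTIADNLVKG"

#: Residue types carrying a methyl group → get a Cγ pseudo-methyl.
METHYL_TYPES = set("VLITM")

# Backbone internal coordinates (Å, degrees) — standard peptide geometry.
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_B_CA_CB, _B_CB_CG, _B_C_H = 1.530, 1.530, 1.090
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.5
# Torsion offsets of Cβ and Hα from C′ about the N–CA axis (L-configuration).
_CB_TORSION_OFFSET = 122.6
_HA_TORSION_OFFSET = -119.3


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D bonded to c with |cD| = bond, angle(b,c,D) = angle and
    torsion(a,b,c,D) = torsion (natural-extension reference frame)."""
    theta = np.radians(angle_deg)
    chi = -np.radians(torsion_deg)  # frame handedness vs IUPAC sign
    d2 = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d2


def _element_of(name: str) -> str:
    if name.startswith("BR"):
        return "BR"
    return name[0]


class _Builder:
    """Accumulates atom rows + coordinates into a Structure."""

    def __init__(self) -> None:
        self.rows: list[tuple[str, int, str, str, str]] = []
        self.coords: list[np.ndarray] = []

    def add(self, chain: str, resnum: int, resname: str, name: str, pos) -> None:
        self.rows.append((chain, resnum, resname, name, _element_of(name)))
        self.coords.append(np.asarray(pos, dtype=float))

    def build(self, model_id: int = 1) -> Structure:
        atoms = pd.DataFrame(
            self.rows,
            columns=["chain_id", "residue_number", "residue_name", "atom_name", "element"],
        )
        return Structure(atoms=atoms, coords=np.array(self.coords), model_id=model_id)


# ---------------------------------------------------------------------------
# Ideal helix
# ---------------------------------------------------------------------------

def make_ideal_helix(
    sequence: str = DEFAULT_SEQUENCE,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
) -> Structure:
    """Build an ideal α-helical fragment by chained torsions.

    Backbone N/H/CA/HA/C/O per residue; non-glycine residues get a Cβ with
    pseudo-methyl protons (HB1–3 for alanine, HB1–2 otherwise); methyl
    residue types (V/L/I/T/M) additionally get a Cγ pseudo-methyl with
    HG1–3.  The built φ/ψ equal the requested values to well under 0.5°
    (internal-coordinate construction is exact to rounding).
    """
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")

    b = _Builder()
    # dummy residue-0 frame seeding the torsion chain
    prev_n = np.array([0.0, 0.0, 0.0])
    prev_ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    prev_c = prev_ca + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i, letter in enumerate(sequence, start=1):
        resname = ONE_TO_THREE[letter]
        n = nerf_place(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi)
        ca = nerf_place(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, 180.0)
        c = nerf_place(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = nerf_place(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        # amide H in the peptide plane, bisecting away from C′(i−1) and CA
        u = n - prev_c
        v = n - ca
        h = n + _B_N_H * _unit(_unit(u) + _unit(v))
        b.add(chain_id, i, resname, "N", n)
        b.add(chain_id, i, resname, "H", h)
        b.add(chain_id, i, resname, "CA", ca)
        ha = nerf_place(prev_c, n, ca, _B_C_H, 109.0, phi + _HA_TORSION_OFFSET)
        b.add(chain_id, i, resname, "HA", ha)
        if letter != "G":
            cb = nerf_place(prev_c, n, ca, _B_CA_CB, 110.5, phi + _CB_TORSION_OFFSET)
            b.add(chain_id, i, resname, "CB", cb)
            if letter in METHYL_TYPES:
                cg = nerf_place(n, ca, cb, _B_CB_CG, 114.0, 180.0)
                for name, tors in (("HB1", 60.0), ("HB2", -60.0)):
                    b.add(chain_id, i, resname, name,
                          nerf_place(n, ca, cb, _B_C_H, 109.5, tors))
                b.add(chain_id, i, resname, "CG", cg)
                for name, tors in (("HG1", 60.0), ("HG2", -60.0), ("HG3", 180.0)):
                    b.add(chain_id, i, resname, name,
                          nerf_place(ca, cb, cg, _B_C_H, 109.5, tors))
            else:
                hb_torsions = (
                    (("HB1", 60.0), ("HB2", -60.0), ("HB3", 180.0))
                    if letter == "A"
                    else (("HB1", 60.0), ("HB2", -60.0))
                )
                for name, tors in hb_torsions:
                    b.add(chain_id, i, resname, name,
                          nerf_place(n, ca, cb, _B_C_H, 109.5, tors))
        b.add(chain_id, i, resname, "C", c)
        b.add(chain_id, i, resname, "O", o)
        prev_n, prev_ca, prev_c = n, ca, c
    return b.build()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Toy chiral ligand
# ---------------------------------------------------------------------------

#: Ligand chain/residue identity.
LIGAND_CHAIN = "L"
LIGAND_RESNAME = "LIG"

_TET = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def make_toy_ligand(
    handedness: Literal["R", "S"] = "S",
    chirality_k: float = 50.0,
) -> tuple[Structure, CovalentTopology, ChiralCenter]:
    """A rigid toy ligand: one tetrahedral stereocenter C1 carrying a
    proton (H1), an N-methyl amine (N1 with HN1 and C5/HI1–3), a methyl
    (C2/HF1–3), and a two-carbon arm ending in a methyl (C3–C4/HG1–3).

    Every substituent direction carries restrainable protons, so NOE
    contacts triangulate the center in 3D and distinguish the hands.  The
    chirality is encoded by a single improper torsion over the four
    substituents (the two arm-orienting torsions are trans, hence
    mirror-invariant); ``chirality_k`` sets its strength — a weak value
    lets the restraint field invert the center during refinement.  ``R``
    and ``S`` outputs are exact mirror images with identical atom tables.
    """
    b = _Builder()
    c1 = np.zeros(3)
    n1 = 1.47 * _TET[0]
    c3 = 1.53 * _TET[1]
    c2 = 1.53 * _TET[2]
    h1 = 1.09 * _TET[3]
    c4 = nerf_place(n1, c1, c3, 1.53, 111.0, 180.0)
    c5 = nerf_place(c3, c1, n1, 1.47, 111.0, 180.0)
    hn1 = nerf_place(c3, c1, n1, 1.01, 109.5, 60.0)
    add = lambda name, pos: b.add(LIGAND_CHAIN, 1, LIGAND_RESNAME, name, pos)
    add("C1", c1)
    add("H1", h1)
    add("N1", n1)
    add("HN1", hn1)
    add("C2", c2)
    for name, tors in (("HF1", 60.0), ("HF2", -60.0), ("HF3", 180.0)):
        add(name, nerf_place(n1, c1, c2, 1.09, 109.5, tors))
    add("C3", c3)
    add("C4", c4)
    for name, tors in (("HG1", 60.0), ("HG2", -60.0), ("HG3", 180.0)):
        add(name, nerf_place(c1, c3, c4, 1.09, 109.5, tors))
    add("C5", c5)
    for name, tors in (("HI1", 60.0), ("HI2", -60.0), ("HI3", 180.0)):
        add(name, nerf_place(c1, n1, c5, 1.09, 109.5, tors))
    lig = b.build()

    center = ChiralCenter(
        center=_lsel("C1"),
        substituents=(_lsel("N1"), _lsel("C3"), _lsel("C2"), _lsel("H1")),
    )
    from .geometry import chirality_sign  # local import avoids cycle at load

    built_hand = chirality_sign(center, lig)[0]
    if built_hand != handedness:
        coords = lig.coords.copy()
        coords[:, 0] *= -1.0
        lig = lig.copy_with(coords)

    topo = _ligand_topology(lig, chirality_k)
    return lig, topo, center


def _lsel(name: str) -> AtomSelector:
    return AtomSelector(LIGAND_CHAIN, 1, name, residue_name=LIGAND_RESNAME)


_LIGAND_BONDS = [
    ("C1", "H1"), ("C1", "N1"), ("C1", "C2"), ("C1", "C3"),
    ("C3", "C4"), ("N1", "C5"), ("N1", "HN1"),
    ("C2", "HF1"), ("C2", "HF2"), ("C2", "HF3"),
    ("C4", "HG1"), ("C4", "HG2"), ("C4", "HG3"),
    ("C5", "HI1"), ("C5", "HI2"), ("C5", "HI3"),
]
#: The single chirality-encoding improper (substituents in priority order)
#: plus two arm-orienting trans torsions whose equilibria (180°) are
#: mirror-invariant — the two hands' topologies differ only in the first.
_LIGAND_IMPROPERS = [
    ("N1", "C3", "C2", "H1"),
    ("N1", "C1", "C3", "C4"),
    ("C3", "C1", "N1", "C5"),
]


def _ligand_topology(lig: Structure, chirality_k: float) -> CovalentTopology:
    key = lambda n: (LIGAND_CHAIN, 1, n)
    bonds = [(key(a), key(b)) for a, b in _LIGAND_BONDS]
    imps = [tuple(key(n) for n in quad) for quad in _LIGAND_IMPROPERS]
    topo = measured_topology(lig, bonds, imps, ligand_chain=LIGAND_CHAIN)
    # the first improper is the chirality enforcement; give it its own k
    topo.impropers[0] = replace(topo.impropers[0], k=chirality_k)
    return topo


# ---------------------------------------------------------------------------
# Measured-geometry topology
# ---------------------------------------------------------------------------

def measured_topology(
    structure: Structure,
    bond_keys: list[tuple],
    improper_quads: list[tuple],
    k_bond: float = 1000.0,
    k_angle: float = 100.0,
    k_improper: float = 50.0,
    ligand_chain: str = LIGAND_CHAIN,
) -> CovalentTopology:
    """Topology whose equilibrium values are measured from ``structure``.

    Bonds come from ``bond_keys``; angle terms are generated for every pair
    of bonded neighbours at each atom; impropers from the explicit
    quadruples.  A structure thus measures to exactly zero covalent energy
    against its own topology.
    """
    coords = structure.coords

    def pos(k):
        return coords[structure.atom_index(*k)]

    bonds = [
        BondTerm(atoms=(a, b), r0=float(np.linalg.norm(pos(a) - pos(b))), k=k_bond)
        for a, b in bond_keys
    ]
    neighbours: dict[tuple, list[tuple]] = {}
    for a, b in bond_keys:
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)
    angles = []
    for center, nbrs in neighbours.items():
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                a, c = nbrs[x], nbrs[y]
                u, v = pos(a) - pos(center), pos(c) - pos(center)
                theta = np.degrees(
                    np.arccos(
                        np.clip(
                            float(u @ v)
                            / (np.linalg.norm(u) * np.linalg.norm(v)),
                            -1.0,
                            1.0,
                        )
                    )
                )
                angles.append(
                    AngleTerm(atoms=(a, center, c), theta0_deg=float(theta), k=k_angle)
                )
    impropers = [
        ImproperTerm(
            atoms=quad,
            phi0_deg=float(dihedral_angle(*(pos(k) for k in quad))),
            k=k_improper,
        )
        for quad in improper_quads
    ]
    return CovalentTopology(
        bonds=bonds, angles=angles, impropers=impropers, ligand_chain=ligand_chain
    )


def protein_topology(helix: Structure, chain_id: str = "A") -> CovalentTopology:
    """Measured-geometry covalent topology for a built helix fragment."""
    at = helix.atoms
    resnums = sorted(at.loc[at["chain_id"] == chain_id, "residue_number"].unique())
    names_by_res = {
        i: set(at.loc[(at["chain_id"] == chain_id) & (at["residue_number"] == i),
                      "atom_name"])
        for i in resnums
    }
    key = lambda i, n: (chain_id, int(i), n)
    bonds: list[tuple] = []
    imps: list[tuple] = []
    for i in resnums:
        names = names_by_res[i]
        bonds += [(key(i, "N"), key(i, "CA")), (key(i, "CA"), key(i, "C")),
                  (key(i, "C"), key(i, "O")), (key(i, "N"), key(i, "H")),
                  (key(i, "CA"), key(i, "HA"))]
        if "CB" in names:
            bonds.append((key(i, "CA"), key(i, "CB")))
            bonds += [(key(i, "CB"), key(i, n)) for n in names
                      if n.startswith("HB")]
            imps.append((key(i, "N"), key(i, "C"), key(i, "CA"), key(i, "CB")))
        if "CG" in names:
            bonds.append((key(i, "CB"), key(i, "CG")))
            bonds += [(key(i, "CG"), key(i, n)) for n in names
                      if n.startswith("HG")]
            imps.append((key(i, "N"), key(i, "CA"), key(i, "CB"), key(i, "CG")))
        imps.append((key(i, "N"), key(i, "CA"), key(i, "C"), key(i, "O")))
        imps.append((key(i, "N"), key(i, "C"), key(i, "CA"), key(i, "HA")))
        if i + 1 in names_by_res:
            bonds.append((key(i, "C"), key(i + 1, "N")))
            imps.append((key(i, "CA"), key(i, "C"), key(i + 1, "N"),
                         key(i + 1, "CA")))                      # omega
            imps.append((key(i, "O"), key(i, "CA"), key(i, "C"),
                         key(i + 1, "N")))                       # peptide plane
            imps.append((key(i, "CA"), key(i, "C"), key(i + 1, "N"),
                         key(i + 1, "H")))                       # amide H plane
    return measured_topology(helix, bonds, imps)


# ---------------------------------------------------------------------------
# Restraint derivation from true coordinates
# ---------------------------------------------------------------------------

def _proton_groups(structure: Structure) -> list[tuple[AtomSelector, list[int]]]:
    """Group degenerate protons (methyl/methylene) into wildcard selectors.

    Within each residue, hydrogens whose names differ only in a trailing
    digit collapse into a ``stem*`` pseudoatom selector; lone protons keep
    their exact name.
    """
    at = structure.atoms
    groups: list[tuple[AtomSelector, list[int]]] = []
    hmask = at["element"] == "H"
    frame = at[hmask].copy()
    frame["idx"] = np.flatnonzero(hmask.to_numpy())
    for (chain, resnum, resname), sub in frame.groupby(
        ["chain_id", "residue_number", "residue_name"], sort=False
    ):
        stems: dict[str, list[int]] = {}
        for name, idx in zip(sub["atom_name"], sub["idx"]):
            stem = name[:-1] if name[-1].isdigit() else name
            stems.setdefault(stem, []).append(int(idx))
        merged: dict[str, list[int]] = {}
        for name, idx in zip(sub["atom_name"], sub["idx"]):
            stem = name[:-1] if name[-1].isdigit() else name
            if name[-1].isdigit() and len(stems[stem]) > 1:
                merged.setdefault(stem + "*", []).append(int(idx))
            else:
                merged.setdefault(name, []).append(int(idx))
        for pattern, idxs in merged.items():
            groups.append(
                (
                    AtomSelector(chain, int(resnum), pattern, residue_name=resname),
                    idxs,
                )
            )
    return groups


def derive_restraints(
    truth: Structure,
    cutoff: float = 5.0,
    seed: int = 0,
    noise: float = 0.0,
    ligand_chain: str = LIGAND_CHAIN,
    intermolecular_cutoff: float | None = None,
) -> RestraintSet:
    """Derive a restraint set that the true structure satisfies exactly.

    Every proton-group pair (intramolecular within the protein, plus all
    protein–ligand pairs) whose r⁻⁶-averaged effective distance is within
    ``cutoff`` becomes an NOE restraint in the tightest intensity class
    covering that distance (widened by |N(0, noise)| — noise never
    tightens).  Pairs whose r⁻⁶-sum effective distance falls below the
    1.8 Å floor are skipped so the truth is violation-free under both
    conventions.  Helical i→i+4 hydrogen bonds contribute paired H/O and
    N/O restraints where the true geometry satisfies the fixed bounds; φ/ψ
    restraints use the true angles with a 20° half-width.

    ``intermolecular_cutoff`` lets protein–ligand pairs reach further than
    intramolecular ones (long-mixing interface NOEs); default: same cutoff.
    """
    if intermolecular_cutoff is None:
        intermolecular_cutoff = cutoff
    if max(cutoff, intermolecular_cutoff) > INTENSITY_BOUNDS[IntensityClass.very_weak][1]:
        raise ValueError("cutoff exceeds the very-weak class bound (6.0 Å)")
    rng = np.random.default_rng(seed)
    groups = _proton_groups(truth)
    restraints: list[DistanceRestraint] = []
    for gi in range(len(groups)):
        sel_i, idx_i = groups[gi]
        for gj in range(gi + 1, len(groups)):
            sel_j, idx_j = groups[gj]
            on_lig_i = sel_i.chain_id == ligand_chain
            on_lig_j = sel_j.chain_id == ligand_chain
            if on_lig_i and on_lig_j:
                continue  # no intra-ligand protocol
            pairs = [(a, b) for a in idx_i for b in idx_j]
            d_avg = effective_distance(pairs, truth, "r6_average")
            pair_cutoff = intermolecular_cutoff if (on_lig_i or on_lig_j) else cutoff
            if d_avg > pair_cutoff:
                continue
            d_sum = d_avg * len(pairs) ** (-1.0 / 6.0)
            if d_sum < NOE_LOWER_BOUND:
                continue  # would read as a short-contact violation under r6_sum
            widen = abs(rng.normal(0.0, noise)) if noise > 0 else 0.0
            cls = class_for_distance(min(d_avg + widen, 6.0))
            lower, upper = INTENSITY_BOUNDS[cls]
            restraints.append(
                DistanceRestraint(
                    selector_i=sel_i,
                    selector_j=sel_j,
                    lower_bound=lower,
                    upper_bound=upper,
                    origin="noe",
                    intensity_class=cls,
                )
            )

    # helical i -> i-4 hydrogen bonds, where the true geometry qualifies
    protein_chain = None
    for chain in truth.atoms["chain_id"].unique():
        if chain != ligand_chain:
            protein_chain = chain
            break
    hb_pairs = []
    resnums = sorted(
        truth.atoms.loc[
            truth.atoms["chain_id"] == protein_chain, "residue_number"
        ].unique()
    )
    for i in resnums:
        if i - 4 not in resnums:
            continue
        try:
            h = truth.coords[truth.atom_index(protein_chain, i, "H")]
            n = truth.coords[truth.atom_index(protein_chain, i, "N")]
            o = truth.coords[truth.atom_index(protein_chain, i - 4, "O")]
        except KeyError:
            continue
        d_ho = float(np.linalg.norm(h - o))
        d_no = float(np.linalg.norm(n - o))
        if 1.7 <= d_ho <= 2.5 and 2.7 <= d_no <= 3.5:
            hb_pairs.append(
                (
                    AtomSelector(protein_chain, i, "N"),
                    AtomSelector(protein_chain, i, "H"),
                    AtomSelector(protein_chain, i - 4, "O"),
                )
            )
    hbonds = make_hbond_restraints(hb_pairs)

    # phi/psi from true angles, 20 degree half-width
    dihedrals: list[DihedralRestraint] = []
    for i in resnums:
        if i - 1 in resnums:
            sels = (
                AtomSelector(protein_chain, i - 1, "C"),
                AtomSelector(protein_chain, i, "N"),
                AtomSelector(protein_chain, i, "CA"),
                AtomSelector(protein_chain, i, "C"),
            )
            target = _measured_torsion(truth, sels)
            dihedrals.append(
                DihedralRestraint(
                    selectors=sels, target_deg=target, half_width_deg=20.0,
                    angle_name="phi",
                )
            )
        if i + 1 in resnums:
            sels = (
                AtomSelector(protein_chain, i, "N"),
                AtomSelector(protein_chain, i, "CA"),
                AtomSelector(protein_chain, i, "C"),
                AtomSelector(protein_chain, i + 1, "N"),
            )
            target = _measured_torsion(truth, sels)
            dihedrals.append(
                DihedralRestraint(
                    selectors=sels, target_deg=target, half_width_deg=20.0,
                    angle_name="psi",
                )
            )

    rset = RestraintSet(
        distance_restraints=restraints + hbonds,
        dihedral_restraints=dihedrals,
        provenance=f"derived from truth (cutoff {cutoff} Å, seed {seed}, noise {noise})",
    )
    accounting(rset, ligand_chain=ligand_chain)
    return rset


def _measured_torsion(structure: Structure, sels) -> float:
    pts = [structure.coords[structure.atom_index(s.chain_id, s.residue_number,
                                                 s.atom_pattern)] for s in sels]
    return float(dihedral_angle(*pts))


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    sequence: str = DEFAULT_SEQUENCE
    helix_phi: float = -57.0
    helix_psi: float = -47.0
    ligand_handedness: Literal["R", "S"] = "S"
    restraint_cutoff: float = 5.0
    intermolecular_cutoff: float | None = None  # default: restraint_cutoff
    noise: float = 0.0            # Å widening noise on derived bounds
    perturbation_rms: float = 1.0 # Å rms displacement of the starts
    seed: int = 0
    n_starts: int = 10
    chirality_k: float = 50.0

    def __post_init__(self) -> None:
        if max(self.restraint_cutoff, self.intermolecular_cutoff or 0.0) > 6.0:
            raise ValueError("cutoff must not exceed the largest class bound (6 Å)")
        if len(self.sequence) < 9:
            raise ValueError(
                "fixture needs at least 9 residues to carry the docking pocket"
            )


@dataclass
class Fixture:
    """Synthetic true complex + derived restraints + perturbed starts."""

    truth: Structure
    restraints: RestraintSet
    topology: CovalentTopology
    protein_topology: CovalentTopology
    ligand_topology: CovalentTopology
    starts: list[Structure]
    manifest: dict[str, int]
    chiral_center: ChiralCenter
    config: FixtureConfig
    pocket_residues: list[int] = field(default_factory=list)


def _dock_ligand(helix: Structure, ligand: Structure) -> tuple[Structure, list[int]]:
    """Rigidly place the ligand against the helix face at known contacts.

    The pocket is the Cβ centroid of four same-face residues around the
    helix midpoint; the ligand's methyl cluster is pointed at it from the
    outside, then backed off until no heavy-atom clash (< 2.9 Å) remains.
    Deterministic.
    """
    at = helix.atoms
    resnums = sorted(int(r) for r in at["residue_number"].unique())
    m = resnums[len(resnums) // 2]
    pocket = [m - 4, m - 1, m, m + 3]
    anchor_pos = []
    for r in pocket:
        names = set(at.loc[at["residue_number"] == r, "atom_name"])
        anchor = "CG" if "CG" in names else ("CB" if "CB" in names else "CA")
        anchor_pos.append(helix.coords[helix.atom_index("A", r, anchor)])
    pocket_centroid = np.mean(anchor_pos, axis=0)

    ca_idx = [helix.atom_index("A", r, "CA") for r in resnums]
    ca = helix.coords[ca_idx]
    axis_point = ca.mean(axis=0)
    axis_dir = _unit(ca[-1] - ca[0])
    proj = axis_point + axis_dir * float((pocket_centroid - axis_point) @ axis_dir)
    outward = _unit(pocket_centroid - proj)

    # ligand frame: long axis (arm methyl C4 -> N-methyl C5) lies along the
    # helix axis so both ends touch side chains, while the central H1/C2
    # face points at the pocket — contacts then span four non-coplanar
    # proton groups, which is what lets the NOE field resolve the hands
    def lpos(n):
        return ligand.coords[ligand.atom_index(LIGAND_CHAIN, 1, n)]

    lig_c1 = lpos("C1")
    v_long = _unit(lpos("C5") - lpos("C4"))
    v_face = lpos("H1") - lig_c1
    v_face = _unit(v_face - v_long * float(v_face @ v_long))
    t_long = axis_dir
    t_face = _unit(-outward - t_long * float(-outward @ t_long))
    src = np.column_stack([v_long, v_face, np.cross(v_long, v_face)])
    dst = np.column_stack([t_long, t_face, np.cross(t_long, t_face)])
    R = dst @ src.T
    placed = (ligand.coords - lig_c1) @ R.T

    helix_heavy = helix.coords[(at["element"] != "H").to_numpy()]
    lig_heavy_mask = (ligand.atoms["element"] != "H").to_numpy()
    offset = 2.6
    while True:
        candidate = placed + pocket_centroid + outward * offset
        dmin = np.min(
            np.linalg.norm(
                candidate[lig_heavy_mask][:, None, :] - helix_heavy[None, :, :],
                axis=2,
            )
        )
        if dmin >= 2.9:
            break
        offset += 0.25
    docked = ligand.copy_with(candidate)
    return docked, pocket


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degree turn about any axis perpendicular to a
        perp = _unit(np.cross(a, [1.0, 0.0, 0.0]))
        if not np.all(np.isfinite(perp)):
            perp = _unit(np.cross(a, [0.0, 1.0, 0.0]))
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _concat(a: Structure, b: Structure) -> Structure:
    atoms = pd.concat([a.atoms, b.atoms], ignore_index=True)
    return Structure(atoms=atoms, coords=np.vstack([a.coords, b.coords]))


def make_fixture(config: FixtureConfig = FixtureConfig()) -> Fixture:
    """Assemble the full synthetic complex, deterministically from config."""
    helix = make_ideal_helix(config.sequence, config.helix_phi, config.helix_psi)
    ligand, lig_topo, center = make_toy_ligand(
        config.ligand_handedness, config.chirality_k
    )
    docked, pocket = _dock_ligand(helix, ligand)
    # topology equilibria are measured on the docked pose (rigid motion
    # leaves bond/angle/torsion values unchanged, so this equals the
    # fragment topology; re-measuring keeps the zero-energy contract exact)
    lig_topo = _ligand_topology(docked, config.chirality_k)
    truth = _concat(helix, docked)
    prot_topo = protein_topology(helix)
    topology = prot_topo.merged_with(lig_topo)
    restraints = derive_restraints(
        truth,
        cutoff=config.restraint_cutoff,
        seed=config.seed,
        noise=config.noise,
        intermolecular_cutoff=config.intermolecular_cutoff,
    )
    rng = np.random.default_rng(config.seed)
    starts = []
    for k in range(config.n_starts):
        noise = rng.normal(
            0.0, config.perturbation_rms / np.sqrt(3.0), size=truth.coords.shape
        )
        starts.append(truth.copy_with(truth.coords + noise, model_id=k + 1))
    manifest = accounting(restraints, ligand_chain=LIGAND_CHAIN)
    return Fixture(
        truth=truth,
        restraints=restraints,
        topology=topology,
        protein_topology=prot_topo,
        ligand_topology=lig_topo,
        starts=starts,
        manifest=manifest,
        chiral_center=center,
        config=config,
        pocket_residues=pocket,
    )


#: Reduced fixture used by the enantiomer screen: a 12-residue helix with
#: interface NOEs out to the very-weak bound (long-mixing interface data).
SCREEN_FIXTURE_CONFIG = FixtureConfig(
    sequence="ADKLVEAMTRLF", restraint_cutoff=4.5, intermolecular_cutoff=6.0
)

#: Refinement protocol of the screen: small pools of gently perturbed
#: starts per hand, compared on the three lowest NOE energies.
SCREEN_REFINE_KWARGS = dict(
    pool_size=4, keep_n=1, max_iterations=800,
    perturbation_rms=0.5, gradient_tolerance=1e-4,
)


def make_screen_problem(
    fixture: Fixture,
) -> tuple[RestraintSet, dict[str, Structure], dict[str, CovalentTopology]]:
    """Set up the two-hand refinement problem for the enantiomer screen.

    The restraints are the fixture's (derived from its true hand).  The
    other hand's start replaces the ligand with its mirror image reflected
    in place through the plane of C1/BR1/N1, keeping the protein fixed;
    its topology carries the sign-flipped chirality improper.
    """
    hand = fixture.config.ligand_handedness
    other = "R" if hand == "S" else "S"
    truth = fixture.truth
    lig_mask = (truth.atoms["chain_id"] == LIGAND_CHAIN).to_numpy()
    coords = truth.coords.copy()
    p0 = coords[truth.atom_index(LIGAND_CHAIN, 1, "C1")]
    p1 = coords[truth.atom_index(LIGAND_CHAIN, 1, "N1")]
    p2 = coords[truth.atom_index(LIGAND_CHAIN, 1, "C3")]
    normal = _unit(np.cross(p1 - p0, p2 - p0))
    lig = coords[lig_mask]
    coords[lig_mask] = lig - 2.0 * ((lig - p0) @ normal)[:, None] * normal
    other_start = truth.copy_with(coords)
    other_topo = fixture.protein_topology.merged_with(
        mirror_topology(fixture.ligand_topology)
    )
    starts = {hand: truth, other: other_start}
    topologies = {hand: fixture.topology, other: other_topo}
    return fixture.restraints, starts, topologies


def mirror_screen_problem(
    restraints: RestraintSet,
    starts: dict[str, Structure],
    topologies: dict[str, CovalentTopology],
) -> tuple[RestraintSet, dict[str, Structure], dict[str, CovalentTopology]]:
    """The exact mirror image of a screen problem.

    Distance restraints are reflection-invariant; dihedral targets negate;
    structures reflect; topology improper equilibria negate; the R/S roles
    swap.  A screen that picks S on the original must pick R here.
    """
    from .energy import mirror_structure

    m_rset = RestraintSet(
        distance_restraints=list(restraints.distance_restraints),
        dihedral_restraints=[
            DihedralRestraint(
                selectors=d.selectors,
                target_deg=(180.0 if d.target_deg == 180.0 else -d.target_deg),
                half_width_deg=d.half_width_deg,
                angle_name=d.angle_name,
            )
            for d in restraints.dihedral_restraints
        ],
        provenance=restraints.provenance + " (mirrored)",
    )
    m_starts = {
        "R": mirror_structure(starts["S"]),
        "S": mirror_structure(starts["R"]),
    }
    m_topos = {
        "R": mirror_topology(topologies["S"]),
        "S": mirror_topology(topologies["R"]),
    }
    return m_rset, m_starts, m_topos
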