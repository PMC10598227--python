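"""Restraint energies, simplified covalent terms, and restrained refinement.

The restraint surface is a flat-bottom "soft-square" form: zero inside the
[lower, upper] band, harmonic k·v² for a violation v up to a switch
distance, then linear with matched value and slope (energy and first
derivative continuous everywhere).  Ambiguous/pseudoatom restraints are
evaluated on the r⁻⁶-averaged (or r⁻⁶-summed) effective distance over the
expanded proton pairs, with the exact analytic gradient of that effective
distance.  Dihedral restraints are harmonic in the wrapped excess violation
(radians).  Covalent geometry is enforced by harmonic bond/angle/improper
terms; impropers encode planarity and chirality.  Ligand covalent terms are
multiplied by a scale factor (default 0.2) — strong enough to hold the
ligand together without overwhelming the restraint terms.

Refinement is Cartesian: analytic-gradient minimization (L-BFGS-B) of the
total energy, repeated from randomly perturbed starts to build a pool, from
which the lowest-NOE-energy conformers are selected.  The enantiomer screen
runs the same protocol once per ligand hand and compares the low-energy
tails of the two pools.

All terms are compiled to flat index arrays once per (structure topology,
restraint set), so a single energy/gradient evaluation is a handful of
vectorized numpy operations regardless of the number of restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .geometry import (
    ChiralCenter,
    Ensemble,
    GeometryError,
    Structure,
    chirality_sign,
    expand_pair,
    wrap_angle,
)
from .restraints import DihedralRestraint, DistanceRestraint, RestraintSet

__all__ = [
    "EnergyModel",
    "BondTerm",
    "AngleTerm",
    "ImproperTerm",
    "CovalentTopology",
    "RefineConfig",
    "EnergyBreakdown",
    "PoolMember",
    "EnantiomerReport",
    "noe_energy",
    "dihedral_energy",
    "covalent_energy",
    "total_energy",
    "minimize",
    "perturb",
    "generate_pool",
    "select_lowest",
    "ensemble_from_members",
    "enantiomer_screen",
    "mirror_structure",
    "mirror_topology",
]

AtomKey = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


@dataclass(frozen=True)
class EnergyModel:
    """Force constants and scales for the restrained-refinement energy."""

    k_noe: float = 50.0           # energy / Å²
    k_dihedral: float = 200.0     # energy / rad²
    soft_switch: float = 1.0      # Å; quadratic→linear switch of the NOE term
    ligand_scale: float = 0.2     # scale on ligand covalent force constants
    k_repel: float = 25.0         # energy / Å²; 0 disables the clash term
    repel_scale: float = 0.80     # scale on summed element radii (onset)

    def __post_init__(self) -> None:
        if min(self.k_noe, self.k_dihedral, self.soft_switch) <= 0:
            raise ValueError("force constants and switch must be positive")
        if not (0.0 < self.ligand_scale <= 1.0):
            raise ValueError("ligand_scale must be in (0, 1]")
        if self.k_repel < 0 or self.repel_scale <= 0:
            raise ValueError("repulsion parameters must be non-negative")


#: Element radii (Å) for the soft-core clash onset (scaled sums).
REPEL_RADII = {"H": 1.1, "C": 1.55, "N": 1.4, "O": 1.35, "S": 1.8, "BR": 1.85}


@dataclass(frozen=True)
class BondTerm:
    atoms: tuple[AtomKey, AtomKey]
    r0: float          # Å
    k: float = 1000.0  # energy / Å²


@dataclass(frozen=True)
class AngleTerm:
    atoms: tuple[AtomKey, AtomKey, AtomKey]
    theta0_deg: float
    k: float = 100.0   # energy / rad²


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic torsion over four named atoms; encodes planarity (target
    0/180°) or chirality (signed non-planar target)."""

    atoms: tuple[AtomKey, AtomKey, AtomKey, AtomKey]
    phi0_deg: float
    k: float = 50.0    # energy / rad²


@dataclass
class CovalentTopology:
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    impropers: list[ImproperTerm] = field(default_factory=list)
    ligand_chain: str = "L"

    def merged_with(self, other: "CovalentTopology") -> "CovalentTopology":
        return CovalentTopology(
            bonds=self.bonds + other.bonds,
            angles=self.angles + other.angles,
            impropers=self.impropers + other.impropers,
            ligand_chain=self.ligand_chain,
        )


@dataclass(frozen=True)
class RefineConfig:
    max_iterations: int = 500
    gradient_tolerance: float = 1e-3
    perturbation_rms: float = 1.0   # Å per-atom rms displacement
    seed: int = 0
    pool_size: int = 20
    keep_n: int = 10

    def __post_init__(self) -> None:
        if self.keep_n > self.pool_size:
            raise ValueError("keep_n must be ≤ pool_size")
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient tolerance must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    noe: float
    dihedral: float
    covalent: float
    repulsion: float = 0.0

    @property
    def total(self) -> float:
        return self.noe + self.dihedral + self.covalent + self.repulsion


@dataclass
class PoolMember:
    run_index: int
    structure: Structure
    energy: EnergyBreakdown
    n_iterations: int
    converged: bool
    energy_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Compiled term tables
# ---------------------------------------------------------------------------

@dataclass
class _DistTable:
    """All distance restraints flattened into one pair list with segment ids."""

    pair_idx: np.ndarray   # (P, 2)
    seg: np.ndarray        # (P,) restraint index per pair
    weight: np.ndarray     # (T,) 1/N for r6_average, 1 for r6_sum
    lower: np.ndarray      # (T,)
    upper: np.ndarray      # (T,)
    n_terms: int

    def effective_distances(self, coords: np.ndarray) -> np.ndarray:
        if self.n_terms == 0:
            return np.empty(0)
        diff = coords[self.pair_idx[:, 0]] - coords[self.pair_idx[:, 1]]
        d = np.linalg.norm(diff, axis=1)
        if np.any(d < 1e-8):
            raise GeometryError("coincident atoms in restraint pair")
        s6 = np.bincount(self.seg, weights=d**-6.0, minlength=self.n_terms)
        return (self.weight * s6) ** (-1.0 / 6.0)


def _compile_distances(
    restraints: Sequence[DistanceRestraint],
    structure: Structure,
    method: str,
) -> _DistTable:
    pair_rows, seg, weight, lower, upper = [], [], [], [], []
    for t, r in enumerate(restraints):
        pairs = expand_pair(r.selector_i, r.selector_j, structure)
        pair_rows.extend(pairs)
        seg.extend([t] * len(pairs))
        weight.append(1.0 / len(pairs) if method == "r6_average" else 1.0)
        lower.append(r.lower_bound)
        upper.append(r.upper_bound)
    return _DistTable(
        pair_idx=np.asarray(pair_rows, dtype=int).reshape(-1, 2),
        seg=np.asarray(seg, dtype=int),
        weight=np.asarray(weight, dtype=float),
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        n_terms=len(restraints),
    )


@dataclass
class _TorsionTable:
    idx: np.ndarray        # (M, 4)
    target: np.ndarray     # (M,) degrees
    half_width: np.ndarray # (M,) degrees; 0 for pure-harmonic impropers
    k: np.ndarray          # (M,) energy / rad²


def _compile_dihedrals(
    restraints: Sequence[DihedralRestraint],
    structure: Structure,
    k_dihedral: float,
) -> _TorsionTable:
    rows, target, half = [], [], []
    for r in restraints:
        quad = []
        for sel in r.selectors:
            matches = structure.select(sel)
            if len(matches) != 1:
                raise GeometryError(f"dihedral selector not unique: {sel}")
            quad.append(matches[0])
        rows.append(quad)
        target.append(r.target_deg)
        half.append(r.half_width_deg)
    m = len(rows)
    return _TorsionTable(
        idx=np.asarray(rows, dtype=int).reshape(-1, 4),
        target=np.asarray(target, dtype=float),
        half_width=np.asarray(half, dtype=float),
        k=np.full(m, k_dihedral, dtype=float),
    )


@dataclass
class _CompiledTopology:
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_t0: np.ndarray   # radians
    angle_k: np.ndarray
    torsions: _TorsionTable  # impropers (half_width 0)
    repel_idx: np.ndarray    # (P, 2) non-bonded atom pairs
    repel_onset: np.ndarray  # (P,) clash onset distances, Å


def _repulsion_pairs(
    structure: Structure, bond_idx: np.ndarray, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-residue atom pairs more than four bonds apart (1-5 and
    beyond) with their clash onset distances scale·(rᵢ + rⱼ).

    These feel the soft-core clash term; everything closer in the bonded
    graph — and everything within one residue — is governed by the
    explicit bond/angle/improper terms.
    """
    n = structure.n_atoms
    adj: dict[int, set[int]] = {}
    for i, j in bond_idx:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    res_id = list(
        zip(structure.atoms["chain_id"], structure.atoms["residue_number"])
    )
    pairs = []
    for i in range(n):
        seen = {i}
        frontier = {i}
        for _ in range(4):
            frontier = set().union(*(adj.get(x, set()) for x in frontier)) - seen
            seen |= frontier
        pairs.extend(
            (i, j)
            for j in range(i + 1, n)
            if j not in seen and res_id[j] != res_id[i]
        )
    idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    radii = structure.atoms["element"].map(
        lambda e: REPEL_RADII.get(e, 1.6)
    ).to_numpy(dtype=float)
    onset = scale * (radii[idx[:, 0]] + radii[idx[:, 1]])
    # neighbour pruning: pairs far beyond the onset at compile time cannot
    # clash within the excursions a single minimization makes (margin 3 Å)
    if len(idx):
        d0 = np.linalg.norm(
            structure.coords[idx[:, 0]] - structure.coords[idx[:, 1]], axis=1
        )
        keep = d0 < onset + 3.0
        idx, onset = idx[keep], onset[keep]
    return idx, onset


def _repulsion_energy_grad(
    repel_idx: np.ndarray,
    repel_onset: np.ndarray,
    coords: np.ndarray,
    model: EnergyModel,
    grad: np.ndarray | None,
) -> float:
    """Soft-core clash penalty k·(onset − d)² for d < onset.

    A pure repulsive excluded-volume term (no attractive van der Waals,
    no electrostatics), as restrained annealing protocols use."""
    if model.k_repel == 0.0 or len(repel_idx) == 0:
        return 0.0
    diff = coords[repel_idx[:, 0]] - coords[repel_idx[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    mask = d < repel_onset
    if not np.any(mask):
        return 0.0
    dd = np.maximum(d[mask], 1e-6)
    dev = repel_onset[mask] - dd
    if grad is not None:
        g = (-2.0 * model.k_repel * dev / dd)[:, None] * diff[mask]
        _scatter_add(grad, repel_idx[mask, 0], g)
        _scatter_add(grad, repel_idx[mask, 1], -g)
    return float(model.k_repel * np.sum(dev * dev))


def _compile_topology(
    topo: CovalentTopology, structure: Structure, model: EnergyModel
) -> _CompiledTopology:
    def resolve(key: AtomKey) -> int:
        return structure.atom_index(*key)

    def scale(keys: Sequence[AtomKey]) -> float:
        return model.ligand_scale if all(k[0] == topo.ligand_chain for k in keys) else 1.0

    b_idx = [[resolve(a) for a in b.atoms] for b in topo.bonds]
    a_idx = [[resolve(x) for x in a.atoms] for a in topo.angles]
    i_idx = [[resolve(x) for x in im.atoms] for im in topo.impropers]
    repel_idx, repel_onset = _repulsion_pairs(
        structure, np.asarray(b_idx, dtype=int).reshape(-1, 2), model.repel_scale
    )
    return _CompiledTopology(
        bond_idx=np.asarray(b_idx, dtype=int).reshape(-1, 2),
        bond_r0=np.asarray([b.r0 for b in topo.bonds], dtype=float),
        bond_k=np.asarray([b.k * scale(b.atoms) for b in topo.bonds], dtype=float),
        angle_idx=np.asarray(a_idx, dtype=int).reshape(-1, 3),
        angle_t0=np.radians([a.theta0_deg for a in topo.angles]),
        angle_k=np.asarray([a.k * scale(a.atoms) for a in topo.angles], dtype=float),
        torsions=_TorsionTable(
            idx=np.asarray(i_idx, dtype=int).reshape(-1, 4),
            target=np.asarray([im.phi0_deg for im in topo.impropers], dtype=float),
            half_width=np.zeros(len(topo.impropers)),
            k=np.asarray(
                [im.k * scale(im.atoms) for im in topo.impropers], dtype=float
            ),
        ),
        repel_idx=repel_idx,
        repel_onset=repel_onset,
    )


# ---------------------------------------------------------------------------
# Batched energy/gradient kernels
# ---------------------------------------------------------------------------


def _scatter_add(grad: np.ndarray, idx: np.ndarray, vecs: np.ndarray) -> None:
    """grad[idx] += vecs via bincount (much faster than np.add.at)."""
    n = grad.shape[0]
    for k in range(3):
        grad[:, k] += np.bincount(idx, weights=vecs[:, k], minlength=n)


def _soft_square_vec(v: np.ndarray, k: float, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Flat-bottom soft-square energies and dE/dv for violations v ≥ 0."""
    quad = v <= s
    e = np.where(quad, k * v * v, k * s * s + 2.0 * k * s * (v - s))
    dedv = np.where(quad, 2.0 * k * v, 2.0 * k * s)
    e[v <= 0.0] = 0.0
    dedv[v <= 0.0] = 0.0
    return e, dedv


def _distance_energy_grad(
    tab: _DistTable, coords: np.ndarray, model: EnergyModel, grad: np.ndarray | None
) -> float:
    if tab.n_terms == 0:
        return 0.0
    diff = coords[tab.pair_idx[:, 0]] - coords[tab.pair_idx[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d < 1e-8):
        raise GeometryError("coincident atoms in restraint pair")
    s6 = np.bincount(tab.seg, weights=d**-6.0, minlength=tab.n_terms)
    d_eff = (tab.weight * s6) ** (-1.0 / 6.0)
    over = d_eff - tab.upper
    under = tab.lower - d_eff
    v = np.maximum(0.0, np.maximum(over, under))
    sign = np.where(over > 0.0, 1.0, np.where(under > 0.0, -1.0, 0.0))
    e, dedv = _soft_square_vec(v, model.k_noe, model.soft_switch)
    if grad is not None and np.any(v > 0.0):
        # d(d_eff)/d(d_p) = d_eff^7 · w · d_p^-7
        factor = (sign * dedv * tab.weight * d_eff**7)[tab.seg] * d**-8.0
        gvec = factor[:, None] * diff
        _scatter_add(grad, tab.pair_idx[:, 0], gvec)
        _scatter_add(grad, tab.pair_idx[:, 1], -gvec)
    return float(np.sum(e))


def _torsion_values(
    coords: np.ndarray, idx: np.ndarray, with_grad: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Batched torsions (degrees) and, optionally, d(phi_rad)/d(coords).

    Returns phi (M,) and grads (M, 4, 3) for the four defining atoms.
    """
    p = coords[idx]  # (M, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    # clamp near-collinear geometry (transient states during line search)
    # instead of raising; the clamped gradient stays finite
    n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-10)
    n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-10)
    nb2 = np.maximum(nb2, 1e-6)
    m1 = np.cross(n1, b2 / nb2[:, None])
    phi = np.degrees(
        np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))
    )
    if not with_grad:
        return phi, None
    d1 = (nb2 / n1sq)[:, None] * n1
    d4 = (nb2 / n2sq)[:, None] * n2
    c12 = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
    c32 = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
    dp1 = d1
    dp2 = -(1.0 + c12) * d1 - c32 * d4
    dp3 = c12 * d1 + (1.0 + c32) * d4
    dp4 = -d4
    return phi, np.stack([dp1, dp2, dp3, dp4], axis=1)


def _wrap_vec(deg: np.ndarray) -> np.ndarray:
    d = (deg + 180.0) % 360.0 - 180.0
    d[d <= -180.0] += 360.0
    return d


def _torsion_energy_grad(
    tab: _TorsionTable, coords: np.ndarray, grad: np.ndarray | None
) -> float:
    if len(tab.idx) == 0:
        return 0.0
    phi, dphi = _torsion_values(coords, tab.idx, with_grad=grad is not None)
    delta = _wrap_vec(phi - tab.target)
    excess_deg = np.maximum(0.0, np.abs(delta) - tab.half_width)
    v = np.radians(excess_deg)
    e = tab.k * v * v
    if grad is not None and np.any(v > 0.0):
        dedphi = 2.0 * tab.k * v * np.sign(delta)  # per radian of phi
        g = dedphi[:, None, None] * dphi           # (M, 4, 3)
        for a in range(4):
            _scatter_add(grad, tab.idx[:, a], g[:, a])
    return float(np.sum(e))


def _bond_energy_grad(
    comp: _CompiledTopology, coords: np.ndarray, grad: np.ndarray | None
) -> float:
    if len(comp.bond_idx) == 0:
        return 0.0
    i, j = comp.bond_idx[:, 0], comp.bond_idx[:, 1]
    diff = coords[i] - coords[j]
    d = np.linalg.norm(diff, axis=1)
    dev = d - comp.bond_r0
    if grad is not None:
        g = (2.0 * comp.bond_k * dev / d)[:, None] * diff
        _scatter_add(grad, i, g)
        _scatter_add(grad, j, -g)
    return float(np.sum(comp.bond_k * dev * dev))


def _angle_energy_grad(
    comp: _CompiledTopology, coords: np.ndarray, grad: np.ndarray | None
) -> float:
    if len(comp.angle_idx) == 0:
        return 0.0
    ia, ib, ic = comp.angle_idx[:, 0], comp.angle_idx[:, 1], comp.angle_idx[:, 2]
    u = coords[ia] - coords[ib]
    v = coords[ic] - coords[ib]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dev = theta - comp.angle_t0
    if grad is not None:
        sin_t = np.sqrt(np.maximum(1e-12, 1.0 - cos_t * cos_t))
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        da = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
        dc = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
        dedt = (2.0 * comp.angle_k * dev)[:, None]
        _scatter_add(grad, ia, dedt * da)
        _scatter_add(grad, ic, dedt * dc)
        _scatter_add(grad, ib, -dedt * (da + dc))
    return float(np.sum(comp.angle_k * dev * dev))


# ---------------------------------------------------------------------------
# Public per-restraint energies
# ---------------------------------------------------------------------------

def noe_energy(
    restraint: DistanceRestraint,
    structure: Structure,
    model: EnergyModel,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> float:
    """Soft-square energy of one distance restraint (NOE or H-bond)."""
    tab = _compile_distances([restraint], structure, method)
    return _distance_energy_grad(tab, structure.coords, model, None)


def dihedral_energy(
    restraint: DihedralRestraint, structure: Structure, model: EnergyModel
) -> float:
    """Harmonic energy k·δ² of the wrapped excess violation δ (radians)."""
    tab = _compile_dihedrals([restraint], structure, model.k_dihedral)
    return _torsion_energy_grad(tab, structure.coords, None)


def covalent_energy(
    structure: Structure, topology: CovalentTopology, model: EnergyModel
) -> float:
    """Harmonic bond + angle + improper energy; ligand terms scaled."""
    comp = _compile_topology(topology, structure, model)
    c = structure.coords
    return (
        _bond_energy_grad(comp, c, None)
        + _angle_energy_grad(comp, c, None)
        + _torsion_energy_grad(comp.torsions, c, None)
    )


def total_energy(
    structure: Structure,
    restraints: RestraintSet,
    topology: CovalentTopology,
    model: EnergyModel,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> EnergyBreakdown:
    """Component-wise energies; ``total`` is their exact sum."""
    obj = _Objective(structure, restraints, topology, model, method)
    return obj.breakdown(structure.coords)


# ---------------------------------------------------------------------------
# Objective and minimizer
# ---------------------------------------------------------------------------

class _Objective:
    """Total energy + analytic gradient, with selectors compiled once."""

    def __init__(
        self,
        structure: Structure,
        restraints: RestraintSet,
        topology: CovalentTopology,
        model: EnergyModel,
        method: str,
    ) -> None:
        self.shape = structure.coords.shape
        self.model = model
        self.dist = _compile_distances(
            restraints.distance_restraints, structure, method
        )
        self.dih = _compile_dihedrals(
            restraints.dihedral_restraints, structure, model.k_dihedral
        )
        self.topo = _compile_topology(topology, structure, model)
        self.last_energy = float("nan")

    def breakdown(self, coords: np.ndarray) -> EnergyBreakdown:
        return EnergyBreakdown(
            noe=_distance_energy_grad(self.dist, coords, self.model, None),
            dihedral=_torsion_energy_grad(self.dih, coords, None),
            covalent=(
                _bond_energy_grad(self.topo, coords, None)
                + _angle_energy_grad(self.topo, coords, None)
                + _torsion_energy_grad(self.topo.torsions, coords, None)
            ),
            repulsion=_repulsion_energy_grad(
                self.topo.repel_idx, self.topo.repel_onset, coords, self.model, None
            ),
        )

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = x.reshape(self.shape)
        grad = np.zeros_like(coords)
        e = _distance_energy_grad(self.dist, coords, self.model, grad)
        e += _torsion_energy_grad(self.dih, coords, grad)
        e += _bond_energy_grad(self.topo, coords, grad)
        e += _angle_energy_grad(self.topo, coords, grad)
        e += _torsion_energy_grad(self.topo.torsions, coords, grad)
        e += _repulsion_energy_grad(
            self.topo.repel_idx, self.topo.repel_onset, coords, self.model, grad
        )
        if not np.isfinite(e) or not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite energy or gradient")
        self.last_energy = e
        return e, grad.ravel()


def minimize(
    start: Structure,
    restraints: RestraintSet,
    topology: CovalentTopology,
    model: EnergyModel,
    config: RefineConfig,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
    run_index: int = 0,
) -> PoolMember:
    """Minimize the total energy from ``start`` with analytic gradients.

    L-BFGS-B with the exact gradient; the energy over accepted iterates is
    non-increasing, and termination is on the projected-gradient norm
    falling below ``config.gradient_tolerance`` or on
    ``config.max_iterations``.  A start that already satisfies every
    restraint has (near-)zero gradient and is returned unchanged.
    """
    obj = _Objective(start, restraints, topology, model, method)
    trace: list[float] = []

    e0, g0 = obj.value_and_grad(start.coords.ravel())
    trace.append(e0)
    if float(np.max(np.abs(g0))) < config.gradient_tolerance:
        return PoolMember(
            run_index=run_index,
            structure=start,
            energy=obj.breakdown(start.coords),
            n_iterations=0,
            converged=True,
            energy_trace=trace,
        )

    def cb(xk: np.ndarray) -> None:
        trace.append(obj.last_energy)

    res = _scipy_minimize(
        obj.value_and_grad,
        start.coords.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={
            "maxiter": config.max_iterations,
            "gtol": config.gradient_tolerance,
            "ftol": 1e-14,
        },
    )
    coords = res.x.reshape(start.coords.shape)
    return PoolMember(
        run_index=run_index,
        structure=start.copy_with(coords),
        energy=obj.breakdown(coords),
        n_iterations=int(res.nit),
        converged=bool(res.success) or int(res.nit) >= config.max_iterations,
        energy_trace=trace,
    )


def perturb(structure: Structure, rms: float, rng: np.random.Generator) -> Structure:
    """Isotropic Gaussian coordinate noise with per-atom rms displacement
    ``rms`` Å (per-coordinate sd = rms/√3)."""
    noise = rng.normal(0.0, rms / np.sqrt(3.0), size=structure.coords.shape)
    return structure.copy_with(structure.coords + noise)


def generate_pool(
    start: Structure,
    restraints: RestraintSet,
    topology: CovalentTopology,
    model: EnergyModel,
    config: RefineConfig,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> list[PoolMember]:
    """``pool_size`` independent perturb-and-minimize runs.

    Run ``i`` perturbs ``start`` with a PCG64 generator seeded
    ``config.seed + i``, so a pool is bitwise reproducible from its config.
    """
    pool = []
    for i in range(config.pool_size):
        rng = np.random.default_rng(config.seed + i)
        noisy = perturb(start, config.perturbation_rms, rng)
        pool.append(
            minimize(noisy, restraints, topology, model, config, method, run_index=i)
        )
    return pool


def select_lowest(
    pool: Sequence[PoolMember],
    keep_n: int,
    key: Literal["noe", "total"] = "noe",
) -> list[PoolMember]:
    """The ``keep_n`` lowest-energy members, stable-sorted by the chosen
    energy component with run index breaking ties."""
    if keep_n > len(pool):
        raise ValueError("keep_n exceeds pool size")
    keyfun = (lambda m: m.energy.noe) if key == "noe" else (lambda m: m.energy.total)
    ordered = sorted(pool, key=lambda m: (keyfun(m), m.run_index))
    return list(ordered[:keep_n])


def ensemble_from_members(members: Sequence[PoolMember]) -> Ensemble:
    return Ensemble(models=[
        m.structure.copy_with(m.structure.coords, model_id=i + 1)
        for i, m in enumerate(members)
    ])


# ---------------------------------------------------------------------------
# Mirroring and the enantiomer screen
# ---------------------------------------------------------------------------

def mirror_structure(structure: Structure) -> Structure:
    """Reflect through the x = 0 plane (negates every torsion and
    chirality sign)."""
    coords = structure.coords.copy()
    coords[:, 0] *= -1.0
    return structure.copy_with(coords)


def mirror_topology(topology: CovalentTopology) -> CovalentTopology:
    """Mirror-image topology: bond/angle terms unchanged, improper torsion
    equilibria negated (±180° maps to itself)."""
    return CovalentTopology(
        bonds=list(topology.bonds),
        angles=list(topology.angles),
        impropers=[
            ImproperTerm(atoms=im.atoms, phi0_deg=wrap_angle(-im.phi0_deg), k=im.k)
            for im in topology.impropers
        ],
        ligand_chain=topology.ligand_chain,
    )


@dataclass
class EnantiomerReport:
    lowest_noe: dict[str, list[float]]       # hand → n lowest NOE energies
    winner: str                              # "R" or "S"
    final_hands: dict[str, list[str]]        # hand → chirality label per run
    inversions: dict[str, list[int]]         # hand → run indices that flipped

    @property
    def n_inversions(self) -> int:
        return sum(len(v) for v in self.inversions.values())


def enantiomer_screen(
    restraints: RestraintSet,
    starts: dict[str, Structure],
    topologies: dict[str, CovalentTopology],
    chiral_center: ChiralCenter,
    model: EnergyModel,
    config: RefineConfig,
    n_lowest: int = 10,
    method: Literal["r6_average", "r6_sum"] = "r6_average",
) -> EnantiomerReport:
    """Run the refinement protocol once per ligand hand and compare.

    For each hand ("R", "S") a pool is generated from that hand's start
    structure and topology against the *same* experimental restraints.  The
    report lists the ``n_lowest`` NOE energies per hand, the winning hand
    (lower mean over those), and the chirality label of every final
    structure; a run whose final hand differs from its topology's hand is
    flagged as an inversion — a ligand forced through its chirality improper
    by the restraint field.
    """
    lowest: dict[str, list[float]] = {}
    hands: dict[str, list[str]] = {}
    inversions: dict[str, list[int]] = {}
    for hand in ("R", "S"):
        pool = generate_pool(
            starts[hand], restraints, topologies[hand], model, config, method
        )
        n = min(n_lowest, len(pool))
        lowest[hand] = [m.energy.noe for m in select_lowest(pool, n, key="noe")]
        labels = []
        flipped = []
        for m in pool:
            label = chirality_sign(chiral_center, m.structure)
            labels.append(label)
            if label[0] != hand:
                flipped.append(m.run_index)
        hands[hand] = labels
        inversions[hand] = flipped
    winner = "S" if np.mean(lowest["S"]) < np.mean(lowest["R"]) else "R"
    return EnantiomerReport(
        lowest_noe=lowest, winner=winner, final_hands=hands, inversions=inversions
    )
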