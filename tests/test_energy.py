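"""Energy surface and refinement: soft-square forms, analytic gradients,
minimization contracts, pool reproducibility, selection, mirror symmetry."""

import numpy as np
import pandas as pd
import pytest

from noetools.energy import (
    AngleTerm,
    BondTerm,
    CovalentTopology,
    EnergyModel,
    ImproperTerm,
    RefineConfig,
    _Objective,
    covalent_energy,
    dihedral_energy,
    ensemble_from_members,
    generate_pool,
    minimize,
    mirror_structure,
    mirror_topology,
    noe_energy,
    perturb,
    select_lowest,
    total_energy,
)
from noetools.geometry import Structure
from noetools.restraints import (
    AtomSelector,
    DihedralRestraint,
    DistanceRestraint,
    RestraintSet,
)


def _two_atom(d, chain="A"):
    atoms = pd.DataFrame(
        {
            "chain_id": chain,
            "residue_number": 1,
            "residue_name": "ALA",
            "atom_name": ["HA", "HB"],
            "element": "H",
        }
    )
    return Structure(atoms=atoms, coords=np.array([[0.0, 0, 0], [d, 0, 0]]))


def _restraint(lower=1.8, upper=3.0, chain="A"):
    return DistanceRestraint(
        selector_i=AtomSelector(chain, 1, "HA"),
        selector_j=AtomSelector(chain, 1, "HB"),
        lower_bound=lower,
        upper_bound=upper,
    )


# ---------------------------------------------------------------------------
# Soft-square restraint energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d,expected",
    [
        (2.5, 0.0),            # inside the band
        (3.5, 12.5),           # v = 0.5: 50·0.25
        (4.5, 100.0),          # v = 1.5: 50·1² + (2·50·1)·0.5 (linear branch)
        (1.3, 12.5),           # lower-bound violation, same form
    ],
)
def test_noe_energy_piecewise_values(d, expected):
    model = EnergyModel()
    assert noe_energy(_restraint(), _two_atom(d), model) == pytest.approx(expected)


def test_noe_energy_continuity_at_switch():
    """Energy and slope are continuous across the quadratic→linear switch."""
    model = EnergyModel()
    eps = 1e-7
    below = noe_energy(_restraint(), _two_atom(3.0 + 1.0 - eps), model)
    above = noe_energy(_restraint(), _two_atom(3.0 + 1.0 + eps), model)
    assert above - below == pytest.approx(0.0, abs=1e-4)
    slope_below = (
        noe_energy(_restraint(), _two_atom(4.0 - eps), model)
        - noe_energy(_restraint(), _two_atom(4.0 - 2 * eps), model)
    ) / eps
    slope_above = (
        noe_energy(_restraint(), _two_atom(4.0 + 2 * eps), model)
        - noe_energy(_restraint(), _two_atom(4.0 + eps), model)
    ) / eps
    assert slope_below == pytest.approx(slope_above, rel=1e-2)
    assert slope_above == pytest.approx(2 * 50.0 * 1.0, rel=1e-2)


# ---------------------------------------------------------------------------
# Dihedral restraint energy
# ---------------------------------------------------------------------------

def _quad_structure(angle_deg):
    coords = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 1.5, 0.0],
            [np.cos(np.radians(angle_deg)), 1.5, -np.sin(np.radians(angle_deg))],
        ]
    )
    atoms = pd.DataFrame(
        {
            "chain_id": "A",
            "residue_number": 1,
            "residue_name": "ALA",
            "atom_name": ["C", "N", "CA", "CB"],
            "element": ["C", "N", "C", "C"],
        }
    )
    return Structure(atoms=atoms, coords=coords)


def _dih_restraint(target, half=20.0):
    return DihedralRestraint(
        selectors=(
            AtomSelector("A", 1, "C"),
            AtomSelector("A", 1, "N"),
            AtomSelector("A", 1, "CA"),
            AtomSelector("A", 1, "CB"),
        ),
        target_deg=target,
        half_width_deg=half,
    )


def test_dihedral_energy_values():
    model = EnergyModel()
    s = _quad_structure(25.0)
    from noetools.geometry import dihedral_angle

    obs = dihedral_angle(*s.coords)
    # in-band restraint costs nothing
    assert dihedral_energy(_dih_restraint(obs), s, model) == 0.0
    # 5 degrees past the band: 200·(5π/180)² ≈ 1.523
    r = _dih_restraint(target=(obs - 25.0), half=20.0)
    assert dihedral_energy(r, s, model) == pytest.approx(1.5230870989, rel=1e-6)
    # a full-turn rotation of the observed geometry leaves the energy
    # unchanged (the difference is wrapped): rotate atom 4 by 360 degrees
    # about the central bond, i.e. identical coordinates
    assert dihedral_energy(r, _quad_structure(25.0 - 360.0), model) == pytest.approx(
        dihedral_energy(r, s, model)
    )


# ---------------------------------------------------------------------------
# Covalent energy and ligand scaling
# ---------------------------------------------------------------------------

def _bond_system(chain):
    atoms = pd.DataFrame(
        {
            "chain_id": chain,
            "residue_number": 1,
            "residue_name": "LIG" if chain == "L" else "ALA",
            "atom_name": ["C1", "C2"],
            "element": "C",
        }
    )
    s = Structure(atoms=atoms, coords=np.array([[0.0, 0, 0], [1.6, 0, 0]]))
    topo = CovalentTopology(
        bonds=[BondTerm(atoms=((chain, 1, "C1"), (chain, 1, "C2")), r0=1.5, k=1000.0)],
        ligand_chain="L",
    )
    return s, topo


def test_covalent_ligand_scaling():
    model = EnergyModel(ligand_scale=0.2)
    s_prot, topo_prot = _bond_system("A")
    s_lig, topo_lig = _bond_system("L")
    # 0.1 Å stretch: protein 1000·0.01 = 10; ligand scaled by 0.2 → 2
    assert covalent_energy(s_prot, topo_prot, model) == pytest.approx(10.0)
    assert covalent_energy(s_lig, topo_lig, model) == pytest.approx(2.0)


def test_covalent_zero_at_equilibrium(default_fixture, energy_model):
    assert covalent_energy(
        default_fixture.truth, default_fixture.topology, energy_model
    ) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Total energy and its breakdown
# ---------------------------------------------------------------------------

def test_total_energy_is_component_sum(default_fixture, energy_model, rng):
    noisy = default_fixture.truth.copy_with(
        default_fixture.truth.coords + rng.normal(0, 0.3, default_fixture.truth.coords.shape)
    )
    eb = total_energy(noisy, default_fixture.restraints, default_fixture.topology, energy_model)
    assert eb.total == pytest.approx(eb.noe + eb.dihedral + eb.covalent + eb.repulsion, rel=1e-12)
    # oracle loop: per-restraint energies computed one at a time sum to the component
    noe_sum = sum(
        noe_energy(r, noisy, energy_model)
        for r in default_fixture.restraints.distance_restraints
    )
    assert eb.noe == pytest.approx(noe_sum, rel=1e-9)
    empty = total_energy(noisy, RestraintSet(), default_fixture.topology, energy_model)
    assert empty.noe == 0.0 and empty.dihedral == 0.0


# ---------------------------------------------------------------------------
# Gradient oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["r6_average", "r6_sum"])
def test_analytic_gradient_matches_finite_differences(default_fixture, energy_model, method):
    """The refinement oracle: exact gradient vs central differences."""
    obj = _Objective(
        default_fixture.truth,
        default_fixture.restraints,
        default_fixture.topology,
        energy_model,
        method,
    )
    rng = np.random.default_rng(7)
    x = default_fixture.truth.coords.ravel() + rng.normal(
        0, 0.4, default_fixture.truth.coords.size
    )
    _, g = obj.value_and_grad(x)
    h = 1e-6
    for i in rng.choice(x.size, 40, replace=False):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd = (obj.value_and_grad(xp)[0] - obj.value_and_grad(xm)[0]) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-5)


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def test_minimize_leaves_satisfying_start_unchanged(default_fixture, energy_model):
    cfg = RefineConfig(max_iterations=200)
    mem = minimize(
        default_fixture.truth,
        default_fixture.restraints,
        default_fixture.topology,
        energy_model,
        cfg,
    )
    assert mem.n_iterations == 0
    assert np.array_equal(mem.structure.coords, default_fixture.truth.coords)
    assert mem.energy.total == pytest.approx(0.0, abs=1e-9)


def test_minimize_energy_trace_non_increasing(small_fixture, energy_model, rng):
    start = perturb(small_fixture.truth, 0.8, rng)
    cfg = RefineConfig(max_iterations=300)
    mem = minimize(start, small_fixture.restraints, small_fixture.topology, energy_model, cfg)
    trace = np.asarray(mem.energy_trace)
    assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1.0, trace[:-1]))
    assert trace[-1] < trace[0]


# ---------------------------------------------------------------------------
# Pool generation and selection
# ---------------------------------------------------------------------------

def test_pool_is_bitwise_reproducible(small_fixture, energy_model):
    cfg = RefineConfig(seed=11, pool_size=2, keep_n=1, max_iterations=150)
    p1 = generate_pool(
        small_fixture.starts[0], small_fixture.restraints, small_fixture.topology,
        energy_model, cfg,
    )
    p2 = generate_pool(
        small_fixture.starts[0], small_fixture.restraints, small_fixture.topology,
        energy_model, cfg,
    )
    for a, b in zip(p1, p2):
        assert a.energy.total == b.energy.total
        assert np.array_equal(a.structure.coords, b.structure.coords)


def test_select_lowest_contract(small_fixture):
    class M:
        def __init__(self, run_index, noe):
            self.run_index = run_index
            self.energy = type("E", (), {"noe": noe, "total": noe})()

    pool = [M(0, 3.0), M(1, 1.0), M(2, 2.0)]
    picked = select_lowest(pool, 2)
    assert [m.run_index for m in picked] == [1, 2]
    # ties break by run index, stably
    pool = [M(0, 1.0), M(1, 1.0), M(2, 0.5)]
    picked = select_lowest(pool, 2)
    assert [m.run_index for m in picked] == [2, 0]
    # keep_n = pool size keeps every member
    assert {m.run_index for m in select_lowest(pool, 3)} == {0, 1, 2}
    with pytest.raises(ValueError):
        select_lowest(pool, 4)


# ---------------------------------------------------------------------------
# Mirror symmetry
# ---------------------------------------------------------------------------

def test_mirror_symmetry_of_total_energy(small_fixture, energy_model, rng):
    """Reflecting coordinates, topology torsion signs, and dihedral targets
    leaves every energy component unchanged."""
    noisy = perturb(small_fixture.truth, 0.5, rng)
    eb = total_energy(noisy, small_fixture.restraints, small_fixture.topology, energy_model)
    mirrored = mirror_structure(noisy)
    m_topo = mirror_topology(small_fixture.topology)
    m_restraints = RestraintSet(
        distance_restraints=small_fixture.restraints.distance_restraints,
        dihedral_restraints=[
            DihedralRestraint(
                selectors=d.selectors,
                target_deg=(-d.target_deg if d.target_deg != 180.0 else 180.0),
                half_width_deg=d.half_width_deg,
                angle_name=d.angle_name,
            )
            for d in small_fixture.restraints.dihedral_restraints
        ],
    )
    eb_m = total_energy(mirrored, m_restraints, m_topo, energy_model)
    assert eb_m.noe == pytest.approx(eb.noe, rel=1e-9, abs=1e-9)
    assert eb_m.dihedral == pytest.approx(eb.dihedral, rel=1e-9, abs=1e-9)
    assert eb_m.covalent == pytest.approx(eb.covalent, rel=1e-9, abs=1e-9)
    assert eb_m.repulsion == pytest.approx(eb.repulsion, rel=1e-9, abs=1e-9)
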