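"""Geometry primitives: selector expansion, r⁻⁶ effective distances,
torsions, chirality, superposition, ensemble RMSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noetools.geometry import (
    BACKBONE_ATOMS,
    ChiralCenter,
    Ensemble,
    GeometryError,
    Selection,
    SelectorError,
    Structure,
    chirality_sign,
    dihedral_angle,
    dihedral_violation,
    distance_violation,
    effective_distance,
    expand_pair,
    mean_pairwise_rmsd,
    superpose,
    wrap_angle,
)
from noetools.geometry import _kabsch
from noetools.restraints import AtomSelector, DihedralRestraint, DistanceRestraint


def _structure(names, coords, chain="A", resnum=1, resname="LEU"):
    atoms = pd.DataFrame(
        {
            "chain_id": chain,
            "residue_number": resnum,
            "residue_name": resname,
            "atom_name": names,
            "element": [("H" if n.startswith("H") else n[0]) for n in names],
        }
    )
    return Structure(atoms=atoms, coords=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# Selector expansion
# ---------------------------------------------------------------------------

def test_expand_pair_cartesian_product():
    s = _structure(
        ["HD11", "HD12", "HD13", "HM1"],
        [[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 0, 0]],
    )
    pairs = expand_pair(
        AtomSelector("A", 1, "HD1*"), AtomSelector("A", 1, "HM1"), s
    )
    assert pairs == [(0, 3), (1, 3), (2, 3)]
    exact = expand_pair(AtomSelector("A", 1, "HD11"), AtomSelector("A", 1, "HM1"), s)
    assert exact == [(0, 3)]


def test_expand_pair_counts_multiply():
    names = [f"HG{i}" for i in range(1, 7)] + [f"HM{i}" for i in range(1, 4)]
    coords = [[i, 0, 0] for i in range(9)]
    s = _structure(names, coords)
    pairs = expand_pair(AtomSelector("A", 1, "HG*"), AtomSelector("A", 1, "HM*"), s)
    assert len(pairs) == 18


def test_expand_pair_zero_match_names_selector():
    s = _structure(["HA"], [[0, 0, 0]])
    with pytest.raises(SelectorError, match="HZ"):
        expand_pair(AtomSelector("A", 1, "HZ*"), AtomSelector("A", 1, "HA"), s)


def test_amide_proton_name_alias():
    s = _structure(["H"], [[0, 0, 0]])
    assert s.select(AtomSelector("A", 1, "HN")) == [0]


# ---------------------------------------------------------------------------
# Effective distances
# ---------------------------------------------------------------------------

def _pair_structure(distances):
    names = [f"HX{i}" for i in range(len(distances))] + ["HY1"]
    coords = [[d, 0, 0] for d in distances] + [[0, 0, 0]]
    return _structure(names, coords), [(i, len(distances)) for i in range(len(distances))]


def test_single_pair_equals_plain_distance():
    s, pairs = _pair_structure([3.30])
    assert effective_distance(pairs, s, "r6_average") == pytest.approx(3.30)
    assert effective_distance(pairs, s, "r6_sum") == pytest.approx(3.30)


def test_two_pair_frozen_oracle():
    # independently evaluated: ((2⁻⁶+4⁻⁶)/2)^(-1/6) and (2⁻⁶+4⁻⁶)^(-1/6)
    s, pairs = _pair_structure([2.0, 4.0])
    assert effective_distance(pairs, s, "r6_average") == pytest.approx(
        2.2391306314306676, abs=1e-12
    )
    assert effective_distance(pairs, s, "r6_sum") == pytest.approx(
        1.9948386092903505, abs=1e-12
    )


def test_identical_distances_closed_form():
    d, n = 3.1, 5
    s = _structure(
        [f"HX{i}" for i in range(n)] + ["HY1"],
        [[d * np.cos(2 * np.pi * i / n), d * np.sin(2 * np.pi * i / n), 0.0] for i in range(n)]
        + [[0, 0, 0]],
    )
    pairs = [(i, n) for i in range(n)]
    assert effective_distance(pairs, s, "r6_average") == pytest.approx(d)
    assert effective_distance(pairs, s, "r6_sum") == pytest.approx(d * n ** (-1 / 6))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    ds=st.lists(st.floats(min_value=1.5, max_value=8.0), min_size=1, max_size=6),
    scale=st.floats(min_value=0.5, max_value=2.0),
)
def test_r6_identities_and_oracle(ds, scale):
    """Naive high-precision oracle plus the N^(1/6) closed form, the
    min/max bracketing, and monotonicity under uniform scaling."""
    s, pairs = _pair_structure(ds)
    avg = effective_distance(pairs, s, "r6_average")
    tot = effective_distance(pairs, s, "r6_sum")
    n = len(ds)
    # independent oracle: direct evaluation at high precision
    oracle_avg = float(np.mean([d ** -6.0 for d in ds])) ** (-1 / 6)
    oracle_sum = float(np.sum([d ** -6.0 for d in ds])) ** (-1 / 6)
    assert avg == pytest.approx(oracle_avg, rel=1e-9)
    assert tot == pytest.approx(oracle_sum, rel=1e-9)
    assert avg == pytest.approx(n ** (1 / 6) * tot, rel=1e-12)
    assert tot <= avg + 1e-12
    assert tot <= min(ds) + 1e-9          # the summed form is contact-biased
    assert avg <= max(ds) + 1e-9
    # uniform scaling multiplies both results by the scale
    s2, pairs2 = _pair_structure([scale * d for d in ds])
    assert effective_distance(pairs2, s2, "r6_average") == pytest.approx(scale * avg, rel=1e-9)
    assert effective_distance(pairs2, s2, "r6_sum") == pytest.approx(scale * tot, rel=1e-9)


def test_coincident_atoms_rejected():
    s = _structure(["HA", "HB"], [[0, 0, 0], [0, 0, 0]])
    with pytest.raises(GeometryError):
        effective_distance([(0, 1)], s)


@pytest.mark.parametrize(
    "d_eff,lower,upper,expected",
    [(3.5, 1.8, 3.3, 0.2), (3.0, 1.8, 4.5, 0.0), (1.6, 1.8, 4.5, 0.2)],
)
def test_distance_violation_arithmetic(d_eff, lower, upper, expected):
    s = _structure(["HA", "HB"], [[0, 0, 0], [d_eff, 0, 0]])
    r = DistanceRestraint(
        selector_i=AtomSelector("A", 1, "HA"),
        selector_j=AtomSelector("A", 1, "HB"),
        lower_bound=lower,
        upper_bound=upper,
    )
    assert distance_violation(r, s) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def test_dihedral_cis_trans():
    assert dihedral_angle((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)
    assert dihedral_angle((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_dihedral_mirror_negates(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 3
    try:
        a = dihedral_angle(*pts)
    except GeometryError:
        return
    mirrored = pts.copy()
    mirrored[:, 0] *= -1
    b = dihedral_angle(*mirrored)
    assert wrap_angle(a + b) == pytest.approx(0.0, abs=1e-6)


def test_dihedral_collinear_rejected():
    with pytest.raises(GeometryError):
        dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def _dih_structure(angle_deg):
    coords = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 1.5, 0.0],
            [np.cos(np.radians(angle_deg)), 1.5, np.sin(np.radians(angle_deg))],
        ]
    )
    # adjust p4 so torsion(p1..p4) = angle_deg
    got = dihedral_angle(*coords)
    if not np.isclose(got, angle_deg, atol=1e-6):
        coords[3, 2] *= -1
    return _structure(["C", "N", "CA", "C2"], coords)


@pytest.mark.parametrize(
    "target,observed,half,expected",
    [(170.0, -175.0, 20.0, 0.0), (0.0, 25.0, 20.0, 5.0)],
)
def test_dihedral_violation_wraps(target, observed, half, expected):
    s = _dih_structure(observed)
    r = DihedralRestraint(
        selectors=(
            AtomSelector("A", 1, "C"),
            AtomSelector("A", 1, "N"),
            AtomSelector("A", 1, "CA"),
            AtomSelector("A", 1, "C2"),
        ),
        target_deg=target,
        half_width_deg=half,
    )
    assert dihedral_violation(r, s) == pytest.approx(expected, abs=1e-6)


def test_wrap_invariance_under_full_turns():
    assert wrap_angle(25.0 + 360.0) == pytest.approx(25.0)
    assert wrap_angle(-175.0 - 360.0) == pytest.approx(-175.0)
    assert wrap_angle(180.0) == 180.0
    assert wrap_angle(-180.0) == 180.0


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------

def _chiral_structure(flip=False):
    r4 = -np.ones(3) / np.sqrt(3.0)
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], r4])
    if flip:
        coords = coords * np.array([-1.0, 1.0, 1.0])
    return _structure(["C1", "S1", "S2", "S3", "S4"], coords)


def _center():
    return ChiralCenter(
        center=AtomSelector("A", 1, "C1"),
        substituents=tuple(AtomSelector("A", 1, f"S{i}") for i in (1, 2, 3, 4)),
    )


def test_chirality_hand_and_mirror():
    # substituents at +x, +y, +z with the lowest priority at −(1,1,1)/√3:
    # positive triple product → S_like (evaluated by hand)
    assert chirality_sign(_center(), _chiral_structure()) == "S_like"
    assert chirality_sign(_center(), _chiral_structure(flip=True)) == "R_like"


def test_planar_center_rejected():
    s = _structure(
        ["C1", "S1", "S2", "S3", "S4"],
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]],
    )
    with pytest.raises(GeometryError):
        chirality_sign(_center(), s)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_chirality_rigid_motion_invariant(seed):
    rng = np.random.default_rng(seed)
    s = _chiral_structure()
    # random proper rotation + translation
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = s.copy_with(s.coords @ R.T + rng.normal(size=3) * 10)
    assert chirality_sign(_center(), moved) == chirality_sign(_center(), s)


# ---------------------------------------------------------------------------
# Superposition and ensemble RMSD
# ---------------------------------------------------------------------------

def _backbone_structure(rng, n_res=6, jitter=0.0):
    names, coords, resnums = [], [], []
    for i in range(n_res):
        for j, n in enumerate(BACKBONE_ATOMS):
            names.append(n)
            resnums.append(i + 1)
            coords.append([3.0 * i + 0.5 * j, (i % 3) * 1.2, 0.7 * j + 0.3 * i])
    coords = np.asarray(coords) + (jitter * rng.normal(size=(len(names), 3)) if jitter else 0.0)
    atoms = pd.DataFrame(
        {
            "chain_id": "A",
            "residue_number": resnums,
            "residue_name": "ALA",
            "atom_name": names,
            "element": [n[0] for n in names],
        }
    )
    return Structure(atoms=atoms, coords=coords)


def _rigid(rng, s):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return s.copy_with(s.coords @ R.T + rng.normal(size=3) * 5)


def test_superpose_recovers_rigid_copy(rng):
    s = _backbone_structure(rng)
    moved = _rigid(rng, s)
    sel = Selection(ranges={"A": [(1, 6)]})
    R, t, rmsd = superpose(moved, s, sel)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_superpose_symmetric_and_proper(rng):
    a = _backbone_structure(rng, jitter=0.3)
    b = _backbone_structure(rng, jitter=0.3)
    sel = Selection(ranges={"A": [(1, 6)]})
    Rab, _, r_ab = superpose(a, b, sel)
    Rba, _, r_ba = superpose(b, a, sel)
    assert r_ab == pytest.approx(r_ba, rel=1e-9)
    assert np.linalg.det(Rab) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_two_point_by_hand():
    # centred sets {(-1,0,0),(1,0,0)} vs {(-2,0,0),(2,0,0)} leave residuals
    # of 1 at both atoms
    P = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    Q = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    _, _, rmsd = _kabsch(P, Q)
    assert rmsd == pytest.approx(1.0)


def test_superpose_against_independent_svd_oracle(rng):
    from Bio.SVDSuperimposer import SVDSuperimposer

    a = _backbone_structure(rng, jitter=0.4)
    b = _backbone_structure(rng, jitter=0.4)
    sel = Selection(ranges={"A": [(1, 6)]})
    _, _, rmsd = superpose(a, b, sel)
    idx = sel.resolve(a)
    sup = SVDSuperimposer()
    sup.set(b.coords[idx], a.coords[idx])
    sup.run()
    assert rmsd == pytest.approx(sup.get_rms(), abs=1e-9)


def test_superpose_atom_mismatch_reported(rng):
    a = _backbone_structure(rng)
    atoms = a.atoms.copy()
    atoms.loc[0, "atom_name"] = "NZ"
    b = Structure(atoms=atoms, coords=a.coords)
    with pytest.raises(ValueError, match="mismatch"):
        superpose(a, b, Selection(ranges={"A": [(1, 6)]}, atom_names=None))


def test_mean_pairwise_rmsd_identical_and_two_model(rng):
    s = _backbone_structure(rng)
    sel = Selection(ranges={"A": [(1, 6)]})
    ens = Ensemble(models=[s, s.copy_with(s.coords, model_id=2)])
    assert mean_pairwise_rmsd(ens, sel) == pytest.approx(0.0, abs=1e-12)
    noisy = s.copy_with(s.coords + rng.normal(0, 0.4, s.coords.shape), model_id=2)
    ens2 = Ensemble(models=[s, noisy])
    _, _, pair_rmsd = superpose(s, noisy, sel)
    assert mean_pairwise_rmsd(ens2, sel) == pytest.approx(pair_rmsd)


def test_mean_pairwise_rmsd_is_pair_average(rng):
    s = _backbone_structure(rng)
    sel = Selection(ranges={"A": [(1, 6)]})
    models = [s] + [
        s.copy_with(s.coords + rng.normal(0, sd, s.coords.shape), model_id=k + 2)
        for k, sd in enumerate((0.2, 0.5))
    ]
    ens = Ensemble(models=models)
    pair_vals = [
        superpose(models[i], models[j], sel)[2]
        for i in range(3)
        for j in range(i + 1, 3)
    ]
    assert mean_pairwise_rmsd(ens, sel) == pytest.approx(np.mean(pair_vals))


def test_selection_parse_round_trip():
    sel = Selection.parse("A:10-31,47-176@backbone")
    assert sel.ranges == {"A": [(10, 31), (47, 176)]}
    assert sel.atom_names == BACKBONE_ATOMS
    heavy = Selection.parse("L:1@heavy")
    assert heavy.atom_names == "heavy"
    with pytest.raises(ValueError):
        Selection(ranges={"A": [(1, 10), (5, 20)]})
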