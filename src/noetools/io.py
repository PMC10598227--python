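"""Structure file I/O (multi-model PDB, mmCIF read), topology files,
fixture export, and packaged reference tables.

PDB is the primary coordinate dialect (deposited NMR ensembles are
multi-model PDB); mmCIF is read-only.  Parsing and writing go through
gemmi; this module adapts between gemmi's hierarchy and the flat atom
table used throughout the package.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np
import pandas as pd

from . import restraints as _restraints
from .energy import AngleTerm, BondTerm, CovalentTopology, ImproperTerm
from .geometry import Ensemble, Structure

__all__ = [
    "read_structure",
    "write_structure",
    "write_topology",
    "read_topology",
    "write_fixture",
    "load_intermolecular_table",
    "load_count_manifest",
]

#: PDB fixed-width coordinate field limit, Å.
_PDB_COORD_LIMIT = 9999.999


def _structure_from_gemmi_model(model: gemmi.Model, model_id: int) -> Structure:
    rows = []
    coords = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.element.name.upper(),
                    )
                )
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    atoms = pd.DataFrame(
        rows,
        columns=["chain_id", "residue_number", "residue_name", "atom_name", "element"],
    )
    return Structure(atoms=atoms, coords=np.asarray(coords), model_id=model_id)


def read_structure(
    path: str | Path, format: Literal["pdb", "mmcif", "auto"] = "auto"
) -> Ensemble:
    """Read a (multi-model) coordinate file into an Ensemble.

    One Structure per MODEL record (a single implicit model if none);
    HETATM ligand atoms are retained with their chain/residue identity.
    Raises if the models' atom identity sequences disagree (the error names
    the first offending model).
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FileNotFoundError(f"missing or empty coordinate file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format: {format!r}")
    st = gemmi.read_structure(str(path), format=fmt)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    models = []
    for i, model in enumerate(st, start=1):
        models.append(_structure_from_gemmi_model(model, model_id=i))
    ref = models[0].identity()
    for m in models[1:]:
        if m.identity() != ref:
            raise ValueError(
                f"model {m.model_id} atom table differs from model 1 in {path}"
            )
    return Ensemble(models=models)


def write_structure(
    ensemble: Ensemble | Structure,
    path: str | Path,
    format: Literal["pdb"] = "pdb",
) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks).

    Round-trip through :func:`read_structure` reproduces identities exactly
    and coordinates to 3 decimals (PDB fixed width).  Coordinates beyond
    the fixed-width field limit raise.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if isinstance(ensemble, Structure):
        ensemble = Ensemble(models=[ensemble])
    for m in ensemble:
        if np.any(np.abs(m.coords) > _PDB_COORD_LIMIT):
            raise ValueError("coordinates exceed the PDB fixed-width limit")
    st = gemmi.Structure()
    st.name = "noetools"
    for m in ensemble:
        model = gemmi.Model(m.model_id)
        chain_map: dict[str, gemmi.Chain] = {}
        at = m.atoms
        for i in range(len(at)):
            chain_id = at.at[i, "chain_id"]
            if chain_id not in chain_map:
                chain_map[chain_id] = gemmi.Chain(chain_id)
            chain = chain_map[chain_id]
            resnum = int(at.at[i, "residue_number"])
            resname = at.at[i, "residue_name"]
            if (
                len(chain) == 0
                or chain[-1].seqid.num != resnum
                or chain[-1].name != resname
            ):
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = at.at[i, "atom_name"]
            atom.element = gemmi.Element(at.at[i, "element"])
            x, y, z = m.coords[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            chain[-1].add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Topology files (columnar text)
# ---------------------------------------------------------------------------

def write_topology(topology: CovalentTopology, path: str | Path) -> None:
    """Columnar text: BOND/ANGLE/IMPROPER records with chain-qualified
    atoms, equilibrium value, and force constant."""
    lines = [f"# noetools topology; ligand_chain={topology.ligand_chain}"]

    def fmt(key):
        return f"{key[0]} {key[1]} {key[2]}"

    for b in topology.bonds:
        lines.append(f"BOND {fmt(b.atoms[0])} {fmt(b.atoms[1])} {b.r0:.6f} {b.k:g}")
    for a in topology.angles:
        lines.append(
            "ANGLE "
            + " ".join(fmt(k) for k in a.atoms)
            + f" {a.theta0_deg:.6f} {a.k:g}"
        )
    for im in topology.impropers:
        lines.append(
            "IMPROPER "
            + " ".join(fmt(k) for k in im.atoms)
            + f" {im.phi0_deg:.6f} {im.k:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path: str | Path) -> CovalentTopology:
    ligand_chain = "L"
    bonds, angles, impropers = [], [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("#"):
            if "ligand_chain=" in line:
                ligand_chain = line.split("ligand_chain=")[1].strip()
            continue
        if not line:
            continue
        parts = line.split()
        kind = parts[0]
        n_atoms = {"BOND": 2, "ANGLE": 3, "IMPROPER": 4}[kind]
        keys = tuple(
            (parts[1 + 3 * i], int(parts[2 + 3 * i]), parts[3 + 3 * i])
            for i in range(n_atoms)
        )
        eq, k = float(parts[1 + 3 * n_atoms]), float(parts[2 + 3 * n_atoms])
        if kind == "BOND":
            bonds.append(BondTerm(atoms=keys, r0=eq, k=k))
        elif kind == "ANGLE":
            angles.append(AngleTerm(atoms=keys, theta0_deg=eq, k=k))
        else:
            impropers.append(ImproperTerm(atoms=keys, phi0_deg=eq, k=k))
    return CovalentTopology(
        bonds=bonds, angles=angles, impropers=impropers, ligand_chain=ligand_chain
    )


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_fixture(fixture, outdir: str | Path) -> None:
    """Write a fixture as multi-model PDB (truth + starts), a CNS-dialect
    restraint table, a dihedral TSV, a topology file, and a config echo."""
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = [fixture.truth.copy_with(fixture.truth.coords, model_id=1)]
    for i, s in enumerate(fixture.starts, start=2):
        models.append(s.copy_with(s.coords, model_id=i))
    write_structure(Ensemble(models=models), outdir / "fixture.pdb")
    (outdir / "restraints.tbl").write_text(
        _restraints.write_distance_table(fixture.restraints, dialect="cns_tbl")
    )
    dih_lines = ["# resnum\tangle\ttarget_deg\thalf_width_deg"]
    for d in fixture.restraints.dihedral_restraints:
        resnum = d.selectors[2].residue_number if d.angle_name == "phi" else d.selectors[1].residue_number
        dih_lines.append(
            f"{resnum}\t{d.angle_name}\t{d.target_deg:.3f}\t{d.half_width_deg:.3f}"
        )
    (outdir / "dihedrals.tsv").write_text("\n".join(dih_lines) + "\n")
    write_topology(fixture.topology, outdir / "topology.txt")
    from . import __version__

    echo = {"tool": "noetools", "version": __version__}
    echo.update(asdict(fixture.config))
    echo["manifest"] = fixture.manifest
    echo["pocket_residues"] = fixture.pocket_residues
    (outdir / "config.json").write_text(json.dumps(echo, indent=2, default=int) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def load_intermolecular_table() -> str:
    """The transcribed intermolecular distance-restraint table (TSV dialect)."""
    return (
        resources.files("noetools").joinpath("data/intermolecular_restraints.tsv").read_text()
    )


def load_count_manifest() -> dict[str, int]:
    """Published per-category restraint counts for the accounting check."""
    text = resources.files("noetools").joinpath("data/restraint_count_manifest.json").read_text()
    return json.loads(text)
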