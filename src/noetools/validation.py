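"""Ensemble-level validation: violation reports under both r⁻⁶ conventions,
region RMSD tables, and ligand contact-site overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Ensemble,
    Selection,
    SelectorError,
    Structure,
    dihedral_violation,
    distance_violation,
    mean_pairwise_rmsd,
)
from .restraints import RestraintSet

logger = logging.getLogger(__name__)

__all__ = [
    "ViolationReport",
    "ContactSite",
    "violation_report",
    "region_rmsd_table",
    "contact_residues",
    "site_overlap",
]

#: Reporting thresholds: distance (Å) and dihedral (degrees).
DEFAULT_THRESHOLDS = (0.2, 2.0)


@dataclass
class ViolationReport:
    """Per-restraint × per-model violations under both averaging conventions.

    ``distance_matrix[conv]`` has shape (n_restraints, n_models) in Å;
    ``dihedral_matrix`` is (n_dihedrals, n_models) in degrees.  The ensemble
    mean/sd statistics follow the convention of averaging within each model
    first, then taking mean and sd over the per-model means (configurable
    via ``stat_over_cells`` at build time).
    """

    distance_matrix: dict[str, np.ndarray]
    dihedral_matrix: np.ndarray
    per_model_mean: dict[str, np.ndarray]
    ensemble_mean: dict[str, float]
    ensemble_sd: dict[str, float]
    max_violation: dict[str, float]
    count_above: dict[str, int]
    dihedral_per_model_mean: np.ndarray
    dihedral_ensemble_mean: float
    dihedral_ensemble_sd: float
    dihedral_max: float
    dihedral_count_above: int
    thresholds: tuple[float, float]
    skipped: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["convention\tstat\tvalue"]
        for conv in ("r6_average", "r6_sum"):
            lines.append(f"{conv}\tmean\t{self.ensemble_mean[conv]:.6g}")
            lines.append(f"{conv}\tsd\t{self.ensemble_sd[conv]:.6g}")
            lines.append(f"{conv}\tmax\t{self.max_violation[conv]:.6g}")
            lines.append(
                f"{conv}\tcount_above_{self.thresholds[0]}A\t{self.count_above[conv]}"
            )
        lines.append(f"dihedral\tmean\t{self.dihedral_ensemble_mean:.6g}")
        lines.append(f"dihedral\tsd\t{self.dihedral_ensemble_sd:.6g}")
        lines.append(f"dihedral\tmax\t{self.dihedral_max:.6g}")
        lines.append(
            f"dihedral\tcount_above_{self.thresholds[1]}deg\t{self.dihedral_count_above}"
        )
        for s in self.skipped:
            lines.append(f"skipped\trestraint\t{s}")
        return "\n".join(lines) + "\n"


def violation_report(
    ensemble: Ensemble,
    restraints: RestraintSet,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    stat_over_cells: bool = False,
) -> ViolationReport:
    """Evaluate every restraint on every model under both conventions.

    Restraints whose selectors cannot be resolved on the ensemble's atom
    table are collected in ``skipped`` (deposited restraint files use
    varying pseudoatom dialects) rather than failing the whole report.

    The headline "mean ± sd" is over the per-model mean violations by
    default; ``stat_over_cells=True`` switches to mean/sd over all
    restraint × model cells.
    """
    from .energy import _compile_distances

    n_models = len(ensemble)
    usable = []
    skipped: list[str] = []
    for r in restraints.distance_restraints:
        try:
            distance_violation(r, ensemble[0])
            usable.append(r)
        except SelectorError as exc:
            skipped.append(str(exc))
            logger.warning("skipping unresolvable restraint: %s", exc)
    # selector expansion once per convention; violations vectorized per model
    tables = {
        conv: _compile_distances(usable, ensemble[0], conv)
        for conv in ("r6_average", "r6_sum")
    }
    dist_mat = {
        conv: np.zeros((len(usable), n_models)) for conv in ("r6_average", "r6_sum")
    }
    for j, model in enumerate(ensemble):
        for conv, tab in tables.items():
            if tab.n_terms == 0:
                continue
            d_eff = tab.effective_distances(model.coords)
            dist_mat[conv][:, j] = np.maximum(
                0.0, np.maximum(d_eff - tab.upper, tab.lower - d_eff)
            )

    usable_dih = []
    for r in restraints.dihedral_restraints:
        try:
            dihedral_violation(r, ensemble[0])
            usable_dih.append(r)
        except SelectorError as exc:
            skipped.append(str(exc))
            logger.warning("skipping unresolvable dihedral restraint: %s", exc)
    dih_mat = np.zeros((len(usable_dih), n_models))
    for j, model in enumerate(ensemble):
        for i, r in enumerate(usable_dih):
            dih_mat[i, j] = dihedral_violation(r, model)

    def stats(mat: np.ndarray) -> tuple[np.ndarray, float, float, float]:
        if mat.size == 0:
            return np.zeros(n_models), 0.0, 0.0, 0.0
        per_model = mat.mean(axis=0)
        pool = mat.ravel() if stat_over_cells else per_model
        return per_model, float(np.mean(pool)), float(np.std(pool, ddof=1) if len(pool) > 1 else 0.0), float(mat.max())

    per_model_mean, ens_mean, ens_sd, vmax = {}, {}, {}, {}
    count_above = {}
    for conv in ("r6_average", "r6_sum"):
        pm, m, s, mx = stats(dist_mat[conv])
        per_model_mean[conv] = pm
        ens_mean[conv] = m
        ens_sd[conv] = s
        vmax[conv] = mx
        count_above[conv] = int(np.sum(dist_mat[conv] > thresholds[0]))
    dpm, dmean, dsd, dmax = stats(dih_mat)
    return ViolationReport(
        distance_matrix=dist_mat,
        dihedral_matrix=dih_mat,
        per_model_mean=per_model_mean,
        ensemble_mean=ens_mean,
        ensemble_sd=ens_sd,
        max_violation=vmax,
        count_above=count_above,
        dihedral_per_model_mean=dpm,
        dihedral_ensemble_mean=dmean,
        dihedral_ensemble_sd=dsd,
        dihedral_max=dmax,
        dihedral_count_above=int(np.sum(dih_mat > thresholds[1])),
        thresholds=thresholds,
        skipped=skipped,
    )


def region_rmsd_table(
    ensemble: Ensemble, selections: dict[str, Selection]
) -> pd.DataFrame:
    """Mean pairwise backbone and heavy-atom RMSD per named selection."""
    if len(ensemble) < 2:
        raise ValueError("region RMSD needs at least 2 models")
    rows = []
    for name, sel in selections.items():
        if not sel.resolve(ensemble[0]):
            raise ValueError(f"selection {name!r} matches no atoms")
        backbone = Selection(ranges=sel.ranges, atom_names=sel.atom_names)
        heavy = Selection(ranges=sel.ranges, atom_names="heavy")
        rows.append(
            {
                "name": name,
                "backbone_rmsd": mean_pairwise_rmsd(ensemble, backbone),
                "heavy_rmsd": mean_pairwise_rmsd(ensemble, heavy),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContactSite:
    """Residues with any heavy atom within ``cutoff`` of the ligand."""

    residues: frozenset[tuple[str, int, str]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.residues)

    def residue_numbers(self) -> list[int]:
        return sorted(r[1] for r in self.residues)


def contact_residues(
    structure: Structure,
    ligand_selection: Selection,
    cutoff: float = 4.5,
) -> ContactSite:
    """Heavy-atom contact map: residues (outside the ligand selection) with
    any non-hydrogen atom within ``cutoff`` Å of any ligand heavy atom."""
    lig_sel = Selection(ranges=ligand_selection.ranges, atom_names="heavy")
    lig_idx = lig_sel.resolve(structure)
    if not lig_idx:
        raise ValueError("ligand selection matches no atoms")
    at = structure.atoms
    heavy_idx = np.flatnonzero((at["element"] != "H").to_numpy())
    heavy_idx = np.setdiff1d(heavy_idx, np.asarray(lig_idx))
    lig_coords = structure.coords[lig_idx]
    other = structure.coords[heavy_idx]
    d = np.linalg.norm(other[:, None, :] - lig_coords[None, :, :], axis=2)
    close = heavy_idx[np.any(d <= cutoff, axis=1)]
    residues = frozenset(
        (at.at[i, "chain_id"], int(at.at[i, "residue_number"]), at.at[i, "residue_name"])
        for i in close
    )
    return ContactSite(residues=residues, cutoff=cutoff)


def site_overlap(site_a: ContactSite, site_b: ContactSite) -> tuple[float, float]:
    """Jaccard overlap and the fraction of A not shared with B.

    Returns ``(|A∩B|/|A∪B|, |A∖B|/|A|)``; raises if both sites are empty.
    """
    a, b = set(site_a.residues), set(site_b.residues)
    if not a and not b:
        raise ValueError("both contact sites are empty")
    jaccard = len(a & b) / len(a | b)
    frac_a_unique = len(a - b) / len(a) if a else 0.0
    return jaccard, frac_a_unique
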