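"""Ensemble statistics: pairwise RMSD, pass fractions and S1 occupancy.

Binding modes passing the geometric criteria tend to form a tight structural
cluster around the productive placement, whereas discarded modes scatter
over the docking box. This module quantifies that contrast: pairwise RMSD is
computed over backbone heavy atoms (N, CA, C, O) in the shared receptor
frame *without* superposition — the placement relative to the catalytic site
is exactly what is being compared, so superposing first would erase it.

The two within-group pairwise-RMSD samples are compared with a two-sided
Mann–Whitney U test by default. Because pairwise distances are not mutually
independent, a label-permutation alternative is offered (pose labels are
permuted, within-group pairwise means recomputed); the report always names
the method used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import ComparisonError, EmptyInputError, ValidationError
from .pose_evaluation import PoseEvaluation
from .site_enumeration import CleavageCandidate, SpecificityRules
from .structure_io import BACKBONE_ATOMS, PeptidePose, PoseSet

__all__ = [
    "GroupComparison",
    "EnsembleSummary",
    "pairwise_rmsd",
    "rmsd_matrix",
    "summarize_ensemble",
    "site_ranking",
]


@dataclass(frozen=True)
class GroupComparison:
    """Selected-vs-discarded RMSD comparison: statistic, p-value, method."""

    method: str
    statistic: float
    p_value: float
    mean_selected: float
    mean_discarded: float


@dataclass
class EnsembleSummary:
    """Per-peptide ensemble summary mirroring the pass-fraction bar charts."""

    peptide_label: str
    n_total: int
    n_selected: int
    occupancy_counts: dict[int, int] = field(default_factory=dict)
    occupancy_residues: dict[int, str] = field(default_factory=dict)
    rmsd_selected: list[float] = field(default_factory=list)
    rmsd_discarded: list[float] = field(default_factory=list)
    group_comparison: GroupComparison | None = None

    @property
    def pass_fraction_percent(self) -> float:
        return 100.0 * self.n_selected / self.n_total if self.n_total else 0.0


def _scoped_coords(pose: PeptidePose, atom_scope: str) -> dict[tuple[int, str], np.ndarray]:
    if atom_scope == "backbone":
        keep = set(BACKBONE_ATOMS)
        return {
            (a.residue_number, a.name): a.xyz()
            for a in pose.atoms
            if a.name in keep
        }
    if atom_scope == "heavy":
        return {(a.residue_number, a.name): a.xyz() for a in pose.atoms}
    raise ValidationError(f"unknown atom scope {atom_scope!r}")


def pairwise_rmsd(
    pose_a: PeptidePose, pose_b: PeptidePose, atom_scope: str = "backbone"
) -> float:
    """RMSD (Å) over matched atoms in the shared frame, no superposition."""
    if pose_a.peptide_label != pose_b.peptide_label:
        raise ComparisonError(
            f"cannot compare poses of different peptides "
            f"({pose_a.peptide_label!r} vs {pose_b.peptide_label!r})"
        )
    ca = _scoped_coords(pose_a, atom_scope)
    cb = _scoped_coords(pose_b, atom_scope)
    if set(ca) != set(cb):
        missing = sorted(set(ca) ^ set(cb))
        raise ComparisonError(f"atom sets differ; unmatched atoms: {missing}")
    keys = sorted(ca)
    xa = np.asarray([ca[k] for k in keys])
    xb = np.asarray([cb[k] for k in keys])
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def rmsd_matrix(poses: Sequence[PeptidePose], atom_scope: str = "backbone") -> np.ndarray:
    """Full symmetric pairwise-RMSD matrix for an ensemble (vectorised)."""
    if not poses:
        raise EmptyInputError("rmsd_matrix requires at least one pose")
    key_sets = [_scoped_coords(p, atom_scope) for p in poses]
    keys = sorted(key_sets[0])
    for i, ks in enumerate(key_sets[1:], start=1):
        if sorted(ks) != keys:
            raise ComparisonError(
                f"pose {poses[i].pose_id}: atom set differs from first pose"
            )
    coords = np.asarray([[ks[k] for k in keys] for ks in key_sets])  # (n, m, 3)
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))


def _within_group(matrix: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub[iu]


def summarize_ensemble(
    evaluations: Sequence[PoseEvaluation],
    poses: PoseSet,
    test: str = "mann_whitney",
    n_permutations: int = 1000,
    seed: int | None = None,
    atom_scope: str = "backbone",
) -> EnsembleSummary:
    """Summarise one ensemble: pass fraction, S1 occupancy, RMSD contrast.

    A group with fewer than two members yields an empty RMSD list; the group
    comparison is null unless both groups have at least two pairwise values.
    """
    if len(evaluations) != len(poses):
        raise ValidationError(
            f"{len(evaluations)} evaluations for {len(poses)} poses"
        )
    selected_mask = np.asarray([ev.selected for ev in evaluations], dtype=bool)
    n_total = len(poses)
    n_selected = int(selected_mask.sum())

    occupancy: dict[int, int] = {}
    occupancy_res: dict[int, str] = {}
    for ev in evaluations:
        if ev.selected and ev.s1_occupant is not None:
            occupancy[ev.s1_occupant] = occupancy.get(ev.s1_occupant, 0) + 1
            for row in ev.per_residue_detail:
                if row["residue_number"] == ev.s1_occupant:
                    occupancy_res[ev.s1_occupant] = row["residue"]

    matrix = rmsd_matrix(poses.poses, atom_scope=atom_scope)
    sel_idx = np.flatnonzero(selected_mask)
    dis_idx = np.flatnonzero(~selected_mask)
    rmsd_sel = _within_group(matrix, sel_idx) if len(sel_idx) >= 2 else np.array([])
    rmsd_dis = _within_group(matrix, dis_idx) if len(dis_idx) >= 2 else np.array([])

    comparison = None
    if len(rmsd_sel) >= 2 and len(rmsd_dis) >= 2:
        if test == "mann_whitney":
            stat, p = mannwhitneyu(rmsd_sel, rmsd_dis, alternative="two-sided")
            comparison = GroupComparison(
                method="Mann-Whitney U (two-sided)",
                statistic=float(stat),
                p_value=float(p),
                mean_selected=float(rmsd_sel.mean()),
                mean_discarded=float(rmsd_dis.mean()),
            )
        elif test == "permutation":
            comparison = _permutation_comparison(
                matrix, selected_mask, n_permutations, seed
            )
        else:
            raise ValidationError(f"unknown test {test!r}")

    return EnsembleSummary(
        peptide_label=poses.peptide_label,
        n_total=n_total,
        n_selected=n_selected,
        occupancy_counts=occupancy,
        occupancy_residues=occupancy_res,
        rmsd_selected=rmsd_sel.tolist(),
        rmsd_discarded=rmsd_dis.tolist(),
        group_comparison=comparison,
    )


def _permutation_comparison(
    matrix: np.ndarray,
    selected_mask: np.ndarray,
    n_permutations: int,
    seed: int | None,
) -> GroupComparison:
    """Label-permutation test on the difference of within-group mean RMSD."""
    rng = np.random.default_rng(seed)
    n = len(selected_mask)
    k = int(selected_mask.sum())

    def stat_for(mask: np.ndarray) -> float:
        sel = _within_group(matrix, np.flatnonzero(mask))
        dis = _within_group(matrix, np.flatnonzero(~mask))
        return float(dis.mean() - sel.mean())

    observed = stat_for(selected_mask)
    hits = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        if abs(stat_for(perm)) >= abs(observed):
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    sel = _within_group(matrix, np.flatnonzero(selected_mask))
    dis = _within_group(matrix, np.flatnonzero(~selected_mask))
    return GroupComparison(
        method=f"label permutation ({n_permutations} permutations, two-sided)",
        statistic=observed,
        p_value=float(p),
        mean_selected=float(sel.mean()),
        mean_discarded=float(dis.mean()),
    )


def site_ranking(
    summaries: Sequence[EnsembleSummary],
    rules: SpecificityRules | None = None,
    candidates: Sequence[CleavageCandidate] | None = None,
) -> pd.DataFrame:
    """Rank P1 positions by selected-mode S1 occupancy across ensembles.

    Ties are broken by the rules' P1 preference order (Arg before Lys), then
    by lower residue number. Sites excluded by the P2 rule are annotated,
    not removed.
    """
    if not summaries:
        raise EmptyInputError("site_ranking requires at least one summary")
    rules = rules or SpecificityRules()
    excluded_by_pos = {}
    if candidates:
        excluded_by_pos = {
            c.p1_position: (c.excluded, c.exclusion_reason) for c in candidates
        }
    rows = []
    for summary in summaries:
        for position, count in summary.occupancy_counts.items():
            residue = summary.occupancy_residues.get(position, "")
            excluded, reason = excluded_by_pos.get(position, (False, ""))
            rows.append(
                {
                    "p1_position": position,
                    "p1_residue": residue,
                    "peptide_label": summary.peptide_label,
                    "occupancy_count": count,
                    "occupancy_percent": round(100.0 * count / summary.n_total, 1),
                    "excluded": excluded,
                    "reason": reason,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["_pref"] = frame["p1_residue"].map(rules.preference_rank)
    frame = frame.sort_values(
        by=["occupancy_count", "_pref", "p1_position"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_pref")
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return frame.reset_index(drop=True)
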