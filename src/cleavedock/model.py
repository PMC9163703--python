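"""Model/Results interface over the cleavage-site analysis.

:class:`CleavageSiteModel` bundles a receptor, one pose ensemble per peptide
window and the rule/criteria configuration; :meth:`CleavageSiteModel.fit`
applies the geometric criteria to every pose, computes per-ensemble
statistics and returns a :class:`CleavageSiteResults` carrying pass
fractions, S1 occupancy counts, the selected-vs-discarded RMSD comparison
and a ranked table of predicted cleavage sites, with ``summary()`` for a
human-readable report. :func:`run_full_pipeline` is the end-to-end driver:
candidate enumeration → pose evaluation → ranking → fragment mapping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cluster_stats import EnsembleSummary, site_ranking, summarize_ensemble
from .exceptions import ConfigurationError, EmptyInputError
from .fragments import CleavageEvent, FragmentSet, fragment_map
from .pose_evaluation import (
    PoseEvaluation,
    SelectionCriteria,
    evaluate_pose_set,
    evaluations_to_frame,
)
from .site_enumeration import (
    CleavageCandidate,
    SpecificityRules,
    SubstrateSequence,
    enumerate_candidates,
)
from .structure_io import PoseSet, ProteaseReceptor, read_pose_ensemble, read_receptor

__all__ = ["CleavageSiteModel", "CleavageSiteResults", "run_full_pipeline"]


class CleavageSiteModel:
    """Docking-based cleavage-site prediction for one substrate region.

    Parameters
    ----------
    receptor
        Annotated protease structure (catalytic triad + S1 anchor).
    pose_sets
        Mapping of peptide window label to its docked pose ensemble.
    criteria
        Geometric selection thresholds; defaults to the 4 Å / 4 Å pair.
    rules
        P1/P2 specificity rules used for occupant tie-breaks and site
        annotation.
    candidates
        Optional enumerated candidates; used to annotate excluded sites in
        the ranking.
    """

    def __init__(
        self,
        receptor: ProteaseReceptor,
        pose_sets: Mapping[str, PoseSet],
        criteria: SelectionCriteria | None = None,
        rules: SpecificityRules | None = None,
        candidates: Sequence[CleavageCandidate] | None = None,
    ):
        if not pose_sets:
            raise EmptyInputError("at least one pose ensemble is required")
        self.receptor = receptor
        self.pose_sets = dict(pose_sets)
        self.criteria = criteria or SelectionCriteria()
        self.rules = rules or SpecificityRules()
        self.candidates = list(candidates) if candidates else None

    @classmethod
    def from_files(
        cls,
        receptor_path: str | Path,
        pose_files: Mapping[str, str | Path],
        residue_offsets: Mapping[str, int] | None = None,
        triad: tuple[int, int, int] = (296, 345, 441),
        s1_anchor: int = 435,
        **kwargs,
    ) -> "CleavageSiteModel":
        """Build a model from a receptor PDB and per-window pose PDB files."""
        receptor = read_receptor(receptor_path, triad=triad, s1_anchor=s1_anchor)
        offsets = residue_offsets or {}
        pose_sets = {
            label: read_pose_ensemble(
                path, label, residue_offset=offsets.get(label, 0)
            )
            for label, path in pose_files.items()
        }
        return cls(receptor, pose_sets, **kwargs)

    def fit(
        self,
        test: str = "mann_whitney",
        n_permutations: int = 1000,
        seed: int | None = None,
    ) -> "CleavageSiteResults":
        """Evaluate every ensemble and assemble the results object."""
        evaluations: dict[str, list[PoseEvaluation]] = {}
        summaries: dict[str, EnsembleSummary] = {}
        for label, pose_set in self.pose_sets.items():
            evals = evaluate_pose_set(pose_set, self.receptor, self.criteria, self.rules)
            evaluations[label] = evals
            summaries[label] = summarize_ensemble(
                evals, pose_set, test=test, n_permutations=n_permutations, seed=seed
            )
        ranking = site_ranking(
            list(summaries.values()), self.rules, self.candidates
        )
        return CleavageSiteResults(
            model=self,
            evaluations=evaluations,
            summaries=summaries,
            ranking=ranking,
        )


@dataclass
class CleavageSiteResults:
    """Fitted results: per-ensemble statistics and the site ranking."""

    model: CleavageSiteModel
    evaluations: dict[str, list[PoseEvaluation]]
    summaries: dict[str, EnsembleSummary]
    ranking: pd.DataFrame
    fragment_set: FragmentSet | None = field(default=None)

    @property
    def pass_fractions(self) -> dict[str, float]:
        """Percent of binding modes per window passing both criteria."""
        return {
            label: round(s.pass_fraction_percent, 1)
            for label, s in self.summaries.items()
        }

    def top_site(self) -> int | None:
        """Highest-ranked non-excluded P1 position, if any."""
        if self.ranking.empty:
            return None
        usable = self.ranking[~self.ranking["excluded"]]
        if usable.empty:
            return None
        return int(usable.iloc[0]["p1_position"])

    def to_frame(self) -> pd.DataFrame:
        """One row per ensemble: counts, pass fraction, RMSD contrast."""
        rows = []
        for label, s in self.summaries.items():
            cmp = s.group_comparison
            rows.append(
                {
                    "peptide": label,
                    "n_total": s.n_total,
                    "n_selected": s.n_selected,
                    "pass_fraction_percent": round(s.pass_fraction_percent, 1),
                    "mean_rmsd_selected": (
                        round(cmp.mean_selected, 2) if cmp else None
                    ),
                    "mean_rmsd_discarded": (
                        round(cmp.mean_discarded, 2) if cmp else None
                    ),
                    "p_value": cmp.p_value if cmp else None,
                    "test": cmp.method if cmp else None,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        lines = [
            "Cleavage-site docking analysis",
            "=" * 62,
            f"Selection criteria: salt bridge < {self.model.criteria.salt_bridge_max} A "
            f"(P1 side chain to S1 Asp OD1/OD2),",
            f"                    scissile C to Ser OG < {self.model.criteria.scissile_max} A",
            "",
        ]
        for label, s in self.summaries.items():
            lines.append(
                f"{label}: {s.n_selected}/{s.n_total} binding modes selected "
                f"({s.pass_fraction_percent:.1f}%)"
            )
            for pos, count in sorted(
                s.occupancy_counts.items(), key=lambda kv: -kv[1]
            ):
                res = s.occupancy_residues.get(pos, "?")
                lines.append(f"    S1 occupant {res}{pos}: {count} modes")
            cmp = s.group_comparison
            if cmp:
                lines.append(
                    f"    pairwise backbone RMSD: selected {cmp.mean_selected:.2f} A "
                    f"vs discarded {cmp.mean_discarded:.2f} A "
                    f"({cmp.method}, p = {cmp.p_value:.3g})"
                )
        lines.append("")
        if self.ranking.empty:
            lines.append("No S1-occupying binding modes: no sites ranked.")
        else:
            lines.append("Predicted cleavage sites (by selected-mode occupancy):")
            for _, row in self.ranking.iterrows():
                note = "  [excluded: " + row["reason"] + "]" if row["excluded"] else ""
                lines.append(
                    f"  {row['rank']:>2}. {row['p1_residue']}{row['p1_position']} "
                    f"({row['occupancy_count']} modes, "
                    f"{row['occupancy_percent']:.1f}% of {row['peptide_label']})"
                    + note
                )
        if self.fragment_set is not None:
            lines.append("")
            lines.append(
                f"Fragment map for {self.fragment_set.substrate_id} "
                "(unmodified average masses; gel mobility of glycosylated "
                "fragments will differ):"
            )
            for frag in self.fragment_set.fragments:
                lines.append(
                    f"  {frag.role:<15} {frag.span[0]}-{frag.span[1]} "
                    f"({frag.length} aa, {frag.mass:.2f} Da)"
                )
        return "\n".join(lines)

    def plot_occupancy(self, ax=None):
        """Bar chart of per-window pass fractions (percent of modes)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        labels = list(self.summaries)
        values = [self.summaries[k].pass_fraction_percent for k in labels]
        ax.bar(labels, values, color="#4878a8")
        ax.set_ylabel("binding modes passing criteria (%)")
        ax.set_ylim(0, 100)
        for i, v in enumerate(values):
            ax.text(i, v + 1.5, f"{v:.1f}", ha="center", fontsize=9)
        return ax

    def to_json(self) -> str:
        payload = {
            "pass_fractions": self.pass_fractions,
            "ensembles": {
                label: {
                    "n_total": s.n_total,
                    "n_selected": s.n_selected,
                    "pass_fraction_percent": s.pass_fraction_percent,
                    "occupancy_counts": {str(k): v for k, v in s.occupancy_counts.items()},
                    "group_comparison": (
                        {
                            "method": s.group_comparison.method,
                            "statistic": s.group_comparison.statistic,
                            "p_value": s.group_comparison.p_value,
                            "mean_rmsd_selected": s.group_comparison.mean_selected,
                            "mean_rmsd_discarded": s.group_comparison.mean_discarded,
                        }
                        if s.group_comparison
                        else None
                    ),
                }
                for label, s in self.summaries.items()
            },
            "ranking": self.ranking.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def run_full_pipeline(
    receptor: ProteaseReceptor,
    substrate: SubstrateSequence,
    region: tuple[int, int],
    pose_sets: Mapping[str, PoseSet],
    rules: SpecificityRules | None = None,
    criteria: SelectionCriteria | None = None,
    proximal_site: int | None = None,
    test: str = "mann_whitney",
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> CleavageSiteResults:
    """Candidate enumeration → pose evaluation → ranking → fragment map.

    ``proximal_site`` (e.g. the furin-region P1) pairs with the top-ranked
    distal site to produce the released-tract fragment map; without it the
    fragment stage is skipped. When ``outdir`` is given, TSV/JSON reports
    are written there.
    """
    rules = rules or SpecificityRules()
    if region[0] > region[1]:
        warnings.warn("empty region: nothing to enumerate", stacklevel=2)
        candidates: list[CleavageCandidate] = []
    else:
        candidates = enumerate_candidates(substrate, region, rules)
    model = CleavageSiteModel(
        receptor, pose_sets, criteria=criteria, rules=rules, candidates=candidates
    )
    results = model.fit(test=test, seed=seed)

    top = results.top_site()
    if proximal_site is not None and top is not None:
        if proximal_site >= top:
            raise ConfigurationError(
                f"proximal site {proximal_site} must precede the top-ranked "
                f"distal site {top}"
            )
        results.fragment_set = fragment_map(
            substrate,
            [
                CleavageEvent(proximal_site, label="proximal"),
                CleavageEvent(top, label="distal"),
            ],
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .site_enumeration import candidates_to_frame

        candidates_to_frame(candidates).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        results.to_frame().to_csv(outdir / "ensembles.tsv", sep="\t", index=False)
        results.ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(results.to_json() + "\n")
        for label, evals in results.evaluations.items():
            evaluations_to_frame(evals).to_csv(
                outdir / f"evaluations_{label}.tsv", sep="\t", index=False
            )
        if results.fragment_set is not None:
            results.fragment_set.to_frame().to_csv(
                outdir / "fragments.tsv", sep="\t", index=False
            )
        (outdir / "summary.txt").write_text(results.summary() + "\n")
    return results
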