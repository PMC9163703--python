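"""Pairwise RMSD, ensemble summaries and site ranking."""

import numpy as np
import pytest

from cleavedock import (
    ComparisonError,
    EnsembleSummary,
    SpecificityRules,
    SyntheticEnsembleConfig,
    build_extended_peptide,
    evaluate_pose_set,
    make_ensemble,
    pairwise_rmsd,
    rmsd_matrix,
    site_ranking,
    summarize_ensemble,
)
from cleavedock.structure_io import Atom, PeptidePose


class TestPairwiseRmsd:
    def test_identity(self):
        pose = build_extended_peptide("GKARDF", 169)
        assert pairwise_rmsd(pose, pose) == 0.0

    def test_uniform_translation_equals_shift(self):
        pose = build_extended_peptide("GKARDF", 169)
        moved = pose.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert pairwise_rmsd(pose, moved) == pytest.approx(3.0, abs=1e-9)

    def test_matches_atom_by_atom_oracle(self):
        rng = np.random.default_rng(5)
        base = build_extended_peptide("GKARDF", 169)
        other = PeptidePose(
            pose_id=2,
            peptide_label=base.peptide_label,
            atoms=[
                Atom(a.name, a.element, tuple(a.xyz() + rng.normal(0, 2, 3)),
                     a.residue_number, a.residue_name, a.chain_id)
                for a in base.atoms
            ],
        )
        backbone = {"N", "CA", "C", "O"}
        sq = [
            float(np.sum((a.xyz() - b.xyz()) ** 2))
            for a, b in zip(base.atoms, other.atoms)
            if a.name in backbone
        ]
        oracle = float(np.sqrt(np.mean(sq)))
        assert pairwise_rmsd(base, other) == pytest.approx(oracle, abs=1e-9)
        assert pairwise_rmsd(other, base) == pytest.approx(oracle, abs=1e-9)

    def test_atom_mismatch_lists_missing_atoms(self):
        a = build_extended_peptide("GKARDF", 169)
        b = build_extended_peptide("GKARDF", 170)
        with pytest.raises(ComparisonError, match="unmatched"):
            pairwise_rmsd(a, b)

    def test_heavy_scope_includes_side_chains(self):
        pose = build_extended_peptide("GAARDF", 169)
        moved = pose.transformed(np.eye(3), np.array([0.0, 2.0, 0.0]))
        assert pairwise_rmsd(pose, moved, atom_scope="heavy") == pytest.approx(
            2.0, abs=1e-9
        )

    def test_matrix_agrees_with_pairwise_calls(self, small_ensemble):
        _, pose_set, _ = small_ensemble
        subset = pose_set.poses[:6]
        matrix = rmsd_matrix(subset)
        for i in range(6):
            for j in range(6):
                assert matrix[i, j] == pytest.approx(
                    pairwise_rmsd(subset[i], subset[j]), abs=1e-9
                )


class TestSummarizeEnsemble:
    def test_pass_fraction_arithmetic(self, mock_receptor, small_ensemble):
        _, pose_set, labels = small_ensemble
        evaluations = evaluate_pose_set(pose_set, mock_receptor)
        summary = summarize_ensemble(evaluations, pose_set)
        assert summary.n_total == 30
        assert summary.n_selected == sum(labels)
        assert summary.pass_fraction_percent == pytest.approx(
            100.0 * sum(labels) / 30
        )
        assert sum(summary.occupancy_counts.values()) == summary.n_selected

    def test_clustered_selected_modes_have_lower_rmsd(self, mock_receptor):
        config = SyntheticEnsembleConfig(
            peptide_window="GKARDF", peptide_start=169, occupant_position=172,
            n_poses=90, productive_fraction=0.4, jitter_sd=0.3, decoy_box=40.0,
            seed=42,
        )
        pose_set, _ = make_ensemble(config, mock_receptor)
        evaluations = evaluate_pose_set(pose_set, mock_receptor)
        summary = summarize_ensemble(evaluations, pose_set)
        cmp = summary.group_comparison
        assert np.mean(summary.rmsd_selected) < np.mean(summary.rmsd_discarded)
        assert cmp.p_value < 0.05

    def test_permutation_and_mann_whitney_agree_in_direction(self, mock_receptor,
                                                             small_ensemble):
        _, pose_set, _ = small_ensemble
        evaluations = evaluate_pose_set(pose_set, mock_receptor)
        mw = summarize_ensemble(evaluations, pose_set, test="mann_whitney")
        perm = summarize_ensemble(
            evaluations, pose_set, test="permutation",
            n_permutations=200, seed=0,
        )
        assert mw.group_comparison.mean_selected < mw.group_comparison.mean_discarded
        assert perm.group_comparison.statistic > 0  # discarded mean - selected mean
        assert perm.group_comparison.p_value < 0.05
        assert "permutation" in perm.group_comparison.method

    def test_zero_selected_degenerates_cleanly(self, mock_receptor):
        config = SyntheticEnsembleConfig(
            peptide_window="GKARDF", peptide_start=169, occupant_position=172,
            n_poses=20, productive_fraction=0.0, seed=9,
        )
        pose_set, _ = make_ensemble(config, mock_receptor)
        evaluations = evaluate_pose_set(pose_set, mock_receptor)
        summary = summarize_ensemble(evaluations, pose_set)
        assert summary.pass_fraction_percent == 0.0
        assert summary.occupancy_counts == {}
        assert summary.rmsd_selected == []
        assert summary.group_comparison is None

    def test_pass_fraction_invariant_under_reordering(self, mock_receptor,
                                                      small_ensemble):
        from cleavedock.structure_io import PoseSet

        _, pose_set, _ = small_ensemble
        evaluations = evaluate_pose_set(pose_set, mock_receptor)
        order = np.random.default_rng(2).permutation(len(pose_set))
        shuffled = PoseSet(
            receptor_ref=pose_set.receptor_ref,
            peptide_label=pose_set.peptide_label,
            poses=[pose_set.poses[i] for i in order],
        )
        shuffled_evals = [evaluations[i] for i in order]
        a = summarize_ensemble(evaluations, pose_set)
        b = summarize_ensemble(shuffled_evals, shuffled)
        assert a.pass_fraction_percent == b.pass_fraction_percent
        assert a.occupancy_counts == b.occupancy_counts


class TestSiteRanking:
    def _summary(self, label, occupancy, residues, n_total=90):
        return EnsembleSummary(
            peptide_label=label,
            n_total=n_total,
            n_selected=sum(occupancy.values()),
            occupancy_counts=occupancy,
            occupancy_residues=residues,
        )

    def test_ranks_by_occupancy_count(self):
        ranking = site_ranking([
            self._summary("GKARDF", {172: 38}, {172: "R"}),
            self._summary("IHKASN", {189: 7}, {189: "K"}),
        ])
        assert ranking["p1_position"].tolist() == [172, 189]
        assert ranking["rank"].tolist() == [1, 2]

    def test_single_occupant_ranked_first(self):
        ranking = site_ranking([self._summary("GKARDF", {172: 20}, {172: "R"})])
        assert ranking.iloc[0]["p1_position"] == 172

    def test_tie_prefers_arginine_over_lysine(self):
        ranking = site_ranking([
            self._summary("GRKRKV", {179: 10, 178: 10}, {178: "R", 179: "K"}),
        ])
        assert ranking["p1_position"].tolist() == [178, 179]

    def test_excluded_sites_annotated_not_removed(self, distal_seq):
        from cleavedock import enumerate_candidates

        with pytest.warns(UserWarning):
            candidates = enumerate_candidates(distal_seq, (168, 192))
        ranking = site_ranking(
            [self._summary("GRKRKV", {180: 5, 178: 12}, {178: "R", 180: "R"})],
            SpecificityRules(),
            candidates,
        )
        r180 = ranking[ranking["p1_position"] == 180].iloc[0]
        assert bool(r180["excluded"])
        assert r180["reason"]
        assert 180 in ranking["p1_position"].tolist()
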