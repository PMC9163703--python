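"""The Model/Results interface, the end-to-end pipeline and the CLI."""

import json

import pytest
import yaml
from click.testing import CliRunner

from cleavedock import (
    CleavageSiteModel,
    SyntheticEnsembleConfig,
    enumerate_candidates,
    make_ensemble,
    run_full_pipeline,
    write_pose_ensemble,
    write_receptor,
)
from cleavedock.cli import main

THREE_WINDOW_SPEC = [
    # (window, start, occupant, productive fraction, seed)
    ("GKARDF", 169, 172, 0.45, 101),
    ("GRKRKV", 177, 178, 0.35, 102),
    ("IHKASN", 187, 189, 0.08, 103),
]


@pytest.fixture(scope="module")
def three_window_sets(mock_receptor):
    sets = {}
    for window, start, occupant, fraction, seed in THREE_WINDOW_SPEC:
        config = SyntheticEnsembleConfig(
            peptide_window=window, peptide_start=start, occupant_position=occupant,
            n_poses=90, productive_fraction=fraction, seed=seed,
        )
        sets[window], _ = make_ensemble(config, mock_receptor)
    return sets


class TestCleavageSiteModel:
    def test_fit_produces_pass_fractions_and_ranking(self, mock_receptor,
                                                     three_window_sets, full_seq):
        candidates = enumerate_candidates(full_seq, (168, 192))
        model = CleavageSiteModel(
            mock_receptor, three_window_sets, candidates=candidates
        )
        results = model.fit()
        fractions = results.pass_fractions
        assert fractions["GKARDF"] > 40.0
        assert fractions["GRKRKV"] > 30.0
        assert fractions["IHKASN"] < 10.0
        # ranking mirrors the productive-fraction ordering of the windows
        assert results.ranking.iloc[0]["p1_position"] == 172
        occupant_order = results.ranking["p1_position"].tolist()
        assert occupant_order.index(172) < occupant_order.index(189)
        assert results.top_site() == 172

    def test_summary_names_method_and_sites(self, mock_receptor, three_window_sets):
        results = CleavageSiteModel(mock_receptor, three_window_sets).fit()
        text = results.summary()
        assert "Mann-Whitney" in text
        assert "R172" in text
        assert "%" in text

    def test_to_frame_one_row_per_window(self, mock_receptor, three_window_sets):
        frame = CleavageSiteModel(mock_receptor, three_window_sets).fit().to_frame()
        assert len(frame) == 3
        assert set(frame["peptide"]) == {"GKARDF", "GRKRKV", "IHKASN"}
        assert (frame["mean_rmsd_selected"] < frame["mean_rmsd_discarded"]).all()

    def test_from_files_round_trip(self, mock_receptor, three_window_sets, tmp_path):
        receptor_path = tmp_path / "receptor.pdb"
        write_receptor(mock_receptor, receptor_path)
        pose_files = {}
        for label, pose_set in three_window_sets.items():
            path = tmp_path / f"{label}.pdb"
            write_pose_ensemble(pose_set.poses, path)
            pose_files[label] = path
        model = CleavageSiteModel.from_files(receptor_path, pose_files)
        results = model.fit()
        direct = CleavageSiteModel(mock_receptor, three_window_sets).fit()
        assert results.pass_fractions == direct.pass_fractions


class TestRunFullPipeline:
    def test_ranking_and_fragment_map(self, mock_receptor, three_window_sets,
                                      full_seq, tmp_path):
        results = run_full_pipeline(
            mock_receptor, full_seq, (168, 192), three_window_sets,
            proximal_site=138, outdir=tmp_path / "out",
        )
        assert results.ranking.iloc[0]["p1_position"] == 172
        assert results.fragment_set is not None
        tract = results.fragment_set.fragments[1]
        assert tract.role == "released-tract"
        assert tract.span == (139, 172)
        for name in ("candidates.tsv", "ensembles.tsv", "ranking.tsv",
                     "report.json", "summary.txt"):
            assert (tmp_path / "out" / name).exists()

    def test_reports_are_byte_identical_across_runs(self, mock_receptor,
                                                    three_window_sets, full_seq,
                                                    tmp_path):
        for run in ("a", "b"):
            run_full_pipeline(
                mock_receptor, full_seq, (168, 192), three_window_sets,
                proximal_site=138, seed=5, outdir=tmp_path / run,
            )
        for name in ("candidates.tsv", "ensembles.tsv", "ranking.tsv",
                     "report.json", "fragments.tsv", "summary.txt"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_empty_region_warns_and_ranks_without_annotation(self, mock_receptor,
                                                             three_window_sets,
                                                             full_seq):
        with pytest.warns(UserWarning, match="empty region"):
            results = run_full_pipeline(
                mock_receptor, full_seq, (180, 168), three_window_sets
            )
        assert not results.ranking.empty


class TestCli:
    @pytest.fixture()
    def runner(self):
        return CliRunner()

    def test_simulate_then_evaluate(self, runner, tmp_path):
        config = {
            "peptide_window": "GKARDF", "peptide_start": 169,
            "occupant_position": 172, "n_poses": 12,
            "productive_fraction": 0.5, "seed": 3,
        }
        config_path = tmp_path / "sim.yaml"
        config_path.write_text(yaml.safe_dump(config))
        outdir = tmp_path / "sim"
        result = runner.invoke(main, ["simulate", "--config", str(config_path),
                                      "--outdir", str(outdir)])
        assert result.exit_code == 0, result.output
        assert (outdir / "receptor.pdb").exists()
        assert (outdir / "labels.tsv").exists()
        assert (outdir / "provenance.json").exists()

        out_tsv = tmp_path / "eval.tsv"
        result = runner.invoke(main, [
            "evaluate", "--receptor", str(outdir / "receptor.pdb"),
            "--poses", str(outdir / "poses.pdb"), "--peptide-label", "GKARDF",
            "--out", str(out_tsv),
        ])
        assert result.exit_code == 0, result.output
        assert "6/12" in result.output
        assert "50.0%" in result.output

    def test_simulate_requires_seed(self, runner, tmp_path):
        config_path = tmp_path / "sim.yaml"
        config_path.write_text(yaml.safe_dump(
            {"peptide_window": "GKARDF", "peptide_start": 169,
             "occupant_position": 172}
        ))
        result = runner.invoke(main, ["simulate", "--config", str(config_path),
                                      "--outdir", str(tmp_path / "x")])
        assert result.exit_code != 0
        assert "seed" in result.output

    def test_enumerate_with_mutant(self, runner, tmp_path, distal_seq):
        fasta = tmp_path / "distal.fasta"
        fasta.write_text(f">gamma_distal\n{distal_seq.residues}\n")
        out = tmp_path / "candidates.tsv"
        result = runner.invoke(main, [
            "enumerate", "--fasta", str(fasta), "--start-number", "168",
            "--mutant", "RKRK178AAAA;K168A;K170A;R172A;K189A",
            "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert "0 candidate site(s)" in result.output

    def test_fragments_command_reports_release(self, runner, tmp_path, full_seq):
        fasta = tmp_path / "gamma.fasta"
        fasta.write_text(f">gamma\n{full_seq.residues}\n")
        out = tmp_path / "fragments.tsv"
        result = runner.invoke(main, [
            "fragments", "--fasta", str(fasta), "--start-number", "134",
            "--cleave-after", "138", "--cleave-after", "178",
            "--tract", "139", "178", "--key-span", "153", "163",
            "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert "released-tract" in result.output
        assert "inhibitory tract: released" in result.output

    def test_run_fails_naming_missing_window(self, runner, tmp_path, full_seq,
                                             mock_receptor):
        receptor_path = tmp_path / "receptor.pdb"
        write_receptor(mock_receptor, receptor_path)
        fasta = tmp_path / "gamma.fasta"
        fasta.write_text(f">gamma\n{full_seq.residues}\n")
        cfg = {
            "receptor": str(receptor_path),
            "substrate": str(fasta),
            "start_number": 134,
            "region": [168, 192],
            "windows": [{"label": "GKARDF", "poses": str(tmp_path / "nope.pdb")}],
        }
        config_path = tmp_path / "run.yaml"
        config_path.write_text(yaml.safe_dump(cfg))
        result = runner.invoke(main, ["run", "--config", str(config_path),
                                      "--outdir", str(tmp_path / "out")])
        assert result.exit_code != 0
        assert "GKARDF" in result.output

    def test_run_full_config(self, runner, tmp_path, full_seq, mock_receptor,
                             three_window_sets):
        receptor_path = tmp_path / "receptor.pdb"
        write_receptor(mock_receptor, receptor_path)
        fasta = tmp_path / "gamma.fasta"
        fasta.write_text(f">gamma\n{full_seq.residues}\n")
        windows = []
        for label, pose_set in three_window_sets.items():
            path = tmp_path / f"{label}.pdb"
            write_pose_ensemble(pose_set.poses, path)
            windows.append({"label": label, "poses": str(path)})
        cfg = {
            "receptor": str(receptor_path),
            "substrate": str(fasta),
            "start_number": 134,
            "region": [168, 192],
            "proximal_site": 138,
            "windows": windows,
        }
        config_path = tmp_path / "run.yaml"
        config_path.write_text(yaml.safe_dump(cfg))
        result = runner.invoke(main, ["run", "--config", str(config_path),
                                      "--outdir", str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        report = json.loads((tmp_path / "out" / "report.json").read_text())
        assert report["pass_fractions"]["GKARDF"] > 40.0
        assert report["ranking"][0]["p1_position"] == 172
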