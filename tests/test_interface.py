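import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from stdmat.cli import main
from stdmat.interface import RunConfig, load_config, run_dynamic, run_static
from stdmat.synthetic_fixtures import FixtureSpec, make_spin_fixture, make_trajectory_fixture


@pytest.fixture(scope="module")
def static_case(tmp_path_factory):
    """mini-complex protein/ligand + experimental epitope from the sidecar."""
    d = tmp_path_factory.mktemp("static")
    res = make_spin_fixture(FixtureSpec("mini_complex"), d)
    ep = d / "exp_epitope.tsv"
    ep.write_text(
        "".join(f"{k}\t{v}\n" for k, v in res["truth"]["relative_epitope"].items())
    )
    return {"res": res, "epitope": ep, "dir": d}


def _static_config(static_case, **kw):
    base = dict(
        mode="static",
        protein=str(static_case["res"]["protein"]),
        ligand=str(static_case["res"]["ligand"]),
        epitope=str(static_case["epitope"]),
        tau_c_ns=34.5,
        kd_uM=2000.0,
        protein_conc_uM=20.0,
        ligand_conc_uM=1000.0,
        cutoff_angstrom=12.0,
    )
    base.update(kw)
    return RunConfig(**base)


class TestRunConfig:
    def test_mode_required_paths(self):
        with pytest.raises(ValueError, match="requires"):
            RunConfig(mode="static", protein="x.pdb")

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RunConfig(mode="oracle", protein="a", ligand="b", kd_uM=-1.0)

    def test_config_file_round_trip(self, tmp_path, static_case):
        cfg_path = tmp_path / "run.cfg"
        cfg_path.write_text(
            "mode = static\n"
            f"protein = {static_case['res']['protein']}\n"
            f"ligand = {static_case['res']['ligand']}\n"
            f"epitope = {static_case['epitope']}\n"
            "tau_c_ns = 34.5   # bound complex\n"
            "kd_uM = 2000\n"
            "protein_conc_uM = 20\n"
            "key_map = H2a:H2,H2b:H2\n"
            "methyl_averaging = false\n"
        )
        cfg = load_config(cfg_path, ligand_conc_uM=1000.0)
        assert cfg.tau_c_ns == 34.5
        assert cfg.key_map == {"H2a": "H2", "H2b": "H2"}
        assert cfg.ligand_conc_uM == 1000.0

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("mode = static\nwavelength = 7\n")
        with pytest.raises(KeyError, match="wavelength"):
            load_config(p)


class TestRunStatic:
    def test_self_consistent_epitope_scores_near_zero(self, static_case):
        table = run_static(_static_config(static_case))
        assert len(table) == 1
        assert table.loc[0, "r_factor"] < 0.01
        assert table.loc[0, "classification"] == "good"

    def test_planted_pose_ranks_first(self, tmp_path, static_case):
        res = make_spin_fixture(
            FixtureSpec("poses", params={"n_poses": 5, "native_index": 2}, seed=7),
            tmp_path,
        )
        cfg = _static_config(
            static_case, protein=str(res["protein"]), ligand=str(res["ligand"])
        )
        table = run_static(cfg)
        assert len(table) == 5
        assert table.loc[0, "model"] == 2
        assert table["r_factor"].is_monotonic_increasing

    def test_unscorable_model_reported_without_aborting(self, tmp_path, static_case):
        res = make_spin_fixture(
            FixtureSpec("poses", params={"n_poses": 3, "native_index": 0}, seed=3),
            tmp_path,
        )
        cfg = _static_config(
            static_case,
            protein=str(res["protein"]),
            ligand=str(res["ligand"]),
            cutoff_angstrom=4.0,  # decoys drift out of range
        )
        table = run_static(cfg)
        assert len(table) == 3
        bad = table[table["classification"] == "un-scorable"]
        assert (bad["error"] != "").all()
        assert (table["classification"] == "un-scorable").any()

    def test_output_files_and_determinism(self, tmp_path, static_case):
        cfg = _static_config(static_case)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        run_static(cfg, out_dir=out1)
        run_static(cfg, out_dir=out2)
        assert (out1 / "static_scores.tsv").read_bytes() == (
            out2 / "static_scores.tsv"
        ).read_bytes()
        record = (out1 / "run_record.txt").read_text()
        assert "tau_c_ns = 34.5" in record and "bound fraction" in record


class TestRunDynamic:
    def test_timeseries_matches_sidecar_flags(self, tmp_path, static_case):
        res = make_trajectory_fixture(FixtureSpec("trajectory"), tmp_path)
        cfg = RunConfig(
            mode="trajectory",
            topology=str(res["topology"]),
            trajectory=str(res["trajectory"]),
            epitope=str(static_case["epitope"]),
            tau_c_ns=34.5, kd_uM=2000.0, protein_conc_uM=20.0,
        )
        score = run_dynamic(cfg, out_dir=tmp_path / "dyn")
        assert score.dissociated_frames == res["truth"]["dissociated_frames"]
        table = pd.read_csv(tmp_path / "dyn" / "r_factor_timeseries.tsv", sep="\t")
        assert list(table["frame"]) == list(range(10))
        assert (table["r_factor"] == "NA").sum() == 3 or table["r_factor"].isna().sum() == 3

    def test_stride_beyond_length_scores_single_frame(self, tmp_path, static_case):
        res = make_trajectory_fixture(FixtureSpec("trajectory"), tmp_path)
        cfg = RunConfig(
            mode="trajectory",
            topology=str(res["topology"]),
            trajectory=str(res["trajectory"]),
            epitope=str(static_case["epitope"]),
            stride=50,
        )
        assert len(run_dynamic(cfg).frames) == 1

    def test_missing_epitope_fails_before_compute(self, tmp_path, static_case):
        res = make_trajectory_fixture(FixtureSpec("trajectory"), tmp_path)
        cfg = RunConfig(
            mode="trajectory",
            topology=str(res["topology"]),
            trajectory=str(res["trajectory"]),
            epitope=str(tmp_path / "nowhere.tsv"),
        )
        with pytest.raises(FileNotFoundError):
            run_dynamic(cfg)


class TestCli:
    def test_static_subcommand(self, static_case, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "static",
                "--protein", str(static_case["res"]["protein"]),
                "--ligand", str(static_case["res"]["ligand"]),
                "--epitope", str(static_case["epitope"]),
                "--tau-c-ns", "34.5", "--kd-um", "2000",
                "--protein-conc-um", "20", "--ligand-conc-um", "1000",
                "--out", str(tmp_path / "cli_out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "good" in result.output
        assert (tmp_path / "cli_out" / "static_scores.tsv").exists()

    def test_fixtures_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["fixtures", "mini_complex", "--out", str(tmp_path / "fx")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "ground_truth.json").exists()

    def test_oracle_subcommand(self, tmp_path):
        from stdmat.synthetic_fixtures import make_spin_fixture as mk

        res = mk(FixtureSpec("methyl_probe"), tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "oracle",
                "--protein", str(res["protein"]),
                "--ligand", str(res["ligand"]),
                "--tau-c-ns", "34.5", "--kd-um", "2000",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "relative_%" in result.output


def test_static_mode_runtime_is_interactive(static_case):
    """A single static scoring call completes in well under 10 s."""
    import time

    t0 = time.perf_counter()
    run_static(_static_config(static_case))
    assert time.perf_counter() - t0 < 10.0
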