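"""Configuration, file round-trips, orchestration, determinism."""

import json

import numpy as np
import pytest

from photoseam import fileio
from photoseam.geometry import Geometry
from photoseam.workflow import WorkflowConfig, run_workflow, stage_seed


@pytest.fixture(scope="module")
def cascade_config():
    return dict(
        model={"name": "three_state_cascade", "params": {}},
        ladder=[[2, 1], [1, 0]],
        md={"n_steps": 2000},
        cascade_md={"n_steps": 800},
        cone={"cascade": {"R": 0.4, "n": 5}},
        seed=11,
    )


@pytest.fixture(scope="module")
def cascade_report(cascade_config):
    return run_workflow(WorkflowConfig(**cascade_config))


class TestConfig:
    def test_roundtrip_through_yaml(self, tmp_path, cascade_config):
        cfg = WorkflowConfig(**cascade_config)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = WorkflowConfig.from_yaml(tmp_path / "c.yaml")
        assert back.to_dict() == cfg.to_dict()

    def test_increasing_ladder_rejected(self):
        with pytest.raises(ValueError):
            WorkflowConfig(ladder=[[0, 1]])
        with pytest.raises(ValueError):
            WorkflowConfig(ladder=[[1, 0], [2, 1]])
        with pytest.raises(ValueError):
            WorkflowConfig(ladder=[[2, 0]])

    def test_stage_seeds_distinct_and_stable(self):
        seeds = {stage_seed(7, i, j) for i in range(5) for j in range(5)}
        assert len(seeds) == 25
        assert stage_seed(7, 3, 1) == stage_seed(7, 3, 1)
        assert all(0 <= s < 2 ** 31 for s in seeds)


class TestFrameIO:
    def test_xyz_roundtrip_full_precision(self, tmp_path, cluster):
        rng = np.random.default_rng(0)
        frames = [cluster.geometry(cluster.tetrahedron().coords
                                   + rng.normal(size=cluster.n_coords) * 0.1)
                  for _ in range(100)]
        metas = [{"step": k, "E_i": rng.normal(), "E_j": rng.normal(),
                  "gap": abs(rng.normal())} for k in range(100)]
        fileio.write_frames(tmp_path / "t.xyz", frames, metas)
        back, metas2 = fileio.read_frames(tmp_path / "t.xyz")
        assert len(back) == 100
        for a, b in zip(frames, back):
            assert np.array_equal(a.coords, b.coords)
        for m, m2 in zip(metas, metas2):
            assert m2["step"] == m["step"]
            assert m2["gap"] == m["gap"]

    def test_abstract_dialect_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = [Geometry(rng.normal(size=3), 1, 3) for _ in range(20)]
        metas = [{"gap": float(abs(rng.normal()))} for _ in range(20)]
        fileio.write_frames(tmp_path / "t.dat", frames, metas)
        back, metas2 = fileio.read_frames(tmp_path / "t.dat", 1, 3)
        for a, b in zip(frames, back):
            assert np.array_equal(a.coords, b.coords)
        assert [m["gap"] for m in metas] == [m["gap"] for m in metas2]

    def test_malformed_atom_count_reports_frame(self, tmp_path):
        (tmp_path / "bad.xyz").write_text("3\ncomment\nA 0 0 0\nB 1 1 1\n")
        with pytest.raises(ValueError, match="frame 0"):
            fileio.read_frames(tmp_path / "bad.xyz")

    def test_wrong_atom_line_arity(self, tmp_path):
        (tmp_path / "bad.xyz").write_text("1\nc\nA 0 0\n")
        with pytest.raises(ValueError, match="fields"):
            fileio.read_frames(tmp_path / "bad.xyz")


class TestReportIO:
    def test_report_roundtrip(self, tmp_path, cascade_report):
        fileio.write_report(cascade_report, tmp_path / "r.json")
        back = fileio.load_report(tmp_path / "r.json")
        clean = {k: v for k, v in back.items() if k != "schema_version"}
        assert json.dumps(clean, sort_keys=True, default=str) == json.dumps(
            cascade_report, sort_keys=True, default=str)

    def test_schema_version_checked(self, tmp_path):
        (tmp_path / "r.json").write_text('{"schema_version": 999}')
        with pytest.raises(ValueError, match="schema version"):
            fileio.load_report(tmp_path / "r.json")

    def test_census_fractions_sum_to_one_in_file(self, tmp_path,
                                                 cascade_report):
        fileio.write_report(cascade_report, tmp_path / "r.json")
        back = fileio.load_report(tmp_path / "r.json")
        for cens in back["censuses"]:
            assert sum(cens["fractions"].values()) == pytest.approx(1.0,
                                                                    abs=1e-12)


class TestCascadeWorkflow:
    def test_discovers_both_seams_and_products(self, cascade_report):
        rep = cascade_report
        assert len(rep["levels"]) == 2
        assert rep["levels"][0]["pair"] == [1, 2]
        assert rep["levels"][1]["pair"] == [0, 1]
        assert len(rep["levels"][0]["mecis"]) >= 1
        assert len(rep["levels"][1]["mecis"]) >= 1
        assert len(rep["products"]) >= 2
        for lv in rep["levels"]:
            for m in lv["mecis"]:
                assert m["converged"]
                assert m["gap_at_convergence"] < 1e-5

    def test_same_seed_reports_byte_identical(self, cascade_config,
                                              cascade_report, tmp_path):
        rep2 = run_workflow(WorkflowConfig(**cascade_config))
        fileio.write_report(cascade_report, tmp_path / "a.json")
        fileio.write_report(rep2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == \
            (tmp_path / "b.json").read_bytes()

    def test_checkpoint_resume_matches_uninterrupted(self, cascade_config,
                                                     cascade_report,
                                                     tmp_path):
        cfg = dict(cascade_config)
        cfg["out_dir"] = str(tmp_path / "run")
        run_workflow(WorkflowConfig(**cfg))          # populates checkpoints
        resumed = run_workflow(WorkflowConfig(**cfg), resume=True)
        fileio.write_report(cascade_report, tmp_path / "fresh.json")
        resumed.pop("config")
        fresh = dict(cascade_report)
        fresh = {k: v for k, v in fresh.items() if k != "config"}
        assert json.dumps(resumed, sort_keys=True, default=str) == \
            json.dumps(fresh, sort_keys=True, default=str)

    def test_stage_log_lines_present(self, cascade_report):
        stages = [entry["stage"] for entry in cascade_report["log"]]
        assert any("seam_md" in s for s in stages)
        assert any("cluster" in s for s in stages)
        assert any("meci" in s for s in stages)
        assert "products" in stages
        assert "paths" in stages


class TestCLI:
    def test_run_all_and_staged_pipeline(self, tmp_path):
        from click.testing import CliRunner
        from photoseam.cli import main
        cfg = tmp_path / "cfg.yaml"
        WorkflowConfig(
            model={"name": "two_state_photo", "params": {}},
            start=[0.828, -0.138], ladder=[[1, 0]],
            md={"n_steps": 1500}, seed=5,
            cone={"lower_seam": {"n": 60}},
        ).to_yaml(cfg)
        runner = CliRunner()
        r = runner.invoke(main, ["seam-md", "-c", str(cfg), "-o",
                                 str(tmp_path / "md")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["select-cis", "-c", str(cfg), "-o",
                                 str(tmp_path / "ci"), "--frames",
                                 str(tmp_path / "md" / "harvested.dat")])
        assert r.exit_code == 0, r.output
        mecis = fileio.load_report(tmp_path / "ci" / "mecis.json")["mecis"]
        assert len(mecis) >= 1
        r = runner.invoke(main, ["cone-sample", "-c", str(cfg), "-o",
                                 str(tmp_path / "cone"), "--mecis",
                                 str(tmp_path / "ci" / "mecis.json")])
        assert r.exit_code == 0, r.output
        cone_file = tmp_path / "cone" / f"cone_{mecis[0]['meci_id']}.dat"
        r = runner.invoke(main, ["product-search", "-c", str(cfg), "-o",
                                 str(tmp_path / "prod"), "--cone",
                                 str(cone_file)])
        assert r.exit_code == 0, r.output
        doc = fileio.load_report(tmp_path / "prod" / "census.json")
        assert doc["censuses"][0]["total"] == 60
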