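"""Registry, condition mapping, run plans, reports, fixtures, config, CLI."""

import json
from pathlib import Path

import numpy as np
import pytest

from torquefold.chain import Sequence, add_handles, build_topology
from torquefold.config import Config, load_config, save_config
from torquefold.machine import MachineProtocol
from torquefold.protocol import (CONDITIONS, RunPlan, derive_seed,
                                 generate_fixtures, load_registry,
                                 make_condition, run_plan, table2_report)


class TestRegistry:
    def test_five_entries_with_expected_lengths(self):
        reg = load_registry()
        lengths = {pid: len(reg[pid].core) for pid in reg}
        assert lengths == {"P1": 19, "P2": 15, "P3": 19, "P4": 15, "P5": 21}

    def test_fs_peptide_expansion(self):
        assert load_registry()["P1"].core == "AAAA" + "AAARA" * 3

    def test_every_entry_builds_topology(self):
        for entry in load_registry().values():
            seq = add_handles(Sequence(entry.core), 2)
            top = build_topology(seq)
            assert top.n_residues == len(entry.core) + 4


class TestConditions:
    def test_free_has_no_machine(self):
        c = make_condition("free")
        assert not c.rotate and not c.restrain and c.sign == 0

    def test_restrained_without_rotation(self):
        c = make_condition("restrained")
        assert not c.rotate and c.restrain

    def test_cw_ccw_differ_only_in_sign(self):
        cw, ccw = make_condition("cw"), make_condition("ccw")
        assert cw.rotate and ccw.rotate and cw.restrain and ccw.restrain
        assert cw.sign == -ccw.sign == 1

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_condition("sideways")

    def test_protocols_from_conditions(self):
        reg = load_registry()
        seq = add_handles(Sequence(reg["P2"].core), 2)
        top = build_topology(seq)
        from torquefold.chain import build_extended_conformation

        ext = build_extended_conformation(top)
        cfg = Config()
        free = MachineProtocol.for_condition("free", cfg.machine, top, ext)
        assert free.k_plane == free.k_x == free.k_fix == 0.0 and not free.rotate
        cw = MachineProtocol.for_condition("cw", cfg.machine, top, ext)
        ccw = MachineProtocol.for_condition("ccw", cfg.machine, top, ext)
        assert cw.direction == -ccw.direction
        assert cw.k_rot == ccw.k_rot == cfg.machine.k_rot


class TestSeeds:
    def test_pure_function(self):
        assert derive_seed(1, "P1", "cw", 0) == derive_seed(1, "P1", "cw", 0)

    def test_replicates_never_share(self):
        seeds = {derive_seed(7, p, c, r)
                 for p in ("P1", "P2") for c in CONDITIONS for r in range(5)}
        assert len(seeds) == 2 * 4 * 5

    def test_below_31_bits(self):
        assert 0 <= derive_seed(2**31 - 1, "P5", "ccw", 2) < 2**31


class TestRunPlan:
    def test_twelve_runs_per_peptide(self):
        plan = RunPlan(peptides=("P1",), replicates=3)
        assert sum(1 for _ in plan.cells()) == 12

    def test_full_design_matrix(self):
        plan = RunPlan(replicates=3)
        cells = list(plan.cells())
        assert len(cells) == 5 * 4 * 3
        assert {c[0] for c in cells} == {"P1", "P2", "P3", "P4", "P5"}
        assert {c[1] for c in cells} == set(CONDITIONS)

    def test_replicates_must_be_positive(self):
        with pytest.raises(ValueError):
            RunPlan(replicates=0)

    def test_execution_and_resume(self, tmp_path):
        cfg = Config()
        plan = RunPlan(peptides=("P2",), conditions=("free", "cw"),
                       replicates=1, base_seed=3,
                       durations_ps={"free": 1.0, "cw": 1.0})
        results = run_plan(plan, cfg, tmp_path)
        assert len(results) == 2
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert all(v["status"] == "done" for v in manifest.values())
        # resume: nothing re-runs, results reload from disk
        stamp = {p: p.stat().st_mtime for p in tmp_path.glob("*/*/rep*/result.json")}
        again = run_plan(plan, cfg, tmp_path)
        assert len(again) == 2
        assert {p: p.stat().st_mtime for p in stamp} == stamp
        for r in again:
            assert r.duration_ps == 1.0 and r.condition in ("free", "cw")


class TestReport:
    def test_table_layout(self, tmp_path):
        from torquefold.analysis import FoldingResult

        results = [FoldingResult("P1", c, s, None, 500.0, 0.8)
                   for c in CONDITIONS for s in (0, 1)]
        results.append(FoldingResult("P2", "cw", 0, 22.0, 100.0, 0.1))
        out = tmp_path / "table2.tsv"
        df = table2_report(results, out)
        assert list(df.columns[:4]) == list(CONDITIONS)
        assert out.exists() and out.with_suffix(".csv").exists()
        body = out.read_text()
        assert "500/500 500/500" in body and "22/100" in body
        # cells parse back to (time, duration) with time <= duration
        for cell in df.loc["P1", list(CONDITIONS)]:
            for item in cell.split():
                t, d = map(float, item.split("/"))
                assert t <= d


class TestFixtures:
    @pytest.mark.parametrize("kind", ["extended", "helix", "perturbed-helix",
                                      "synthetic-pdb", "rmsd-series"])
    def test_deterministic_bytes(self, tmp_path, kind):
        a = generate_fixtures(kind, seed=9, out_dir=tmp_path / "a")
        b = generate_fixtures(kind, seed=9, out_dir=tmp_path / "b")
        for fa, fb in zip(a, b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_rmsd_series_crosses_threshold(self, tmp_path):
        (p,) = generate_fixtures("rmsd-series", 0, tmp_path)
        data = np.loadtxt(p, skiprows=1)
        below = np.nonzero(data[:, 1] <= 0.2)[0]
        assert data[below[0], 0] == 15.0

    def test_helix_fixture_has_helix_dihedrals(self, tmp_path):
        from torquefold.io import read_reference_pdb
        from torquefold.analysis import _dihedrals_for_quads
        from torquefold.protocol import load_registry

        (p,) = generate_fixtures("synthetic-pdb", 0, tmp_path)
        core = load_registry()["P2"].core
        top = build_topology(Sequence(core))
        conf = read_reference_pdb(p, top)
        phi = _dihedrals_for_quads(conf.positions, top.phi_quads[1:])
        assert np.abs(phi + 57.0).max() < 0.5


class TestPdbImport:
    def test_round_trip(self, tmp_path):
        from torquefold.chain import build_ideal_helix
        from torquefold.io import read_reference_pdb, write_pdb

        top = build_topology(Sequence("SWAEFKQRLAAIKTR"))
        conf = build_ideal_helix(top)
        path = tmp_path / "helix.pdb"
        write_pdb(path, top, conf)
        back = read_reference_pdb(path, top)
        assert np.abs(back.positions - conf.positions).max() < 1e-4

    def test_wrong_range_rejected(self, tmp_path):
        from torquefold.chain import build_ideal_helix
        from torquefold.io import read_reference_pdb, write_pdb

        top = build_topology(Sequence("SWAEFKQRLAAIKTR"))
        write_pdb(tmp_path / "h.pdb", top, build_ideal_helix(top))
        short = build_topology(Sequence("SWAEF"))
        with pytest.raises(ValueError):
            read_reference_pdb(tmp_path / "h.pdb", short, res_id_range=(1, 10))

    def test_helical_fragment_close_to_builder(self, tmp_path):
        from torquefold.analysis import kabsch_superpose
        from torquefold.chain import build_ideal_helix
        from torquefold.io import read_reference_pdb, write_pdb

        top = build_topology(Sequence("SWAEFKQRLAAIKTR"))
        conf = build_ideal_helix(top)
        write_pdb(tmp_path / "h.pdb", top, conf)
        back = read_reference_pdb(tmp_path / "h.pdb", top)
        sel = top.backbone_atom_indices(core_only=False)
        _, _, rmsd = kabsch_superpose(back.positions[sel], conf.positions[sel])
        assert rmsd < 0.1


class TestConfig:
    def test_yaml_round_trip_exact(self, tmp_path):
        cfg = Config()
        cfg.machine.rate_deg_ps = 45.5
        cfg.forcefield.eps_hb = 19.25
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.to_dict() == cfg.to_dict()

    def test_dt_stability_warning(self):
        from torquefold.config import IntegratorParams

        with pytest.warns(UserWarning):
            IntegratorParams(dt=0.01).validate(k_bond=20000.0)


class TestCli:
    def test_analyze_reports_first_passage(self, tmp_path):
        from click.testing import CliRunner
        from torquefold.cli import main

        generate_fixtures("rmsd-series", 0, tmp_path)
        runner = CliRunner()
        res = runner.invoke(main, ["analyze", "--rmsd",
                                   str(tmp_path / "rmsd_series.tsv")])
        assert res.exit_code == 0
        assert "folded at 15" in res.output

    def test_run_single_cell(self, tmp_path):
        from click.testing import CliRunner
        from torquefold.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["run", "--peptide", "P2", "--condition",
                                   "free", "--duration-ps", "1",
                                   "--seed", "1", "--out-dir", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "rmsd.tsv").exists()
        assert (tmp_path / "config.yaml").exists()
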