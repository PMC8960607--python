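import json
import time

import numpy as np
import pytest
from click.testing import CliRunner

from ocdsim import degradation as dg
from ocdsim.cli import main as cli_main
from ocdsim.config import preset
from ocdsim.driver import (Failure, detect_failure, make_fixture,
                           run_simulation, write_outputs)
from ocdsim.vtkio import write_lattice_vtk


@pytest.fixture(scope="module")
def small_run():
    fx = make_fixture("small")
    t0 = time.perf_counter()
    result = run_simulation(fx.config, fx.params)
    return fx, result, time.perf_counter() - t0


class TestFixtureRun:
    def test_small_fixture_completes_quickly(self, small_run):
        fx, result, elapsed = small_run
        assert elapsed < 10.0
        assert len(result.records) == 5

    def test_record_schema(self, small_run):
        _, result, _ = small_run
        rec = result.records
        assert list(rec["day"]) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(rec["stiffness"]) <= 1e-9)
        for name in ("resorption", "bone", "cartilage", "fibrous"):
            col = rec[f"frac_{name}"]
            assert np.all((col >= 0) & (col <= 100))

    def test_degradation_disabled_leaves_scaffold_untouched(self):
        import dataclasses
        fx = make_fixture("small")
        frozen = dataclasses.replace(fx.params, k_N=0.0, k_E=0.0, k_e=0.0)
        result = run_simulation(fx.config, frozen)
        assert result.records["mean_modulus"].iloc[-1] == 1000.0
        assert result.records["scaffold_fraction_pct"].iloc[0] == \
            result.records["scaffold_fraction_pct"].iloc[-1]

    def test_full_fixture_matches_reference_configuration(self):
        fx = make_fixture("full")
        assert fx.lattice.n_elements == 1600
        assert fx.params == preset("bulk", "matched")

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("medium")


class TestDeterminism:
    def test_identical_configs_give_byte_identical_outputs(self, tmp_path,
                                                           small_run):
        fx, first, _ = small_run
        second = run_simulation(fx.config, fx.params)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(first, d1)
        write_outputs(second, d2)
        assert (d1 / "timeseries.csv").read_bytes() == \
            (d2 / "timeseries.csv").read_bytes()


class TestOutputs:
    def test_written_files_and_manifest(self, tmp_path, small_run):
        fx, result, _ = small_run
        files = write_outputs(result, tmp_path / "out", vtk=True)
        names = {f.name for f in files}
        assert "timeseries.csv" in names
        assert "manifest.json" in names
        assert "final_fields.vtk" in names
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        layout_m = dg.milestones(fx.params, _layout_of(fx))
        assert manifest["milestones"] == {
            k: v for k, v in layout_m.as_dict().items()}
        assert manifest["config"]["total_days"] == fx.config.total_days

    def test_vtk_writer_emits_legacy_header(self, tmp_path):
        from ocdsim.config import scaled_fixture_config
        cfg = scaled_fixture_config()
        path = tmp_path / "f.vtk"
        write_lattice_vtk(path, cfg, {"demo": np.arange(64.0).reshape(8, 8)})
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert "DATASET STRUCTURED_GRID" in text
        assert "CELL_DATA 64" in text


def _layout_of(fx):
    from ocdsim.config import build_scaffold_layout
    return build_scaffold_layout(fx.lattice, fx.config.strut_center_radii,
                                 fx.config.strut_thickness)


class TestFailureSurrogate:
    def test_undegraded_scaffold_under_physiological_load(self, small_run):
        """No failure for the intact scaffold under the daily load."""
        fx, result, _ = small_run
        assert result.failure is None

    def test_strain_cap_triggers_on_load_bearing_elements(self):
        from ocdsim.config import RunConfig, build_defect_lattice, \
            build_scaffold_layout
        from ocdsim.mechanics import StimulusField
        cfg = RunConfig()
        lat = build_defect_lattice(cfg)
        lay = build_scaffold_layout(lat)
        state = dg.init_scaffold_state(lay, preset("bulk", "matched"))
        big = np.full((40, 40), 150.0)  # gamma 150% everywhere
        stim = StimulusField(big, np.zeros_like(big), big,
                             np.zeros((40, 40), int), -0.001 * np.ones((40, 40)))
        failure = detect_failure(state, stim, cfg)
        assert failure is not None and failure.cause == "excessive_strain"

    def test_empty_shell_gate_requires_degraded_interior(self):
        from ocdsim.config import RunConfig, build_defect_lattice, \
            build_scaffold_layout
        from ocdsim.mechanics import StimulusField
        cfg = RunConfig()
        lat = build_defect_lattice(cfg)
        lay = build_scaffold_layout(lat)
        params = preset("bulk_autocatalytic", "fast")
        state = dg.init_scaffold_state(lay, params)
        small = np.full((40, 40), 0.1)
        ezz = -0.002 * np.ones((40, 40))  # above the thin-sheet Euler strain
        stim = StimulusField(small, np.zeros_like(small), small,
                             np.zeros((40, 40), int), ezz)
        # intact strut: the same strain is far below the intact capacity
        assert detect_failure(state, stim, cfg) is None
        for _ in range(14):
            state = dg.step(state, params)
        assert np.all(state.fully_degraded[state.label == dg.BULK])
        failure = detect_failure(state, stim, cfg)
        assert failure is not None
        assert failure.cause == "empty_shell_buckling"


class TestEquilibrium:
    def test_slow_exponential_tissue_fractions_settle(self, scenario_runs):
        """Between day 75 and day 125 of the slow-exponential run no
        tissue-class area fraction moves by more than 5 points."""
        result = scenario_runs.get("exponential", "slow")
        assert result.failure is None
        assert result.class_fraction_drift(75, 125) <= 5.0


class TestCLI:
    def test_milestones_command(self):
        out = CliRunner().invoke(
            cli_main, ["milestones", "--modality", "exponential",
                       "--speed", "slow"])
        assert out.exit_code == 0
        assert "erosion_onset_day_surface: 768" in out.output

    def test_stiffness_curve_command(self, tmp_path):
        path = tmp_path / "curve.csv"
        out = CliRunner().invoke(
            cli_main, ["stiffness-curve", "--modality", "bulk",
                       "--speed", "matched", "--days", "10",
                       "--out", str(path)])
        assert out.exit_code == 0
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 12  # header + days 0..10
        assert lines[1].startswith("0,2445")

    def test_simulate_command_small_config(self, tmp_path):
        cfg = tmp_path / "run.toml"
        cfg.write_text(
            "[geometry]\nelement_size = 0.625\nstrut_center_radii = [2.5]\n"
            "strut_thickness = 1.25\n"
            "[mechanics]\nfe_element_size = 2.5\n"
            "n_compression_steps = 3\nn_consolidation_steps = 3\n"
            "[degradation]\nmodality = 'bulk'\nspeed = 'matched'\n"
            "[run]\ntotal_days = 3\n")
        out = CliRunner().invoke(
            cli_main, ["simulate", "--config", str(cfg),
                       "--out", str(tmp_path / "res")])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "res" / "timeseries.csv").exists()
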