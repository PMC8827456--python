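"""Orchestrator: metrics, presets, determinism, bookkeeping."""

import dataclasses

import numpy as np
import pytest

from thrombosim import flow as fl
from thrombosim import geometry as geo
from thrombosim import simulation as sim

FAST_FLOW = fl.FlowParams(inlet_wall_shear=200.0, convergence_tol=5e-4,
                          check_every=50)


def tiny_config(**overrides):
    cfg = sim.SimulationConfig(
        geometry={"kind": "channel", "length": 150.0, "width": 50.0,
                  "height": 40.0, "patch_start": 50.0, "patch_length": 50.0,
                  "h": 5.0, "tf_on": True},
        flow=FAST_FLOW,
        schedule=sim.ScheduleParams(t_end=20.0, flow_resolve_interval=5.0,
                                    flow_resolve_voxels=50, output_interval=5.0),
        lkmc=sim.LKMCParams(mean_concentration=5.0e4),
        seed=3,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestClotHeightProfile:
    def test_single_platelet(self, small_channel):
        mask = np.zeros(small_channel.shape, dtype=bool)
        mask[12, 4, 0] = True
        prof = sim.clot_height_profile(mask, small_channel)
        assert prof[12] == pytest.approx(small_channel.h)
        assert prof.sum() == pytest.approx(small_channel.h)

    def test_full_monolayer_flat(self, small_channel):
        mask = np.zeros(small_channel.shape, dtype=bool)
        mask[10:20, :, 0] = True
        prof = sim.clot_height_profile(mask, small_channel)
        assert np.allclose(prof[10:20], small_channel.h)
        assert np.all(prof[:10] == 0) and np.all(prof[20:] == 0)

    def test_synthetic_dome_recovered(self, small_channel):
        """A deposit of known column heights is read back exactly."""
        nx, ny, nz = small_channel.shape
        h = small_channel.h
        rng = np.random.default_rng(5)
        heights = rng.integers(1, nz, size=(6, ny))
        mask = np.zeros(small_channel.shape, dtype=bool)
        for di in range(6):
            for j in range(ny):
                mask[10 + di, j, : heights[di, j]] = True
        prof = sim.clot_height_profile(mask, small_channel)
        expect = heights.mean(axis=1) * h
        np.testing.assert_allclose(prof[10:16], expect)


class TestOcclusionTime:
    def _result(self, times, Q, Q0=1.0):
        r = object.__new__(sim.SimulationResult)
        r.times = np.asarray(times, float)
        r.Q = np.asarray(Q, float)
        r.Q0 = Q0
        return r

    def test_constant_flow_never_occludes(self):
        assert sim.occlusion_time(self._result([0, 10, 20], [1, 1, 1])) is None

    def test_linear_interpolation_of_crossing(self):
        # Q drops from Q0 to 0.04 Q0 between t=0 and t=10:
        # crossing 0.05 at t = 10 * (1 - 0.05) / (1 - 0.04)
        t = sim.occlusion_time(self._result([0.0, 10.0], [1.0, 0.04]))
        assert t == pytest.approx(10.0 * 0.95 / 0.96)

    def test_first_crossing_reported_on_recovery(self):
        t = sim.occlusion_time(
            self._result([0, 10, 20, 30], [1.0, 0.02, 0.8, 0.01])
        )
        assert 0 < t < 10


class TestPresets:
    def test_stenosis_75_parameters(self):
        cfg = sim.get_preset("stenosis_75")
        assert cfg.geometry["area_reduction"] == 0.75
        assert cfg.flow.bc_kind == "constant_pressure_drop"
        assert cfg.pressure_from_shear == 1000.0

    def test_channel_preset_with_treatment(self):
        cfg = sim.get_preset("channel_200", treatment="no_ADP")
        assert cfg.treatment == "no_ADP"
        assert cfg.flow.inlet_wall_shear == 200.0

    def test_tube_preset_geometry(self):
        cfg = sim.get_preset("tube_100")
        assert cfg.geometry["diameter"] == 60.0
        assert cfg.geometry["patch_arc_fraction"] == 0.5
        assert cfg.flow.inlet_wall_shear == 100.0

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="stenosis_75"):
            sim.get_preset("nope")

    def test_full_scale_flag_restores_paper_resolution(self):
        desk = sim.get_preset("channel_200")
        full = sim.get_preset("channel_200", full_scale=True)
        assert full.geometry["h"] < desk.geometry["h"]
        assert full.schedule.t_end >= 400.0


class TestRun:
    def test_zero_horizon_empty(self):
        res = sim.run(tiny_config(schedule=sim.ScheduleParams(t_end=0.0)))
        assert len(res.times) == 1
        assert res.platelet_count[0] == 0

    def test_determinism_bit_identical(self):
        r1 = sim.run(tiny_config())
        r2 = sim.run(tiny_config())
        np.testing.assert_array_equal(r1.platelet_count, r2.platelet_count)
        np.testing.assert_array_equal(r1.Q, r2.Q)
        np.testing.assert_array_equal(r1.injected, r2.injected)
        assert [p.voxel for p in r1.final_snapshot] == \
            [p.voxel for p in r2.final_snapshot]

    def test_platelet_bookkeeping(self):
        res = sim.run(tiny_config())
        in_domain = res.platelet_count[-1] + res.mobile_count[-1]
        assert res.injected[-1] == in_domain + res.exited[-1]

    def test_constant_basal_model_limits_to_primary_adhesion(self):
        """A plug-in calcium model pinned at basal level: no granule release
        and essentially no growth beyond the collagen monolayer."""

        class BasalModel:
            def initial_aux(self, n):
                return np.zeros((n, 3))

            def step(self, ca, aux, exposure, dt):
                return np.full_like(np.asarray(ca, float), 100.0), aux

        cfg = tiny_config(calcium_model=BasalModel())
        cfg.schedule = sim.ScheduleParams(t_end=40.0, flow_resolve_interval=10.0,
                                          flow_resolve_voxels=100,
                                          output_interval=10.0)
        res = sim.run(cfg)
        assert all(not p.release_triggered for p in res.final_snapshot)
        above_floor = res.bound_mask[:, :, 1:].sum()
        assert above_floor <= max(0.15 * res.bound_mask.sum(), 2)

    def test_collagen_platelets_more_activated_than_shell(self):
        res = sim.run(tiny_config(schedule=sim.ScheduleParams(
            t_end=60.0, flow_resolve_interval=10.0, flow_resolve_voxels=100,
            output_interval=20.0)))
        assert res.mean_xi_collagen_thrombin > res.mean_xi_soluble_only


class TestIO:
    def test_outputs_roundtrip(self, tmp_path):
        import h5py

        from thrombosim import io as tio

        res = sim.run(tiny_config())
        tio.write_metrics_csv(tmp_path / "m.csv", res)
        tio.write_platelets_h5(tmp_path / "p.h5", res)
        tio.write_vtk_scalars(tmp_path / "f.vtk", res.domain.h,
                              {"bound": res.bound_mask.astype(float)})
        lines = (tmp_path / "m.csv").read_text().splitlines()
        assert lines[0].startswith("t_s,")
        assert len(lines) == len(res.times) + 1
        with h5py.File(tmp_path / "p.h5") as f:
            assert f["voxel"].shape[0] == len(res.final_snapshot)
        head = (tmp_path / "f.vtk").read_text().splitlines()[:7]
        assert head[3] == "DATASET STRUCTURED_POINTS"
        nx, ny, nz = res.domain.shape
        assert head[4] == f"DIMENSIONS {nx} {ny} {nz}"


class TestCLI:
    def test_run_from_yaml(self, tmp_path):
        from click.testing import CliRunner

        from thrombosim.cli import main

        cfg = """
geometry:
  kind: channel
  length: 150.0
  width: 50.0
  height: 40.0
  patch_start: 50.0
  patch_length: 50.0
  h: 5.0
  tf_on: true
flow: {inlet_wall_shear: 200.0, convergence_tol: 5.0e-4, check_every: 50}
schedule: {t_end: 5.0, flow_resolve_interval: 10.0, output_interval: 5.0}
seed: 4
"""
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(cfg)
        runner = CliRunner()
        out_dir = tmp_path / "out"
        result = runner.invoke(
            main, ["run", str(cfg_path), "--out", str(out_dir), "--seed", "4"]
        )
        assert result.exit_code == 0, result.output
        for fname in ("metrics.csv", "platelets_final.h5", "run_manifest.json",
                      "clot_final.vtk"):
            assert (out_dir / fname).exists()

    def test_presets_listed(self):
        from click.testing import CliRunner

        from thrombosim.cli import main

        result = CliRunner().invoke(main, ["presets"])
        assert result.exit_code == 0
        assert "stenosis_75" in result.output
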