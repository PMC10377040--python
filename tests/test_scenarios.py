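"""Scenario presets, summary metrics and the run driver."""

import json

import numpy as np
import pytest

from abdyn import (
    PRESET_NAMES,
    Trajectory,
    initial_composition,
    metrics,
    preset,
    run,
)


def _model2_traj(y_rows, times=None):
    """Assemble a minimal Model 2 trajectory from per-time y vectors."""
    y = np.atleast_2d(np.asarray(y_rows, dtype=float))
    nt, n = y.shape
    times = np.arange(nt, dtype=float) if times is None else np.asarray(times)
    states = np.hstack([np.full((nt, 1), 2e6), np.zeros((nt, n)), y])
    labels = ("z",) + tuple(f"x_{i}" for i in range(1, n + 1)) + tuple(
        f"y_{i}" for i in range(1, n + 1))
    return Trajectory(times=times, states=states, labels=labels)


class TestPresets:
    def test_all_names_resolve(self):
        for name in PRESET_NAMES:
            assert preset(name).name == name

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="clonal_deletion"):
            preset("not_a_scenario")

    def test_clonal_deletion_parameters(self):
        spec = preset("clonal_deletion")
        p = spec.params
        assert (p.k3, p.k4, p.k6) == (0.5, 0.1, 0.02)
        assert p.k_minus2 == 1e-18
        assert {m.k2 for m in spec.members.values()} == {1e-8, 1e-9}
        s = spec.initial_state
        assert (s.x, s.y, s.z) == (0.0, 1e5, 3e7)

    def test_pathogen_selection_parameters(self):
        spec = preset("pathogen_selection")
        clones = spec.members["competition"]
        assert [c.k2 for c in clones] == [1e-5, 9e-6, 8e-6, 7e-6, 6e-6]
        assert clones[0].k1 == 0.1 and clones[0].k5 == 0.02
        assert clones[0].k3 == 1.0 and clones[0].k4 == 2.0

    def test_shm_presets_parameters(self):
        tol = preset("shm_self_tolerance")
        assert tol.params.k4 == 0.6
        assert tol.p_values == (0.1, 0.2, 0.3, 0.4)
        assert tol.initial_state.y[8] == 1e5
        assert tol.initial_state.y[:8].sum() == 0.0

        foreign = preset("shm_foreign")
        assert foreign.params.k4 == 1.1
        assert foreign.p_values == (0.0, 0.5)
        # seeded in the weakest-binding class
        assert foreign.initial_state.y[0] == 1e5
        assert foreign.initial_state.y[1:].sum() == 0.0

    def test_aging_initial_state_is_normal_composition(self):
        spec = preset("aging_sweep")
        assert spec.params.k4 == 0.7
        np.testing.assert_allclose(
            spec.initial_state.y,
            initial_composition(spec.params.grid, 1e6),
        )
        assert spec.report_times[0] == 0.0
        assert spec.report_times[-1] == spec.t_end


class TestMetrics:
    def test_uniform_repertoire(self):
        m = metrics(_model2_traj([np.ones(9), np.ones(9)]))
        np.testing.assert_allclose(m.composition, 1.0 / 9)
        assert list(m.dominant_class) == [1, 1]  # ties break low
        np.testing.assert_allclose(m.mean_class_index, 5.0)

    def test_concentrated_repertoire(self):
        y = np.zeros(9)
        y[6] = 42.0
        m = metrics(_model2_traj([y]))
        assert m.dominant_class[0] == 7
        assert m.mean_class_index[0] == pytest.approx(7.0)
        assert m.total_antibody[0] == pytest.approx(42.0)

    def test_composition_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        m = metrics(_model2_traj(rng.uniform(0.1, 9.0, size=(6, 9))))
        np.testing.assert_allclose(m.composition.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_zero_total_flagged_as_nan(self):
        m = metrics(_model2_traj([np.zeros(9), np.ones(9)]))
        assert np.all(np.isnan(m.composition[0]))
        assert np.isfinite(m.composition[1]).all()

    def test_time_to_fraction(self):
        rows = [np.full(9, v) for v in (8.0, 6.0, 3.0, 1.0)]
        m = metrics(_model2_traj(rows))
        assert m.time_to_fraction(1, 0.5) == 2.0  # first sample at <= 4.0
        assert m.time_to_fraction(1, 0.01) is None

    def test_rejects_single_antibody_trajectory(self):
        traj = Trajectory(times=np.array([0.0, 1.0]),
                          states=np.zeros((2, 3)), labels=("x", "y", "z"))
        with pytest.raises(ValueError):
            metrics(traj)

    def test_shm_accelerates_self_binder_elimination(self):
        # time for the seeded strong binder to fall to 1% of its start
        # shrinks as the hypermutation rate grows (at p=0.1 it never
        # happens: the clone's net growth is positive)
        out = run(preset("shm_self_tolerance"))
        times = [out[label][1].time_to_fraction(9, 0.01)
                 for label in ("p=0.1", "p=0.2", "p=0.3", "p=0.4")]
        finite = [np.inf if t is None else t for t in times]
        assert all(a > b for a, b in zip(finite, finite[1:]))


class TestRun:
    def test_deterministic_repeat(self):
        spec = preset("clonal_deletion")
        a = run(spec)["strong_binder"][0]
        b = run(spec)["strong_binder"][0]
        assert np.array_equal(a.states, b.states)

    def test_member_count_matches_sweep(self):
        out = run(preset("shm_self_tolerance"))
        assert sorted(out) == ["p=0.1", "p=0.2", "p=0.3", "p=0.4"]
        for traj, summ in out.values():
            assert summ is not None
            assert summ.composition.shape[1] == 9

    def test_model1_members_have_no_repertoire_metrics(self):
        out = run(preset("clonal_deletion"))
        for _, summ in out.values():
            assert summ is None

    def test_output_files(self, tmp_path):
        spec = preset("clonal_deletion")
        run(spec, out_dir=tmp_path)
        csvs = sorted(p.name for p in tmp_path.glob("*.csv"))
        assert csvs == ["clonal_deletion_strong_binder.csv",
                        "clonal_deletion_weak_binder.csv"]
        payload = json.loads(
            (tmp_path / "clonal_deletion_metrics.json").read_text())
        assert payload["scenario"] == "clonal_deletion"
        # CSV parses back to the in-memory trajectory at full precision
        traj = run(spec)["strong_binder"][0]
        back = Trajectory.from_csv(tmp_path / "clonal_deletion_strong_binder.csv")
        np.testing.assert_array_equal(back.states, traj.states)
        assert back.labels == traj.labels
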