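"""Multilevel VAR estimation: single-subject oracle, shrinkage, networks."""

import numpy as np
import pandas as pd
import pytest

from emonet.ema_data import NEGATIVE_EMOTIONS, EmaPanel, StudyDesign, build_lagged_design
from emonet.mlvar import (
    EstimationError,
    FixedEffects,
    MlvarFit,
    RandomEffects,
    PersonNetwork,
    fit_mlvar,
    fit_var_single,
    group_network,
    networks_to_edgelist,
    person_networks,
)


def _design_frame(series: dict[str, np.ndarray], sid="s"):
    """One subject, one long day: turn value series into lagged x/y rows."""
    emotions = list(series)
    T = len(next(iter(series.values())))
    rows = {"subject_id": [sid] * (T - 1), "day_index": [1] * (T - 1), "slot_t0": range(2, T + 1)}
    for e, v in series.items():
        v = np.asarray(v, dtype=float)
        rows[f"x_{e}"] = v[:-1] - v.mean()
        rows[f"y_{e}"] = v[1:]
    return pd.DataFrame(rows), tuple(emotions)


class TestFitVarSingle:
    def test_alternating_series_autoregression_is_minus_one(self):
        x = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        y = np.array([0.0, 0.01, -0.01, 0.02, -0.02, 0.0])  # tiny jitter: nonzero variance
        frame, emotions = _design_frame({"a": x, "b": y})
        Phi = fit_var_single(frame, emotions)
        assert Phi[0, 0] == pytest.approx(-1.0, abs=1e-9)
        assert abs(Phi[0, 1]) < 0.1  # jitter cannot predict the alternation scale
        assert abs(Phi[1, 0]) < 0.05

    def test_iid_noise_coefficients_vanish_for_long_series(self):
        rng = np.random.default_rng(0)
        frame, emotions = _design_frame({"a": rng.normal(size=5000), "b": rng.normal(size=5000)})
        Phi = fit_var_single(frame, emotions)
        assert np.all(np.abs(Phi) < 0.05)

    def test_constant_series_guarded(self):
        frame, emotions = _design_frame({"a": np.full(10, 50.0), "b": np.arange(10.0)})
        with pytest.raises(EstimationError, match="zero variance"):
            fit_var_single(frame, emotions)

    def test_too_few_rows(self):
        frame, emotions = _design_frame({"a": [1.0, 2.0, 0.5], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(EstimationError, match="at least"):
            fit_var_single(frame, emotions)

    def test_known_var_recovered_exactly_from_noiseless_recursion(self):
        # x_t = A x_{t-1} exactly -> least squares returns A
        A = np.array([[0.5, 0.2], [-0.1, 0.3]])
        x = np.empty((12, 2))
        x[0] = [1.0, -2.0]
        for t in range(1, 12):
            x[t] = A @ x[t - 1]
        frame, emotions = _design_frame({"a": x[:, 0], "b": x[:, 1]})
        # noiseless series is centered at ~0; re-center exactly like the oracle
        Phi = fit_var_single(frame, emotions)
        assert np.allclose(Phi, A, atol=1e-6)


class TestNoPoolingLimit:
    def test_pooled_fit_equals_single_subject_least_squares(self, small_cohort):
        cfg, panel, _ = small_cohort
        one = EmaPanel(
            panel.data[panel.data["subject_id"] == 1].reset_index(drop=True),
            panel.design,
            panel.emotion_names,
        )
        design = build_lagged_design(one, cfg.emotions)
        fit = fit_mlvar(design, re_structure="pooled")
        Phi = fit_var_single(design)
        assert np.allclose(fit.fixed.B, Phi, atol=1e-6)

    def test_multilevel_refuses_single_subject(self, small_cohort):
        cfg, panel, _ = small_cohort
        one = EmaPanel(
            panel.data[panel.data["subject_id"] == 1].reset_index(drop=True),
            panel.design,
            panel.emotion_names,
        )
        design = build_lagged_design(one, cfg.emotions)
        with pytest.raises(EstimationError, match="fit_var_single"):
            fit_mlvar(design)


class TestMultilevel:
    def test_identical_subjects_have_no_between_variance(self):
        rng = np.random.default_rng(1)
        T = 60
        base = {
            "a": 50 + rng.normal(0, 10, T).cumsum() * 0.1 + rng.normal(0, 5, T),
            "b": 40 + rng.normal(0, 5, T),
        }
        frames = []
        for sid in ("s1", "s2", "s3"):
            f, emotions = _design_frame(base, sid=sid)
            frames.append(f)
        from emonet.ema_data import LaggedDesign

        data = pd.concat(frames, ignore_index=True)
        means = pd.DataFrame(
            {e: [np.mean(base[e])] * 3 for e in base}, index=["s1", "s2", "s3"]
        )
        design = LaggedDesign(data, means, emotions)
        fit = fit_mlvar(design, re_structure="diagonal")
        nets = person_networks(fit)
        for net in nets:
            assert np.allclose(net.Phi, fit.fixed.B, atol=1e-2)

    def test_person_network_count_and_shrinkage(self, small_fit):
        cfg, truth, design, fit = small_fit
        nets = person_networks(fit)
        assert len(nets) == cfg.n_subjects
        # empirical-Bayes contraction: person networks vary less than
        # per-subject least-squares fits on the same data
        singles = []
        for sid in design.subjects:
            rows = design.data[design.data["subject_id"] == sid]
            singles.append(fit_var_single(rows, cfg.emotions))
        singles = np.stack(singles)
        eb = np.stack([n.Phi for n in nets])
        assert np.all(eb.var(axis=0) <= singles.var(axis=0) + 1e-12)

    def test_blups_center_near_zero(self, small_fit):
        *_, fit = small_fit
        mean_dev = np.mean([fit.random.b[s] for s in fit.random.subjects], axis=0)
        assert np.all(np.abs(mean_dev) < 0.02)

    def test_subject_relabeling_invariance(self, small_cohort):
        cfg, panel, _ = small_cohort
        design = build_lagged_design(panel, cfg.emotions)
        relabeled = EmaPanel(
            panel.data.assign(subject_id=panel.data["subject_id"] + 1000),
            panel.design,
            panel.emotion_names,
        )
        design2 = build_lagged_design(relabeled, cfg.emotions)
        f1 = fit_mlvar(design, re_structure="intercept_only")
        f2 = fit_mlvar(design2, re_structure="intercept_only")
        assert np.allclose(f1.fixed.B, f2.fixed.B, atol=1e-6)

    def test_emotion_permutation_equivariance(self, small_cohort):
        cfg, panel, _ = small_cohort
        perm = (2, 0, 3, 1)
        emotions_p = tuple(cfg.emotions[i] for i in perm)
        f1 = fit_mlvar(build_lagged_design(panel, cfg.emotions), re_structure="intercept_only")
        f2 = fit_mlvar(build_lagged_design(panel, emotions_p), re_structure="intercept_only")
        P = np.asarray(perm)
        assert np.allclose(f1.fixed.B[np.ix_(P, P)], f2.fixed.B, atol=1e-6)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(2)
        frames = []
        for sid in range(4):
            v = rng.normal(50, 10, 40)
            f, _ = _design_frame({"a": v, "b": v * 1.0}, sid=sid)
            frames.append(f)
        from emonet.ema_data import LaggedDesign

        design = LaggedDesign(pd.concat(frames, ignore_index=True), None, ("a", "b"))
        with pytest.raises(EstimationError, match="collinear"):
            fit_mlvar(design, re_structure="intercept_only")


class TestGroupNetwork:
    def _fit_with_pvalues(self, pv):
        p = pv.shape[0]
        emotions = tuple("abcd"[:p])
        fixed = FixedEffects(emotions, np.zeros(p), np.full((p, p), 0.2), np.ones((p, p)), pv)
        random = RandomEffects((), {}, {}, [])
        return MlvarFit(fixed=fixed, random=random)

    def test_all_insignificant_gives_empty_network(self):
        g = group_network(self._fit_with_pvalues(np.ones((4, 4))))
        assert g.number_of_edges() == 0
        assert set(g.nodes) == set("abcd")

    def test_threshold_and_direction(self):
        pv = np.ones((3, 3))
        pv[1, 0] = 0.01  # emotion 0 at t-1 predicts emotion 1 at t0
        g = group_network(self._fit_with_pvalues(pv), alpha=0.05)
        assert list(g.edges) == [("a", "b")]
        assert g.edges["a", "b"]["weight"] == pytest.approx(0.2)

    def test_edgelist_export_shape(self, small_fit):
        *_, fit = small_fit
        nets = person_networks(fit)
        edges = networks_to_edgelist(nets)
        assert len(edges) == len(nets) * 16
        assert set(edges.columns) == {"subject_id", "from", "to", "weight"}
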