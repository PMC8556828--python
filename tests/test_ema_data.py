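"""Panel reading, exclusion rules, lag construction and design arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emonet.ema_data import (
    NEGATIVE_EMOTIONS,
    EmaPanel,
    ExclusionReport,
    PanelConfigError,
    PanelValidationError,
    StudyDesign,
    apply_exclusions,
    build_lagged_design,
    design_arithmetic,
    read_ema_panel,
)

DESIGN = StudyDesign()


def _write(df, path, sep=";"):
    df.to_csv(path, sep=sep, index=False)
    return path


def _full_subject_frame(sid, design=DESIGN, value=None, rng=None):
    rows = []
    for day in range(1, design.n_days + 1):
        for slot in range(1, design.prompts_per_day + 1):
            vals = (
                np.full(4, value)
                if value is not None
                else rng.uniform(5, 95, 4)
            )
            rows.append((sid, day, slot, *vals))
    return pd.DataFrame(rows, columns=["subject_id", "day_index", "slot_index", *NEGATIVE_EMOTIONS])


class TestReader:
    def test_toy_file_row_count(self, toy_panel_frame, tmp_path):
        path = _write(toy_panel_frame, tmp_path / "ema.csv")
        panel = read_ema_panel(
            path,
            design=StudyDesign(n_days=2, prompts_per_day=3),
            emotion_columns={e: e for e in NEGATIVE_EMOTIONS},
        )
        assert len(panel.data) == 12
        assert panel.n_subjects == 2

    def test_out_of_range_rating_rejected(self, toy_panel_frame, tmp_path):
        bad = toy_panel_frame.copy()
        bad.loc[3, "stressed"] = 150.0
        path = _write(bad, tmp_path / "bad.csv")
        with pytest.raises(PanelValidationError, match=r"outside \[0, 100\]"):
            read_ema_panel(path, design=StudyDesign(n_days=2, prompts_per_day=3),
                           emotion_columns={e: e for e in NEGATIVE_EMOTIONS})

    def test_duplicate_prompt_rejected(self, toy_panel_frame, tmp_path):
        dup = pd.concat([toy_panel_frame, toy_panel_frame.iloc[[0]]])
        path = _write(dup, tmp_path / "dup.csv")
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_ema_panel(path, design=StudyDesign(n_days=2, prompts_per_day=3),
                           emotion_columns={e: e for e in NEGATIVE_EMOTIONS})

    def test_unknown_emotion_column_is_config_error(self, toy_panel_frame, tmp_path):
        path = _write(toy_panel_frame, tmp_path / "ema.csv")
        with pytest.raises(PanelConfigError, match="angry"):
            read_ema_panel(path, design=StudyDesign(n_days=2, prompts_per_day=3),
                           emotion_columns={"angry": "angry"})


class TestExclusions:
    def _panel_with_missing(self, n_answered):
        rng = np.random.default_rng(0)
        df = _full_subject_frame("s1", rng=rng)
        df = df.iloc[:n_answered]
        return EmaPanel(df, DESIGN, NEGATIVE_EMOTIONS)

    def test_over_20_percent_missing_excluded(self):
        # 67 of 85 answered: 18/85 = 21.2% missing -> excluded
        panel = self._panel_with_missing(67)
        with pytest.raises(PanelValidationError, match="no subjects retained"):
            apply_exclusions(panel, {"s1": True})

    def test_exactly_20_percent_missing_retained(self):
        # 68 of 85 answered: exactly 20% missing; "more than 20%" is strict
        panel = self._panel_with_missing(68)
        kept, report = apply_exclusions(panel, {"s1": True})
        assert report.n_final == 1
        assert report.n_excess_missing_ema == 0

    def test_burnout_missing_counted_first(self):
        rng = np.random.default_rng(1)
        df = pd.concat(
            [_full_subject_frame("ok", rng=rng), _full_subject_frame("both", rng=rng).iloc[:50]]
        )
        panel = EmaPanel(df.reset_index(drop=True), DESIGN, NEGATIVE_EMOTIONS)
        # 'both' lacks burnout AND has >20% missing EMA: counted as burnout-missing
        kept, report = apply_exclusions(panel, {"ok": True, "both": False})
        assert report.n_missing_burnout == 1
        assert report.n_excess_missing_ema == 0
        assert report.n_final == 1

    def test_partition_identity_is_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            ExclusionReport(n_enrolled=10, n_missing_burnout=2, n_excess_missing_ema=3, n_final=6)

    @settings(max_examples=25, deadline=None)
    @given(
        n_sub=st.integers(3, 10),
        data=st.data(),
    )
    def test_partition_identity_on_random_panels(self, n_sub, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        frames = []
        burnout = {}
        for i in range(n_sub):
            sid = f"s{i}"
            n_ans = data.draw(st.integers(40, 85))
            frames.append(_full_subject_frame(sid, rng=rng).iloc[:n_ans])
            burnout[sid] = data.draw(st.booleans())
        panel = EmaPanel(pd.concat(frames, ignore_index=True), DESIGN, NEGATIVE_EMOTIONS)
        try:
            _, rep = apply_exclusions(panel, burnout)
        except PanelValidationError:
            return  # everyone excluded; partition trivially checked inside
        assert rep.n_enrolled == rep.n_missing_burnout + rep.n_excess_missing_ema + rep.n_final


class TestLaggedDesign:
    def test_complete_subject_yields_68_transitions(self):
        rng = np.random.default_rng(2)
        panel = EmaPanel(_full_subject_frame("s", rng=rng), DESIGN, NEGATIVE_EMOTIONS)
        design = build_lagged_design(panel, NEGATIVE_EMOTIONS)
        # 85 prompts minus 17 overnight transitions
        assert design.n_rows == 68

    def test_missing_interior_cell_drops_two_transitions(self):
        rng = np.random.default_rng(3)
        df = _full_subject_frame("s", rng=rng)
        mask = (df["day_index"] == 3) & (df["slot_index"] == 2)
        df.loc[mask, "worried"] = np.nan
        panel = EmaPanel(df, DESIGN, NEGATIVE_EMOTIONS)
        design = build_lagged_design(panel, NEGATIVE_EMOTIONS)
        assert design.n_rows == 66  # slot1->2 and slot2->3 of day 3 both gone

    def test_listwise_deletion_monotone(self):
        rng = np.random.default_rng(4)
        df = _full_subject_frame("s", rng=rng)
        base = build_lagged_design(EmaPanel(df.copy(), DESIGN, NEGATIVE_EMOTIONS), NEGATIVE_EMOTIONS).n_rows
        for idx in (0, 10, 42, 84):
            df2 = df.copy()
            df2.loc[idx, "frustrated"] = np.nan
            n = build_lagged_design(EmaPanel(df2, DESIGN, NEGATIVE_EMOTIONS), NEGATIVE_EMOTIONS).n_rows
            assert base - 2 <= n <= base

    def test_constant_subject_centers_to_zero(self):
        panel = EmaPanel(_full_subject_frame("s", value=50.0), DESIGN, NEGATIVE_EMOTIONS)
        design = build_lagged_design(panel, NEGATIVE_EMOTIONS)
        assert np.allclose(design.data[design.predictor_columns()].to_numpy(), 0.0)

    def test_centering_mean_zero_over_observed_ratings(self):
        rng = np.random.default_rng(5)
        panel = EmaPanel(_full_subject_frame("s", rng=rng), DESIGN, NEGATIVE_EMOTIONS)
        design = build_lagged_design(panel, NEGATIVE_EMOTIONS)
        raw = panel.data.groupby("subject_id")[list(NEGATIVE_EMOTIONS)].mean()
        assert np.allclose(raw.loc["s"].to_numpy(), design.person_means.loc["s"].to_numpy())

    def test_no_overnight_transitions(self):
        rng = np.random.default_rng(6)
        panel = EmaPanel(_full_subject_frame("s", rng=rng), DESIGN, NEGATIVE_EMOTIONS)
        design = build_lagged_design(panel, NEGATIVE_EMOTIONS)
        assert (design.data["slot_t0"] >= 2).all()


class TestDesignArithmetic:
    @pytest.mark.parametrize(
        "days,ppd,missing,expect",
        [
            (17, 5, 0.0, {"total_prompts": 85, "usable_transitions": 68, "expected_assessments": 68}),
            (17, 5, 0.20, {"expected_assessments": 54, "expected_complete_transitions": 43}),
            (2, 2, 0.0, {"total_prompts": 4, "usable_transitions": 2}),
        ],
    )
    def test_planning_examples(self, days, ppd, missing, expect):
        out = design_arithmetic(StudyDesign(n_days=days, prompts_per_day=ppd), missing)
        for k, v in expect.items():
            assert out[k] == v

    def test_overnight_loss_is_one_per_day(self):
        for days, ppd in [(3, 4), (10, 2), (17, 5)]:
            out = design_arithmetic(StudyDesign(n_days=days, prompts_per_day=ppd), 0.0)
            assert out["usable_transitions"] == ppd * days - days

    def test_invalid_missing_rate(self):
        with pytest.raises(ValueError):
            design_arithmetic(DESIGN, 1.0)


def test_day_index_inferred_from_timestamps_at_midnight_boundary():
    from emonet.ema_data import infer_day_index_from_timestamps

    df = pd.DataFrame(
        {
            "subject_id": ["s"] * 4,
            "timestamp": pd.to_datetime(
                ["2020-01-01 07:30", "2020-01-01 23:59", "2020-01-02 00:01", "2020-01-04 12:00"]
            ),
        }
    )
    assert infer_day_index_from_timestamps(df).tolist() == [1, 1, 2, 4]
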