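"""Reading, validation and preparation of ecological momentary assessment panels.

An EMA panel is a long table of momentary emotion ratings: one row per
answered prompt, identified by (subject, study day, prompt-of-day slot), with
ratings on a 0-100 visual-analogue scale.  Preparation for the temporal
network model means

* excluding subjects with a missing burnout assessment or excessive EMA
  nonresponse,
* pairing consecutive same-day prompts into (t-1, t0) transitions while
  removing the overnight lag (last prompt of a day onto the first of the
  next), because that interval is much longer than the within-day lag,
* within-person centering of the lagged predictors, and
* listwise deletion of transitions with any missing rating among the
  modeled emotions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Emotion item sets, in their canonical display order.
NEGATIVE_EMOTIONS: tuple[str, ...] = ("frustrated", "stressed", "worried", "exhausted")
POSITIVE_EMOTIONS: tuple[str, ...] = ("happy", "satisfied", "relaxed", "full_of_energy")

RATING_MIN = 0.0
RATING_MAX = 100.0


class PanelValidationError(ValueError):
    """A panel violates a structural or range constraint."""


class PanelConfigError(ValueError):
    """The column mapping does not match the file."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule of the EMA protocol.

    Defaults follow a 17-day protocol with five prompts per day, delivered
    pseudorandomly within 30-minute windows between 06:00 and 18:00 on
    workdays (08:00-20:00 on weekends), with a 90-minute response window.
    """

    n_days: int = 17
    prompts_per_day: int = 5
    workday_window: tuple[time, time] = (time(6, 0), time(18, 0))
    weekend_window: tuple[time, time] = (time(8, 0), time(20, 0))
    prompt_window_minutes: int = 30
    response_window_minutes: int = 90

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (lagged design needs at least two days)")
        if self.prompts_per_day < 2:
            raise ValueError("prompts_per_day must be >= 2 (no within-day lag otherwise)")
        for lo, hi in (self.workday_window, self.weekend_window):
            if not lo < hi:
                raise ValueError("clock windows must have start < end")

    @property
    def total_prompts(self) -> int:
        return self.n_days * self.prompts_per_day


@dataclass
class EmaPanel:
    """Long-format EMA ratings with schedule metadata.

    ``data`` has columns ``subject_id``, ``day_index`` (1-based),
    ``slot_index`` (1-based), optionally ``timestamp``, and one float column
    per emotion in ``emotion_names`` (NaN = missing rating).
    """

    data: pd.DataFrame
    design: StudyDesign
    emotion_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.emotion_names = tuple(self.emotion_names)
        required = {"subject_id", "day_index", "slot_index", *self.emotion_names}
        missing = required - set(self.data.columns)
        if missing:
            raise PanelConfigError(f"panel frame lacks columns: {sorted(missing)}")
        validate_panel_frame(self.data, self.design, self.emotion_names)

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject_id"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def answered_counts(self) -> pd.Series:
        """Answered prompts per subject (rows with at least one rating)."""
        answered = self.data[list(self.emotion_names)].notna().any(axis=1)
        return self.data.loc[answered].groupby("subject_id").size().reindex(
            self.subjects, fill_value=0
        )

    def completion_fractions(self) -> pd.Series:
        """Answered prompts divided by scheduled prompts, per subject."""
        return self.answered_counts() / self.design.total_prompts

    def to_csv(self, path: str | Path, sep: str = ";") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def validate_panel_frame(
    df: pd.DataFrame, design: StudyDesign, emotions: Sequence[str]
) -> None:
    if df["slot_index"].min() < 1 or df["slot_index"].max() > design.prompts_per_day:
        bad = df.loc[
            (df["slot_index"] < 1) | (df["slot_index"] > design.prompts_per_day)
        ].iloc[0]
        raise PanelValidationError(
            f"slot_index {bad['slot_index']} out of 1..{design.prompts_per_day} "
            f"(subject {bad['subject_id']}, day {bad['day_index']})"
        )
    dup = df.duplicated(subset=["subject_id", "day_index", "slot_index"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate record for subject {bad['subject_id']}, "
            f"day {bad['day_index']}, slot {bad['slot_index']}"
        )
    vals = df[list(emotions)]
    out = (vals < RATING_MIN) | (vals > RATING_MAX)
    if out.any().any():
        col = next(c for c in emotions if out[c].any())
        row = df.loc[out[col], ["subject_id", "day_index", "slot_index", col]].iloc[0]
        raise PanelValidationError(
            f"rating {row[col]} for '{col}' outside [0, 100] "
            f"(subject {row['subject_id']}, day {row['day_index']}, slot {row['slot_index']})"
        )


#: Default mapping from logical column roles to file column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "subject_id": "subject_id",
    "day_index": "day_index",
    "slot_index": "slot_index",
    "timestamp": "timestamp",
}


def read_ema_panel(
    path: str | Path,
    delimiter: str = ";",
    column_map: Mapping[str, str] | None = None,
    emotion_columns: Mapping[str, str] | None = None,
    design: StudyDesign | None = None,
) -> EmaPanel:
    """Read a delimited EMA file into a validated :class:`EmaPanel`.

    Parameters
    ----------
    path
        Delimited text file, one row per answered prompt.
    delimiter
        Field separator; the study's supplementary dialect uses ``";"``.
    column_map
        Mapping of logical roles (``subject_id``, ``day_index``,
        ``slot_index``, optionally ``timestamp``) to file column names.
    emotion_columns
        Mapping of canonical emotion names to file column names; defaults to
        the eight standard items named canonically.
    design
        Study schedule; defaults to the 17-day x 5-prompt protocol.
    """
    design = design or StudyDesign()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, on_bad_lines="error")
    except pd.errors.ParserError as err:
        raise PanelValidationError(f"malformed row in {path.name}: {err}") from err

    if emotion_columns:
        emap = dict(emotion_columns)
    else:
        # canonical emotion columns present in the file (4 or 8 of them)
        emap = {e: e for e in (*NEGATIVE_EMOTIONS, *POSITIVE_EMOTIONS) if e in raw.columns}
        if not emap:
            raise PanelConfigError(
                f"no canonical emotion columns found in {path.name}; "
                "pass emotion_columns= explicitly"
            )

    for role in ("subject_id", "day_index", "slot_index"):
        if cmap[role] not in raw.columns:
            raise PanelConfigError(
                f"column '{cmap[role]}' (role {role}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
    present_emotions = {}
    for canon, col in emap.items():
        if col in raw.columns:
            present_emotions[canon] = col
        else:
            raise PanelConfigError(
                f"emotion column '{col}' (for '{canon}') not found in {path.name}"
            )

    df = pd.DataFrame(
        {
            "subject_id": raw[cmap["subject_id"]],
            "day_index": raw[cmap["day_index"]].astype(int),
            "slot_index": raw[cmap["slot_index"]].astype(int),
        }
    )
    if cmap.get("timestamp") in raw.columns:
        df["timestamp"] = pd.to_datetime(raw[cmap["timestamp"]])
    for canon, col in present_emotions.items():
        df[canon] = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & df[canon].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        if bad.any():
            raise PanelValidationError(
                f"non-numeric rating '{raw.loc[bad, col].iloc[0]}' in column "
                f"'{col}', line {line} of {path.name}"
            )
    return EmaPanel(df, design, tuple(present_emotions))


@dataclass
class ExclusionReport:
    """Accounting of subject exclusions, partitioned so counts add up.

    A subject lacking the burnout assessment is counted there even when they
    also exceed the EMA-missingness threshold (the burnout rule is applied
    first), so ``n_enrolled = n_missing_burnout + n_excess_missing_ema +
    n_final``.
    """

    n_enrolled: int
    n_missing_burnout: int
    n_excess_missing_ema: int
    n_final: int
    completion: dict = field(default_factory=dict)
    excluded_subjects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_final != self.n_enrolled - self.n_missing_burnout - self.n_excess_missing_ema:
            raise ValueError("exclusion counts do not partition the enrolled sample")

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_missing_burnout": self.n_missing_burnout,
            "n_excess_missing_ema": self.n_excess_missing_ema,
            "n_final": self.n_final,
            "completion_fraction": {str(k): float(v) for k, v in self.completion.items()},
            "excluded_subjects": {str(k): v for k, v in self.excluded_subjects.items()},
        }


def apply_exclusions(
    panel: EmaPanel,
    burnout_available: Mapping,
    max_missing_fraction: float = 0.20,
) -> tuple[EmaPanel, ExclusionReport]:
    """Exclude subjects with missing burnout or excessive EMA nonresponse.

    A subject is retained when (a) ``burnout_available`` is truthy for them
    and (b) their missing fraction — unanswered scheduled prompts over
    ``n_days * prompts_per_day`` — is at most ``max_missing_fraction``.
    "More than 20% missing" is a strict inequality: exactly 20% is retained.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    completion = panel.completion_fractions()
    # subjects never seen in the panel answered nothing
    all_subjects = sorted(set(panel.subjects) | set(burnout_available.keys()))
    completion = completion.reindex(all_subjects, fill_value=0.0)

    excluded: dict = {}
    retained = []
    for sid in all_subjects:
        if not bool(burnout_available.get(sid, False)):
            excluded[sid] = "missing_burnout"
        elif 1.0 - completion[sid] > max_missing_fraction:
            excluded[sid] = "excess_missing_ema"
        else:
            retained.append(sid)

    n_mb = sum(1 for v in excluded.values() if v == "missing_burnout")
    n_me = sum(1 for v in excluded.values() if v == "excess_missing_ema")
    report = ExclusionReport(
        n_enrolled=len(all_subjects),
        n_missing_burnout=n_mb,
        n_excess_missing_ema=n_me,
        n_final=len(retained),
        completion=completion.to_dict(),
        excluded_subjects=excluded,
    )
    if not retained:
        raise PanelValidationError("no subjects retained after exclusions")
    out = EmaPanel(
        panel.data[panel.data["subject_id"].isin(retained)].reset_index(drop=True),
        panel.design,
        panel.emotion_names,
    )
    return out, report


@dataclass
class LaggedDesign:
    """Same-day (t-1, t0) transition pairs ready for the multilevel VAR.

    ``data`` has one row per complete transition with columns ``subject_id``,
    ``day_index``, ``slot_t0``, ``x_<emotion>`` (lagged predictor, within-
    person centered) and ``y_<emotion>`` (outcome at t0, raw scale).
    ``person_means`` indexes subject x emotion means used for centering,
    computed over all observed ratings of the subject in the prepared panel.
    """

    data: pd.DataFrame
    person_means: pd.DataFrame
    emotions: tuple[str, ...]
    empty_subjects: tuple = ()

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject_id"].unique().tolist())

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def rows_per_subject(self) -> pd.Series:
        return self.data.groupby("subject_id").size()

    def predictor_columns(self) -> list[str]:
        return [f"x_{e}" for e in self.emotions]

    def outcome_columns(self) -> list[str]:
        return [f"y_{e}" for e in self.emotions]

    def to_csv(self, path: str | Path, sep: str = ";") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def infer_day_index_from_timestamps(df: pd.DataFrame) -> pd.Series:
    """Fallback day assignment from timestamps, midnight as the boundary."""
    if "timestamp" not in df.columns:
        raise PanelConfigError("no timestamp column to infer day_index from")
    days = df["timestamp"].dt.normalize()
    first = days.groupby(df["subject_id"]).transform("min")
    return (days - first).dt.days + 1


def build_lagged_design(panel: EmaPanel, emotions: Sequence[str]) -> LaggedDesign:
    """Construct the lagged (t-1, t0) design for the selected emotions.

    Transitions pair prompt slot s with slot s+1 of the same subject and day;
    the overnight transition never appears.  Rows with any missing rating at
    either endpoint among the selected emotions are dropped (listwise
    deletion).  Predictors are centered at the subject's mean of each emotion
    over all of that subject's observed ratings in ``panel``.
    """
    emotions = tuple(emotions)
    unknown = set(emotions) - set(panel.emotion_names)
    if unknown:
        raise PanelConfigError(f"emotions not in panel: {sorted(unknown)}")

    df = panel.data
    means = df.groupby("subject_id")[list(emotions)].mean()

    left = df[["subject_id", "day_index", "slot_index", *emotions]].copy()
    right = left.copy()
    right["slot_index"] = right["slot_index"] - 1  # align t0 onto its t-1 slot
    merged = left.merge(
        right,
        on=["subject_id", "day_index", "slot_index"],
        suffixes=("_lag", "_t0"),
    )
    lag_cols = [f"{e}_lag" for e in emotions]
    t0_cols = [f"{e}_t0" for e in emotions]
    complete = merged[lag_cols + t0_cols].notna().all(axis=1)
    merged = merged.loc[complete].reset_index(drop=True)

    out = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "day_index": merged["day_index"],
            "slot_t0": merged["slot_index"] + 1,
        }
    )
    centered = merged[lag_cols].to_numpy() - means.loc[
        merged["subject_id"], list(emotions)
    ].to_numpy()
    for i, e in enumerate(emotions):
        out[f"x_{e}"] = centered[:, i]
        out[f"y_{e}"] = merged[f"{e}_t0"].to_numpy()

    empty = tuple(s for s in panel.subjects if s not in set(out["subject_id"]))
    for s in empty:
        logger.warning("subject %s has no usable transitions", s)
    return LaggedDesign(out, means, emotions, empty)


def design_arithmetic(design: StudyDesign, missing_rate: float) -> dict:
    """Planning arithmetic for the sampling schedule.

    Returns the scheduled prompt total, the number of usable same-day
    transitions for a fully compliant subject (overnight lags removed, a
    ``1/prompts_per_day`` loss), and two conventions for the expected number
    of analyzable assessments under a missing rate ``m``:

    * ``expected_assessments`` — the planning convention that applies the
      overnight-loss fraction and the missing rate to the assessment count,
      ``floor(total * (1 - 1/prompts_per_day) * (1 - m))``;
    * ``expected_complete_transitions`` — transitions with both endpoints
      observed, ``floor(usable * (1 - m)^2)``.

    ``expected_assessments`` is the headline planning figure.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    total = design.total_prompts
    usable = total - design.n_days  # one overnight lag removed per day
    assert usable == round(total * (1 - 1 / design.prompts_per_day))
    return {
        "total_prompts": total,
        "usable_transitions": usable,
        "expected_assessments": math.floor(total * (1 - 1 / design.prompts_per_day) * (1 - missing_rate)),
        "expected_complete_transitions": math.floor(usable * (1 - missing_rate) ** 2),
    }
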