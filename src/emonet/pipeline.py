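"""End-to-end study pipeline: prepare -> fit -> density -> score -> correlate.

One configured call runs the full analysis — on real ';'-separated study
files or on a simulated cohort — and returns a reproducible report:
exclusion accounting, density median and quartiles, burnout summary and
internal consistency, and one-sided Pearson/Spearman correlations between
network density and burnout severity.  Quartiles use the linear-
interpolation convention (numpy default), which is recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from emonet import burnout_scales, ema_data, inference, mlvar, network_metrics
from emonet.burnout_scales import MbiResponse, cronbach_alpha, reverse_code, score_mbi
from emonet.ema_data import (
    NEGATIVE_EMOTIONS,
    POSITIVE_EMOTIONS,
    EmaPanel,
    apply_exclusions,
    build_lagged_design,
    read_ema_panel,
)
from emonet.mlvar import fit_mlvar, group_network, networks_to_edgelist, person_networks
from emonet.network_metrics import density, screen_outliers
from emonet.synthetic_data import SimConfig, simulate_study

logger = logging.getLogger(__name__)

EMOTION_SETS = {"negative": NEGATIVE_EMOTIONS, "positive": POSITIVE_EMOTIONS}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: ``sim`` (a :class:`SimConfig`) or both
    ``ema_path`` and ``subjects_path``.  ``paper_mode`` bundles the published
    analysis conventions: divisor 20, default dimension weights, one-sided
    alpha 0.05.
    """

    sim: SimConfig | None = None
    ema_path: str | Path | None = None
    subjects_path: str | Path | None = None
    emotion_set: str = "negative"
    divisor: int | str = "auto"
    re_structure: str = "correlated"
    estimation: str = "reml"
    alpha: float = 0.05
    weights: tuple[float, float, float] = burnout_scales.DEFAULT_WEIGHTS
    max_missing_fraction: float = 0.20
    outlier_k: float = 3.0
    mbi_columns: Sequence[str] | None = None
    output_dir: str | Path | None = None
    seed: int | None = None
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if self.paper_mode:
            self.divisor = 20
            self.alpha = 0.05
            self.weights = burnout_scales.DEFAULT_WEIGHTS
        if self.emotion_set not in EMOTION_SETS:
            raise ValueError("emotion_set must be 'negative' or 'positive'")
        has_files = self.ema_path is not None and self.subjects_path is not None
        if (self.sim is None) == (not has_files):
            raise ValueError("provide either sim= or both ema_path= and subjects_path=")


@dataclass
class RunReport:
    """Every number here is reproducible from inputs + config + seed."""

    exclusions: dict
    emotion_set: str
    emotions: tuple[str, ...]
    density_summary: dict
    burnout_summary: dict
    correlations: dict
    psychometrics: dict
    group_edges: list
    settings: dict
    per_subject: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    convergence: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exclusions": self.exclusions,
            "emotion_set": self.emotion_set,
            "emotions": list(self.emotions),
            "density": self.density_summary,
            "burnout": self.burnout_summary,
            "correlations": self.correlations,
            "psychometrics": self.psychometrics,
            "group_network_edges": self.group_edges,
            "convergence": self.convergence,
            "settings": self.settings,
        }


def _quartile_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "quartile_convention": "linear interpolation",
    }


def _mbi_item_columns(table: pd.DataFrame, explicit: Sequence[str] | None) -> list[str]:
    if explicit is not None:
        cols = list(explicit)
    else:
        cols = [c for c in table.columns if c.lower().startswith("mbi")]
    if len(cols) != burnout_scales.N_ITEMS:
        raise ValueError(
            f"expected {burnout_scales.N_ITEMS} MBI item columns, found {len(cols)}: {cols}"
        )
    return cols


def run_study(config: RunConfig) -> RunReport:
    """Execute the three analysis stages and assemble the report."""
    # --- stage 0: inputs -------------------------------------------------
    try:
        if config.sim is not None:
            sim = config.sim
            if config.seed is not None and sim.seed != config.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            panel, subjects, _truth = simulate_study(sim)
        else:
            panel = read_ema_panel(config.ema_path)
            subjects = pd.read_csv(config.subjects_path, sep=";")
    except Exception as err:
        raise RuntimeError(f"stage 'input' failed: {err}") from err

    emotions = EMOTION_SETS[config.emotion_set]
    missing = set(emotions) - set(panel.emotion_names)
    if missing:
        raise RuntimeError(
            f"stage 'input' failed: panel lacks {config.emotion_set} emotions {sorted(missing)}"
        )

    # --- stage a: preparation -------------------------------------------
    try:
        item_cols = _mbi_item_columns(subjects, config.mbi_columns)
        subjects = subjects.set_index("subject_id", drop=False)
        available = subjects[item_cols].notna().all(axis=1)
        panel, report = apply_exclusions(
            panel, available.to_dict(), config.max_missing_fraction
        )
        design = build_lagged_design(panel, emotions)
    except Exception as err:
        raise RuntimeError(f"stage 'preparation' failed: {err}") from err

    # --- stage b: network estimation and density ------------------------
    try:
        fit = fit_mlvar(design, re_structure=config.re_structure, estimation=config.estimation)
        nets = person_networks(fit)
        densities = pd.Series(
            {n.subject_id: density(n, config.divisor).density for n in nets}
        ).sort_index()
        gnet = group_network(fit, config.alpha)
    except Exception as err:
        raise RuntimeError(f"stage 'network estimation' failed: {err}") from err

    # --- stage c: scoring and correlation -------------------------------
    try:
        retained = densities.index.tolist()
        scores = {}
        for sid in retained:
            items = subjects.loc[sid, item_cols].to_numpy(dtype=float)
            resp = MbiResponse(subject_id=sid, items=tuple(int(v) for v in items))
            scores[sid] = score_mbi(resp, weights=config.weights).total
        burnout = pd.Series(scores).sort_index()

        item_mat = subjects.loc[retained, item_cols].to_numpy(dtype=float)
        eff = [i - 1 for i in burnout_scales.DEFAULT_DIMENSIONS["professional_efficacy"]]
        item_mat[:, eff] = reverse_code(item_mat[:, eff])
        alpha_val = cronbach_alpha(item_mat)

        dens_screen = screen_outliers(densities.to_numpy(), config.outlier_k)
        burn_screen = screen_outliers(burnout.to_numpy(), config.outlier_k)
        keep = dens_screen.retained & burn_screen.retained
        x = densities.to_numpy()[keep]
        y = burnout.to_numpy()[keep]
        correlations = {
            "pearson": inference.pearson_one_sided(x, y).to_dict(),
            "spearman": inference.spearman_one_sided(x, y).to_dict(),
        }
    except Exception as err:
        raise RuntimeError(f"stage 'correlation' failed: {err}") from err

    per_subject = pd.DataFrame(
        {
            "subject_id": densities.index,
            "density": densities.to_numpy(),
            "burnout": burnout.to_numpy(),
            "density_outlier": ~dens_screen.retained,
            "burnout_outlier": ~burn_screen.retained,
            "n_transitions": [fit.n_transitions.get(s, 0) for s in densities.index],
        }
    )

    settings = {
        "emotion_set": config.emotion_set,
        "divisor": config.divisor if config.divisor == "auto" else int(config.divisor),
        "re_structure": config.re_structure,
        "estimation": config.estimation,
        "alpha": config.alpha,
        "weights": list(config.weights),
        "max_missing_fraction": config.max_missing_fraction,
        "outlier_k": config.outlier_k,
        "paper_mode": config.paper_mode,
        "seed": config.seed if config.seed is not None else (config.sim.seed if config.sim else None),
    }
    for k, v in settings.items():
        logger.info("setting %s = %r", k, v)

    obs = panel.answered_counts().to_numpy(dtype=float)
    run_report = RunReport(
        exclusions=report.to_dict(),
        emotion_set=config.emotion_set,
        emotions=emotions,
        density_summary=_quartile_summary(densities.to_numpy()),
        burnout_summary={
            **_quartile_summary(burnout.to_numpy()),
            "observations_median": float(np.median(obs)),
        },
        correlations=correlations,
        psychometrics={"cronbach_alpha": alpha_val, "n_items": len(item_cols)},
        group_edges=[
            {"from": u, "to": v, "weight": d["weight"], "p_value": d["p_value"]}
            for u, v, d in gnet.edges(data=True)
        ],
        settings=settings,
        per_subject=per_subject,
        convergence=fit.convergence,
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(run_report.to_dict(), indent=1))
        per_subject.to_csv(outdir / "per_subject.csv", sep=";", index=False)
        networks_to_edgelist(nets).to_csv(outdir / "person_networks.csv", sep=";", index=False)
    return run_report
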