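"""Two-step multilevel lag-1 vector autoregression (mlVAR).

Each emotion at t0 is regressed on the within-person centered ratings of all
emotions (including itself) at t-1, one univariate linear mixed model per
emotion.  Population-average coefficients are the fixed effects; subject
deviations enter as random effects whose empirical-Bayes predictions (BLUPs)
yield person-specific coefficient matrices Phi_i = B + b_i.

The mixed models are fit with statsmodels' MixedLM (REML by default).  A
fallback ladder handles non-convergence: a correlated random-effects
structure falls back to independent (diagonal) random slopes, then to a
random intercept only; every fallback is recorded on the fit.  ``pooled``
disables random effects entirely (plain least squares) — the explicit
no-pooling/zero-variance limit used by the single-subject oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from emonet.ema_data import LaggedDesign

logger = logging.getLogger(__name__)

RE_STRUCTURES = ("correlated", "diagonal", "intercept_only", "pooled")
_FALLBACK = {"correlated": "diagonal", "diagonal": "intercept_only"}


class EstimationError(RuntimeError):
    pass


@dataclass
class FixedEffects:
    """Population-average temporal effects.

    ``B[j, k]`` is the effect of emotion ``k`` at t-1 on emotion ``j`` at t0.
    p-values are two-sided on the coefficient/standard-error ratio under a
    normal approximation.
    """

    emotions: tuple[str, ...]
    intercepts: np.ndarray          # (p,)
    B: np.ndarray                   # (p, p)
    standard_errors: np.ndarray     # (p, p)
    p_values: np.ndarray            # (p, p)


@dataclass
class RandomEffects:
    """Empirical-Bayes subject deviations and variance components."""

    subjects: tuple
    b: dict                          # subject -> (p, p) slope deviations
    intercept_dev: dict              # subject -> (p,) intercept deviations
    variance_components: list[dict]  # per equation


@dataclass
class PersonNetwork:
    """A subject's temporal network: Phi_i = B + b_i."""

    subject_id: object
    Phi: np.ndarray
    emotions: tuple[str, ...]
    n_transitions: int

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        p = len(self.emotions)
        if self.Phi.shape != (p, p):
            raise ValueError("Phi must be p x p for p emotions")
        if not np.all(np.isfinite(self.Phi)):
            raise ValueError("Phi contains non-finite entries")


@dataclass
class MlvarFit:
    """Result of the per-equation multilevel VAR fit."""

    fixed: FixedEffects
    random: RandomEffects
    convergence: list[dict] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    n_transitions: dict = field(default_factory=dict)

    @property
    def emotions(self) -> tuple[str, ...]:
        return self.fixed.emotions

    def to_dict(self) -> dict:
        return {
            "emotions": list(self.emotions),
            "intercepts": self.fixed.intercepts.tolist(),
            "B": self.fixed.B.tolist(),
            "standard_errors": self.fixed.standard_errors.tolist(),
            "p_values": self.fixed.p_values.tolist(),
            "variance_components": self.random.variance_components,
            "convergence": self.convergence,
            "settings": self.settings,
        }


def _working_frame(design: LaggedDesign) -> tuple[pd.DataFrame, list[str], list[str]]:
    # canonical names x0.. / y0.. keep the formula interface safe for
    # emotion labels with spaces
    p = len(design.emotions)
    xcols = [f"x{k}" for k in range(p)]
    ycols = [f"y{k}" for k in range(p)]
    df = pd.DataFrame({"grp": design.data["subject_id"].to_numpy()})
    for k, e in enumerate(design.emotions):
        df[xcols[k]] = design.data[f"x_{e}"].to_numpy()
        df[ycols[k]] = design.data[f"y_{e}"].to_numpy()
    return df, xcols, ycols


def _check_rank(df: pd.DataFrame, xcols: list[str], emotions: Sequence[str]) -> None:
    X = df[xcols].to_numpy()
    if np.linalg.matrix_rank(np.corrcoef(X, rowvar=False)) < len(xcols):
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (emotions[a], emotions[b])
            for a in range(len(xcols))
            for b in range(a + 1, len(xcols))
            if abs(corr[a, b]) > 0.999
        ]
        raise EstimationError(f"collinear lagged predictors: {pairs or 'rank deficient'}")


def _fit_one_equation(df, y, xcols, structure, reml, maxiter):
    """Fit one univariate mixed model, trying bfgs then powell."""
    formula = f"{y} ~ " + " + ".join(xcols)
    if structure == "correlated":
        model = smf.mixedlm(formula, df, groups=df["grp"], re_formula="1 + " + " + ".join(xcols))
    elif structure == "diagonal":
        vcf = {x: f"0 + {x}" for x in xcols}
        model = smf.mixedlm(formula, df, groups=df["grp"], re_formula="1", vc_formula=vcf)
    elif structure == "intercept_only":
        model = smf.mixedlm(formula, df, groups=df["grp"], re_formula="1")
    else:
        raise ValueError(structure)
    last = None
    for method in ("powell", "lbfgs"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml, method=method, maxiter=maxiter)
            except (np.linalg.LinAlgError, ValueError) as err:
                logger.debug("optimizer %s failed: %s", method, err)
                continue
        last = res
        if res.converged:
            return res, True
    return last, False


def fit_mlvar(
    design: LaggedDesign,
    re_structure: str = "correlated",
    estimation: str = "reml",
    maxiter: int = 2000,
) -> MlvarFit:
    """Fit the two-step multilevel VAR(1) to a lagged design.

    Parameters
    ----------
    design
        Output of :func:`emonet.ema_data.build_lagged_design`.
    re_structure
        ``"correlated"`` (random intercept + slopes with free covariance),
        ``"diagonal"`` (independent random intercept and slopes),
        ``"intercept_only"``, or ``"pooled"`` (no random effects; ordinary
        least squares — the zero-between-subject-variance limit).
    estimation
        ``"reml"`` (restricted maximum likelihood, default) or ``"ml"``.
    """
    if re_structure not in RE_STRUCTURES:
        raise ValueError(f"re_structure must be one of {RE_STRUCTURES}")
    if estimation not in ("reml", "ml"):
        raise ValueError("estimation must be 'reml' or 'ml'")
    p = len(design.emotions)
    if p < 2:
        raise EstimationError("need at least 2 emotions for a network")
    subjects = design.subjects
    if re_structure != "pooled" and len(subjects) < 2:
        raise EstimationError(
            "multilevel fit needs >= 2 subjects with transitions; "
            "use fit_var_single (or re_structure='pooled') for one subject"
        )
    df, xcols, ycols = _working_frame(design)
    _check_rank(df, xcols, design.emotions)
    reml = estimation == "reml"

    intercepts = np.zeros(p)
    B = np.zeros((p, p))
    se = np.zeros((p, p))
    pv = np.zeros((p, p))
    b = {s: np.zeros((p, p)) for s in subjects}
    idev = {s: np.zeros(p) for s in subjects}
    vcomps: list[dict] = []
    convergence: list[dict] = []

    for j, y in enumerate(ycols):
        if re_structure == "pooled":
            ols = sm.OLS(df[y], sm.add_constant(df[xcols])).fit()
            intercepts[j] = ols.params["const"]
            B[j] = ols.params[xcols].to_numpy()
            se[j] = ols.bse[xcols].to_numpy()
            pv[j] = 2 * stats.norm.sf(np.abs(B[j] / se[j]))
            vcomps.append({"residual_var": float(ols.mse_resid)})
            convergence.append({"equation": design.emotions[j], "structure": "pooled", "converged": True})
            continue

        structure = re_structure
        res, ok = _fit_one_equation(df, y, xcols, structure, reml, maxiter)
        while not ok and structure in _FALLBACK:
            structure = _FALLBACK[structure]
            logger.warning("equation %s did not converge; falling back to %s", y, structure)
            res, ok = _fit_one_equation(df, y, xcols, structure, reml, maxiter)
        if res is None:
            raise EstimationError(f"equation for {design.emotions[j]} failed at every structure")
        convergence.append(
            {"equation": design.emotions[j], "structure": structure, "converged": bool(ok)}
        )
        fe = res.fe_params
        intercepts[j] = fe["Intercept"]
        B[j] = fe[xcols].to_numpy()
        se[j] = res.bse_fe[xcols].to_numpy()
        pv[j] = res.pvalues[xcols].to_numpy()
        vc: dict = {"residual_var": float(res.scale)}
        if structure == "correlated":
            names = ["Group"] + xcols
            cov = np.asarray(res.cov_re)
            vc["re_cov"] = {
                f"{names[a]}:{names[bb]}": float(cov[a, bb])
                for a in range(len(names))
                for bb in range(a, len(names))
            }
        elif structure == "diagonal":
            vc["intercept_var"] = float(np.asarray(res.cov_re)[0, 0])
            vc["slope_var"] = {x: float(v) for x, v in zip(xcols, res.vcomp)}
        else:
            vc["intercept_var"] = float(np.asarray(res.cov_re)[0, 0])
        vcomps.append(vc)

        for s, dev in res.random_effects.items():
            if structure == "correlated":
                idev[s][j] = dev["Group"] if "Group" in dev.index else dev.iloc[0]
                for k, x in enumerate(xcols):
                    b[s][j, k] = dev[x]
            elif structure == "diagonal":
                idev[s][j] = dev["Group"]
                for k, x in enumerate(xcols):
                    b[s][j, k] = dev[f"{x}[{x}]"]
            else:
                idev[s][j] = dev.iloc[0]

    fixed = FixedEffects(tuple(design.emotions), intercepts, B, se, pv)
    random = RandomEffects(tuple(subjects), b, idev, vcomps)
    return MlvarFit(
        fixed=fixed,
        random=random,
        convergence=convergence,
        settings={"re_structure": re_structure, "estimation": estimation, "maxiter": maxiter},
        n_transitions=design.rows_per_subject().to_dict() if len(design.data) else {},
    )


def fit_var_single(
    rows: pd.DataFrame | LaggedDesign, emotions: Sequence[str] | None = None
) -> np.ndarray:
    """Per-subject least-squares VAR(1): the no-pooling oracle.

    ``rows`` holds one subject's transitions with ``x_<e>`` / ``y_<e>``
    columns; each emotion's outcome is regressed on all lagged predictors
    plus an intercept by ordinary least squares.  Returns the p x p
    coefficient matrix (row = outcome emotion).
    """
    if isinstance(rows, LaggedDesign):
        if emotions is None:
            emotions = rows.emotions
        rows = rows.data
    if emotions is None:
        raise ValueError("emotions required when passing a bare frame")
    emotions = tuple(emotions)
    p = len(emotions)
    if "subject_id" in rows and rows["subject_id"].nunique() > 1:
        raise ValueError("fit_var_single expects a single subject's rows")
    n = len(rows)
    if n < p + 2:
        raise EstimationError(f"need at least {p + 2} complete transitions, got {n}")
    X = rows[[f"x_{e}" for e in emotions]].to_numpy()
    if np.any(X.std(axis=0) == 0):
        raise EstimationError("a lagged predictor has zero variance (constant series)")
    Xd = np.column_stack([np.ones(n), X])
    Phi = np.empty((p, p))
    for j, e in enumerate(emotions):
        beta, *_ = np.linalg.lstsq(Xd, rows[f"y_{e}"].to_numpy(), rcond=None)
        Phi[j] = beta[1:]
    return Phi


def person_networks(fit: MlvarFit) -> list[PersonNetwork]:
    """Extract person-specific networks Phi_i = B + b_i from a fit."""
    nets = []
    for s in fit.random.subjects:
        nets.append(
            PersonNetwork(
                subject_id=s,
                Phi=fit.fixed.B + fit.random.b[s],
                emotions=fit.emotions,
                n_transitions=int(fit.n_transitions.get(s, 0)),
            )
        )
    return nets


def group_network(fit: MlvarFit, alpha: float = 0.05) -> nx.DiGraph:
    """Group-level (fixed-effect) network keeping only significant edges.

    Edge k -> j is present iff the two-sided p-value of B[j, k] is below
    ``alpha``; weight and sign are the fixed-effect estimate.
    """
    g = nx.DiGraph(alpha=alpha)
    g.add_nodes_from(fit.emotions)
    p = len(fit.emotions)
    for j in range(p):
        for k in range(p):
            if fit.fixed.p_values[j, k] < alpha:
                g.add_edge(
                    fit.emotions[k],
                    fit.emotions[j],
                    weight=float(fit.fixed.B[j, k]),
                    p_value=float(fit.fixed.p_values[j, k]),
                )
    return g


def networks_to_edgelist(networks: Sequence[PersonNetwork]) -> pd.DataFrame:
    """Long-form (subject, from, to, weight) export of person networks."""
    rows = []
    for net in networks:
        for j, to in enumerate(net.emotions):
            for k, frm in enumerate(net.emotions):
                rows.append((net.subject_id, frm, to, net.Phi[j, k]))
    return pd.DataFrame(rows, columns=["subject_id", "from", "to", "weight"])
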