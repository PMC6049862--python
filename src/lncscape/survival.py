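"""Expression-based survival signature.

Per-lncRNA univariate Cox proportional-hazards screening (after subtype and
detectability eligibility filters), construction of a risk score

    score(sample) = sum_i  beta_i * log2 expression_i(sample)

over the top-k features (ranked by univariate Wald p), median-split
stratification into low/high-risk groups, Kaplan-Meier curves with the
two-group log-rank test, and a multivariate Cox fit adjusting the score for
age, G-CIMP, IDH1 and MGMT status.

Cox and KM fitting delegate to lifelines; the screening loop, filters,
score and stratification logic live here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceError

from .config import PipelineConfig
from .io import ExpressionMatrix, SurvivalRecord, survival_frame
from .subtypes import SubtypeCall

#: subtypes whose quantitation is considered reliable for survival screening
ELIGIBLE_SUBTYPES = frozenset({"intergenic", "intron_sense_overlapping"})


@dataclass(frozen=True)
class CoxResult:
    feature_id: str
    coefficient: float      # log hazard per log2 expression unit
    hazard_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if not self.hazard_ratio > 0:
                raise ValueError("hazard ratio must be positive")
            if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
                raise ValueError("confidence interval must bracket the HR")


@dataclass(frozen=True)
class RiskScore:
    sample_id: str
    score: float
    group: str  # low | high


def eligibility_filter(lnc_expr: ExpressionMatrix,
                       subtypes: list[SubtypeCall] | dict[str, str],
                       cfg: PipelineConfig | None = None,
                       allowed_subtypes: frozenset[str] = ELIGIBLE_SUBTYPES,
                       ) -> list[str]:
    """Features of an allowed subtype detected in enough samples.

    Detection means expression > 0 (>= 1 read before normalisation, or a
    positive log2 value); the fraction threshold is inclusive.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if isinstance(subtypes, dict):
        subtype_of = subtypes
    else:
        subtype_of = {c.lncrna_id: c.subtype for c in subtypes}
    n = len(lnc_expr.sample_ids)
    detected_frac = (lnc_expr.values > 0).sum(axis=1) / n
    out = []
    for fid in lnc_expr.feature_ids:
        if subtype_of.get(fid) not in allowed_subtypes:
            continue
        if detected_frac[fid] >= cfg.expression_presence_fraction:
            out.append(fid)
    return out


def univariate_cox(expr_row: pd.Series | np.ndarray,
                   surv: list[SurvivalRecord],
                   feature_id: str = "") -> CoxResult:
    """Cox PH fit of survival on one continuous log2-expression covariate."""
    sf = survival_frame(surv)
    if isinstance(expr_row, pd.Series):
        x = expr_row.reindex(sf.index)
        if x.isna().any():
            missing = list(x.index[x.isna()])[:5]
            raise ValueError(f"expression missing for samples {missing}")
        feature_id = feature_id or str(expr_row.name)
    else:
        x = pd.Series(np.asarray(expr_row, dtype=float), index=sf.index)
    if int(sf["event"].sum()) < 10:
        raise ValueError("univariate Cox needs >= 10 events")
    df = pd.DataFrame({"time": sf["time"], "event": sf["event"], "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return CoxResult(feature_id=feature_id, coefficient=float("nan"),
                         hazard_ratio=float("nan"), p_value=float("nan"),
                         ci_low=float("nan"), ci_high=float("nan"),
                         converged=False)
    coef = float(cph.params_["x"])
    ci = cph.confidence_intervals_
    return CoxResult(
        feature_id=feature_id, coefficient=coef,
        hazard_ratio=float(np.exp(coef)),
        p_value=float(cph.summary.loc["x", "p"]),
        ci_low=float(np.exp(ci.iloc[0, 0])),
        ci_high=float(np.exp(ci.iloc[0, 1])))


def screen_features(lnc_expr: ExpressionMatrix, surv: list[SurvivalRecord],
                    feature_ids: list[str] | None = None,
                    p_threshold: float = 0.05) -> list[CoxResult]:
    """Univariate Cox over many features; non-converged fits are excluded."""
    ids = feature_ids if feature_ids is not None else lnc_expr.feature_ids
    results = []
    for fid in ids:
        res = univariate_cox(lnc_expr.values.loc[fid], surv, feature_id=fid)
        if res.converged:
            results.append(res)
    return [r for r in results if r.p_value < p_threshold]


def select_top(results: list[CoxResult], k: int = 5) -> list[CoxResult]:
    """Top-k features by univariate p (|coefficient| breaks ties)."""
    ranked = sorted(results, key=lambda r: (r.p_value, -abs(r.coefficient)))
    return ranked[:k]


def risk_score(selected: list[CoxResult], lnc_expr: ExpressionMatrix,
               samples: list[str] | None = None) -> list[RiskScore]:
    """Coefficient-weighted sum of log2 expression; strict median split.

    A sample is high-risk iff its score is strictly greater than the cohort
    median (ties at the median go to low-risk).
    """
    if samples is None:
        samples = lnc_expr.sample_ids
    missing = [r.feature_id for r in selected
               if r.feature_id not in lnc_expr.values.index]
    if missing:
        raise ValueError(f"signature features missing from matrix: {missing}")
    coefs = np.array([r.coefficient for r in selected])
    X = lnc_expr.values.loc[[r.feature_id for r in selected], samples]
    scores = coefs @ X.to_numpy(dtype=float)
    median = float(np.median(scores)) if len(scores) else 0.0
    return [RiskScore(sample_id=s, score=float(sc),
                      group="high" if sc > median else "low")
            for s, sc in zip(samples, scores)]


@dataclass
class StratificationResult:
    median_survival: dict[str, float]     # group -> months (inf = not reached)
    logrank_p: float
    logrank_stat: float
    km_curves: dict[str, pd.DataFrame]    # group -> timeline/survival columns
    n_per_group: dict[str, int]


def stratify_and_test(scores: list[RiskScore],
                      surv: list[SurvivalRecord]) -> StratificationResult:
    """KM estimates per risk group, median survival and the log-rank test."""
    sf = survival_frame(surv)
    group_of = {s.sample_id: s.group for s in scores}
    sf = sf.loc[[sid for sid in sf.index if sid in group_of]]
    groups = {g: sf.loc[[sid for sid in sf.index if group_of[sid] == g]]
              for g in ("low", "high")}
    if any(len(df) == 0 for df in groups.values()):
        raise ValueError("both risk groups must be non-empty")

    medians, curves = {}, {}
    for g, df in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(df["time"], event_observed=df["event"], label=g)
        medians[g] = float(kmf.median_survival_time_)
        curves[g] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", g: "survival"})
    lr = logrank_test(groups["low"]["time"], groups["high"]["time"],
                      event_observed_A=groups["low"]["event"],
                      event_observed_B=groups["high"]["event"])
    return StratificationResult(
        median_survival=medians, logrank_p=float(lr.p_value),
        logrank_stat=float(lr.test_statistic), km_curves=curves,
        n_per_group={g: len(df) for g, df in groups.items()})


def multivariate_cox(scores: list[RiskScore], surv: list[SurvivalRecord],
                     use_group: bool = False) -> dict[str, CoxResult]:
    """Joint Cox fit of the risk score with the clinical covariates.

    Covariate-incomplete rows are dropped (count reported via warning).
    A covariate collinear with the others is flagged non-converged and the
    model is refit without it.
    """
    sf = survival_frame(surv)
    score_of = {s.sample_id: (1.0 if s.group == "high" else 0.0) if use_group
                else s.score for s in scores}
    sf = sf.loc[[sid for sid in sf.index if sid in score_of]].copy()
    sf["risk_score"] = [score_of[sid] for sid in sf.index]
    # the score leads the design: a clinical covariate collinear with it is
    # the one flagged and refit without
    covs = ["risk_score"] + [c for c in sf.columns
                             if c not in ("time", "event", "risk_score")]
    n0 = len(sf)
    sf = sf.dropna()
    if len(sf) < n0:
        warnings.warn(f"dropped {n0 - len(sf)} covariate-incomplete rows")

    flagged: dict[str, CoxResult] = {}
    active = list(covs)
    while True:
        drop = _collinear_covariate(sf[active])
        if drop is None:
            break
        warnings.warn(f"covariate {drop!r} is collinear; refit without it")
        flagged[drop] = CoxResult(feature_id=drop, coefficient=float("nan"),
                                  hazard_ratio=float("nan"),
                                  p_value=float("nan"), ci_low=float("nan"),
                                  ci_high=float("nan"), converged=False)
        active.remove(drop)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sf[["time", "event"] + active], duration_col="time",
                event_col="event")
    out: dict[str, CoxResult] = dict(flagged)
    ci = cph.confidence_intervals_
    for name in active:
        coef = float(cph.params_[name])
        out[name] = CoxResult(
            feature_id=name, coefficient=coef,
            hazard_ratio=float(np.exp(coef)),
            p_value=float(cph.summary.loc[name, "p"]),
            ci_low=float(np.exp(ci.loc[name].iloc[0])),
            ci_high=float(np.exp(ci.loc[name].iloc[1])))
    return out


def _collinear_covariate(X: pd.DataFrame) -> str | None:
    """Name of a covariate linearly dependent on the preceding ones."""
    M = X.to_numpy(dtype=float)
    M = np.column_stack([np.ones(len(M)), M])  # intercept absorbs constants
    for j in range(1, M.shape[1]):
        if np.linalg.matrix_rank(M[:, :j + 1]) < j + 1:
            return X.columns[j - 1]
    return None


def cox_table(results: list[CoxResult] | dict[str, CoxResult]) -> pd.DataFrame:
    if isinstance(results, dict):
        results = list(results.values())
    return pd.DataFrame([r.__dict__ for r in results]).set_index("feature_id")
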