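"""Normalization and differential expression.

Quantile normalization (microarray intensities), median-of-ratios size
factors (RNA-Seq counts), the Present/Marginal detection-flag filter, and
a two-sample t-test DE caller with Benjamini-Hochberg FDR.

Fold changes are computed on the log2 scale as the difference of group
means; the linear fold change reported alongside is ``2**|log2FC|``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEThresholds, PipelineConfig
from .io import CONTROL, TUMOR, ExpressionMatrix


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    mean_log2_tumor: float
    mean_log2_control: float
    log2_fc: float          # tumor - control, log2 scale
    p_value: float
    fdr: float
    direction: str          # up | down | unchanged


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares one value distribution.

    The target distribution is the vector of row means of the column-sorted
    matrix; ties within a column receive the mean of the target values at
    their tied ranks (average-rank convention).
    """
    X = m.values.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    n_feat, n_samp = X.shape
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        group_labels=m.group_labels, scale=m.scale, flags=m.flags)


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors for sequencing-depth correction.

    The per-feature reference is the geometric mean across samples, taken
    over features positive in every sample; each sample's factor is the
    median over those features of count/reference.
    """
    if counts.scale != "linear_count":
        raise ValueError("size factors require a linear_count matrix")
    X = counts.values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (X > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature has positive counts in every sample; "
                         "cannot form a geometric-mean reference")
    logX = np.log(X[all_positive])
    log_ref = logX.mean(axis=1)
    factors = np.exp(np.median(logX - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    f = size_factors(counts)
    return ExpressionMatrix(values=counts.values / f, group_labels=counts.group_labels,
                            scale="linear_count", flags=counts.flags)


def flag_filter(m: ExpressionMatrix, min_present: int = 7) -> ExpressionMatrix:
    """Keep features detected (Present or Marginal) in >= min_present samples.

    A no-op with a warning when the matrix carries no detection flags.
    """
    if m.flags is None:
        warnings.warn("no detection flags on matrix; flag filter skipped")
        return m
    detected = m.flags.isin(["Present", "Marginal"]).sum(axis=1)
    keep = detected[detected >= min_present].index
    return m.subset_features(list(keep))


def differential_expression(m: ExpressionMatrix,
                            thresholds: DEThresholds | None = None,
                            cfg: PipelineConfig | None = None,
                            welch: bool | None = None) -> list[DEResult]:
    """Per-feature two-sample t-test between tumor and control samples.

    log2 fold change is the difference of group means on the log2 scale;
    BH FDR is computed across all tested features.  A feature is called
    up/down when ``2**|log2FC|`` meets the linear fold-change threshold and
    the p-value (or FDR, per the stage's threshold block) is below the cut.
    Zero variance in both groups with equal means yields p = 1 with a
    warning rather than an error.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if thresholds is None:
        thresholds = cfg.de_lnc
    if welch is None:
        welch = cfg.welch
    if m.scale != "log2":
        raise ValueError("differential expression expects a log2 matrix")
    tum, ctl = m.tumor_samples, m.control_samples
    if len(tum) < 2 or len(ctl) < 2:
        raise ValueError("both groups need >= 2 samples")

    T = m.values[tum].to_numpy(dtype=float)
    C = m.values[ctl].to_numpy(dtype=float)
    mean_t, mean_c = T.mean(axis=1), C.mean(axis=1)
    lfc = mean_t - mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(T, C, axis=1, equal_var=not welch)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} feature(s) with zero variance "
                      "in both groups; p set to 1")
        p[degenerate] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]

    linear_fc = 2.0 ** np.abs(lfc)
    sig = fdr < thresholds.p if thresholds.use_fdr else p < thresholds.p
    called = sig & (linear_fc >= thresholds.fc)
    out = []
    for i, fid in enumerate(m.values.index):
        if called[i]:
            direction = "up" if lfc[i] > 0 else "down"
        else:
            direction = "unchanged"
        out.append(DEResult(feature_id=str(fid),
                            mean_log2_tumor=float(mean_t[i]),
                            mean_log2_control=float(mean_c[i]),
                            log2_fc=float(lfc[i]), p_value=float(p[i]),
                            fdr=float(fdr[i]), direction=direction))
    return out


def de_directions(results: list[DEResult]) -> dict[str, str]:
    """feature_id -> up/down/unchanged lookup."""
    return {r.feature_id: r.direction for r in results}


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("feature_id")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
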