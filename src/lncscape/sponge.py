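"""ceRNA (sponge) module inference.

A sponge module is a lncRNA-miRNA-mRNA triplet in which the lncRNA
plausibly titrates the miRNA away from the mRNA.  The six-filter chain:

1. restrict to differentially expressed lncRNAs (RNA-Seq stage thresholds);
2. predicted lncRNA-miRNA pairs with negative correlation;
3. validated miRNA-mRNA pairs with negative correlation;
4. inner-join the two pair lists on the shared miRNA into raw triplets;
5. keep triplets where lncRNA, miRNA and mRNA are all upregulated and
   lncRNA-mRNA correlation is positive (and significant);
6. keep triplets whose lncRNA is significantly more abundant than the mRNA
   across tumor samples (one-sided paired test) — a sponge must outnumber
   its target to titrate the shared miRNA effectively.

Each filter's attrition is recorded so a run can be audited end to end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .coexpression import spearman
from .io import ExpressionMatrix, InteractionTable


@dataclass(frozen=True)
class SpongeModule:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    rho_lnc_mir: float      # < 0
    p_lnc_mir: float
    rho_mir_mrna: float     # < 0
    p_mir_mrna: float
    rho_lnc_mrna: float     # > 0
    p_lnc_mrna: float
    abundance_stat: float
    abundance_p: float
    mean_abundance_lnc: float
    mean_abundance_mrna: float

    def __post_init__(self) -> None:
        if not (self.rho_lnc_mir < 0 and self.rho_mir_mrna < 0):
            raise ValueError("lncRNA-miRNA and miRNA-mRNA correlations must "
                             "be negative in a sponge module")
        if not self.rho_lnc_mrna > 0:
            raise ValueError("lncRNA-mRNA correlation must be positive")
        if not self.mean_abundance_lnc > self.mean_abundance_mrna:
            raise ValueError("sponge lncRNA must be more abundant than mRNA")


@dataclass
class Attrition:
    """Counts surviving each filter of the sponge chain."""

    de_lncrnas: int = 0
    predicted_pairs: int = 0
    lnc_mir_negative: int = 0
    validated_pairs: int = 0
    mir_mrna_negative: int = 0
    raw_triplets: int = 0
    direction_and_positive_corr: int = 0
    abundance_final: int = 0
    dropped_missing_expression: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _shared_tumor_samples(a: ExpressionMatrix, b: ExpressionMatrix,
                          stage: str) -> list[str]:
    shared = [s for s in a.tumor_samples if s in set(b.tumor_samples)]
    if len(shared) < 4:
        raise ValueError(f"{stage}: matrices share {len(shared)} tumor "
                         "samples; >= 4 required")
    return shared


def _negative_pairs(table: InteractionTable, src_expr: ExpressionMatrix,
                    tgt_expr: ExpressionMatrix, src_keep: set[str] | None,
                    cfg: PipelineConfig, attr_counter: list[int],
                    stage: str) -> list[tuple[str, str, float, float]]:
    samples = _shared_tumor_samples(src_expr, tgt_expr, stage)
    out = []
    for src, tgt in table.pairs.itertuples(index=False):
        if src_keep is not None and src not in src_keep:
            continue
        if (src not in src_expr.values.index
                or tgt not in tgt_expr.values.index):
            attr_counter[0] += 1
            continue
        try:
            rho, p = spearman(
                src_expr.values.loc[src, samples].to_numpy(),
                tgt_expr.values.loc[tgt, samples].to_numpy())
        except ValueError:
            attr_counter[0] += 1
            continue
        if rho >= 0:
            continue
        if cfg.sponge_require_corr_p and p >= cfg.corr_p_threshold:
            continue
        out.append((src, tgt, rho, p))
    return out


def candidate_lnc_mir(lnc_de_up_down: set[str], predicted: InteractionTable,
                      lnc_expr: ExpressionMatrix, mir_expr: ExpressionMatrix,
                      cfg: PipelineConfig | None = None,
                      attrition: Attrition | None = None,
                      ) -> list[tuple[str, str, float, float]]:
    """Predicted lncRNA-miRNA pairs with negative (significant) correlation.

    ``lnc_de_up_down`` restricts to the differentially expressed lncRNAs of
    the sponge input stage (both directions enter here; the up-only
    constraint is applied at module filtering).
    """
    if cfg is None:
        cfg = PipelineConfig()
    ctr = [0]
    out = _negative_pairs(predicted, lnc_expr, mir_expr, lnc_de_up_down,
                          cfg, ctr, "lncRNA-miRNA correlation")
    if attrition is not None:
        attrition.de_lncrnas = len(lnc_de_up_down)
        attrition.predicted_pairs = len(predicted)
        attrition.lnc_mir_negative = len(out)
        attrition.dropped_missing_expression += ctr[0]
    return out


def candidate_mir_mrna(mirnas: set[str], validated: InteractionTable,
                       mir_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                       cfg: PipelineConfig | None = None,
                       attrition: Attrition | None = None,
                       ) -> list[tuple[str, str, float, float]]:
    """Validated miRNA-mRNA pairs with negative (significant) correlation."""
    if cfg is None:
        cfg = PipelineConfig()
    ctr = [0]
    out = _negative_pairs(validated, mir_expr, mrna_expr, mirnas,
                          cfg, ctr, "miRNA-mRNA correlation")
    if attrition is not None:
        attrition.validated_pairs = len(validated)
        attrition.mir_mrna_negative = len(out)
        attrition.dropped_missing_expression += ctr[0]
    return out


def merge_modules(lm: list[tuple[str, str, float, float]],
                  mm: list[tuple[str, str, float, float]],
                  ) -> list[tuple[str, str, str, float, float, float, float]]:
    """Inner join on the shared miRNA: one raw triplet per combination."""
    by_mir: dict[str, list[tuple[str, float, float]]] = {}
    for mir, mrna, rho, p in mm:
        by_mir.setdefault(mir, []).append((mrna, rho, p))
    out = []
    for lnc, mir, rho_lm, p_lm in lm:
        for mrna, rho_mm, p_mm in by_mir.get(mir, ()):
            out.append((lnc, mir, mrna, rho_lm, p_lm, rho_mm, p_mm))
    return out


def filter_modules(triplets, de_directions_all: dict[str, str],
                   lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                   cfg: PipelineConfig | None = None,
                   attrition: Attrition | None = None) -> list[SpongeModule]:
    """Apply the direction, positive-correlation and abundance filters.

    ``de_directions_all`` maps every feature id (lncRNA, miRNA and mRNA —
    merge the three stage dictionaries) to up/down/unchanged.  The abundance
    test is a one-sided paired comparison of per-tumor-sample log2 values
    (Wilcoxon signed-rank by default, paired t-test via config).
    """
    if cfg is None:
        cfg = PipelineConfig()
    samples = _shared_tumor_samples(lnc_expr, mrna_expr, "abundance test")
    if attrition is not None:
        attrition.raw_triplets = len(triplets)

    survivors = []
    for lnc, mir, mrna, rho_lm, p_lm, rho_mm, p_mm in triplets:
        if not (de_directions_all.get(lnc) == "up"
                and de_directions_all.get(mir) == "up"
                and de_directions_all.get(mrna) == "up"):
            continue
        if (lnc not in lnc_expr.values.index
                or mrna not in mrna_expr.values.index):
            if attrition is not None:
                attrition.dropped_missing_expression += 1
            continue
        x = lnc_expr.values.loc[lnc, samples].to_numpy(dtype=float)
        y = mrna_expr.values.loc[mrna, samples].to_numpy(dtype=float)
        try:
            rho_xy, p_xy = spearman(x, y)
        except ValueError:
            continue
        if rho_xy <= 0 or p_xy >= cfg.corr_p_threshold:
            continue
        survivors.append((lnc, mir, mrna, rho_lm, p_lm, rho_mm, p_mm,
                          rho_xy, p_xy, x, y))
    if attrition is not None:
        attrition.direction_and_positive_corr = len(survivors)

    out: list[SpongeModule] = []
    for (lnc, mir, mrna, rho_lm, p_lm, rho_mm, p_mm,
         rho_xy, p_xy, x, y) in survivors:
        stat, p_ab = abundance_test(x, y, cfg)
        if p_ab >= cfg.abundance_test_p or x.mean() <= y.mean():
            continue
        out.append(SpongeModule(
            lncrna_id=lnc, mirna_id=mir, mrna_id=mrna,
            rho_lnc_mir=rho_lm, p_lnc_mir=p_lm,
            rho_mir_mrna=rho_mm, p_mir_mrna=p_mm,
            rho_lnc_mrna=rho_xy, p_lnc_mrna=p_xy,
            abundance_stat=float(stat), abundance_p=float(p_ab),
            mean_abundance_lnc=float(x.mean()),
            mean_abundance_mrna=float(y.mean())))
    if attrition is not None:
        attrition.abundance_final = len(out)
    return out


def abundance_test(x: np.ndarray, y: np.ndarray,
                   cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """One-sided paired test of lncRNA (x) abundance exceeding mRNA (y).

    Wilcoxon signed-rank on the per-sample differences by default; paired
    t-test when configured.  Identical vectors give p = 1.
    """
    if cfg is None:
        cfg = PipelineConfig()
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 0.0, 1.0
    if cfg.abundance_test == "ttest":
        stat, p = stats.ttest_rel(x, y, alternative="greater")
        return float(stat), float(p)
    res = stats.wilcoxon(d, alternative="greater", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def module_gene_set(modules: list[SpongeModule]) -> list[str]:
    """Deduplicated mRNA ids of the final modules (for external enrichment)."""
    return sorted({m.mrna_id for m in modules})
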