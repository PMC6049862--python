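"""Cis/trans co-expression networks from sample-wise Spearman correlation.

All cross pairs between the differentially expressed lncRNAs and mRNAs (or
among lncRNAs) are enumerated over tumor samples.  A pair is *cis* when the
partner's span intersects the lncRNA span extended by the +/-500 kb window
(boundary inclusive: a span-to-span gap of exactly 500,000 bp is still cis),
otherwise *trans* — inter-chromosomal pairs are always trans.  Cis pairs are
retained at p < 0.05; the vastly larger trans set additionally requires
|rho| > 0.9.  For lncRNA-lncRNA mode, self pairs are removed and the
symmetric A-B / B-A duplicates collapsed to a single record.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .de import bh_adjust
from .io import ExpressionMatrix, GeneAnnotation


@dataclass(frozen=True)
class CorrelationPair:
    a_id: str
    b_id: str
    pair_kind: str            # lnc_mrna | lnc_lnc
    rho: float
    p_value: float
    distance_class: str       # cis | trans
    quadrant: str             # up_up | down_down | up_down | down_up
    genomic_gap: int | None   # bp span gap; None when inter-chromosomal
    fdr: float = float("nan")


@dataclass
class NetworkStats:
    """Bookkeeping for one network build (conservation-checked)."""

    enumerated: int = 0
    cis_enumerated: int = 0
    trans_enumerated: int = 0
    skipped_constant: int = 0
    skipped_unannotated: int = 0
    cis_significant: int = 0
    trans_significant: int = 0
    self_pairs_removed: int = 0
    symmetric_collapsed: int = 0


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and t-approximation p-value (n-2 df, mean-rank ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("spearman needs two equal-length vectors, n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def classify_pair_distance(a: GeneAnnotation, b: GeneAnnotation,
                           cfg: PipelineConfig | None = None) -> str:
    """cis iff same chromosome and span gap <= the cis window (inclusive)."""
    if cfg is None:
        cfg = PipelineConfig()
    if a.chrom != b.chrom:
        return "trans"
    return "cis" if genomic_gap(a, b) <= cfg.cis_window else "trans"


def genomic_gap(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Span-to-span gap in bp on one chromosome; 0 when spans overlap."""
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return 0


def quadrant(dir_a: str, dir_b: str) -> str:
    return f"{dir_a}_{dir_b}"


# -- vectorised rank correlation --------------------------------------------

def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _rank_corr_block(RA: np.ndarray, RB: np.ndarray) -> np.ndarray:
    """Pearson correlation of pre-ranked rows: RA (a x n) vs RB (b x n)."""
    A = RA - RA.mean(axis=1, keepdims=True)
    B = RB - RB.mean(axis=1, keepdims=True)
    na = np.sqrt((A * A).sum(axis=1))
    nb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    return np.clip(C, -1.0, 1.0)


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation on n-2 degrees of freedom."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |rho| == 1
    return p


def build_network(lnc_de: dict[str, str], partner_de: dict[str, str],
                  lnc_expr: ExpressionMatrix, partner_expr: ExpressionMatrix,
                  annotations: dict[str, GeneAnnotation],
                  cfg: PipelineConfig | None = None,
                  pair_kind: str = "lnc_mrna",
                  chunk_size: int = 256,
                  ) -> tuple[list[CorrelationPair], NetworkStats]:
    """Enumerate, correlate and filter all cross pairs.

    ``lnc_de`` / ``partner_de`` map DE feature ids to their direction
    (up/down); only those features enter.  For ``pair_kind="lnc_lnc"`` pass
    the same DE map and matrix on both sides: self pairs are dropped and
    symmetric duplicates collapsed (a_id < b_id).  Correlation is computed
    over tumor samples (all samples when ``cfg.tumor_only_correlation`` is
    off), chunked so the full cross product is never materialised at once.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if pair_kind not in ("lnc_mrna", "lnc_lnc"):
        raise ValueError(f"unknown pair_kind {pair_kind!r}")
    symmetric = pair_kind == "lnc_lnc"

    samples = (lnc_expr.tumor_samples if cfg.tumor_only_correlation
               else lnc_expr.sample_ids)
    samples = [s for s in samples if s in partner_expr.sample_ids]
    if len(samples) < 4:
        raise ValueError("need >= 4 shared tumor samples for correlation")
    n = len(samples)

    stats_out = NetworkStats()

    def usable(ids: list[str], expr: ExpressionMatrix) -> list[str]:
        out = []
        for fid in ids:
            if fid not in expr.values.index:
                stats_out.skipped_unannotated += 1
                continue
            if fid not in annotations:
                stats_out.skipped_unannotated += 1
                warnings.warn(f"{fid}: no annotation; excluded from network")
                continue
            out.append(fid)
        return out

    a_ids = usable(sorted(lnc_de), lnc_expr)
    b_ids = usable(sorted(partner_de), partner_expr)
    if not a_ids or not b_ids:
        raise ValueError("empty DE feature list after annotation matching")

    A = lnc_expr.values.loc[a_ids, samples].to_numpy(dtype=float)
    B = partner_expr.values.loc[b_ids, samples].to_numpy(dtype=float)
    const_a = np.ptp(A, axis=1) == 0
    const_b = np.ptp(B, axis=1) == 0
    RB = _rank_rows(B)

    if symmetric:
        stats_out.enumerated = len(a_ids) * len(b_ids)
        stats_out.self_pairs_removed = sum(1 for x in a_ids if x in set(b_ids))
    else:
        stats_out.enumerated = len(a_ids) * len(b_ids)

    raw_records: list[CorrelationPair] = []
    b_ann = [annotations[b] for b in b_ids]
    for start in range(0, len(a_ids), chunk_size):
        block_ids = a_ids[start:start + chunk_size]
        RA = _rank_rows(A[start:start + chunk_size])
        C = _rank_corr_block(RA, RB)
        P = _rho_pvalues(C, n)
        for i, aid in enumerate(block_ids):
            a_ann = annotations[aid]
            for j, bid in enumerate(b_ids):
                if symmetric and aid == bid:
                    continue
                cls = classify_pair_distance(a_ann, b_ann[j], cfg)
                if cls == "cis":
                    stats_out.cis_enumerated += 1
                else:
                    stats_out.trans_enumerated += 1
                if const_a[start + i] or const_b[j]:
                    stats_out.skipped_constant += 1
                    continue
                rho, p = float(C[i, j]), float(P[i, j])
                if p >= cfg.corr_p_threshold:
                    continue
                if cls == "trans" and abs(rho) <= cfg.trans_abs_rho_threshold:
                    continue
                gap = (genomic_gap(a_ann, b_ann[j])
                       if a_ann.chrom == b_ann[j].chrom else None)
                raw_records.append(CorrelationPair(
                    a_id=aid, b_id=bid, pair_kind=pair_kind, rho=rho,
                    p_value=p, distance_class=cls,
                    quadrant=quadrant(lnc_de[aid], partner_de[bid]),
                    genomic_gap=gap))

    if symmetric:
        records = dedupe_symmetric(raw_records)
        stats_out.symmetric_collapsed = len(raw_records) - len(records)
    else:
        records = raw_records

    if records:
        fdrs = bh_adjust(np.array([r.p_value for r in records]))
        records = [replace(r, fdr=float(f)) for r, f in zip(records, fdrs)]
    for r in records:
        if r.distance_class == "cis":
            stats_out.cis_significant += 1
        else:
            stats_out.trans_significant += 1
    return records, stats_out


def dedupe_symmetric(pairs: list[CorrelationPair]) -> list[CorrelationPair]:
    """Collapse A-B / B-A duplicates to one record with a_id < b_id."""
    seen: dict[tuple[str, str], CorrelationPair] = {}
    for p in pairs:
        if p.a_id == p.b_id:
            continue
        key = (p.a_id, p.b_id) if p.a_id < p.b_id else (p.b_id, p.a_id)
        if key not in seen:
            seen[key] = (p if p.a_id < p.b_id
                         else replace(p, a_id=key[0], b_id=key[1],
                                      quadrant=quadrant(*reversed(p.quadrant.split("_")))))
    return list(seen.values())


# -- pair-count arithmetic ---------------------------------------------------

def cross_pair_count(n_a: int, n_b: int) -> int:
    """Number of enumerated A x B cross pairs."""
    return n_a * n_b


def self_cross_pair_count(n: int, drop_self: bool = False) -> int:
    """Pairs from crossing a set with itself, optionally minus self pairs."""
    return n * n - (n if drop_self else 0)


def unique_symmetric_count(n_records: int) -> int:
    """Unique pairs after collapsing a fully symmetric record set."""
    if n_records % 2:
        raise ValueError("a fully symmetric record set has even cardinality")
    return n_records // 2
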