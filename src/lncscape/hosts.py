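"""miRNA host-gene mapping.

A lncRNA *hosts* a miRNA when the miRNA hairpin's genomic interval overlaps
the lncRNA span (>= 1 bp, same strand by default — a host transcript must
encode the hairpin on its own strand).  Host pairs are then filtered for
concordant regulation (both up or both down), the pattern expected when a
miRNA is processed from its differentially regulated parent transcript, and
annotated with the sample-wise Spearman correlation between host lncRNA and
miRNA expression where both matrices share samples.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .coexpression import spearman
from .io import ExpressionMatrix, GeneAnnotation


@dataclass(frozen=True)
class HostPair:
    lncrna_id: str
    mirna_id: str
    overlap: tuple[str, int, int]   # chrom, start, end of the intersection
    same_strand: bool
    lnc_direction: str = "unchanged"
    mir_direction: str = "unchanged"
    concordant: bool = False
    rho: float | None = None
    corr_p: float | None = None

    def __post_init__(self) -> None:
        chrom, s, e = self.overlap
        if e - s < 1:
            raise ValueError(f"{self.lncrna_id}/{self.mirna_id}: overlap "
                             f"must be >= 1 bp, got [{s},{e})")
        ok = (self.lnc_direction == self.mir_direction
              and self.lnc_direction in ("up", "down"))
        if self.concordant != ok:
            raise ValueError("concordant flag inconsistent with directions")


def intersect_hosts(lncs: list[GeneAnnotation], mirnas: list[GeneAnnotation],
                    require_same_strand: bool = True) -> list[HostPair]:
    """All overlapping (lncRNA, miRNA) combinations by interval intersection."""
    trees: dict[str, IntervalTree] = {}
    for i, lnc in enumerate(lncs):
        trees.setdefault(lnc.chrom, IntervalTree()).addi(lnc.start, lnc.end, i)
    out: list[HostPair] = []
    for mir in mirnas:
        tree = trees.get(mir.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(mir.start, mir.end),
                          key=lambda h: h.data):
            lnc = lncs[hit.data]
            same = lnc.strand == mir.strand
            if require_same_strand and not same:
                continue
            out.append(HostPair(
                lncrna_id=lnc.gene_id, mirna_id=mir.gene_id,
                overlap=(mir.chrom, max(lnc.start, mir.start),
                         min(lnc.end, mir.end)),
                same_strand=same))
    return out


def filter_concordant(pairs: list[HostPair],
                      lnc_de: dict[str, str], mir_de: dict[str, str],
                      lnc_expr: ExpressionMatrix | None = None,
                      mir_expr: ExpressionMatrix | None = None,
                      ) -> list[HostPair]:
    """Keep host pairs whose lncRNA and miRNA move in the same direction.

    Both must be called up, or both down, by their respective DE stages
    (the two feature classes may come from different assay platforms).
    When expression matrices with shared samples are supplied, the Spearman
    correlation between host and miRNA is annotated; otherwise the pair is
    retained on direction alone with rho = None.
    """
    shared: list[str] = []
    if lnc_expr is not None and mir_expr is not None:
        shared = [s for s in lnc_expr.sample_ids if s in mir_expr.sample_ids]
    out: list[HostPair] = []
    for p in pairs:
        ld = lnc_de.get(p.lncrna_id, "unchanged")
        md = mir_de.get(p.mirna_id, "unchanged")
        if ld != md or ld not in ("up", "down"):
            continue
        rho = corr_p = None
        if (len(shared) >= 4 and lnc_expr is not None and mir_expr is not None
                and p.lncrna_id in lnc_expr.values.index
                and p.mirna_id in mir_expr.values.index):
            try:
                rho, corr_p = spearman(
                    lnc_expr.values.loc[p.lncrna_id, shared].to_numpy(),
                    mir_expr.values.loc[p.mirna_id, shared].to_numpy())
            except ValueError:
                rho = corr_p = None
        out.append(replace(p, lnc_direction=ld, mir_direction=md,
                           concordant=True, rho=rho, corr_p=corr_p))
    return out
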