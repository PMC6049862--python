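"""Positional classification of lncRNAs relative to protein-coding genes.

Each lncRNA is assigned exactly one of six positional subtypes by geometry
against nearby mRNA genes, in decreasing order of evidence strength:

1. exon_sense_overlapping  - exon overlap with an mRNA on the same strand
2. natural_antisense       - exon overlap on the opposite strand
3. intron_sense_overlapping- span inside an mRNA intron, same strand
4. intronic_antisense      - span inside an mRNA intron, opposite strand
5. bidirectional           - opposite strands, disjoint spans, TSS-to-TSS
                             distance within the 1 kb window (inclusive)
6. intergenic              - none of the above

Exon-sense-overlapping lncRNAs whose whole span lies inside the same-strand
exonic footprint of an mRNA are flagged for removal: microarray probes
there cannot distinguish lncRNA from mRNA signal.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from .config import PipelineConfig
from .io import GeneAnnotation

SUBTYPES = ("intergenic", "intronic_antisense", "intron_sense_overlapping",
            "natural_antisense", "exon_sense_overlapping", "bidirectional")


@dataclass(frozen=True)
class SubtypeCall:
    lncrna_id: str
    subtype: str
    partner_gene_id: str | None = None
    removed_by_exon_rule: bool = False

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if (self.subtype == "intergenic") != (self.partner_gene_id is None):
            raise ValueError("intergenic iff no partner gene")
        if self.removed_by_exon_rule and self.subtype != "exon_sense_overlapping":
            raise ValueError("removal flag only applies to exon_sense_overlapping")


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exon_overlap(lnc: GeneAnnotation, mrna: GeneAnnotation) -> bool:
    return any(_intervals_overlap(le, me)
               for le in lnc.exon_intervals for me in mrna.exon_intervals)


def _span_in_intron(lnc: GeneAnnotation, mrna: GeneAnnotation) -> bool:
    return any(s <= lnc.start and lnc.end <= e for s, e in mrna.introns())


def classify_lncrna(lnc: GeneAnnotation, mrnas: list[GeneAnnotation],
                    cfg: PipelineConfig | None = None,
                    _by_chrom: dict[str, list[GeneAnnotation]] | None = None,
                    ) -> SubtypeCall:
    """Assign the positional subtype of one lncRNA against the mRNA set."""
    if cfg is None:
        cfg = PipelineConfig()
    if _by_chrom is None:
        _by_chrom = index_by_chrom(mrnas)
    neighbours = _by_chrom.get(lnc.chrom)
    if neighbours is None:
        if mrnas:
            warnings.warn(f"{lnc.gene_id}: chromosome {lnc.chrom} absent from "
                          "mRNA annotation; classified intergenic")
        return SubtypeCall(lnc.gene_id, "intergenic")

    best: tuple[int, int, str] | None = None  # (precedence, distance, partner)
    for m in neighbours:
        same = m.strand == lnc.strand
        span_overlap = _intervals_overlap((lnc.start, lnc.end), (m.start, m.end))
        if _exon_overlap(lnc, m):
            rank = 0 if same else 1
        elif span_overlap and _span_in_intron(lnc, m):
            rank = 2 if same else 3
        elif (not same and not span_overlap
              and abs(lnc.tss - m.tss) <= cfg.bidirectional_tss_window):
            rank = 4
        else:
            continue
        dist = _gene_distance(lnc, m)
        if best is None or (rank, dist) < best[:2]:
            best = (rank, dist, m.gene_id)
    if best is None:
        return SubtypeCall(lnc.gene_id, "intergenic")
    subtype = ("exon_sense_overlapping", "natural_antisense",
               "intron_sense_overlapping", "intronic_antisense",
               "bidirectional")[best[0]]
    return SubtypeCall(lnc.gene_id, subtype, partner_gene_id=best[2])


def classify_all(lncs: list[GeneAnnotation], mrnas: list[GeneAnnotation],
                 cfg: PipelineConfig | None = None) -> list[SubtypeCall]:
    by_chrom = index_by_chrom(mrnas)
    return [classify_lncrna(l, mrnas, cfg, _by_chrom=by_chrom) for l in lncs]


def index_by_chrom(genes: list[GeneAnnotation]) -> dict[str, list[GeneAnnotation]]:
    idx: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for g in genes:
        idx[g.chrom].append(g)
    return dict(idx)


def _gene_distance(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Span-to-span gap in bp; 0 when overlapping."""
    if _intervals_overlap((a.start, a.end), (b.start, b.end)):
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def apply_exon_overlap_removal(calls: list[SubtypeCall],
                               lncs: list[GeneAnnotation],
                               mrnas: list[GeneAnnotation]) -> list[SubtypeCall]:
    """Flag exon-sense-overlapping lncRNAs fully inside same-strand mRNA exons.

    The lncRNA span must be contained in one merged interval of the union of
    exon intervals of same-strand mRNAs on its chromosome; partial overlaps
    are retained.  Returns updated calls (``removed_by_exon_rule`` set).
    """
    # merged same-strand exon footprint per (chrom, strand)
    footprint: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for m in mrnas:
        footprint[(m.chrom, m.strand)].extend(m.exon_intervals)
    merged: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for key, ivs in footprint.items():
        out: list[list[int]] = []
        for s, e in sorted(ivs):
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[key] = [(s, e) for s, e in out]

    lnc_by_id = {l.gene_id: l for l in lncs}
    updated = []
    for call in calls:
        removed = False
        if call.subtype == "exon_sense_overlapping":
            lnc = lnc_by_id[call.lncrna_id]
            for s, e in merged.get((lnc.chrom, lnc.strand), ()):
                if s <= lnc.start and lnc.end <= e:
                    removed = True
                    break
        updated.append(SubtypeCall(call.lncrna_id, call.subtype,
                                   call.partner_gene_id, removed))
    return updated


def surviving_ids(calls: list[SubtypeCall]) -> list[str]:
    """lncRNA ids retained after the exon-sense-overlap removal rule."""
    return [c.lncrna_id for c in calls if not c.removed_by_exon_rule]


def subtype_summary(calls: list[SubtypeCall]) -> dict[str, tuple[int, float]]:
    """Per-subtype (count, percentage of total), percentages to 2 decimals."""
    if not calls:
        raise ValueError("no subtype calls to summarise")
    total = len(calls)
    counts: dict[str, int] = defaultdict(int)
    for c in calls:
        counts[c.subtype] += 1
    return {s: (n, round(100.0 * n / total, 2)) for s, n in counts.items()}
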