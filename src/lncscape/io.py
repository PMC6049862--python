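"""Domain types and file I/O.

Internal genomic coordinates are 0-based half-open (BED-native); GTF/GFF3
input (1-based inclusive) is shifted at the boundary and shifted back on
write, so a GTF -> internal -> GTF round trip is exact.

Expression matrices are thin wrappers around a features x samples pandas
DataFrame with tumor/control group labels and optional Present/Marginal/
Absent detection flags.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
CONTROL = "control"

#: default mapping from annotation-source biotype attributes to the three
#: internal feature classes; user-extensible via ``read_annotation``.
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "miRNA": "miRNA",
}


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene/transcript: span, strand, exon structure and biotype.

    Coordinates are 0-based half-open base pairs.  Exons are sorted,
    pairwise non-overlapping and contained in ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    symbol: str = ""
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', "
                             f"got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span "
                                 f"[{self.start},{self.end})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on '+', ``end - 1`` on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exons, or the full span when no exon structure is recorded."""
        return self.exons if self.exons else ((self.start, self.end),)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (empty without exon structure)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression with group labels.

    ``scale`` is ``"log2"`` (normalised intensities / log counts) or
    ``"linear_count"`` (raw non-negative counts).  ``flags`` optionally
    carries per-cell Present/Marginal/Absent detection labels.
    """

    values: pd.DataFrame
    group_labels: pd.Series
    scale: str = "log2"
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear_count"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.group_labels.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.group_labels.loc[list(self.values.columns)]) - {TUMOR, CONTROL}
        if bad:
            raise ValueError(f"group labels must be tumor/control, got {bad}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.flags is not None:
            if (not self.flags.index.equals(self.values.index)
                    or not self.flags.columns.equals(self.values.columns)):
                raise ValueError("flags must share the matrix index/columns")
        self.group_labels = self.group_labels.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == group]

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group(TUMOR)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(CONTROL)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            values=self.values.loc[ids],
            group_labels=self.group_labels,
            scale=self.scale,
            flags=None if self.flags is None else self.flags.loc[ids],
        )


# ---------------------------------------------------------------------------
# InteractionTable / SurvivalRecord
# ---------------------------------------------------------------------------

@dataclass
class InteractionTable:
    """Source -> target interaction pairs (predicted or validated).

    Duplicate (source, target) rows are collapsed on construction.
    """

    pairs: pd.DataFrame  # columns: source_id, target_id
    evidence: str        # "predicted" | "validated"
    origin: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in ("predicted", "validated"):
            raise ValueError(f"evidence must be predicted/validated, "
                             f"got {self.evidence!r}")
        need = {"source_id", "target_id"}
        if not need <= set(self.pairs.columns):
            raise ValueError(f"interaction table needs columns {need}")
        self.pairs = (self.pairs[["source_id", "target_id"]]
                      .astype(str)
                      .drop_duplicates(ignore_index=True))

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, source_id: str) -> list[str]:
        sel = self.pairs["source_id"] == source_id
        return self.pairs.loc[sel, "target_id"].tolist()


SURVIVAL_COVARIATES = ("age", "g_cimp", "idh1", "mgmt")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (months), event status and covariates."""

    sample_id: str
    time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")
        unknown = set(self.covariates) - set(SURVIVAL_COVARIATES)
        if unknown:
            raise ValueError(f"{self.sample_id}: unknown covariates {unknown}")


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by sample, for model fitting."""
    rows = {}
    for r in records:
        rows[r.sample_id] = {"time": r.time, "event": r.event, **r.covariates}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Annotation readers / writers
# ---------------------------------------------------------------------------

_GTF_BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype", "transcript_biotype")
_GTF_SYMBOL_KEYS = ("gene_name", "Name", "gene_symbol")


def read_annotation(path: str | Path, format: str = "GTF",
                    biotype_map: Mapping[str, str] | None = None,
                    ) -> list[GeneAnnotation]:
    """Read gene annotations from GTF, GFF3 or BED12.

    GTF/GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED passes through.  Biotypes are mapped
    to {mRNA, lncRNA, miRNA} via ``biotype_map`` (defaults to
    :data:`DEFAULT_BIOTYPE_MAP`); records with an unmapped biotype are
    dropped with a warning.
    """
    fmt = format.upper()
    if fmt in ("GTF", "GFF3"):
        return _read_gxf(path, fmt, biotype_map)
    if fmt == "BED12":
        return _read_bed12(path, biotype_map)
    raise ValueError(f"unknown annotation format {format!r}")


def _map_biotype(raw: str, biotype_map: Mapping[str, str] | None,
                 context: str) -> str | None:
    mapping = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    mapped = mapping.get(raw)
    if mapped is None:
        warnings.warn(f"{context}: unknown biotype {raw!r}; record dropped")
    return mapped


def _read_gxf(path: str | Path, fmt: str,
              biotype_map: Mapping[str, str] | None) -> list[GeneAnnotation]:
    import gffutils

    dialect = "gtf" if fmt == "GTF" else "gff3"
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ParseError(f"{path}: {exc}") from exc

    genes: dict[str, dict] = {}
    for feat in db.all_features():
        gid = (feat.attributes.get("gene_id") or feat.attributes.get("ID")
               or [feat.id])[0]
        rec = genes.setdefault(gid, {"exons": [], "gene": None})
        if feat.featuretype == "gene":
            rec["gene"] = feat
        elif feat.featuretype == "exon":
            rec["exons"].append((feat.start - 1, feat.end))
        elif rec["gene"] is None and feat.featuretype in ("transcript", "mRNA"):
            rec["gene"] = feat

    out: list[GeneAnnotation] = []
    for gid, rec in genes.items():
        feat = rec["gene"]
        if feat is None:
            continue
        raw_biotype = next(
            (feat.attributes[k][0] for k in _GTF_BIOTYPE_KEYS
             if k in feat.attributes), "")
        biotype = _map_biotype(raw_biotype, biotype_map, f"{path}:{gid}")
        if biotype is None:
            continue
        symbol = next(
            (feat.attributes[k][0] for k in _GTF_SYMBOL_KEYS
             if k in feat.attributes), gid)
        exons = _merge_sorted_exons(rec["exons"])
        try:
            out.append(GeneAnnotation(
                gene_id=gid, symbol=symbol, chrom=feat.seqid,
                start=feat.start - 1, end=feat.end, strand=feat.strand,
                biotype=biotype, exons=exons,
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: gene {gid}: {exc}") from exc
    return out


def _merge_sorted_exons(exons: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge touching/overlapping exon intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _read_bed12(path: str | Path,
                biotype_map: Mapping[str, str] | None) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, "
                                 f"got {len(parts)}")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + off, start + off + sz)
                          for off, sz in zip(starts, sizes))
            # biotype rides in the (non-standard but common) 13th column if
            # present; otherwise default to lncRNA, the typical BED12 payload
            raw = parts[12] if len(parts) > 12 else "lncRNA"
            biotype = _map_biotype(raw, biotype_map, f"{path}:{lineno}")
            if biotype is None:
                continue
            try:
                out.append(GeneAnnotation(
                    gene_id=name, symbol=name, chrom=chrom, start=start,
                    end=end, strand=strand, biotype=biotype, exons=exons))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_mirna_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read miRNA hairpin coordinates from BED6 (miRBase dialect)."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns")
            try:
                out.append(GeneAnnotation(
                    gene_id=parts[3], symbol=parts[3], chrom=parts[0],
                    start=int(parts[1]), end=int(parts[2]), strand=parts[5],
                    biotype="miRNA"))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


_INV_BIOTYPE = {"mRNA": "protein_coding", "lncRNA": "lncRNA", "miRNA": "miRNA"}


def write_annotation_gtf(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations as GTF (back to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.symbol or g.gene_id}"; '
                     f'gene_biotype "{_INV_BIOTYPE[g.biotype]}";')
            fh.write("\t".join([g.chrom, "lncscape", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for s, e in g.exons:
                fh.write("\t".join([g.chrom, "lncscape", "exon", str(s + 1),
                                    str(e), ".", g.strand, ".", attrs]) + "\n")


def write_mirna_bed(mirnas: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write("\t".join([m.chrom, str(m.start), str(m.end),
                                m.gene_id, "0", m.strand]) + "\n")


# ---------------------------------------------------------------------------
# Expression readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, sample_sheet: str | Path,
                    scale: str = "log2",
                    flags_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a features x samples TSV plus a sample-sheet TSV.

    The matrix TSV has sample ids in the header and feature ids in the first
    column.  The sample sheet has columns ``sample_id`` and ``group``
    (tumor/control) and must cover every sample in the matrix.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique()[0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in values.columns:
            bad = pd.to_numeric(values[col], errors="coerce")
            nonnum = values.index[bad.isna() & values[col].notna()]
            if len(nonnum):
                raise ParseError(f"{path}: non-numeric cell at feature "
                                 f"{nonnum[0]!r}, sample {col!r}")
        raise ParseError(f"{path}: non-numeric values")
    sheet = pd.read_csv(sample_sheet, sep="\t")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise ParseError(f"{sample_sheet}: needs sample_id and group columns")
    labels = sheet.set_index("sample_id")["group"].astype(str)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
        flags.index = flags.index.astype(str)
    return ExpressionMatrix(values=values, group_labels=labels, scale=scale,
                            flags=flags)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     sample_sheet: str | Path | None = None) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")
    if sample_sheet is not None:
        (m.group_labels.rename("group").rename_axis("sample_id")
         .reset_index().to_csv(sample_sheet, sep="\t", index=False))


def read_interactions(path: str | Path, evidence: str,
                      origin: str = "") -> InteractionTable:
    """Read a two-column (source_id, target_id) TSV interaction table."""
    df = pd.read_csv(path, sep="\t")
    if not {"source_id", "target_id"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["source_id", "target_id"])
    return InteractionTable(pairs=df, evidence=evidence,
                            origin=origin or str(path))


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read per-sample survival TSV: sample_id, time, event [+ covariates]."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "time", "event"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(need)}")
    cov_cols = [c for c in df.columns if c in SURVIVAL_COVARIATES]
    out = []
    for _, row in df.iterrows():
        out.append(SurvivalRecord(
            sample_id=str(row["sample_id"]), time=float(row["time"]),
            event=int(row["event"]),
            covariates={c: float(row[c]) for c in cov_cols},
        ))
    return out


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    df = survival_frame(records).rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pair / module writers (documented column orders)
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["a_id", "b_id", "pair_kind", "rho", "p_value", "fdr",
                "distance_class", "quadrant", "genomic_gap"]

MODULE_COLUMNS = ["lncrna_id", "mirna_id", "mrna_id",
                  "rho_lnc_mir", "p_lnc_mir", "rho_mir_mrna", "p_mir_mrna",
                  "rho_lnc_mrna", "p_lnc_mrna",
                  "abundance_stat", "abundance_p",
                  "mean_abundance_lnc", "mean_abundance_mrna"]


def write_pairs(pairs, path: str | Path) -> None:
    """Write correlation pairs as TSV with the documented column order."""
    rows = [{c: getattr(p, c) for c in PAIR_COLUMNS} for p in pairs]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edge_list(pairs, path: str | Path) -> None:
    """Minimal (a_id, b_id, rho) edge list for graph tools."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.a_id}\t{p.b_id}\t{p.rho:.6g}\n")


def write_modules(modules, path: str | Path) -> None:
    rows = [{c: getattr(m, c) for c in MODULE_COLUMNS} for m in modules]
    pd.DataFrame(rows, columns=MODULE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_modules(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
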