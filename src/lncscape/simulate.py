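"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study's inputs end to end: a synthetic genome in
which mRNA genes are laid out with exon/intron structure and lncRNAs are
placed to realise every positional subtype with known labels (including the
1 kb TSS and 500 kb window boundary cases), miRNAs embedded inside host
lncRNAs on the same strand, log2 expression with planted group differences,
latent-factor cis-correlated pairs, sponge chains
(miRNA = a - 0.8*lncRNA + noise; mRNA = b - 0.8*miRNA + noise, all three
upregulated and the lncRNA offset +2 log2 units above the mRNA), and
proportional-hazards survival times driven by a planted lncRNA signature.

Expression is Gaussian on the log2 scale (the analysis operates on log
scale); an optional count mode feeds the size-factor operation.  Each file
class draws from its own RNG stream seeded from ``seed`` plus a fixed
per-class offset, so regenerating one class does not perturb the others.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CONTROL, TUMOR, ExpressionMatrix, GeneAnnotation,
                 InteractionTable, SurvivalRecord, write_annotation_gtf,
                 write_expression, write_mirna_bed, write_survival)

_SEED_OFFSETS = {"annotation": 0, "lnc": 1, "mrna": 2, "mirna": 3,
                 "survival": 4, "decoys": 5}

_SUBTYPE_CYCLE = ("intergenic", "exon_sense_overlapping", "natural_antisense",
                  "intron_sense_overlapping", "intronic_antisense",
                  "bidirectional")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    de_up: dict[str, list[str]] = field(default_factory=dict)    # class -> ids
    de_down: dict[str, list[str]] = field(default_factory=dict)
    subtype_of: dict[str, str] = field(default_factory=dict)
    exon_removed: list[str] = field(default_factory=list)
    planted_cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    boundary_trans_pairs: list[tuple[str, str]] = field(default_factory=list)
    host_pairs: list[tuple[str, str]] = field(default_factory=list)
    sponge_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    survival_signature: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("planted_cis_pairs", "boundary_trans_pairs", "host_pairs",
                    "sponge_triplets", "decoy_triplets"):
            d[key] = [tuple(x) for x in d.get(key, [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Annotation geometry
# ---------------------------------------------------------------------------

_SPACING = 1_500_000       # bp between mRNA slots; > 2x the cis window
_EXON_LEN = 1_000
_INTRON_LEN = 5_000
_PER_CHROM = 20            # mRNA slots per synthetic chromosome


def _make_mrna(idx: int, rng: np.random.Generator) -> GeneAnnotation:
    chrom = f"chr{idx // _PER_CHROM + 1}"
    base = 100_000 + (idx % _PER_CHROM) * _SPACING
    n_exons = int(rng.integers(2, 11))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = tuple(
        (base + k * (_EXON_LEN + _INTRON_LEN),
         base + k * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN)
        for k in range(n_exons))
    return GeneAnnotation(gene_id=f"MRNA{idx:04d}", symbol=f"GENE{idx:04d}",
                          chrom=chrom, start=exons[0][0], end=exons[-1][1],
                          strand=strand, biotype="mRNA", exons=exons)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_lncrna(idx: int, subtype: str, partner: GeneAnnotation,
                  cis_gap: int | None, removal_case: bool,
                  boundary_tss: bool) -> GeneAnnotation:
    """Deterministically place one lncRNA realising ``subtype``."""
    gid = f"LNC{idx:04d}"
    m = partner
    e0 = m.exons[0]
    if subtype == "exon_sense_overlapping":
        strand = m.strand
        if removal_case:  # strictly inside the first exon -> removed by rule
            span = (e0[0] + 100, e0[1] - 100)
        else:             # partial overlap, extends into the intron
            span = (e0[0] + 200, e0[1] + 800)
        return GeneAnnotation(gid, m.chrom, span[0], span[1], strand, "lncRNA",
                              symbol=gid)
    if subtype == "natural_antisense":
        return GeneAnnotation(gid, m.chrom, e0[0] + 200, e0[1] + 800,
                              _flip(m.strand), "lncRNA", symbol=gid)
    if subtype in ("intron_sense_overlapping", "intronic_antisense"):
        strand = m.strand if subtype == "intron_sense_overlapping" else _flip(m.strand)
        return GeneAnnotation(gid, m.chrom, e0[1] + 500, e0[1] + 3_000,
                              strand, "lncRNA", symbol=gid)
    if subtype == "bidirectional":
        dist = 1_000 if boundary_tss else 501
        if m.strand == "+":   # divergent partner upstream of the mRNA TSS
            end = m.start - dist + 1          # lnc TSS (end-1) at distance dist
            return GeneAnnotation(gid, m.chrom, end - 2_000, end, "-",
                                  "lncRNA", symbol=gid)
        start = m.end - 1 + dist              # mRNA TSS at end-1; lnc on '+'
        return GeneAnnotation(gid, m.chrom, start, start + 2_000, "+",
                              "lncRNA", symbol=gid)
    if subtype == "intergenic":
        gap = cis_gap if cis_gap is not None else 620_000
        start = m.end + gap
        return GeneAnnotation(gid, m.chrom, start, start + 2_000, "+",
                              "lncRNA", symbol=gid)
    raise ValueError(f"unknown subtype {subtype!r}")


def simulate_annotation(n_mrna: int = 80, n_lnc: int = 120, n_mirna: int = 40,
                        seed: int = 7, n_cis_pairs: int = 20,
                        n_host_pairs: int = 10,
                        ) -> tuple[dict[str, list[GeneAnnotation]], GroundTruth]:
    """Synthetic annotation realising every subtype with known labels.

    Returns ``{"mrna": [...], "lnc": [...], "mirna": [...]}`` and a
    :class:`GroundTruth` holding subtype labels, exon-removal cases, planted
    cis pairs (span gap 100 kb, plus one pair at the exact 500 kb boundary
    and one just beyond it) and host-embedded miRNA pairs.
    """
    if min(n_mrna, n_lnc, n_mirna) < 1:
        raise ValueError("feature counts must be >= 1")
    rng = np.random.default_rng(seed + _SEED_OFFSETS["annotation"])
    truth = GroundTruth()
    mrnas = [_make_mrna(i, rng) for i in range(n_mrna)]

    # subtype plan: first 6 cover every class, the rest lean intergenic
    plan: list[str] = list(_SUBTYPE_CYCLE[:min(6, n_lnc)])
    while len(plan) < n_lnc:
        i = len(plan)
        plan.append("intergenic" if i % 2 == 0
                    else _SUBTYPE_CYCLE[1 + (i // 2) % 5])
    intergenic_idx = [i for i, s in enumerate(plan) if s == "intergenic"]
    # each planted pair needs its own partner mRNA (shared partners would
    # entangle the planted latent factors), so cap at the mRNA count
    n_cis_pairs = min(n_cis_pairs, max(n_mrna - 2, 0))
    cis_idx = set(intergenic_idx[:n_cis_pairs])
    boundary_cis = intergenic_idx[n_cis_pairs:n_cis_pairs + 1]    # gap = 500 kb
    boundary_trans = intergenic_idx[n_cis_pairs + 1:n_cis_pairs + 2]  # 500,001

    lncs: list[GeneAnnotation] = []
    n_exon_sense = 0
    cis_counter = 0
    for i, subtype in enumerate(plan):
        cis_gap = None
        if i in cis_idx:
            cis_gap = 100_000
        elif i in boundary_cis:
            cis_gap = 500_000
        elif i in boundary_trans:
            cis_gap = 500_001
        if cis_gap is not None:
            partner = mrnas[cis_counter % n_mrna]
            cis_counter += 1
        else:
            partner = mrnas[i % n_mrna]
        removal_case = False
        if subtype == "exon_sense_overlapping":
            removal_case = n_exon_sense % 2 == 1  # alternate partial/contained
            n_exon_sense += 1
        boundary_tss = subtype == "bidirectional" and i < 6
        lnc = _place_lncrna(i, subtype, partner, cis_gap, removal_case,
                            boundary_tss)
        lncs.append(lnc)
        truth.subtype_of[lnc.gene_id] = subtype
        if removal_case:
            truth.exon_removed.append(lnc.gene_id)
        if i in cis_idx or i in boundary_cis:
            truth.planted_cis_pairs.append((lnc.gene_id, partner.gene_id))
        if i in boundary_trans:
            truth.boundary_trans_pairs.append((lnc.gene_id, partner.gene_id))

    # miRNAs: the first n_host_pairs sit inside intergenic host lncRNAs on
    # the same strand (skipping the cis-planted ones so each lncRNA plays a
    # single role); the rest go to gene deserts far from every lncRNA
    host_candidates = [lncs[i] for i in intergenic_idx[n_cis_pairs + 2:]]
    if not host_candidates:
        host_candidates = [lncs[i] for i in intergenic_idx]
    mirnas: list[GeneAnnotation] = []
    for j in range(n_mirna):
        gid = f"MIR{j:04d}"
        if j < n_host_pairs and host_candidates:
            host = host_candidates[j % len(host_candidates)]
            s = host.start + 300 + (j // len(host_candidates)) * 200
            mir = GeneAnnotation(gid, host.chrom, s, s + 80, host.strand,
                                 "miRNA", symbol=gid)
            truth.host_pairs.append((host.gene_id, gid))
        else:
            chrom = f"chr{j % max(1, n_mrna // _PER_CHROM or 1) + 1}"
            s = 100_000 + (j % _PER_CHROM) * _SPACING - 40_000
            mir = GeneAnnotation(gid, chrom, s, s + 80, "+", "miRNA",
                                 symbol=gid)
        mirnas.append(mir)

    return {"mrna": mrnas, "lnc": lncs, "mirna": mirnas}, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _sample_ids(n_tumor: int, n_control: int) -> tuple[list[str], list[str]]:
    return ([f"T{i + 1:03d}" for i in range(n_tumor)],
            [f"N{i + 1:03d}" for i in range(n_control)])


def simulate_expression(truth: GroundTruth,
                        annotations: dict[str, list[GeneAnnotation]],
                        n_tumor: int = 19, n_control: int = 9,
                        effect_log2fc: float = 2.0, rho_cis: float = 0.9,
                        beta_sponge: float = 0.8, n_sponge: int = 20,
                        n_decoys: int = 500, de_fraction: float = 0.4,
                        seed: int = 7,
                        ) -> tuple[dict[str, ExpressionMatrix],
                                   dict[str, InteractionTable]]:
    """Log2 expression matrices plus interaction tables, with planted truth.

    Baselines are Gaussian (mRNA ~ N(8,1), lncRNA ~ N(6,1), miRNA ~ N(7,1));
    DE features are shifted by ``effect_log2fc`` in tumors; planted cis
    pairs share a latent factor giving Pearson ~ ``rho_cis``; sponge chains
    couple miRNA to lncRNA and mRNA to miRNA with slope ``-beta_sponge`` on
    within-group deviations so all three can be upregulated while the chain
    correlations are (-,-,+); sponge lncRNA baselines sit +2 log2 units
    above their mRNA.  ``truth`` is updated in place with DE labels, sponge
    and decoy triplets.
    """
    if not (0 <= rho_cis <= 1):
        raise ValueError("rho_cis must be in [0, 1]")
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be >= 0")
    if n_tumor < 4 or n_control < 2:
        raise ValueError("need n_tumor >= 4 and n_control >= 2")

    tumors, controls = _sample_ids(n_tumor, n_control)
    samples = tumors + controls
    n = len(samples)
    is_tumor = np.array([1.0] * n_tumor + [0.0] * n_control)
    labels = pd.Series([TUMOR] * n_tumor + [CONTROL] * n_control,
                       index=samples)

    ids = {cls: [g.gene_id for g in annotations[cls]]
           for cls in ("lnc", "mrna", "mirna")}
    rngs = {cls: np.random.default_rng(seed + _SEED_OFFSETS[cls])
            for cls in ("lnc", "mrna", "mirna")}
    rng_decoy = np.random.default_rng(seed + _SEED_OFFSETS["decoys"])

    # --- choose the planted roles -------------------------------------
    cis_lnc = {a for a, _ in truth.planted_cis_pairs + truth.boundary_trans_pairs}
    cis_mrna = {b for _, b in truth.planted_cis_pairs + truth.boundary_trans_pairs}
    host_lnc = {a for a, _ in truth.host_pairs}
    host_mir = {b for _, b in truth.host_pairs}

    free_lnc = [x for x in ids["lnc"]
                if x not in cis_lnc and x not in host_lnc]
    free_mir = [x for x in ids["mirna"] if x not in host_mir]
    free_mrna = [x for x in ids["mrna"] if x not in cis_mrna]
    k = min(n_sponge, len(free_lnc), len(free_mir), len(free_mrna))
    truth.sponge_triplets = [(free_lnc[i], free_mir[i], free_mrna[i])
                             for i in range(k)]
    sponge_feats = {x for t in truth.sponge_triplets for x in t}

    # DE labels: constrained features first, then a random fraction
    de_up: dict[str, set[str]] = {c: set() for c in ("lnc", "mrna", "mirna")}
    de_down: dict[str, set[str]] = {c: set() for c in ("lnc", "mrna", "mirna")}
    for a, b in truth.planted_cis_pairs:
        de_up["lnc"].add(a)
        de_up["mrna"].add(b)
    for a, b in truth.boundary_trans_pairs:
        de_up["lnc"].add(a)
        de_up["mrna"].add(b)
    for l, m, r in truth.sponge_triplets:
        de_up["lnc"].add(l)
        de_up["mirna"].add(m)
        de_up["mrna"].add(r)
    for i, (l, m) in enumerate(truth.host_pairs):
        if l in de_up["lnc"] or l in de_down["lnc"]:  # lncRNA plays two roles
            side = de_up if l in de_up["lnc"] else de_down
        else:
            side = de_up if i % 2 == 0 else de_down
            side["lnc"].add(l)
        side["mirna"].add(m)
    for cls in ("lnc", "mrna", "mirna"):
        unconstrained = [x for x in ids[cls]
                         if x not in de_up[cls] and x not in de_down[cls]]
        rng = rngs[cls]
        n_extra = int(de_fraction * len(unconstrained))
        picked = list(rng.choice(unconstrained, size=n_extra, replace=False)) \
            if n_extra else []
        half = len(picked) // 2
        de_up[cls].update(picked[:half])
        de_down[cls].update(picked[half:])
    truth.de_up = {c: sorted(v) for c, v in de_up.items()}
    truth.de_down = {c: sorted(v) for c, v in de_down.items()}

    # --- baselines and shifts -----------------------------------------
    base_mean = {"lnc": 6.0, "mrna": 8.0, "mirna": 7.0}
    base: dict[str, pd.Series] = {}
    shift: dict[str, pd.Series] = {}
    for cls in ("lnc", "mrna", "mirna"):
        rng = rngs[cls]
        b = pd.Series(rng.normal(base_mean[cls], 1.0, len(ids[cls])),
                      index=ids[cls])
        s = pd.Series(0.0, index=ids[cls])
        s[list(de_up[cls])] = effect_log2fc
        s[list(de_down[cls])] = -effect_log2fc
        base[cls], shift[cls] = b, s
    # sponge abundance: lncRNA baseline = its mRNA baseline + 2
    for l, _, r in truth.sponge_triplets:
        base["lnc"][l] = base["mrna"][r] + 2.0

    X: dict[str, pd.DataFrame] = {}
    for cls in ("lnc", "mrna", "mirna"):
        rng = rngs[cls]
        noise = rng.normal(0.0, 1.0, (len(ids[cls]), n))
        X[cls] = pd.DataFrame(
            base[cls].to_numpy()[:, None]
            + np.outer(shift[cls].to_numpy(), is_tumor) + noise,
            index=ids[cls], columns=samples)

    # cis pairs: replace the independent deviations with a shared factor
    a = float(np.sqrt(rho_cis))
    resid = float(np.sqrt(1.0 - rho_cis))
    rng = rngs["lnc"]
    for lnc_id, mrna_id in (truth.planted_cis_pairs
                            + truth.boundary_trans_pairs):
        z = rng.normal(0.0, 1.0, n)
        for cls, fid in (("lnc", lnc_id), ("mrna", mrna_id)):
            e = rng.normal(0.0, 1.0, n)
            dev = a * z + resid * e
            X[cls].loc[fid] = (base[cls][fid]
                               + shift[cls][fid] * is_tumor + dev)

    # sponge chains: couple deviations down the lncRNA -> miRNA -> mRNA chain
    sd_resid = float(np.sqrt(max(1.0 - beta_sponge ** 2, 1e-9)))
    rng = rngs["mirna"]
    for l, m, r in truth.sponge_triplets:
        dev_l = X["lnc"].loc[l].to_numpy() - base["lnc"][l] \
            - shift["lnc"][l] * is_tumor
        dev_m = -beta_sponge * dev_l + sd_resid * rng.normal(0, 1, n)
        X["mirna"].loc[m] = base["mirna"][m] + shift["mirna"][m] * is_tumor + dev_m
        dev_r = -beta_sponge * dev_m + sd_resid * rng.normal(0, 1, n)
        X["mrna"].loc[r] = base["mrna"][r] + shift["mrna"][r] * is_tumor + dev_r

    # host pairs: embedded miRNA tracks its host transcript
    for l, m in truth.host_pairs:
        dev_l = X["lnc"].loc[l].to_numpy() - base["lnc"][l] \
            - shift["lnc"][l] * is_tumor
        dev_m = 0.8 * dev_l + 0.6 * rng.normal(0, 1, n)
        X["mirna"].loc[m] = base["mirna"][m] + shift["mirna"][m] * is_tumor + dev_m

    matrices = {cls: ExpressionMatrix(values=X[cls], group_labels=labels,
                                      scale="log2")
                for cls in ("lnc", "mrna", "mirna")}

    # --- interaction tables (planted edges + decoy chains) ------------
    decoy_lnc = [x for x in ids["lnc"] if x not in sponge_feats]
    decoy_mir = [x for x in ids["mirna"] if x not in sponge_feats]
    decoy_mrna = [x for x in ids["mrna"] if x not in sponge_feats]
    decoys: set[tuple[str, str, str]] = set()
    if decoy_lnc and decoy_mir and decoy_mrna:
        guard = 0
        while len(decoys) < n_decoys and guard < 50 * n_decoys:
            guard += 1
            decoys.add((decoy_lnc[int(rng_decoy.integers(len(decoy_lnc)))],
                        decoy_mir[int(rng_decoy.integers(len(decoy_mir)))],
                        decoy_mrna[int(rng_decoy.integers(len(decoy_mrna)))]))
    truth.decoy_triplets = sorted(decoys)

    pred_rows = ([(l, m) for l, m, _ in truth.sponge_triplets]
                 + [(l, m) for l, m, _ in truth.decoy_triplets])
    val_rows = ([(m, r) for _, m, r in truth.sponge_triplets]
                + [(m, r) for _, m, r in truth.decoy_triplets])
    tables = {
        "predicted": InteractionTable(
            pairs=pd.DataFrame(pred_rows, columns=["source_id", "target_id"]),
            evidence="predicted", origin="synthetic lncRNA->miRNA"),
        "validated": InteractionTable(
            pairs=pd.DataFrame(val_rows, columns=["source_id", "target_id"]),
            evidence="validated", origin="synthetic miRNA->mRNA"),
    }
    return matrices, tables


def simulate_counts(truth: GroundTruth,
                    annotations: dict[str, list[GeneAnnotation]],
                    n_tumor: int = 19, n_control: int = 9,
                    seed: int = 7, mean_depth: float = 1e6,
                    ) -> ExpressionMatrix:
    """Negative-binomial-free count mode for the size-factor operation.

    Counts are Poisson around depth-scaled linear expression so that
    per-sample depth differences are exactly what median-of-ratios corrects.
    """
    matrices, _ = simulate_expression(
        truth, annotations, n_tumor=n_tumor, n_control=n_control, seed=seed)
    m = matrices["mrna"]
    rng = np.random.default_rng(seed + _SEED_OFFSETS["mrna"] + 100)
    linear = 2.0 ** m.values.to_numpy()
    depth = rng.uniform(0.5, 2.0, linear.shape[1])
    lam = linear / linear.sum(axis=0, keepdims=True) * mean_depth * depth
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(
        values=pd.DataFrame(counts, index=m.values.index,
                            columns=m.values.columns),
        group_labels=m.group_labels, scale="linear_count")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def simulate_survival(truth: GroundTruth, lnc_expr: ExpressionMatrix,
                      censor_frac: float = 0.3, seed: int = 7,
                      signature_size: int = 5, coefficient: float = 0.5,
                      base_median_months: float = 12.0,
                      ) -> list[SurvivalRecord]:
    """Proportional-hazards survival for the tumor samples.

    Event times are exponential with per-sample rate proportional to
    ``exp(sum_f coef_f * (x_f - mean_f))`` over a planted signature of
    ``signature_size`` intergenic lncRNAs (one protective, negative
    coefficient; the rest risky at ``+coefficient``).  Censoring is an
    independent exponential clock calibrated so the expected censored
    fraction is ``censor_frac``; covariates (age and the three binary
    markers) are generated independent of the score.
    """
    if not (0 <= censor_frac < 1):
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed + _SEED_OFFSETS["survival"])
    tumors = lnc_expr.tumor_samples

    if not truth.survival_signature:
        eligible = [fid for fid in lnc_expr.feature_ids
                    if truth.subtype_of.get(fid) == "intergenic"]
        chosen = eligible[:signature_size]
        if len(chosen) < signature_size:
            raise ValueError("not enough intergenic lncRNAs for the signature")
        coefs = {fid: coefficient for fid in chosen}
        coefs[chosen[-1]] = -coefficient      # one protective feature
        truth.survival_signature = coefs

    Xs = lnc_expr.values.loc[list(truth.survival_signature), tumors]
    centred = Xs.sub(Xs.mean(axis=1), axis=0)
    lp = np.array([truth.survival_signature[f] for f in Xs.index]) @ \
        centred.to_numpy()
    base_rate = np.log(2.0) / base_median_months
    rates = base_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    if censor_frac > 0:
        # independent exponential censoring clock; its rate is solved so the
        # expected censored fraction E[mu/(lambda_i + mu)] hits censor_frac
        from scipy.optimize import brentq

        def expected_censored(mu: float) -> float:
            return float(np.mean(mu / (rates + mu)))

        lo, hi = rates.min() * 1e-6, rates.max() * 1e6
        censor_rate = brentq(lambda mu: expected_censored(mu) - censor_frac,
                             lo, hi)
        t_censor = rng.exponential(1.0 / censor_rate, size=len(tumors))
    else:
        t_censor = np.full(len(tumors), np.inf)
    times = np.minimum(t_event, t_censor)
    events = (t_event <= t_censor).astype(int)

    records = []
    for i, sid in enumerate(tumors):
        records.append(SurvivalRecord(
            sample_id=sid, time=float(max(times[i], 1e-3)),
            event=int(events[i]),
            covariates={"age": float(rng.normal(55.0, 10.0)),
                        "g_cimp": float(rng.random() < 0.1),
                        "idh1": float(rng.random() < 0.1),
                        "mgmt": float(rng.random() < 0.4)}))
    return records


# ---------------------------------------------------------------------------
# Dataset assembly / file emission
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    annotations: dict[str, list[GeneAnnotation]]
    matrices: dict[str, ExpressionMatrix]
    tables: dict[str, InteractionTable]
    survival: list[SurvivalRecord]
    truth: GroundTruth


def simulate_dataset(n_mrna: int = 80, n_lnc: int = 120, n_mirna: int = 40,
                     n_tumor: int = 19, n_control: int = 9,
                     effect_log2fc: float = 2.0, rho_cis: float = 0.9,
                     beta_sponge: float = 0.8, n_sponge: int = 20,
                     n_decoys: int = 500, censor_frac: float = 0.3,
                     seed: int = 7) -> Dataset:
    """All pipeline inputs with ground truth, in one call."""
    annotations, truth = simulate_annotation(n_mrna, n_lnc, n_mirna, seed=seed)
    matrices, tables = simulate_expression(
        truth, annotations, n_tumor=n_tumor, n_control=n_control,
        effect_log2fc=effect_log2fc, rho_cis=rho_cis,
        beta_sponge=beta_sponge, n_sponge=n_sponge, n_decoys=n_decoys,
        seed=seed)
    survival = simulate_survival(truth, matrices["lnc"],
                                 censor_frac=censor_frac, seed=seed)
    return Dataset(annotations=annotations, matrices=matrices, tables=tables,
                   survival=survival, truth=truth)


def write_dataset(ds: Dataset, outdir: str | Path) -> dict[str, str]:
    """Emit every input file (GTF, BED6, TSVs, ground-truth JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_annotation_gtf(ds.annotations["mrna"] + ds.annotations["lnc"],
                         out / "annotation.gtf")
    paths["annotation"] = str(out / "annotation.gtf")
    write_mirna_bed(ds.annotations["mirna"], out / "mirna.bed")
    paths["mirna_bed"] = str(out / "mirna.bed")
    for cls, m in ds.matrices.items():
        write_expression(m, out / f"{cls}_expr.tsv",
                         sample_sheet=out / "samples.tsv")
        paths[f"{cls}_expr"] = str(out / f"{cls}_expr.tsv")
    paths["samples"] = str(out / "samples.tsv")
    for name, t in ds.tables.items():
        t.pairs.to_csv(out / f"{name}_interactions.tsv", sep="\t", index=False)
        paths[name] = str(out / f"{name}_interactions.tsv")
    write_survival(ds.survival, out / "survival.tsv")
    paths["survival"] = str(out / "survival.tsv")
    ds.truth.to_json(out / "ground_truth.json")
    paths["truth"] = str(out / "ground_truth.json")
    return paths
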