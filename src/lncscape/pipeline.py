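"""End-to-end orchestration.

Stage order: normalization -> differential expression -> positional subtype
classification (+ exon-sense-overlap removal) -> cis/trans co-expression
networks -> miRNA host mapping -> sponge-module inference -> survival
signature.  Each stage's outputs are written before the next begins and the
whole run is summarised in a machine-readable JSON (per-stage input/output
counts, thresholds, seed, version, timestamps).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .coexpression import build_network
from .de import de_directions, de_table, differential_expression, flag_filter, \
    quantile_normalize
from .hosts import filter_concordant, intersect_hosts
from .io import (ExpressionMatrix, GeneAnnotation, InteractionTable,
                 SurvivalRecord, write_edge_list, write_modules, write_pairs)
from .sponge import (Attrition, candidate_lnc_mir, candidate_mir_mrna,
                     filter_modules, merge_modules, module_gene_set)
from .subtypes import (apply_exon_overlap_removal, classify_all,
                       subtype_summary, surviving_ids)
from .survival import (cox_table, eligibility_filter, multivariate_cox,
                       risk_score, screen_features, select_top,
                       stratify_and_test)

log = logging.getLogger("lncscape")


class RunSummary(dict):
    """stage -> {n_in, n_out, thresholds} plus run metadata."""

    def add_stage(self, name: str, n_in: int, n_out: int,
                  thresholds: dict | None = None, **extra) -> None:
        if n_in < 0 or n_out < 0:
            raise ValueError("stage counts must be non-negative")
        self.setdefault("stages", {})[name] = {
            "n_in": n_in, "n_out": n_out,
            "thresholds": thresholds or {}, **extra}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=1, sort_keys=True)


def run_all(annotations: dict[str, list[GeneAnnotation]],
            matrices: dict[str, ExpressionMatrix],
            tables: dict[str, InteractionTable],
            survival: list[SurvivalRecord],
            cfg: PipelineConfig | None = None,
            outdir: str | Path = "results",
            timestamps: bool = True) -> RunSummary:
    """Execute every stage in order, writing outputs under ``outdir``.

    ``timestamps=False`` omits wall-clock fields so summaries of repeated
    runs with the same seed/config compare equal.
    """
    if cfg is None:
        cfg = PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()
    summary["seed"] = cfg.rng_seed
    summary["version"] = __version__
    summary["config"] = cfg.to_dict()
    if timestamps:
        summary["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    ann_index = {g.gene_id: g for cls in annotations.values() for g in cls}

    # 1. normalization (+ optional detection-flag filter)
    log.info("normalizing expression matrices")
    norm: dict[str, ExpressionMatrix] = {}
    for cls, m in matrices.items():
        n_in = len(m.feature_ids)
        # log2 matrices are taken as already normalised upstream (the usual
        # array-processing convention); re-quantile-normalisation is opt-in
        if m.scale == "log2" and cfg.quantile_normalize:
            m = quantile_normalize(m)
        if m.flags is not None:
            m = flag_filter(m, cfg.flag_min_present)
        norm[cls] = m
        summary.add_stage(f"normalize_{cls}", n_in, len(m.feature_ids),
                          {"flag_min_present": cfg.flag_min_present})

    # 2. differential expression per feature class
    log.info("differential expression")
    de, de_dirs = {}, {}
    stage_thresholds = {"lnc": cfg.de_lnc, "mrna": cfg.de_mrna,
                        "mirna": cfg.de_mirna}
    for cls, m in norm.items():
        thr = stage_thresholds.get(cls, cfg.de_lnc)
        de[cls] = differential_expression(m, thresholds=thr, cfg=cfg)
        de_dirs[cls] = de_directions(de[cls])
        de_table(de[cls]).to_csv(out / f"de_{cls}.tsv", sep="\t")
        n_called = sum(1 for r in de[cls] if r.direction != "unchanged")
        summary.add_stage(f"de_{cls}", len(de[cls]), n_called,
                          {"fc": thr.fc, "p": thr.p, "use_fdr": thr.use_fdr})

    de_lnc_called = {f: d for f, d in de_dirs["lnc"].items()
                     if d != "unchanged"}
    de_mrna_called = {f: d for f, d in de_dirs["mrna"].items()
                      if d != "unchanged"}

    # 3. subtype classification + exon-sense-overlap removal
    log.info("positional subtype classification")
    de_lnc_ann = [ann_index[f] for f in de_lnc_called if f in ann_index]
    calls = classify_all(de_lnc_ann, annotations["mrna"], cfg)
    calls = apply_exon_overlap_removal(calls, de_lnc_ann, annotations["mrna"])
    kept = set(surviving_ids(calls))
    subtype_of = {c.lncrna_id: c.subtype for c in calls}
    with open(out / "subtypes.tsv", "w") as fh:
        fh.write("lncrna_id\tsubtype\tpartner_gene_id\tremoved_by_exon_rule\n")
        for c in calls:
            fh.write(f"{c.lncrna_id}\t{c.subtype}\t{c.partner_gene_id or ''}"
                     f"\t{int(c.removed_by_exon_rule)}\n")
    summary.add_stage("subtypes", len(calls), len(kept),
                      summary_counts={s: n for s, (n, _)
                                      in subtype_summary(calls).items()}
                      if calls else {})
    de_lnc_kept = {f: d for f, d in de_lnc_called.items() if f in kept}

    # 4. co-expression networks
    log.info("co-expression networks")
    pairs_lm, stats_lm = build_network(
        de_lnc_kept, de_mrna_called, norm["lnc"], norm["mrna"], ann_index,
        cfg, pair_kind="lnc_mrna")
    write_pairs(pairs_lm, out / "pairs_lnc_mrna.tsv")
    write_edge_list(pairs_lm, out / "edges_lnc_mrna.tsv")
    summary.add_stage("coexpression_lnc_mrna", stats_lm.enumerated,
                      len(pairs_lm),
                      {"corr_p": cfg.corr_p_threshold,
                       "trans_abs_rho": cfg.trans_abs_rho_threshold},
                      cis_enumerated=stats_lm.cis_enumerated,
                      trans_enumerated=stats_lm.trans_enumerated)
    pairs_ll, stats_ll = build_network(
        de_lnc_kept, de_lnc_kept, norm["lnc"], norm["lnc"], ann_index,
        cfg, pair_kind="lnc_lnc")
    write_pairs(pairs_ll, out / "pairs_lnc_lnc.tsv")
    summary.add_stage("coexpression_lnc_lnc", stats_ll.enumerated,
                      len(pairs_ll),
                      {"corr_p": cfg.corr_p_threshold,
                       "trans_abs_rho": cfg.trans_abs_rho_threshold},
                      self_pairs_removed=stats_ll.self_pairs_removed)

    # 5. miRNA hosts
    log.info("miRNA host mapping")
    host_all = intersect_hosts(de_lnc_ann, annotations["mirna"],
                               require_same_strand=cfg.require_host_same_strand)
    host_conc = filter_concordant(host_all, de_dirs["lnc"], de_dirs["mirna"],
                                  norm["lnc"], norm["mirna"])
    with open(out / "hosts.tsv", "w") as fh:
        fh.write("lncrna_id\tmirna_id\tlnc_direction\tmir_direction\t"
                 "rho\tcorr_p\n")
        for p in host_conc:
            fh.write(f"{p.lncrna_id}\t{p.mirna_id}\t{p.lnc_direction}\t"
                     f"{p.mir_direction}\t{'' if p.rho is None else p.rho:.4g}"
                     f"\t{'' if p.corr_p is None else p.corr_p:.4g}\n")
    summary.add_stage("mirna_hosts", len(host_all), len(host_conc))

    # 6. sponge modules
    log.info("sponge-module inference")
    attr = Attrition()
    sponge_de_lnc = {r.feature_id for r in de[ "lnc"]
                     if r.direction != "unchanged"
                     and 2 ** abs(r.log2_fc) >= cfg.de_sponge_lnc.fc
                     and (r.fdr if cfg.de_sponge_lnc.use_fdr else r.p_value)
                     < cfg.de_sponge_lnc.p}
    lm = candidate_lnc_mir(sponge_de_lnc, tables["predicted"], norm["lnc"],
                           norm["mirna"], cfg, attrition=attr)
    mm = candidate_mir_mrna({m for _, m, *_ in lm}, tables["validated"],
                            norm["mirna"], norm["mrna"], cfg, attrition=attr)
    triplets = merge_modules(lm, mm)
    all_dirs = {**de_dirs["lnc"], **de_dirs["mirna"], **de_dirs["mrna"]}
    modules = filter_modules(triplets, all_dirs, norm["lnc"], norm["mrna"],
                             cfg, attrition=attr)
    write_modules(modules, out / "sponge_modules.tsv")
    with open(out / "sponge_attrition.json", "w") as fh:
        json.dump(attr.as_dict(), fh, indent=1)
    with open(out / "sponge_gene_set.txt", "w") as fh:
        fh.write("\n".join(module_gene_set(modules)) + "\n")
    summary.add_stage("sponge", attr.raw_triplets, len(modules),
                      {"corr_p": cfg.corr_p_threshold,
                       "abundance_p": cfg.abundance_test_p},
                      attrition=attr.as_dict())

    # 7. survival signature
    log.info("survival signature")
    eligible = eligibility_filter(norm["lnc"], subtype_of, cfg)
    screened = screen_features(norm["lnc"], survival, eligible)
    top = select_top(screened, cfg.signature_size)
    scores = risk_score(top, norm["lnc"],
                        samples=[r.sample_id for r in survival])
    strat = stratify_and_test(scores, survival)
    multi = multivariate_cox(scores, survival)
    cox_table(top).to_csv(out / "signature_cox.tsv", sep="\t")
    with open(out / "risk_scores.tsv", "w") as fh:
        fh.write("sample_id\tscore\tgroup\n")
        for s in scores:
            fh.write(f"{s.sample_id}\t{s.score:.6g}\t{s.group}\n")
    cox_table(multi).to_csv(out / "multivariate_cox.tsv", sep="\t")
    summary.add_stage("survival", len(eligible), len(top),
                      {"presence_fraction": cfg.expression_presence_fraction,
                       "k": cfg.signature_size},
                      logrank_p=strat.logrank_p,
                      median_survival=strat.median_survival)

    if timestamps:
        summary["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    summary.write(out / "run_summary.json")
    return summary
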