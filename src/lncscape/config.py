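"""Pipeline-wide configuration.

A single :class:`PipelineConfig` carries every threshold used across the
stages, with the glioblastoma study defaults.  Stages that use distinct
fold-change / significance cut-offs (the microarray DE list, the mRNA DE
list, the RNA-Seq sponge input) each read their own threshold block.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass(frozen=True)
class DEThresholds:
    """Fold-change / significance block for one differential-expression stage.

    ``fc`` is on the linear scale (e.g. 1.5 means 2**|log2FC| >= 1.5);
    ``use_fdr`` selects BH-adjusted FDR instead of the raw p-value for the
    significance test.
    """

    fc: float = 1.5
    p: float = 0.05
    use_fdr: bool = False

    def __post_init__(self) -> None:
        if self.fc <= 0 or not (0 < self.p <= 1):
            raise ValueError(f"invalid DE thresholds: fc={self.fc}, p={self.p}")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the pipeline.

    Defaults reproduce the study conditions: a +/-500 kb cis window around the
    lncRNA span, a 1 kb TSS window for bidirectional calls, stage-specific DE
    thresholds, raw p < 0.05 for correlation pairs with |rho| > 0.9 added for
    trans pairs, detectability in >= 30% of samples for survival screening,
    and p < 0.05 for the lncRNA-vs-mRNA abundance test of sponge modules.
    """

    cis_window: int = 500_000          # bp, inclusive on both flanks
    bidirectional_tss_window: int = 1_000  # bp, inclusive
    # stage-specific DE thresholds
    de_lnc: DEThresholds = field(default_factory=lambda: DEThresholds(fc=1.5, p=0.05))
    de_mrna: DEThresholds = field(default_factory=lambda: DEThresholds(fc=2.0, p=0.05))
    de_mirna: DEThresholds = field(default_factory=lambda: DEThresholds(fc=1.5, p=0.05))
    de_sponge_lnc: DEThresholds = field(
        default_factory=lambda: DEThresholds(fc=1.5, p=0.05, use_fdr=True)
    )
    corr_p_threshold: float = 0.05
    trans_abs_rho_threshold: float = 0.9
    expression_presence_fraction: float = 0.30
    abundance_test_p: float = 0.05
    flag_min_present: int = 7          # "at least 7 out of 28 samples"
    quantile_normalize: bool = False   # re-normalize log2 input matrices
    welch: bool = True                 # Welch t-test; False = pooled variance
    require_host_same_strand: bool = True
    sponge_require_corr_p: bool = True  # sign + p for sponge correlations
    abundance_test: str = "wilcoxon"   # or "ttest" (paired)
    signature_size: int = 5            # top-k lncRNAs for the risk score
    tumor_only_correlation: bool = True
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.cis_window < 0 or self.bidirectional_tss_window < 0:
            raise ValueError("window sizes must be >= 0")
        for name in ("corr_p_threshold", "abundance_test_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.expression_presence_fraction <= 1):
            raise ValueError("expression_presence_fraction must be in (0, 1]")
        if self.trans_abs_rho_threshold < 0 or self.trans_abs_rho_threshold > 1:
            raise ValueError("trans_abs_rho_threshold must be in [0, 1]")
        if self.abundance_test not in ("wilcoxon", "ttest"):
            raise ValueError("abundance_test must be 'wilcoxon' or 'ttest'")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key in ("de_lnc", "de_mrna", "de_mirna", "de_sponge_lnc"):
            if key in d and isinstance(d[key], dict):
                d[key] = DEThresholds(**d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(payload)
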