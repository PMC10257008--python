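"""Configuration objects for the simulation and analysis pipeline.

Two frozen dataclasses hold every tunable: :class:`SimulationConfig` defines
the synthetic data-generating process (LD-block genotypes, an eQTL/disease
architecture, an expression-GWAS cohort and a case-control study) and
:class:`PipelineConfig` holds the analysis thresholds (p-value filters, the
positional clumping gap, cis/cis-x/trans distance cut-offs, the HLA exclusion
window, and the core-gene selection criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds.

    Defaults follow the published analysis: summary statistics are retained at
    p < 1e-5, a clump must contain a lead SNP at p < 1e-6 and be separated
    from other clumps by at least 1 Mb; a locus is *cis* within 50 kb of the
    transcription site, *cis-x* from 50 kb to 5 Mb and *trans* beyond 5 Mb;
    the HLA region (chr6:25-34 Mb) is excluded from trans aggregation; core
    genes require effective eQTL number > 5 at p < 1e-9, or membership of the
    monogenic-diabetes list at p < 1e-6.
    """

    p_retain: float = 1e-5
    p_lead: float = 1e-6
    clump_gap_bp: int = 1_000_000
    cis_max_bp: int = 50_000
    cisx_max_bp: int = 5_000_000
    hla_chrom: str = "6"
    hla_start_bp: int = 25_000_000
    hla_end_bp: int = 34_000_000
    known_hit_window_bp: int = 200_000
    p_core: float = 1e-9
    p_core_monogenic: float = 1e-6
    p_cis_report: float = 1e-3
    diversity_min: float = 5.0
    r2_high: float = 0.7
    master_regulator_min_scores: int = 2
    ridge_lambda: float = 1e-3

    def __post_init__(self) -> None:
        if not self.p_lead <= self.p_retain:
            raise ConfigurationError("p_lead must be <= p_retain")
        if not self.cis_max_bp < self.cisx_max_bp:
            raise ConfigurationError("cis_max_bp must be < cisx_max_bp")
        if not self.hla_start_bp < self.hla_end_bp:
            raise ConfigurationError("hla_start_bp must be < hla_end_bp")
        if self.clump_gap_bp <= 0:
            raise ConfigurationError("clump_gap_bp must be positive")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    Genotypes are organised in unlinked LD blocks (within-block dosage
    correlation ``block_correlation``, zero across blocks).  Expression of
    each gene is controlled by one cis block plus ``trans_eqtls_per_gene``
    unlinked trans blocks; 70% of expression heritability is attributed to
    trans variants by default.  Disease liability is logistic in the genetic
    expression values of the core genes plus a direct effect of the "HLA"
    blocks, which are also a trans-eQTL hotspot for every gene -- the
    confounding that motivates HLA exclusion.  Only ``tested_snp_fraction``
    of SNPs are reported in trans summary statistics, emulating a GWAS of
    expression that tested a restricted trait-associated SNP set in trans.
    """

    seed: int = 0
    n_reference: int = 2_000
    n_cases: int = 2_000
    n_controls: int = 2_000
    n_gwas: int = 10_000
    n_blocks: int = 120
    snps_per_block: int = 4
    block_correlation: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genes: int = 14
    n_core_genes: int = 4
    n_hla_driven_genes: int = 2
    trans_eqtls_per_gene: int = 12
    trans_heritability_fraction: float = 0.7
    expression_heritability: float = 0.3
    cis_effect_sd: float | None = None
    trans_effect_sd: float = 0.1
    liability_effect_sd: float = 1.9
    hla_liability_effect: float = 0.8
    liability_noise_sd: float = 0.5
    baseline_log_odds: float = -2.2
    tested_snp_fraction: float = 0.9
    hla_block_ids: tuple[int, ...] = (0, 1)
    snp_spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        for name in ("n_reference", "n_cases", "n_controls", "n_gwas",
                     "n_blocks", "snps_per_block", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_core_genes > self.n_genes:
            raise ConfigurationError("n_core_genes must be <= n_genes")
        if self.n_core_genes + self.n_hla_driven_genes > self.n_genes:
            raise ConfigurationError(
                "n_core_genes + n_hla_driven_genes must be <= n_genes")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf bounds must lie in (0, 0.5]")
        if not 0.0 <= self.trans_heritability_fraction <= 1.0:
            raise ConfigurationError("trans_heritability_fraction in [0,1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigurationError("block_correlation in [0,1)")
        if not 0.0 < self.expression_heritability < 1.0:
            raise ConfigurationError("expression_heritability in (0,1)")
        if not 0.0 <= self.tested_snp_fraction <= 1.0:
            raise ConfigurationError("tested_snp_fraction in [0,1]")
        if any(b < 0 or b >= self.n_blocks for b in self.hla_block_ids):
            raise ConfigurationError("hla_block_ids out of range")

    def asdict(self) -> dict:
        return asdict(self)
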