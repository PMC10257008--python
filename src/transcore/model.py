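"""scikit-learn style estimators wrapping the score pipeline.

:class:`TransScorer` is a transformer: ``fit`` learns clumps and LD-adjusted
weights from expression-GWAS summary statistics plus a reference panel, and
``transform`` turns study genotypes into standardized genome-wide trans-scores
(one column per target gene).  :class:`LogisticScoreAssociation` fits the
covariate-adjusted logistic association of each score with a binary outcome,
:class:`HLARiskScorer` learns the tag-SNP HLA summary risk score, and
:class:`CoreGeneSelector` applies the core-gene selection criteria.  All
compose with sklearn model selection via ``get_params``/``set_params``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import association as assoc
from . import selection as sel
from .config import PipelineConfig
from .ld import LocusSkipped, adjust_weights, compute_ld
from .scores import (GenomeWideTransScore, LocusScore, aggregate_trans,
                     build_cis_scores, locus_score)
from .simulate import GenotypeMatrix
from .sumstats import (GeneAnnotation, annotation_index, classify_clumps,
                       clump_all, harmonize_alleles, validate_sumstats)

logger = logging.getLogger("transcore")


def _as_annotation(annotation) -> dict[str, GeneAnnotation]:
    if isinstance(annotation, dict):
        return annotation
    return annotation_index(annotation)


class TransScorer(BaseEstimator, TransformerMixin):
    """Genome-wide trans-score transformer.

    Parameters mirror the analysis thresholds; see
    :class:`~transcore.config.PipelineConfig`.  ``exclude_hla=False`` keeps
    HLA-region loci in the aggregation and exists only to demonstrate the
    confounding that the exclusion controls.

    Attributes (after fit): ``clumps_`` maps target to its classified clumps,
    ``weights_`` maps clump id to its LD-adjusted weights, ``skipped_`` lists
    loci that could not be scored.  ``transform`` additionally records
    ``trans_scores_`` (target -> GenomeWideTransScore with provenance and
    effective eQTL number) for the most recent study, since standardization
    and the Hill number are defined in the analysis sample.
    """

    def __init__(self, p_retain: float = 1e-5, p_lead: float = 1e-6,
                 clump_gap_bp: int = 1_000_000, cis_max_bp: int = 50_000,
                 cisx_max_bp: int = 5_000_000, hla_chrom: str = "6",
                 hla_start_bp: int = 25_000_000, hla_end_bp: int = 34_000_000,
                 ridge_lambda: float = 1e-3, exclude_hla: bool = True,
                 harmonize: bool = True):
        self.p_retain = p_retain
        self.p_lead = p_lead
        self.clump_gap_bp = clump_gap_bp
        self.cis_max_bp = cis_max_bp
        self.cisx_max_bp = cisx_max_bp
        self.hla_chrom = hla_chrom
        self.hla_start_bp = hla_start_bp
        self.hla_end_bp = hla_end_bp
        self.ridge_lambda = ridge_lambda
        self.exclude_hla = exclude_hla
        self.harmonize = harmonize

    def config(self) -> PipelineConfig:
        return PipelineConfig(
            p_retain=self.p_retain, p_lead=self.p_lead,
            clump_gap_bp=self.clump_gap_bp, cis_max_bp=self.cis_max_bp,
            cisx_max_bp=self.cisx_max_bp, hla_chrom=self.hla_chrom,
            hla_start_bp=self.hla_start_bp, hla_end_bp=self.hla_end_bp,
            ridge_lambda=self.ridge_lambda)

    def fit(self, sumstats: pd.DataFrame, y=None, *, annotation,
            panel: GenotypeMatrix):
        """Clump the summary statistics and learn LD-adjusted locus weights."""
        config = self.config()
        records = validate_sumstats(sumstats)
        if self.harmonize:
            records = harmonize_alleles(records, panel.variants)
        ann = _as_annotation(annotation)
        self.clumps_ = {}
        self.weights_ = {}
        self.skipped_ = []
        for target, clumps in clump_all(records, config).items():
            clumps = classify_clumps(clumps, ann, config)
            kept = []
            for clump in clumps:
                try:
                    ld = compute_ld(panel, clump)
                    members = clump.members.set_index("variant_id")
                    beta = members.loc[ld.variant_ids, "beta"].to_numpy()
                    pval = members.loc[ld.variant_ids, "pvalue"].to_numpy()
                    self.weights_[clump.clump_id] = adjust_weights(
                        beta, ld, ridge_lambda=self.ridge_lambda,
                        pvalues=pval)
                    kept.append(clump)
                except LocusSkipped as err:
                    logger.warning("skipping locus %s: %s", clump.clump_id, err)
                    self.skipped_.append(clump.clump_id)
            self.clumps_[target] = kept
        self.n_loci_ = sum(len(v) for v in self.clumps_.values())
        return self

    def locus_scores(self, study: GenotypeMatrix) -> list[LocusScore]:
        check_is_fitted(self, "clumps_")
        out = []
        for clumps in self.clumps_.values():
            for clump in clumps:
                try:
                    out.append(locus_score(study,
                                           self.weights_[clump.clump_id],
                                           clump))
                except LocusSkipped as err:
                    logger.warning("study scoring skipped %s: %s",
                                   clump.clump_id, err)
        return out

    def transform(self, study: GenotypeMatrix) -> pd.DataFrame:
        """Standardized genome-wide trans-scores, one column per target."""
        check_is_fitted(self, "clumps_")
        config = self.config()
        by_target: dict[str, list[LocusScore]] = {}
        for s in self.locus_scores(study):
            by_target.setdefault(s.target_id, []).append(s)
        self.trans_scores_: dict[str, GenomeWideTransScore] = {}
        cols = {}
        for target in sorted(by_target):
            score = aggregate_trans(by_target[target], config,
                                    apply_hla_exclusion=self.exclude_hla)
            if score is not None:
                self.trans_scores_[target] = score
                cols[target] = score.values
        index = (study.samples["sample_id"].to_numpy()
                 if "sample_id" in study.samples else None)
        return pd.DataFrame(cols, index=index)

    def cis_scores(self, study: GenotypeMatrix) -> dict[str, list[LocusScore]]:
        """Individually standardized cis and cis-x locus scores."""
        return build_cis_scores(self.locus_scores(study))

    def effective_n(self) -> pd.Series:
        check_is_fitted(self, "trans_scores_")
        return pd.Series({t: s.effective_n
                          for t, s in self.trans_scores_.items()},
                         name="effective_n")


class LogisticScoreAssociation(BaseEstimator):
    """Per-score covariate-adjusted logistic association.

    Each column of X is standardized to unit SD (unless already) and tested
    one score at a time, the design used in score-based association testing.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y, covariates=None):
        results = []
        for name in X.columns:
            score = X[name].to_numpy(dtype=float)
            if self.standardize:
                sd = score.std(ddof=1)
                if sd > 0:
                    score = score / sd
            results.append(assoc.fit_score_association(
                score, y, covariates, score_id=str(name)))
        self.results_ = results
        self.results_table_ = sel.associations_table(results)
        return self

    def result_for(self, score_id: str) -> assoc.AssociationResult:
        check_is_fitted(self, "results_")
        for r in self.results_:
            if r.score_id == score_id:
                return r
        raise KeyError(score_id)


class HLARiskScorer(BaseEstimator, TransformerMixin):
    """HLA summary risk score learned from five tag-SNP dosages."""

    def fit(self, X, y):
        self.model_ = assoc.build_hla_score(np.asarray(X, dtype=float), y)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        derived = assoc.derive_hla_variables(np.asarray(X, dtype=float))
        return derived.to_numpy() @ self.model_.weights.to_numpy()


class CoreGeneSelector(BaseEstimator):
    """Apply the diversity and monogenic core-gene criteria."""

    def __init__(self, diversity_min: float = 5.0, p_core: float = 1e-9,
                 p_core_monogenic: float = 1e-6, p_cis_report: float = 1e-3,
                 master_regulator_min_scores: int = 2):
        self.diversity_min = diversity_min
        self.p_core = p_core
        self.p_core_monogenic = p_core_monogenic
        self.p_cis_report = p_cis_report
        self.master_regulator_min_scores = master_regulator_min_scores

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            diversity_min=self.diversity_min, p_core=self.p_core,
            p_core_monogenic=self.p_core_monogenic,
            p_cis_report=self.p_cis_report,
            master_regulator_min_scores=self.master_regulator_min_scores)

    def fit(self, associations, y=None, *, trans_scores,
            monogenic=(), cis_associations=None, known_labels=None):
        config = self._config()
        self.calls_ = sel.select_core_genes(
            list(associations), trans_scores, set(monogenic), config,
            cis_associations)
        self.regions_ = sel.identify_master_regulators(
            list(associations), trans_scores, config, known_labels)
        return self
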