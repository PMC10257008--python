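"""Locus-specific genotypic scores, genome-wide trans-score aggregation, and
the Hill-number effective count of contributing eQTLs.

The locus score of an individual is the dot product of their dosages with the
clump's LD-adjusted weights.  A gene's genome-wide trans-score is the plain
sum of its trans-class, non-HLA locus scores, divided by the sample standard
deviation so downstream log odds ratios are per 1 SD of score.  The Hill
number 2^(-sum p_i log2 p_i), with p_i the share of locus-score variance i,
measures how many unlinked eQTLs effectively contribute: 1 when a single
locus dominates, K when all K variances are equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .ld import LocusWeights
from .simulate import GenotypeMatrix
from .sumstats import CIS, CISX, TRANS, Clump

logger = logging.getLogger("transcore")


@dataclass
class LocusScore:
    """Per-individual score of one clump, with interval provenance."""

    clump_id: str
    target_id: str
    locus_class: str
    chrom: str
    start: int
    end: int
    values: np.ndarray

    @property
    def variance(self) -> float:
        return float(np.var(self.values, ddof=1))

    def overlaps_hla(self, config: PipelineConfig) -> bool:
        return (self.chrom == config.hla_chrom
                and self.start <= config.hla_end_bp
                and config.hla_start_bp <= self.end)


@dataclass
class GenomeWideTransScore:
    """Standardized sum of a target's non-HLA trans locus scores."""

    target_id: str
    contributing: list[LocusScore]
    values: np.ndarray
    effective_n: float

    def __post_init__(self) -> None:
        sd = float(np.std(self.values, ddof=1))
        if abs(sd - 1.0) > 1e-9:
            raise ValueError(f"trans-score for {self.target_id} not unit SD")
        k = len(self.contributing)
        if not (1.0 - 1e-9 <= self.effective_n <= k + 1e-9):
            raise ValueError("effective_n outside [1, K]")
        if any(s.locus_class != TRANS for s in self.contributing):
            raise ValueError("contributing loci must all be trans-class")


def hill_diversity(variances) -> float:
    """Effective number of loci: 2 to the Shannon entropy of variance shares."""
    v = np.asarray(variances, dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("variances must be non-negative and non-empty")
    total = v.sum()
    if total <= 0:
        raise ValueError("at least one variance must be positive")
    p = v / total
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log2(nz))
    return float(2.0 ** entropy)


def locus_score(study: GenotypeMatrix, weights: LocusWeights,
                clump: Clump) -> LocusScore:
    """Dot product of study dosages with the clump's adjusted weights.

    Weight variants absent from the study genotypes are dropped with a
    warning (none present raises); missing dosages are mean-imputed.
    """
    study_ids = {v: i for i, v in enumerate(study.variants["variant_id"])}
    pairs = [(v, w) for v, w in zip(weights.variant_ids,
                                    weights.adjusted_weights)
             if v in study_ids]
    if not pairs:
        from .ld import LocusSkipped
        raise LocusSkipped(f"clump {clump.clump_id}: no weight variants in "
                           "study genotypes")
    if len(pairs) < len(weights.variant_ids):
        logger.warning("clump %s: %d weight variants missing from study",
                       clump.clump_id,
                       len(weights.variant_ids) - len(pairs))
    cols = [study_ids[v] for v, _ in pairs]
    w = np.array([wt for _, wt in pairs])
    x = study.dosages[:, cols].astype(float)
    if np.isnan(x).any():
        means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = means[idx[1]]
    return LocusScore(clump_id=clump.clump_id, target_id=clump.target_id,
                      locus_class=clump.locus_class, chrom=clump.chrom,
                      start=clump.start, end=clump.end, values=x @ w)


def aggregate_trans(locus_scores: list[LocusScore],
                    config: PipelineConfig,
                    apply_hla_exclusion: bool = True
                    ) -> GenomeWideTransScore | None:
    """Sum a target's trans locus scores and scale to unit SD.

    Loci overlapping the HLA region are excluded (unless disabled, which is
    only useful for demonstrating the confounding the exclusion controls).
    Returns None, with a log entry, when no locus contributes or the summed
    score has zero variance.
    """
    targets = {s.target_id for s in locus_scores}
    if len(targets) > 1:
        raise ValueError("aggregate_trans expects scores for one target")
    contributing = [s for s in locus_scores if s.locus_class == TRANS]
    if apply_hla_exclusion:
        contributing = [s for s in contributing if not s.overlaps_hla(config)]
    if not contributing:
        logger.info("no contributing trans loci for %s; no score emitted",
                    targets.pop() if targets else "?")
        return None
    total = np.sum([s.values for s in contributing], axis=0)
    sd = float(np.std(total, ddof=1))
    if sd == 0:
        logger.warning("zero-variance trans-score for %s; no score emitted",
                       contributing[0].target_id)
        return None
    effective_n = hill_diversity([s.variance for s in contributing])
    return GenomeWideTransScore(
        target_id=contributing[0].target_id, contributing=contributing,
        values=total / sd,
        effective_n=effective_n)


def standardize(values: np.ndarray) -> np.ndarray:
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant score")
    return values / sd


def build_cis_scores(locus_scores: list[LocusScore]
                     ) -> dict[str, list[LocusScore]]:
    """Split per-class and standardize cis and cis-x scores individually.

    cis-x loci are reported as their own class and never enter genome-wide
    trans aggregation.
    """
    out: dict[str, list[LocusScore]] = {CIS: [], CISX: []}
    for s in locus_scores:
        if s.locus_class not in (CIS, CISX):
            continue
        if np.std(s.values, ddof=1) == 0:
            logger.warning("constant %s score for clump %s skipped",
                           s.locus_class, s.clump_id)
            continue
        out[s.locus_class].append(LocusScore(
            clump_id=s.clump_id, target_id=s.target_id,
            locus_class=s.locus_class, chrom=s.chrom, start=s.start,
            end=s.end, values=standardize(s.values)))
    return out
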