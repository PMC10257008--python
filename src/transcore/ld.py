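"""Reference-panel LD extraction and conversion of marginal betas to joint
weights.

Premultiplying a clump's marginal regression coefficients by the inverse of
the reference-panel genotype correlation matrix approximates the coefficients
a multiple regression on the individual-level GWAS data would give.  Plain
inversion is numerically fragile for clumped SNPs, so near-duplicate variants
(|r| > 0.99) are pruned (keeping the smaller p-value) and a small ridge term
is added to the diagonal by default; set ``ridge_lambda=0`` for the exact
inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .simulate import GenotypeMatrix
from .sumstats import Clump

logger = logging.getLogger("transcore")

DUPLICATE_R = 0.99


class LocusSkipped(RuntimeError):
    """A locus that cannot be scored (no matchable variants, singular LD)."""


@dataclass
class LDMatrix:
    variant_ids: list[str]
    R: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        self.R = R


@dataclass
class LocusWeights:
    """Marginal betas and their LD-adjusted joint counterparts for one clump."""

    variant_ids: list[str]
    marginal_betas: np.ndarray
    adjusted_weights: np.ndarray
    ridge_lambda: float

    def __post_init__(self) -> None:
        if not (len(self.variant_ids) == len(self.marginal_betas)
                == len(self.adjusted_weights)):
            raise ValueError("weights vectors must match variant list")
        if not np.all(np.isfinite(self.adjusted_weights)):
            raise ValueError("adjusted weights must be finite")


def compute_ld(panel: GenotypeMatrix, clump: Clump) -> LDMatrix:
    """Pearson dosage correlations of the clump's variants in the panel.

    Variants missing from the panel (or monomorphic in it) are dropped with a
    warning; a clump with no matchable variant raises :class:`LocusSkipped`.
    Missing dosage entries are mean-imputed per variant.
    """
    panel_ids = {v: i for i, v in enumerate(panel.variants["variant_id"])}
    wanted = list(clump.members["variant_id"])
    present = [v for v in wanted if v in panel_ids]
    if len(present) < len(wanted):
        logger.warning("clump %s: %d of %d variants missing from LD panel",
                       clump.clump_id, len(wanted) - len(present), len(wanted))
    cols = [panel_ids[v] for v in present]
    x = panel.dosages[:, cols].astype(float).copy()
    if np.isnan(x).any():
        means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = means[idx[1]]
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("clump %s: dropping %d monomorphic panel variants",
                       clump.clump_id, int((~keep).sum()))
        present = [v for v, k in zip(present, keep) if k]
        x = x[:, keep]
    if not present:
        raise LocusSkipped(f"clump {clump.clump_id}: no matchable variants "
                           "in LD panel")
    R = np.corrcoef(x, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(variant_ids=present, R=R,
                    n_reference=panel.n_individuals)


def _prune_duplicates(ld: LDMatrix, pvalues: np.ndarray | None) -> np.ndarray:
    """Indices to keep after removing |r| > DUPLICATE_R partners.

    Of each near-duplicate pair the variant with the smaller p is kept (first
    listed when p-values are unavailable).
    """
    k = len(ld.variant_ids)
    order = np.argsort(pvalues, kind="mergesort") if pvalues is not None \
        else np.arange(k)
    keep: list[int] = []
    for i in order:
        if all(abs(ld.R[i, j]) <= DUPLICATE_R for j in keep):
            keep.append(int(i))
    return np.array(sorted(keep), dtype=int)


def adjust_weights(marginal_betas: np.ndarray, ld: LDMatrix,
                   ridge_lambda: float = 1e-3,
                   pvalues: np.ndarray | None = None) -> LocusWeights:
    """Solve (R + lambda I) w = beta_marginal for the joint weights."""
    beta = np.asarray(marginal_betas, dtype=float)
    if beta.shape[0] != len(ld.variant_ids):
        raise ValueError("marginal betas do not match LD matrix")
    keep = _prune_duplicates(ld, pvalues)
    if len(keep) < len(beta):
        logger.info("pruned %d near-duplicate variants before LD adjustment",
                    len(beta) - len(keep))
    R = ld.R[np.ix_(keep, keep)] + ridge_lambda * np.eye(len(keep))
    try:
        w = linalg.solve(R, beta[keep], assume_a="sym")
    except linalg.LinAlgError as err:
        raise LocusSkipped(f"LD matrix singular after pruning/ridging: {err}")
    if not np.all(np.isfinite(w)):
        raise LocusSkipped("LD adjustment produced non-finite weights")
    return LocusWeights(
        variant_ids=[ld.variant_ids[i] for i in keep],
        marginal_betas=beta[keep], adjusted_weights=w,
        ridge_lambda=ridge_lambda)
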