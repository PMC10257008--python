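"""Covariate-adjusted logistic association of scores (and single SNPs) with
disease, information for discrimination, the case-only HLA interaction test
and the control-group score-correlation check.

Scores are scaled to unit standard deviation before fitting, so the log odds
ratio is the change in log odds per 1 SD of score.  The information for
discrimination of a unit-SD score with standardized log odds ratio b is b^2/2
natural log units; on that scale a total of ln(lambda_s) corresponds to a
sibling recurrence risk ratio of lambda_s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PipelineConfig

logger = logging.getLogger("transcore")


@dataclass
class AssociationResult:
    score_id: str
    log_or: float
    se: float
    pvalue: float
    info_discrimination: float
    n_used: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not np.isclose(
                self.info_discrimination, self.log_or ** 2 / 2.0):
            raise ValueError("info_discrimination must equal log_or^2 / 2")


@dataclass
class InteractionResult:
    slope: float
    se: float
    pvalue: float
    n_cases: int


@dataclass
class HLARiskScore:
    """Summary risk score for the HLA region from five tag-SNP dosages.

    Eight per-individual variables are derived from the five tags -- the five
    dosages, two class-II haplotype-pair indicators (a compound-heterozygote
    and a homozygote indicator built from the first two tags) and one class-I
    composite (an indicator of carrying two or more risk alleles across the
    remaining three tags).  This derivation is a
    synthetic stand-in for published tag-SNP haplotype coding; the weights are
    learned by multiple logistic regression on the case-control study itself.
    """

    tag_genotypes: np.ndarray
    derived_variables: pd.DataFrame
    weights: pd.Series
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.derived_variables.shape[1] != 8:
            raise ValueError("exactly 8 derived variables are required")
        if not np.all(np.isfinite(self.weights.to_numpy())):
            raise ValueError("weights must be finite")


def information_for_discrimination(log_or: float) -> float:
    """Half the square of the standardized log odds ratio, in nats."""
    return log_or ** 2 / 2.0


def proportion_of_information(info: float, total_info: float,
                              fraction_outside_hla: float = 0.5) -> float:
    """Share of the non-HLA genetic information a score accounts for."""
    return info / (total_info * fraction_outside_hla)


def total_information_from_sibling_risk(lambda_s: float) -> float:
    """Total genetic information equivalent to a sibling recurrence ratio."""
    return float(np.log(lambda_s))


def _design(score: np.ndarray, covariates: pd.DataFrame | np.ndarray | None,
            n: int) -> np.ndarray:
    cols = [np.ones(n), np.asarray(score, dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def fit_score_association(score: np.ndarray, outcome: np.ndarray,
                          covariates=None,
                          score_id: str = "score") -> AssociationResult:
    """Maximum-likelihood logistic fit of outcome on one standardized score.

    Non-convergence or separation flags the result (converged=False) rather
    than reporting a silent estimate.
    """
    y = np.asarray(outcome, dtype=float)
    x = _design(score, covariates, len(y))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        logger.warning("%s: design matrix rank-deficient; flagged", score_id)
        return AssociationResult(score_id, np.nan, np.nan, np.nan, np.nan,
                                 len(y), converged=False)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
    except Exception as err:  # separation raises PerfectSeparationError
        logger.warning("%s: logistic fit failed (%s); flagged", score_id, err)
        return AssociationResult(score_id, np.nan, np.nan, np.nan, np.nan,
                                 len(y), converged=False)
    log_or, se = float(fit.params[1]), float(fit.bse[1])
    if not (converged and np.isfinite(log_or) and np.isfinite(se)
            and se < 1e3):
        logger.warning("%s: non-convergence or separation; flagged", score_id)
        return AssociationResult(score_id, log_or, se, np.nan, np.nan,
                                 len(y), converged=False)
    pvalue = float(2 * stats.norm.sf(abs(log_or / se)))
    pvalue = max(pvalue, np.nextafter(0, 1))
    return AssociationResult(score_id, log_or, se, pvalue,
                             information_for_discrimination(log_or), len(y))


def per_snp_association(study, outcome: np.ndarray, covariates=None,
                        maf_min: float = 0.005) -> pd.DataFrame:
    """Single-SNP logistic GWAS over the study genotypes.

    SNPs that are monomorphic or below the minor-allele-frequency floor are
    excluded.  Dosages are standardized so log odds ratios are per SD.
    """
    rows = []
    dosages = study.dosages
    for j, variant_id in enumerate(study.variants["variant_id"]):
        d = dosages[:, j].astype(float)
        freq = d.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            continue
        sd = d.std(ddof=1)
        if sd == 0:
            continue
        res = fit_score_association(d / sd, outcome, covariates,
                                    score_id=variant_id)
        rows.append({
            "variant_id": variant_id,
            "chrom": study.variants["chrom"].iloc[j],
            "pos": study.variants["pos"].iloc[j],
            "maf": maf, "log_or": res.log_or, "se": res.se,
            "pvalue": res.pvalue, "n_used": res.n_used,
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def derive_hla_variables(tag_genotypes: np.ndarray) -> pd.DataFrame:
    tags = np.asarray(tag_genotypes, dtype=float)
    if tags.ndim != 2 or tags.shape[1] != 5:
        raise ValueError("expected an n x 5 matrix of tag-SNP dosages")
    d = {f"tag{i + 1}": tags[:, i] for i in range(5)}
    d["classII_het_pair"] = ((tags[:, 0] == 1) & (tags[:, 1] == 1)).astype(float)
    d["classII_homozygote"] = ((tags[:, 0] == 2) | (tags[:, 1] == 2)).astype(float)
    d["classI_composite"] = (tags[:, 2:5].sum(axis=1) >= 2).astype(float)
    return pd.DataFrame(d)


def build_hla_score(tag_genotypes: np.ndarray,
                    outcome: np.ndarray) -> HLARiskScore:
    """Learn HLA risk-score weights by multiple logistic regression.

    Constant or collinear derived variables are dropped with a warning (their
    weight is reported as 0) and the model refitted on the remainder; the
    score is the fitted linear predictor without the intercept.
    """
    derived = derive_hla_variables(tag_genotypes)
    y = np.asarray(outcome, dtype=float)
    cols = list(derived.columns)
    dropped: list[str] = []
    for c in list(cols):
        if derived[c].std() == 0:
            cols.remove(c)
            dropped.append(c)
    x = derived[cols].to_numpy()
    while np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < len(cols) + 1:
        dropped.append(cols.pop())
        x = derived[cols].to_numpy()
    if dropped:
        logger.warning("HLA score: dropped degenerate variables %s", dropped)
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
    weights = pd.Series(0.0, index=derived.columns)
    weights[cols] = fit.params[1:]
    values = derived.to_numpy() @ weights.to_numpy()
    return HLARiskScore(tag_genotypes=np.asarray(tag_genotypes, dtype=float),
                        derived_variables=derived, weights=weights,
                        values=values)


def case_only_interaction(trans_score: np.ndarray, hla_score: np.ndarray,
                          case_mask: np.ndarray,
                          min_cases: int = 30) -> InteractionResult:
    """Case-only interaction test: regress trans-score on HLA score in cases.

    Valid as an interaction test when the two scores are independent in the
    population; the slope estimates departure from a multiplicative
    (no-interaction) joint effect on disease odds.
    """
    mask = np.asarray(case_mask, dtype=bool)
    n_cases = int(mask.sum())
    if n_cases < min_cases:
        raise ValueError(f"need at least {min_cases} cases, got {n_cases}")
    t = np.asarray(trans_score, dtype=float)[mask]
    h = np.asarray(hla_score, dtype=float)[mask]
    if t.std() == 0 or h.std() == 0:
        raise ValueError("scores must be non-constant among cases")
    fit = sm.OLS(t, sm.add_constant(h)).fit()
    return InteractionResult(slope=float(fit.params[1]),
                             se=float(fit.bse[1]),
                             pvalue=float(fit.pvalues[1]),
                             n_cases=n_cases)


def score_correlation_matrix(scores: pd.DataFrame, control_mask: np.ndarray,
                             config: PipelineConfig
                             ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson r among controls; flag pairs with r^2 above threshold.

    Constant scores are excluded with a warning.  The specificity check: a
    gene whose trans-score is nearly collinear with another's cannot be
    interpreted as independent evidence.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two scores")
    mask = np.asarray(control_mask, dtype=bool)
    sub = scores.loc[mask]
    keep = [c for c in sub.columns if sub[c].std() > 0]
    excluded = set(scores.columns) - set(keep)
    if excluded:
        logger.warning("correlation check: excluding constant scores %s",
                       sorted(excluded))
    corr = sub[keep].corr()
    flags = [(a, b, float(corr.loc[a, b]))
             for i, a in enumerate(keep) for b in keep[i:]
             if corr.loc[a, b] ** 2 > config.r2_high]
    return corr, flags
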