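"""Summary-statistics handling: p-value filters, positional clumping and
cis/cis-x/trans locus classification.

A clump is a maximal group of retained SNPs (p below the retain threshold) on
one chromosome in which consecutive SNPs are separated by less than the clump
gap, kept only if it contains a lead SNP below the lead threshold.  Clump
formation is single-linkage chaining: deterministic and independent of input
order.  Intervals are 1-based and closed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger("transcore")

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta", "se", "pvalue", "target_id", "n"]

CIS, CISX, TRANS, UNCLASSIFIED = "cis", "cis-x", "trans", "unclassified"

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcription-site interval of one target gene (promoter excluded)."""

    target_id: str
    chrom: str
    site_start: int
    site_end: int

    def __post_init__(self) -> None:
        if self.site_start > self.site_end:
            raise ValueError("site_start must be <= site_end")


@dataclass
class Clump:
    """A >=1 Mb-separated block of retained SNPs for one target."""

    clump_id: str
    target_id: str
    chrom: str
    start: int
    end: int
    members: pd.DataFrame
    lead_pvalue: float
    locus_class: str = UNCLASSIFIED

    @property
    def positions(self) -> np.ndarray:
        return self.members["pos"].to_numpy()

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def validate_sumstats(records: pd.DataFrame) -> pd.DataFrame:
    """Check the flat-table invariants; returns the frame unchanged."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if (records["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive SE")
    p = records["pvalue"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (records["effect_allele"] == records["other_allele"]).any():
        raise ValueError("effect and other allele must differ")
    return records


def filter_and_clump(records: pd.DataFrame,
                     config: PipelineConfig) -> list[Clump]:
    """Filter one target's records and form positional clumps.

    SNPs with p < ``p_retain`` are chained per chromosome wherever consecutive
    retained SNPs are less than ``clump_gap_bp`` apart; chains whose minimum p
    is not below ``p_lead`` are discarded.  Empty input gives empty output.
    """
    if records.empty:
        return []
    targets = records["target_id"].unique()
    if len(targets) != 1:
        raise ValueError("filter_and_clump expects records for one target; "
                         "use clump_all for a multi-target table")
    target = targets[0]
    retained = records[records["pvalue"] < config.p_retain]
    clumps: list[Clump] = []
    for chrom, grp in retained.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "variant_id"], kind="mergesort")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= config.clump_gap_bp) + 1
        for piece in np.split(np.arange(len(grp)), breaks):
            members = grp.iloc[piece]
            lead = float(members["pvalue"].min())
            if lead >= config.p_lead:
                continue
            start, end = int(members["pos"].iloc[0]), int(members["pos"].iloc[-1])
            clumps.append(Clump(
                clump_id=f"{target}:{chrom}:{start}",
                target_id=target, chrom=str(chrom), start=start, end=end,
                members=members.reset_index(drop=True), lead_pvalue=lead))
    clumps.sort(key=lambda c: (c.chrom, c.start))
    return clumps


def clump_all(records: pd.DataFrame,
              config: PipelineConfig) -> dict[str, list[Clump]]:
    """filter_and_clump applied per target of a multi-target table."""
    return {target: filter_and_clump(grp, config)
            for target, grp in records.groupby("target_id", sort=True)}


def clump_gene_distance(clump: Clump, gene: GeneAnnotation) -> int | None:
    """Minimum bp gap from the clump's member SNPs to the transcription site.

    0 if any member lies inside the (closed) site interval; None if the clump
    and the gene are on different chromosomes.
    """
    if clump.chrom != gene.chrom:
        return None
    pos = clump.positions
    below = gene.site_start - pos
    above = pos - gene.site_end
    gaps = np.maximum(np.maximum(below, above), 0)
    return int(gaps.min())


def classify_locus(clump: Clump, gene: GeneAnnotation | None,
                   config: PipelineConfig) -> str:
    """cis (<= 50 kb), cis-x (50 kb to 5 Mb) or trans (> 5 Mb / other chrom)."""
    if gene is None:
        logger.warning("no annotation for target %s; clump %s unclassified",
                       clump.target_id, clump.clump_id)
        return UNCLASSIFIED
    dist = clump_gene_distance(clump, gene)
    if dist is None:
        return TRANS
    if dist <= config.cis_max_bp:
        return CIS
    if dist <= config.cisx_max_bp:
        return CISX
    return TRANS


def classify_clumps(clumps: list[Clump],
                    annotation: dict[str, GeneAnnotation],
                    config: PipelineConfig) -> list[Clump]:
    return [replace(c, locus_class=classify_locus(
                c, annotation.get(c.target_id), config))
            for c in clumps]


def exclude_hla(clumps: list[Clump], config: PipelineConfig) -> list[Clump]:
    """Drop every clump whose interval overlaps the configured HLA region."""
    return [c for c in clumps
            if not c.overlaps(config.hla_chrom, config.hla_start_bp,
                              config.hla_end_bp)]


def annotation_index(table: pd.DataFrame) -> dict[str, GeneAnnotation]:
    """Build a target_id -> GeneAnnotation map from a BED-like TSV frame."""
    required = {"target_id", "chrom", "site_start", "site_end"}
    if not required.issubset(table.columns):
        raise ValueError(f"gene annotation needs columns {sorted(required)}")
    return {row.target_id: GeneAnnotation(row.target_id, str(row.chrom),
                                          int(row.site_start),
                                          int(row.site_end))
            for row in table.itertuples()}


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_start <= b_end and b_start <= a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


def annotate_known_regions(clumps: list[Clump], known_hits: pd.DataFrame,
                           config: PipelineConfig) -> dict[str, list[str]]:
    """Labels of known disease-associated regions within the annotation window.

    A clump is annotated if its interval lies within ``known_hit_window_bp``
    (inclusive) of a known-hit interval on the same chromosome.
    """
    required = {"chrom", "start", "end", "label"}
    if not required.issubset(known_hits.columns):
        raise ValueError(f"known-hit table needs columns {sorted(required)}")
    out: dict[str, list[str]] = {}
    for c in clumps:
        labels = [row.label for row in known_hits.itertuples()
                  if str(row.chrom) == c.chrom
                  and _interval_distance(c.start, c.end, int(row.start),
                                         int(row.end))
                  <= config.known_hit_window_bp]
        out[c.clump_id] = labels
    return out


def annotate_genes_near_hits(annotation: dict[str, GeneAnnotation],
                             known_hits: pd.DataFrame,
                             config: PipelineConfig) -> dict[str, list[str]]:
    """Known-hit labels within the window of each transcription site."""
    out: dict[str, list[str]] = {}
    for target, gene in annotation.items():
        labels = [row.label for row in known_hits.itertuples()
                  if str(row.chrom) == gene.chrom
                  and _interval_distance(gene.site_start, gene.site_end,
                                         int(row.start), int(row.end))
                  <= config.known_hit_window_bp]
        out[target] = labels
    return out


def harmonize_alleles(records: pd.DataFrame, variants: pd.DataFrame,
                      ambiguous_maf_max: float = 0.4) -> pd.DataFrame:
    """Align summary-statistic effect alleles with genotype data.

    Matches on variant_id and the unordered allele pair; flips the beta sign
    when the effect allele in the genotype data is the summary statistics'
    other allele; drops variants whose allele pairs disagree and
    strand-ambiguous A/T and C/G variants with MAF above
    ``ambiguous_maf_max``, where strand cannot be resolved from frequency.
    """
    geno = variants.set_index("variant_id")
    keep_rows = []
    n_flip = n_drop = 0
    for row in records.itertuples(index=False):
        if row.variant_id not in geno.index:
            n_drop += 1
            continue
        g = geno.loc[row.variant_id]
        pair = frozenset((row.effect_allele, row.other_allele))
        if pair != frozenset((g["effect_allele"], g["other_allele"])):
            n_drop += 1
            continue
        if pair in _AMBIGUOUS and float(g.get("maf", 0.0)) > ambiguous_maf_max:
            n_drop += 1
            continue
        rec = row._asdict()
        if row.effect_allele != g["effect_allele"]:
            rec["beta"] = -rec["beta"]
            rec["effect_allele"], rec["other_allele"] = (
                rec["other_allele"], rec["effect_allele"])
            n_flip += 1
        keep_rows.append(rec)
    if n_flip or n_drop:
        logger.info("harmonization: flipped %d, dropped %d of %d records",
                    n_flip, n_drop, len(records))
    return pd.DataFrame(keep_rows, columns=list(records.columns))
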