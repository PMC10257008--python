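"""Core-gene calling, master-regulator region detection and report tables.

A target is called a putative core gene when its genome-wide trans-score is
disease-associated and either (1) its effective number of eQTLs exceeds the
diversity floor at p below the stringent threshold, or (2) it is a known
monogenic cause of the disease at the relaxed threshold.  Regions formed by
merging overlapping contributing clumps across disease-associated scores are
candidate peripheral master regulators when they feed more than the
configured number of scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .association import AssociationResult
from .scores import GenomeWideTransScore

logger = logging.getLogger("transcore")

CRITERION_DIVERSITY = "diversity"
CRITERION_MONOGENIC = "monogenic"


@dataclass
class CoreGeneCall:
    target_id: str
    criterion: str
    log_or: float
    pvalue: float
    effective_n: float
    cis_log_or: float | None = None
    cis_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.criterion not in (CRITERION_DIVERSITY, CRITERION_MONOGENIC):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class MasterRegulatorRegion:
    chrom: str
    start: int
    end: int
    n_scores: int
    targets: list[str]
    flagged: bool
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_scores < 1:
            raise ValueError("a region must contribute to at least one score")


def select_core_genes(associations: list[AssociationResult],
                      trans_scores: dict[str, GenomeWideTransScore],
                      monogenic: set[str],
                      config: PipelineConfig,
                      cis_associations: dict[str, AssociationResult] | None = None
                      ) -> list[CoreGeneCall]:
    """Apply the two selection criteria to trans-score associations.

    The diversity criterion takes precedence when both hold, so a monogenic
    gene passing the stringent threshold is recorded under criterion 1.
    cis evidence is attached when a cis-score association below the cis
    reporting threshold exists for the called target.
    """
    cis_associations = cis_associations or {}
    calls: list[CoreGeneCall] = []
    for res in associations:
        if not res.converged:
            continue
        score = trans_scores.get(res.score_id)
        if score is None:
            logger.warning("no trans-score/diversity for %s; excluded",
                           res.score_id)
            continue
        eff = score.effective_n
        if eff > config.diversity_min and res.pvalue < config.p_core:
            criterion = CRITERION_DIVERSITY
        elif res.score_id in monogenic and res.pvalue < config.p_core_monogenic:
            criterion = CRITERION_MONOGENIC
        else:
            continue
        call = CoreGeneCall(target_id=res.score_id, criterion=criterion,
                            log_or=res.log_or, pvalue=res.pvalue,
                            effective_n=eff)
        cis = cis_associations.get(res.score_id)
        if cis is not None and cis.converged and cis.pvalue < config.p_cis_report:
            call.cis_log_or, call.cis_pvalue = cis.log_or, cis.pvalue
        calls.append(call)
    calls.sort(key=lambda c: (c.criterion, c.pvalue, c.target_id))
    return calls


def _merge_intervals(intervals: list[tuple[str, int, int, str]]
                     ) -> list[tuple[str, int, int, set[str]]]:
    """Union of any-overlap chains of (chrom, start, end, target) intervals."""
    merged: list[tuple[str, int, int, set[str]]] = []
    for chrom, start, end, target in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end),
                          prev[3] | {target})
        else:
            merged.append((chrom, start, end, {target}))
    return merged


def identify_master_regulators(associations: list[AssociationResult],
                               trans_scores: dict[str, GenomeWideTransScore],
                               config: PipelineConfig,
                               known_labels: dict[str, list[str]] | None = None
                               ) -> list[MasterRegulatorRegion]:
    """Regions of overlapping clumps contributing to disease-associated scores.

    Qualifying scores are those associated below ``p_core``; their
    contributing clumps are pooled, overlapping intervals merged, and each
    merged region counted once per distinct target score it feeds.  Regions
    feeding more than ``master_regulator_min_scores`` scores are flagged.
    """
    known_labels = known_labels or {}
    qualifying = [r for r in associations
                  if r.converged and r.pvalue < config.p_core
                  and r.score_id in trans_scores]
    intervals = []
    labels_by_interval: dict[tuple[str, int, int], list[str]] = {}
    for res in qualifying:
        for locus in trans_scores[res.score_id].contributing:
            intervals.append((locus.chrom, locus.start, locus.end,
                              res.score_id))
            if locus.clump_id in known_labels:
                labels_by_interval.setdefault(
                    (locus.chrom, locus.start, locus.end),
                    []).extend(known_labels[locus.clump_id])
    regions = []
    for chrom, start, end, targets in _merge_intervals(intervals):
        labels = sorted({lab
                         for (c, s, e), labs in labels_by_interval.items()
                         if c == chrom and s >= start and e <= end
                         for lab in labs})
        regions.append(MasterRegulatorRegion(
            chrom=chrom, start=start, end=end, n_scores=len(targets),
            targets=sorted(targets),
            flagged=len(targets) > config.master_regulator_min_scores,
            labels=labels))
    regions.sort(key=lambda r: (-r.n_scores, r.chrom, r.start))
    return regions


def calls_table(calls: list[CoreGeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"target_id": c.target_id, "criterion": c.criterion,
          "log_or": c.log_or, "pvalue": c.pvalue,
          "effective_n": c.effective_n, "cis_log_or": c.cis_log_or,
          "cis_pvalue": c.cis_pvalue} for c in calls],
        columns=["target_id", "criterion", "log_or", "pvalue", "effective_n",
                 "cis_log_or", "cis_pvalue"])


def regions_table(regions: list[MasterRegulatorRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end,
          "n_scores": r.n_scores, "flagged": r.flagged,
          "targets": ",".join(r.targets), "labels": ",".join(r.labels)}
         for r in regions],
        columns=["chrom", "start", "end", "n_scores", "flagged", "targets",
                 "labels"])


def associations_table(associations: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"score_id": r.score_id, "log_or": r.log_or, "se": r.se,
          "pvalue": r.pvalue, "info_discrimination": r.info_discrimination,
          "n_used": r.n_used, "converged": r.converged}
         for r in associations],
        columns=["score_id", "log_or", "se", "pvalue", "info_discrimination",
                 "n_used", "converged"]).sort_values(
        ["pvalue", "score_id"], na_position="last").reset_index(drop=True)


def report(calls: list[CoreGeneCall],
           regions: list[MasterRegulatorRegion],
           associations: list[AssociationResult],
           out_dir: str | Path,
           metadata: dict | None = None) -> dict[str, pd.DataFrame]:
    """Write deterministic TSV tables and a run-metadata JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "core_genes": calls_table(calls),
        "master_regulators": regions_table(regions),
        "associations": associations_table(associations),
    }
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.6g")
    meta = dict(metadata or {})
    meta["counts"] = {name: int(len(t)) for name, t in tables.items()}
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return tables
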