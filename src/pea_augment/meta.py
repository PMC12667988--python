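"""Meta-analysis across a corpus: the 2x3 configuration grid and gain/loss accounting.

Six run configurations span {original, cross_referenced} identifier sets x
{ground_truth, predictions, union} annotation tables. For each dataset the
enrichment pipeline yields a PC-summed enriched count and a set of uniquely
enriched pathways. Comparing the ground-truth run against a run that adds
predictions classifies every enriched (dataset, pathway) outcome as lost
(enriched only under ground truth), gained (enriched only after adding
predictions), or unchanged (enriched under both); summing these over datasets
gives the grid's information-gain/loss table with one-decimal percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotations import (
    AnnotationTable,
    PathwayPredictionQuality,
    detectable_pathways,
    lookup_annotations,
    total_associations,
    union_annotations,
)
from .dataset import MetabolomicsDataset, filter_dataset
from .enrichment import EnrichmentConfig, enrich_dataset
from .idmap import KnowledgebaseSnapshot, chain_all, resolve_dataset_pubchem_ids

logger = logging.getLogger(__name__)

XREF_MODES = ("original", "cross_referenced")
ANNOTATION_MODES = ("ground_truth", "predictions", "union")


@dataclass(frozen=True)
class RunConfiguration:
    """One cell of the 2x3 grid."""

    xref: str  # "original" | "cross_referenced"
    annotations: str  # "ground_truth" | "predictions" | "union"

    def __post_init__(self) -> None:
        if self.xref not in XREF_MODES:
            raise ValueError(f"xref must be one of {XREF_MODES}")
        if self.annotations not in ANNOTATION_MODES:
            raise ValueError(f"annotations must be one of {ANNOTATION_MODES}")

    @property
    def label(self) -> str:
        return f"{self.xref}/{self.annotations}"


ALL_CONFIGURATIONS = tuple(
    RunConfiguration(x, a) for x in XREF_MODES for a in ANNOTATION_MODES
)


@dataclass
class GainLossSummary:
    """Corpus-wide gain/loss totals with one-decimal percentages."""

    n_gt_only: int
    n_pred_only: int
    n_both: int
    total: int = 0
    pct_lost: Optional[float] = None
    pct_gained: Optional[float] = None
    pct_unchanged: Optional[float] = None

    def __post_init__(self) -> None:
        self.total = self.n_gt_only + self.n_pred_only + self.n_both
        if self.total > 0:
            self.pct_lost = _pct(self.n_gt_only, self.total)
            self.pct_gained = _pct(self.n_pred_only, self.total)
            self.pct_unchanged = _pct(self.n_both, self.total)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (matches printed tables)."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def classify_gain_loss(
    gt_enriched: set[str], combined_enriched: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition enriched pathways into (lost, gained, unchanged).

    Lost: enriched under ground truth but no longer after adding predictions.
    Gained: enriched only after adding predictions. Unchanged: enriched under
    both. The three sets partition gt | combined.
    """
    lost = gt_enriched - combined_enriched
    gained = combined_enriched - gt_enriched
    unchanged = gt_enriched & combined_enriched
    return lost, gained, unchanged


def summarize_gain_loss(
    per_dataset: Sequence[tuple[set[str], set[str], set[str]]],
) -> GainLossSummary:
    """Sum per-dataset (lost, gained, unchanged) triples into corpus totals.

    With a zero total the percentages are undefined and reported as None.
    """
    return GainLossSummary(
        n_gt_only=sum(len(t[0]) for t in per_dataset),
        n_pred_only=sum(len(t[1]) for t in per_dataset),
        n_both=sum(len(t[2]) for t in per_dataset),
    )


def median_summary(values: Sequence[float]) -> float:
    """Median of per-dataset counts (mean of middle two for even length)."""
    if len(values) == 0:
        raise ValueError("median of an empty list is undefined")
    return float(np.median(np.asarray(values, dtype=float)))


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (tie-corrected); returns (U for a, p)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def mcc_stratified_gain(
    quality: PathwayPredictionQuality,
    gained_counts: dict[str, int],
    threshold: float = 0.7,
) -> dict:
    """Contrast per-pathway gain counts below vs at/above a prediction-MCC cutoff.

    ``gained_counts`` maps each pathway to the number of datasets where it was
    enriched only after adding predictions. Pathways are split at
    MCC < threshold vs >= threshold; group means, their high/low ratio, and a
    two-sided Mann-Whitney p are returned. The mean ratio is used (not the
    median ratio) because the low-MCC group's median gain is typically 0.
    Pathways without a quality score are dropped with a log message.
    """
    low, high = [], []
    for pid, count in gained_counts.items():
        if pid not in quality:
            logger.warning("pathway %s missing from quality map; dropped from stratification", pid)
            continue
        (high if quality[pid] >= threshold else low).append(count)
    mean_low = float(np.mean(low)) if low else None
    mean_high = float(np.mean(high)) if high else None
    ratio = (
        mean_high / mean_low
        if mean_low is not None and mean_high is not None and mean_low > 0
        else None
    )
    p = compare_distributions(low, high)[1] if low and high else None
    return {
        "mean_low": mean_low,
        "mean_high": mean_high,
        "mean_ratio": ratio,
        "pvalue": p,
        "n_low": len(low),
        "n_high": len(high),
    }


# ---------------------------------------------------------------------------
# The full grid
# ---------------------------------------------------------------------------


@dataclass
class DatasetResult:
    """Per-dataset, per-configuration enrichment outcome."""

    dataset_id: str
    configuration: RunConfiguration
    n_detectable: int
    n_associations: int
    enriched_count: int  # PC-summed: a pathway enriched on 2 PCs counts twice
    enriched_pathways: set[str]  # unique pathways enriched on >= 1 selected PC


@dataclass
class GridReport:
    results: list[DatasetResult] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # dataset_id -> reason
    summary: dict = field(default_factory=dict)

    def counts(self, cfg: RunConfiguration) -> list[int]:
        return [r.enriched_count for r in self.results if r.configuration == cfg]

    def enriched_sets(self, cfg: RunConfiguration) -> dict[str, set[str]]:
        return {
            r.dataset_id: r.enriched_pathways
            for r in self.results
            if r.configuration == cfg
        }


def run_grid(
    corpus: Sequence[MetabolomicsDataset],
    snapshot: KnowledgebaseSnapshot,
    gt_table: AnnotationTable,
    pred_table: AnnotationTable,
    config: EnrichmentConfig = EnrichmentConfig(),
    quality: Optional[PathwayPredictionQuality] = None,
    min_mcc: Optional[float] = None,
) -> GridReport:
    """Run all six configurations over a corpus and assemble the summary.

    Per dataset: usability filtering, PubChem CID/SID resolution, optional
    chained cross-referencing, annotation projection, and enrichment — for
    each of the six (xref, annotations) cells. Datasets failing a stage are
    excluded with a reason rather than aborting the corpus (mirroring the
    requirement that the pipeline finish without software errors). Results
    are deterministic under ``config.seed`` and independent of corpus order.

    ``min_mcc`` (with ``quality``) optionally applies the recommended
    precaution of dropping predicted pathways below that overall MCC.
    """
    from .annotations import filter_predictions_by_mcc  # local: optional path

    if min_mcc is not None:
        if quality is None:
            raise ValueError("min_mcc filtering requires a quality map")
        pred_table = filter_predictions_by_mcc(pred_table, quality, min_mcc)
    union_table = union_annotations(gt_table, pred_table)
    tables = {
        "ground_truth": gt_table,
        "predictions": pred_table,
        "union": union_table,
    }

    report = GridReport()
    for ds in corpus:
        fr = filter_dataset(ds)
        if not fr.passed:
            report.excluded[ds.dataset_id] = f"filtered: {fr.first_failed_check}"
            logger.info("dataset %s excluded (%s)", ds.dataset_id, fr.first_failed_check)
            continue
        try:
            base_ids = resolve_dataset_pubchem_ids(ds.metabolites, snapshot)
            idsets = {
                "original": base_ids,
                "cross_referenced": chain_all(base_ids, snapshot),
            }
            for cfg in ALL_CONFIGURATIONS:
                membership = lookup_annotations(
                    idsets[cfg.xref], tables[cfg.annotations], ds.dataset_id
                )
                records, count = enrich_dataset(ds, membership, config)
                report.results.append(
                    DatasetResult(
                        dataset_id=ds.dataset_id,
                        configuration=cfg,
                        n_detectable=len(detectable_pathways(membership, config.min_set_size)),
                        n_associations=total_associations(membership),
                        enriched_count=count,
                        enriched_pathways={r.pathway_id for r in records if r.enriched},
                    )
                )
        except Exception as exc:  # per-dataset failure is an exclusion, not a crash
            report.excluded[ds.dataset_id] = f"pipeline error: {exc}"
            logger.warning("dataset %s excluded (pipeline error: %s)", ds.dataset_id, exc)
            report.results = [r for r in report.results if r.dataset_id != ds.dataset_id]

    report.summary = _summarize_grid(report)
    return report


def _summarize_grid(report: GridReport) -> dict:
    summary: dict = {"medians": {}, "comparisons": {}, "gain_loss": {}}
    for cfg in ALL_CONFIGURATIONS:
        counts = report.counts(cfg)
        summary["medians"][cfg.label] = median_summary(counts) if counts else None

    # pairwise Mann-Whitney comparisons along the grid's axes
    pairs = []
    for ann in ANNOTATION_MODES:
        pairs.append((RunConfiguration("original", ann), RunConfiguration("cross_referenced", ann)))
    for xr in XREF_MODES:
        pairs.append((RunConfiguration(xr, "ground_truth"), RunConfiguration(xr, "union")))
        pairs.append((RunConfiguration(xr, "ground_truth"), RunConfiguration(xr, "predictions")))
        pairs.append((RunConfiguration(xr, "predictions"), RunConfiguration(xr, "union")))
    for a_cfg, b_cfg in pairs:
        a, b = report.counts(a_cfg), report.counts(b_cfg)
        if a and b and (len(set(a)) > 1 or len(set(b)) > 1 or set(a) != set(b)):
            u, p = compare_distributions(a, b)
        else:
            u, p = None, None
        summary["comparisons"][f"{a_cfg.label} vs {b_cfg.label}"] = {"U": u, "p": p}

    # gain/loss: ground truth vs each prediction-bearing configuration,
    # per xref mode, on unique (dataset, pathway) enriched outcomes
    for xr in XREF_MODES:
        gt_sets = report.enriched_sets(RunConfiguration(xr, "ground_truth"))
        for ann in ("union", "predictions"):
            comb_sets = report.enriched_sets(RunConfiguration(xr, ann))
            triples = [
                classify_gain_loss(gt_sets[did], comb_sets[did])
                for did in sorted(gt_sets)
                if did in comb_sets
            ]
            gl = summarize_gain_loss(triples)
            summary["gain_loss"][f"{xr}: ground_truth -> {ann}"] = {
                "n_gt_only": gl.n_gt_only,
                "n_pred_only": gl.n_pred_only,
                "n_both": gl.n_both,
                "total": gl.total,
                "pct_lost": gl.pct_lost,
                "pct_gained": gl.pct_gained,
                "pct_unchanged": gl.pct_unchanged,
            }
    return summary


def gained_counts_by_pathway(report: GridReport, xref: str, annotations: str = "union") -> dict[str, int]:
    """Per-pathway count of datasets where it was enriched only after adding predictions."""
    gt_sets = report.enriched_sets(RunConfiguration(xref, "ground_truth"))
    comb_sets = report.enriched_sets(RunConfiguration(xref, annotations))
    counts: dict[str, int] = {}
    for did, gt in gt_sets.items():
        if did not in comb_sets:
            continue
        for pid in comb_sets[did] - gt:
            counts[pid] = counts.get(pid, 0) + 1
    return counts
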