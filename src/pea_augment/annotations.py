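"""Metabolite-pathway annotation tables and their projection onto datasets.

An :class:`AnnotationTable` maps pathway IDs to sets of namespaced compound
identifiers and carries a source tag (``ground_truth``, ``predicted``, or
``combined``) plus each pathway's origin knowledgebase (KEGG, MetaCyc, or
Reactome). Projection onto a dataset (:func:`lookup_annotations`) resolves
membership at the metabolite level: a metabolite belongs to a pathway if any
of its identifiers, in any namespace, is annotated to it — and it is counted
once no matter how many of its identifiers are, because enrichment ranks
measured metabolites and double-counting one feature would inflate set sizes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .idmap import IdSet

logger = logging.getLogger(__name__)

PATHWAY_KBS = ("KEGG", "MetaCyc", "Reactome")

#: pathway ID -> overall Matthews correlation coefficient of the upstream
#: prediction model for that pathway, in [-1, 1].
PathwayPredictionQuality = dict[str, float]


@dataclass
class AnnotationTable:
    source: str  # "ground_truth" | "predicted" | "combined"
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    pathway_kb: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not s for s in self.entries.values()):
            raise ValueError("annotation entry sets must be non-empty")

    @property
    def n_pathways(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str) -> "AnnotationTable":
        """Read one-row-per-association TSV: pathway_id, pathway_kb, namespace, identifier."""
        entries: dict[str, set[tuple[str, str]]] = {}
        kb: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                pid = row["pathway_id"]
                entries.setdefault(pid, set()).add((row["namespace"], row["identifier"]))
                prev = kb.setdefault(pid, row["pathway_kb"])
                if prev != row["pathway_kb"]:
                    raise ValueError(f"pathway {pid} assigned to both {prev} and {row['pathway_kb']}")
        return cls(source=source, entries=entries, pathway_kb=kb)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["pathway_id", "pathway_kb", "namespace", "identifier"])
            for pid in sorted(self.entries):
                for ns, ident in sorted(self.entries[pid]):
                    w.writerow([pid, self.pathway_kb.get(pid, ""), ns, ident])


@dataclass
class DatasetMembership:
    """Pathway -> set of metabolite local indices, for one dataset."""

    dataset_id: str
    members: dict[str, set[int]] = field(default_factory=dict)


def lookup_annotations(idsets: dict[int, IdSet], table: AnnotationTable, dataset_id: str = "") -> DatasetMembership:
    """Project an annotation table onto a dataset's metabolites.

    Metabolite ``m`` belongs to pathway ``P`` iff any identifier held by
    ``m`` (any namespace) appears in ``P``'s entry set. Membership is
    deduplicated at the metabolite level. Metabolites with no identifiers
    contribute nothing. Two metabolites sharing an annotated identifier both
    become members (membership is per measured metabolite, not per unique ID).
    """
    # invert the table: (namespace, identifier) -> pathways
    by_id: dict[tuple[str, str], list[str]] = {}
    for pid, idents in table.entries.items():
        for key in idents:
            by_id.setdefault(key, []).append(pid)
    members: dict[str, set[int]] = {}
    for local_index, ids in idsets.items():
        for ns, vals in ids.items():
            for ident in vals:
                for pid in by_id.get((ns, ident), ()):
                    members.setdefault(pid, set()).add(local_index)
    return DatasetMembership(dataset_id=dataset_id, members=members)


def filter_predictions_by_mcc(
    table: AnnotationTable,
    quality: PathwayPredictionQuality,
    min_mcc: float = 0.7,
) -> AnnotationTable:
    """Drop predicted pathways whose overall prediction MCC is below ``min_mcc``.

    The recommended precaution against low-quality predictions: pathways the
    upstream model predicts poorly contribute mostly noise. Pathways absent
    from the quality map are dropped with a warning.
    """
    if table.source != "predicted":
        raise ValueError("MCC filtering applies to predicted annotation tables only")
    kept: dict[str, set[tuple[str, str]]] = {}
    kb: dict[str, str] = {}
    n_unscored = 0
    for pid, idents in table.entries.items():
        if pid not in quality:
            n_unscored += 1
            logger.warning("pathway %s has no prediction-quality score; dropped", pid)
            continue
        if quality[pid] >= min_mcc:
            kept[pid] = set(idents)
            if pid in table.pathway_kb:
                kb[pid] = table.pathway_kb[pid]
    if n_unscored:
        logger.warning("%d pathway(s) dropped for missing quality scores", n_unscored)
    return AnnotationTable(source="predicted", entries=kept, pathway_kb=kb)


def union_annotations(a: AnnotationTable, b: AnnotationTable) -> AnnotationTable:
    """Per-pathway set union of two annotation tables (source tag 'combined').

    Conflicting knowledgebase assignments for the same pathway ID indicate
    malformed inputs and raise.
    """
    entries: dict[str, set[tuple[str, str]]] = {p: set(s) for p, s in a.entries.items()}
    kb = dict(a.pathway_kb)
    for pid, idents in b.entries.items():
        entries.setdefault(pid, set()).update(idents)
    for pid, kb_b in b.pathway_kb.items():
        if pid in kb and kb[pid] != kb_b:
            raise ValueError(f"pathway {pid}: conflicting knowledgebase assignments {kb[pid]} vs {kb_b}")
        kb[pid] = kb_b
    return AnnotationTable(source="combined", entries=entries, pathway_kb=kb)


def detectable_pathways(m: DatasetMembership, min_size: int = 15) -> set[str]:
    """Pathways with >= ``min_size`` member metabolites in this dataset.

    Fifteen annotated members is the practical minimum for a pathway to reach
    adjusted p <= 0.01 in the enrichment test.
    """
    return {pid for pid, mem in m.members.items() if len(mem) >= min_size}


def total_associations(m: DatasetMembership) -> int:
    """Total metabolite-pathway associations: sum of member-set sizes."""
    return sum(len(mem) for mem in m.members.values())


def read_quality_tsv(path: str | Path) -> PathwayPredictionQuality:
    """Read pathway_id / overall_mcc TSV into a quality map."""
    out: PathwayPredictionQuality = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mcc = float(row["overall_mcc"])
            if not -1.0 <= mcc <= 1.0:
                raise ValueError(f"MCC {mcc} out of [-1, 1] for pathway {row['pathway_id']}")
            out[row["pathway_id"]] = mcc
    return out


def write_quality_tsv(quality: PathwayPredictionQuality, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pathway_id", "overall_mcc"])
        for pid in sorted(quality):
            w.writerow([pid, repr(quality[pid])])
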