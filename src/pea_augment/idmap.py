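"""Compound identifier disambiguation and chained cross-referencing.

Public metabolomics depositions frequently carry bare PubChem integers
without saying whether they are compound IDs (CIDs) or substance IDs (SIDs)
-- two overlapping positive-integer namespaces. ``resolve_pubchem_id``
decides by comparing the metabolite's metadata against both record spaces of
a local knowledgebase snapshot: first fuzzy name/synonym matching, then
formula+mass equality.

``chain_cross_references`` augments a metabolite's identifier set by applying
inter-knowledgebase cross-reference edges back and forth until the set stops
growing (a fixed point). Edges are directed and applied as given; no symmetric
completion is inferred, since real knowledgebase cross-references are
asymmetric and incomplete.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .dataset import NAMESPACES, MetaboliteRecord

IdSet = dict[str, set[str]]  # namespace -> identifiers held by one metabolite


@dataclass(frozen=True)
class CompoundRecord:
    namespace: str
    identifier: str
    names: tuple[str, ...] = ()
    formula: Optional[str] = None
    mass: Optional[float] = None


@dataclass
class KnowledgebaseSnapshot:
    """Local stand-in for web cross-referencing: compound records + edges.

    ``xrefs`` edges are (src_ns, src_id, dst_ns, dst_id) tuples. Tables may be
    asymmetric and incomplete, as real knowledgebase exports are.
    """

    records: dict[tuple[str, str], CompoundRecord] = field(default_factory=dict)
    xrefs: list[tuple[str, str, str, str]] = field(default_factory=list)

    def add_record(self, rec: CompoundRecord) -> None:
        key = (rec.namespace, rec.identifier)
        if key in self.records:
            raise ValueError(f"duplicate compound record {key}")
        self.records[key] = rec

    def get(self, namespace: str, identifier: str) -> Optional[CompoundRecord]:
        return self.records.get((namespace, identifier))

    def edge_index(self) -> dict[tuple[str, str], list[tuple[str, str]]]:
        """(src_ns, src_id) -> list of (dst_ns, dst_id), in insertion order."""
        index: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for src_ns, src_id, dst_ns, dst_id in self.xrefs:
            index.setdefault((src_ns, src_id), []).append((dst_ns, dst_id))
        return index

    @classmethod
    def from_tsv(cls, records_path: str | Path, xrefs_path: str | Path) -> "KnowledgebaseSnapshot":
        """Load `records.tsv` and `xrefs.tsv` (UTF-8, header row required)."""
        snap = cls()
        with open(records_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                snap.add_record(
                    CompoundRecord(
                        namespace=row["namespace"],
                        identifier=row["identifier"],
                        names=tuple(s for s in row.get("synonyms", "").split(";") if s)
                        or ((row["name"],) if row.get("name") else ()),
                        formula=row.get("formula") or None,
                        mass=float(row["mass"]) if row.get("mass") else None,
                    )
                )
        with open(xrefs_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                snap.xrefs.append((row["src_ns"], row["src_id"], row["dst_ns"], row["dst_id"]))
        return snap

    def to_tsv(self, records_path: str | Path, xrefs_path: str | Path) -> None:
        with open(records_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["namespace", "identifier", "name", "synonyms", "formula", "mass"])
            for rec in self.records.values():
                w.writerow(
                    [
                        rec.namespace,
                        rec.identifier,
                        rec.names[0] if rec.names else "",
                        ";".join(rec.names),
                        rec.formula or "",
                        repr(rec.mass) if rec.mass is not None else "",
                    ]
                )
        with open(xrefs_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["src_ns", "src_id", "dst_ns", "dst_id"])
            w.writerows(self.xrefs)


@dataclass
class IdResolution:
    """Outcome of CID/SID disambiguation for one PubChem integer."""

    input_id: str
    decision: str  # "CID" | "SID" | "unresolved"
    evidence: str  # "name_match" | "formula_and_mass_match" | "none"
    matched_record: Optional[CompoundRecord] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.decision == "unresolved") != (self.evidence == "none"):
            raise ValueError("decision 'unresolved' must pair with evidence 'none'")


# ---------------------------------------------------------------------------
# Fuzzy name matching
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


def normalize_name(name: str, strip_punctuation: bool = False) -> str:
    """Default normalizer chain: case-fold, trim, collapse internal whitespace.

    Punctuation stripping is opt-in; exotic sub-classification conventions
    (lipid shorthand, isotopologue tags) are pluggable, not built in.
    """
    out = _WS.sub(" ", name.strip().casefold())
    if strip_punctuation:
        out = _WS.sub(" ", _PUNCT.sub(" ", out)).strip()
    return out


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (insert/delete/substitute, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on a 0-100 scale."""
    if not a and not b:
        return 100.0
    longest = max(len(a), len(b))
    return 100.0 * (1.0 - levenshtein(a, b) / longest)


def match_name(
    query: str,
    candidates: Iterable[str],
    threshold: float = 95.0,
) -> tuple[Optional[str], float]:
    """Best fuzzy match for ``query`` among ``candidates``.

    Both sides pass through :func:`normalize_name` before scoring. Returns
    ``(candidate, score)`` for the highest-similarity candidate, or
    ``(None, best_score)`` if the best score falls below ``threshold``.
    Ties break by lexicographic candidate order (original spelling).
    An empty candidate list yields ``(None, 0.0)``.
    """
    if not query:
        raise ValueError("query must be non-empty")
    nq = normalize_name(query)
    best: Optional[str] = None
    best_score = 0.0
    for cand in sorted(candidates):
        score = similarity(nq, normalize_name(cand))
        if score > best_score:
            best, best_score = cand, score
    if best is None or best_score < threshold:
        return None, best_score
    return best, best_score


# ---------------------------------------------------------------------------
# CID/SID resolution
# ---------------------------------------------------------------------------

#: Rounding precision (decimal places) for mass "simple equality".
MASS_DECIMALS = 4


def _mass_equal(a: float, b: float, decimals: int = MASS_DECIMALS) -> bool:
    return round(a, decimals) == round(b, decimals)


def resolve_pubchem_id(
    id_: str,
    meta: MetaboliteRecord,
    snapshot: KnowledgebaseSnapshot,
    threshold: float = 95.0,
    mass_decimals: int = MASS_DECIMALS,
) -> IdResolution:
    """Decide whether a bare PubChem integer is a CID or an SID.

    Stage 1 (names): if the metabolite's name or any synonym strongly matches
    (similarity >= ``threshold``) any name on the CID record with this
    identifier, the ID is a CID; failing that, a strong match against the SID
    record makes it an SID. Stage 2 (formula+mass): with no name match on
    either side and both formula and mass present in the metadata, simple
    equality against the CID record (formula string equality, mass equal
    after rounding to ``mass_decimals`` places) decides CID, else the same
    comparison against the SID record decides SID. Anything else is
    unresolved and the ID cannot be used.
    """
    if not id_.isdigit() or int(id_) <= 0:
        raise ValueError(f"PubChem ID must be a positive integer string, got {id_!r}")
    cid_rec = snapshot.get("pubchem_cid", id_)
    sid_rec = snapshot.get("pubchem_sid", id_)
    if cid_rec is None and sid_rec is None:
        return IdResolution(id_, "unresolved", "none")

    queries = [meta.name, *meta.synonyms]
    for decision, rec in (("CID", cid_rec), ("SID", sid_rec)):
        if rec is None or not rec.names:
            continue
        for q in queries:
            if not q:
                continue
            cand, score = match_name(q, rec.names, threshold)
            if cand is not None:
                return IdResolution(id_, decision, "name_match", rec, score)

    if meta.formula is not None and meta.mass is not None:
        for decision, rec in (("CID", cid_rec), ("SID", sid_rec)):
            if rec is None or rec.formula is None or rec.mass is None:
                continue
            if rec.formula == meta.formula and _mass_equal(rec.mass, meta.mass, mass_decimals):
                return IdResolution(id_, decision, "formula_and_mass_match", rec)

    return IdResolution(id_, "unresolved", "none")


def resolve_dataset_pubchem_ids(
    metabolites: Iterable[MetaboliteRecord],
    snapshot: KnowledgebaseSnapshot,
    threshold: float = 95.0,
) -> dict[int, IdSet]:
    """Per-metabolite starting IdSets with ``pubchem_ambiguous`` resolved.

    Ambiguous PubChem integers that resolve become ``pubchem_cid`` or
    ``pubchem_sid`` entries; unresolved ones are dropped (they cannot be
    used for lookup or cross-referencing).
    """
    idsets: dict[int, IdSet] = {}
    for m in metabolites:
        ids: IdSet = {}
        for ns, value in m.ids.items():
            if not value:
                continue
            if ns == "pubchem_ambiguous":
                res = resolve_pubchem_id(value, m, snapshot, threshold)
                if res.decision == "CID":
                    ids.setdefault("pubchem_cid", set()).add(value)
                elif res.decision == "SID":
                    ids.setdefault("pubchem_sid", set()).add(value)
            else:
                ids.setdefault(ns, set()).add(value)
        idsets[m.local_index] = ids
    return idsets


# ---------------------------------------------------------------------------
# Chained cross-referencing
# ---------------------------------------------------------------------------


def chain_cross_references(
    ids: IdSet,
    snapshot: KnowledgebaseSnapshot,
    max_rounds: int = 10_000,
) -> IdSet:
    """Grow an identifier set to its fixed point under the snapshot's edges.

    Each round applies every applicable cross-reference edge to every held
    identifier, adding targets; rounds repeat until one adds nothing. The
    result is the directed-reachability closure of the input over the edge
    table: output is a superset of input, deterministic, idempotent, and
    monotone in the input. ``max_rounds`` is a guard against pathological
    snapshots only; finite tables converge in at most as many rounds as
    there are distinct (namespace, identifier) pairs.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    index = snapshot.edge_index()
    held: set[tuple[str, str]] = {(ns, i) for ns, vals in ids.items() for i in vals}
    for _ in range(max_rounds):
        added = False
        for key in list(held):
            for target in index.get(key, ()):
                if target not in held:
                    held.add(target)
                    added = True
        if not added:
            break
    else:
        raise RuntimeError(f"cross-reference chaining did not converge within {max_rounds} rounds")
    out: IdSet = {}
    for ns, identifier in held:
        out.setdefault(ns, set()).add(identifier)
    return out


def chain_all(
    idsets: dict[int, IdSet],
    snapshot: KnowledgebaseSnapshot,
) -> dict[int, IdSet]:
    """Apply :func:`chain_cross_references` to every metabolite's IdSet."""
    return {
        idx: chain_cross_references(ids, snapshot) if ids else {}
        for idx, ids in idsets.items()
    }
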