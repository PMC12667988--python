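"""Metabolomics dataset model, readers/writers, and usability filtering.

A dataset is a samples x metabolites intensity matrix plus per-metabolite
metadata: a free-text name, optional synonyms, optional chemical formula and
monoisotopic/molecular mass, and namespaced compound identifiers. Two on-disk
dialects are supported: a sectioned TSV and a JSON mirror of the same model.

Filtering mirrors the usability checks applied to public repository
depositions before a pathway-enrichment meta-analysis: a dataset is kept only
if enough metabolites carry compound identifiers for pathway lookup to be
worthwhile (>= 15 by default, since a pathway needs >= 15 annotated members
to be pragmatically detectable at adjusted p <= 0.01) and the intensity
matrix is on a sensible scale (minimum >= 0, maximum >= 20).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

#: Closed set of identifier namespaces. ``pubchem_ambiguous`` holds PubChem
#: integers whose CID-vs-SID status has not yet been resolved.
NAMESPACES = (
    "pubchem_ambiguous",
    "pubchem_cid",
    "pubchem_sid",
    "kegg",
    "metacyc",
    "chebi",
)

#: Check codes, in the order they are evaluated.
CHECK_ORDER = ("readable", "insufficient_ids", "intensity_floor", "intensity_scale")


class DatasetParseError(ValueError):
    """Malformed dataset file; carries line/field context in the message."""


@dataclass
class MetaboliteRecord:
    """One measured metabolite: metadata plus namespaced compound IDs."""

    local_index: int
    name: str
    synonyms: list[str] = field(default_factory=list)
    formula: Optional[str] = None
    mass: Optional[float] = None
    ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.ids) - set(NAMESPACES)
        if bad:
            raise ValueError(f"unknown ID namespace(s) {sorted(bad)} on metabolite {self.local_index}")

    def has_id(self) -> bool:
        return any(v for v in self.ids.values())


@dataclass
class MetabolomicsDataset:
    """Intensity matrix (rows = samples, columns = metabolites) with metadata."""

    dataset_id: str
    metabolites: list[MetaboliteRecord]
    samples: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.samples), len(self.metabolites)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.samples)} samples x {len(self.metabolites)} metabolites"
            )
        idx = [m.local_index for m in self.metabolites]
        if len(set(idx)) != len(idx):
            raise ValueError("metabolite local_index values are not unique")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensity matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)


@dataclass
class FilterReport:
    """Outcome of the ordered usability checks for one dataset."""

    dataset_id: str
    passed: bool
    first_failed_check: Optional[str]
    checks_evaluated: list[tuple[str, bool]]


def count_identified(ds: MetabolomicsDataset) -> int:
    """Number of metabolites carrying at least one non-empty namespaced ID.

    Metabolites, not identifiers, are counted: a metabolite with both a KEGG
    and a ChEBI ID contributes one.
    """
    return sum(1 for m in ds.metabolites if m.has_id())


def filter_dataset(
    ds: MetabolomicsDataset,
    min_ids: int = 15,
    min_intensity_floor: float = 0.0,
    min_intensity_ceiling: float = 20.0,
) -> FilterReport:
    """Apply the ordered usability checks; all boundaries are inclusive.

    A dataset passes iff >= ``min_ids`` metabolites carry a compound ID, the
    matrix minimum is >= ``min_intensity_floor`` and the matrix maximum is
    >= ``min_intensity_ceiling``. The readability check is vacuously true for
    an in-memory dataset (unreadable files never reach this function).
    """
    checks: list[tuple[str, bool]] = [("readable", True)]
    checks.append(("insufficient_ids", count_identified(ds) >= min_ids))
    checks.append(("intensity_floor", float(ds.intensities.min()) >= min_intensity_floor))
    checks.append(("intensity_scale", float(ds.intensities.max()) >= min_intensity_ceiling))
    first_failed = next((code for code, ok in checks if not ok), None)
    return FilterReport(
        dataset_id=ds.dataset_id,
        passed=first_failed is None,
        first_failed_check=first_failed,
        checks_evaluated=checks,
    )


# ---------------------------------------------------------------------------
# TSV dialect
#
#   #dataset_id\t<id>
#   #metabolites
#   local_index\tname\tsynonyms\tformula\tmass\t<one column per namespace>
#   ...
#   #intensities
#   sample\t<metabolite name per column, in local_index order>
#   <sample_id>\t<float>...
#
# Synonyms are ';'-joined; empty cells mean absent. Floats are written with
# repr-stable formatting so write -> read round-trips bit-stably.
# ---------------------------------------------------------------------------

_META_COLUMNS = ["local_index", "name", "synonyms", "formula", "mass", *NAMESPACES]


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_dataset(ds: MetabolomicsDataset, path: str | Path, dialect: str = "tsv") -> None:
    """Write a dataset in the given dialect ('tsv' or 'json')."""
    path = Path(path)
    if dialect == "json":
        doc = {
            "dataset_id": ds.dataset_id,
            "samples": list(ds.samples),
            "metabolites": [
                {
                    "local_index": m.local_index,
                    "name": m.name,
                    "synonyms": list(m.synonyms),
                    "formula": m.formula,
                    "mass": m.mass,
                    "ids": dict(sorted(m.ids.items())),
                }
                for m in ds.metabolites
            ],
            "intensities": [[float(v) for v in row] for row in ds.intensities],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [f"#dataset_id\t{ds.dataset_id}", "#metabolites", "\t".join(_META_COLUMNS)]
    for m in ds.metabolites:
        row = [
            str(m.local_index),
            m.name,
            ";".join(m.synonyms),
            m.formula or "",
            _fmt_float(m.mass) if m.mass is not None else "",
        ]
        row.extend(m.ids.get(ns, "") for ns in NAMESPACES)
        lines.append("\t".join(row))
    lines.append("#intensities")
    lines.append("\t".join(["sample"] + [m.name for m in ds.metabolites]))
    for si, sample in enumerate(ds.samples):
        lines.append("\t".join([sample] + [_fmt_float(v) for v in ds.intensities[si]]))
    path.write_text("\n".join(lines) + "\n")


def read_dataset(path: str | Path, dialect: str = "tsv") -> MetabolomicsDataset:
    """Read a dataset file; malformed input raises :class:`DatasetParseError`.

    Parse errors name the offending line and field rather than silently
    skipping records, because "file is readable" is itself the first
    usability check of the meta-analysis.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetParseError(f"{path}: file does not exist")
    if dialect == "json":
        return _read_json(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _read_tsv(path)


def _read_json(path: Path) -> MetabolomicsDataset:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        metabolites = [
            MetaboliteRecord(
                local_index=int(m["local_index"]),
                name=str(m["name"]),
                synonyms=[str(s) for s in m.get("synonyms", [])],
                formula=m.get("formula"),
                mass=None if m.get("mass") is None else float(m["mass"]),
                ids={k: str(v) for k, v in m.get("ids", {}).items() if v},
            )
            for m in doc["metabolites"]
        ]
        return MetabolomicsDataset(
            dataset_id=str(doc["dataset_id"]),
            metabolites=metabolites,
            samples=[str(s) for s in doc["samples"]],
            intensities=np.asarray(doc["intensities"], dtype=float),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DatasetParseError(f"{path}: malformed dataset document ({exc})") from exc


def _read_tsv(path: Path) -> MetabolomicsDataset:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#dataset_id\t"):
        raise DatasetParseError(f"{path}:1: expected '#dataset_id\\t<id>' header")
    dataset_id = lines[0].split("\t", 1)[1]

    try:
        meta_start = lines.index("#metabolites") + 1
        int_start = lines.index("#intensities") + 1
    except ValueError as exc:
        raise DatasetParseError(f"{path}: missing #metabolites or #intensities section") from exc

    header = lines[meta_start].split("\t")
    if header != _META_COLUMNS:
        raise DatasetParseError(
            f"{path}:{meta_start + 1}: metabolite header mismatch; expected {_META_COLUMNS}"
        )
    metabolites: list[MetaboliteRecord] = []
    for lineno in range(meta_start + 1, int_start - 1):
        cells = lines[lineno].split("\t")
        if len(cells) != len(_META_COLUMNS):
            raise DatasetParseError(
                f"{path}:{lineno + 1}: expected {len(_META_COLUMNS)} fields, got {len(cells)}"
            )
        try:
            mass = float(cells[4]) if cells[4] else None
        except ValueError as exc:
            raise DatasetParseError(f"{path}:{lineno + 1}: field 'mass': {cells[4]!r} is not a number") from exc
        try:
            local_index = int(cells[0])
        except ValueError as exc:
            raise DatasetParseError(f"{path}:{lineno + 1}: field 'local_index': not an integer") from exc
        ids = {ns: cells[5 + k] for k, ns in enumerate(NAMESPACES) if cells[5 + k]}
        metabolites.append(
            MetaboliteRecord(
                local_index=local_index,
                name=cells[1],
                synonyms=[s for s in cells[2].split(";") if s],
                formula=cells[3] or None,
                mass=mass,
                ids=ids,
            )
        )

    samples: list[str] = []
    rows: list[list[float]] = []
    for lineno in range(int_start + 1, len(lines)):
        if not lines[lineno]:
            continue
        cells = lines[lineno].split("\t")
        if len(cells) != len(metabolites) + 1:
            raise DatasetParseError(
                f"{path}:{lineno + 1}: expected {len(metabolites) + 1} fields, got {len(cells)}"
            )
        samples.append(cells[0])
        row = []
        for col, cell in enumerate(cells[1:]):
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise DatasetParseError(
                    f"{path}:{lineno + 1}: intensity cell for metabolite "
                    f"{metabolites[col].name!r} (column {col}): {cell!r} is not numeric"
                ) from exc
        rows.append(row)
    if len(samples) < 2:
        raise DatasetParseError(f"{path}: dataset needs at least 2 samples, got {len(samples)}")
    try:
        return MetabolomicsDataset(dataset_id, metabolites, samples, np.asarray(rows))
    except ValueError as exc:
        raise DatasetParseError(f"{path}: {exc}") from exc
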