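"""Self-contained synthetic corpora with known ground truth.

The generator builds the whole world the pipeline assumes: a compound
universe with names, formulas, masses and identifiers across five namespaces
linked by true cross-reference edges; pathways over that universe; an
incomplete "ground truth" annotation table (true associations removed at a
dropout rate, emulating knowledgebase incompleteness); accuracy-controlled
"predicted" annotations at a (TPR, FPR) operating point with the realized
per-pathway Matthews correlation coefficient reported; ambiguous PubChem
integers whose CID and SID pools overlap; and intensity matrices where
metabolites of planted pathways carry a between-group mean shift in log
space — the systematic variance the PCA step is meant to capture.

Everything is bit-reproducible under (seed, config).

Default conditions
------------------
Defaults mirror the study regime the pipeline targets: a 70%
annotation-dropout ground truth (knowledgebase annotations are grossly
incomplete relative to true metabolism), predictions at TPR 0.95 / FPR 1e-4
(realized per-pathway MCC ~= 0.9, the upstream model's reported overall
accuracy), pathways of 20-28 members (comfortably above the 15-member
detectability floor), 70-metabolite / 20-sample datasets in two balanced
groups, a 2.0 log2-unit planted group shift over 0.5-unit noise, and a 5%
zero rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .annotations import AnnotationTable, DatasetMembership, PathwayPredictionQuality
from .dataset import MetaboliteRecord, MetabolomicsDataset
from .idmap import CompoundRecord, KnowledgebaseSnapshot

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}

#: Per-namespace probability that a dataset metabolite carries that ID.
#: KEGG and bare PubChem integers are common in public depositions; MetaCyc
#: and ChEBI IDs are rare, which is what makes cross-referencing valuable.
DEFAULT_ID_COVERAGE = {
    "kegg": 0.9,
    "pubchem_ambiguous": 0.9,
    "metacyc": 0.05,
    "chebi": 0.05,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_datasets: int = 50
    n_samples: int = 20
    n_metabolites: int = 70
    n_compounds: int = 500
    n_pathways: int = 40
    pathway_size_min: int = 20
    pathway_size_max: int = 28
    n_planted: int = 2
    gt_dropout: float = 0.7
    pred_tpr: float = 0.95
    pred_fpr: float = 1e-4
    low_quality_fraction: float = 0.0  # fraction of pathways given a degraded operating point
    low_pred_tpr: float = 0.25
    low_pred_fpr: float = 0.02
    xref_completeness: float = 1.0
    id_coverage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ID_COVERAGE))
    cid_sid_overlap: float = 0.3
    effect_size: float = 2.0  # between-group mean shift, log2 units
    noise_sd: float = 0.5  # per-observation noise, log2 units
    base_mean: float = 8.0  # baseline log2 intensity
    base_sd: float = 1.5  # between-metabolite baseline spread
    zero_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "gt_dropout", "pred_tpr", "pred_fpr", "low_quality_fraction",
            "low_pred_tpr", "low_pred_fpr", "xref_completeness",
            "cid_sid_overlap", "zero_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.pathway_size_max > self.n_compounds:
            raise ValueError("pathway size exceeds the compound universe")
        if self.pathway_size_max > self.n_metabolites:
            raise ValueError("planted pathways must fit within a dataset")


@dataclass
class Compound:
    index: int
    name: str
    synonyms: list[str]
    formula: str
    mass: float
    ids: dict[str, str]  # namespace -> identifier (the compound's true IDs)


@dataclass
class World:
    """The generator's ground truth: compounds, pathways, true annotations."""

    config: SimulationConfig
    compounds: list[Compound]
    snapshot: KnowledgebaseSnapshot
    true_table: AnnotationTable  # complete associations, keyed by every namespace
    pathways: dict[str, list[int]]  # pathway ID -> compound indices
    pathway_kb: dict[str, str]


def _make_formula(rng: np.random.Generator) -> tuple[str, float]:
    counts = {
        "C": int(rng.integers(2, 30)),
        "H": int(rng.integers(4, 50)),
        "N": int(rng.integers(0, 6)),
        "O": int(rng.integers(0, 12)),
    }
    formula = "".join(
        f"{el}{n}" if n > 1 else el for el, n in counts.items() if n > 0
    )
    mass = sum(_ATOMIC_MASS[el] * n for el, n in counts.items())
    return formula, round(mass, 4)


def generate_world(config: SimulationConfig) -> World:
    """Build the compound universe, knowledgebase snapshot, and true annotations.

    Each compound holds one identifier per namespace. CID integers run
    1..n; a ``cid_sid_overlap`` fraction of compounds receive an SID integer
    that collides with some other compound's CID (the PubChem ambiguity the
    resolver must untangle), the rest get unique SIDs. True cross-reference
    edges form a directed ring pubchem_cid -> kegg -> chebi -> metacyc ->
    pubchem_cid plus pubchem_cid <-> pubchem_sid, so with a complete edge
    table the chained closure from any one ID recovers all five. A
    ``xref_completeness`` fraction of true edges is emitted into the
    snapshot. The true annotation table is keyed by every namespace, so
    projections under any identifier regime are possible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_compounds
    overlap = rng.random(n) < config.cid_sid_overlap
    shift = int(rng.integers(1, n)) if n > 1 else 0
    compounds: list[Compound] = []
    snapshot = KnowledgebaseSnapshot()
    for i in range(n):
        formula, mass = _make_formula(rng)
        name = f"metabolite {i:04d}"
        synonyms = [f"MET-{i:04d}", name.upper()]
        cid = str(i + 1)
        # colliding SIDs reuse another compound's CID integer
        sid = str(((i + shift) % n) + 1) if overlap[i] else str(n + i + 1)
        ids = {
            "pubchem_cid": cid,
            "pubchem_sid": sid,
            "kegg": f"C{i:05d}",
            "metacyc": f"META-{i}",
            "chebi": str(30000 + i),
        }
        compounds.append(Compound(i, name, synonyms, formula, mass, ids))

    for c in compounds:
        names = (c.name, *c.synonyms)
        snapshot.add_record(
            CompoundRecord("pubchem_cid", c.ids["pubchem_cid"], names, c.formula, c.mass)
        )
    for c in compounds:
        names = (c.name, *c.synonyms)
        key = ("pubchem_sid", c.ids["pubchem_sid"])
        if key not in snapshot.records:
            snapshot.add_record(CompoundRecord(*key, names, c.formula, c.mass))

    true_edges: list[tuple[str, str, str, str]] = []
    ring = ["pubchem_cid", "kegg", "chebi", "metacyc"]
    for c in compounds:
        for a, b in zip(ring, ring[1:] + ring[:1]):
            true_edges.append((a, c.ids[a], b, c.ids[b]))
        true_edges.append(("pubchem_cid", c.ids["pubchem_cid"], "pubchem_sid", c.ids["pubchem_sid"]))
        true_edges.append(("pubchem_sid", c.ids["pubchem_sid"], "pubchem_cid", c.ids["pubchem_cid"]))
    keep = rng.random(len(true_edges)) < config.xref_completeness
    snapshot.xrefs = [e for e, k in zip(true_edges, keep) if k]

    pathways: dict[str, list[int]] = {}
    pathway_kb: dict[str, str] = {}
    kbs = ("KEGG", "MetaCyc", "Reactome")
    for p in range(config.n_pathways):
        size = int(rng.integers(config.pathway_size_min, config.pathway_size_max + 1))
        members = sorted(rng.choice(n, size=size, replace=False).tolist())
        pid = f"PW{p:04d}"
        pathways[pid] = members
        pathway_kb[pid] = kbs[p % 3]

    entries = {
        pid: {
            (ns, compounds[ci].ids[ns])
            for ci in members
            for ns in ("kegg", "metacyc", "chebi", "pubchem_cid", "pubchem_sid")
        }
        for pid, members in pathways.items()
    }
    true_table = AnnotationTable(source="ground_truth", entries=entries, pathway_kb=dict(pathway_kb))
    return World(config, compounds, snapshot, true_table, pathways, pathway_kb)


#: Native compound-ID namespace of each pathway knowledgebase. Reactome
#: reaches compounds through ChEBI.
_KB_NAMESPACE = {"KEGG": "kegg", "MetaCyc": "metacyc", "Reactome": "chebi"}

#: Namespaces predictions are keyed by: structures come from KEGG molfiles
#: and PubChem CID records, the identifiers most depositions carry.
_PRED_NAMESPACES = ("kegg", "pubchem_cid")


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def generate_annotation_tables(
    world: World,
    config: Optional[SimulationConfig] = None,
) -> tuple[AnnotationTable, AnnotationTable, PathwayPredictionQuality]:
    """Derive incomplete ground truth and accuracy-controlled predictions.

    Ground truth: each true association survives with probability
    ``1 - gt_dropout`` and is keyed by the pathway's native knowledgebase
    namespace (KEGG pathways by KEGG IDs, MetaCyc by MetaCyc, Reactome by
    ChEBI) — reachable only for metabolites that hold, or can chain to, that
    namespace. Predictions: per pathway, each true member is kept with
    probability ``pred_tpr`` and each non-member added with ``pred_fpr``
    (a ``low_quality_fraction`` of pathways uses the degraded operating
    point instead); entries are keyed by KEGG and PubChem CID. The returned
    quality map is the realized per-pathway MCC computed from the actual
    confusion counts over the compound universe — reported, not targeted,
    because MCC does not invert to a unique operating point.
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = config.n_compounds
    compounds = world.compounds

    gt_entries: dict[str, set[tuple[str, str]]] = {}
    gt_kb: dict[str, str] = {}
    for pid, members in world.pathways.items():
        ns = _KB_NAMESPACE[world.pathway_kb[pid]]
        kept = [ci for ci in members if rng.random() >= config.gt_dropout]
        if kept:
            gt_entries[pid] = {(ns, compounds[ci].ids[ns]) for ci in kept}
            gt_kb[pid] = world.pathway_kb[pid]

    pids = sorted(world.pathways)
    n_low = int(round(config.low_quality_fraction * len(pids)))
    low_set = set(rng.choice(pids, size=n_low, replace=False).tolist()) if n_low else set()

    pred_entries: dict[str, set[tuple[str, str]]] = {}
    pred_kb: dict[str, str] = {}
    quality: PathwayPredictionQuality = {}
    for pid in pids:
        members = set(world.pathways[pid])
        tpr = config.low_pred_tpr if pid in low_set else config.pred_tpr
        fpr = config.low_pred_fpr if pid in low_set else config.pred_fpr
        draws = rng.random(n)
        predicted = {
            ci for ci in range(n)
            if (draws[ci] < tpr if ci in members else draws[ci] < fpr)
        }
        tp = len(predicted & members)
        fp = len(predicted - members)
        fn = len(members - predicted)
        tn = n - tp - fp - fn
        quality[pid] = float(_mcc(tp, fp, tn, fn))
        if predicted:
            pred_entries[pid] = {
                (ns, compounds[ci].ids[ns]) for ci in predicted for ns in _PRED_NAMESPACES
            }
            pred_kb[pid] = world.pathway_kb[pid]

    gt = AnnotationTable(source="ground_truth", entries=gt_entries, pathway_kb=gt_kb)
    pred = AnnotationTable(source="predicted", entries=pred_entries, pathway_kb=pred_kb)
    return gt, pred, quality


def generate_dataset(
    world: World,
    config: Optional[SimulationConfig] = None,
    planted: Optional[set[str]] = None,
    dataset_id: str = "SIM000001",
    rng: Optional[np.random.Generator] = None,
) -> tuple[MetabolomicsDataset, DatasetMembership]:
    """One intensity matrix with planted pathway effects, plus its true membership.

    Samples split into two balanced groups. In log2 space every metabolite
    draws a baseline level; metabolites belonging to a planted pathway get a
    between-group mean shift of ``effect_size`` (+/- half per group), noise
    is Gaussian with ``noise_sd``, values are exponentiated back to the
    intensity scale, and a ``zero_rate`` fraction is zeroed (non-detects).
    Metadata carries each namespace ID with its coverage probability; the
    PubChem integer is deposited as an *ambiguous* ID — the CID or the SID
    integer with equal probability — as real depositions do.

    Returns the dataset and the oracle membership (every pathway's members
    actually present, by local index, regardless of ID coverage).
    """
    config = config or world.config
    planted = planted or set()
    if rng is None:
        entropy = int.from_bytes(dataset_id.encode()[:8].ljust(8, b"\0"), "little")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303, entropy]))
    n_met = config.n_metabolites
    planted_members: list[int] = sorted({ci for pid in planted for ci in world.pathways[pid]})
    if len(planted_members) > n_met:
        raise ValueError("planted pathways do not fit in the dataset")
    pool = np.setdiff1d(np.arange(config.n_compounds), planted_members)
    fillers = rng.choice(pool, size=n_met - len(planted_members), replace=False)
    chosen = np.concatenate([planted_members, np.sort(fillers)]).astype(int)
    rng.shuffle(chosen)

    n_samp = config.n_samples
    group = np.zeros(n_samp)
    group[n_samp // 2 :] = 1.0
    baseline = rng.normal(config.base_mean, config.base_sd, size=n_met)
    # Per-metabolite group shift: planted pathways alternate direction (one
    # pathway's members rise in group B, the next one's fall), as pathway
    # effects in real contrasts need not point the same way. Overlapping
    # members sum their pathways' shifts.
    local_of = {ci: li for li, ci in enumerate(chosen)}
    shift_vec = np.zeros(n_met)
    for k, pid in enumerate(sorted(planted)):
        direction = 1.0 if k % 2 == 0 else -1.0
        for ci in world.pathways[pid]:
            shift_vec[local_of[ci]] += direction * config.effect_size
    shift = np.outer(group - 0.5, shift_vec)
    log2_intensity = baseline + shift + rng.normal(0.0, config.noise_sd, size=(n_samp, n_met))
    intensities = np.power(2.0, log2_intensity)
    intensities[rng.random(intensities.shape) < config.zero_rate] = 0.0

    metabolites: list[MetaboliteRecord] = []
    for local_index, ci in enumerate(chosen):
        c = world.compounds[ci]
        ids: dict[str, str] = {}
        for ns in ("kegg", "metacyc", "chebi"):
            if rng.random() < config.id_coverage.get(ns, 0.0):
                ids[ns] = c.ids[ns]
        if rng.random() < config.id_coverage.get("pubchem_ambiguous", 0.0):
            which = "pubchem_cid" if rng.random() < 0.5 else "pubchem_sid"
            ids["pubchem_ambiguous"] = c.ids[which]
        metabolites.append(
            MetaboliteRecord(
                local_index=local_index,
                name=c.name,
                synonyms=list(c.synonyms),
                formula=c.formula,
                mass=c.mass,
                ids=ids,
            )
        )
    ds = MetabolomicsDataset(
        dataset_id=dataset_id,
        metabolites=metabolites,
        samples=[f"S{j + 1:03d}" for j in range(n_samp)],
        intensities=intensities,
    )
    chosen_set = {ci: li for li, ci in enumerate(chosen)}
    members = {
        pid: {chosen_set[ci] for ci in mem if ci in chosen_set}
        for pid, mem in world.pathways.items()
        if any(ci in chosen_set for ci in mem)
    }
    return ds, DatasetMembership(dataset_id=dataset_id, members=members)


@dataclass
class Corpus:
    world: World
    gt_table: AnnotationTable
    pred_table: AnnotationTable
    quality: PathwayPredictionQuality
    datasets: list[MetabolomicsDataset]
    true_memberships: dict[str, DatasetMembership]
    planted: dict[str, set[str]]  # dataset_id -> planted pathway IDs


def generate_corpus(config: SimulationConfig) -> Corpus:
    """A full corpus: world, annotation tables, and ``n_datasets`` datasets.

    Each dataset plants ``n_planted`` randomly chosen pathways (all their
    members included, so each planted pathway clears the 15-member
    detectability floor by construction).
    """
    world = generate_world(config)
    gt, pred, quality = generate_annotation_tables(world, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    pids = sorted(world.pathways)
    datasets = []
    memberships: dict[str, DatasetMembership] = {}
    planted_map: dict[str, set[str]] = {}
    for d in range(config.n_datasets):
        planted: set[str] = set()
        # rejection-sample pathway combinations until the union fits
        for _ in range(100):
            cand = set(rng.choice(pids, size=config.n_planted, replace=False).tolist())
            if len({ci for p in cand for ci in world.pathways[p]}) <= config.n_metabolites:
                planted = cand
                break
        dataset_id = f"SIM{d:06d}"
        ds, membership = generate_dataset(world, config, planted, dataset_id, rng)
        datasets.append(ds)
        memberships[dataset_id] = membership
        planted_map[dataset_id] = planted
    return Corpus(world, gt, pred, quality, datasets, memberships, planted_map)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same conditions with no planted effect (for calibration checks)."""
    return replace(config, effect_size=0.0)
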