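import numpy as np
import pytest

from pea_augment.dataset import MetaboliteRecord, MetabolomicsDataset
from pea_augment.idmap import CompoundRecord, KnowledgebaseSnapshot


def make_dataset(
    n_samples=3,
    n_metabolites=4,
    dataset_id="DS1",
    ids=None,
    intensities=None,
    names=None,
):
    """Small in-memory dataset; ids is a list of per-metabolite id dicts."""
    mets = []
    for i in range(n_metabolites):
        mets.append(
            MetaboliteRecord(
                local_index=i,
                name=(names[i] if names else f"met-{i}"),
                synonyms=[f"MET{i}"],
                formula="H2O" if i % 2 == 0 else None,
                mass=18.0153 if i % 2 == 0 else None,
                ids=(ids[i] if ids else {"kegg": f"C{i:05d}"}),
            )
        )
    if intensities is None:
        rng = np.random.default_rng(0)
        intensities = rng.uniform(1, 50, size=(n_samples, n_metabolites))
    return MetabolomicsDataset(
        dataset_id=dataset_id,
        metabolites=mets,
        samples=[f"S{j}" for j in range(n_samples)],
        intensities=np.asarray(intensities, dtype=float),
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture
def chain_snapshot():
    """Snapshot with the edge chain cid:10 -> chebi:7 -> kegg:C1 -> metacyc:W."""
    snap = KnowledgebaseSnapshot()
    snap.xrefs = [
        ("pubchem_cid", "10", "chebi", "7"),
        ("chebi", "7", "kegg", "C1"),
        ("kegg", "C1", "metacyc", "W"),
    ]
    return snap


@pytest.fixture
def cid_sid_snapshot():
    """CID-10 and SID-10 records with distinct names/formulas/masses."""
    snap = KnowledgebaseSnapshot()
    snap.add_record(
        CompoundRecord("pubchem_cid", "10", ("alpha-D-glucose", "glucose"), "C6H12O6", 180.1559)
    )
    snap.add_record(
        CompoundRecord("pubchem_sid", "10", ("water", "oxidane"), "H2O", 18.0153)
    )
    return snap


def random_snapshot(rng, n_ids=8, n_edges=12):
    """Random directed edge table over a small (namespace, id) universe."""
    namespaces = ["pubchem_cid", "kegg", "metacyc", "chebi"]
    universe = [(namespaces[i % 4], str(i)) for i in range(n_ids)]
    snap = KnowledgebaseSnapshot()
    for _ in range(n_edges):
        a, b = rng.choice(len(universe), size=2, replace=False)
        snap.xrefs.append((*universe[a], *universe[b]))
    return snap, universe


def closure_oracle(start, xrefs):
    """Brute-force directed reachability closure over an edge list."""
    held = set(start)
    changed = True
    while changed:
        changed = False
        for s_ns, s_id, d_ns, d_id in xrefs:
            if (s_ns, s_id) in held and (d_ns, d_id) not in held:
                held.add((d_ns, d_id))
                changed = True
    return held
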