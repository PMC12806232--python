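"""Self-contained synthetic DDI datasets with planted, recoverable structure.

Real DDI-event corpora (drug tables with SMILES, binary bind-protein
annotation tables, and event-labeled interacting pairs) are external
downloads; this module emulates all three inputs at desk scale:

* molecules: random chemically plausible graphs (trees plus an occasional
  ring) over C/N/O/S under valence caps, emitted as SMILES;
* descriptors: each latent drug cluster owns one block of bits per entity
  class; drugs inherit their cluster's pattern with per-bit flip probability
  ``noise_rate``, so within-cluster Jaccard similarity exceeds cross-cluster;
* events, under one of three label rules:
  - ``cluster_pair``: the event of (i, j) is a fixed function of the two
    drugs' clusters (bind-protein similarity is informative);
  - ``metapath``: the event is a binned count of common neighbors in a hidden
    relation graph (2-hop structure is informative);
  - ``random``: uniform labels, a negative control for leakage.

A ``noise_rate`` fraction of labels is resampled uniformly.  Everything is
deterministic under ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MolecularGraph, graph_from_smiles, smiles_from_graph
from .data import ENTITY_CLASSES, DrugRecord, EventDataset

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ATOM_P = {"C": 0.7, "N": 0.15, "O": 0.1, "S": 0.05}


@dataclass
class SyntheticSpec:
    """Knobs of the generator; defaults are the desk-scale study conditions."""

    n_drugs: int = 60
    n_events: int = 3
    n_clusters: int = 3
    descriptor_lengths: dict = field(
        default_factory=lambda: {
            "transporter": 60, "carrier": 42, "enzyme": 81, "target": 120,
        }
    )
    molecule_size_range: tuple = (6, 14)
    label_rule: str = "cluster_pair"  # cluster_pair | metapath | random
    noise_rate: float = 0.05
    descriptor_noise: float | None = None  # per-bit flip prob; noise_rate if None
    pair_density: float = 0.35  # fraction of unordered pairs that interact
    relation_p_in: float = 0.5  # hidden relation: within-community edge prob
    relation_p_out: float = 0.05  # hidden relation: cross-community edge prob
    ring_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.label_rule not in ("cluster_pair", "metapath", "random"):
            raise ValueError(f"unknown label_rule {self.label_rule!r}")


def _random_molecule(rng: np.random.Generator, n_atoms: int,
                     ring_prob: float) -> MolecularGraph:
    symbols = list(rng.choice(list(_ATOM_P), size=n_atoms, p=list(_ATOM_P.values())))
    degree = np.zeros(n_atoms, dtype=int)
    edges = []
    for k in range(1, n_atoms):
        cand = [u for u in range(k) if degree[u] < _VALENCE[symbols[u]]]
        u = int(rng.choice(cand))
        edges.append((u, k))
        degree[u] += 1
        degree[k] += 1
    if n_atoms >= 3 and rng.random() < ring_prob:
        adj = {tuple(sorted(e)) for e in edges}
        spare = [v for v in range(n_atoms) if degree[v] < _VALENCE[symbols[v]]]
        rng.shuffle(spare)
        for a in spare:
            for b in spare:
                if a < b and (a, b) not in adj:
                    edges.append((a, b))
                    degree[a] += 1
                    degree[b] += 1
                    break
            else:
                continue
            break
    return MolecularGraph(symbols, edges, ["single"] * len(edges))


def generate_molecules(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Random small molecules; returns (graphs, smiles), SMILES round-trip safe."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.molecule_size_range
    graphs, smiles = [], []
    for _ in range(spec.n_drugs):
        g = _random_molecule(rng, int(rng.integers(lo, hi + 1)), spec.ring_prob)
        smi = smiles_from_graph(g)
        graph_from_smiles(smi)  # fail fast if not round-trippable
        graphs.append(g)
        smiles.append(smi)
    return graphs, smiles


def assign_clusters(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Balanced latent cluster labels, shuffled."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    clusters = np.arange(spec.n_drugs) % spec.n_clusters
    rng.shuffle(clusters)
    return clusters


def generate_descriptors(spec: SyntheticSpec, clusters: np.ndarray,
                         rng: np.random.Generator | None = None) -> dict:
    """Per entity class: cluster-block bit patterns with noise_rate bit flips."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    out = {}
    for cls in ENTITY_CLASSES:
        L = spec.descriptor_lengths[cls]
        if L < spec.n_clusters:
            raise ValueError(f"descriptor length {L} < n_clusters for {cls!r}")
        block = L // spec.n_clusters
        patterns = np.zeros((spec.n_clusters, L), dtype=np.uint8)
        for c in range(spec.n_clusters):
            patterns[c, c * block:(c + 1) * block] = 1
        bits = patterns[clusters]
        flip_p = spec.noise_rate if spec.descriptor_noise is None else spec.descriptor_noise
        flips = rng.random(bits.shape) < flip_p
        out[cls] = (bits ^ flips).astype(np.uint8)
    return out


def _sample_pairs(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    iu, ju = np.triu_indices(spec.n_drugs, k=1)
    keep = rng.random(iu.size) < spec.pair_density
    return np.stack([iu[keep], ju[keep]], axis=1)


def two_hop_events(relation: np.ndarray, hidden: np.ndarray, pairs: np.ndarray,
                   n_events: int) -> np.ndarray:
    """Noiseless metapath-rule labels for a pair set.

    The event of pair (i, j) is read off its 2-hop co-neighborhood (the set
    of common neighbors) in the hidden relation graph: the two dominant
    hidden communities among the common neighbors are summed modulo
    ``n_events``.  Under a stochastic block model the co-neighborhood of a
    same-community pair is nearly pure (event ~ 2h mod E) and that of a
    cross-community pair is an even mix of the two endpoint communities
    (event ~ (h_i + h_j) mod E), so per-drug label marginals are flat and
    the signal is irreducibly pair-level.  Pairs with no common neighbor
    fall back to ``(i + j) mod n_events``.  Doubles as the brute-force
    2-hop oracle classifier.
    """
    n_com = int(hidden.max()) + 1
    # per-community common-neighbor counts: (R diag(h==c) R)[i,j]
    per_com = np.stack(
        [(relation * (hidden == c)) @ relation for c in range(n_com)]
    )
    i, j = pairs[:, 0], pairs[:, 1]
    counts = per_com[:, i, j]  # (n_com, n_pairs)
    labels = np.empty(len(pairs), dtype=int)
    for k in range(len(pairs)):
        col = counts[:, k]
        if col.sum() == 0:
            labels[k] = (i[k] + j[k]) % n_events
            continue
        order = np.lexsort((np.arange(len(col)), -col))  # count desc, index asc
        c1 = order[0]
        c2 = order[1] if len(col) > 1 and col[order[1]] > 0 else c1
        labels[k] = (c1 + c2) % n_events
    return labels


def generate_events(spec: SyntheticSpec, clusters: np.ndarray,
                    rng: np.random.Generator | None = None):
    """Labeled triples under ``spec.label_rule``; returns (triples, ground_truth)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    pairs = _sample_pairs(spec, rng)
    truth: dict = {"rule": spec.label_rule, "clusters": clusters.tolist()}

    if spec.label_rule == "cluster_pair":
        cluster_pairs = [(a, b) for a in range(spec.n_clusters)
                         for b in range(a, spec.n_clusters)]
        event_of = {cp: k % spec.n_events for k, cp in enumerate(cluster_pairs)}
        ci, cj = clusters[pairs[:, 0]], clusters[pairs[:, 1]]
        labels = np.array([event_of[(min(a, b), max(a, b))] for a, b in zip(ci, cj)])
        truth["event_of_cluster_pair"] = {f"{a},{b}": e for (a, b), e in event_of.items()}
    elif spec.label_rule == "metapath":
        # hidden relation graph: a stochastic block model over hidden
        # communities drawn independently of the descriptor clusters, so the
        # label signal lives purely in the interaction graph structure
        hidden = np.arange(spec.n_drugs) % spec.n_clusters
        rng.shuffle(hidden)
        same = hidden[:, None] == hidden[None, :]
        p_edge = np.where(same, spec.relation_p_in, spec.relation_p_out)
        relation = (rng.random((spec.n_drugs, spec.n_drugs)) < p_edge)
        relation = np.triu(relation, k=1)
        relation = (relation + relation.T).astype(float)
        truth["hidden_communities"] = hidden.tolist()
        # pairs with an empty co-neighborhood carry no 2-hop signal: they
        # simply do not interact in this rule
        nonempty = (relation @ relation)[pairs[:, 0], pairs[:, 1]] > 0
        pairs = pairs[nonempty]
        labels = two_hop_events(relation, hidden, pairs, spec.n_events)
        truth["relation"] = relation.tolist()
    else:  # random
        labels = rng.integers(0, spec.n_events, size=len(pairs))

    noisy = rng.random(len(pairs)) < spec.noise_rate
    labels = np.where(noisy, rng.integers(0, spec.n_events, size=len(pairs)), labels)
    # guarantee every event type occurs at least once
    for e in range(spec.n_events):
        if not np.any(labels == e):
            labels[int(rng.integers(len(labels)))] = e
    triples = [(int(i), int(j), int(e)) for (i, j), e in zip(pairs, labels)]
    truth["seed"] = spec.seed
    return triples, truth


def generate_dataset(spec: SyntheticSpec):
    """Full synthetic :class:`EventDataset` plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    clusters = assign_clusters(spec, rng)
    graphs, smiles = generate_molecules(spec, rng)
    bits = generate_descriptors(spec, clusters, rng)
    triples, truth = generate_events(spec, clusters, rng)
    drugs = [
        DrugRecord(f"SD{k:04d}", smiles[k],
                   {cls: bits[cls][k] for cls in ENTITY_CLASSES})
        for k in range(spec.n_drugs)
    ]
    dataset = EventDataset(drugs, triples, spec.n_events,
                           event_names=list(range(spec.n_events)))
    return dataset, truth


def write_dataset_csvs(outdir, dataset: EventDataset, truth: dict) -> dict:
    """Emit the three standard tables plus a ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"drugs": outdir / "drugs.csv", "events": outdir / "events.csv"}
    pd.DataFrame(
        {"drug_id": [d.drug_id for d in dataset.drugs],
         "smiles": [d.smiles for d in dataset.drugs]}
    ).to_csv(paths["drugs"], index=False)
    for cls in ENTITY_CLASSES:
        mat = dataset.descriptor_matrix(cls)
        df = pd.DataFrame(mat, columns=[f"bit_{k}" for k in range(mat.shape[1])])
        df.insert(0, "drug_id", [d.drug_id for d in dataset.drugs])
        paths[cls] = outdir / f"descriptors_{cls}.csv"
        df.to_csv(paths[cls], index=False)
    pd.DataFrame(
        {"drug_a": [dataset.drugs[i].drug_id for i, _, _ in dataset.triples],
         "drug_b": [dataset.drugs[j].drug_id for _, j, _ in dataset.triples],
         "event": [e for _, _, e in dataset.triples]}
    ).to_csv(paths["events"], index=False)
    paths["truth"] = outdir / "ground_truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
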