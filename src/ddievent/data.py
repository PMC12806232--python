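"""Dataset tables, the heterogeneous DDI graph, and fold management.

Three plain-text tables describe a dataset:

* a drug table (``drug_id``, ``smiles``);
* one binary-descriptor table per bind-protein entity class (transporter,
  carrier, enzyme, target): first column ``drug_id``, remaining columns 0/1;
* an event table of interacting pairs (``drug_a``, ``drug_b``, ``event``).

Event labels are re-coded to dense integers ``0..E-1`` in order of first
appearance.  Pairs are unordered records; both ``(i, j)`` and ``(j, i)`` are
set in the per-event adjacency matrices, and the event subgraphs are built
from *training-fold* triples only so held-out labels cannot leak through the
adjacency stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MolecularGraph, graph_from_smiles

ENTITY_CLASSES: tuple[str, ...] = ("transporter", "carrier", "enzyme", "target")


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    descriptor_bits: dict  # entity class -> 1-D uint8 array of 0/1

    def graph(self) -> MolecularGraph:
        return graph_from_smiles(self.smiles)


@dataclass
class EventDataset:
    """Drugs, their descriptors, and labeled interaction triples."""

    drugs: list  # list[DrugRecord]
    triples: list  # list[(i, j, e)] with i, j drug indices, e in 0..E-1
    n_events: int
    event_names: list = field(default=None)  # original labels, index = code
    fold_of_triple: np.ndarray = None  # int fold id per triple, or None

    def __post_init__(self):
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate drug_id in dataset")
        for cls in ENTITY_CLASSES:
            lengths = {len(d.descriptor_bits[cls]) for d in self.drugs}
            if len(lengths) > 1:
                raise ValueError(f"inconsistent descriptor length for {cls!r}")
        seen = set()
        n = len(self.drugs)
        for i, j, e in self.triples:
            if i == j:
                raise ValueError(f"self-interaction triple for drug index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"triple ({i},{j}) out of drug range")
            if not 0 <= e < self.n_events:
                raise ValueError(f"event {e} outside 0..{self.n_events - 1}")
            if (i, j) in seen:
                raise ValueError(f"duplicate ordered pair ({i},{j}) in event table")
            seen.add((i, j))

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def descriptor_matrix(self, entity_class: str) -> np.ndarray:
        """N_d x L binary matrix for one entity class."""
        return np.stack([d.descriptor_bits[entity_class] for d in self.drugs])

    def train_triples(self, test_fold: int) -> list:
        if self.fold_of_triple is None:
            raise ValueError("folds not assigned")
        return [t for t, f in zip(self.triples, self.fold_of_triple) if f != test_fold]

    def test_triples(self, test_fold: int) -> list:
        if self.fold_of_triple is None:
            raise ValueError("folds not assigned")
        return [t for t, f in zip(self.triples, self.fold_of_triple) if f == test_fold]


@dataclass
class AdjacencyStack:
    """Ordered candidate subgraphs for meta-path learning.

    One symmetric 0/1 matrix per event type, optionally two feature-similarity
    graphs, and the identity matrix ``A_0 = I`` last (self-connectivity enters
    the stack only through it).
    """

    matrices: list  # list of N_d x N_d arrays
    tags: list  # parallel names, e.g. "event_3", "sim_structure", "identity"

    def __post_init__(self):
        if len(self.matrices) != len(self.tags):
            raise ValueError("matrices and tags must be parallel")
        dims = {m.shape for m in self.matrices}
        if len(dims) > 1:
            raise ValueError(f"inconsistent matrix shapes: {dims}")
        (shape,) = dims
        if shape[0] != shape[1]:
            raise ValueError("adjacency matrices must be square")
        for m, tag in zip(self.matrices, self.tags):
            if tag.startswith("event"):
                if not np.array_equal(m, m.T):
                    raise ValueError(f"{tag} not symmetric")
                if not np.isin(m, (0, 1)).all() or np.trace(m) != 0:
                    raise ValueError(f"{tag} must be 0/1 with zero diagonal")
            if tag == "identity" and not np.array_equal(m, np.eye(shape[0])):
                raise ValueError("identity slot is not I")

    def __len__(self):
        return len(self.matrices)

    @property
    def n_drugs(self) -> int:
        return self.matrices[0].shape[0]


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def load_dataset(drug_table_path, descriptor_table_paths: dict, event_table_path) -> EventDataset:
    """Read the three tables into a validated :class:`EventDataset`.

    ``descriptor_table_paths`` maps entity class -> path.  Event labels may be
    arbitrary strings or integers; they are densely re-coded in order of first
    appearance and the original labels kept in ``event_names``.
    """
    drug_df = _read_table(drug_table_path)
    if not {"drug_id", "smiles"} <= set(drug_df.columns):
        raise ValueError("drug table needs columns drug_id, smiles")

    bits_by_class: dict[str, dict[str, np.ndarray]] = {}
    for cls in ENTITY_CLASSES:
        df = _read_table(descriptor_table_paths[cls])
        df = df.set_index(df.columns[0])
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary descriptor entry in {cls!r} table at "
                f"row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        bits_by_class[cls] = {
            str(did): row.astype(np.uint8) for did, row in zip(df.index, values)
        }

    drugs: list[DrugRecord] = []
    bad_smiles: list[str] = []
    for _, row in drug_df.iterrows():
        did, smi = str(row["drug_id"]), str(row["smiles"])
        try:
            graph_from_smiles(smi)
        except ValueError:
            bad_smiles.append(did)
            continue
        desc = {}
        for cls in ENTITY_CLASSES:
            if did not in bits_by_class[cls]:
                raise ValueError(f"drug {did!r} missing from {cls!r} descriptor table")
            desc[cls] = bits_by_class[cls][did]
        drugs.append(DrugRecord(did, smi, desc))
    if bad_smiles:
        raise ValueError(f"unparsable SMILES for drugs: {bad_smiles}")

    index_of = {d.drug_id: k for k, d in enumerate(drugs)}
    event_df = _read_table(event_table_path)
    if not {"drug_a", "drug_b", "event"} <= set(event_df.columns):
        raise ValueError("event table needs columns drug_a, drug_b, event")

    code_of: dict = {}
    event_names: list = []
    triples: list[tuple[int, int, int]] = []
    for _, row in event_df.iterrows():
        a, b = str(row["drug_a"]), str(row["drug_b"])
        for did in (a, b):
            if did not in index_of:
                raise ValueError(f"event table references unknown drug {did!r}")
        ev = row["event"]
        if ev not in code_of:
            code_of[ev] = len(code_of)
            event_names.append(ev)
        triples.append((index_of[a], index_of[b], code_of[ev]))

    return EventDataset(drugs, triples, len(code_of), event_names)


def build_event_subgraphs(dataset: EventDataset, triples=None) -> AdjacencyStack:
    """One symmetric 0/1 adjacency matrix per event type, plus ``A_0 = I``.

    ``triples`` defaults to all of the dataset's triples; pass the training
    fold's triples to keep held-out edges out of the stack.  An event type
    with no triples keeps an all-zero matrix at its slot.
    """
    if triples is None:
        triples = dataset.triples
    n = dataset.n_drugs
    mats = [np.zeros((n, n)) for _ in range(dataset.n_events)]
    for i, j, e in triples:
        mats[e][i, j] = mats[e][j, i] = 1.0
    tags = [f"event_{e}" for e in range(dataset.n_events)]
    mats.append(np.eye(n))
    tags.append("identity")
    return AdjacencyStack(mats, tags)


def assign_folds(dataset: EventDataset, k: int = 5, seed: int = 0) -> EventDataset:
    """Randomly partition the triples (pairs, not drugs) into ``k`` folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(dataset.triples)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available triples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    dataset.fold_of_triple = folds
    return dataset


def write_predictions(path, dataset: EventDataset, pairs, probs: np.ndarray) -> None:
    """Write per-pair event probabilities as CSV (drug_a, drug_b, predicted_event, prob_*)."""
    probs = np.asarray(probs)
    rows = {
        "drug_a": [dataset.drugs[i].drug_id for i, _ in pairs],
        "drug_b": [dataset.drugs[j].drug_id for _, j in pairs],
        "predicted_event": probs.argmax(axis=1),
    }
    for e in range(probs.shape[1]):
        rows[f"prob_{e}"] = probs[:, e]
    pd.DataFrame(rows).to_csv(path, index=False)
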