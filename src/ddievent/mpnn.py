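"""Gated message-passing encoder for drug molecular graphs.

Each molecule is an undirected atom/bond graph.  Atom hidden states start
from a learnable embedding table keyed by element symbol, then ``T`` rounds
of message passing update them:

* message:  m_v = sum_{w in N(v)} W h_w  (one shared matrix per step, or one
  per bond type when ``bond_typed``);
* update:   h~ = h (+) m  (concatenation), then
            h' = C(W_c, h~) * h  +  F(W_f, h~) * m
  with sigmoid carry gate C (keeps the node's own features) and fuse gate F
  (blends in the neighborhood message), in the highway-gate style.

The readout is a soft-attention node sum over [h^0 (+) h^T]:
  E' = sum_v sigmoid(W1 z_v + b1) * tanh(W2 z_v + b2),   z_v = h_v^0 (+) h_v^T,
which is permutation invariant and additive over disjoint node sets.

All molecules in a batch are packed into one block-diagonal graph and pooled
with a molecule-membership matrix, so a whole dataset is encoded with a
handful of dense matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .chem import ATOM_VOCAB, BOND_TYPES, MolecularGraph


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_out, fan_in))


@dataclass
class MPNNParams:
    """Message-passing parameters: per-step message matrices, gates, h^0 table."""

    n_dim: int
    T: int
    message_weights: list  # per step: Tensor (n_dim,n_dim) or {bond_type: Tensor}
    W_c: Tensor  # carry gate, (n_dim, 2 n_dim)
    b_c: Tensor
    W_f: Tensor  # fuse gate
    b_f: Tensor
    embed: Tensor  # atom-type embedding table, (len(ATOM_VOCAB), n_dim)

    @classmethod
    def init(cls, rng: np.random.Generator, n_dim: int, T: int = 3,
             tied: bool = False, bond_typed: bool = False,
             embed_scale: float = 0.1) -> "MPNNParams":
        """``embed_scale`` sets the standard deviation of the random initial
        atom embeddings: small values keep structure embeddings tame so
        descriptor-driven signal dominates early training; values near 1
        make each molecule's embedding a strong node signature, which graph
        propagation can exploit on tasks where only the interaction graph
        is informative."""
        if T < 1:
            raise ValueError("T must be >= 1")

        def one_step():
            if bond_typed:
                return {bt: Tensor(_glorot(rng, n_dim, n_dim), requires_grad=True)
                        for bt in BOND_TYPES}
            return Tensor(_glorot(rng, n_dim, n_dim), requires_grad=True)

        first = one_step()
        weights = [first if tied else one_step() for _ in range(T)]
        if tied:
            weights = [first] * T
        return cls(
            n_dim=n_dim, T=T, message_weights=weights,
            W_c=Tensor(_glorot(rng, n_dim, 2 * n_dim), requires_grad=True),
            b_c=Tensor(np.zeros(n_dim), requires_grad=True),
            W_f=Tensor(_glorot(rng, n_dim, 2 * n_dim), requires_grad=True),
            b_f=Tensor(np.zeros(n_dim), requires_grad=True),
            embed=Tensor(embed_scale * rng.standard_normal((len(ATOM_VOCAB), n_dim)),
                         requires_grad=True),
        )

    def parameters(self) -> list:
        out = []
        seen = set()
        for w in self.message_weights:
            ws = w.values() if isinstance(w, dict) else [w]
            for t in ws:
                if id(t) not in seen:
                    seen.add(id(t))
                    out.append(t)
        out += [self.W_c, self.b_c, self.W_f, self.b_f, self.embed]
        return out


@dataclass
class ReadoutParams:
    """Attentive-readout parameters mapping 2*n_dim -> n_dim twice."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, n_dim: int) -> "ReadoutParams":
        return cls(
            W1=Tensor(_glorot(rng, n_dim, 2 * n_dim), requires_grad=True),
            b1=Tensor(np.zeros(n_dim), requires_grad=True),
            W2=Tensor(_glorot(rng, n_dim, 2 * n_dim), requires_grad=True),
            b2=Tensor(np.zeros(n_dim), requires_grad=True),
        )

    def parameters(self) -> list:
        return [self.W1, self.b1, self.W2, self.b2]


# --------------------------------------------------------------- batch packing

def _adjacency(graph: MolecularGraph) -> np.ndarray:
    A = np.zeros((graph.n_atoms, graph.n_atoms))
    for u, v in graph.edges:
        A[u, v] = A[v, u] = 1.0
    return A


class PackedGraphs:
    """A batch of molecules as one block-diagonal graph.

    ``adjacency`` is the (total_atoms, total_atoms) block matrix (one per bond
    type when typed), ``pool`` the (n_mols, total_atoms) membership matrix
    whose row sums recover per-molecule node sums, and ``atom_types`` the
    embedding-table index per atom.
    """

    def __init__(self, graphs: list, bond_typed: bool = False):
        if any(g.n_atoms == 0 for g in graphs):
            raise ValueError("cannot encode an empty molecular graph")
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        total = offsets[-1]
        self.n_mols = len(graphs)
        self.atom_types = np.concatenate(
            [np.asarray(g.atom_type_indices, dtype=int) for g in graphs]
        )
        self.pool = np.zeros((self.n_mols, total))
        for k in range(self.n_mols):
            self.pool[k, offsets[k]:offsets[k + 1]] = 1.0
        if bond_typed:
            self.adjacency = {bt: np.zeros((total, total)) for bt in BOND_TYPES}
            for k, g in enumerate(graphs):
                bts = g.bond_types or ["single"] * len(g.edges)
                for (u, v), bt in zip(g.edges, bts):
                    A = self.adjacency[bt]
                    A[offsets[k] + u, offsets[k] + v] = 1.0
                    A[offsets[k] + v, offsets[k] + u] = 1.0
        else:
            self.adjacency = np.zeros((total, total))
            for k, g in enumerate(graphs):
                A = _adjacency(g)
                self.adjacency[offsets[k]:offsets[k + 1], offsets[k]:offsets[k + 1]] = A


# ----------------------------------------------------------------- operations

def message_pass(graph, states, W_step) -> Tensor:
    """m_v = sum over neighbors w of W h_w; isolated nodes get zero messages.

    ``graph`` may be a :class:`MolecularGraph` or a precomputed adjacency
    matrix (single-type) / dict of per-bond-type adjacencies.
    """
    states = as_tensor(states)
    if isinstance(graph, MolecularGraph):
        if isinstance(W_step, dict):
            graph = PackedGraphs([graph], bond_typed=True).adjacency
        else:
            graph = _adjacency(graph)
    if isinstance(W_step, dict):
        terms = [(as_tensor(graph[bt]) @ states) @ W_step[bt].T
                 for bt in W_step if np.any(graph[bt])]
        if not terms:
            return states * 0.0
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out
    W_step = as_tensor(W_step)
    if W_step.shape[1] != states.shape[1]:
        raise ValueError("message weight / state dimension mismatch")
    return (as_tensor(graph) @ states) @ W_step.T


def gated_update(states, messages, params: MPNNParams) -> Tensor:
    """Carry/fuse gated state update: h' = C(h~)*h + F(h~)*m."""
    states, messages = as_tensor(states), as_tensor(messages)
    if states.shape != messages.shape:
        raise ValueError("states and messages must align")
    h_tilde = concat([states, messages], axis=1)
    carry = (h_tilde @ params.W_c.T + params.b_c).sigmoid()
    fuse = (h_tilde @ params.W_f.T + params.b_f).sigmoid()
    return carry * states + fuse * messages


def attentive_readout(h0, hT, params: ReadoutParams, pool=None) -> Tensor:
    """Soft-attention node sum over [h^0 (+) h^T].

    With ``pool`` (n_mols, n_atoms) the per-node terms are summed per
    molecule; without it all nodes are summed into a single embedding.
    """
    h0, hT = as_tensor(h0), as_tensor(hT)
    if h0.shape != hT.shape:
        raise ValueError("h0 and hT must cover the same node set")
    if h0.shape[0] == 0:
        raise ValueError("readout of an empty graph")
    z = concat([h0, hT], axis=1)
    att = (z @ params.W1.T + params.b1).sigmoid()
    val = (z @ params.W2.T + params.b2).tanh()
    terms = att * val
    if pool is None:
        return terms.sum(axis=0)
    return as_tensor(pool) @ terms


def encode_structures(graphs: list, params: MPNNParams,
                      readout: ReadoutParams) -> Tensor:
    """Encode a list of molecules into an (n_mols, n_dim) embedding matrix E'."""
    bond_typed = isinstance(params.message_weights[0], dict)
    packed = PackedGraphs(graphs, bond_typed=bond_typed)
    h = params.embed[packed.atom_types]
    h0 = h
    for t in range(params.T):
        m = message_pass(packed.adjacency, h, params.message_weights[t])
        h = gated_update(h, m, params)
    return attentive_readout(h0, h, readout, pool=packed.pool)


def encode_structure(graph: MolecularGraph, params: MPNNParams,
                     readout: ReadoutParams) -> Tensor:
    """Structure embedding E'_i of a single molecule (vector of length n_dim)."""
    return encode_structures([graph], params, readout)[0]
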