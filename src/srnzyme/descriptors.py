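"""Markov-matrix descriptors of a sequence recurrence network.

The binary adjacency α of an SRN is row-normalised into the one-step
stochastic matrix Π with entries

    p_ab = α_ab / Σ_b α_ab ,

the probability of a random walker stepping from node a to node b.  Two
descriptor families are computed from Π:

* trace descriptors  Tr_k = trace(Π^k), the total k-step return probability
  summed over nodes (dimensionless; "order" k = 3 and 5 by default);
* Markov–Shannon entropies  θ_k = −Σ_a π_k(a) ln π_k(a)  (nats), where
  π_k = π_0 Π^k is the node-occupancy distribution after k steps from the
  uniform start π_0 = (1/n, …, 1/n).

Traces may alternatively be taken on the raw adjacency matrix
(``matrix_kind="adjacency"``), in which case Tr_k counts closed k-walks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import ProteinSequence
from .srn import RecurrenceNetwork, build_srn

DEFAULT_ORDERS: tuple[int, ...] = (3, 5)


@dataclass
class StochasticMatrix:
    """Row-stochastic walk matrix of an SRN (plus its source adjacency)."""

    p: np.ndarray
    adjacency: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.p.shape[0]

    def occupancy(self, k: int) -> np.ndarray:
        """π_k = π_0 Π^k with the uniform start π_0 = (1/n, …, 1/n)."""
        if k < 0:
            raise ValueError("k must be non-negative")
        pi = np.full(self.n, 1.0 / self.n)
        for _ in range(k):
            pi = pi @ self.p
        return pi


@dataclass
class DescriptorVector:
    """Per-sequence trace (Tr_k) and entropy (θ_k) descriptor values."""

    sequence_id: str
    tr: dict[int, float]
    theta: dict[int, float]

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for k in sorted(self.tr):
            row[f"Tr{k}"] = self.tr[k]
        for k in sorted(self.theta):
            row[f"Theta{k}"] = self.theta[k]
        return row


def to_stochastic(net: RecurrenceNetwork) -> StochasticMatrix:
    """Row-normalise the SRN adjacency into the stochastic matrix Π."""
    adj = net.adjacency.astype(float)
    degrees = adj.sum(axis=1)
    if np.any(degrees == 0):
        isolated = [net.node_ids[i] for i in np.nonzero(degrees == 0)[0]]
        raise ValueError(
            f"SRN of {net.sequence_id!r} has isolated node(s) {isolated}; "
            "cannot normalise rows"
        )
    return StochasticMatrix(p=adj / degrees[:, None], adjacency=net.adjacency.copy())


def trace_descriptor(
    sm: StochasticMatrix, k: int, matrix_kind: str = "stochastic"
) -> float:
    """Tr_k = trace of the k-th power of the walk matrix.

    ``matrix_kind="stochastic"`` (default) uses Π; ``"adjacency"`` uses the
    binary α, so Tr_k counts closed k-walks.  k = 0 degenerately returns n
    (trace of the identity) with a warning.
    """
    if k < 0:
        raise ValueError("order k must be non-negative")
    if matrix_kind == "stochastic":
        m = sm.p
    elif matrix_kind == "adjacency":
        m = sm.adjacency.astype(float)
    else:
        raise ValueError(f"unknown matrix_kind {matrix_kind!r}")
    if k == 0:
        warnings.warn("Tr_0 is the trace of the identity (= n); degenerate order")
        return float(sm.n)
    return float(np.trace(np.linalg.matrix_power(m, k)))


def shannon_entropy(sm: StochasticMatrix, k: int, base: float | None = None) -> float:
    """Markov–Shannon entropy θ_k of the k-step occupancy distribution.

    θ_k = −Σ_a π_k(a) log π_k(a); zero-probability terms contribute 0.
    Natural log (nats) by default; pass ``base`` for another unit.
    """
    pi = sm.occupancy(k)
    nz = pi[pi > 0]
    theta = float(-(nz * np.log(nz)).sum())
    if base is not None:
        theta /= math.log(base)
    return theta


def compute_descriptors(
    seq: ProteinSequence,
    orders: tuple[int, ...] = DEFAULT_ORDERS,
    include_dummy: bool = True,
    matrix_kind: str = "stochastic",
) -> DescriptorVector:
    """Build the SRN of one sequence and evaluate Tr_k and θ_k for each order."""
    net = build_srn(seq, include_dummy=include_dummy)
    sm = to_stochastic(net)
    tr = {k: trace_descriptor(sm, k, matrix_kind=matrix_kind) for k in orders}
    theta = {k: shannon_entropy(sm, k) for k in orders}
    return DescriptorVector(sequence_id=seq.id, tr=tr, theta=theta)


def descriptor_table(
    seqs: list[ProteinSequence],
    orders: tuple[int, ...] = DEFAULT_ORDERS,
    include_dummy: bool = True,
    matrix_kind: str = "stochastic",
) -> pd.DataFrame:
    """Descriptor rows for a batch of sequences.

    Returns a DataFrame with a ``sequence_id`` column followed by ``Tr{k}``
    then ``Theta{k}`` columns in ascending order of k; deterministic and one
    row per input sequence.  Per-sequence failures are re-raised with the
    offending sequence id.
    """
    if not seqs:
        raise ValueError("descriptor_table requires at least one sequence")
    rows = []
    for seq in seqs:
        try:
            vec = compute_descriptors(
                seq, orders=orders, include_dummy=include_dummy, matrix_kind=matrix_kind
            )
        except Exception as exc:
            raise type(exc)(f"sequence {seq.id!r}: {exc}") from exc
        rows.append({"sequence_id": seq.id, **vec.as_row()})
    columns = (
        ["sequence_id"]
        + [f"Tr{k}" for k in sorted(orders)]
        + [f"Theta{k}" for k in sorted(orders)]
    )
    return pd.DataFrame(rows, columns=columns)
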