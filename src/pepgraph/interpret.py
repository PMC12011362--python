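"""Attention-derived interpretability statistics.

Residue importance sums encoder attention received by each position
(d_j = Σ_i β_ij).  Node connection symmetrizes GAT attention
(r_ij = γ_ij + γ_ji).  Function correlation counts, over samples and
attention matrices, which off-diagonal label pair carries the maximum
node connection — concentrating on genuinely co-occurring label pairs in
a well-trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphnet import GraphNodeClassifier


class InterpretError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueImportance:
    d: np.ndarray  # length-L importance per position
    layer: int | None = None
    head: int | None = None


@dataclass(frozen=True)
class NodeConnectionMatrix:
    r: np.ndarray  # M x M symmetric
    layer: int | None = None
    head: int | None = None


@dataclass(frozen=True)
class FunctionCorrelationCounts:
    counts: np.ndarray  # M x M symmetric, fractional under ties
    labels: tuple[str, ...]

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    def top_pair(self) -> tuple[str, str]:
        """The off-diagonal label pair with the largest count."""
        c = self.counts.copy()
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        return self.labels[min(i, j)], self.labels[max(i, j)]


def residue_importance(beta: np.ndarray, layer: int | None = None,
                       head: int | None = None) -> ResidueImportance:
    """d_j = Σ_i β_ij (column sums of one attention map)."""
    beta = np.asarray(beta, dtype=np.float64)
    if beta.ndim != 2 or beta.shape[0] != beta.shape[1]:
        raise InterpretError(f"attention map must be square, got {beta.shape}")
    return ResidueImportance(d=beta.sum(axis=0), layer=layer, head=head)


def node_connection(gamma: np.ndarray, layer: int | None = None,
                    head: int | None = None) -> NodeConnectionMatrix:
    """r = γ + γᵀ."""
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise InterpretError(f"attention matrix must be square, got {gamma.shape}")
    return NodeConnectionMatrix(r=gamma + gamma.T, layer=layer, head=head)


def argmax_pairs(r: np.ndarray, tol: float = 1e-12) -> list[tuple[int, int]]:
    """Off-diagonal maxima of a symmetric matrix; all ties returned.

    Self-connections (the diagonal) are not function pairs and are
    excluded from the search.
    """
    masked = np.asarray(r, dtype=np.float64).copy()
    np.fill_diagonal(masked, -np.inf)
    best = masked.max()
    return [
        (i, j)
        for i in range(r.shape[0])
        for j in range(i + 1, r.shape[1])
        if masked[i, j] >= best - tol
    ]


def accumulate_argmax_pair(counts: np.ndarray, r: np.ndarray) -> None:
    """Add one attention matrix's argmax pair to ``counts`` (in place).

    Ties split the unit of count mass fractionally (1/n_ties per tied
    pair), keeping the total off-diagonal mass exactly 2 per matrix.
    """
    pairs = argmax_pairs(r)
    w = 1.0 / len(pairs)
    for i, j in pairs:
        counts[i, j] += w
        counts[j, i] += w


def function_correlation(inputs, model: GraphNodeClassifier,
                         selection=None) -> FunctionCorrelationCounts:
    """Count argmax node-connection pairs over samples x attention matrices.

    ``selection`` is an optional iterable of (layer, head) pairs; by
    default every GAT layer/head the model traces is used.  Ties at the
    maximum are split fractionally (1/n_ties to each tied pair), keeping
    the total off-diagonal mass at 2 x n_samples x n_matrices exactly.
    """
    M = model.label_space.M
    if M < 2:
        raise InterpretError("need at least 2 labels for pairwise correlation")
    _, tr = model.forward_batch(inputs, training=False, trace=True)
    gammas = tr["gamma"]  # list over layers of (B, K, M, M)
    if not gammas:
        raise InterpretError("model traced no GAT attention (GAT disabled?)")
    if selection is None:
        selection = [
            (li, k) for li, g in enumerate(gammas) for k in range(g.shape[1])
        ]
    counts = np.zeros((M, M))
    n_inputs = gammas[0].shape[0]
    for b in range(n_inputs):
        for li, k in selection:
            accumulate_argmax_pair(counts, node_connection(gammas[li][b, k]).r)
    return FunctionCorrelationCounts(counts=counts, labels=model.label_space.names)


def importance_track(sequence: str, model: GraphNodeClassifier,
                     layer: int = -1, head: int | None = None) -> np.ndarray:
    """Residue importance for one sequence from the encoder's attention.

    Averages d_j over heads of the chosen layer unless ``head`` is given;
    special (start/end) token positions are stripped so the track aligns
    with the residue sequence.
    """
    _, tr = model.forward_batch([sequence], training=False, trace=True)
    betas = tr["beta"]
    if not betas:
        raise InterpretError("encoder does not produce attention maps")
    maps = betas[layer][0]  # (H, L, L)
    if head is not None:
        maps = maps[head][None]
    d = np.stack([residue_importance(m).d for m in maps]).mean(axis=0)
    return d[1 : 1 + len(sequence)]


def export_connection_matrix(matrix: NodeConnectionMatrix, labels, path) -> None:
    pd.DataFrame(matrix.r, index=list(labels), columns=list(labels)).to_csv(path)


def export_importance_track(sequence: str, d: np.ndarray, path) -> None:
    pd.DataFrame({
        "position": np.arange(1, len(sequence) + 1),
        "residue": list(sequence),
        "importance": d,
    }).to_csv(path, index=False)
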