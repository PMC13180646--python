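"""Markov transition structure of courtship sequences.

Transition-count matrices over composite behavioral states, permutation
screening for nonrandom transitions, and Dirichlet-smoothed Kullback–Leibler
divergences between individual courtship chains.

The permutation null shuffles the order of states independently within each
sequence (preserving per-sequence state multisets) and recounts; a cell's
one-sided p-value is ``(1 + #{permuted >= observed}) / (B + 1)``.  Edges with
``p <= alpha`` form the "significant transition" network.

KL divergence between two count vectors y1, y2 with pseudocount ``a`` uses
the Dirichlet-smoothed frequencies ``(y + a) / (n + a*S)`` and natural logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class TransitionCountMatrix:
    """S x S transition counts over an ordered state list."""

    states: list[str]
    counts: np.ndarray  # (S, S) int
    scope: str = "individual"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        S = len(self.states)
        if self.counts.shape != (S, S):
            raise ValueError("counts shape does not match state list")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.states, columns=self.states)

    def flatten(self) -> np.ndarray:
        """Row-major S^2 count vector (canonical vectorization)."""
        return self.counts.ravel().astype(float)


@dataclass
class TransitionNetwork:
    """Permutation-screened transition network.

    ``edges`` has columns source, target, count, probability (count / row
    total of the source state), p_value; ``centrality`` is the percentage of
    all state occurrences contributed by each state (the node-size statistic
    of the display networks).
    """

    states: list[str]
    edges: pd.DataFrame
    centrality: pd.Series
    alpha: float
    n_perm: int
    p_values: pd.DataFrame = field(repr=False, default=None)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for s in self.states:
            g.add_node(s, centrality_pct=float(self.centrality.get(s, 0.0)))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source, row.target,
                count=int(row.count), probability=float(row.probability),
                p_value=float(row.p_value),
            )
        return g

    def write_graphml(self, path):
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def _encode(sequences: Iterable[Sequence[str]], states: list[str] | None):
    seqs = [list(s) for s in sequences]
    if states is None:
        states = sorted({x for s in seqs for x in s})
    index = {s: i for i, s in enumerate(states)}
    try:
        coded = [np.array([index[x] for x in s], dtype=np.intp) for s in seqs]
    except KeyError as exc:
        raise ValueError(f"state {exc.args[0]!r} not in the shared state universe") from exc
    return states, coded


def count_transitions(
    sequences: Iterable[Sequence[str]],
    states: list[str] | None = None,
    scope: str = "population",
) -> TransitionCountMatrix:
    """Tally first-order transitions within each sequence, aggregated.

    Each sequence contributes its adjacent pairs; sequences are never
    concatenated across individuals, so the result is invariant to their
    order.
    """
    states, coded = _encode(sequences, states)
    S = len(states)
    counts = np.zeros(S * S, dtype=np.int64)
    any_transition = False
    for seq in coded:
        if len(seq) < 2:
            continue
        any_transition = True
        counts += np.bincount(seq[:-1] * S + seq[1:], minlength=S * S)
    if not any_transition:
        warnings.warn("no sequence contains two or more states; all-zero matrix")
    return TransitionCountMatrix(states, counts.reshape(S, S), scope=scope)


def per_individual_matrices(
    sequences: Mapping[str, Iterable[Sequence[str]]],
    states: list[str],
) -> dict[str, TransitionCountMatrix]:
    """One aggregated matrix per individual (key), on a shared state order."""
    return {
        ind: count_transitions(seqs, states=states, scope="individual")
        for ind, seqs in sequences.items()
    }


def permutation_edge_test(
    sequences: Iterable[Sequence[str]],
    states: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> TransitionNetwork:
    """Screen transitions more frequent than expected under within-sequence
    order shuffles.

    Returns the network of edges with ``p <= alpha`` among observed cells
    (count > 0).  ``n_perm`` below 100 is refused: the resulting p-values
    would be too unstable to threshold.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    states, coded = _encode(sequences, states)
    S = len(states)

    observed = np.zeros(S * S, dtype=np.int64)
    for seq in coded:
        if len(seq) >= 2:
            observed += np.bincount(seq[:-1] * S + seq[1:], minlength=S * S)

    perm_counts = np.zeros((n_perm, S * S), dtype=np.int64)
    offsets = np.arange(n_perm, dtype=np.intp)[:, None] * (S * S)
    for seq in coded:
        L = len(seq)
        if L < 2:
            continue
        order = np.argsort(rng.random((n_perm, L)), axis=1)
        perm = seq[order]
        flat = (offsets + perm[:, :-1] * S + perm[:, 1:]).ravel()
        perm_counts += np.bincount(flat, minlength=n_perm * S * S).reshape(
            n_perm, S * S
        )

    geq = (perm_counts >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + geq) / (n_perm + 1.0)

    occ = np.zeros(S, dtype=np.int64)
    for seq in coded:
        occ += np.bincount(seq, minlength=S)
    total_occ = occ.sum()
    centrality = pd.Series(
        100.0 * occ / total_occ if total_occ else np.zeros(S), index=states,
        name="centrality_pct",
    )

    obs = observed.reshape(S, S)
    p = pvals.reshape(S, S)
    row_tot = obs.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(row_tot > 0, obs / np.maximum(row_tot, 1), 0.0)
    src, dst = np.nonzero((obs > 0) & (p <= alpha))
    edges = pd.DataFrame(
        {
            "source": [states[i] for i in src],
            "target": [states[j] for j in dst],
            "count": obs[src, dst],
            "probability": prob[src, dst],
            "p_value": p[src, dst],
        }
    ).sort_values(["source", "target"], ignore_index=True)
    p_frame = pd.DataFrame(p, index=states, columns=states).where(obs > 0)
    return TransitionNetwork(states, edges, centrality, alpha, n_perm, p_frame)


def kl_dirichlet(y1, y2, a: float = 1.0) -> float:
    """KL divergence (nats) between Dirichlet-smoothed count vectors.

    ``p_i = (y1_i + a) / (n1 + a*S)`` against ``q_i`` likewise; returns
    ``sum p_i * ln(p_i / q_i)``.  Always >= 0; 0 iff the smoothed
    distributions coincide.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if y1.size < 2:
        raise ValueError("need at least two categories")
    if (y1 < 0).any() or (y2 < 0).any():
        raise ValueError("negative counts")
    if a <= 0:
        raise ValueError("pseudocount must be positive")
    S = y1.size
    p = (y1 + a) / (y1.sum() + a * S)
    q = (y2 + a) / (y2.sum() + a * S)
    return float(np.sum(p * np.log(p / q)))


def pairwise_courtship_distances(
    matrices: Mapping[str, TransitionCountMatrix],
    pseudocount: float = 1.0,
    symmetrize: bool = False,
) -> pd.DataFrame:
    """KL divergence between every ordered pair of individuals' vectorized
    transition-count matrices.

    Row i, column j holds KL(i -> j); the matrix is generally asymmetric
    unless ``symmetrize`` (mean of both directions) is requested.  Diagonal
    is 0.
    """
    ids = list(matrices)
    if len(ids) < 2:
        raise ValueError("need at least two individuals")
    ref = matrices[ids[0]].states
    for ind in ids[1:]:
        if matrices[ind].states != ref:
            raise ValueError(f"state order of {ind!r} differs from {ids[0]!r}")
    vecs = {i: matrices[i].flatten() for i in ids}
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in ids:
        for j in ids:
            if i != j:
                D.loc[i, j] = kl_dirichlet(vecs[i], vecs[j], pseudocount)
    if symmetrize:
        D = (D + D.T) / 2.0
    return D


def population_divergence_summary(
    distances: pd.DataFrame,
    populations: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Mean within- and between-population courtship divergences with SE.

    Divergences are symmetrized per unordered individual pair (mean of both
    KL directions) before pooling.  Within-population means exclude
    self-comparisons; a population with a single individual reports NaN.
    """
    populations = pd.Series(populations)
    missing = [i for i in distances.index if i not in populations.index]
    if missing:
        raise ValueError(f"individuals without a population: {missing}")
    sym = (distances + distances.T) / 2.0
    pops = sorted(populations.loc[distances.index].unique())
    rows = []
    for ai, a in enumerate(pops):
        for b in pops[ai:]:
            ia = [i for i in distances.index if populations[i] == a]
            ib = [i for i in distances.index if populations[i] == b]
            if a == b:
                vals = np.array(
                    [sym.loc[x, y] for k, x in enumerate(ia) for y in ia[k + 1:]]
                )
            else:
                vals = sym.loc[ia, ib].to_numpy().ravel()
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "kind": "within" if a == b else "between",
                    "n_pairs": len(vals),
                    "mean_kl": vals.mean() if len(vals) else np.nan,
                    "se_kl": (
                        vals.std(ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def interleave_pair_sequences(male: "StateSequence", female: "StateSequence"):
    """Merge the two actors' state sequences of one pair by onset time.

    Sentinels are collapsed to a single bout-start / bout-end for the merged
    chain.  This is the alternative counting mode in which male and female
    states form one chain per courting pair.
    """
    timed = [
        (iv[0], lab)
        for seq in (male, female)
        for lab, iv in zip(seq.states, seq.intervals)
        if iv is not None
    ]
    timed.sort(key=lambda t: t[0])
    labels = [lab for _, lab in timed]
    merged = [x for k, x in enumerate(labels) if k == 0 or labels[k - 1] != x]
    start = male.states[0]
    end = male.states[-1]
    return [start] + merged + [end]
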