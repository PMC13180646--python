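"""Independent brute-force reference implementations used only by tests.

Each function recomputes a quantity by direct enumeration or explicit
summation, deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def grid_state_labels(events, pair_id, actor, dt, t_max, bout_start, bout_end):
    """Composite-state sequence by per-grid-point labeling.

    Samples the timeline at midpoints of consecutive grid steps of width
    ``dt`` (events must lie on a coarser lattice), labels each point by the
    sorted active behavior set, collapses runs, and adds sentinels.
    """
    sub = events[(events["pair_id"] == pair_id) & (events["actor"] == actor)]
    labels = []
    t = dt / 2.0
    while t < t_max:
        active = sorted({
            b
            for b, s, e in zip(sub["behavior"], sub["start_s"], sub["end_s"])
            if s < t < e
        })
        labels.append("-".join(active) + f"-({actor})" if active else None)
        t += dt
    # inactive gaps carry no state: drop them, then collapse runs (the
    # no-self-transition convention merges identical states across a gap)
    active_only = [k for k in labels if k is not None]
    collapsed = [k for k, _ in itertools.groupby(active_only)]
    return [bout_start] + collapsed + [bout_end]


def count_transitions_naive(sequences):
    """Adjacent-pair tally as a plain dict {(src, dst): count}."""
    tally = {}
    for seq in sequences:
        for a, b in zip(seq[:-1], seq[1:]):
            tally[(a, b)] = tally.get((a, b), 0) + 1
    return tally


def kosman_naive(g1, g2):
    """Mean per-locus unshared-allele fraction over jointly typed loci."""
    num, den = 0.0, 0
    for a, b in zip(g1, g2):
        if np.isnan(a) or np.isnan(b):
            continue
        shared = min(a, b) + min(2 - a, 2 - b)  # shared alleles of 2
        num += 1.0 - shared / 2.0
        den += 1
    return num / den if den else np.nan


def nei_naive(p1, p2):
    """Nei (1972) standard distance from alt-allele frequency vectors."""
    jx = sum(p**2 + (1 - p) ** 2 for p in p1)
    jy = sum(p**2 + (1 - p) ** 2 for p in p2)
    jxy = sum(a * b + (1 - a) * (1 - b) for a, b in zip(p1, p2))
    if jxy == 0:
        return np.inf
    return -np.log(jxy / np.sqrt(jx * jy))


def amova_naive(genotypes, groups):
    """Three-stratum AMOVA by explicit allele-copy expansion.

    ``genotypes``: (N, L) int array without missing data.  Each individual
    becomes two haploid copies (het loci split 1/0; the split is arbitrary
    because all sums of squares run over every copy pair of a group).
    Returns sums of squares (per-locus scale, i.e. divided by L) and
    variance components.
    """
    g = np.asarray(genotypes, dtype=int)
    N, L = g.shape
    copies = np.zeros((2 * N, L))
    for i in range(N):
        for l in range(L):
            if g[i, l] == 2:
                copies[2 * i, l] = copies[2 * i + 1, l] = 1
            elif g[i, l] == 1:
                copies[2 * i, l] = 1

    def ss_group(copy_idx):
        tot = 0.0
        for a, b in itertools.combinations(copy_idx, 2):
            tot += np.sum((copies[a] - copies[b]) ** 2)
        return tot / len(copy_idx)

    all_idx = list(range(2 * N))
    ss_total = ss_group(all_idx)
    ss_wi = sum(ss_group([2 * i, 2 * i + 1]) for i in range(N))
    labels = sorted(set(groups))
    ss_pop = 0.0
    sizes = []
    for lab in labels:
        idx = [i for i in range(N) if groups[i] == lab]
        sizes.append(len(idx))
        ss_pop += ss_group([c for i in idx for c in (2 * i, 2 * i + 1)])
    ss_ai = ss_pop - ss_wi
    ss_ap = ss_total - ss_pop

    r = len(labels)
    df_ap, df_ai, df_wi = r - 1, N - r, N
    ms_ap, ms_ai, ms_wi = ss_ap / df_ap, ss_ai / df_ai, ss_wi / df_wi
    sizes = np.array(sizes, float)
    n0 = (2 * N - np.sum((2 * sizes) ** 2) / (2 * N)) / (r - 1)
    sigma_c = ms_wi
    sigma_b = (ms_ai - sigma_c) / 2
    sigma_a = (ms_ap - sigma_c - 2 * sigma_b) / n0
    scale = 1.0 / L  # package works on per-locus-averaged distances
    return {
        "ss": {"among_pops": ss_ap * scale, "among_ind_within": ss_ai * scale,
               "within_ind": ss_wi * scale},
        "sigma": {"among_pops": sigma_a * scale, "among_ind_within": sigma_b * scale,
                  "within_ind": sigma_c * scale},
    }


def wc_theta_naive(genos_by_pop):
    """Multilocus Weir–Cockerham theta from per-population genotype lists.

    ``genos_by_pop``: list of (n_i, L) int arrays, complete data.  Scalar
    per-locus loop over the textbook component formulas.
    """
    r = len(genos_by_pop)
    L = genos_by_pop[0].shape[1]
    num = den = 0.0
    for l in range(L):
        n = [g.shape[0] for g in genos_by_pop]
        p = [g[:, l].mean() / 2.0 for g in genos_by_pop]
        h = [(g[:, l] == 1).mean() for g in genos_by_pop]
        nbar = sum(n) / r
        nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def mantel_exact_p(d1, d2):
    """Exact one-sided Mantel p by full enumeration of row permutations."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    x = d1[iu]
    r_obs = np.corrcoef(x, d2[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        y = d2[np.ix_(perm, perm)][iu]
        r = np.corrcoef(x, y)[0, 1]
        hits += r >= r_obs - 1e-12
        total += 1
    return r_obs, hits / total


def alternating_exceedance(seq, src, dst):
    """Exact P(count(src->dst) >= observed) under uniform order shuffles."""
    obs = sum(1 for a, b in zip(seq[:-1], seq[1:]) if (a, b) == (src, dst))
    hits = total = 0
    for perm in itertools.permutations(seq):
        c = sum(1 for a, b in zip(perm[:-1], perm[1:]) if (a, b) == (src, dst))
        hits += c >= obs
        total += 1
    return Fraction(hits, total)
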