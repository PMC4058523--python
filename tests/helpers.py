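"""Independent oracles and small builders shared across the test suite.

Everything here is deliberately naive (enumeration, O(n²) counting,
rejection sampling) and independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pomanet import InteractionEdgeList, RegulatorySubnetwork, build_subnetwork


def make_net(edges, rho=-0.8, p=1e-3) -> RegulatorySubnetwork:
    """Build a RegulatorySubnetwork directly from an edge list."""
    pairs = pd.DataFrame(
        [{"mirna_id": m, "gene_id": g, "rho": rho, "p_value": p} for m, g in edges]
    )
    return build_subnetwork(pairs, InteractionEdgeList(set(edges)))


def split_oracle(values):
    """Exhaustive enumeration of every contiguous split of the sorted vector;
    returns (k, cost) with smallest-k tie-breaking."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def ss(block):
        m = sum(block) / len(block)
        return sum((v - m) ** 2 for v in block)

    best_k, best_cost = None, None
    for k in range(1, n):
        cost = ss(xs[:k]) + ss(xs[k:])
        if best_cost is None or cost < best_cost - 1e-12:
            best_k, best_cost = k, cost
    return best_k, best_cost


def auc_pair_oracle(scores, is_case) -> float:
    """O(n²) concordant/discordant/tied pair counting (midrank ties)."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    case = scores[is_case]
    ctrl = scores[~is_case]
    total = 0.0
    for c in case:
        for d in ctrl:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(case) * len(ctrl))


def exact_spearman_p(x, y) -> float:
    """Two-sided exact p by full enumeration of rank permutations of y,
    written independently of the package (itertools-free, recursive heap)."""
    from itertools import permutations

    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho_of(r1, r2):
        r1 = np.asarray(r1, float)
        r2 = np.asarray(r2, float)
        a = r1 - r1.mean()
        b = r2 - r2.mean()
        return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))

    obs = abs(rho_of(rx, ry))
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(rho_of(rx, perm)) >= obs - 1e-12:
            count += 1
    return count / total


def stub_shuffle_alpha_samples(net: RegulatorySubnetwork, n_samples: int, seed: int):
    """Configuration-model sampler of the degree-fixed bipartite null:
    permute gene stubs against miRNA stubs, rejecting multigraphs.

    Returns (mirna_ids, samples) with samples an (n_samples, n_mirna) array
    of alpha values — an independent second implementation of the
    degree-preserving null used for alpha significance.
    """
    rng = np.random.default_rng(seed)
    mirnas = sorted(net.mirnas)
    genes = sorted(net.genes)
    m_index = {m: i for i, m in enumerate(mirnas)}
    g_index = {g: j for j, g in enumerate(genes)}
    edges = sorted(net.edges)
    m_stubs = np.array([m_index[m] for m, _ in edges])
    g_stubs = np.array([g_index[g] for _, g in edges])
    n_gene = len(genes)

    out = np.zeros((n_samples, len(mirnas)), dtype=int)
    got = 0
    while got < n_samples:
        perm = rng.permutation(len(g_stubs))
        gp = g_stubs[perm]
        pair_ids = m_stubs * n_gene + gp
        if len(np.unique(pair_ids)) != len(pair_ids):
            continue  # multi-edge: reject
        indeg = np.bincount(gp, minlength=n_gene)
        exclusive = indeg[gp] == 1
        out[got] = np.bincount(m_stubs[exclusive], minlength=len(mirnas))
        got += 1
    return mirnas, out
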