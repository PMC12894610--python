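"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementation paths they check: NMI by an
explicit double loop over contingency cells, complete linkage by greedy
agglomeration with all pairwise maximum distances recomputed from scratch at
every step, and univariate R² via sklearn.
"""

import math

import numpy as np


def nmi_bruteforce(counts) -> float:
    counts = np.asarray(counts, float)
    n = counts.sum()
    r, c = counts.shape
    row = [counts[i, :].sum() for i in range(r)]
    col = [counts[:, j].sum() for j in range(c)]
    hr = -sum((x / n) * math.log(x / n) for x in row if x > 0)
    hc = -sum((x / n) * math.log(x / n) for x in col if x > 0)
    if hr == 0 or hc == 0:
        return 0.0
    mi = 0.0
    for i in range(r):
        for j in range(c):
            if counts[i, j] > 0:
                pij = counts[i, j] / n
                mi += pij * math.log(pij / ((row[i] / n) * (col[j] / n)))
    return 2.0 * mi / (hr + hc)


def complete_linkage_bruteforce(X, k):
    """Greedy complete-linkage agglomeration, distances recomputed each step.

    Returns 0-based cluster codes in order of first appearance, matching the
    implementation's relabeling convention.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        best_d = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.linalg.norm(X[i] - X[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d < best_d - 1e-12:
                    best_d = d
                    best = (a, b)
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, int)
    for idx, members in enumerate(clusters):
        for i in members:
            labels[i] = idx
    # relabel in order of first appearance
    seen = {}
    out = np.empty(n, int)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def partition_sets(labels):
    """Cluster memberships as a set of frozensets (label-invariant)."""
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == v).tolist()) for v in np.unique(labels)}
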