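"""Cluster-structure evaluation of classifier outputs.

Pipeline: z-score the five probability features, cut a complete-linkage
hierarchical tree at k clusters, and quantify agreement with the validated
emotion categories by normalized mutual information,

    NMI = 2 * MI(truth, clusters) / (H(truth) + H(clusters)),

with natural-log entropies (arithmetic-mean normalization; NMI is then
base-invariant). NMI is 0 when either partition is a single cluster and 1
when the partitions coincide.

Representations are compared with a permutation test: both clusterings are
held fixed, the truth labels are jointly permuted, and the one-sided p-value
for the observed NMI difference is (1 + #{permuted >= observed}) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError
from .io import CATEGORIES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ClusteringResult:
    assignments: np.ndarray  # 0-based cluster index per item
    k: int
    linkage: str = "complete"
    nmi: float | None = None


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # truth-category x cluster, nonnegative ints
    row_labels: tuple  # truth categories
    col_labels: tuple  # cluster ids

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=list(self.row_labels),
            columns=[f"cluster_{c}" for c in self.col_labels],
        )
        df.index.name = "category"
        return df


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    permuted_mean: float
    permuted_sd: float
    permuted_max: float


@dataclass(frozen=True)
class MajorityLabels:
    mapping: dict  # cluster id -> modal category
    tied_clusters: tuple  # cluster ids whose modal category was tied


# ---------------------------------------------------------------------------
# operations


def zscore_columns(features) -> np.ndarray:
    """Standardize each column to mean 0, sample sd 1 (n-1 denominator)."""
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"zero-variance column(s): {zero.tolist()}")
    return (X - X.mean(axis=0)) / sd


def complete_linkage_cluster(features, k: int) -> ClusteringResult:
    """Cut a complete-linkage tree (Euclidean distances) at k clusters."""
    X = np.asarray(features, float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValidationError(f"k={k} outside [2, n={n}]")
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0-based codes in order of first appearance (determinism)
    _, assignments = np.unique(raw, return_inverse=True)
    order = {}
    remap = np.empty(assignments.max() + 1, int)
    nxt = 0
    for a in assignments:
        if a not in order:
            order[a] = nxt
            remap[a] = nxt
            nxt += 1
    return ClusteringResult(assignments=remap[assignments], k=k)


def contingency(assignments, truth) -> ContingencyTable:
    """Co-occurrence counts of truth categories (rows) vs. clusters (columns)."""
    a = np.asarray(assignments)
    t = np.asarray(truth)
    if a.shape != t.shape:
        raise ValidationError("assignments and truth must have equal length")
    row_labels, t_codes = np.unique(t, return_inverse=True)
    # keep the canonical category order when truth uses the canonical tokens
    if set(row_labels) <= set(CATEGORIES):
        ordered = tuple(c for c in CATEGORIES if c in set(row_labels))
        lut = {c: i for i, c in enumerate(ordered)}
        t_codes = np.array([lut[x] for x in t])
        row_labels = np.array(ordered)
    col_labels, a_codes = np.unique(a, return_inverse=True)
    counts = np.zeros((len(row_labels), len(col_labels)), int)
    np.add.at(counts, (t_codes, a_codes), 1)
    return ContingencyTable(
        counts=counts, row_labels=tuple(row_labels), col_labels=tuple(col_labels)
    )


def _nmi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n < 1:
        raise ValidationError("contingency total must be >= 1")
    pr = counts.sum(axis=1) / n
    pc = counts.sum(axis=0) / n
    hr = -np.sum(pr[pr > 0] * np.log(pr[pr > 0]))
    hc = -np.sum(pc[pc > 0] * np.log(pc[pc > 0]))
    if hr == 0.0 or hc == 0.0:
        return 0.0  # single-cluster convention
    p = counts / n
    mask = p > 0
    outer = pr[:, None] * pc[None, :]
    mi = np.sum(p[mask] * np.log(p[mask] / outer[mask]))
    return float(min(max(2.0 * mi / (hr + hc), 0.0), 1.0))


def nmi(table) -> float:
    """Normalized mutual information of a contingency table, in [0, 1]."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, float)
    if (counts < 0).any():
        raise ValidationError("contingency counts must be nonnegative")
    return _nmi_from_counts(counts)


def nmi_from_labels(labels_a, labels_b) -> float:
    """NMI of two label vectors (convenience wrapper over contingency)."""
    return nmi(contingency(labels_b, labels_a))


def nmi_curve(features, truth, k_range) -> pd.DataFrame:
    """NMI between the k-cut complete-linkage clustering and truth, per k."""
    X = np.asarray(features, float)
    ks = list(k_range)
    if min(ks) < 2 or max(ks) > X.shape[0] - 1:
        raise ValidationError("k_range must lie within [2, n-1]")
    rows = []
    for k in ks:
        res = complete_linkage_cluster(X, k)
        rows.append({"k": k, "nmi": nmi(contingency(res.assignments, truth))})
    return pd.DataFrame(rows)


def nmi_difference_permutation_test(
    features_a,
    features_b,
    truth,
    k: int,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test of NMI_A(k) - NMI_B(k).

    Both clusterings are computed once and held fixed; the null distribution
    jointly permutes the truth labels across items. One-sided in the
    direction "representation A fits the truth better".
    """
    A = np.asarray(features_a, float)
    B = np.asarray(features_b, float)
    t = np.asarray(truth)
    if A.shape[0] != B.shape[0] or A.shape[0] != t.shape[0]:
        raise ValidationError("feature sets and truth must cover the same items")
    if n_permutations < 99:
        raise ValidationError("need at least 99 permutations")
    la = complete_linkage_cluster(A, k).assignments
    lb = complete_linkage_cluster(B, k).assignments
    _, t_codes = np.unique(t, return_inverse=True)

    ka = la.max() + 1
    kb = lb.max() + 1
    kt = t_codes.max() + 1

    def _pair_nmi(tc: np.ndarray, lab: np.ndarray, kl: int) -> float:
        counts = np.bincount(tc * kl + lab, minlength=kt * kl).reshape(kt, kl)
        return _nmi_from_counts(counts)

    observed = _pair_nmi(t_codes, la, ka) - _pair_nmi(t_codes, lb, kb)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(t_codes)
        diffs[b] = _pair_nmi(perm, la, ka) - _pair_nmi(perm, lb, kb)
    p = (1.0 + np.count_nonzero(diffs >= observed)) / (n_permutations + 1.0)
    return PermutationResult(
        observed=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        permuted_mean=float(diffs.mean()),
        permuted_sd=float(diffs.std(ddof=1)),
        permuted_max=float(diffs.max()),
    )


def majority_cluster_labels(table: ContingencyTable) -> MajorityLabels:
    """Label each cluster by its modal truth category (ties -> canonical order)."""
    counts = table.counts
    mapping = {}
    tied = []
    for j, cl in enumerate(table.col_labels):
        col = counts[:, j]
        if col.sum() == 0:
            logger.warning("cluster %r is empty; skipped", cl)
            continue
        best = int(col.argmax())  # argmax returns the first (canonical) max
        if (col == col[best]).sum() > 1:
            tied.append(cl)
        mapping[cl] = table.row_labels[best]
    return MajorityLabels(mapping=mapping, tied_clusters=tuple(tied))
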