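"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: UniFrac is
tallied branch by branch with explicit leaf-set traversal, and ANOSIM R is
recomputed from first principles on explicitly enumerated distance pairs.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def _branches(tree):
    """(length, descendant-leaf-name set) per branch, root edge included
    when it has positive length."""
    out = []
    for node in tree.postorder(include_self=True):
        length = node.length or 0.0
        if node.is_root() and length == 0.0:
            continue
        if node.is_tip():
            leaves = {node.name}
        else:
            leaves = {t.name for t in node.tips()}
        out.append((length, leaves))
    return out


def brute_unweighted_unifrac(tree, counts_a, counts_b):
    """counts_* map leaf name -> count."""
    unique = covered = 0.0
    for length, leaves in _branches(tree):
        in_a = any(counts_a.get(l, 0) > 0 for l in leaves)
        in_b = any(counts_b.get(l, 0) > 0 for l in leaves)
        if in_a or in_b:
            covered += length
        if in_a != in_b:
            unique += length
    return unique / covered if covered else 0.0


def brute_weighted_unifrac(tree, counts_a, counts_b, normalized=False):
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    raw = depth = 0.0
    for length, leaves in _branches(tree):
        pa = sum(counts_a.get(l, 0) for l in leaves) / tot_a
        pb = sum(counts_b.get(l, 0) for l in leaves) / tot_b
        raw += length * abs(pa - pb)
        depth += length * (pa + pb)
    if normalized:
        return raw / depth if depth else 0.0
    return raw


def brute_faith_pd(tree, counts):
    pd_sum = 0.0
    for length, leaves in _branches(tree):
        if any(counts.get(l, 0) > 0 for l in leaves):
            pd_sum += length
    return pd_sum


def brute_anosim_r(distances, labels):
    """R from explicit enumeration of all unordered sample pairs."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([distances[i, j] for i, j in pairs])
    ranks = rankdata(d, method="average")
    within = [r for (i, j), r in zip(pairs, ranks) if labels[i] == labels[j]]
    between = [r for (i, j), r in zip(pairs, ranks) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2.0)


def procrustes_m2_closed_form(a, b):
    """1 - (sum of singular values of A^T B)^2 after centering and unit
    Frobenius scaling of both configurations."""
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return 1.0 - s.sum() ** 2
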