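"""Alpha and beta diversity on rarefied count tables.

Alpha: observed OTUs, Chao1 richness and Faith's phylogenetic diversity
(sum of branch lengths spanned by the observed leaves, root edge included),
with a Monte-Carlo permutation two-sample t-test for group comparisons.

Beta: unweighted and weighted (raw or normalized) UniFrac, computed over a
precomputed branch-incidence matrix so that full distance matrices and
count-reassignment permutation tests stay cheap. The per-pair significance
test reassigns each sequence to one of the two samples at random while
preserving both sequencing depths, which is a multivariate hypergeometric
split of the pooled counts.

All permutation p-values use the add-one estimator
``(1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import DataError, ParameterError
from .io_formats import CountTable, PhyloTree

METRICS = ("uwuf", "wuf", "wuf-normalized")


# ---------------------------------------------------------------------------
# branch incidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchIndex:
    """Flattened view of a rooted tree: one row per branch.

    ``incidence[i, j]`` is True when leaf ``j`` descends through branch
    ``i``; ``lengths[i]`` is that branch's length. The root's own edge is
    included when it carries a positive length.
    """

    leaf_names: tuple[str, ...]
    lengths: np.ndarray
    incidence: np.ndarray  # bool, (n_branches, n_leaves)

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "BranchIndex":
        leaves = [t.name for t in tree.tips()]
        if len(leaves) != len(set(leaves)):
            raise DataError("duplicate leaf names in tree")
        col = {name: j for j, name in enumerate(leaves)}
        masks: dict[int, np.ndarray] = {}
        lengths = []
        rows = []
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(leaves), dtype=bool)
                mask[col[node.name]] = True
            else:
                mask = np.zeros(len(leaves), dtype=bool)
                for child in node.children:
                    mask |= masks[id(child)]
            masks[id(node)] = mask
            length = node.length or 0.0
            if node.is_root() and length == 0.0:
                continue
            lengths.append(length)
            rows.append(mask)
        return cls(
            leaf_names=tuple(leaves),
            lengths=np.asarray(lengths, dtype=float),
            incidence=np.asarray(rows, dtype=bool),
        )

    def align(self, otu_ids: list[str]) -> np.ndarray:
        """Column order mapping table OTUs onto tree leaves."""
        col = {name: j for j, name in enumerate(self.leaf_names)}
        missing = [o for o in otu_ids if o not in col]
        if missing:
            raise DataError(
                f"OTUs absent from the tree: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.array([col[o] for o in otu_ids], dtype=np.intp)


def _leaf_vector(
    counts: np.ndarray, order: np.ndarray, n_leaves: int
) -> np.ndarray:
    """Scatter table-ordered counts into tree-leaf order."""
    v = np.zeros(n_leaves, dtype=float)
    v[order] = counts
    return v


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def observed_otus(column: np.ndarray) -> int:
    """Number of OTUs with a positive count."""
    return int(np.count_nonzero(np.asarray(column)))


def chao1(column: np.ndarray) -> float:
    """Chao1 richness: ``S_obs + F1^2 / (2 F2)``, or the bias-corrected
    ``S_obs + F1 (F1 - 1) / 2`` when there are no doubletons."""
    col = np.asarray(column)
    s_obs = float(np.count_nonzero(col))
    f1 = float(np.count_nonzero(col == 1))
    f2 = float(np.count_nonzero(col == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1.0) / 2.0


def faith_pd(
    column: np.ndarray, tree: PhyloTree | BranchIndex,
    otu_ids: list[str] | None = None,
) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sum of branch lengths on the union of root-to-leaf paths over observed
    OTUs. ``otu_ids`` gives the order of ``column``; by default the tree's
    own leaf order is assumed.
    """
    index = tree if isinstance(tree, BranchIndex) else BranchIndex.from_tree(tree)
    col = np.asarray(column, dtype=float)
    order = (
        index.align(otu_ids)
        if otu_ids is not None
        else np.arange(len(index.leaf_names))
    )
    if col.shape[0] != order.shape[0]:
        raise ParameterError("column length does not match OTU ids")
    v = _leaf_vector(col, order, len(index.leaf_names))
    present = index.incidence @ (v > 0) > 0
    return float(index.lengths[present].sum())


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _branch_fractions(index: BranchIndex, v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise ParameterError("UniFrac is undefined for an empty sample")
    return index.incidence @ (v / total)


def unweighted_unifrac(
    col_a: np.ndarray, col_b: np.ndarray,
    tree: PhyloTree | BranchIndex, otu_ids: list[str] | None = None,
) -> float:
    """Fraction of covered branch length unique to one of the two samples."""
    index = tree if isinstance(tree, BranchIndex) else BranchIndex.from_tree(tree)
    order = (
        index.align(otu_ids)
        if otu_ids is not None
        else np.arange(len(index.leaf_names))
    )
    a = _leaf_vector(np.asarray(col_a, float), order, len(index.leaf_names))
    b = _leaf_vector(np.asarray(col_b, float), order, len(index.leaf_names))
    if a.sum() == 0 and b.sum() == 0:
        raise ParameterError("UniFrac is undefined for two empty samples")
    in_a = index.incidence @ (a > 0) > 0
    in_b = index.incidence @ (b > 0) > 0
    covered = float(index.lengths[in_a | in_b].sum())
    unique = float(index.lengths[in_a ^ in_b].sum())
    if covered == 0:
        return 0.0
    return unique / covered


def weighted_unifrac(
    col_a: np.ndarray, col_b: np.ndarray,
    tree: PhyloTree | BranchIndex, otu_ids: list[str] | None = None,
    normalized: bool = False,
) -> float:
    """Abundance-weighted UniFrac ``sum_i b_i |p_Ai - p_Bi|`` over branches.

    ``p_Xi`` is the fraction of sample X's sequences descending through
    branch ``i``. The normalized form divides by
    ``sum_i b_i (p_Ai + p_Bi)``, the abundance-weighted depth, bounding the
    distance in [0, 1].
    """
    index = tree if isinstance(tree, BranchIndex) else BranchIndex.from_tree(tree)
    order = (
        index.align(otu_ids)
        if otu_ids is not None
        else np.arange(len(index.leaf_names))
    )
    a = _leaf_vector(np.asarray(col_a, float), order, len(index.leaf_names))
    b = _leaf_vector(np.asarray(col_b, float), order, len(index.leaf_names))
    pa = _branch_fractions(index, a)
    pb = _branch_fractions(index, b)
    raw = float(index.lengths @ np.abs(pa - pb))
    if not normalized:
        return raw
    depth = float(index.lengths @ (pa + pb))
    return raw / depth if depth > 0 else 0.0


def _metric_fn(metric: str):
    if metric == "uwuf":
        return lambda a, b, idx: unweighted_unifrac(a, b, idx)
    if metric == "wuf":
        return lambda a, b, idx: weighted_unifrac(a, b, idx)
    if metric == "wuf-normalized":
        return lambda a, b, idx: weighted_unifrac(a, b, idx, normalized=True)
    raise ParameterError(f"unknown beta metric {metric!r}; use one of {METRICS}")


def unifrac_matrix(
    table: CountTable, tree: PhyloTree, metric: str = "wuf"
) -> DistanceMatrix:
    """Square UniFrac distance matrix over all samples of a table."""
    index = BranchIndex.from_tree(tree)
    order = index.align(table.otu_ids)
    fn = _metric_fn(metric)
    n_leaves = len(index.leaf_names)
    cols = {
        s: _leaf_vector(table.column(s).astype(float), order, n_leaves)
        for s in table.sample_ids
    }
    ids = table.sample_ids
    d = np.zeros((len(ids), len(ids)))
    for i, j in itertools.combinations(range(len(ids)), 2):
        d[i, j] = d[j, i] = fn(cols[ids[i]], cols[ids[j]], index)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def _permuted_distances(
    a: np.ndarray, b: np.ndarray, index: BranchIndex,
    metric: str, n_perm: int, rng: np.random.Generator,
) -> np.ndarray:
    """Null UniFrac distances from random depth-preserving reassignment."""
    pooled = (a + b).astype(np.int64)
    n_a = int(a.sum())
    perm_a = rng.multivariate_hypergeometric(pooled, n_a, size=n_perm)
    perm_b = pooled[None, :] - perm_a
    inc = index.incidence.astype(float)
    if metric == "uwuf":
        pres_a = (perm_a > 0) @ inc.T > 0
        pres_b = (perm_b > 0) @ inc.T > 0
        covered = ((pres_a | pres_b).astype(float)) @ index.lengths
        unique = ((pres_a ^ pres_b).astype(float)) @ index.lengths
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(covered > 0, unique / covered, 0.0)
        return d
    pa = (perm_a / n_a) @ inc.T
    pb = (perm_b / (pooled.sum() - n_a)) @ inc.T
    raw = np.abs(pa - pb) @ index.lengths
    if metric == "wuf":
        return raw
    depth = (pa + pb) @ index.lengths
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, raw / depth, 0.0)


def unifrac_pair_significance(
    col_a: np.ndarray, col_b: np.ndarray,
    tree: PhyloTree | BranchIndex, metric: str = "wuf",
    n_perm: int = 1000, seed: int = 0,
    otu_ids: list[str] | None = None,
) -> tuple[float, float]:
    """Monte-Carlo significance of the UniFrac distance between two samples.

    The null keeps both sequencing depths fixed and reassigns every
    sequence to one of the two samples uniformly at random. Returns
    ``(observed_distance, p)``.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    index = tree if isinstance(tree, BranchIndex) else BranchIndex.from_tree(tree)
    order = (
        index.align(otu_ids)
        if otu_ids is not None
        else np.arange(len(index.leaf_names))
    )
    a = _leaf_vector(np.asarray(col_a, float), order, len(index.leaf_names))
    b = _leaf_vector(np.asarray(col_b, float), order, len(index.leaf_names))
    # canonical order: the null draw must not depend on which sample is
    # called "a", so the p-value is invariant to labeling order
    if (a.sum(), a.tobytes()) > (b.sum(), b.tobytes()):
        a, b = b, a
    fn = _metric_fn(metric)
    observed = fn(a, b, index)
    rng = np.random.default_rng(seed)
    null = _permuted_distances(a, b, index, metric, n_perm, rng)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return observed, p


def pairwise_unifrac_significance(
    table: CountTable, tree: PhyloTree, metric: str = "wuf",
    n_perm: int = 1000, seed: int = 0,
) -> pd.DataFrame:
    """Permutation significance for every unordered sample pair.

    Bonferroni multiplies each raw p by the number of comparisons actually
    run (``n (n - 1) / 2``), capped at 1.
    """
    index = BranchIndex.from_tree(tree)
    order = index.align(table.otu_ids)
    n_leaves = len(index.leaf_names)
    cols = {
        s: _leaf_vector(table.column(s).astype(float), order, n_leaves)
        for s in table.sample_ids
    }
    ids = table.sample_ids
    combos = list(itertools.combinations(ids, 2))
    n_comparisons = len(combos)
    fn = _metric_fn(metric)
    rng = np.random.default_rng(seed)
    rows = []
    for sa, sb in combos:
        a, b = cols[sa], cols[sb]
        observed = fn(a, b, index)
        null = _permuted_distances(a, b, index, metric, n_perm, rng)
        p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "distance": observed,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * n_comparisons),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alpha summaries and group test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaResult:
    sample_id: str
    observed_otus: int
    chao1: float
    faith_pd: float


def alpha_diversity(table: CountTable, tree: PhyloTree) -> list[AlphaResult]:
    """Observed OTUs, Chao1 and Faith PD for every sample of a table."""
    index = BranchIndex.from_tree(tree)
    order = index.align(table.otu_ids)
    out = []
    for s in table.sample_ids:
        col = table.column(s)
        out.append(
            AlphaResult(
                sample_id=s,
                observed_otus=observed_otus(col),
                chao1=chao1(col),
                faith_pd=faith_pd(col, index, otu_ids=table.otu_ids),
            )
        )
    return out


def _t_statistic(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    denom = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    diff = x.mean() - y.mean()
    if denom == 0:
        return 0.0 if diff == 0 else np.inf * np.sign(diff)
    return float(diff / denom)


def alpha_group_test(
    values_a: np.ndarray, values_b: np.ndarray,
    n_perm: int = 999, seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric two-sample t-test by Monte-Carlo label permutation.

    Returns ``(t_observed, p)`` with
    ``p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm)``.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 values")
    t_obs = _t_statistic(x, y)
    if np.isnan(t_obs):
        raise ParameterError("t statistic undefined")
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = _t_statistic(perm[: len(x)], perm[len(x):])
        if abs(t) >= abs(t_obs):
            hits += 1
    return t_obs, (1.0 + hits) / (1.0 + n_perm)
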