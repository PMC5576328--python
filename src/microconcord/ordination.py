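"""Ordination and configuration comparison: classical PCoA, least-squares
Procrustes superimposition with a Monte-Carlo match test, and ANOSIM.

PCoA is classical metric scaling: double-center ``-0.5 * D^2``,
eigendecompose, and scale eigenvectors by the square roots of the positive
eigenvalues. Negative eigenvalues are reported but contribute no axes (no
Lingoes/Cailliez correction, which would alter Procrustes residuals).

Procrustes M^2 follows the standard least-squares convention: both
configurations are centered and scaled to unit sum of squares, an optimal
rotation (reflections allowed) and dilation are applied, and M^2 is the
residual sum of squares — 0 for identical shapes, 1 for completely
dissimilar ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .errors import ParameterError

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class OrdinationResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray        # samples x positive axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive axes


@dataclass(frozen=True)
class ProcrustesResult:
    m_squared: float
    p_monte_carlo: float
    n_perm: int
    axes_used: int


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinates analysis of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ParameterError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T):
        raise ParameterError("distance matrix is not symmetric")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = (
        eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    )
    return OrdinationResult(
        sample_ids=tuple(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def _take_axes(config: np.ndarray, axes: int) -> np.ndarray:
    """First ``axes`` columns, zero-padded when fewer are available."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2:
        raise ParameterError("configuration must be 2-d")
    k = config.shape[1]
    if k >= axes:
        return config[:, :axes]
    return np.hstack([config, np.zeros((config.shape[0], axes - k))])


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_m2(
    config_a: np.ndarray, config_b: np.ndarray, axes: int = 3
) -> float:
    """Least-squares Procrustes residual M^2 between two configurations.

    Rows must correspond to the same samples in the same order. Both
    configurations are trimmed or zero-padded to ``axes`` columns.
    """
    a = _take_axes(config_a, axes)
    b = _take_axes(config_b, axes)
    if a.shape[0] != b.shape[0]:
        raise ParameterError("configurations must have the same sample count")
    if a.shape[0] < 2:
        raise ParameterError("need at least 2 points")
    try:
        _, _, disparity = _scipy_procrustes(a, b)
    except ValueError as exc:
        raise ParameterError(f"degenerate configuration: {exc}") from exc
    return float(disparity)


def procrustes_monte_carlo(
    dm_a: DistanceMatrix, dm_b: DistanceMatrix,
    n_perm: int = 1000, seed: int = 0, axes: int = 3,
) -> ProcrustesResult:
    """Procrustes M^2 between the PCoA configurations of two matched
    distance matrices, with Monte-Carlo significance.

    The two matrices must index the same paired entities in the same
    order (e.g. one distance matrix among induced and one among
    spontaneous samples, rows matched by pair). The null shuffles the row
    correspondence of the second configuration;
    ``p = (1 + #{M^2_perm <= M^2_obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if len(dm_a.ids) != len(dm_b.ids):
        raise ParameterError("distance matrices must have equal size")
    conf_a = _take_axes(pcoa(dm_a).coordinates, axes)
    conf_b = _take_axes(pcoa(dm_b).coordinates, axes)
    m2_obs = procrustes_m2(conf_a, conf_b, axes)
    rng = np.random.default_rng(seed)
    hits = 0
    n = conf_b.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if procrustes_m2(conf_a, conf_b[perm], axes) <= m2_obs:
            hits += 1
    return ProcrustesResult(
        m_squared=m2_obs,
        p_monte_carlo=(1.0 + hits) / (1.0 + n_perm),
        n_perm=n_perm,
        axes_used=axes,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dm: DistanceMatrix, groups: dict[str, str] | list[str],
    n_perm: int = 999, seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: are between-group distances larger than
    within-group distances?

    ``R = (mean between-group rank - mean within-group rank) / (M / 2)``
    over the ranks (average ties) of all ``M = n (n - 1) / 2`` distances;
    R is in [-1, 1], 0 under the null. Significance by group-label
    permutation with the add-one estimator.
    """
    ids = list(dm.ids)
    if isinstance(groups, dict):
        labels = np.array([groups[i] for i in ids])
    else:
        if len(groups) != len(ids):
            raise ParameterError("group list length must match matrix size")
        labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ParameterError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ParameterError("every group needs at least 2 samples")
    d = np.asarray(dm.data, dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    ranks = rankdata(d[iu], method="average")
    rng = np.random.default_rng(seed)
    within = (labels[iu[0]] == labels[iu[1]])
    r_obs = _anosim_r(ranks, within)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            hits += 1
    return AnosimResult(
        R=r_obs, p=(1.0 + hits) / (1.0 + n_perm), n_perm=n_perm
    )
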