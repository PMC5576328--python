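"""Generator of paired sputum-like community datasets.

The generator emulates the design of a two-method sputum comparison study:
each of ``n_pairs`` subjects contributes an induced and a spontaneous
sample sequenced to ~19,000-20,000 reads, with ~1000 OTUs collapsing to
~106 genus-level taxa and an 11/25 stable/exacerbation split.

Model: a global mean profile ``m ~ Dirichlet(1)`` over OTUs; each pair
draws its own base composition ``pi_j ~ Dirichlet(c * m)`` (``c`` the base
concentration, controlling between-subject variation). The induced sample
is a multinomial draw from ``pi_j``. The spontaneous composition applies a
logistic-normal perturbation — ``pi'_j = softmax(log pi_j + eps)`` with
``eps ~ Normal(0, sigma^2)`` per OTU — so the divergence parameter
``sigma`` acts multiplicatively on log-abundance, then any systematic
method effects (per-genus fold changes) are applied and the composition
renormalized before the spontaneous multinomial draw. ``sigma = 0`` with
no effects makes both members share one composition (pure sequencing
noise); increasing sigma spans near-identical to strongly discordant
pairs.

A Dirichlet-resampling alternative (``pi'_j ~ Dirichlet(c' * pi_j)``) is
available via ``perturbation='dirichlet'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ParameterError
from .io_formats import (
    CountTable,
    PairRecord,
    PhyloTree,
    SamplePairing,
    TaxonomyMap,
)

_TINY = 1e-12


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters defining the statistical structure of a simulated study."""

    n_pairs: int = 36
    n_otus: int = 1000
    n_genera: int = 106
    depth_mean: int = 19500
    depth_dispersion: float = 0.05   # depths uniform in [1-d, 1+d] * mean
    base_concentration: float = 200.0
    divergence: float | Sequence[float] = 1.0
    state_split: float = 25 / 36     # fraction of pairs at exacerbation
    effect_taxa: tuple[tuple[object, float], ...] = ()
    perturbation: str = "logistic-normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_otus, self.n_genera, self.depth_mean) < 1:
            raise ParameterError("sizes must be >= 1")
        if self.n_genera > self.n_otus:
            raise ParameterError("n_genera cannot exceed n_otus")
        if not 0 <= self.state_split <= 1:
            raise ParameterError("state_split must be in [0, 1]")
        if not 0 <= self.depth_dispersion < 1:
            raise ParameterError("depth_dispersion must be in [0, 1)")
        sig = np.atleast_1d(np.asarray(self.divergence, dtype=float))
        if np.any(sig < 0):
            raise ParameterError("divergence must be >= 0")
        if sig.size not in (1, self.n_pairs):
            raise ParameterError(
                "divergence must be a scalar or one value per pair"
            )
        if self.perturbation not in ("logistic-normal", "dirichlet"):
            raise ParameterError(
                f"unknown perturbation {self.perturbation!r}"
            )

    def per_pair_divergence(self) -> np.ndarray:
        sig = np.atleast_1d(np.asarray(self.divergence, dtype=float))
        if sig.size == 1:
            return np.full(self.n_pairs, float(sig[0]))
        return sig


def simulate_tree(n_otus: int, seed: int) -> PhyloTree:
    """Random bifurcating rooted tree over ``OTU_1 ... OTU_n``.

    Built by sequential random joins with exponential(1) branch lengths,
    giving a total branch length of order ``2 n``.
    """
    if n_otus < 2:
        raise ParameterError("need at least 2 OTUs for a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"OTU_{i + 1}") for i in range(n_otus)]
    for node in nodes:
        node.length = float(rng.exponential(1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _genus_lineage(g: int, unnamed_every: int = 12) -> tuple[str, ...]:
    genus = "g_" if (g + 1) % unnamed_every == 0 else f"g_Genus{g + 1}"
    return (
        "k_Bacteria",
        f"p_Phylum{g % 8 + 1}",
        f"c_Class{g % 16 + 1}",
        f"o_Order{g % 32 + 1}",
        f"f_Family{g + 1}",
        genus,
    )


def _effect_mask(
    spec: object, genus_of_otu: np.ndarray, lineages: list[tuple[str, ...]]
) -> np.ndarray:
    """OTU mask for an effect target given as genus index or 'g_Name' label."""
    if isinstance(spec, (int, np.integer)):
        return genus_of_otu == int(spec)
    genus_labels = np.array([lineages[g][-1] for g in genus_of_otu])
    mask = genus_labels == str(spec)
    if not mask.any():
        raise ParameterError(f"effect target {spec!r} matches no genus")
    return mask


def simulate_paired_tables(
    cfg: SyntheticConfig,
) -> tuple[CountTable, TaxonomyMap, PhyloTree, SamplePairing, dict]:
    """Simulate a full paired dataset plus a ground-truth record.

    Returns ``(counts, taxonomy, tree, pairing, truth)`` where ``truth``
    holds the per-pair base and perturbed compositions, their L1
    divergence, the drawn depths and the applied effects.
    """
    rng = np.random.default_rng(cfg.seed)
    tree_seed = int(rng.integers(0, 2**31 - 1))
    n = cfg.n_otus

    # taxonomy: every genus gets at least one OTU, the rest are assigned
    # uniformly at random
    genus_of_otu = np.concatenate(
        [
            np.arange(cfg.n_genera),
            rng.integers(0, cfg.n_genera, size=n - cfg.n_genera),
        ]
    )
    lineages = [_genus_lineage(g) for g in range(cfg.n_genera)]
    otu_ids = [f"OTU_{i + 1}" for i in range(n)]
    taxonomy = TaxonomyMap(
        {otu_ids[i]: lineages[genus_of_otu[i]] for i in range(n)}
    )

    m = rng.dirichlet(np.ones(n))
    alpha = np.maximum(cfg.base_concentration * m, 1e-8)

    n_exac = int(round(cfg.state_split * cfg.n_pairs))
    n_stable = cfg.n_pairs - n_exac
    sigmas = cfg.per_pair_divergence()

    lo = int(round(cfg.depth_mean * (1 - cfg.depth_dispersion)))
    hi = int(round(cfg.depth_mean * (1 + cfg.depth_dispersion)))

    columns: dict[str, np.ndarray] = {}
    pairs = []
    truth_pairs = []
    for j in range(cfg.n_pairs):
        pair_id = f"pair{j + 1:02d}"
        state = "stable" if j < n_stable else "exacerbation"
        pi = rng.dirichlet(alpha)
        if cfg.perturbation == "logistic-normal":
            eps = rng.normal(0.0, sigmas[j], size=n)
            logp = np.log(pi + _TINY) + eps
            logp -= logp.max()
            pi2 = np.exp(logp)
            pi2 /= pi2.sum()
        else:  # dirichlet resampling; concentration falls with divergence
            if sigmas[j] == 0:
                pi2 = pi.copy()
            else:
                conc = np.maximum(
                    (cfg.base_concentration / sigmas[j] ** 2) * pi, 1e-8
                )
                pi2 = rng.dirichlet(conc)
        applied_effects = []
        for target, fold in cfg.effect_taxa:
            mask = _effect_mask(target, genus_of_otu, lineages)
            pi2 = pi2.copy()
            pi2[mask] *= float(fold)
            pi2 /= pi2.sum()
            applied_effects.append(
                {"target": str(target), "fold": float(fold)}
            )
        depth_i = int(rng.integers(lo, hi + 1))
        depth_s = int(rng.integers(lo, hi + 1))
        iss = f"{pair_id}.ISS"
        sss = f"{pair_id}.SSS"
        columns[iss] = rng.multinomial(depth_i, pi)
        columns[sss] = rng.multinomial(depth_s, pi2)
        pairs.append(
            PairRecord(
                pair_id=pair_id,
                induced_id=iss,
                spontaneous_id=sss,
                state=state,
            )
        )
        truth_pairs.append(
            {
                "pair_id": pair_id,
                "state": state,
                "sigma": float(sigmas[j]),
                "l1_divergence": float(np.abs(pi - pi2).sum()),
                "depth_induced": depth_i,
                "depth_spontaneous": depth_s,
                "pi": pi,
                "pi_prime": pi2,
                "effects": applied_effects,
            }
        )

    table = CountTable(
        pd.DataFrame(columns, index=otu_ids, columns=list(columns))
    )
    tree = simulate_tree(n, tree_seed)
    pairing = SamplePairing(tuple(pairs))
    truth = {
        "config": {
            "n_pairs": cfg.n_pairs,
            "n_otus": cfg.n_otus,
            "n_genera": cfg.n_genera,
            "depth_mean": cfg.depth_mean,
            "base_concentration": cfg.base_concentration,
            "perturbation": cfg.perturbation,
            "seed": cfg.seed,
        },
        "mean_profile": m,
        "genus_of_otu": genus_of_otu,
        "pairs": truth_pairs,
    }
    return table, taxonomy, tree, pairing, truth
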