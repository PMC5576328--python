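"""Pair-level and group-level taxonomic concordance statistics.

Two complementary statistics quantify how well the two members of a sample
pair agree on composition:

* the Yue-Clayton dissimilarity ``1 - theta`` with
  ``theta = sum(a*b) / (sum(a^2) + sum(b^2) - sum(a*b))`` on
  relative-abundance vectors (0 = identical composition, 1 = disjoint);
* Bland-Altman 95% limits of agreement (LOA) on percent abundances, with
  the range statistic ``(upper - lower) / 100`` in [0, ~) where 0 means
  perfect agreement.

A pair is flagged discordant when a statistic strictly exceeds its cut-off
(defaults: 0.2 for ``1 - theta``, 0.1 for the LOA range). Per-taxon
abundance differences between sampling methods are tested with a G-test
(log-likelihood ratio) on group totals with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .community import to_relative
from .errors import ParameterError
from .io_formats import SamplePairing, TaxaTable

NORMALIZATION_TOL = 1e-6


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairConcordanceResult:
    pair_id: str
    state: str
    one_minus_theta_all: float
    one_minus_theta_dom: float
    mean_diff: float
    loa_lower: float
    loa_upper: float
    loa_range: float
    theta_discordant_all: bool = False
    theta_discordant_dom: bool = False
    loa_discordant: bool = False

    @property
    def discordant(self) -> bool:
        return (
            self.theta_discordant_all
            or self.theta_discordant_dom
            or self.loa_discordant
        )


@dataclass(frozen=True)
class TaxonTestResult:
    taxon: str
    mean_induced: float
    mean_spontaneous: float
    G: float
    df: int
    p_raw: float
    p_bonferroni: float


# ---------------------------------------------------------------------------
# Yue-Clayton
# ---------------------------------------------------------------------------

def yue_clayton_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - theta_YC`` for two relative-abundance vectors.

    Both vectors must sum to 1 (tolerance 1e-6). Returns 0 for identical
    and 1 for disjoint compositions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("profiles must be 1-d vectors of equal length")
    for name, v in (("a", a), ("b", b)):
        if abs(v.sum() - 1.0) > NORMALIZATION_TOL:
            raise ParameterError(
                f"profile {name} does not sum to 1 (got {v.sum():.8f})"
            )
    prod = float(np.dot(a, b))
    denom = float(np.dot(a, a) + np.dot(b, b)) - prod
    if denom == 0:
        raise ParameterError("both profiles are all-zero")
    theta = prod / denom
    return 1.0 - theta


def _normalize(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise ParameterError("cannot normalize an all-zero profile")
    return v / total


def group_mean_dissimilarity(
    taxa: TaxaTable,
    pairing: SamplePairing,
    subset: str = "all",
) -> float:
    """Yue-Clayton dissimilarity between the mean induced and mean
    spontaneous relative-abundance profiles over the pairs in ``subset``
    (``all``, ``stable`` or ``exacerbation``).

    This is a group comparison: averaging first can hide differences that
    per-pair comparisons reveal.
    """
    pairs = pairing.subset(subset)
    if len(pairs) == 0:
        raise ParameterError(f"no pairs in subset {subset!r}")
    rel = to_relative(taxa).data
    induced = rel[[p.induced_id for p in pairs]].mean(axis=1).to_numpy()
    spont = rel[[p.spontaneous_id for p in pairs]].mean(axis=1).to_numpy()
    return yue_clayton_dissimilarity(_normalize(induced), _normalize(spont))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman_pair(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float, float, float]:
    """Bland-Altman agreement of two percent-abundance vectors.

    Returns ``(mean_diff, loa_lower, loa_upper, loa_range)`` where the 95%
    limits of agreement are ``mean(d) +/- 1.96 * sd(d)`` with the sample
    (n-1) standard deviation of the paired differences ``d = a - b``, and
    ``loa_range = (loa_upper - loa_lower) / 100``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("profiles must be 1-d vectors of equal length")
    if a.size < 3:
        raise ParameterError("Bland-Altman needs at least 3 paired values")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lower = mean_diff - 1.96 * sd
    loa_upper = mean_diff + 1.96 * sd
    return mean_diff, loa_lower, loa_upper, (loa_upper - loa_lower) / 100.0


# ---------------------------------------------------------------------------
# per-pair statistics and classification
# ---------------------------------------------------------------------------

def pair_statistics(
    taxa_all: TaxaTable,
    taxa_dom: TaxaTable,
    pairing: SamplePairing,
) -> list[PairConcordanceResult]:
    """Per-pair Yue-Clayton dissimilarities (on the full and the
    dominant-OTU taxa tables) and Bland-Altman LOA (on the full table, in
    percent). Flags are left unset; pass the result to ``classify_pairs``.
    """
    rel_all = to_relative(taxa_all)
    rel_dom = to_relative(taxa_dom)
    pct = rel_all.percent
    results = []
    for p in pairing:
        th_all = yue_clayton_dissimilarity(
            rel_all.data[p.induced_id].to_numpy(),
            rel_all.data[p.spontaneous_id].to_numpy(),
        )
        th_dom = yue_clayton_dissimilarity(
            rel_dom.data[p.induced_id].to_numpy(),
            rel_dom.data[p.spontaneous_id].to_numpy(),
        )
        mean_diff, lo, hi, rng = bland_altman_pair(
            pct[p.induced_id].to_numpy(), pct[p.spontaneous_id].to_numpy()
        )
        results.append(
            PairConcordanceResult(
                pair_id=p.pair_id,
                state=p.state,
                one_minus_theta_all=th_all,
                one_minus_theta_dom=th_dom,
                mean_diff=mean_diff,
                loa_lower=lo,
                loa_upper=hi,
                loa_range=rng,
            )
        )
    return results


def classify_pairs(
    pairs: Sequence[PairConcordanceResult],
    theta_cut: float = 0.2,
    loa_cut: float = 0.1,
) -> list[PairConcordanceResult]:
    """Set discordance flags by strict comparison against the cut-offs.

    A pair exactly at a cut-off counts as concordant.
    """
    return [
        replace(
            r,
            theta_discordant_all=r.one_minus_theta_all > theta_cut,
            theta_discordant_dom=r.one_minus_theta_dom > theta_cut,
            loa_discordant=r.loa_range > loa_cut,
        )
        for r in pairs
    ]


def classification_summary(
    results: Sequence[PairConcordanceResult],
) -> dict[str, int]:
    return {
        "n_pairs": len(results),
        "theta_discordant_all": sum(r.theta_discordant_all for r in results),
        "theta_discordant_dom": sum(r.theta_discordant_dom for r in results),
        "loa_discordant": sum(r.loa_discordant for r in results),
        "any_discordant": sum(r.discordant for r in results),
    }


# ---------------------------------------------------------------------------
# per-taxon G-test
# ---------------------------------------------------------------------------

def taxon_g_test(
    taxa: TaxaTable,
    groups: Mapping[str, str],
    correction: str = "none",
) -> list[TaxonTestResult]:
    """Per-taxon log-likelihood ratio (G) test of group totals.

    For each taxon the observed per-group sequence totals ``O_g`` are
    compared to expectations proportional to group sample counts under
    homogeneity: ``G = 2 * sum_g O_g * ln(O_g / E_g)`` (zero totals
    contribute 0), with a chi-square null on ``n_groups - 1`` degrees of
    freedom. The table should be rarefied to a common depth so that sample
    counts are a fair exposure measure. ``correction='williams'`` applies
    the Williams small-sample adjustment. Bonferroni multiplies by the
    number of taxa tested, capped at 1.
    """
    if correction not in ("none", "williams"):
        raise ParameterError(f"unknown correction {correction!r}")
    sample_ids = taxa.sample_ids
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ParameterError(f"samples without a group label: {missing}")
    labels = sorted({groups[s] for s in sample_ids})
    if len(labels) < 2:
        raise ParameterError("need at least 2 groups")
    members = {g: [s for s in sample_ids if groups[s] == g] for g in labels}
    for g, mem in members.items():
        if not mem:
            raise ParameterError(f"group {g!r} has no samples")
    n_samples = {g: len(mem) for g, mem in members.items()}
    n_total_samples = sum(n_samples.values())
    k = len(labels)
    n_taxa = len(taxa.taxon_labels)
    results = []
    data = taxa.data
    group_tot = {g: data[mem].sum(axis=1) for g, mem in members.items()}
    for taxon in taxa.taxon_labels:
        O = np.array([float(group_tot[g][taxon]) for g in labels])
        total = O.sum()
        E = total * np.array(
            [n_samples[g] / n_total_samples for g in labels]
        )
        if total == 0:
            G, p = 0.0, 1.0
        else:
            nz = O > 0
            G = 2.0 * float(np.sum(O[nz] * np.log(O[nz] / E[nz])))
            G = max(G, 0.0)
            if correction == "williams":
                q = 1.0 + (k + 1.0) / (6.0 * total)
                G = G / q
            p = float(stats.chi2.sf(G, df=k - 1))
        mean_by = {
            g: float(group_tot[g][taxon]) / n_samples[g] for g in labels
        }
        results.append(
            TaxonTestResult(
                taxon=taxon,
                mean_induced=mean_by.get("induced", mean_by[labels[0]]),
                mean_spontaneous=mean_by.get(
                    "spontaneous", mean_by[labels[-1]]
                ),
                G=G,
                df=k - 1,
                p_raw=p,
                p_bonferroni=min(1.0, p * n_taxa),
            )
        )
    return results
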