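"""End-to-end orchestration of the paired-concordance analysis.

Stages, in order: rare-OTU filter -> taxonomic collapse (with and without
the dominance filter) -> per-pair Yue-Clayton / Bland-Altman statistics and
classification, plus group-mean dissimilarities -> per-subset rarefaction
-> per-taxon G-tests -> alpha diversity with permutation group tests ->
UniFrac distance matrices -> all-pairs WUF permutation significance with
Bonferroni -> PCoA -> Procrustes (axes 1-3, Monte Carlo) -> ANOSIM by
sample type. Subsets are ``all``, ``exacerbation`` and ``stable``; each
uses only the pairs whose disease state matches.

Every stochastic stage consumes a child seed derived deterministically
from the master seed, so a fixed configuration reproduces its report
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from . import community, concordance_stats, diversity, ordination
from .errors import MicroconcordError, ParameterError
from .io_formats import (
    CountTable,
    PhyloTree,
    SamplePairing,
    TaxonomyMap,
    read_count_table,
    read_newick,
    read_pairing,
    read_taxonomy,
    write_report,
)

logger = logging.getLogger(__name__)

SUBSETS = ("all", "exacerbation", "stable")

_SEED_NAMES = (
    "rarefy_all",
    "rarefy_exacerbation",
    "rarefy_stable",
    "pairwise_unifrac",
    "alpha_test",
    "procrustes",
    "anosim",
)


class PipelineStageError(MicroconcordError):
    """A stage failed; the message names the stage and the offending ids."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and permutation settings for one pipeline run."""

    counts_path: str | None = None
    counts_dialect: str = "tsv"
    taxonomy_path: str | None = None
    tree_path: str | None = None
    pairing_path: str | None = None
    output_dir: str | None = None

    min_otu_fraction: float = 5e-5
    dominance_fraction: float = 0.01
    tax_level: int = 6

    # "auto" rarefies each subset to its shallowest retained sample
    rarefy_depths: Mapping[str, int | str] = field(
        default_factory=lambda: {s: "auto" for s in SUBSETS}
    )

    theta_cut: float = 0.2
    loa_cut: float = 0.1
    m2_indicative: float = 0.3
    alpha_pairwise: float = 0.01
    alpha_default: float = 0.05

    beta_metrics: tuple[str, ...] = ("uwuf", "wuf")
    pairwise_metric: str = "wuf"
    n_perm_pairwise: int = 100
    n_perm_alpha: int = 999
    n_perm_procrustes: int = 999
    n_perm_anosim: int = 999
    procrustes_axes: int = 3
    g_test_correction: str = "none"

    master_seed: int = 0

    def __post_init__(self) -> None:
        for s, d in self.rarefy_depths.items():
            if d != "auto" and int(d) <= 0:
                raise ParameterError(f"rarefaction depth for {s!r} must be > 0")
        for a in (self.alpha_pairwise, self.alpha_default):
            if not 0 < a < 1:
                raise ParameterError("significance levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class PipelineResult:
    config: PipelineConfig
    seeds: dict[str, int]
    pair_results: list
    classification: dict[str, int]
    group_theta: dict[tuple[str, str], float]
    rarefied_depths: dict[str, int]
    taxon_tests: dict[str, list]
    alpha: dict[str, dict]
    beta: dict[str, DistanceMatrix]
    pairwise: pd.DataFrame
    pairwise_significant_pairs: list[str]
    pcoa: ordination.OrdinationResult
    procrustes: ordination.ProcrustesResult
    anosim: dict[tuple[str, str], ordination.AnosimResult]


def child_seeds(master_seed: int) -> dict[str, int]:
    """Named per-stage seeds derived deterministically from the master."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_SEED_NAMES))
    return {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(_SEED_NAMES, children)
    }


def load_inputs(
    cfg: PipelineConfig,
) -> tuple[CountTable, TaxonomyMap, PhyloTree, SamplePairing]:
    if None in (
        cfg.counts_path, cfg.taxonomy_path, cfg.tree_path, cfg.pairing_path
    ):
        raise ParameterError(
            "counts_path, taxonomy_path, tree_path and pairing_path are all "
            "required when no in-memory dataset is supplied"
        )
    table = read_count_table(cfg.counts_path, cfg.counts_dialect)
    tax = read_taxonomy(cfg.taxonomy_path)
    tree = read_newick(cfg.tree_path)
    pairing = read_pairing(cfg.pairing_path)
    return table, tax, tree, pairing


def _subset_table(
    table: CountTable, pairing: SamplePairing, subset: str
) -> tuple[CountTable, SamplePairing]:
    sub = pairing.subset(subset)
    ids = [s for s in sub.sample_ids() if s in table.sample_ids]
    return CountTable(table.data[ids]), sub


def _resolve_depth(
    table: CountTable, requested: int | str, subset: str
) -> int:
    if requested == "auto":
        depth = int(table.data.sum(axis=0).min())
        logger.info("rarefy depth for %s resolved to %d (auto)", subset, depth)
        return depth
    return int(requested)


def run_pipeline(
    cfg: PipelineConfig,
    dataset: tuple[CountTable, TaxonomyMap, PhyloTree, SamplePairing]
    | None = None,
) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the order."""
    seeds = child_seeds(cfg.master_seed)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MicroconcordError as exc:
            raise PipelineStageError(f"stage {name!r}: {exc}") from exc

    if dataset is None:
        dataset = stage("load_inputs", load_inputs, cfg)
    table, tax, tree, pairing = dataset
    if len(pairing) == 0:
        raise PipelineStageError("stage 'load_inputs': empty sample pairing")
    stage("validate", pairing.validate_against, table)

    filtered = stage(
        "filter_rare", community.filter_rare, table, cfg.min_otu_fraction
    )

    # --- branch A: composition concordance (unrarefied, filtered) ---------
    taxa_all = stage(
        "collapse_all", community.collapse_taxonomy, filtered, tax,
        cfg.tax_level,
    )
    dominant = stage(
        "filter_dominant", community.filter_dominant, filtered,
        cfg.dominance_fraction,
    )
    taxa_dom = stage(
        "collapse_dominant", community.collapse_taxonomy, dominant, tax,
        cfg.tax_level,
    )
    pair_stats = stage(
        "pair_statistics", concordance_stats.pair_statistics,
        taxa_all, taxa_dom, pairing,
    )
    pair_results = concordance_stats.classify_pairs(
        pair_stats, cfg.theta_cut, cfg.loa_cut
    )
    classification = concordance_stats.classification_summary(pair_results)

    group_theta: dict[tuple[str, str], float] = {}
    for subset in SUBSETS:
        if len(pairing.subset(subset)) == 0:
            continue
        for otu_set, taxa in (("all", taxa_all), ("dominant", taxa_dom)):
            group_theta[(subset, otu_set)] = stage(
                f"group_theta_{subset}_{otu_set}",
                concordance_stats.group_mean_dissimilarity,
                taxa, pairing, subset,
            )

    # --- rarefied analyses per subset --------------------------------------
    rarefied: dict[str, CountTable] = {}
    rarefied_depths: dict[str, int] = {}
    taxon_tests: dict[str, list] = {}
    alpha_results: dict[str, dict] = {}
    for subset in SUBSETS:
        sub_table, sub_pairing = _subset_table(filtered, pairing, subset)
        if len(sub_pairing) == 0:
            continue
        depth = _resolve_depth(
            sub_table, cfg.rarefy_depths.get(subset, "auto"), subset
        )
        rt = stage(
            f"rarefy_{subset}", community.rarefy, sub_table, depth,
            seeds[f"rarefy_{subset}"],
        )
        rarefied[subset] = rt
        rarefied_depths[subset] = depth
        groups = {}
        for p in sub_pairing:
            groups[p.induced_id] = "induced"
            groups[p.spontaneous_id] = "spontaneous"
        groups = {s: g for s, g in groups.items() if s in rt.sample_ids}
        taxa_sub = stage(
            f"collapse_{subset}", community.collapse_taxonomy, rt, tax,
            cfg.tax_level,
        )
        taxon_tests[subset] = stage(
            f"g_test_{subset}", concordance_stats.taxon_g_test,
            taxa_sub, groups, cfg.g_test_correction,
        )
        per_sample = stage(
            f"alpha_{subset}", diversity.alpha_diversity, rt, tree
        )
        by_id = {a.sample_id: a for a in per_sample}
        tests = {}
        for metric in ("observed_otus", "chao1", "faith_pd"):
            vals_i = np.array(
                [
                    getattr(by_id[p.induced_id], metric)
                    for p in sub_pairing
                    if p.induced_id in by_id
                ],
                dtype=float,
            )
            vals_s = np.array(
                [
                    getattr(by_id[p.spontaneous_id], metric)
                    for p in sub_pairing
                    if p.spontaneous_id in by_id
                ],
                dtype=float,
            )
            tests[metric] = stage(
                f"alpha_test_{subset}_{metric}", diversity.alpha_group_test,
                vals_i, vals_s, cfg.n_perm_alpha,
                seeds["alpha_test"],
            )
        alpha_results[subset] = {"per_sample": per_sample, "tests": tests}

    # --- beta diversity on the all-samples rarefied table -------------------
    rt_all = rarefied["all"]
    beta: dict[str, DistanceMatrix] = {}
    for metric in cfg.beta_metrics:
        beta[metric] = stage(
            f"unifrac_{metric}", diversity.unifrac_matrix, rt_all, tree,
            metric,
        )
    pairwise = stage(
        "pairwise_significance", diversity.pairwise_unifrac_significance,
        rt_all, tree, cfg.pairwise_metric, cfg.n_perm_pairwise,
        seeds["pairwise_unifrac"],
    )
    sig_lookup = {
        frozenset((r.sample_a, r.sample_b)): r.p_bonferroni
        for r in pairwise.itertuples()
    }
    significant_pairs = []
    for p in pairing:
        key = frozenset((p.induced_id, p.spontaneous_id))
        if key in sig_lookup and sig_lookup[key] < cfg.alpha_pairwise:
            significant_pairs.append(p.pair_id)

    # --- ordination ---------------------------------------------------------
    if cfg.pairwise_metric in beta:
        wuf = beta[cfg.pairwise_metric]
    else:
        wuf = stage(
            "unifrac_pairwise_metric", diversity.unifrac_matrix,
            rt_all, tree, cfg.pairwise_metric,
        )
    pcoa_result = stage("pcoa", ordination.pcoa, wuf)

    retained = set(rt_all.sample_ids)
    matched = [
        p for p in pairing
        if p.induced_id in retained and p.spontaneous_id in retained
    ]
    dm_induced = wuf.filter([p.induced_id for p in matched])
    dm_spont = wuf.filter([p.spontaneous_id for p in matched])
    procrustes_result = stage(
        "procrustes", ordination.procrustes_monte_carlo,
        DistanceMatrix(dm_induced.data, [p.pair_id for p in matched]),
        DistanceMatrix(dm_spont.data, [p.pair_id for p in matched]),
        cfg.n_perm_procrustes, seeds["procrustes"], cfg.procrustes_axes,
    )

    anosim_results: dict[tuple[str, str], ordination.AnosimResult] = {}
    for subset in rarefied:
        ids = rarefied[subset].sample_ids
        sub_pairing = pairing.subset(subset)
        types = {}
        for p in sub_pairing:
            types[p.induced_id] = "induced"
            types[p.spontaneous_id] = "spontaneous"
        for metric in cfg.beta_metrics:
            dm = (
                beta[metric].filter(ids)
                if subset != "all"
                else beta[metric]
            )
            anosim_results[(subset, metric)] = stage(
                f"anosim_{subset}_{metric}", ordination.anosim,
                dm, {s: types[s] for s in dm.ids},
                cfg.n_perm_anosim, seeds["anosim"],
            )

    result = PipelineResult(
        config=cfg,
        seeds=seeds,
        pair_results=pair_results,
        classification=classification,
        group_theta=group_theta,
        rarefied_depths=rarefied_depths,
        taxon_tests=taxon_tests,
        alpha=alpha_results,
        beta=beta,
        pairwise=pairwise,
        pairwise_significant_pairs=significant_pairs,
        pcoa=pcoa_result,
        procrustes=procrustes_result,
        anosim=anosim_results,
    )
    if cfg.output_dir:
        write_outputs(result, Path(cfg.output_dir))
    return result


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------

def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    for sub in ("tables", "distances", "ordination"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    cfg = result.config

    write_report(result.pair_results, out_dir / "report.tsv")

    for metric, dm in result.beta.items():
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out_dir / "distances" / f"{metric}.tsv", sep="\t",
            float_format="%.10g",
        )
    result.pairwise.to_csv(
        out_dir / "distances" / "pairwise_significance.tsv", sep="\t",
        index=False, float_format="%.10g",
    )

    coords = pd.DataFrame(
        result.pcoa.coordinates,
        index=list(result.pcoa.sample_ids),
        columns=[f"PC{i + 1}" for i in range(result.pcoa.coordinates.shape[1])],
    )
    coords.to_csv(
        out_dir / "ordination" / "pcoa_coordinates.tsv", sep="\t",
        float_format="%.10g",
    )
    pd.DataFrame(
        {
            "eigenvalue": result.pcoa.eigenvalues,
        }
    ).to_csv(
        out_dir / "ordination" / "pcoa_eigenvalues.tsv", sep="\t",
        index=False, float_format="%.10g",
    )

    for subset, tests in result.taxon_tests.items():
        pd.DataFrame([t.__dict__ for t in tests]).to_csv(
            out_dir / "tables" / f"taxon_tests_{subset}.tsv", sep="\t",
            index=False, float_format="%.10g",
        )
    for subset, alpha in result.alpha.items():
        pd.DataFrame([a.__dict__ for a in alpha["per_sample"]]).to_csv(
            out_dir / "tables" / f"alpha_{subset}.tsv", sep="\t",
            index=False, float_format="%.10g",
        )

    lines = [
        "# Paired-sample concordance report",
        "",
        "## Seeds",
        "",
    ] + [f"- {k}: {v}" for k, v in result.seeds.items()] + [
        "",
        "## Classification",
        "",
        f"- pairs analysed: {result.classification['n_pairs']}",
        f"- 1-theta > {cfg.theta_cut} (all taxa): "
        f"{result.classification['theta_discordant_all']}",
        f"- 1-theta > {cfg.theta_cut} (dominant taxa): "
        f"{result.classification['theta_discordant_dom']}",
        f"- LOA range > {cfg.loa_cut}: "
        f"{result.classification['loa_discordant']}",
        f"- discordant on any statistic: "
        f"{result.classification['any_discordant']}",
        "",
        "## Group-mean Yue-Clayton dissimilarity",
        "",
    ] + [
        f"- {subset}/{otu_set}: {v:.4f}"
        for (subset, otu_set), v in sorted(result.group_theta.items())
    ] + [
        "",
        "## Rarefaction depths",
        "",
    ] + [
        f"- {s}: {d}" for s, d in sorted(result.rarefied_depths.items())
    ] + [
        "",
        "## Beta diversity",
        "",
        f"- pairwise comparisons run: {len(result.pairwise)}",
        f"- pairs significant at Bonferroni-corrected p < "
        f"{cfg.alpha_pairwise}: {len(result.pairwise_significant_pairs)} "
        f"({', '.join(result.pairwise_significant_pairs) or 'none'})",
        f"- Procrustes M^2 (axes 1-{result.procrustes.axes_used}): "
        f"{result.procrustes.m_squared:.4f} "
        f"(p = {result.procrustes.p_monte_carlo:.4g}, "
        f"{result.procrustes.n_perm} permutations; "
        f"> {cfg.m2_indicative} indicative of influential differences)",
        "",
        "## ANOSIM by sample type",
        "",
    ] + [
        f"- {subset}/{metric}: R = {r.R:.4f}, p = {r.p:.4g}"
        for (subset, metric), r in sorted(result.anosim.items())
    ]
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")

    log_lines = [f"seed {k} = {v}" for k, v in result.seeds.items()]
    (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
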