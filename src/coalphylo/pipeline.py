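"""End-to-end experiments: simulate -> gene trees -> species trees -> scores.

A :class:`MethodSpec` names one species-tree estimation method together with
its gene-tree source and point-estimate rule, in the pipeline's naming
convention "Method(GeneTreeEstimate)", e.g. ``Greedy(NJ-75%)`` = greedy
consensus of neighbor-joining gene trees with branches under 75% bootstrap
support contracted.  :func:`run_experiment` sweeps replicate simulated
datasets and scores every method's species tree against the true species
tree with the missing-branch rate; :func:`compare_methods` runs the paired
Wilcoxon signed-rank comparisons with Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consensus import greedy_consensus, majority_consensus
from .genetrees import (
    bootstrap_support,
    logdet_distance,
    nj_tree,
    tree_path_distances,
)
from .glass import glass_tree
from .metrics import missing_branch_rate
from .search import SearchConfig, search_species_tree
from .simulate import DatasetBundle, ExperimentConfig, generate_dataset
from .stats import bonferroni, wilcoxon_signed_rank
from .trees import contract_low_support

__all__ = ["MethodSpec", "run_experiment", "score_methods_on_bundle", "compare_methods"]

_SPECIES_METHODS = ("greedy", "majority", "glass", "mdc", "dup", "duploss")


@dataclass(frozen=True)
class MethodSpec:
    """One (gene-tree source, point estimate, species method) combination.

    ``gene_tree_source``: "true" uses the simulated gene trees; "nj" estimates
    each gene tree with NJ on logdet distances from the true alignment.
    ``point_estimate``: "full" keeps the estimate as is; "contracted"
    collapses branches with bootstrap support below ``contract_threshold``;
    "majority"/"map" summarise the bootstrap replicate sample instead of
    using the point tree (the desk-scale analogue of consensus/MAP trees
    from a Bayesian sample).
    """

    label: str
    species_method: str
    gene_tree_source: str = "true"
    point_estimate: str = "full"
    contract_threshold: float = 0.75
    bootstrap_replicates: int = 100
    search_max_iterations: int = 50
    search_restarts: int = 2

    def __post_init__(self):
        if self.species_method not in _SPECIES_METHODS:
            raise ValueError(f"species_method must be one of {_SPECIES_METHODS}")
        if self.gene_tree_source not in ("true", "nj"):
            raise ValueError("gene_tree_source must be 'true' or 'nj'")
        if self.point_estimate not in ("full", "contracted", "majority", "map"):
            raise ValueError("bad point_estimate")


def _gene_tree_inputs(spec: MethodSpec, bundle: DatasetBundle, seed: int, cache: dict):
    """Gene trees (and per-gene distance matrices for GLASS) for one method."""
    if spec.gene_tree_source == "true":
        trees = bundle.gene_trees
        if spec.species_method == "glass":
            key = ("true-dist",)
            if key not in cache:
                cache[key] = [tree_path_distances(t) for t in trees]
            return trees, cache[key]
        return trees, None

    needs_support = spec.point_estimate in ("contracted", "majority", "map")
    key = ("nj", needs_support, spec.bootstrap_replicates)
    if key not in cache:
        trees = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, aln in enumerate(bundle.alignments):
                rng = np.random.default_rng([seed, 0xB00, i])
                if needs_support:
                    trees.append(
                        bootstrap_support(aln, spec.bootstrap_replicates, rng)
                    )
                else:
                    trees.append(nj_tree(logdet_distance(aln)))
        cache[key] = trees
    trees = cache[key]
    if spec.point_estimate == "contracted":
        ckey = ("nj-contracted", spec.contract_threshold, spec.bootstrap_replicates)
        if ckey not in cache:
            cache[ckey] = [
                contract_low_support(t, spec.contract_threshold) for t in trees
            ]
        trees = cache[ckey]
    if spec.species_method == "glass":
        dkey = ("nj-dist",)
        if dkey not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[dkey] = [logdet_distance(a) for a in bundle.alignments]
        return trees, cache[dkey]
    return trees, None


def _estimate_species_tree(spec: MethodSpec, trees, dists, seed: int):
    if spec.species_method == "greedy":
        return greedy_consensus(trees)
    if spec.species_method == "majority":
        return majority_consensus(trees)
    if spec.species_method == "glass":
        return glass_tree(dists)
    config = SearchConfig(
        criterion=spec.species_method,
        max_iterations=spec.search_max_iterations,
        random_restarts=spec.search_restarts,
        seed=seed,
    )
    tree, _score = search_species_tree(trees, config)
    return tree


def score_methods_on_bundle(
    bundle: DatasetBundle,
    methods: Sequence[MethodSpec],
    dataset_id: int = 0,
    seed: int = 0,
) -> List[dict]:
    """Score each method on one simulated dataset; errors become records."""
    records = []
    cache: dict = {}
    for spec in methods:
        rec = {
            "dataset_id": dataset_id,
            "n_taxa": bundle.config.n_taxa,
            "n_genes": bundle.config.n_genes,
            "alignment_kind": "true",
            "method_label": spec.label,
            "fn_rate": np.nan,
            "error": "",
        }
        try:
            trees, dists = _gene_tree_inputs(spec, bundle, seed, cache)
            est = _estimate_species_tree(spec, trees, dists, seed)
            rec["fn_rate"] = float(missing_branch_rate(bundle.species_tree, est))
        except Exception as exc:  # per-record failure, sweep continues
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return records


def run_experiment(
    config: ExperimentConfig,
    methods: Sequence[MethodSpec],
    n_datasets: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate ``n_datasets`` replicates of ``config`` and score ``methods``.

    Returns one record per (dataset, method) with the missing-branch rate
    against the true species tree.  Fully reproducible given ``seed`` (which
    defaults to ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    records: List[dict] = []
    for d in range(n_datasets):
        cfg = dataclasses.replace(config, seed=(seed + 1000003 * d) % (2**31))
        bundle = generate_dataset(cfg)
        records.extend(
            score_methods_on_bundle(bundle, methods, dataset_id=d, seed=cfg.seed)
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "dataset_id",
            "n_taxa",
            "n_genes",
            "alignment_kind",
            "method_label",
            "fn_rate",
            "error",
        ],
    )


def compare_methods(
    table: pd.DataFrame, pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparisons of method FN rates.

    Each pair is compared on the datasets both methods completed; raw
    p-values are Bonferroni-corrected with m = number of pairs.  The output
    also reports per-method mean FN rates over the shared datasets.
    """
    known = set(table["method_label"])
    rows = []
    for la, lb in pairs:
        for lbl in (la, lb):
            if lbl not in known:
                raise ValueError(f"unknown method label {lbl!r}")
        ta = table[(table["method_label"] == la) & table["fn_rate"].notna()]
        tb = table[(table["method_label"] == lb) & table["fn_rate"].notna()]
        merged = ta.merge(tb, on="dataset_id", suffixes=("_a", "_b"))
        if len(merged) < 5:
            raise ValueError(
                f"pair ({la}, {lb}) shares only {len(merged)} datasets (need >= 5)"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon_signed_rank(
                merged["fn_rate_a"].to_numpy(), merged["fn_rate_b"].to_numpy()
            )
        rows.append(
            {
                "method_a": la,
                "method_b": lb,
                "n": len(merged),
                "mean_fn_a": merged["fn_rate_a"].mean(),
                "mean_fn_b": merged["fn_rate_b"].mean(),
                "p_raw": res.p_value,
            }
        )
    out = pd.DataFrame.from_records(
        rows,
        columns=["method_a", "method_b", "n", "mean_fn_a", "mean_fn_b", "p_raw"],
    )
    out["p_bonferroni"] = bonferroni(out["p_raw"].tolist(), m=len(pairs)) if rows else []
    return out
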