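"""End-to-end analysis workflows and the run manifest.

Two studies mirror the core experiments the library supports:

* the **correlation study**: per-medium loss costs for every analysis gene
  across a media set, rank-averaged evolutionary rates, and Spearman
  correlation distributions for each cost metric over the standard gene
  subsets (all genes; non-isoenzymes; isoenzymes; multifunctional
  non-isoenzymes; fast-/slow-evolving isoenzyme selections);

* the **interaction study**: pairwise epistasis predictions under both the
  redundant and the non-redundant isoenzyme semantics, scored against an
  experimental-style interaction table, with confusion matrices and
  precision/recall curves.

Both return plain dataclasses of DataFrames/dicts that the CLI serialises to
TSV/JSON, and a :class:`RunManifest` records inputs, seeds and output digests
for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .costs import compute_cost_table
from .epistasis import (EpistasisRecord, InteractionComparison,
                        compare_with_experiment, filter_deletion_fitness,
                        precision_recall_curve, predict_pairwise)
from .evo import (CorrelationDistribution, average_rank_rate,
                  classify_isoenzyme_speed, correlation_distribution)
from .fba import Medium, find_blocked_reactions
from .gpr import isoenzyme_set
from .model import GeneCatalog, MetabolicModel, classify_genes

__all__ = ["RunManifest", "CorrelationReport", "InteractionReport",
           "prepare_catalog", "subset_genes", "run_correlation_study",
           "run_interaction_study", "SUBSETS", "COST_METRICS"]

logger = logging.getLogger(__name__)

COST_METRICS = ("glc", "flc", "hybrid1", "hybrid2")
SUBSETS = ("all", "non_isoenzymes", "isoenzymes",
           "multifunctional_non_isoenzymes", "fast_iso", "slow_iso",
           "fast_iso_only", "slow_iso_only")


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)

    def add_input(self, name: str, payload: bytes | str) -> None:
        if isinstance(payload, str):
            payload = payload.encode()
        self.inputs[name] = hashlib.sha256(payload).hexdigest()[:16]

    def add_output(self, name: str, payload: bytes | str) -> None:
        if isinstance(payload, str):
            payload = payload.encode()
        self.output_digests[name] = hashlib.sha256(payload).hexdigest()[:16]

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.timings_s[name] = round(
                    time.perf_counter() - self.t0, 3)

        return _Timer()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)


def prepare_catalog(model: MetabolicModel, media: list[Medium],
                    permissive: bool = True
                    ) -> tuple[frozenset[str], GeneCatalog]:
    """Blocked-reaction detection followed by gene classification.

    Blocked reactions are found under the given media plus (by default) an
    all-open medium where every exchange imports at a large finite cap (a
    truly unbounded all-open medium would make the growth LP unbounded);
    genes associated only with blocked reactions are purged from the
    catalog's analysis set.
    """
    test_media = list(media)
    if permissive:
        open_medium = Medium("all-open", {r.id: 1000.0
                                          for r in model.exchanges()})
        test_media.append(open_medium)
    blocked = frozenset(find_blocked_reactions(model, test_media))
    catalog = classify_genes(model, set(blocked))
    if catalog.blocked_only:
        logger.info("purged %d genes associated only with blocked reactions",
                    len(catalog.blocked_only))
    return blocked, catalog


def subset_genes(catalog: GeneCatalog, name: str,
                 speed_labels: dict[str, str] | None = None) -> set[str]:
    """Resolve a named gene subset against the catalog.

    ``fast_iso`` / ``slow_iso`` are inclusion subsets: all non-isoenzyme
    genes plus the fast-/slow-labelled isoenzyme from each set (the labels
    come from :func:`fluxcost.evo.classify_isoenzyme_speed`);
    ``fast_iso_only`` / ``slow_iso_only`` restrict to the labelled
    isoenzymes alone.
    """
    genes = catalog.analysis_genes
    iso = catalog.isoenzymes & genes
    if name == "all":
        return genes
    if name == "non_isoenzymes":
        return genes - iso
    if name == "isoenzymes":
        return iso
    if name == "multifunctional_non_isoenzymes":
        return (catalog.multifunctional & genes) - iso
    if name in ("fast_iso", "slow_iso", "fast_iso_only", "slow_iso_only"):
        if speed_labels is None:
            raise ValueError(f"subset {name!r} requires isoenzyme speed labels")
        speed = "fast" if name.startswith("fast") else "slow"
        chosen = {g for g, lab in speed_labels.items()
                  if lab == speed} & genes
        return chosen if name.endswith("_only") else (genes - iso) | chosen
    raise ValueError(f"unknown gene subset {name!r}; one of {SUBSETS}")


@dataclass
class CorrelationReport:
    cost_table: pd.DataFrame
    khat: pd.Series
    speed_labels: dict[str, str]
    distributions: dict[tuple[str, str], CorrelationDistribution]
    summary: pd.DataFrame
    blocked: frozenset[str]
    catalog: GeneCatalog


def run_correlation_study(model: MetabolicModel,
                          rates: dict[str, dict[str, float]],
                          media: list[Medium],
                          subsets: tuple[str, ...] = SUBSETS[:6],
                          metrics: tuple[str, ...] = COST_METRICS,
                          blocked: frozenset[str] | None = None,
                          catalog: GeneCatalog | None = None
                          ) -> CorrelationReport:
    """Costs on all media -> rank-averaged rates -> correlation distributions.

    Subsets without enough genes are skipped with a warning rather than
    failing the whole study (a fixture without isoenzymes simply yields no
    isoenzyme panel).
    """
    if blocked is None or catalog is None:
        blocked, catalog = prepare_catalog(model, media)
    costs = compute_cost_table(model, media, blocked=blocked, catalog=catalog)
    khat = average_rank_rate(rates)
    iso_sets = [isoenzyme_set(expr) for rid, expr in model.gpr.items()
                if rid not in blocked and isoenzyme_set(expr)]
    speed_labels = classify_isoenzyme_speed(iso_sets, khat) if iso_sets else {}
    distributions: dict[tuple[str, str], CorrelationDistribution] = {}
    rows = []
    for subset in subsets:
        genes = subset_genes(catalog, subset, speed_labels)
        if len(genes) < 3:
            logger.warning("subset %s skipped: only %d genes", subset,
                           len(genes))
            continue
        for metric in metrics:
            dist = correlation_distribution(costs, metric, khat,
                                            genes=genes, subset_name=subset)
            if not dist.rho:
                logger.warning("subset %s / metric %s: no medium yielded a "
                               "defined correlation", subset, metric)
                continue
            distributions[(metric, subset)] = dist
            rows.append((metric, subset, len(genes), len(dist.rho),
                         dist.mean, dist.std))
    summary = pd.DataFrame(rows, columns=["metric", "subset", "n_genes",
                                          "n_media", "mean_rho", "sd_rho"])
    return CorrelationReport(costs, khat, speed_labels, distributions,
                             summary, blocked, catalog)


@dataclass
class InteractionReport:
    predictions: dict[str, list[EpistasisRecord]]  # semantics -> records
    comparisons: dict[str, InteractionComparison]
    pr_curves: dict[str, pd.DataFrame]
    n_pairs_input: int
    n_pairs_compared: int


def run_interaction_study(model: MetabolicModel,
                          experimental: pd.DataFrame,
                          medium: Medium,
                          wt_fitness: float = 1.0,
                          wt_sd: float = 0.05,
                          blocked: frozenset[str] = frozenset()
                          ) -> InteractionReport:
    """Epistasis predictions under both semantics scored against experiment.

    The experimental table is first filtered to pairs whose single-mutant
    fitnesses do not exceed the wild type by more than two standard
    deviations; predictions are then made for the remaining pairs only.
    An empty pair table yields an empty (but well-formed) report.
    """
    n_input = len(experimental)
    filtered = filter_deletion_fitness(experimental, wt_fitness, wt_sd)
    model_genes = model.genes
    pairs = [(i, j) for i, j in zip(filtered["gene_i"], filtered["gene_j"])
             if i in model_genes and j in model_genes]
    predictions, comparisons, pr_curves = {}, {}, {}
    for semantics in ("redundant", "nonredundant"):
        records = predict_pairwise(model, pairs, medium,
                                   semantics=semantics, blocked=blocked)
        predictions[semantics] = records
        if records:
            comparisons[semantics] = compare_with_experiment(records, filtered)
            pr_curves[semantics] = precision_recall_curve(records, filtered)
        else:
            pr_curves[semantics] = pd.DataFrame(
                columns=["cutoff", "class", "precision", "recall"])
    return InteractionReport(predictions, comparisons, pr_curves,
                             n_input, len(pairs))
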