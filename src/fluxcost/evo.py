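"""Evolutionary-rate processing and cost/rate correlation distributions.

Per-gene evolutionary rates are d_N/d_S ratios (k) against orthologs in
several related species.  Because raw ratios are not comparable across
species, each species' ratios are converted to ranks (1 = slowest, i.e.
strongest purifying selection, within that species among genes with data) and
each gene's representative rate k-hat is the mean of its ranks over the
species where it has an ortholog.  Genes with no ortholog in any species are
excluded.  Being rank-based, every downstream correlation is invariant to
monotone transforms of the raw ratios.

A correlation distribution collects, for one cost metric and one gene subset,
the Spearman rank correlation between cost and k-hat separately in each
growth-supporting medium.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["average_rank_rate", "rates_from_tsv", "spearman_correlation",
           "CorrelationDistribution", "correlation_distribution",
           "classify_isoenzyme_speed", "compare_distributions",
           "DistributionComparison"]

logger = logging.getLogger(__name__)


def rates_from_tsv(path) -> dict[str, dict[str, float]]:
    """Read a long-format rate table (columns: gene, species, dnds)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "species", "dnds"} - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        if pd.notna(row.dnds):
            out.setdefault(row.gene, {})[row.species] = float(row.dnds)
    return out


def average_rank_rate(rates: dict[str, dict[str, float]]) -> pd.Series:
    """Species-wise rank-average of per-gene evolutionary rates.

    Within each species, genes with data are ranked ascending by d_N/d_S
    (ties get average ranks); a gene's k-hat is the mean of its ranks over
    the species where it has data.  Genes with no data in any species are
    excluded from the output (logged).
    """
    if not rates:
        raise ValueError("empty rate table")
    wide = pd.DataFrame.from_dict(rates, orient="index").astype(float)
    no_data = wide.index[wide.notna().sum(axis=1) == 0]
    if len(no_data):
        logger.warning("excluding %d genes with no ortholog in any species: %s",
                       len(no_data), sorted(no_data)[:10])
        wide = wide.drop(index=no_data)
    if wide.empty:
        raise ValueError("no gene has a rate in any species")
    ranks = wide.rank(axis=0, method="average", na_option="keep")
    khat = ranks.mean(axis=1, skipna=True)
    khat.name = "khat"
    return khat.sort_index()


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationDistribution:
    """Per-medium Spearman correlations for one cost metric and gene subset."""

    metric: str
    subset: str
    rho: dict[str, float] = field(default_factory=dict)
    skipped_media: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.rho[m] for m in sorted(self.rho)])

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.rho else float("nan")

    @property
    def std(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.rho) > 1 else float("nan")


def correlation_distribution(costs: pd.DataFrame, metric: str,
                             khat: pd.Series,
                             genes: set[str] | None = None,
                             subset_name: str = "all"
                             ) -> CorrelationDistribution:
    """One Spearman rho per medium between a cost column and k-hat.

    Genes are paired by identifier after dropping genes missing either
    value; media with fewer than 3 paired genes, or with zero variance in
    either variable (undefined rho), are skipped with a warning.
    """
    if metric not in costs.columns:
        raise ValueError(f"unknown cost column {metric!r}")
    khat = pd.Series(khat).rename("khat")
    dist = CorrelationDistribution(metric=metric, subset=subset_name)
    table = costs if genes is None else costs[costs["gene"].isin(genes)]
    for medium, grp in table.groupby("medium", sort=True):
        merged = grp.set_index("gene")[metric].to_frame().join(khat, how="inner")
        merged = merged.dropna()
        if (len(merged) < 3
                or merged[metric].nunique() < 2
                or merged["khat"].nunique() < 2):
            logger.warning("medium %s skipped for %s/%s: "
                           "<3 paired genes or zero variance",
                           medium, metric, subset_name)
            dist.skipped_media.append(medium)
            continue
        dist.rho[medium] = spearman_correlation(merged[metric].to_numpy(),
                                                merged["khat"].to_numpy())
    return dist


def classify_isoenzyme_speed(sets: list[frozenset[str]],
                             khat: pd.Series | dict[str, float]
                             ) -> dict[str, str]:
    """Label each isoenzyme as fast-, slow-evolving or neutral within its set.

    Per set with >= 2 rated members: the highest k-hat is "fast", the lowest
    "slow", everything else "neutral"; sets with fewer than two rated members
    are entirely neutral.  Ties, and genes appearing in several sets, are
    resolved deterministically: ties by identifier order, multi-set
    membership by majority vote over the per-set labels then by a fixed
    label preference (fast, slow, neutral); both are logged.
    """
    khat = dict(khat)
    per_gene: dict[str, list[str]] = {}
    for iso_set in sets:
        members = sorted(iso_set)
        rated = [g for g in members if g in khat]
        if len(rated) < 2:
            labels = {g: "neutral" for g in members}
        else:
            hi = max(khat[g] for g in rated)
            lo = min(khat[g] for g in rated)
            fast = min(g for g in rated if khat[g] == hi)
            slow_pool = [g for g in rated if khat[g] == lo and g != fast]
            if not slow_pool:  # all rated members tied
                logger.warning("isoenzyme set %s: all rates tied; "
                               "fast/slow assigned by identifier order", members)
                slow_pool = [g for g in rated if g != fast]
            slow = min(slow_pool)
            labels = {g: "neutral" for g in members}
            labels[fast] = "fast"
            labels[slow] = "slow"
        for g, lab in labels.items():
            per_gene.setdefault(g, []).append(lab)
    out: dict[str, str] = {}
    for g, labels in per_gene.items():
        if len(set(labels)) > 1:
            logger.warning("gene %s has conflicting speed labels %s; "
                           "resolved by majority", g, labels)
        counts = Counter(labels)
        best = max(counts.values())
        out[g] = next(lab for lab in ("fast", "slow", "neutral")
                      if counts.get(lab) == best)
    return out


@dataclass
class DistributionComparison:
    statistic: float
    pvalue: float
    mean_difference: float  # mean(d2) - mean(d1)
    n_media: int


def compare_distributions(d1: CorrelationDistribution,
                          d2: CorrelationDistribution
                          ) -> DistributionComparison:
    """Paired Wilcoxon signed-rank test on per-medium rho values."""
    if set(d1.rho) != set(d2.rho):
        raise ValueError("distributions cover different media; pairing undefined")
    media = sorted(d1.rho)
    a = np.array([d1.rho[m] for m in media])
    b = np.array([d2.rho[m] for m in media])
    if np.allclose(a, b):
        return DistributionComparison(0.0, 1.0, float(np.mean(b - a)), len(media))
    res = stats.wilcoxon(a, b)
    return DistributionComparison(float(res.statistic), float(res.pvalue),
                                  float(np.mean(b - a)), len(media))
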