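"""The prevalence-threshold sweep and its downstream comparisons.

The sweep asks one question: as a core microbiome is defined ever more
strictly (taxa kept only if detected in ≥ t of samples, t = 0, 0.1, …, 0.9),
what happens to each sample's alpha diversity and to its mean beta
dissimilarity from the rest of the dataset?

Procedure per dataset: drop samples under the rarefaction floor, rarefy the
rest to a common depth (default 10,000 reads), filter the *rarefied* table
at each threshold independently, score every configured metric, and
z-standardize scores within each (dataset, metric) group across all
thresholds jointly, so datasets with different absolute diversity can be
compared on one scale.  Downstream: Bartlett's test for variance change
across thresholds, Spearman correlations of filtered vs unfiltered scores,
and a read-depth bias check (reads surviving the filter vs score).

Samples emptied by a harsh filter receive missing scores — not zeros — and
all correlations use pairwise deletion of missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from . import diversity
from .diversity import ALPHA_METRICS, mean_dissimilarity_per_sample, pairwise_matrix
from .errors import CongruenceError, ParameterError, UndefinedValueError
from .io import FeatureTable, SampleMetadata
from .tree import Phylogeny

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 0.91, 0.1), 1))
DEFAULT_BETA = ("jaccard", "unweighted-unifrac", "morisita", "weighted-unifrac")

__all__ = [
    "SweepConfig",
    "TestResult",
    "rarefy_table",
    "prevalence_filter",
    "run_sweep",
    "standardize",
    "bartlett_test",
    "spearman",
    "core_vs_unfiltered",
    "depth_bias",
    "variance_profile",
]


@dataclass(frozen=True)
class SweepConfig:
    """Everything the sweep needs to be reproducible."""

    rarefaction_depth: int = 10_000
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    alpha_metrics: tuple[str, ...] = ALPHA_METRICS
    beta_metrics: tuple[str, ...] = DEFAULT_BETA
    theta: float = 0.5
    normalized_unifrac: bool = True
    rarefy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ParameterError("thresholds must be strictly increasing in [0, 1)")
        if self.rarefaction_depth < 1:
            raise ParameterError("rarefaction depth must be >= 1")
        unknown = set(self.beta_metrics) - set(diversity.BETA_METRICS)
        unknown |= set(self.alpha_metrics) - set(ALPHA_METRICS)
        if unknown:
            raise ParameterError(f"unknown metrics: {sorted(unknown)}")


@dataclass
class TestResult:
    """Outcome of one of the pipeline's hypothesis tests."""

    statistic: float
    df: float
    pvalue: float
    method: str


# --------------------------------------------------------------------- #
# normalization and filtering
# --------------------------------------------------------------------- #
def rarefy_table(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged); taxa left
    with zero total are removed.  Deterministic given the seed.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    totals = table.library_sizes()
    keep = np.flatnonzero(totals >= depth)
    dropped = [table.sample_ids[i] for i in np.flatnonzero(totals < depth)]
    if dropped:
        logger.info(
            "rarefy_table: dropping %d sample(s) under %d reads: %s",
            len(dropped), depth, dropped[:10],
        )
    if keep.size == 0:
        raise UndefinedValueError(f"no sample has >= {depth} reads")
    rng = np.random.default_rng(seed)
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        if totals[keep[i]] == depth:
            out[i] = sub.counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    return FeatureTable(sub.sample_ids, sub.taxon_ids, out).drop_empty_taxa()


def prevalence_filter(table: FeatureTable, threshold: float) -> FeatureTable:
    """Keep taxa with occupancy ≥ threshold (inclusive boundary).

    Occupancy is computed on the input table; samples are never dropped
    here, even if the filter empties them — emptiness surfaces downstream
    as missing scores.  Threshold 0 returns the input unchanged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must be in [0, 1]")
    if threshold == 0.0:
        return table
    keep = np.flatnonzero(table.occupancy() >= threshold)
    return table.select_taxa(keep)


# --------------------------------------------------------------------- #
# the sweep itself
# --------------------------------------------------------------------- #
def _beta_mean_scores(
    filt: FeatureTable,
    tree: Phylogeny | None,
    metrics: tuple[str, ...],
    normalized: bool,
) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {}
    for metric in metrics:
        try:
            mat = pairwise_matrix(filt, tree=tree, metric=metric, normalized=normalized)
            out[metric] = mean_dissimilarity_per_sample(mat)
        except UndefinedValueError:
            out[metric] = pd.Series(dtype=float)
    return out


def run_sweep(
    table: FeatureTable,
    tree: Phylogeny,
    metadata: SampleMetadata | None,
    config: SweepConfig,
) -> pd.DataFrame:
    """Score every (dataset, sample, threshold, metric) combination.

    Returns a long-format frame with columns ``dataset, sample, threshold,
    metric, kind, score, z, reads`` where ``reads`` is the per-sample read
    count remaining after prevalence filtering and ``z`` the per
    (dataset, metric) standardized score.  Filtering and rarefaction happen
    once per threshold, not once per metric.
    """
    missing = set(table.taxon_ids) - set(tree.leaf_labels)
    if missing:
        raise CongruenceError(f"table taxa absent from tree: {sorted(missing)[:5]}")
    if metadata is None:
        metadata = SampleMetadata()
    labels = [metadata.label_for(s) for s in table.sample_ids]
    datasets = sorted(set(labels))
    seeds = np.random.SeedSequence(config.seed).spawn(len(datasets))
    rows: list[dict] = []
    for dataset, dseed in zip(datasets, seeds):
        idx = [i for i, lab in enumerate(labels) if lab == dataset]
        sub = table.select_samples(idx).drop_empty_taxa()
        if config.rarefy:
            sub = rarefy_table(
                sub, config.rarefaction_depth,
                seed=int(dseed.generate_state(1)[0] % (2**31)),
            )
        for t in config.thresholds:
            filt = prevalence_filter(sub, float(t))
            reads = pd.Series(filt.library_sizes(), index=filt.sample_ids)
            emptied = reads.index[reads == 0]
            if len(emptied):
                logger.info(
                    "sweep %s t=%.1f: %d sample(s) emptied by filtering",
                    dataset, t, len(emptied),
                )
            alpha = diversity.alpha_diversity_table(
                filt, tree=tree, metrics=config.alpha_metrics, theta=config.theta
            )
            alpha.loc[reads == 0, :] = np.nan  # emptied -> missing, incl. richness
            beta = _beta_mean_scores(
                filt, tree, config.beta_metrics, config.normalized_unifrac
            )
            for sample in filt.sample_ids:
                for metric in config.alpha_metrics:
                    rows.append(
                        dict(dataset=dataset, sample=sample, threshold=float(t),
                             metric=metric, kind="alpha",
                             score=float(alpha.at[sample, metric]),
                             reads=int(reads[sample]))
                    )
                for metric in config.beta_metrics:
                    val = beta[metric].get(sample, np.nan)
                    rows.append(
                        dict(dataset=dataset, sample=sample, threshold=float(t),
                             metric=metric, kind="beta", score=float(val),
                             reads=int(reads[sample]))
                    )
    result = pd.DataFrame(rows)
    return standardize(result)


def standardize(result: pd.DataFrame) -> pd.DataFrame:
    """Add a z-score column, centered/scaled per (dataset, metric).

    Group statistics pool all thresholds jointly (sd with the n−1
    denominator); missing scores propagate, and zero-variance groups yield
    missing z with a warning.
    """
    out = result.copy()

    def _z(s: pd.Series) -> pd.Series:
        vals = s.dropna()
        if len(vals) < 2:
            return pd.Series(np.nan, index=s.index)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("standardize: zero variance in a (dataset, metric) group")
            return pd.Series(np.nan, index=s.index)
        return (s - vals.mean()) / sd

    out["z"] = (
        out.groupby(["dataset", "metric"], sort=False)["score"].transform(_z)
    )
    return out


# --------------------------------------------------------------------- #
# hypothesis tests (from-scratch; scipy only for distributions)
# --------------------------------------------------------------------- #
def bartlett_test(groups: list[np.ndarray]) -> TestResult:
    """Bartlett's test for homogeneity of variances across k groups.

    K² = [(N−k) ln s_p² − Σ (n_i−1) ln s_i²] / C with the usual small-sample
    correction C; the p-value is the chi-square upper tail on k−1 df.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    k = len(arrays)
    if k < 2 or any(a.size < 2 for a in arrays):
        raise ParameterError("Bartlett needs >= 2 groups with >= 2 values each")
    n_i = np.array([a.size for a in arrays], dtype=float)
    s2 = np.array([a.var(ddof=1) for a in arrays])
    if np.any(s2 == 0):
        raise UndefinedValueError("Bartlett statistic undefined: a group has zero variance")
    n_tot = n_i.sum()
    sp2 = ((n_i - 1) @ s2) / (n_tot - k)
    num = (n_tot - k) * np.log(sp2) - (n_i - 1) @ np.log(s2)
    c = 1.0 + (np.sum(1.0 / (n_i - 1)) - 1.0 / (n_tot - k)) / (3.0 * (k - 1))
    stat = num / c
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(float(stat), float(k - 1), p, "bartlett")


def spearman(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation with midranks and the t approximation.

    Pairs with a missing value in either vector are deleted; requires at
    least 3 complete pairs and non-constant ranks on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise UndefinedValueError("Spearman needs >= 3 complete pairs")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedValueError("Spearman undefined: constant ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-12:  # rounding guard: identical rank vectors
        rho = 1.0 if rho > 0 else -1.0
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(rho, float(n - 2), p, "spearman")


# --------------------------------------------------------------------- #
# downstream comparisons over a sweep result
# --------------------------------------------------------------------- #
def _safe_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    try:
        res = spearman(x, y)
        return res.statistic, res.pvalue
    except UndefinedValueError:
        return np.nan, np.nan


def core_vs_unfiltered(result: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of each threshold's per-sample scores vs threshold 0.

    One row per (dataset, metric, threshold > 0); samples missing at either
    threshold are dropped pairwise.
    """
    rows = []
    for (dataset, metric), grp in result.groupby(["dataset", "metric"]):
        wide = grp.pivot_table(index="sample", columns="threshold", values="score",
                               dropna=False)
        if 0.0 not in wide.columns:
            raise ParameterError("core_vs_unfiltered requires threshold-0 scores")
        base = wide[0.0].to_numpy()
        for t in sorted(c for c in wide.columns if c > 0):
            rho, p = _safe_spearman(base, wide[t].to_numpy())
            rows.append(dict(dataset=dataset, metric=metric, threshold=t,
                             rho=rho, pvalue=p))
    return pd.DataFrame(rows)


def depth_bias(result: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of score vs reads remaining, per dataset/metric/threshold.

    Where the filtered read depth is constant across samples (always true at
    threshold 0 on a rarefied table) the correlation is undefined and
    reported missing.  No direction is asserted anywhere: read-depth bias
    has no consistent sign across datasets.
    """
    rows = []
    cols = ["dataset", "metric", "threshold"]
    for (dataset, metric, t), grp in result.groupby(cols):
        rho, p = _safe_spearman(grp["reads"].to_numpy(dtype=float),
                                grp["score"].to_numpy())
        rows.append(dict(dataset=dataset, metric=metric, threshold=t,
                         rho=rho, pvalue=p))
    return pd.DataFrame(rows)


def variance_profile(result: pd.DataFrame, per_dataset: bool = False) -> pd.DataFrame:
    """Bartlett's test with thresholds as groups, per metric.

    Standardized scores are pooled across datasets by default (set
    ``per_dataset=True`` for one test per dataset).  Thresholds with fewer
    than two finite scores, or with zero variance (every sample scoring
    identically, common once a harsh filter leaves a handful of taxa), are
    left out of the test with a warning.
    """
    rows = []
    group_cols = ["dataset", "metric"] if per_dataset else ["metric"]
    for keys, grp in result.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        groups = [
            g["z"].dropna().to_numpy()
            for _, g in grp.groupby("threshold")
        ]
        usable = [g for g in groups if g.size >= 2 and g.var(ddof=1) > 0]
        if len(usable) < len([g for g in groups if g.size >= 2]):
            logger.warning(
                "variance_profile %s: dropping zero-variance threshold group(s)",
                keys,
            )
        groups = usable
        rec = dict(zip(group_cols, keys))
        if len(groups) < 2:
            rec.update(statistic=np.nan, df=np.nan, pvalue=np.nan)
        else:
            res = bartlett_test(groups)
            rec.update(statistic=res.statistic, df=res.df, pvalue=res.pvalue)
        rows.append(rec)
    return pd.DataFrame(rows)
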