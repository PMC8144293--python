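"""Detection-rate curves, richness extrapolation and occupancy diagnostics.

These are the classic macroecological summaries of an ASV table:

* rarefaction within a sample (expected richness vs sequencing depth,
  hypergeometric closed form or seeded subsampling),
* taxon accumulation across samples (permutation curves plus the exact
  combinatorial expectation),
* first-order jackknife extrapolation of the total taxon pool,
  S_jack1 = S_obs + f1 (n−1)/n, and its dependence on sample size,
* occupancy–abundance and rank–abundance relationships, and the
  distribution of taxa over occupancy classes (1, 2, …, 8+ samples).

All binomial coefficients are evaluated in log space (gammaln) so the exact
formulas remain stable at read depths of 1e5 and beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ParameterError
from .io import FeatureTable

__all__ = [
    "IncidenceSummary",
    "AccumulationCurve",
    "rarefaction_curve",
    "sample_accumulation",
    "jackknife1",
    "pool_accumulation",
    "percent_detected",
    "occupancy_abundance",
    "rank_abundance",
    "prevalence_class_distributions",
]


@dataclass
class IncidenceSummary:
    """Incidence (presence/absence) summary of a table.

    ``f_k[k-1]`` is the number of taxa occurring in exactly k samples, so
    ``f_k.sum() == s_obs``; ``occupancy`` is the per-taxon detection
    fraction o_j.
    """

    n: int
    s_obs: int
    f_k: np.ndarray
    occupancy: np.ndarray = field(repr=False)

    @classmethod
    def from_table(cls, table: FeatureTable) -> "IncidenceSummary":
        incidence = (table.counts > 0).sum(axis=0)
        observed = incidence[incidence > 0]
        n = table.n_samples
        f_k = np.bincount(observed, minlength=n + 1)[1:]
        return cls(
            n=n,
            s_obs=int(observed.size),
            f_k=f_k,
            occupancy=incidence / n,
        )

    @property
    def f1(self) -> int:
        """Number of taxa found in exactly one sample."""
        return int(self.f_k[0]) if self.f_k.size else 0


@dataclass
class AccumulationCurve:
    """Mean/dispersion of a statistic on growing accumulations of samples."""

    k: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    permutations: int
    seed: int
    exact: np.ndarray | None = None

    def to_frame(self, statistic: str = "richness") -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.k,
                "statistic": statistic,
                "mean": self.mean,
                "sd": self.sd,
                "permutations": self.permutations,
                "seed": self.seed,
            }
        )
        if self.exact is not None:
            df["exact"] = self.exact
        return df


def _log_choose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log C(a, b), -inf where b > a (choosing more than available)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where(b > a, -np.inf, out)


def rarefaction_curve(
    counts: np.ndarray,
    depth_grid: list[int] | np.ndarray,
    mode: str = "exact",
    iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected richness of a sample rarefied to each depth in the grid.

    Exact mode evaluates the hypergeometric formula
    E[S_m] = Σ_j [1 − C(N − x_j, m) / C(N, m)] in log space; subsample mode
    averages observed richness over seeded draws without replacement.
    Returns columns (depth, mean, sd); the exact sd is left as 0.
    """
    counts = np.asarray(counts)
    x = counts[counts > 0].astype(np.int64)
    total = int(x.sum())
    depths = np.asarray(depth_grid, dtype=np.int64)
    if np.any(depths < 1) or np.any(depths > total):
        raise ParameterError(f"depths must lie in [1, {total}]")
    if mode == "exact":
        means = np.empty(depths.size)
        for i, m in enumerate(depths):
            log_absent = _log_choose(total - x, m) - _log_choose(total, m)
            means[i] = float(np.sum(1.0 - np.exp(log_absent)))
        sds = np.zeros_like(means)
    elif mode == "subsample":
        rng = np.random.default_rng(seed)
        rich = np.empty((iterations, depths.size))
        for it in range(iterations):
            for i, m in enumerate(depths):
                draw = rng.multivariate_hypergeometric(x, int(m))
                rich[it, i] = np.count_nonzero(draw)
        means = rich.mean(axis=0)
        sds = rich.std(axis=0, ddof=1) if iterations > 1 else np.zeros(depths.size)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return pd.DataFrame({"depth": depths, "mean": means, "sd": sds})


def _exact_accumulation(incidence_counts: np.ndarray, n: int) -> np.ndarray:
    """E[S_k] = Σ_j [1 − C(n − m_j, k) / C(n, k)] for k = 1..n."""
    m = incidence_counts[incidence_counts > 0].astype(np.int64)
    ks = np.arange(1, n + 1)
    out = np.empty(n)
    for i, k in enumerate(ks):
        log_absent = _log_choose(n - m, k) - _log_choose(n, k)
        out[i] = float(np.sum(1.0 - np.exp(log_absent)))
    return out


def sample_accumulation(
    table: FeatureTable, permutations: int = 999, seed: int = 0
) -> AccumulationCurve:
    """Taxon accumulation with sample size.

    Mean and sd of the richness of the union of the first k samples over
    random sample orderings, for k = 1..n; the ``exact`` field carries the
    closed-form expectation for validation.
    """
    n = table.n_samples
    if n < 2:
        raise ParameterError("sample accumulation needs at least two samples")
    incidence = table.counts > 0
    rng = np.random.default_rng(seed)
    rich = np.empty((permutations, n))
    for p in range(permutations):
        order = rng.permutation(n)
        cum = np.logical_or.accumulate(incidence[order], axis=0)
        rich[p] = cum.sum(axis=1)
    exact = _exact_accumulation(incidence.sum(axis=0), n)
    return AccumulationCurve(
        k=np.arange(1, n + 1),
        mean=rich.mean(axis=0),
        sd=rich.std(axis=0, ddof=1),
        permutations=permutations,
        seed=seed,
        exact=exact,
    )


def jackknife1(summary: IncidenceSummary) -> float:
    """First-order jackknife richness estimate S_obs + f1 (n−1)/n."""
    if summary.n < 2:
        raise ParameterError("jackknife1 requires at least two samples")
    return summary.s_obs + summary.f1 * (summary.n - 1) / summary.n


def pool_accumulation(
    table: FeatureTable, permutations: int = 200, seed: int = 0
) -> AccumulationCurve:
    """Jackknife-1 pool estimate as a function of sample size.

    For each k = 2..n, the mean and sd over random sample orderings of the
    jackknife-1 estimate computed on the first k samples; the final point is
    the full-table estimate with zero dispersion.
    """
    n = table.n_samples
    if n < 3:
        raise ParameterError("pool accumulation needs at least three samples")
    incidence = (table.counts > 0).astype(np.int32)
    rng = np.random.default_rng(seed)
    ks = np.arange(2, n + 1)
    est = np.empty((permutations, ks.size))
    for p in range(permutations):
        order = rng.permutation(n)
        cum = np.cumsum(incidence[order], axis=0)  # occurrences among first k
        s_obs = (cum > 0).sum(axis=1)
        f1 = (cum == 1).sum(axis=1)
        est[p] = s_obs[1:] + f1[1:] * (ks - 1) / ks
    return AccumulationCurve(
        k=ks,
        mean=est.mean(axis=0),
        sd=est.std(axis=0, ddof=1),
        permutations=permutations,
        seed=seed,
    )


def percent_detected(
    table: FeatureTable, permutations: int = 0, seed: int = 0
) -> tuple[pd.DataFrame, int | None]:
    """Percent of the predicted taxon pool detected at each sample size.

    Uses the exact accumulation expectation E[S_k] against the full-table
    jackknife-1 pool: 100 · E[S_k] / S_jack1.  Returns the curve and the
    smallest k whose value reaches 50% (None if never reached).
    """
    n = table.n_samples
    if n < 3:
        raise ParameterError("percent-detected needs at least three samples")
    summary = IncidenceSummary.from_table(table)
    pool = jackknife1(summary)
    exact = _exact_accumulation((table.counts > 0).sum(axis=0), n)
    pct = 100.0 * exact / pool
    df = pd.DataFrame({"k": np.arange(1, n + 1), "percent_detected": pct})
    reached = df.loc[df["percent_detected"] >= 50.0, "k"]
    return df, (int(reached.iloc[0]) if len(reached) else None)


def occupancy_abundance(
    table: FeatureTable, occupied_only: bool = False
) -> pd.DataFrame:
    """Per-taxon occupancy vs mean relative abundance.

    Mean relative abundance is averaged over *all* samples by default
    (zeros included), the convention behind the classic triangular
    occupancy–abundance cloud; ``occupied_only=True`` averages over the
    samples in which the taxon occurs.
    """
    if not np.any(table.library_sizes() > 0):
        raise ParameterError("occupancy-abundance needs at least one non-empty sample")
    rel = table.relative_abundances()
    occ = table.occupancy()
    if occupied_only:
        present = table.counts > 0
        with np.errstate(invalid="ignore"):
            mean_rel = np.where(
                present.any(axis=0),
                (rel * present).sum(axis=0) / np.maximum(present.sum(axis=0), 1),
                0.0,
            )
    else:
        mean_rel = rel.mean(axis=0)
    return pd.DataFrame(
        {"taxon": table.taxon_ids, "occupancy": occ, "mean_relative_abundance": mean_rel}
    )


def rank_abundance(table: FeatureTable) -> pd.DataFrame:
    """Mean relative abundances in decreasing order (rank–abundance curve).

    For a table whose samples are all non-empty the curve sums to 1.
    """
    oa = occupancy_abundance(table)
    vals = np.sort(oa["mean_relative_abundance"].to_numpy())[::-1]
    return pd.DataFrame(
        {"rank": np.arange(1, vals.size + 1), "mean_relative_abundance": vals}
    )


def prevalence_class_distributions(
    table: FeatureTable, top_class: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion of taxa in occupancy classes 1, 2, …, ``top_class``+.

    Returns two proper probability vectors over classes: the dataset-level
    distribution (fraction of all observed taxa occurring in exactly k
    samples, with the top class absorbing ≥ top_class), and the per-sample
    view (for each sample, the fraction of *its* taxa in each class,
    averaged over samples) — the "how unique is each sample's community"
    companion plot.
    """
    n = table.n_samples
    if n < top_class:
        raise ParameterError(f"need at least {top_class} samples for {top_class}+ classes")
    incidence = (table.counts > 0).sum(axis=0)
    observed = incidence > 0
    cls = np.minimum(incidence, top_class)  # 0 for unobserved
    classes = np.arange(1, top_class + 1)
    dataset_counts = np.array([(cls[observed] == c).sum() for c in classes], dtype=float)
    dataset_prop = dataset_counts / observed.sum()

    present = table.counts > 0
    per_sample = np.zeros((n, top_class))
    for i in range(n):
        mine = cls[present[i]]
        if mine.size:
            per_sample[i] = [(mine == c).mean() for c in classes]
    labels = [str(c) for c in classes[:-1]] + [f"{top_class}+"]
    dataset_df = pd.DataFrame({"occupancy_class": labels, "proportion": dataset_prop})
    sample_df = pd.DataFrame(
        {"occupancy_class": labels, "mean_proportion": per_sample.mean(axis=0)}
    )
    return dataset_df, sample_df
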