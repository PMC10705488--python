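"""Rate estimation and resampling statistics for LOH cohorts.

Rates follow the standard MA-line estimator: with ``k`` events observed (or
inferred) across ``n`` lines propagated for ``T`` generations, the event
rate is ``k / (n T)`` per genome per generation, or ``k / (n T L)`` per bp
per generation within a region of length ``L``.  Group comparisons use
label-reshuffling permutation tests (difference of means or medians) and a
one-dimensional Wasserstein two-sample test on event positions; multiple
windows are corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .markers import MarkerMap

__all__ = [
    "TestResult", "event_rate", "conversion_rate", "bootstrap_ci",
    "permutation_test", "wasserstein_test", "arm_chisq", "bh_adjust",
    "normalized_rate", "window_rates", "arm_counts",
]

_EXACT_LIMIT = 200_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_resamples: int
    null: str
    adjusted_p: float | None = None


def event_rate(k: float, n: int, T: float, L: float | None = None) -> float:
    """LOH event rate: per genome per generation, or per bp when ``L`` given."""
    if n <= 0 or T <= 0:
        raise ValueError("n and T must be > 0")
    rate = k / (n * T)
    if L is not None:
        if L <= 0:
            raise ValueError("L must be > 0")
        rate /= L
    return rate


def conversion_rate(fractions, T: float) -> float:
    """Per-bp per-generation probability of losing heterozygosity.

    ``fractions`` are per-clone fractions of the heterozygous genome
    converted by the end of the experiment; the rate is their mean over T.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if T <= 0:
        raise ValueError("T must be > 0")
    return float(np.mean(f)) / T


def bootstrap_ci(
    values,
    n_boot: int = 1_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-clone values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two clones")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _group_stat(stat: str, x: np.ndarray, axis=None):
    if stat == "mean":
        return np.mean(x, axis=axis)
    if stat == "median":
        return np.median(x, axis=axis)
    raise ValueError("statistic must be 'mean' or 'median'")


def permutation_test(
    values_a,
    values_b,
    statistic: str = "mean",
    n_perm: int = 1_000,
    sidedness: str = "two-sided",
    method: str = "auto",
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Label-reshuffling test on the difference of group means/medians.

    Monte-Carlo p-values use the add-one convention
    ``p = (1 + #extreme) / (1 + n_perm)`` and are never exactly zero.
    ``method='exact'`` enumerates all label splits (small groups only);
    ``'auto'`` switches to exact when the number of splits is below the
    Monte-Carlo resample count.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    if method not in ("auto", "exact", "mc"):
        raise ValueError("method must be 'auto', 'exact' or 'mc'")
    pooled = np.concatenate([a, b])
    na = a.size
    observed = float(_group_stat(statistic, a) - _group_stat(statistic, b))

    n_splits = math.comb(pooled.size, na)
    use_exact = method == "exact" or (method == "auto" and n_splits <= min(n_perm, _EXACT_LIMIT))
    if use_exact and n_splits > _EXACT_LIMIT:
        raise ValueError(f"{n_splits} label splits: too many for exact enumeration")

    if use_exact:
        diffs = np.empty(n_splits)
        all_idx = np.arange(pooled.size)
        for i, comb_idx in enumerate(combinations(range(pooled.size), na)):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb_idx)] = True
            diffs[i] = _group_stat(statistic, pooled[mask]) - _group_stat(statistic, pooled[~mask])
        extreme = _count_extreme(diffs, observed, sidedness)
        p = extreme / n_splits
        return TestResult(observed, float(p), n_splits,
                          f"exact permutation of {statistic} difference")

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diffs = _group_stat(statistic, perm[:, :na], axis=1) - _group_stat(statistic, perm[:, na:], axis=1)
    extreme = _count_extreme(diffs, observed, sidedness)
    p = (1 + extreme) / (1 + n_perm)
    return TestResult(observed, float(p), n_perm,
                      f"Monte-Carlo permutation of {statistic} difference")


def _count_extreme(diffs: np.ndarray, observed: float, sidedness: str) -> int:
    if sidedness == "two-sided":
        return int(np.sum(np.abs(diffs) >= abs(observed)))
    if sidedness == "greater":
        return int(np.sum(diffs >= observed))
    if sidedness == "less":
        return int(np.sum(diffs <= observed))
    raise ValueError("sidedness must be 'two-sided', 'greater' or 'less'")


def wasserstein_test(
    positions_a,
    positions_b,
    n_mc: int = 5_000,
    method: str = "auto",
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Two-sample Wasserstein test on event positions along a chromosome.

    The statistic is the integral of |E1(x) - E2(x)| between the two
    empirical CDFs (the 1-d earth-mover distance).  The null distribution
    comes from reshuffling group labels over the pooled positions, either by
    Monte Carlo (``n_mc`` reshuffles, add-one p) or exhaustively for tiny
    samples.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one event")
    observed = float(sps.wasserstein_distance(a, b))
    pooled = np.concatenate([a, b])
    na = a.size

    n_splits = math.comb(pooled.size, na)
    use_exact = method == "exact" or (method == "auto" and n_splits <= min(n_mc, 10_000))
    if use_exact:
        dists = np.empty(n_splits)
        for i, comb_idx in enumerate(combinations(range(pooled.size), na)):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb_idx)] = True
            dists[i] = sps.wasserstein_distance(pooled[mask], pooled[~mask])
        p = float(np.sum(dists >= observed)) / n_splits
        return TestResult(observed, p, n_splits, "exact label reshuffling, Wasserstein")

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled)
        if sps.wasserstein_distance(perm[:na], perm[na:]) >= observed:
            extreme += 1
    p = (1 + extreme) / (1 + n_mc)
    return TestResult(observed, float(p), n_mc, "Monte-Carlo label reshuffling, Wasserstein")


def arm_counts(events: pd.DataFrame, map: MarkerMap,
               labels: pd.Series) -> pd.DataFrame:
    """Contingency table of event counts by chromosome arm x founder label.

    ``events`` needs ``clone``, ``chrom`` and ``breakpoint`` columns;
    ``labels`` maps clone id to founder label.  Events are assigned to arms
    by breakpoint position.
    """
    rows = []
    for ev in events.itertuples(index=False):
        arm = map.arm_of(ev.chrom, int(ev.breakpoint))
        rows.append({"label": labels[ev.clone], "arm": f"{ev.chrom}{arm}"})
    tab = pd.DataFrame(rows)
    return tab.groupby(["label", "arm"]).size().unstack(fill_value=0)


def arm_chisq(table: pd.DataFrame | np.ndarray) -> TestResult:
    """Pearson chi-square test on a founder x arm contingency table.

    Arms with zero total count are pooled out (dropped) before testing.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a 2-d table with >=2 founders and >=2 arms")
    keep = tab.sum(axis=0) > 0
    tab = tab[:, keep]
    if tab.shape[1] < 2:
        raise ValueError("fewer than 2 arms with events")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult(float(chi2), float(p), 0, f"chi-square, dof={dof}")


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and discovery flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adjusted, reject


def normalized_rate(r_s: float, r_w: float) -> float:
    """Normalized rate contrast (r_s - r_w) / (r_s + r_w) in [-1, 1].

    Undefined (NaN) when both rates are zero — not 0, which would claim
    equality on no evidence.
    """
    if r_s < 0 or r_w < 0:
        raise ValueError("rates must be >= 0")
    total = r_s + r_w
    if total == 0:
        return float("nan")
    return (r_s - r_w) / total


def window_rates(
    events: pd.DataFrame,
    map: MarkerMap,
    n: int,
    T: float,
    window: int = 50_000,
    slide: int | None = None,
) -> pd.DataFrame:
    """Per-window event counts and per-bp rates, assigned by breakpoint.

    Non-overlapping windows (``slide=None``) partition each chromosome into
    closed intervals [1, w], [w+1, 2w], ... with a shorter, flagged terminal
    window; these are the units for statistical tests.  A ``slide`` (e.g.
    10 kb) yields overlapping windows for smooth rate profiles.  Each event
    is assigned by its breakpoint position, so window counts on a chromosome
    sum to the chromosome's event count in the non-overlapping case.
    """
    if "breakpoint" not in events.columns:
        raise ValueError("events need a 'breakpoint' column")
    rows = []
    for chrom in map.chromosome_names:
        clen = map.length_of(chrom)
        bps = events.loc[events["chrom"] == chrom, "breakpoint"].to_numpy(float)
        starts = range(1, clen + 1, slide if slide else window)
        for start in starts:
            end = min(start + window - 1, clen)
            if end < start:
                continue
            k = int(np.sum((bps >= start) & (bps <= end)))
            L = end - start + 1
            rows.append({
                "chrom": chrom, "start": start, "end": end, "L": L, "k": k,
                "rate": event_rate(k, n, T, L), "short_window": L < window,
            })
    return pd.DataFrame(rows)
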