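"""Statistical power of the MA design to detect LOH-rate increases.

Two procedures:

* *Theoretical* power assumes per-clone event counts are Poisson.  Each
  simulated experiment draws a baseline group with mean ``mu`` and an
  alternate group with mean ``mu (1 + f_e)``, where ``f_e`` is the
  fractional effect size, and compares group means with a two-sided
  permutation test; power is the rejection fraction at level ``alpha``.

* *Observed* power resamples the experiment's own pooled per-clone counts:
  the alternate population is formed by sprinkling ``round(n_total * f_e)``
  additional events uniformly at random over all clones, and groups of the
  actual sample sizes are drawn from the baseline and alternate populations.
  This inherits whatever overdispersion the real counts carry, which is why
  observed power can fall well below the Poisson prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PowerCurve", "theoretical_power", "observed_power",
    "normal_approx_power", "DEFAULT_EFFECT_GRID",
]

DEFAULT_EFFECT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass
class PowerCurve:
    """Detection probability as a function of effect size for one design."""

    design: dict
    table: pd.DataFrame    # columns: f_e, power, se, n_sims

    def power_at(self, f_e: float) -> float:
        row = self.table.loc[np.isclose(self.table["f_e"], f_e)]
        if row.empty:
            raise KeyError(f"effect size {f_e} not on the grid")
        return float(row["power"].iloc[0])


def _perm_pvalue(a: np.ndarray, b: np.ndarray, n_perms: int,
                 rng: np.random.Generator) -> float:
    """Two-sided add-one permutation p-value for the difference of means."""
    pooled = np.concatenate([a, b])
    na = a.size
    observed = abs(a.mean() - b.mean())
    perm = rng.permuted(np.tile(pooled, (n_perms, 1)), axis=1)
    diffs = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
    return (1 + int(np.sum(diffs >= observed))) / (1 + n_perms)


def theoretical_power(
    mu: float = 13.2,
    n_lines: int = 95,
    effect_grid: tuple[float, ...] = DEFAULT_EFFECT_GRID,
    alpha: float = 0.01,
    n_sims: int = 1_000,
    n_perms: int = 1_000,
    seed: int | np.random.Generator | None = None,
) -> PowerCurve:
    """Poisson-model power of an ``n_lines`` vs ``n_lines`` comparison."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for f_e in effect_grid:
        rejections = 0
        for _ in range(n_sims):
            base = rng.poisson(mu, size=n_lines).astype(float)
            alt = rng.poisson(mu * (1.0 + f_e), size=n_lines).astype(float)
            if _perm_pvalue(base, alt, n_perms, rng) <= alpha:
                rejections += 1
        power = rejections / n_sims
        rows.append({"f_e": f_e, "power": power,
                     "se": np.sqrt(power * (1 - power) / n_sims), "n_sims": n_sims})
    design = {"mode": "theoretical", "mu": mu, "n_lines": n_lines,
              "alpha": alpha, "n_sims": n_sims, "n_perms": n_perms,
              "statistic": "mean difference, two-sided"}
    return PowerCurve(design, pd.DataFrame(rows))


def observed_power(
    pooled_counts,
    n_a: int,
    n_b: int,
    effect_grid: tuple[float, ...] = DEFAULT_EFFECT_GRID,
    alpha: float = 0.01,
    n_sims: int = 1_000,
    n_perms: int = 1_000,
    literal_augmentation: bool = False,
    seed: int | np.random.Generator | None = None,
) -> PowerCurve:
    """Resampling-based power using the cohort's own per-clone counts.

    ``pooled_counts`` are the observed event counts of all clones pooled
    across groups.  At effect size ``f_e`` the alternate population gains
    ``round(total * f_e)`` events, placed uniformly at random across clones
    (``literal_augmentation=True`` instead adds ``round(total * (1 + f_e))``
    events, an alternative reading of the augmentation recipe that more
    than doubles the mean).
    """
    counts = np.asarray(pooled_counts, dtype=float)
    if counts.size < max(n_a, n_b):
        raise ValueError("pooled population smaller than a requested sample")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("pooled counts must be non-negative integers")
    total = counts.sum()
    n_clones = counts.size
    rng = np.random.default_rng(seed)
    rows = []
    for f_e in effect_grid:
        factor = (1.0 + f_e) if literal_augmentation else f_e
        n_extra = int(round(total * factor))
        rejections = 0
        for _ in range(n_sims):
            extra = rng.multinomial(n_extra, np.full(n_clones, 1.0 / n_clones))
            alternate = counts + extra
            base_sample = counts[rng.choice(n_clones, size=n_a, replace=False)]
            alt_sample = alternate[rng.choice(n_clones, size=n_b, replace=False)]
            if _perm_pvalue(base_sample, alt_sample, n_perms, rng) <= alpha:
                rejections += 1
        power = rejections / n_sims
        rows.append({"f_e": f_e, "power": power,
                     "se": np.sqrt(power * (1 - power) / n_sims), "n_sims": n_sims})
    design = {"mode": "observed", "n_a": n_a, "n_b": n_b, "alpha": alpha,
              "n_sims": n_sims, "n_perms": n_perms,
              "literal_augmentation": literal_augmentation,
              "statistic": "mean difference, two-sided"}
    return PowerCurve(design, pd.DataFrame(rows))


def normal_approx_power(mu: float, n_lines: int, f_e: float,
                        alpha: float = 0.01) -> float:
    """Closed-form normal approximation to the theoretical power.

    The difference of group means is approximately normal with mean
    ``mu f_e`` and variance ``(mu + mu (1 + f_e)) / n``; a two-sided level-
    ``alpha`` test then rejects with probability
    ``Phi(z - z_{alpha/2}) + Phi(-z - z_{alpha/2})`` where ``z`` is the
    standardized effect.
    """
    delta = mu * f_e
    se = np.sqrt((mu + mu * (1.0 + f_e)) / n_lines)
    z = delta / se
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(z - z_crit) + sps.norm.cdf(-z - z_crit))
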