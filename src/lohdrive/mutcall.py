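"""De novo mutation calling from genotype tables.

Putative variants (sites that are neither parental-difference markers nor
ancestrally heterozygous) are filtered to *unique* variants — those observed
in exactly one end-point clone.  The justification is Poissonian: with a
per-bp per-generation mutation rate mu_bp, the expected number of mutations
hitting one site anywhere in the experiment is mu = mu_bp * T * n_clones,
and the chance of two or more independent hits is 1 - exp(-mu)(1 + mu) ~
mu^2 / 2, negligibly small; recurrent variants are therefore artifacts.
Variants within ``window`` bp of each other in the same clone are grouped
into single "complex" mutation events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_P1, HOM_P2, MISSING

__all__ = [
    "MutationRecord", "impute_founder", "call_de_novo", "merge_complex",
    "count_events", "expected_duplicate_sites",
]


@dataclass
class MutationRecord:
    clone: str
    chrom: str
    position: int
    kind: str                    # "SNM" | "indel"
    zygosity: str = "het"
    complex_group: int | None = None


def impute_founder(
    descendant_calls: np.ndarray,
    other_founder_calls: np.ndarray,
    min_descendants: int = 6,
) -> int:
    """Impute an unsequenced founder's call at one marker site.

    The call is imputed as heterozygous (or homozygous for an allele) only
    if at least ``min_descendants`` of its descendant end-point clones and
    *all* other founders genotyped at the site agree on that call; anything
    less returns MISSING.  MISSING entries among descendants and founders
    are ignored (treated as not genotyped).
    """
    desc = np.asarray(descendant_calls)
    founders = np.asarray(other_founder_calls)
    desc = desc[desc != MISSING]
    founders = founders[founders != MISSING]
    if desc.size == 0:
        return MISSING
    for call in (HET, HOM_P1, HOM_P2):
        if (desc == call).sum() >= min_descendants and np.all(founders == call):
            return call
    return MISSING


def call_de_novo(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep only unique variants — sites observed in exactly one clone.

    ``variants`` needs columns ``clone``, ``chrom``, ``pos`` and optionally
    ``type``; it must already exclude parental-difference (marker) sites and
    ancestrally heterozygous sites.  A site shared by two or more clones is
    dropped entirely.
    """
    required = {"clone", "chrom", "pos"}
    if not required.issubset(variants.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    if variants.empty:
        return variants.copy()
    n_clones = variants.groupby(["chrom", "pos"])["clone"].transform("nunique")
    out = variants[n_clones == 1].copy()
    return out.sort_values(["clone", "chrom", "pos"]).reset_index(drop=True)


def merge_complex(records: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Assign complex-event group ids by single-linkage clustering.

    Variants in the same clone and chromosome within ``window`` bp of each
    other (chains allowed) share a ``complex_group`` id; isolated variants
    get their own singleton group.  Group ids are dense integers ordered by
    (clone, chrom, pos).
    """
    out = records.sort_values(["clone", "chrom", "pos"]).reset_index(drop=True)
    if out.empty:
        out["complex_group"] = pd.Series(dtype=int)
        return out
    gid = np.zeros(len(out), dtype=np.int64)
    current = 0
    prev = None
    for i, row in enumerate(out.itertuples(index=False)):
        if prev is not None and row.clone == prev.clone and row.chrom == prev.chrom \
                and (row.pos - prev.pos) <= window:
            gid[i] = current
        else:
            current = current + 1 if prev is not None else 0
            gid[i] = current
        prev = row
    out["complex_group"] = gid
    return out


def count_events(records: pd.DataFrame) -> int:
    """Number of mutation events, counting each complex group once."""
    if records.empty:
        return 0
    if "complex_group" not in records.columns:
        records = merge_complex(records)
    return int(records["complex_group"].nunique())


def expected_duplicate_sites(
    rate: float, T: float, n_clones: int, L: float
) -> tuple[float, float]:
    """Expected number of genome sites hit by two or more mutations.

    With per-site hit expectation ``mu = rate * T * n_clones`` over the whole
    experiment, ``P(>=2 hits) = 1 - exp(-mu)(1 + mu)``; summed over ``2 L``
    sites of the diploid genome of haploid length ``L``.  Returns the exact
    value and its ``mu^2 / 2`` small-mu approximation.
    """
    if min(rate, T, n_clones, L) < 0:
        raise ValueError("all arguments must be >= 0")
    mu = rate * T * n_clones
    p_exact = 1.0 - math.exp(-mu) * (1.0 + mu)
    p_approx = mu * mu / 2.0
    return 2.0 * L * p_exact, 2.0 * L * p_approx
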