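"""CRISPR off-target site indexing and gRNA similarity scoring.

Cas9 requires a protospacer-adjacent motif (PAM) — canonically -NGG, weakly
-NAG — and its cutting propensity at a site depends on how similar the 20-bp
protospacer immediately 5' of the PAM is to the gRNA spacer.  This module
indexes all NGG/NAG sites on both strands of a genome, scores protospacers
against a gRNA with the empirically weighted MIT/Hsu single-site score, and
relates per-window similarity to normalized LOH-rate contrasts.

The MIT/Hsu score for a protospacer with mismatches to the gRNA at
positions ``p_1..p_m`` (1 = PAM-distal, 20 = PAM-proximal) is::

    score = prod_i (1 - W[p_i]) * 1 / ((19 - d) / 19 * 4 + 1) * 1 / m**2

where ``W`` is the experimentally derived per-position penalty vector,
``d`` is the mean pairwise distance between mismatch positions, and the
last two factors are 1 when m < 2.  A perfect match scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import SeqIO
from Bio.Seq import Seq

from .markers import MarkerMap

__all__ = [
    "PamSite", "MIT_WEIGHTS", "index_pam_sites", "mit_score",
    "score_sites", "window_similarity", "rate_similarity_regression",
    "RegressionResult",
]

# Experimentally derived per-position mismatch penalties (Hsu et al. scheme),
# position 1 = PAM-distal ... 20 = PAM-proximal; as distributed with the MIT
# specificity tool and reused by downstream scoring packages.
MIT_WEIGHTS: tuple[float, ...] = (
    0.000, 0.000, 0.014, 0.000, 0.000, 0.395, 0.317, 0.000, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)

_VALID = set("ACGTN")
PROTOSPACER_LEN = 20


@dataclass
class PamSite:
    """One PAM-adjacent genomic site.

    ``pam_start`` is the 1-based leftmost reference coordinate of the 3-bp
    PAM; ``protospacer`` is the 20-bp sequence 5' of the PAM, read on the
    PAM's strand.
    """

    chrom: str
    pam_start: int
    strand: str            # "+" | "-"
    pam_class: str         # "NGG" | "NAG"
    protospacer: str
    score: float | None = None


def _scan_strand(seq: str, classes: tuple[str, ...]) -> list[tuple[int, str, str]]:
    """Yield (pam_index0, pam_class, protospacer) on one strand.

    ``pam_index0`` is the 0-based index of the PAM's first base in ``seq``.
    Sites whose 20-bp context runs off the sequence or contains N are
    dropped.
    """
    out = []
    want = {c[1:] for c in classes}          # {"GG"} and/or {"AG"}
    n = len(seq)
    for i in range(PROTOSPACER_LEN, n - 2):
        two = seq[i + 1:i + 3]
        if two in want:
            proto = seq[i - PROTOSPACER_LEN:i]
            if "N" in proto or "N" in seq[i:i + 3]:
                continue
            out.append((i, "N" + two, proto))
    return out


def index_pam_sites(
    genome: dict[str, str] | str | Path,
    classes: tuple[str, ...] = ("NGG", "NAG"),
) -> list[PamSite]:
    """Index all PAM sites of the requested classes on both strands.

    ``genome`` is a FASTA path or a mapping of contig name to sequence.
    Sequences must use the A/C/G/T/N alphabet; other codes are rejected.
    Minus-strand protospacers are returned reverse-complemented (i.e. in
    the orientation the Cas9:gRNA complex would read them).
    """
    for c in classes:
        if c not in ("NGG", "NAG"):
            raise ValueError(f"unsupported PAM class {c!r}")
    if isinstance(genome, (str, Path)):
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}
    sites: list[PamSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        if set(seq) - _VALID:
            raise ValueError(
                f"{chrom}: ambiguity codes other than N are not supported: "
                f"{sorted(set(seq) - _VALID)}"
            )
        L = len(seq)
        for i, pam_class, proto in _scan_strand(seq, classes):
            sites.append(PamSite(chrom, i + 1, "+", pam_class, proto))
        rc = str(Seq(seq).reverse_complement())
        for i, pam_class, proto in _scan_strand(rc, classes):
            # PAM occupies rc indices i..i+2 -> reference 0-based L-3-i..L-1-i
            sites.append(PamSite(chrom, L - 2 - i, "-", pam_class, proto))
    sites.sort(key=lambda s: (s.chrom, s.pam_start, s.strand))
    return sites


def mit_score(protospacer: str, grna: str) -> float:
    """MIT/Hsu similarity between a 20-bp protospacer and a gRNA spacer.

    Both sequences are read 5'->3' with the PAM adjacent to the last base.
    Raises ``ValueError`` unless both are 20 bp of A/C/G/T.
    """
    protospacer, grna = protospacer.upper(), grna.upper()
    for name, s in (("protospacer", protospacer), ("grna", grna)):
        if len(s) != PROTOSPACER_LEN:
            raise ValueError(f"{name} must be {PROTOSPACER_LEN} bp, got {len(s)}")
        if set(s) - set("ACGT"):
            raise ValueError(f"{name} contains non-ACGT characters")
    mismatches = [i for i in range(PROTOSPACER_LEN) if protospacer[i] != grna[i]]
    m = len(mismatches)
    if m == 0:
        return 1.0
    score = 1.0
    for i in mismatches:
        score *= 1.0 - MIT_WEIGHTS[i]
    if m > 1:
        d_mean = float(np.mean([abs(a - b) for a, b in combinations(mismatches, 2)]))
        score *= 1.0 / ((PROTOSPACER_LEN - 1 - d_mean) / (PROTOSPACER_LEN - 1) * 4.0 + 1.0)
        score *= 1.0 / (m * m)
    return score


def score_sites(sites: list[PamSite], grna: str) -> pd.DataFrame:
    """Score every indexed site against a gRNA; returns a tidy table."""
    rows = []
    for s in sites:
        s.score = mit_score(s.protospacer, grna)
        rows.append({
            "chrom": s.chrom, "pam_start": s.pam_start, "strand": s.strand,
            "pam_class": s.pam_class, "protospacer": s.protospacer,
            "score": s.score,
        })
    return pd.DataFrame(
        rows, columns=["chrom", "pam_start", "strand", "pam_class",
                       "protospacer", "score"]
    )


def window_similarity(
    scored: pd.DataFrame,
    map: MarkerMap,
    window: int = 50_000,
    statistic: str = "max",
) -> pd.DataFrame:
    """Aggregate site scores into non-overlapping windows.

    Windows partition each chromosome as in the rate analysis; sites are
    assigned by PAM start position.  Windows without any site get NaN.
    Also reports the PAM-site density per window (sites per bp), usable as
    a regression covariate.
    """
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")
    rows = []
    for chrom in map.chromosome_names:
        clen = map.length_of(chrom)
        sub = scored.loc[scored["chrom"] == chrom]
        pos = sub["pam_start"].to_numpy()
        sc = sub["score"].to_numpy(float)
        for start in range(1, clen + 1, window):
            end = min(start + window - 1, clen)
            mask = (pos >= start) & (pos <= end)
            agg = float(getattr(np, statistic)(sc[mask])) if mask.any() else float("nan")
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "similarity": agg, "n_sites": int(mask.sum()),
                "pam_density": mask.sum() / (end - start + 1),
            })
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    p_value: float
    n: int
    degenerate: bool = False
    params: dict | None = None


def rate_similarity_regression(
    normalized_rates,
    window_scores,
    pam_density=None,
) -> RegressionResult:
    """OLS of normalized LOH-rate contrasts on per-window gRNA similarity.

    Rows with a missing value in any variable are dropped.  With fewer than
    3 complete pairs the fit is refused; a constant predictor yields a
    degenerate (flagged, NaN-slope) result instead of a spurious fit.
    Passing ``pam_density`` adds it as a covariate; the reported slope and
    p-value always belong to the similarity term.
    """
    y = np.asarray(normalized_rates, dtype=float)
    x = np.asarray(window_scores, dtype=float)
    cols = {"similarity": x}
    if pam_density is not None:
        cols["pam_density"] = np.asarray(pam_density, dtype=float)
    X = pd.DataFrame(cols)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep]
    if len(X) < 3:
        raise ValueError(f"only {len(X)} complete pairs; need >= 3")
    if np.ptp(X["similarity"].to_numpy()) == 0:
        return RegressionResult(float("nan"), float("nan"), len(X), degenerate=True)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        slope=float(fit.params["similarity"]),
        p_value=float(fit.pvalues["similarity"]),
        n=int(fit.nobs),
        params={k: float(v) for k, v in fit.params.items()},
    )
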