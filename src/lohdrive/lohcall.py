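"""Calling loss-of-heterozygosity events from marker genotypes.

An LOH *tract* is a maximal run of adjacent marker sites converted to the
same parental homolog.  Tract boundaries are extrapolated to the midpoint
between the outermost converted marker and the adjacent unconverted marker
(or the chromosome end when no such marker exists).  Tracts of the same
homolog whose boundaries lie within ``merge_gap`` (< 10 kb by default) are
merged into a single *event* — one repair outcome.  Events containing the
telomere-proximal marker of a chromosome arm are terminal (tLOH), the rest
interstitial (iLOH).  The causal double-strand-break position is estimated
at the event midpoint, except for long terminal events where it is placed
10 kb inside the centromere-proximal boundary.

All coordinates are 1-based; boundary intervals are closed and may be
half-integer (midpoints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_P1, HOM_P2, MISSING, GenotypeMatrix
from .markers import MarkerMap

__all__ = [
    "LOHTract", "LOHEvent", "CorrectionModel",
    "call_tracts", "merge_tracts", "classify_event", "estimate_breakpoint",
    "call_clone_events", "call_events", "correct_counts", "events_to_frame",
]

DEFAULT_MERGE_GAP = 10_000
LONG_TERMINAL_BP = 20_000
TERMINAL_BREAKPOINT_OFFSET = 10_000

_HOMOLOG_CODE = {HOM_P1: "P1", HOM_P2: "P2"}


@dataclass
class LOHTract:
    """A maximal run of same-homolog converted markers."""

    clone: str
    chrom: str
    homolog: str                 # "P1" | "P2"
    first_idx: int               # chromosome-local index of first converted marker
    last_idx: int
    left: float                  # boundary interval in bp (midpoint-extrapolated)
    right: float
    marker_indices: np.ndarray   # converted (non-missing homozygous) markers in the run

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


@dataclass
class LOHEvent:
    """One called LOH event (possibly several merged tracts)."""

    clone: str
    chrom: str
    homolog: str
    left: float
    right: float
    tracts: list[LOHTract]
    marker_indices: np.ndarray
    kind: str | None = None            # "interstitial" | "terminal"
    breakpoint: float | None = None
    possible_aneuploidy: bool = False  # whole-chromosome homozygosity

    @property
    def length(self) -> float:
        return self.right - self.left

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


def call_tracts(
    calls: np.ndarray,
    map: MarkerMap,
    chrom: str,
    clone: str = "",
    missing: str = "transparent",
) -> list[LOHTract]:
    """Find LOH tracts in one clone's call vector on one chromosome.

    ``missing`` controls how MISSING calls are treated: ``"transparent"``
    (default) lets a run continue across them without counting them as
    converted; ``"break"`` terminates a run at a MISSING call, with the
    boundary extrapolated toward the missing marker.
    """
    calls = np.asarray(calls)
    pos = map.positions(chrom)
    if calls.shape != pos.shape:
        raise ValueError(f"{chrom}: expected {len(pos)} calls, got {len(calls)}")
    bad = ~np.isin(calls, [HET, HOM_P1, HOM_P2, MISSING])
    if bad.any():
        raise ValueError(
            f"{chrom}: unknown call value(s) {sorted(set(calls[bad].tolist()))}"
        )
    if missing not in ("transparent", "break"):
        raise ValueError("missing must be 'transparent' or 'break'")

    if missing == "transparent":
        informative = np.flatnonzero(calls != MISSING)
    else:
        informative = np.arange(len(calls))
    length = map.length_of(chrom)
    if informative.size == 0:
        return []

    # segment the informative call sequence into maximal equal-value runs
    vals = calls[informative]
    cut = np.flatnonzero(np.diff(vals) != 0) + 1
    starts = np.concatenate([[0], cut])
    ends = np.concatenate([cut, [vals.size]])

    tracts: list[LOHTract] = []
    for s, e in zip(starts, ends):
        v = int(vals[s])
        if v not in (HOM_P1, HOM_P2):
            continue
        first, last = int(informative[s]), int(informative[e - 1])
        left = 1.0 if s == 0 else (pos[informative[s - 1]] + pos[first]) / 2.0
        right = float(length) if e == vals.size else (pos[last] + pos[informative[e]]) / 2.0
        tracts.append(
            LOHTract(clone, chrom, _HOMOLOG_CODE[v], first, last,
                     left, right, informative[s:e].astype(np.int64))
        )
    return tracts


def merge_tracts(
    tracts: list[LOHTract],
    merge_gap: float = DEFAULT_MERGE_GAP,
) -> list[LOHEvent]:
    """Merge same-homolog tracts separated by less than ``merge_gap`` bp.

    The gap is measured between boundary intervals (next tract's left minus
    previous tract's right) and the inequality is strict.  Merging chains
    transitively along each chromosome but never across a homolog switch: a
    tract of the other homolog between two candidates implies distinct
    repair products and keeps them separate events.
    """
    events: list[LOHEvent] = []
    by_key: dict[tuple[str, str], list[LOHTract]] = {}
    for t in sorted(tracts, key=lambda t: (t.clone, t.chrom, t.left, t.right)):
        by_key.setdefault((t.clone, t.chrom), []).append(t)
    for (clone, chrom), group in by_key.items():
        current: list[LOHTract] = []
        for t in group:
            if current and t.homolog == current[-1].homolog and \
                    (t.left - current[-1].right) < merge_gap:
                current.append(t)
            else:
                if current:
                    events.append(_make_event(clone, chrom, current))
                current = [t]
        if current:
            events.append(_make_event(clone, chrom, current))
    return events


def _make_event(clone: str, chrom: str, members: list[LOHTract]) -> LOHEvent:
    return LOHEvent(
        clone=clone,
        chrom=chrom,
        homolog=members[0].homolog,
        left=min(t.left for t in members),
        right=max(t.right for t in members),
        tracts=list(members),
        marker_indices=np.concatenate([t.marker_indices for t in members]),
    )


def classify_event(event: LOHEvent, map: MarkerMap) -> str:
    """Classify an event as terminal or interstitial (sets ``event.kind``).

    Terminal events contain the telomere-proximal marker of an arm: the
    first marker of the chromosome (left arm) or the last (right arm).  An
    event containing both — the whole chromosome homozygous — is reported as
    terminal and flagged ``possible_aneuploidy``.
    """
    n = len(map.positions(event.chrom))
    idx = event.marker_indices
    l_lo, l_hi = map.arm_marker_span(event.chrom, "L")
    r_lo, r_hi = map.arm_marker_span(event.chrom, "R")
    left_terminal = l_hi > l_lo and bool((idx == l_lo).any())
    right_terminal = r_hi > r_lo and bool((idx == r_hi - 1).any())
    event.possible_aneuploidy = left_terminal and right_terminal
    event.kind = "terminal" if (left_terminal or right_terminal) else "interstitial"
    return event.kind


def estimate_breakpoint(event: LOHEvent, map: MarkerMap) -> float:
    """Estimate the causal dsDNA break position (sets ``event.breakpoint``).

    Interstitial events and terminal events shorter than 20 kb: the midpoint
    of the boundary interval.  Longer terminal events: 10 kb inside the
    centromere-proximal boundary, toward the telomere.  Whole-chromosome
    events have no centromere-proximal boundary and fall back to the
    midpoint.
    """
    if event.kind is None:
        classify_event(event, map)
    midpoint = (event.left + event.right) / 2.0
    if event.kind == "interstitial" or event.length < LONG_TERMINAL_BP \
            or event.possible_aneuploidy:
        event.breakpoint = midpoint
        return event.breakpoint
    r_lo, r_hi = map.arm_marker_span(event.chrom, "R")
    right_terminal = r_hi > r_lo and bool((event.marker_indices == r_hi - 1).any())
    if right_terminal:
        event.breakpoint = event.left + TERMINAL_BREAKPOINT_OFFSET
    else:
        event.breakpoint = event.right - TERMINAL_BREAKPOINT_OFFSET
    return event.breakpoint


def call_clone_events(
    gm: GenotypeMatrix,
    clone: str,
    merge_gap: float = DEFAULT_MERGE_GAP,
    missing: str = "transparent",
) -> list[LOHEvent]:
    """Call, classify and locate all LOH events of one clone."""
    events: list[LOHEvent] = []
    for chrom in gm.map.chromosome_names:
        calls = gm.clone_calls(clone, chrom)
        tracts = call_tracts(calls, gm.map, chrom, clone=clone, missing=missing)
        for ev in merge_tracts(tracts, merge_gap=merge_gap):
            classify_event(ev, gm.map)
            estimate_breakpoint(ev, gm.map)
            events.append(ev)
    return events


def call_events(
    gm: GenotypeMatrix,
    merge_gap: float = DEFAULT_MERGE_GAP,
    missing: str = "transparent",
) -> list[LOHEvent]:
    """Call LOH events for every clone in a genotype matrix."""
    out: list[LOHEvent] = []
    for clone in gm.clones:
        out.extend(call_clone_events(gm, clone, merge_gap=merge_gap, missing=missing))
    return out


def events_to_frame(events: list[LOHEvent]) -> pd.DataFrame:
    """Tabulate events (1-based closed coordinates)."""
    rows = [
        {
            "clone": e.clone, "chrom": e.chrom, "left": e.left, "right": e.right,
            "length": e.length, "class": e.kind, "homolog": e.homolog,
            "breakpoint": e.breakpoint, "n_markers": e.n_markers,
            "possible_aneuploidy": e.possible_aneuploidy,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["clone", "chrom", "left", "right", "length", "class",
                 "homolog", "breakpoint", "n_markers", "possible_aneuploidy"],
    )


@dataclass
class CorrectionModel:
    """Inverse-detection-probability correction for undetected LOH events.

    An event is detectable only if its interval covers at least one marker.
    With markers forming an approximately Poisson process of mean spacing
    ``s``, an event of true length ``l`` covers >=1 marker with probability
    ``p(l) = 1 - exp(-l / s)`` — the closed form exposed by
    :meth:`p_detect`.  The universe being estimated is events longer than
    ``min_detectable_length``.

    True lengths of detected events are not observed (boundary
    extrapolation inflates short events systematically), so weighting each
    event by ``1 / p(observed length)`` under-corrects.  When an
    interstitial length model is configured (log-normal with median
    ``iloh_median_bp`` and shape ``iloh_sigma`` — the same family the
    cohorts are modeled with), interstitial events are instead weighted by
    the inverse of the *model-average* detection probability
    ``E[p(l) | l >= min_detectable_length]``, which makes the corrected
    total unbiased under the model.  Terminal events are orders of
    magnitude longer than the marker spacing, so their per-event observed
    length is used directly (``p`` is ~1 and insensitive).  Set
    ``iloh_median_bp=None`` to weight every event by its observed length.

    This is a single parametric approximation to the detailed multi-part
    detection corrections used with real sequencing data, not a replication
    of them.
    """

    min_detectable_length: float = 17.0
    mean_spacing: float | None = None   # derived from the map when None
    p_floor: float = 0.05
    iloh_median_bp: float | None = 471.0
    iloh_sigma: float = 1.5

    def p_detect(self, length: float, mean_spacing: float) -> float:
        """P(event of true length ``length`` covers >=1 marker), floored."""
        p = 1.0 - math.exp(-max(length, 0.0) / mean_spacing)
        p = max(p, self.p_floor)
        if p <= 0.0:
            raise ValueError("non-positive detection probability")
        return p

    def p_detect_interstitial(self, mean_spacing: float) -> float:
        """Model-average detection probability of an interstitial event.

        ``E[1 - exp(-l/s)]`` over the configured log-normal length
        distribution conditional on ``l >= min_detectable_length``.
        """
        if self.iloh_median_bp is None:
            raise ValueError("no interstitial length model configured")
        from scipy import integrate, stats as sps

        dist = sps.lognorm(s=self.iloh_sigma, scale=self.iloh_median_bp)
        lo = self.min_detectable_length
        num, _ = integrate.quad(
            lambda l: (1.0 - math.exp(-l / mean_spacing)) * dist.pdf(l),
            lo, dist.ppf(1 - 1e-12), limit=200,
        )
        p = num / dist.sf(lo)
        p = max(p, self.p_floor)
        if p <= 0.0:
            raise ValueError("non-positive detection probability")
        return p


def correct_counts(
    events: list[LOHEvent],
    map: MarkerMap,
    model: CorrectionModel | None = None,
    clones: list[str] | None = None,
) -> pd.Series:
    """Per-clone corrected (real-valued) event counts.

    Events shorter than ``model.min_detectable_length`` are excluded from
    the estimated universe.  Pass ``clones`` to include clones with zero
    detected events in the output.  Corrected counts are always >= detected
    counts.
    """
    model = model or CorrectionModel()
    spacing = model.mean_spacing
    if spacing is None:
        spacing = map.total_length / map.n_markers
    p_iloh = None
    if model.iloh_median_bp is not None:
        p_iloh = model.p_detect_interstitial(spacing)
    counts: dict[str, float] = {c: 0.0 for c in (clones or [])}
    for e in events:
        if e.length < model.min_detectable_length:
            continue
        if p_iloh is not None and e.kind == "interstitial":
            p = p_iloh
        else:
            p = model.p_detect(e.length, spacing)
        counts[e.clone] = counts.get(e.clone, 0.0) + 1.0 / p
    return pd.Series(counts, name="corrected_count").sort_index()
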