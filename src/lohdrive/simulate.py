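"""Synthetic mutation-accumulation cohorts with known ground truth.

The simulator emulates the statistical structure of a hybrid-diploid yeast MA
experiment: a ~12 Mb, 16-chromosome genome heterozygous at ~40,000 marker
sites spaced on average 320 bp apart, accumulating LOH events as a Poisson
process over hundreds of generations, with a configurable mix of interstitial
(short, log-normal length) and terminal (extending to a chromosome end)
events, plus de novo single-nucleotide mutations and indels at per-bp rates.

Ground truth (every simulated event and mutation) is recorded so that the
caller and the rate estimators can be tested against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_P1, HOM_P2, GenotypeMatrix
from .markers import MarkerMap

__all__ = [
    "SimConfig", "TrueEvent", "TrueMutation", "CloneTruth", "CohortTruth",
    "build_marker_map", "simulate_clone", "simulate_cohort",
    "YEAST_CHROM_LENGTHS",
]

# 16 chromosome lengths (bp) summing to 12.0 Mb, with the size spread of the
# S. cerevisiae karyotype (shortest ~230 kb, longest ~1.5 Mb).
YEAST_CHROM_LENGTHS: tuple[int, ...] = (
    230_000, 810_000, 315_000, 1_530_000, 575_000, 270_000, 1_090_000,
    560_000, 440_000, 745_000, 670_000, 1_075_000, 925_000, 785_000,
    1_090_000, 890_000,
)
assert sum(YEAST_CHROM_LENGTHS) == 12_000_000


@dataclass
class SimConfig:
    """Parameters of the simulated MA experiment.

    Defaults reproduce the design of a hybrid-yeast MA study: LOH events
    accumulate at ``loh_rate`` = 1.76e-2 per genome per generation for
    ``generations`` = 800 single-cell bottleneck divisions, ~19% of events
    terminal; SNMs and indels arise at 1.67e-10 and 7.5e-12 per bp per
    generation on a diploid (``ploidy`` = 2) genome.
    """

    loh_rate: float = 1.76e-2            # events / genome / generation
    generations: int = 800
    n_lines: int = 95                    # per founder label
    terminal_fraction: float = 0.192
    iloh_median_bp: float = 471.0        # log-normal median of iLOH lengths
    iloh_sigma: float = 1.5              # log-normal shape (natural-log scale)
    snm_rate: float = 1.67e-10           # per bp per generation
    indel_rate: float = 7.5e-12          # per bp per generation
    ploidy: int = 2
    rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {"W": 1.0, "C": 1.0, "D": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loh_rate", "snm_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.terminal_fraction <= 1.0:
            raise ValueError("terminal_fraction must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be > 0")


@dataclass
class TrueEvent:
    """One simulated LOH event with its physical interval and marker footprint.

    ``footprint`` holds the chromosome-local indices of markers whose final
    call was written by this event (later overlapping events overwrite
    earlier ones, so the footprint can be smaller than the interval's marker
    content, or empty).
    """

    chrom: str
    start: int
    end: int
    kind: str          # "interstitial" | "terminal"
    homolog: str       # "P1" | "P2"
    footprint: np.ndarray


@dataclass
class TrueMutation:
    chrom: str
    position: int
    kind: str          # "SNM" | "indel"


@dataclass
class CloneTruth:
    events: list[TrueEvent]
    mutations: list[TrueMutation]


CohortTruth = dict[str, CloneTruth]


def build_marker_map(
    n_chromosomes: int = 16,
    chrom_lengths: tuple[int, ...] | None = None,
    mean_spacing: float = 320.0,
    seed: int = 0,
    centromere_rel: float = 0.45,
    centromere_halfwidth: int = 100,
    effective_length: int | None = None,
) -> MarkerMap:
    """Build a random hybrid marker map.

    Inter-marker gaps are i.i.d. exponential with mean ``mean_spacing``,
    truncated so every gap is at least 1 bp — markers then form a (discrete)
    Poisson process along each chromosome, matching the "mean spacing"
    summary available for real hybrid panels.  Centromeres are placed at a
    fixed relative position; markers falling inside the centromere interval
    are dropped (in real data the region is repeat-masked and markerless).

    Raises ``ValueError`` for chromosomes shorter than twice the spacing,
    where the >=2-markers-per-chromosome invariant is not dependable.
    """
    if mean_spacing <= 0:
        raise ValueError("mean_spacing must be > 0")
    if chrom_lengths is None:
        if n_chromosomes == 16:
            chrom_lengths = YEAST_CHROM_LENGTHS
        else:
            chrom_lengths = tuple([int(12_000_000 / n_chromosomes)] * n_chromosomes)
    if len(chrom_lengths) != n_chromosomes:
        raise ValueError("chrom_lengths length mismatch")
    if any(l < 2 * mean_spacing for l in chrom_lengths):
        raise ValueError("chromosome shorter than 2x mean_spacing")

    rng = np.random.default_rng(seed)
    chromosomes, centromeres, markers = [], {}, {}
    for i, length in enumerate(chrom_lengths):
        name = f"chr{i + 1:02d}"
        chromosomes.append((name, int(length)))
        c_mid = int(round(centromere_rel * length))
        cs = max(2, c_mid - centromere_halfwidth)
        ce = min(length - 1, c_mid + centromere_halfwidth)
        centromeres[name] = (cs, ce)
        # expected count + slack, then trim to the chromosome
        n_draw = int(length / mean_spacing * 1.25) + 20
        gaps = np.maximum(1, rng.exponential(mean_spacing, size=n_draw)).astype(np.int64)
        pos = np.cumsum(gaps)
        pos = pos[pos <= length]
        pos = pos[(pos < cs) | (pos > ce)]
        markers[name] = pos
    return MarkerMap(chromosomes, centromeres, markers, effective_length=effective_length)


def _draw_events(map: MarkerMap, cfg: SimConfig, multiplier: float,
                 rng: np.random.Generator) -> list[tuple[str, int, int, str, str]]:
    """Draw (chrom, start, end, kind, homolog) tuples for one clone."""
    mu = cfg.loh_rate * multiplier * cfg.generations
    n_events = rng.poisson(mu)
    names = map.chromosome_names
    lengths = np.array([map.length_of(c) for c in names], dtype=float)
    p_chrom = lengths / lengths.sum()
    events = []
    for _ in range(n_events):
        chrom = names[rng.choice(len(names), p=p_chrom)]
        clen = map.length_of(chrom)
        homolog = "P1" if rng.random() < 0.5 else "P2"
        if rng.random() < cfg.terminal_fraction:
            # terminal: breakpoint uniform along an arm (arm chosen by length),
            # tract runs from the breakpoint to the telomere
            la0, la1 = map.arm_interval(chrom, "L")
            ra0, ra1 = map.arm_interval(chrom, "R")
            l_len, r_len = la1 - la0 + 1, ra1 - ra0 + 1
            if rng.random() < l_len / (l_len + r_len):
                bp = int(rng.integers(la0, la1 + 1))
                start, end = 1, bp
            else:
                bp = int(rng.integers(ra0, ra1 + 1))
                start, end = bp, clen
            events.append((chrom, start, end, "terminal", homolog))
        else:
            length = int(round(rng.lognormal(math.log(cfg.iloh_median_bp), cfg.iloh_sigma)))
            length = min(max(length, 1), clen)
            start = int(rng.integers(1, clen - length + 2))
            events.append((chrom, start, start + length - 1, "interstitial", homolog))
    return events


def simulate_clone(
    map: MarkerMap,
    cfg: SimConfig,
    founder_label: str,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, CloneTruth]:
    """Simulate one end-point clone.

    Returns the clone's call vector over all markers (map order) and its
    ground truth.  LOH events are applied in simulation order with
    last-writer-wins overlap resolution; the truth records, per event, both
    the physical interval and the surviving marker footprint.  Mutations are
    placed uniformly over the effective genome and never alter marker calls.
    """
    if founder_label not in cfg.rate_multipliers:
        raise KeyError(f"no rate multiplier configured for founder {founder_label!r}")
    rng = np.random.default_rng(seed)
    multiplier = cfg.rate_multipliers[founder_label]
    raw = _draw_events(map, cfg, multiplier, rng)

    calls = np.full(map.n_markers, HET, dtype=np.int8)
    writer = np.full(map.n_markers, -1, dtype=np.int64)
    offsets = {}
    off = 0
    for name in map.chromosome_names:
        offsets[name] = off
        off += len(map.positions(name))

    events: list[TrueEvent] = []
    for i, (chrom, start, end, kind, homolog) in enumerate(raw):
        pos = map.positions(chrom)
        lo = int(np.searchsorted(pos, start))
        hi = int(np.searchsorted(pos, end, side="right"))
        g_lo, g_hi = offsets[chrom] + lo, offsets[chrom] + hi
        calls[g_lo:g_hi] = HOM_P1 if homolog == "P1" else HOM_P2
        writer[g_lo:g_hi] = i
        events.append(TrueEvent(chrom, start, end, kind, homolog, footprint=np.empty(0, dtype=np.int64)))
    for i, ev in enumerate(events):
        g0 = offsets[ev.chrom]
        n = len(map.positions(ev.chrom))
        local = np.flatnonzero(writer[g0:g0 + n] == i)
        ev.footprint = local

    mutations: list[TrueMutation] = []
    L_eff = map.effective_length
    names = map.chromosome_names
    lengths = np.array([map.length_of(c) for c in names], dtype=float)
    p_chrom = lengths / lengths.sum()
    for kind, rate in (("SNM", cfg.snm_rate), ("indel", cfg.indel_rate)):
        n_mut = rng.poisson(rate * cfg.ploidy * L_eff * cfg.generations)
        for _ in range(n_mut):
            chrom = names[rng.choice(len(names), p=p_chrom)]
            position = int(rng.integers(1, map.length_of(chrom) + 1))
            mutations.append(TrueMutation(chrom, position, kind))

    return calls, CloneTruth(events, mutations)


def simulate_cohort(
    map: MarkerMap,
    cfg: SimConfig,
    founder_labels: list[str] | None = None,
) -> tuple[GenotypeMatrix, CohortTruth, pd.DataFrame]:
    """Simulate ``cfg.n_lines`` independent MA lines per founder label.

    Per-clone random streams are spawned deterministically from ``cfg.seed``
    (one root :class:`numpy.random.SeedSequence`), so the same config yields a
    bit-identical cohort regardless of chunking.

    Returns the genotype matrix, the cohort ground truth, and a putative
    variant table (clone, chrom, pos, type) suitable for the de novo
    mutation caller.
    """
    if founder_labels is None:
        founder_labels = list(cfg.rate_multipliers)
    if cfg.n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    root = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_lines * len(founder_labels)
    streams = root.spawn(n_total)

    clone_ids, rows, meta_rows = [], [], []
    truth: CohortTruth = {}
    variant_rows = []
    k = 0
    for label in founder_labels:
        for j in range(cfg.n_lines):
            clone = f"{label}_{j + 1:03d}"
            calls, clone_truth = simulate_clone(map, cfg, label, streams[k])
            clone_ids.append(clone)
            rows.append(calls)
            truth[clone] = clone_truth
            meta_rows.append(
                {"clone": clone, "founder_label": label,
                 "founder_id": f"{label}_F00", "generations": cfg.generations}
            )
            for m in clone_truth.mutations:
                variant_rows.append(
                    {"clone": clone, "chrom": m.chrom, "pos": m.position, "type": m.kind}
                )
            k += 1

    metadata = pd.DataFrame(meta_rows).set_index("clone")
    gm = GenotypeMatrix(map, np.vstack(rows), clone_ids, metadata)
    variants = pd.DataFrame(variant_rows, columns=["clone", "chrom", "pos", "type"])
    return gm, truth, variants
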