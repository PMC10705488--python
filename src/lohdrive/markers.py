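"""Marker maps for hybrid-diploid mutation-accumulation genomes.

A :class:`MarkerMap` describes the chromosome structure of a diploid hybrid
founder: chromosome names and lengths, centromere intervals, and the ordered
positions of the heterozygous marker sites at which the two parental
haplotypes differ.  All coordinates are 1-based and intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarkerMap"]


@dataclass
class MarkerMap:
    """Chromosome structure and heterozygous marker positions of a hybrid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Per-chromosome closed interval ``(start, end)`` in bp.  Arms are the
        marker sets strictly left/right of this interval.
    markers
        Per-chromosome strictly increasing array of marker positions (bp,
        1-based).  Markers inside the centromere interval are not allowed:
        every marker belongs to exactly one arm.
    effective_length
        Number of bp effectively monitored for LOH (after masking repeats,
        telomeres, etc. in real data).  Defaults to the genome size.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, tuple[int, int]]
    markers: dict[str, np.ndarray]
    effective_length: int | None = None
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        if len(self._index) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
            pos = np.asarray(self.markers.get(name, ()), dtype=np.int64)
            self.markers[name] = pos
            if pos.size < 2:
                raise ValueError(f"{name}: every chromosome needs >=2 markers")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{name}: marker positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > length:
                raise ValueError(f"{name}: markers outside [1, {length}]")
            cs, ce = self.centromeres[name]
            if not (1 < cs <= ce < length):
                raise ValueError(f"{name}: centromere must lie strictly inside the chromosome")
            inside = (pos >= cs) & (pos <= ce)
            if inside.any():
                raise ValueError(f"{name}: markers inside the centromere interval")
        total = self.total_length
        if self.effective_length is None:
            self.effective_length = total
        if self.effective_length > total:
            raise ValueError("effective_length exceeds genome size")

    # -- basic accessors ---------------------------------------------------

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    @property
    def n_markers(self) -> int:
        return int(sum(len(v) for v in self.markers.values()))

    def length_of(self, chrom: str) -> int:
        return self.chromosomes[self._index[chrom]][1]

    def positions(self, chrom: str) -> np.ndarray:
        return self.markers[chrom]

    # -- arms --------------------------------------------------------------

    def arm_of(self, chrom: str, pos: int) -> str:
        """Return 'L' or 'R' for a position, splitting at the centromere.

        Positions inside the centromere interval are assigned to the left arm
        boundary by convention (no markers live there, so this only matters
        for event intervals).
        """
        cs, _ = self.centromeres[chrom]
        return "L" if pos < cs else "R"

    def arm_marker_span(self, chrom: str, arm: str) -> tuple[int, int]:
        """Index range ``[lo, hi)`` into the marker array for one arm."""
        pos = self.markers[chrom]
        cs, ce = self.centromeres[chrom]
        if arm == "L":
            return 0, int(np.searchsorted(pos, cs))
        if arm == "R":
            return int(np.searchsorted(pos, ce, side="right")), len(pos)
        raise ValueError(f"unknown arm {arm!r}")

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        """Physical closed interval of an arm in bp."""
        cs, ce = self.centromeres[chrom]
        if arm == "L":
            return 1, cs - 1
        if arm == "R":
            return ce + 1, self.length_of(chrom)
        raise ValueError(f"unknown arm {arm!r}")

    def arms(self) -> list[tuple[str, str]]:
        """All (chromosome, arm) pairs that carry at least one marker."""
        out = []
        for name in self.chromosome_names:
            for arm in ("L", "R"):
                lo, hi = self.arm_marker_span(name, arm)
                if hi > lo:
                    out.append((name, arm))
        return out
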