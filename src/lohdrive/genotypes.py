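"""Per-clone genotype calls at heterozygous marker sites."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMap

# Integer encoding of a genotype call at an initially heterozygous marker.
HET = 0        # still heterozygous
HOM_P1 = 1     # converted to parent-1 homolog (e.g. the lab strain)
HOM_P2 = 2     # converted to parent-2 homolog (e.g. the vineyard strain)
MISSING = -1   # no reliable call

CALL_TO_STR = {HET: "HET", HOM_P1: "HOM_P1", HOM_P2: "HOM_P2", MISSING: "MISSING"}
STR_TO_CALL = {v: k for k, v in CALL_TO_STR.items()}

__all__ = [
    "HET", "HOM_P1", "HOM_P2", "MISSING",
    "CALL_TO_STR", "STR_TO_CALL", "GenotypeMatrix",
]


@dataclass
class GenotypeMatrix:
    """Calls for every clone at every marker site of a :class:`MarkerMap`.

    ``calls`` is an int8 array of shape ``(n_clones, n_markers)`` using the
    module-level encoding; markers are ordered chromosome by chromosome in
    map order.  ``metadata`` is indexed by clone id and carries at least
    ``founder_label``, ``founder_id`` and ``generations``.
    """

    map: MarkerMap
    calls: np.ndarray
    clones: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_markers = self.map.n_markers
        if self.calls.shape != (len(self.clones), n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_clones={len(self.clones)}, "
                f"n_markers={n_markers})"
            )
        if len(set(self.clones)) != len(self.clones):
            raise ValueError("duplicate clone ids")
        bad = ~np.isin(self.calls, [HET, HOM_P1, HOM_P2, MISSING])
        if bad.any():
            raise ValueError(f"{int(bad.sum())} calls outside the allowed encoding")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of ``calls`` for one chromosome."""
        offset = 0
        for name in self.map.chromosome_names:
            n = len(self.map.positions(name))
            if name == chrom:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(chrom)

    def clone_calls(self, clone: str, chrom: str) -> np.ndarray:
        """Call vector of one clone on one chromosome."""
        row = self.clones.index(clone)
        return self.calls[row, self.chrom_slice(chrom)]

    def het_fraction_converted(self) -> pd.Series:
        """Per clone, the fraction of marker sites no longer heterozygous.

        MISSING sites are excluded from both numerator and denominator.
        """
        obs = self.calls != MISSING
        hom = (self.calls == HOM_P1) | (self.calls == HOM_P2)
        with np.errstate(invalid="ignore"):
            frac = hom.sum(axis=1) / obs.sum(axis=1)
        return pd.Series(frac, index=self.clones, name="fraction_converted")
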