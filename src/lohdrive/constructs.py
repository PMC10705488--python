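"""Closed-form expectations for mutations inside integrated constructs.

A construct integrated homozygously (``copies`` = 2) of length ``l`` bp
accumulates mutations at the genome-average per-bp rates, so a clone
propagated for ``T`` generations is expected to carry
``copies * (snm_rate + indel_rate) * l * T`` construct mutations; summing
over end-point clones gives the expected number of mutant clones in the
experiment.  Only mutations falling in the drive components (gRNA cassette,
Cas9 gene) can deactivate the drive, so the deactivating fraction is
conservatively the component share of the construct length.  Because
per-site mutation rates vary several-fold across a genome, expectations
carry a fold-range uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConstructSpec", "DEFAULT_CONSTRUCTS", "expected_construct_mutations",
    "expected_mutant_clones", "deactivating_fraction", "uncertainty_band",
    "DEFAULT_SNM_RATE", "DEFAULT_INDEL_RATE",
]

DEFAULT_SNM_RATE = 1.67e-10     # per bp per generation
DEFAULT_INDEL_RATE = 7.5e-12    # per bp per generation


@dataclass
class ConstructSpec:
    """Geometry of one integrated construct.

    ``components`` maps drive-component names to lengths in bp (promoter and
    terminator included); their sum may not exceed the total length.
    """

    name: str
    length: int
    components: dict[str, int] = field(default_factory=dict)
    copies: int = 2
    n_endpoint_clones: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.copies <= 0:
            raise ValueError("length and copies must be positive")
        if any(v <= 0 for v in self.components.values()):
            raise ValueError("component lengths must be positive")
        if sum(self.components.values()) > self.length:
            raise ValueError("component lengths exceed construct length")


# The three founder constructs of the yeast gene-drive MA experiment:
# D = full drive (gRNA cassette + Cas9), C = Cas9 only, W = empty cassette.
DEFAULT_CONSTRUCTS: dict[str, ConstructSpec] = {
    "D": ConstructSpec("D", 7999, {"gRNA": 388, "Cas9": 4890}, 2, 67),
    "C": ConstructSpec("C", 7601, {"Cas9": 4890}, 2, 83),
    "W": ConstructSpec("W", 2770, {}, 2, 79),
}


def expected_construct_mutations(
    spec: ConstructSpec,
    snm_rate: float = DEFAULT_SNM_RATE,
    indel_rate: float = DEFAULT_INDEL_RATE,
    T: float = 800,
) -> float:
    """Expected construct mutations per end-point clone."""
    if snm_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    return spec.copies * (snm_rate + indel_rate) * spec.length * T


def expected_mutant_clones(per_clone_expectation: float, n_clones: int) -> float:
    """Expected number of end-point clones carrying a construct mutation."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    return per_clone_expectation * n_clones


def deactivating_fraction(spec: ConstructSpec) -> float:
    """Fraction of construct mutations expected to hit a drive component."""
    if not spec.components:
        raise ValueError(f"construct {spec.name!r} has no drive components")
    return sum(spec.components.values()) / spec.length


def uncertainty_band(expectation: float, rate_fold_range: float = 6.0) -> tuple[float, float]:
    """Fold-range band around a point expectation.

    With per-site mutation rates varying up to ``rate_fold_range``-fold
    across the genome, the expectation could plausibly lie anywhere in
    ``[expectation / fold, expectation * fold]``.
    """
    if rate_fold_range < 1:
        raise ValueError("rate_fold_range must be >= 1")
    return expectation / rate_fold_range, expectation * rate_fold_range
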