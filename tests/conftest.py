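import numpy as np
import pytest

from lohdrive import MarkerMap, SimConfig, build_marker_map, simulate_cohort


@pytest.fixture(scope="session")
def toy_map():
    """Two tiny chromosomes with hand-placed markers for exact-answer tests.

    chrA: 1000 bp, centromere [250, 255], markers 100..500 step 100
          (left arm: 100, 200; right arm: 300, 400, 500).
    chrB: 600 bp, centromere [290, 300], markers 50, 150, 250, 350, 450, 550.
    """
    return MarkerMap(
        chromosomes=[("chrA", 1000), ("chrB", 600)],
        centromeres={"chrA": (250, 255), "chrB": (290, 300)},
        markers={
            "chrA": np.array([100, 200, 300, 400, 500]),
            "chrB": np.array([50, 150, 250, 350, 450, 550]),
        },
    )


@pytest.fixture(scope="session")
def small_map():
    """A 1 Mb four-chromosome map at realistic marker spacing."""
    return build_marker_map(
        n_chromosomes=4,
        chrom_lengths=(350_000, 300_000, 200_000, 150_000),
        mean_spacing=320,
        seed=7,
    )


@pytest.fixture(scope="session")
def genome_map():
    """Full-scale hybrid map: 12 Mb, 16 chromosomes, ~320 bp marker spacing."""
    return build_marker_map(seed=101)


@pytest.fixture(scope="session")
def genome_cohort(genome_map):
    """200 clones on the full-scale map, ground truth attached."""
    cfg = SimConfig(seed=202, n_lines=100,
                    rate_multipliers={"W": 1.0, "C": 1.0})
    return simulate_cohort(genome_map, cfg)


@pytest.fixture(scope="session")
def small_cohort(small_map):
    """Nine simulated clones (three per founder) with ground truth."""
    cfg = SimConfig(seed=11, n_lines=3)
    return simulate_cohort(small_map, cfg)
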