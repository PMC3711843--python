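import numpy as np
import pytest

from markermine import homology
from markermine import synthetic_data as sd


@pytest.fixture(scope="session")
def small_bundle():
    """A small clean-flank study: reference + one line + contigs, full coverage."""
    config = sd.SimulationConfig(
        n_single=8, n_two=3, n_three=2,
        clean_flanks=True, contig_coverage=1.0,
        depth_law=("poisson", 20.0), seed=11,
    )
    bundle = sd.simulate_reference(config)
    alleles = sd.simulate_line(bundle, "L1")
    contigs, depths = sd.fragment_to_contigs(bundle, alleles)
    sd.compute_expected_markers(bundle)
    return bundle, alleles, contigs, depths


@pytest.fixture(scope="session")
def small_groups(small_bundle):
    bundle, _, contigs, _ = small_bundle
    hits = homology.align_contigs(contigs, bundle.gene_models, k=15, line="L1")
    groups, unassigned = homology.assign_homologs(hits, bundle.paralog_table)
    return hits, groups, unassigned


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()
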