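import numpy as np
import pytest

from bivatlas.domains import build_hc_lists
from bivatlas.synth import (
    GenomeSpec,
    simulate_annotations,
    simulate_peaksets,
    simulate_tracks,
)


SMALL_SCALE = dict(
    n_bivalent=80,
    n_bivalent_x=6,
    n_k4only=60,
    n_k27only=60,
    n_none_cgi=30,
    n_genes=400,
)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by tests that only read from it."""
    spec = GenomeSpec(seed=11, **SMALL_SCALE)
    bundle, truth = simulate_annotations(spec)
    peaksets = simulate_peaksets(truth)
    lists = build_hc_lists(peaksets["H3K4me3"], peaksets["H3K27me3"])
    return {
        "spec": spec,
        "bundle": bundle,
        "truth": truth,
        "peaksets": peaksets,
        "lists": lists,
    }


@pytest.fixture(scope="session")
def small_tracks(small_study):
    return simulate_tracks(small_study["truth"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
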