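"""Shared fixtures: small synthetic instruments for every stage."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nirpipe import RunConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

MIDS = ["ACACACACGT", "TGTGTGTGCA", "AGAGAGAGTC", "CTCTCTCTAG",
        "GAGAGAGAAC", "TCTCTCTCGA"]
PRIMER_16S = "CTGGCTCAGGAYGAACGCTG"
PRIMER_NIRK = "ATCATGGTSCTGCCGCG"


def make_config(samples, marker="16S", primer=PRIMER_16S, **kw):
    return RunConfig(
        sample_map={s: (s[:3], i + 1) for i, s in enumerate(samples)},
        barcode_map={MIDS[i]: s for i, s in enumerate(samples)},
        primer_forward=primer,
        marker=marker,
        **kw,
    )


@pytest.fixture
def config_two_samples():
    return make_config(["HBM1", "LBM1"], seed=1)


@pytest.fixture
def barcode_of(config_two_samples):
    return {s: m for m, s in config_two_samples.barcode_map.items()}


@pytest.fixture(scope="session")
def pool_16s():
    return simulate.generate_marker_pool(25, "16S", (0.80, 0.95), seed=2)


@pytest.fixture(scope="session")
def pool_nir():
    return simulate.generate_marker_pool(12, "coding", (0.70, 0.90), 1, seed=5)


@pytest.fixture(scope="session")
def nir_profile(pool_nir):
    from nirpipe.frameshift import build_codon_profile

    taxa = sorted(set(pool_nir.taxon_of.values()))
    return build_codon_profile([pool_nir.proteins[t] for t in taxa])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
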