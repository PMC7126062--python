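"""Shared fixtures: small genotype-likelihood panels built in memory."""

import numpy as np
import pandas as pd
import pytest

from larkline.gtio import GenotypeLikelihoodMatrix


def make_sites(n, scaffold="s1", variant=True):
    return pd.DataFrame({
        "scaffold": scaffold,
        "pos": np.arange(n),
        "ref": "A",
        "alt": "T" if variant else ".",
        "qual": np.nan,
        "locus": np.arange(n),
    })


def certain_glm(dosages: np.ndarray, depth: int = 30) -> GenotypeLikelihoodMatrix:
    """Likelihood matrix with degenerate (certain) triplets from a dosage array."""
    dosages = np.asarray(dosages)
    n_sites, n_samp = dosages.shape
    gl = np.zeros((n_sites, n_samp, 3))
    for g in range(3):
        gl[dosages == g, g] = 1.0
    return GenotypeLikelihoodMatrix(
        sites=make_sites(n_sites),
        samples=[f"s{i}" for i in range(n_samp)],
        gl=gl,
        depth=np.full((n_sites, n_samp), depth),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
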