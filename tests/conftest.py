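import io

import numpy as np
import pytest

from svdlmm import (
    LMMSpec,
    ScenarioSpec,
    TraitParams,
    additive_matrix,
    block_decompose,
    family_offsets,
    kinship,
    make_pedigree,
    read_pedigree,
    simulate_gaussian,
)

NUCLEAR_FAM = """\
F1 dad 0 0 1 -9
F1 mom 0 0 2 -9
F1 kid1 dad mom 1 -9
F1 kid2 dad mom 2 -9
"""


@pytest.fixture
def nuclear_ped():
    return read_pedigree(io.StringIO(NUCLEAR_FAM))


@pytest.fixture
def two_trios_ped():
    return make_pedigree(ScenarioSpec("two_trios", n_fam=1))


def build_lmm_spec(scenario: str, n_fam: int, sigma_g2: float, sigma_e2: float, seed: int,
                   beta: tuple[float, ...] = (1.0,)) -> LMMSpec:
    """Simulate a Gaussian trait on a scenario pedigree and package it for fitting."""
    ped = make_pedigree(ScenarioSpec(scenario, n_fam=n_fam))
    off = family_offsets(ped)
    X = np.ones((off.n, len(beta)))
    if len(beta) > 1:
        rng = np.random.default_rng(seed + 1)
        X[:, 1:] = rng.standard_normal((off.n, len(beta) - 1))
    par = TraitParams(sigma_g2=sigma_g2, sigma_e2=sigma_e2, beta=beta, seed=seed)
    y = simulate_gaussian(ped, par, X=X)
    G = block_decompose(additive_matrix(kinship(ped)), off)
    return LMMSpec(y=y, X=X, G=G, off=off)
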