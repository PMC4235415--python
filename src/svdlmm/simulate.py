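"""Benchmark family structures and trait simulators.

Four pedigree scenarios are provided, each replicated ``n_fam`` times:

* ``nuclear`` — a couple with two offspring (4 sampled per family);
* ``two_trios`` — two parent-offspring trios linked because one parent of
  each couple is a full sibling of the other, giving first-, second- and
  third-degree sampled pairs (6 sampled per family);
* ``asymmetric`` — the same linkage but the trios have 1 and 10 offspring
  (15 sampled per family);
* ``combination`` — nuclear families plus extended two-trio families with
  3 offspring per trio (4 + 10 sampled per pair of families).

At ``n_fam = 100`` the sampled totals are 400, 600, 1500 and 1400.

The sibling link in the extended scenarios is encoded by two phantom
founder grandparents (``sampled=False``): the kinship recursion needs the
common ancestors to exist, but the phantoms never enter delivered matrices.

Gaussian traits are drawn with the exact model covariance: per family,
V_f = sigma_e^2 I + 2 sigma_g^2 K_f is spectrally decomposed and the trait
is Y = X beta + U D^{1/2} Z with Z standard normal, so Var(Y) = V by
construction.  Binary traits are Bernoulli with logit link on
eta = X beta + G u, u ~ N(0, sigma_g^2 I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, kinship, additive_matrix, family_offsets
from .transform import block_decompose

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "TraitParams",
    "make_pedigree",
    "simulate_gaussian",
    "simulate_binary",
    "simulate_dataset",
]

SCENARIOS = ("nuclear", "two_trios", "asymmetric", "combination")


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str
    n_fam: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_fam < 1:
            raise ValueError("n_fam must be >= 1")


@dataclass(frozen=True)
class TraitParams:
    """Trait-generation parameters; variances in squared trait units."""

    sigma_g2: float = 1.0
    sigma_e2: float = 1.0
    beta: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def _nuclear(fam: str, n_off: int = 2) -> list[Individual]:
    dad = Individual(iid=f"{fam}_p1", sex=1, family=fam)
    mom = Individual(iid=f"{fam}_p2", sex=2, family=fam)
    kids = [
        Individual(
            iid=f"{fam}_o{k + 1}",
            father=dad.iid,
            mother=mom.iid,
            sex=1 + k % 2,
            family=fam,
        )
        for k in range(n_off)
    ]
    return [dad, mom, *kids]


def _linked_trios(fam: str, n_off1: int, n_off2: int) -> list[Individual]:
    """Two trios whose non-spouse parents are full siblings via phantom founders."""
    gp1 = Individual(iid=f"{fam}_gp1", sex=1, family=fam, sampled=False)
    gp2 = Individual(iid=f"{fam}_gp2", sex=2, family=fam, sampled=False)
    sib1 = Individual(iid=f"{fam}_s1", father=gp1.iid, mother=gp2.iid, sex=1, family=fam)
    sib2 = Individual(iid=f"{fam}_s2", father=gp1.iid, mother=gp2.iid, sex=2, family=fam)
    sp1 = Individual(iid=f"{fam}_w1", sex=2, family=fam)
    sp2 = Individual(iid=f"{fam}_w2", sex=1, family=fam)
    out = [gp1, gp2, sib1, sib2, sp1, sp2]
    for k in range(n_off1):
        out.append(
            Individual(
                iid=f"{fam}_a{k + 1}",
                father=sib1.iid,
                mother=sp1.iid,
                sex=1 + k % 2,
                family=fam,
            )
        )
    for k in range(n_off2):
        out.append(
            Individual(
                iid=f"{fam}_b{k + 1}",
                father=sp2.iid,
                mother=sib2.iid,
                sex=1 + k % 2,
                family=fam,
            )
        )
    return out


def make_pedigree(spec: ScenarioSpec) -> Pedigree:
    """Deterministic scenario pedigree (the seed is reserved for trait draws)."""
    records: list[Individual] = []
    if spec.scenario == "nuclear":
        for i in range(spec.n_fam):
            records += _nuclear(f"F{i + 1}")
    elif spec.scenario == "two_trios":
        for i in range(spec.n_fam):
            records += _linked_trios(f"F{i + 1}", 1, 1)
    elif spec.scenario == "asymmetric":
        for i in range(spec.n_fam):
            records += _linked_trios(f"F{i + 1}", 1, 10)
    else:  # combination
        for i in range(spec.n_fam):
            records += _nuclear(f"N{i + 1}")
        for i in range(spec.n_fam):
            records += _linked_trios(f"X{i + 1}", 3, 3)
    return Pedigree(records)


def simulate_gaussian(
    ped: Pedigree,
    par: TraitParams,
    X: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one Gaussian trait vector with covariance sigma_e^2 I + sigma_g^2 A.

    Per family block, V_f = sigma_e^2 I + 2 sigma_g^2 K_f is eigendecomposed
    as U diag(d) U' and the trait is U d^{1/2} z, z ~ N(0, I); the fixed-effect
    mean X beta is added when a design matrix is given.
    """
    rng = np.random.default_rng(par.seed) if rng is None else rng
    K = kinship(ped)
    off = family_offsets(ped)
    n = off.n
    y = np.empty(n)
    for sl in off.slices():
        Vf = par.sigma_e2 * np.eye(sl.stop - sl.start) + 2.0 * par.sigma_g2 * K.values[sl, sl]
        d, U = np.linalg.eigh(Vf)
        d = np.clip(d, 0.0, None)
        z = rng.standard_normal(sl.stop - sl.start)
        y[sl] = U @ (np.sqrt(d) * z)
    if X is not None:
        y += np.asarray(X, dtype=float) @ np.asarray(par.beta, dtype=float)
    return y


def simulate_binary(
    ped: Pedigree,
    par: TraitParams,
    X: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a Bernoulli-logit trait: y_j ~ Bern(expit(x_j' beta + (G u)_j)).

    u ~ N(0, sigma_g2 I) on the log-odds scale; the Bernoulli dispersion is
    fixed at 1.
    """
    rng = np.random.default_rng(par.seed) if rng is None else rng
    A = additive_matrix(kinship(ped))
    off = family_offsets(ped)
    G = block_decompose(A, off)
    u = rng.standard_normal(off.n) * np.sqrt(par.sigma_g2)
    eta = np.asarray(X, dtype=float) @ np.asarray(par.beta, dtype=float) + G.matvec(u)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(off.n) < p).astype(int)


def simulate_dataset(
    spec: ScenarioSpec,
    par: TraitParams,
    trait: str = "gaussian",
) -> tuple[Pedigree, pd.DataFrame]:
    """Scenario pedigree plus a phenotype table with age and sex covariates.

    The design matrix is [1, age, sex01] with age ~ Uniform(30, 80) rounded
    to years and sex01 = sex - 1 (0 = male, 1 = female); ``par.beta`` must
    conform (length 1 uses the intercept only).  Returns the pedigree and a
    tidy table (fid, iid, sex, age, y) over sampled individuals.
    """
    ped = make_pedigree(spec)
    rng = np.random.default_rng(par.seed)
    rec = ped.sampled_records
    age = np.round(rng.uniform(30, 80, size=len(rec)))
    sex01 = np.array([max(r.sex, 1) - 1 for r in rec], dtype=float)
    full_X = np.column_stack([np.ones(len(rec)), age, sex01])
    X = full_X[:, : len(par.beta)]
    if trait == "gaussian":
        y = simulate_gaussian(ped, par, X=X, rng=rng)
    elif trait == "binary":
        y = simulate_binary(ped, par, X=X, rng=rng)
    else:
        raise ValueError(f"unknown trait kind {trait!r}")
    df = pd.DataFrame(
        {
            "fid": [r.family for r in rec],
            "iid": [r.iid for r in rec],
            "sex": [r.sex for r in rec],
            "age": age,
            "y": y,
        }
    )
    return ped, df
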