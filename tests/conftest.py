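"""Shared fixtures: a solved simulator pipeline, random PSD covariance
blocks, and random pedigrees.  Hypothesis runs derandomised so the suite is
reproducible."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lrvalidate as lv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_random_covblocks(
    n: int, rng: np.random.Generator, delta_scale: float = 0.25
) -> lv.CovBlocks:
    """Random structures satisfying every CovBlocks invariant.

    Built constructively: K = var(u_p), D = var(u_w - u_p) and a PSD
    remainder R give Cp = D + R, Cw = R, G = K + Cp.
    """

    def psd(scale: float) -> np.ndarray:
        B = rng.standard_normal((n, n + 2))
        return scale * (B @ B.T) / (n + 2)

    K = psd(1.0)
    D = psd(delta_scale)
    R = psd(0.5)
    return lv.CovBlocks(G22=K + D + R, Cp22=D + R, Cw22=R)


def make_diagonal_covblocks(
    n: int,
    rng: np.random.Generator,
    sigma_g2: float = 1.0,
    c: float = 1.5,
    off_diag: float = 0.0,
) -> tuple[lv.CovBlocks, "lv.ReliabilityTable"]:
    """Diagonal(-dominant) blocks parameterised by reliabilities.

    rel_p ~ U(0.3, 0.6), rel_w = c * rel_p (capped at 0.95); PEV diagonals
    are (1 - rel) sigma_g2.  ``off_diag`` adds a common weak correlation to
    the PEC blocks (kept PSD by construction for small values).
    """
    import pandas as pd

    rel_p = rng.uniform(0.3, 0.6, size=n)
    rel_w = np.minimum(c * rel_p, 0.95)
    cp = np.diag((1.0 - rel_p) * sigma_g2)
    cw = np.diag((1.0 - rel_w) * sigma_g2)
    if off_diag:
        # shared weak PSD perturbation: keeps Cp - Cw diagonal and all
        # CovBlocks invariants intact for small values
        B = rng.standard_normal((n, n))
        P = off_diag * sigma_g2 * (B @ B.T) / n
        cp = cp + P
        cw = cw + P
    blocks = lv.CovBlocks(G22=sigma_g2 * np.eye(n), Cp22=cp, Cw22=cw)
    rels = lv.ReliabilityTable(
        table=pd.DataFrame(
            {"level": np.arange(1, n + 1), "rel_whole": rel_w, "rel_partial": rel_p}
        )
    )
    return blocks, rels


def make_random_pedigree(
    n: int, rng: np.random.Generator, n_founders: int = 20, p_unknown: float = 0.1
) -> lv.Pedigree:
    sire = [0] * n_founders
    dam = [0] * n_founders
    for i in range(n_founders, n):
        if rng.random() < p_unknown:
            sire.append(0)
            dam.append(0)
        else:
            s, d = rng.choice(i, size=2, replace=False) + 1
            sire.append(int(s))
            dam.append(int(d))
    return lv.Pedigree(animal=np.arange(1, n + 1), sire=np.array(sire), dam=np.array(dam))


@dataclass
class Pipeline:
    """One fully solved simulate -> whole/partial BLUP scenario."""

    config: lv.SimConfig
    pop: lv.TruePopulation
    ped: lv.Pedigree
    pheno: "lv.PhenotypeTable"
    partial: "lv.PhenotypeTable"
    model: lv.ModelSpec
    vc: lv.VarianceComponents
    focal: lv.FocalSet
    system_whole: lv.MmeSystem
    system_partial: lv.MmeSystem
    block: lv.FocalBlock
    covblocks: lv.CovBlocks
    rel_whole: np.ndarray
    rel_partial: np.ndarray


def build_pipeline(seed: int = 1, config: lv.SimConfig | None = None) -> Pipeline:
    config = config if config is not None else lv.SimConfig(seed=seed)
    pop = lv.simulate(config)
    ped = pop.pedigree
    pheno = pop.phenotype_table()
    model = pop.model_spec()
    vc = config.variance_components()
    focal = lv.focal_last_generation(pop)
    partial = lv.truncate_to_partial(pheno, focal=focal)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ainv = lv.a_inverse(ped, inbreeding_coeffs=pop.inbreeding_coeffs)
        sw = lv.solve_mme(pheno, ped, vc, model, ainv=ainv,
                          inbreeding_coeffs=pop.inbreeding_coeffs)
        sp = lv.solve_mme(partial, ped, vc, model, ainv=ainv,
                          inbreeding_coeffs=pop.inbreeding_coeffs)
    tw = lv.solutions_table(sw, "whole")
    tp = lv.solutions_table(sp, "partial")
    block = lv.extract_focal(tw, tp, model.genetic_effect_number, focal)
    covblocks, rel_w, rel_p = lv.covblocks_from_runs(sw, sp, ped, focal)
    return Pipeline(
        config=config, pop=pop, ped=ped, pheno=pheno, partial=partial,
        model=model, vc=vc, focal=focal, system_whole=sw, system_partial=sp,
        block=block, covblocks=covblocks, rel_whole=rel_w, rel_partial=rel_p,
    )


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    return build_pipeline(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
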