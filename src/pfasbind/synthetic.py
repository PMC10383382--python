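"""Synthetic data generators mirroring the statistical shape of the study.

Two kinds of inputs are emulated: (a) small descriptor-matrix datasets
with a known linear response plus Gaussian noise — the situation the
small-dataset double-cross-validation workflow is built for (about 22
compounds, a pool of a few dozen candidate descriptors, 3–4 truly
informative ones) — and (b) homologous PFAS-like molecular series
(perfluoroalkyl carboxylic and sulfonic acids, fluorotelomer acids and
alcohols) built programmatically from their repeat-unit chemistry.

Every generator is seed-deterministic and returns its ground truth so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class SyntheticSpec:
    """A stated world for descriptor-matrix simulation.

    Defaults mirror the regression study's shape: 22 compounds, a pool
    of 30 candidate descriptors with mild equicorrelation (rho = 0.3,
    typical of topological descriptor pools), 4 true descriptors, and
    noise at 10% of the noiseless response SD.
    """

    n: int = 22
    pool_size: int = 30
    true_indices: tuple[int, ...] = (0, 1, 2, 3)
    beta: tuple[float, ...] = (2.0, -3.0, 1.5, -1.0)
    noise_sd: Optional[float] = None  # absolute; None -> relative_noise * SD(signal)
    relative_noise: float = 0.1
    rho: float = 0.3
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_indices) != len(self.beta):
            raise ValueError("true_indices and beta must have equal length")
        if any(not 0 <= i < self.pool_size for i in self.true_indices):
            raise ValueError("true indices must lie within the pool")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")


def _correlated_gaussian(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Equicorrelated standard Gaussian columns, cov = (1-rho)I + rho*J."""
    Z = rng.standard_normal((n, p))
    if rho == 0:
        return Z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(abs(rho)) * np.sign(rho) * shared + np.sqrt(1 - abs(rho)) * Z


def make_descriptor_dataset(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Correlated Gaussian descriptors with a planted linear response.

    ``y = intercept + X[:, true] @ beta + N(0, sigma^2)``.  The truth
    record carries the indices, coefficients and realized noise SD.
    """
    rng = np.random.default_rng(spec.seed)
    X = _correlated_gaussian(rng, spec.n, spec.pool_size, spec.rho)
    beta = np.asarray(spec.beta, dtype=float)
    signal = spec.intercept + X[:, list(spec.true_indices)] @ beta
    if spec.noise_sd is not None:
        sigma = spec.noise_sd
    else:
        sd_signal = float(np.std(signal))
        sigma = spec.relative_noise * (sd_signal if sd_signal > 0 else 1.0)
    y = signal + rng.normal(0.0, sigma, size=spec.n) if sigma > 0 else signal.copy()
    truth = {
        "true_indices": tuple(spec.true_indices),
        "beta": tuple(beta),
        "intercept": spec.intercept,
        "noise_sd": sigma,
        "seed": spec.seed,
    }
    return X, y, truth


def make_classification_dataset(
    spec: SyntheticSpec,
    separation: float = 2.0,
    proportions: tuple[float, float] = (0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two Gaussian classes separated by ``separation`` on the true descriptors.

    Class 'H' means are shifted by +separation on each true descriptor;
    label balance matches the requested proportions exactly (counts
    rounded to integers summing to n).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(spec.seed)
    n_h = round(spec.n * proportions[0] / sum(proportions))
    n_l = spec.n - n_h
    X = _correlated_gaussian(rng, spec.n, spec.pool_size, spec.rho)
    labels = np.array(["H"] * n_h + ["L"] * n_l)
    for idx in spec.true_indices:
        X[:n_h, idx] += separation
    perm = rng.permutation(spec.n)
    truth = {"true_indices": tuple(spec.true_indices), "separation": separation,
             "n_h": n_h, "n_l": n_l, "seed": spec.seed}
    return X[perm], labels[perm], truth


# ---------------------------------------------------------------------------
# homologous PFAS series

PFAS_FAMILIES = ("PFCA", "PFSA", "FTCA", "FTSA", "FTOH")


def _perfluoro_chain(n_cf2: int) -> str:
    """SMILES fragment of n_cf2 CF2 units terminated by a fluorine."""
    return "C(F)(F)" * n_cf2 + "F"


def pfas_smiles(family: str, length: int) -> str:
    """SMILES of one homologue.

    ``length`` counts the carbons of the perfluorinated chain for PFCA/
    PFSA (total carbons for PFCA includes the acid carbon, matching the
    usual naming: PFCA(8) is PFOA) and the fluorinated-carbon count x of
    the telomer nomenclature x:3 (FTCA) or x:2 (FTSA, FTOH).
    """
    if length < 2:
        raise ValueError("chain length must be >= 2")
    if family == "PFCA":
        # length = total carbons incl. the carboxyl carbon
        return "OC(=O)" + _perfluoro_chain(length - 1)
    if family == "PFSA":
        return "OS(=O)(=O)" + _perfluoro_chain(length)
    if family == "FTCA":
        # x:3 telomer acid: x fluorinated carbons + CH2CH2 + COOH
        return "OC(=O)CC" + _perfluoro_chain(length)
    if family == "FTSA":
        return "OS(=O)(=O)CC" + _perfluoro_chain(length)
    if family == "FTOH":
        return "OCC" + _perfluoro_chain(length)
    raise ValueError(f"unknown family {family!r}; choose from {PFAS_FAMILIES}")


def make_pfas_series(family: str, lengths: Sequence[int]) -> list[tuple[str, str]]:
    """Homologous series as (SMILES, id) pairs, e.g. PFCA over 4..12.

    Every generated SMILES parses through the descriptor engine's graph
    builder.
    """
    series = []
    for n in lengths:
        smiles = pfas_smiles(family, n)
        series.append((smiles, f"{family}{n}"))
    return series
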