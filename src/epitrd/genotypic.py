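"""Genotypic parameterization of two-locus epistatic transmission ratio distortion.

The model assigns each of the nine offspring classes an unnormalized
weight that is linear in eight TRD parameters: additive and dominance
direct effects per locus (alpha_A, delta_A, alpha_B, delta_B) and four
epistatic effects (additive-by-additive ``aa_e``, additive-by-dominance
``ad_e``, dominance-by-additive ``da_e``, dominance-by-dominance
``dd_e``), all on [-1, 1]. For the double-heterozygous mating the
weights are

    w(g) = base(g) + coef(g) . theta

with base = (1,2,1,2,4,2,1,2,1) (16 times the Mendelian probabilities)
and an integer coefficient row per class. For any other mating the base
becomes 16 times that mating's Mendelian distribution, the coefficient
rows are unchanged, and Mendelian-infeasible classes keep weight zero.
Negative weights are clipped to zero first and the vector is then
normalized to sum to one.

Note the coefficient table is a fixed convention of the model, not a
plain product of additive/dominance contrast codes: the ad/da/dd columns
carry negated products in several rows. It is kept verbatim as a
constant rather than derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trio_data import (
    MatingConfiguration,
    PairTrioData,
    mendelian_table,
)

__all__ = [
    "GenotypicParams",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "BASE_WEIGHTS",
    "COEF",
    "class_weights",
    "offspring_probabilities",
    "log_likelihood",
    "GenotypicLikelihood",
]

PARAM_NAMES = (
    "alpha_A", "alpha_B", "delta_A", "delta_B",
    "aa_e", "ad_e", "da_e", "dd_e",
)
PARAM_BOUNDS = tuple((-1.0, 1.0) for _ in PARAM_NAMES)

#: 16x the Mendelian probabilities of the double-heterozygous mating.
BASE_WEIGHTS = np.array([1, 2, 1, 2, 4, 2, 1, 2, 1], dtype=float)

#: Multipliers of (alpha_A, alpha_B, delta_A, delta_B, aa_e, ad_e, da_e, dd_e)
#: per offspring class, rows in canonical genotype order.
COEF = np.array(
    [
        #        aA  aB  dA  dB  aa  ad  da  dd
        [ 1,  1, -1, -1,  1,  1,  1, -1],  # AABB
        [ 0,  1,  1, -1,  0,  0, -1,  1],  # AaBB
        [-1,  1, -1, -1, -1, -1,  1, -1],  # aaBB
        [ 1,  0, -1,  1,  0, -1,  0,  1],  # AABb
        [ 0,  0,  1,  1,  0,  0,  0, -1],  # AaBb
        [-1,  0, -1,  1,  0,  1,  0,  1],  # aaBb
        [ 1, -1, -1, -1, -1,  1, -1, -1],  # AAbb
        [ 0, -1,  1, -1,  0,  0,  1,  1],  # Aabb
        [-1, -1, -1, -1,  1, -1, -1, -1],  # aabb
    ],
    dtype=float,
)


class DegenerateMatingError(ValueError):
    """All class weights clipped to zero for a mating."""


@dataclass(frozen=True)
class GenotypicParams:
    """The eight genotypic TRD parameters, each on [-1, 1]."""

    alpha_A: float = 0.0
    alpha_B: float = 0.0
    delta_A: float = 0.0
    delta_B: float = 0.0
    aa_e: float = 0.0
    ad_e: float = 0.0
    da_e: float = 0.0
    dd_e: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(PARAM_NAMES, PARAM_BOUNDS):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "GenotypicParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, theta))))


def class_weights(mendelian: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Clipped unnormalized class weights for one mating.

    ``w(g) = 16 * mendelian(g) + coef(g) . theta`` on Mendelian-feasible
    classes, zero elsewhere; negatives clipped to zero.
    """
    w = 16.0 * mendelian + COEF @ theta
    w[mendelian == 0] = 0.0
    return np.clip(w, 0.0, None)


def offspring_probabilities(
    mating: MatingConfiguration, params: GenotypicParams
) -> np.ndarray:
    """Offspring-class probability vector for one mating under the model."""
    w = class_weights(mating.mendelian, params.as_array())
    total = w.sum()
    if total <= 0:
        raise DegenerateMatingError(
            f"all class weights zero for mating "
            f"{mating.sire_genotype.name} x {mating.dam_genotype.name}"
        )
    return w / total


class GenotypicLikelihood:
    """Vectorized log-likelihood of one SNP pair's trio counts.

    Precomputes the matings with observations so that repeated evaluation
    inside the sampler touches only small dense arrays.
    """

    n_params = len(PARAM_NAMES)
    bounds = PARAM_BOUNDS
    param_names = PARAM_NAMES

    def __init__(self, data: PairTrioData):
        if data.counts.sum() == 0:
            raise ValueError("empty trio counts")
        mend = mendelian_table()
        rows = np.flatnonzero(data.counts.sum(axis=1) > 0)
        self._m16 = 16.0 * mend[rows]  # (m, 9)
        self._feasible = mend[rows] > 0
        self._counts = data.counts[rows].astype(float)
        self._row_tot = self._counts.sum(axis=1)
        self._obs = self._counts > 0

    def __call__(self, theta: np.ndarray) -> float:
        w = self._m16 + (COEF @ theta)[None, :]
        w[~self._feasible] = 0.0
        np.clip(w, 0.0, None, out=w)
        totals = w.sum(axis=1)
        w_obs = w[self._obs]
        if np.any(w_obs <= 0.0) or np.any(totals <= 0.0):
            return -np.inf
        return float(
            np.sum(self._counts[self._obs] * np.log(w_obs))
            - np.sum(self._row_tot * np.log(totals))
        )


def log_likelihood(data: PairTrioData, params: GenotypicParams) -> float:
    """Multinomial log-likelihood of the observed trio counts.

    Returns ``-inf`` when any observed offspring class has probability
    zero (e.g. clipped away at a parameter boundary).
    """
    return GenotypicLikelihood(data)(params.as_array())
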