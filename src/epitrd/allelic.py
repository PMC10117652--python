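"""Allelic (gamete-transmission) parameterization of epistatic TRD.

A parent's two-locus genotype produces gametes that can be viewed as
*artificial haplotype* alleles AB, Ab, aB, ab (one allele from each of
the two unlinked SNPs). The model distorts the transmission of each
gamete with two direct parameters (beta_A, beta_B on [-0.5, 0.5]: the
capital allele of a heterozygous locus is transmitted with probability
0.5 + beta) and six epistatic parameters, one per unordered pair of
gametes (beta_AB_Ab, ..., beta_aB_ab on [-1, 1]): when a parent carries
exactly the two gametes of a pair, the canonically earlier gamete
(AB < Ab < aB < ab) receives a factor (1 + beta) and the other
(1 - beta). Unnormalized gamete weights are the product of the per-locus
and pairwise factors, normalized per parent; offspring-class
probabilities are the convolution of the sire's and dam's gamete
distributions.

The simplified biallelic-haplotype screen collapses this to a single
overall transmission parameter alpha_j per designated gamete j:
P(transmit j) = 0.5 + alpha_j from informative parents (heterozygous at
exactly one locus and carrying j), a cheap preliminary scan ahead of the
full eight-parameter model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trio_data import (
    MatingConfiguration,
    PairTrioData,
    TwoLocusGenotype,
    all_matings,
)

__all__ = [
    "Gamete",
    "GAMETE_LABELS",
    "AllelicParams",
    "SimplifiedParams",
    "ALLELIC_PARAM_NAMES",
    "ALLELIC_PARAM_BOUNDS",
    "PAIRWISE_NAMES",
    "gamete_probabilities",
    "offspring_probabilities_allelic",
    "log_likelihood_allelic",
    "AllelicLikelihood",
    "SimplifiedCounts",
    "simplified_transmission_counts",
    "simplified_log_likelihood",
]

GAMETE_LABELS = ("AB", "Ab", "aB", "ab")

# unordered gamete pairs in canonical order; index into the six
# epistatic parameters
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
PAIRWISE_NAMES = tuple(
    f"beta_{GAMETE_LABELS[i]}_{GAMETE_LABELS[j]}" for i, j in _PAIRS
)
_PAIR_INDEX = {p: k for k, p in enumerate(_PAIRS)}

ALLELIC_PARAM_NAMES = ("beta_A", "beta_B") + PAIRWISE_NAMES
ALLELIC_PARAM_BOUNDS = ((-0.5, 0.5), (-0.5, 0.5)) + tuple(
    (-1.0, 1.0) for _ in PAIRWISE_NAMES
)


class Gamete(int):
    """An artificial haplotype allele: AB=0, Ab=1, aB=2, ab=3."""

    def __new__(cls, value) -> "Gamete":
        if isinstance(value, str):
            value = GAMETE_LABELS.index(value)
        if value not in (0, 1, 2, 3):
            raise ValueError(f"invalid gamete {value!r}")
        return super().__new__(cls, value)

    @property
    def label(self) -> str:
        return GAMETE_LABELS[int(self)]

    @property
    def capital_a(self) -> bool:
        """Carries the capital allele at locus A."""
        return int(self) < 2

    @property
    def capital_b(self) -> bool:
        return int(self) % 2 == 0


class DegenerateGameteError(ValueError):
    """All gamete weights zero for a parent."""


@dataclass(frozen=True)
class AllelicParams:
    """Direct (beta_A, beta_B) and six pairwise epistatic TRD parameters."""

    beta_A: float = 0.0
    beta_B: float = 0.0
    beta_AB_Ab: float = 0.0
    beta_AB_aB: float = 0.0
    beta_AB_ab: float = 0.0
    beta_Ab_aB: float = 0.0
    beta_Ab_ab: float = 0.0
    beta_aB_ab: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(ALLELIC_PARAM_NAMES, ALLELIC_PARAM_BOUNDS):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ALLELIC_PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "AllelicParams":
        return cls(**dict(zip(ALLELIC_PARAM_NAMES, map(float, theta))))

    def pairwise(self, g1: int, g2: int) -> float:
        i, j = (g1, g2) if g1 < g2 else (g2, g1)
        return getattr(self, PAIRWISE_NAMES[_PAIR_INDEX[(i, j)]])


def _feasible_gametes(parent: TwoLocusGenotype) -> list[int]:
    a_alleles = {2: [True], 1: [True, False], 0: [False]}[parent.dosage_a]
    b_alleles = {2: [True], 1: [True, False], 0: [False]}[parent.dosage_b]
    out = []
    for ca in a_alleles:
        for cb in b_alleles:
            out.append((0 if ca else 2) + (0 if cb else 1))
    return sorted(out)


def _gamete_weights(parent: TwoLocusGenotype, theta: np.ndarray) -> np.ndarray:
    """Unnormalized gamete weights (length 4; infeasible gametes zero).

    theta is the parameter vector in ``ALLELIC_PARAM_NAMES`` order.
    Homozygous loci contribute no (0.5 +/- beta) factor: any constant
    would cancel under per-parent normalization.
    """
    beta_a, beta_b = theta[0], theta[1]
    feas = _feasible_gametes(parent)
    w = np.zeros(4)
    for g in feas:
        f = 1.0
        if parent.het_a:
            f *= 0.5 + beta_a if g < 2 else 0.5 - beta_a
        if parent.het_b:
            f *= 0.5 + beta_b if g % 2 == 0 else 0.5 - beta_b
        w[g] = f
    if parent.het_a and parent.het_b:
        # each gamete pairs with its double-flip complement
        for g in feas:
            comp = 3 - g
            i, j = (g, comp) if g < comp else (comp, g)
            beta = theta[2 + _PAIR_INDEX[(i, j)]]
            w[g] *= (1.0 + beta) if g < comp else (1.0 - beta)
    elif len(feas) == 2:
        g1, g2 = feas
        beta = theta[2 + _PAIR_INDEX[(g1, g2)]]
        w[g1] *= 1.0 + beta
        w[g2] *= 1.0 - beta
    return w


def gamete_probabilities(
    parent: TwoLocusGenotype, params: AllelicParams
) -> np.ndarray:
    """Gamete transmission distribution of one parent (length-4 vector)."""
    w = _gamete_weights(parent, params.as_array())
    total = w.sum()
    if total <= 0:
        raise DegenerateGameteError(
            f"all gamete weights zero for parent {parent.name}"
        )
    return w / total


def _gamete_matrix(theta: np.ndarray) -> np.ndarray:
    """(9 parent genotypes, 4 gametes) normalized transmission matrix."""
    out = np.zeros((9, 4))
    for g in TwoLocusGenotype:
        w = _gamete_weights(g, theta)
        t = w.sum()
        if t <= 0:
            raise DegenerateGameteError(f"all gamete weights zero for {g.name}")
        out[int(g)] = w / t
    return out


# gamete pair -> offspring class: one-hot (4, 4, 9) transfer tensor
def _transfer_tensor() -> np.ndarray:
    K = np.zeros((4, 4, 9))
    for gs in range(4):
        for gd in range(4):
            da = (gs < 2) + (gd < 2)
            db = (gs % 2 == 0) + (gd % 2 == 0)
            K[gs, gd, int(TwoLocusGenotype.from_dosages(da, db))] = 1.0
    return K


_K = _transfer_tensor()


def offspring_probabilities_allelic(
    mating: MatingConfiguration, params: AllelicParams
) -> np.ndarray:
    """Offspring-class probabilities as the sire x dam gamete convolution."""
    ps = gamete_probabilities(mating.sire_genotype, params)
    pdm = gamete_probabilities(mating.dam_genotype, params)
    return np.einsum("i,j,ijk->k", ps, pdm, _K)


class AllelicLikelihood:
    """Vectorized log-likelihood of one SNP pair under the allelic model."""

    n_params = len(ALLELIC_PARAM_NAMES)
    bounds = ALLELIC_PARAM_BOUNDS
    param_names = ALLELIC_PARAM_NAMES

    def __init__(self, data: PairTrioData):
        if data.counts.sum() == 0:
            raise ValueError("empty trio counts")
        rows = np.flatnonzero(data.counts.sum(axis=1) > 0)
        self._sires = rows // 9
        self._dams = rows % 9
        self._counts = data.counts[rows].astype(float)
        self._obs = self._counts > 0

    def __call__(self, theta: np.ndarray) -> float:
        try:
            G = _gamete_matrix(theta)
        except DegenerateGameteError:
            return -np.inf
        E = G[self._sires][:, :, None] * G[self._dams][:, None, :]
        P = np.einsum("mij,ijk->mk", E, _K)
        p_obs = P[self._obs]
        if np.any(p_obs <= 0.0):
            return -np.inf
        return float(np.sum(self._counts[self._obs] * np.log(p_obs)))


def log_likelihood_allelic(data: PairTrioData, params: AllelicParams) -> float:
    """Multinomial log-likelihood under the allelic model (-inf on zeros)."""
    return AllelicLikelihood(data)(params.as_array())


# ---------------------------------------------------------------------------
# Simplified biallelic artificial-haplotype screen


@dataclass(frozen=True)
class SimplifiedParams:
    """Overall transmission distortion of one designated artificial haplotype."""

    alpha_j: float = 0.0

    def __post_init__(self) -> None:
        if not -0.5 <= self.alpha_j <= 0.5:
            raise ValueError("alpha_j must lie in [-0.5, 0.5]")


@dataclass
class SimplifiedCounts:
    """Transmission tallies of a designated gamete from informative parents.

    An informative parent is heterozygous at exactly one locus and
    carries the designated gamete: its two possible gametes are the
    designated one and a single alternative, and the transmitted one is
    deduced from the offspring given the other parent. Trios where the
    deduction is ambiguous (both parents heterozygous at the same locus
    with a heterozygous offspring) are skipped and tallied.
    """

    n_transmitted: int = 0
    n_alternative: int = 0
    n_informative_parents: int = 0
    n_ambiguous: int = 0


def _parent_contribution(
    het_locus: str,
    offspring_dosage: int,
    other_dosage: int,
) -> int | None:
    """Capital-allele contribution (0/1) of a single-het focal parent,
    or None when ambiguous."""
    if other_dosage == 2:
        c = offspring_dosage - 1
    elif other_dosage == 0:
        c = offspring_dosage
    else:  # other parent heterozygous too
        if offspring_dosage == 0:
            c = 0
        elif offspring_dosage == 2:
            c = 1
        else:
            return None
    return c if c in (0, 1) else None


def simplified_transmission_counts(
    data: PairTrioData, j: Gamete | str | int
) -> SimplifiedCounts:
    """Count transmissions of gamete ``j`` from informative parents.

    Double-heterozygous parents are never scored here: for them the
    Mendelian null transmission probability of a specific gamete is 1/4,
    not 1/2, so pooling them would bias the single-parameter screen.
    They are handled by the full allelic model instead.
    """
    j = Gamete(j)
    out = SimplifiedCounts()
    matings = all_matings()
    for m in matings:
        row = data.counts[m.index]
        if not row.any():
            continue
        for parent, other in (
            (m.sire_genotype, m.dam_genotype),
            (m.dam_genotype, m.sire_genotype),
        ):
            _score_parent(parent, other, j, row, out)
    return out


def _score_parent(
    parent: TwoLocusGenotype,
    other: TwoLocusGenotype,
    j: Gamete,
    class_counts: np.ndarray,
    out: SimplifiedCounts,
) -> None:
    single_het = parent.het_a != parent.het_b
    if not single_het:
        return
    feas = _feasible_gametes(parent)
    if int(j) not in feas:
        return
    n_here = int(class_counts.sum())
    out.n_informative_parents += n_here
    het_locus = "A" if parent.het_a else "B"
    for cls_idx, n in enumerate(class_counts):
        if n == 0:
            continue
        off = TwoLocusGenotype(cls_idx)
        if het_locus == "A":
            c = _parent_contribution("A", off.dosage_a, other.dosage_a)
            j_wants = 1 if j.capital_a else 0
        else:
            c = _parent_contribution("B", off.dosage_b, other.dosage_b)
            j_wants = 1 if j.capital_b else 0
        if c is None:
            out.n_ambiguous += int(n)
        elif c == j_wants:
            out.n_transmitted += int(n)
        else:
            out.n_alternative += int(n)


def simplified_log_likelihood(
    n_j: int, n_alt: int, params: SimplifiedParams
) -> float:
    """Binomial log-likelihood of the simplified screen counts."""
    if n_j < 0 or n_alt < 0:
        raise ValueError("counts must be nonnegative")
    a = params.alpha_j
    ll = 0.0
    for n, p in ((n_j, 0.5 + a), (n_alt, 0.5 - a)):
        if n > 0:
            if p <= 0.0:
                return -np.inf
            ll += n * np.log(p)
    return float(ll)


@dataclass
class SimplifiedScreenResult:
    """Posterior summary of the simplified screen for one gamete."""

    gamete: str
    alpha_mean: float
    alpha_sd: float
    log10_bf: float
    counts: SimplifiedCounts
    promoted: bool


def simplified_screen(
    data: PairTrioData,
    single_snp_trd: float,
    chain_cfg=None,
    gametes=GAMETE_LABELS,
    min_trd_increase: float = 0.05,
    seed: int = 0,
):
    """Run the single-parameter artificial-haplotype screen on one pair.

    Intended for pairs that include at least one SNP already flagged
    with direct single-locus TRD (``single_snp_trd`` is that SNP's TRD
    magnitude estimate; pass 0.0 to screen without the restriction). A
    gamete is *promoted* to full-model re-analysis when its |TRD|
    exceeds the single SNP's by at least ``min_trd_increase`` and its
    under/over-represented offspring count (about alpha_j x 2 x scored
    transmissions) is no smaller than the single SNP's implied count.
    """
    from .inference import ChainConfig, bayes_factor, mh_sample

    if chain_cfg is None:
        chain_cfg = ChainConfig.simplified(seed=seed)
    single_distorted = abs(single_snp_trd) * 2.0
    out = []
    for g in gametes:
        counts = simplified_transmission_counts(data, g)
        n_scored = counts.n_transmitted + counts.n_alternative
        if n_scored == 0:
            continue
        loglik = simplified_loglik_fn(counts.n_transmitted, counts.n_alternative)
        chain = mh_sample(loglik, loglik.bounds, chain_cfg)
        draws = chain.draws[:, 0]
        alpha = float(draws.mean())
        bf = bayes_factor(draws, (-0.5, 0.5))
        distorted = abs(alpha) * 2.0 * n_scored
        promoted = (
            abs(alpha) - abs(single_snp_trd) >= min_trd_increase
            and distorted >= single_distorted * n_scored
        )
        out.append(
            SimplifiedScreenResult(
                gamete=str(g) if isinstance(g, str) else GAMETE_LABELS[int(g)],
                alpha_mean=alpha,
                alpha_sd=float(draws.std(ddof=1)),
                log10_bf=bf,
                counts=counts,
                promoted=promoted,
            )
        )
    return out


def simplified_loglik_fn(n_j: int, n_alt: int):
    """Single-parameter log-likelihood closure for the sampler."""

    def loglik(theta: np.ndarray) -> float:
        a = float(theta[0])
        ll = 0.0
        for n, p in ((n_j, 0.5 + a), (n_alt, 0.5 - a)):
            if n > 0:
                if p <= 0.0:
                    return -np.inf
                ll += n * np.log(p)
        return ll

    loglik.n_params = 1
    loglik.bounds = ((-0.5, 0.5),)
    loglik.param_names = ("alpha_j",)
    return loglik
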