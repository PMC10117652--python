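"""Screen for depletion of double-homozygous offspring (recessive epistatic TRD).

A fully penetrant recessive incompatibility between two unlinked loci
removes offspring homozygous for a specific allele combination (an
artificial haplotype, e.g. aB -> genotype aaBB) while leaving all other
offspring classes at their Mendelian proportions. The screen therefore
flags SNP pairs where the Mendelian-expected count of such offspring,
summed over the observed matings, reaches a minimum (15 by default)
while none are observed, and where the remaining classes within the
carrier matings conform to Mendelian expectation. This pattern is
invisible to the Bayes-factor machinery of the genotypic and allelic
scans, whose pre-filters it deliberately bypasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allelic import Gamete, GAMETE_LABELS
from .trio_data import PairTrioData, TwoLocusGenotype, all_matings, mendelian_table

__all__ = [
    "RecessiveHit",
    "expected_double_homozygotes",
    "recessive_scan",
    "haplotype_frequency",
]


@dataclass
class RecessiveHit:
    """One flagged pair: expected-but-absent double homozygotes.

    ``per_mating_breakdown`` maps the flat mating index of each carrier
    mating (both parents able to transmit the haplotype) to its
    (observed, expected) target-class counts.
    """

    snp_a: str
    snp_b: str
    haplotype: str
    expected_hh: float
    observed_hh: int
    n_het_sires: int
    n_het_dams: int
    haplotype_frequency: float
    per_mating_breakdown: dict = field(default_factory=dict)
    mendelian_ok: bool = True


def _transmit_prob(dosage: int, wants_capital: bool) -> float:
    """P(parent transmits the haplotype's allele at one locus)."""
    p_capital = dosage / 2.0
    return p_capital if wants_capital else 1.0 - p_capital


def _target_class(h: Gamete) -> int:
    da = 2 if h.capital_a else 0
    db = 2 if h.capital_b else 0
    return int(TwoLocusGenotype.from_dosages(da, db))


def expected_double_homozygotes(
    data: PairTrioData, h: Gamete | str | int
) -> tuple[float, int, dict]:
    """Expected vs observed offspring double-homozygous for haplotype ``h``.

    Per trio the probability is the Mendelian product over both loci and
    both parents of transmitting the haplotype's allele; the expectation
    sums this over all trios. Returns (expected, observed, breakdown)
    where breakdown maps carrier-mating index to
    ``(observed_target, expected_target)``.
    """
    h = Gamete(h)
    target = _target_class(h)
    expected = 0.0
    observed = 0
    breakdown: dict[int, tuple[int, float]] = {}
    totals = data.counts.sum(axis=1)
    for m in all_matings():
        n_m = int(totals[m.index])
        if n_m == 0:
            continue
        p = (
            _transmit_prob(m.sire_genotype.dosage_a, h.capital_a)
            * _transmit_prob(m.dam_genotype.dosage_a, h.capital_a)
            * _transmit_prob(m.sire_genotype.dosage_b, h.capital_b)
            * _transmit_prob(m.dam_genotype.dosage_b, h.capital_b)
        )
        if p > 0.0:
            exp_m = n_m * p
            obs_m = int(data.counts[m.index, target])
            expected += exp_m
            observed += obs_m
            breakdown[m.index] = (obs_m, exp_m)
    return expected, observed, breakdown


def haplotype_frequency(data: PairTrioData, h: Gamete | str | int) -> float:
    """Frequency of the haplotype among parental gametes.

    Computed as the product of the two per-locus allele frequencies over
    all parent slots of the observed trios (the two loci are unlinked,
    so gametes form by independent assortment).
    """
    h = Gamete(h)
    totals = data.counts.sum(axis=1)
    n_parents = 2.0 * totals.sum()
    if n_parents == 0:
        return float("nan")
    cap_a = 0.0
    cap_b = 0.0
    for m in all_matings():
        n_m = totals[m.index]
        if n_m == 0:
            continue
        cap_a += n_m * (m.sire_genotype.dosage_a + m.dam_genotype.dosage_a) / 2.0
        cap_b += n_m * (m.sire_genotype.dosage_b + m.dam_genotype.dosage_b) / 2.0
    fa = cap_a / n_parents
    fb = cap_b / n_parents
    pa = fa if h.capital_a else 1.0 - fa
    pb = fb if h.capital_b else 1.0 - fb
    return float(pa * pb)


def _mendelian_conformity(
    data: PairTrioData,
    h: Gamete,
    tolerance: float,
) -> bool:
    """Check non-target classes within carrier matings against Mendel.

    A class conforms when |observed - expected| <= max(tolerance *
    expected, 3 * sqrt(expected)); the square-root floor keeps small
    cells from failing on Poisson noise alone.
    """
    target = _target_class(h)
    mend = mendelian_table()
    totals = data.counts.sum(axis=1)
    for m in all_matings():
        n_m = totals[m.index]
        if n_m == 0:
            continue
        p_carrier = (
            _transmit_prob(m.sire_genotype.dosage_a, h.capital_a)
            * _transmit_prob(m.dam_genotype.dosage_a, h.capital_a)
            * _transmit_prob(m.sire_genotype.dosage_b, h.capital_b)
            * _transmit_prob(m.dam_genotype.dosage_b, h.capital_b)
        )
        if p_carrier == 0.0:
            continue
        for g in range(9):
            if g == target or mend[m.index, g] == 0:
                continue
            exp = n_m * mend[m.index, g]
            obs = data.counts[m.index, g]
            if abs(obs - exp) > max(tolerance * exp, 3.0 * np.sqrt(exp)):
                return False
    return True


def recessive_scan(
    pairs: list[PairTrioData],
    min_expected: float = 15.0,
    mendelian_tolerance: float = 0.10,
) -> list[RecessiveHit]:
    """Flag pairs with expected-but-unobserved double homozygotes.

    For each pair and each of the four artificial haplotypes, a hit
    requires expected >= ``min_expected``, zero observed, and Mendelian
    conformity of all other classes within the carrier matings.
    """
    hits = []
    for d in pairs:
        for label in GAMETE_LABELS:
            h = Gamete(label)
            expected, observed, breakdown = expected_double_homozygotes(d, h)
            if expected < min_expected or observed != 0:
                continue
            ok = _mendelian_conformity(d, h, mendelian_tolerance)
            if not ok:
                continue
            hits.append(
                RecessiveHit(
                    snp_a=d.snp_a,
                    snp_b=d.snp_b,
                    haplotype=label,
                    expected_hh=expected,
                    observed_hh=observed,
                    n_het_sires=d.n_het_sires,
                    n_het_dams=d.n_het_dams,
                    haplotype_frequency=haplotype_frequency(d, h),
                    per_mating_breakdown=breakdown,
                    mendelian_ok=ok,
                )
            )
    return hits
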