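"""Seeded synthetic trio generator with configurable distortion mechanisms.

Emulates the mating structure of a dairy-cattle half-sib design: few
sires each mated to many dams (one offspring per dam by default), with
unbalanced sire usage. Parent genotypes at the two unlinked loci are
drawn independently from Hardy-Weinberg proportions at configurable
allele frequencies. Offspring two-locus genotypes are then sampled under
one of five mechanisms:

``none``
    Mendelian segregation (the null).
``genotypic``
    The genotypic TRD model's offspring-class distribution per mating.
``allelic``
    Each parent's gamete drawn from the allelic model's transmission
    distribution.
``viability``
    Mendelian segregation followed by per-class survival. In the default
    ``drop`` mode a non-surviving trio is removed from the dataset (the
    biologically faithful reading: the offspring was never genotyped);
    in ``redraw`` mode the offspring is resampled until it survives, so
    the trio count is preserved.
``recessive_lethal``
    Viability with survival ``1 - penetrance`` for a single
    double-homozygous class and 1 elsewhere.

The default scale (50 sires x 2,000 dams x 1 offspring) keeps the
informative-offspring count in the thousands, the order of magnitude the
genome-scan pre-filters assume, while simulating in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allelic import AllelicParams, gamete_probabilities, _K
from .genotypic import GenotypicParams, class_weights
from .trio_data import (
    GenotypeMatrix,
    PairTrioData,
    TrioTable,
    TwoLocusGenotype,
    all_matings,
    extract_pair,
    mendelian_table,
    N_CLASSES,
    N_MATINGS,
)

__all__ = [
    "SimConfig",
    "ParentPopulation",
    "SimResult",
    "simulate_parents",
    "simulate_offspring",
    "simulate_pair",
    "simulate_hethet_pair",
    "truth_record",
    "write_truth",
    "read_truth",
    "write_dataset",
]

MECHANISMS = ("none", "genotypic", "allelic", "viability", "recessive_lethal")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic trio study design and distortion mechanism.

    ``family_imbalance`` is the Dirichlet concentration for sire usage:
    1 gives strongly unbalanced half-sib families, large values approach
    equal family sizes. ``mechanism_params`` is a
    :class:`~epitrd.genotypic.GenotypicParams`, an
    :class:`~epitrd.allelic.AllelicParams`, a length-9 per-class fitness
    vector, or a ``(haplotype_label, penetrance)`` tuple, matching the
    mechanism.
    """

    n_sires: int = 50
    n_dams: int = 2000
    offspring_per_dam: int = 1
    family_imbalance: float = 1.0
    freq_a: float = 0.5
    freq_b: float = 0.5
    mechanism: str = "none"
    mechanism_params: object = None
    survival_mode: str = "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not (0.0 < self.freq_a < 1.0 and 0.0 < self.freq_b < 1.0):
            raise ValueError("allele frequencies must lie in the open (0, 1)")
        if min(self.n_sires, self.n_dams, self.offspring_per_dam) < 1:
            raise ValueError("counts must be positive")
        if self.survival_mode not in ("drop", "redraw"):
            raise ValueError("survival_mode must be 'drop' or 'redraw'")
        if self.mechanism == "recessive_lethal":
            _, pen = self.mechanism_params
            if not 0.0 <= float(pen) <= 1.0:
                raise ValueError("penetrance must lie in [0, 1]")


@dataclass
class ParentPopulation:
    """Sampled parental genotypes and the dam-to-sire assignment."""

    sire_ids: list
    dam_ids: list
    sire_classes: np.ndarray  # (n_sires,) genotype index 0..8
    dam_classes: np.ndarray  # (n_dams,)
    dam_sire: np.ndarray  # (n_dams,) index into sires


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    trios: TrioTable
    pair: PairTrioData
    truth: dict


def _hwe_classes(rng, n: int, freq_a: float, freq_b: float) -> np.ndarray:
    da = rng.binomial(2, freq_a, size=n)
    db = rng.binomial(2, freq_b, size=n)
    return 3 * (2 - db) + (2 - da)


def simulate_parents(cfg: SimConfig) -> ParentPopulation:
    """Draw parental genotypes from Hardy-Weinberg and assign dams to sires."""
    rng = np.random.default_rng(cfg.seed)
    sires = _hwe_classes(rng, cfg.n_sires, cfg.freq_a, cfg.freq_b)
    dams = _hwe_classes(rng, cfg.n_dams, cfg.freq_a, cfg.freq_b)
    usage = rng.dirichlet(np.full(cfg.n_sires, cfg.family_imbalance))
    dam_sire = rng.choice(cfg.n_sires, size=cfg.n_dams, p=usage)
    width_s = len(str(cfg.n_sires))
    width_d = len(str(cfg.n_dams))
    return ParentPopulation(
        sire_ids=[f"S{i + 1:0{width_s}d}" for i in range(cfg.n_sires)],
        dam_ids=[f"D{i + 1:0{width_d}d}" for i in range(cfg.n_dams)],
        sire_classes=sires,
        dam_classes=dams,
        dam_sire=dam_sire,
    )


def _mating_distributions(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-mating offspring-class sampling distribution and survival vector.

    Returns (probs, survival): ``probs[m]`` is the class distribution to
    sample from for mating ``m``; ``survival[g]`` the post-sampling
    survival probability per class (all ones except viability modes).
    """
    mend = mendelian_table()
    survival = np.ones(N_CLASSES)
    if cfg.mechanism == "none":
        return mend, survival
    if cfg.mechanism == "genotypic":
        params = cfg.mechanism_params
        if not isinstance(params, GenotypicParams):
            params = GenotypicParams(**dict(params))
        theta = params.as_array()
        probs = np.zeros_like(mend)
        for m in range(N_MATINGS):
            w = class_weights(mend[m], theta)
            t = w.sum()
            if t <= 0:
                mat = all_matings()[m]
                raise ValueError(
                    f"degenerate offspring distribution for mating "
                    f"{mat.sire_genotype.name} x {mat.dam_genotype.name}"
                )
            probs[m] = w / t
        return probs, survival
    if cfg.mechanism == "allelic":
        params = cfg.mechanism_params
        if not isinstance(params, AllelicParams):
            params = AllelicParams(**dict(params))
        G = np.vstack(
            [gamete_probabilities(g, params) for g in TwoLocusGenotype]
        )
        probs = np.zeros_like(mend)
        for m in range(N_MATINGS):
            probs[m] = np.einsum("i,j,ijk->k", G[m // 9], G[m % 9], _K)
        return probs, survival
    if cfg.mechanism == "viability":
        survival = np.asarray(cfg.mechanism_params, dtype=float)
        if survival.shape != (N_CLASSES,) or np.any((survival < 0) | (survival > 1)):
            raise ValueError("viability needs a length-9 fitness vector in [0, 1]")
        return mend, survival
    # recessive_lethal
    hap, penetrance = cfg.mechanism_params
    target = _double_homozygote_class(str(hap))
    survival[target] = 1.0 - float(penetrance)
    return mend, survival


def _double_homozygote_class(hap: str) -> int:
    """Offspring class homozygous for the haplotype's allele at both loci."""
    if sorted(hap.upper()) != ["A", "B"] or len(hap) != 2:
        raise ValueError(f"haplotype must be one of AB/Ab/aB/ab, got {hap!r}")
    da = 2 if hap[0] == "A" else 0
    db = 2 if hap[1] == "B" else 0
    return int(TwoLocusGenotype.from_dosages(da, db))


def simulate_offspring(parents: ParentPopulation, cfg: SimConfig) -> SimResult:
    """Sample offspring for every dam and assemble the full dataset."""
    rng = np.random.default_rng(cfg.seed + 1)
    probs, survival = _mating_distributions(cfg)

    sire_of = parents.dam_sire
    n_trios = len(parents.dam_ids) * cfg.offspring_per_dam
    dam_idx = np.repeat(np.arange(len(parents.dam_ids)), cfg.offspring_per_dam)
    sire_idx = sire_of[dam_idx]
    mating = 9 * parents.sire_classes[sire_idx] + parents.dam_classes[dam_idx]

    # sample offspring classes grouped by mating configuration
    off = np.empty(n_trios, dtype=np.int64)
    for m in np.unique(mating):
        sel = mating == m
        off[sel] = rng.choice(N_CLASSES, size=int(sel.sum()), p=probs[m])

    redraw = cfg.survival_mode == "redraw" and cfg.mechanism in (
        "viability",
        "recessive_lethal",
    )
    keep = rng.random(n_trios) < survival[off]
    if redraw:
        # matings with no surviving offspring class cannot be redrawn;
        # their trios are dropped even in redraw mode
        viable = (probs * survival[None, :]).sum(axis=1) > 0.0
        doomed = ~viable[mating]
        keep[doomed] = False
        retry = ~keep & ~doomed
        while retry.any():
            idx = np.flatnonzero(retry)
            for m in np.unique(mating[idx]):
                sel = idx[mating[idx] == m]
                off[sel] = rng.choice(N_CLASSES, size=len(sel), p=probs[m])
            keep[idx] = rng.random(len(idx)) < survival[off[idx]]
            retry = ~keep & ~doomed

    off = off[keep]
    dam_idx = dam_idx[keep]
    sire_idx = sire_idx[keep]

    width = len(str(max(n_trios, 1)))
    off_ids = [f"O{i + 1:0{width}d}" for i in range(len(off))]
    animal_ids = parents.sire_ids + parents.dam_ids + off_ids
    classes = np.concatenate(
        [parents.sire_classes, parents.dam_classes, off]
    )
    dosage_a = 2 - (classes % 3)
    dosage_b = 2 - (classes // 3)
    calls = np.stack([dosage_a, dosage_b], axis=1).astype(np.int8)
    snp_map = pd.DataFrame(
        {"chrom": ["1", "2"], "pos": [1_000_000, 2_000_000]},
        index=["snpA", "snpB"],
    )
    genotypes = GenotypeMatrix(animal_ids, ["snpA", "snpB"], calls, snp_map)
    trios = TrioTable(
        pd.DataFrame(
            {
                "offspring": off_ids,
                "sire": [parents.sire_ids[i] for i in sire_idx],
                "dam": [parents.dam_ids[i] for i in dam_idx],
            }
        )
    )
    pair = extract_pair(genotypes, trios, "snpA", "snpB")
    return SimResult(genotypes=genotypes, trios=trios, pair=pair, truth=truth_record(cfg))


def simulate_pair(cfg: SimConfig) -> SimResult:
    """Full simulation: parents, matings, offspring, assembled pair data."""
    return simulate_offspring(simulate_parents(cfg), cfg)


def simulate_hethet_pair(
    n_trios: int,
    mechanism: str = "none",
    mechanism_params: object = None,
    seed: int = 0,
) -> PairTrioData:
    """Trios whose parents are all double-heterozygous (AaBb x AaBb).

    A fast fixture for parameter-recovery studies: the offspring classes
    are a single multinomial draw from the mechanism's double-het
    distribution. Every parent is heterozygous, so the het tallies equal
    the trio count.
    """
    cfg = SimConfig(mechanism=mechanism, mechanism_params=mechanism_params, seed=seed)
    probs, survival = _mating_distributions(cfg)
    m = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
    rng = np.random.default_rng(seed)
    classes = rng.choice(N_CLASSES, size=n_trios, p=probs[m])
    keep = rng.random(n_trios) < survival[classes]
    classes = classes[keep]
    counts = np.zeros((N_MATINGS, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (m, classes), 1)
    return PairTrioData(
        snp_a="snpA",
        snp_b="snpB",
        counts=counts,
        n_het_sires=len(classes),
        n_het_dams=len(classes),
    )


def truth_record(cfg: SimConfig) -> dict:
    """Serializable record of the generating mechanism and parameters."""
    params = cfg.mechanism_params
    if isinstance(params, (GenotypicParams, AllelicParams)):
        params = {k: float(v) for k, v in vars(params).items()}
    elif isinstance(params, np.ndarray):
        params = [float(v) for v in params]
    elif isinstance(params, tuple):
        params = [params[0], float(params[1])]
    return {
        "mechanism": cfg.mechanism,
        "params": params,
        "n_sires": cfg.n_sires,
        "n_dams": cfg.n_dams,
        "offspring_per_dam": cfg.offspring_per_dam,
        "family_imbalance": cfg.family_imbalance,
        "freq_a": cfg.freq_a,
        "freq_b": cfg.freq_b,
        "survival_mode": cfg.survival_mode,
        "seed": cfg.seed,
    }


def write_truth(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth_record(cfg), fh, sort_keys=False)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_dataset(result: SimResult, out_prefix) -> None:
    """Write .ped/.map, a pedigree TSV and the truth YAML for a simulation."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    g = result.genotypes
    # allele symbols: 'A' is the capital allele, 'C' the alternative
    with open(out_prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(g.animal_ids):
            fields = ["FAM", animal, "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                d = int(g.calls[i, j])
                if d < 0:
                    fields += ["0", "0"]
                else:
                    fields += ["A"] * d + ["C"] * (2 - d)
            fh.write(" ".join(fields) + "\n")
    with open(out_prefix.with_suffix(".map"), "w") as fh:
        for snp in g.snp_ids:
            fh.write(f"{g.chrom(snp)} {snp} 0 {g.pos(snp)}\n")
    result.trios.table.to_csv(
        out_prefix.parent / (out_prefix.name + ".trios.tsv"), sep="\t", index=False
    )
    with open(out_prefix.parent / (out_prefix.name + ".truth.yaml"), "w") as fh:
        yaml.safe_dump(result.truth, fh, sort_keys=False)
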