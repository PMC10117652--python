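"""Trio genotype containers, Mendelian mating machinery, and file readers.

The unit of observation throughout the package is the *trio*: a genotyped
sire-dam-offspring triple. For a pair of biallelic SNPs (locus A, locus B)
each animal carries one of nine ordered two-locus genotypes
(AABB, AaBB, aaBB, AABb, AaBb, aaBb, AAbb, Aabb, aabb); an ordered
(sire genotype, dam genotype) pair is a *mating configuration* whose
Mendelian offspring distribution follows from independent assortment of
the two loci (pairs are inter-chromosomal by design). A mating is
*informative* when more than one offspring class is possible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TwoLocusGenotype",
    "GenotypeMatrix",
    "TrioTable",
    "MatingConfiguration",
    "PairTrioData",
    "GENOTYPE_LABELS",
    "N_CLASSES",
    "N_MATINGS",
    "mendelian_offspring_distribution",
    "enumerate_matings",
    "extract_pair",
    "read_genotypes",
    "read_trios",
]

N_CLASSES = 9
N_MATINGS = 81

GENOTYPE_LABELS = (
    "AABB", "AaBB", "aaBB",
    "AABb", "AaBb", "aaBb",
    "AAbb", "Aabb", "aabb",
)


class TwoLocusGenotype(enum.IntEnum):
    """The nine ordered two-locus genotype classes.

    Genotypes are written with the "capital" allele of each SNP first;
    the capital allele is whichever allele the 0/1/2 input coding counts.
    Locus A is always the first SNP of the pair as given by the caller.
    """

    AABB = 0
    AaBB = 1
    aaBB = 2
    AABb = 3
    AaBb = 4
    aaBb = 5
    AAbb = 6
    Aabb = 7
    aabb = 8

    @property
    def dosage_a(self) -> int:
        """Count of capital alleles at locus A (0, 1 or 2)."""
        return 2 - (int(self) % 3)

    @property
    def dosage_b(self) -> int:
        """Count of capital alleles at locus B (0, 1 or 2)."""
        return 2 - (int(self) // 3)

    @classmethod
    def from_dosages(cls, dosage_a: int, dosage_b: int) -> "TwoLocusGenotype":
        if dosage_a not in (0, 1, 2) or dosage_b not in (0, 1, 2):
            raise ValueError(f"dosages must be in 0..2, got ({dosage_a}, {dosage_b})")
        return cls(3 * (2 - dosage_b) + (2 - dosage_a))

    @property
    def het_a(self) -> bool:
        return self.dosage_a == 1

    @property
    def het_b(self) -> bool:
        return self.dosage_b == 1


def _single_locus_transmission(dosage: int) -> np.ndarray:
    """P(offspring receives the capital allele twice / once / never is not
    what this returns -- it returns the distribution of the transmitted
    allele count {0,1} from one parent as [P(lowercase), P(capital)]."""
    if dosage == 2:
        return np.array([0.0, 1.0])
    if dosage == 1:
        return np.array([0.5, 0.5])
    return np.array([1.0, 0.0])


def _single_locus_offspring(d_sire: int, d_dam: int) -> np.ndarray:
    """Distribution of offspring dosage (index 0,1,2) at one locus."""
    ps = _single_locus_transmission(d_sire)
    pdm = _single_locus_transmission(d_dam)
    out = np.zeros(3)
    for i in (0, 1):
        for j in (0, 1):
            out[i + j] += ps[i] * pdm[j]
    return out


def mendelian_offspring_distribution(
    sire: TwoLocusGenotype, dam: TwoLocusGenotype
) -> np.ndarray:
    """Mendelian offspring distribution over the 9 two-locus classes.

    The two loci are on different chromosomes, so the distribution is the
    outer product of the per-locus Mendelian transmission distributions.
    Entries are multiples of 1/16 and sum to 1.
    """
    pa = _single_locus_offspring(sire.dosage_a, dam.dosage_a)
    pb = _single_locus_offspring(sire.dosage_b, dam.dosage_b)
    out = np.zeros(N_CLASSES)
    for da in (0, 1, 2):
        for db in (0, 1, 2):
            out[TwoLocusGenotype.from_dosages(da, db)] = pa[da] * pb[db]
    return out


@dataclass(frozen=True)
class MatingConfiguration:
    """One ordered (sire, dam) two-locus genotype pair.

    ``mendelian`` is the offspring-class distribution under Mendelian
    segregation; ``informative`` is true when more than one offspring
    class has positive probability.
    """

    sire_genotype: TwoLocusGenotype
    dam_genotype: TwoLocusGenotype
    mendelian: np.ndarray
    informative: bool

    @property
    def index(self) -> int:
        """Flat index in 0..80 (9 * sire + dam)."""
        return 9 * int(self.sire_genotype) + int(self.dam_genotype)


def enumerate_matings() -> list[MatingConfiguration]:
    """All 81 ordered two-locus matings with Mendelian vectors and flags.

    Of these, 65 are informative; the 16 uninformative ones have both
    parents homozygous at both loci.
    """
    out = []
    for s in TwoLocusGenotype:
        for d in TwoLocusGenotype:
            m = mendelian_offspring_distribution(s, d)
            out.append(
                MatingConfiguration(
                    sire_genotype=s,
                    dam_genotype=d,
                    mendelian=m,
                    informative=int(np.count_nonzero(m)) > 1,
                )
            )
    return out


_MATINGS: list[MatingConfiguration] | None = None


def all_matings() -> list[MatingConfiguration]:
    """Cached ``enumerate_matings()``."""
    global _MATINGS
    if _MATINGS is None:
        _MATINGS = enumerate_matings()
    return _MATINGS


def mendelian_table() -> np.ndarray:
    """(81, 9) matrix of Mendelian offspring distributions, row = mating index."""
    return np.vstack([m.mendelian for m in all_matings()])


# ---------------------------------------------------------------------------
# Containers


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a set of animals.

    ``calls`` holds the count of the designated capital allele per animal
    per SNP (0/1/2), with -1 for missing. ``snp_map`` gives chromosome and
    1-based position per SNP.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # (n_animals, n_snps) int8, -1 = missing
    snp_map: pd.DataFrame  # index snp_id, columns: chrom (str), pos (int)

    def __post_init__(self) -> None:
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match ids")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        missing_map = set(self.snp_ids) - set(self.snp_map.index)
        if missing_map:
            raise ValueError(f"map does not cover SNPs: {sorted(missing_map)[:5]}")
        self._animal_index = {a: i for i, a in enumerate(self.animal_ids)}
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def animal_index(self, animal_id: str) -> int:
        return self._animal_index[animal_id]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not found") from None

    def chrom(self, snp_id: str) -> str:
        return str(self.snp_map.loc[snp_id, "chrom"])

    def pos(self, snp_id: str) -> int:
        return int(self.snp_map.loc[snp_id, "pos"])


@dataclass
class TrioTable:
    """Pedigree rows linking each offspring to its sire and dam."""

    table: pd.DataFrame  # columns: offspring, sire, dam

    def __post_init__(self) -> None:
        required = ["offspring", "sire", "dam"]
        if list(self.table.columns[:3]) != required:
            self.table = self.table.iloc[:, :3].set_axis(required, axis=1)
        self.table = self.table.astype(str)
        dup = self.table["offspring"].duplicated()
        if dup.any():
            raise ValueError(
                f"offspring listed more than once: {self.table.loc[dup, 'offspring'].tolist()[:5]}"
            )
        selfp = (self.table["offspring"] == self.table["sire"]) | (
            self.table["offspring"] == self.table["dam"]
        )
        if selfp.any():
            raise ValueError(
                f"self-parenting rows: {self.table.loc[selfp, 'offspring'].tolist()[:5]}"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PairTrioData:
    """Observed per-trio two-locus genotype counts for one SNP pair.

    ``counts[m, g]`` is the number of trios whose parents form mating
    configuration ``m`` (flat index 9*sire+dam) and whose offspring is in
    class ``g``. Trios with a missing call in any member, or whose
    offspring class is Mendelian-impossible under the parental mating,
    are excluded (and tallied in ``n_excluded``), never stored.
    """

    snp_a: str
    snp_b: str
    counts: np.ndarray  # (81, 9) int64
    n_het_sires: int = 0
    n_het_dams: int = 0
    n_excluded: int = 0
    exclusion_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_MATINGS, N_CLASSES):
            raise ValueError("counts must be (81, 9)")
        mend = mendelian_table()
        if np.any((self.counts > 0) & (mend == 0)):
            raise ValueError("counts present on Mendelian-impossible offspring classes")

    @property
    def n_trios(self) -> int:
        return int(self.counts.sum())

    @property
    def n_informative_offspring(self) -> int:
        informative = np.array([m.informative for m in all_matings()])
        return int(self.counts[informative].sum())

    def mating_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


# ---------------------------------------------------------------------------
# Readers

_DEFAULT_MISSING = ("NA", "-9", "")


def read_trios(path: str | Path) -> TrioTable:
    """Read a 3-column pedigree table (offspring, sire, dam; TSV/CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (offspring, sire, dam)")
    return TrioTable(df.iloc[:, :3].set_axis(["offspring", "sire", "dam"], axis=1))


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] == 4:  # PLINK: chrom, snp, cM, pos
        out = pd.DataFrame(
            {"chrom": df[0].to_numpy(), "pos": df[3].astype(int).to_numpy()},
            index=df[1].tolist(),
        )
    elif df.shape[1] == 3:  # snp, chrom, pos
        out = pd.DataFrame(
            {"chrom": df[1].to_numpy(), "pos": df[2].astype(int).to_numpy()},
            index=df[0].tolist(),
        )
    else:
        raise ValueError(f"{path}: cannot interpret map with {df.shape[1]} columns")
    return out


def _parse_ped(path: Path, map_df: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Parse a PLINK .ped file into capital-allele counts.

    Within each SNP the *capital* allele is the alphabetically smaller of
    the two observed allele symbols (a deterministic, label-symmetric
    choice; downstream statistics are invariant to it). '0' is missing.
    """
    n_snps = len(map_df)
    animal_ids: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            animal_ids.append(fields[1])
            pairs = [
                (fields[6 + 2 * i], fields[7 + 2 * i]) for i in range(n_snps)
            ]
            rows.append(pairs)
    # designate per-SNP capital allele
    capital: list[str | None] = []
    for j in range(n_snps):
        seen = sorted(
            {a for pairs in rows for a in pairs[j] if a != "0"}
        )
        if len(seen) > 2:
            raise ValueError(
                f"{path}: SNP {map_df.index[j]!r} has more than two alleles: {seen}"
            )
        capital.append(seen[0] if seen else None)
    calls = np.full((len(rows), n_snps), -1, dtype=np.int8)
    for i, pairs in enumerate(rows):
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == capital[j]) + (a2 == capital[j])
    return animal_ids, calls


def _coerce_call(value: str, missing: tuple[str, ...], where: str) -> int:
    v = str(value).strip()
    if v in missing or v.lower() == "nan":
        return -1
    try:
        iv = int(float(v))
    except ValueError:
        raise ValueError(f"{where}: unknown genotype code {value!r}") from None
    if iv not in (0, 1, 2):
        raise ValueError(f"{where}: genotype code {value!r} not in 0/1/2")
    return iv


def read_genotypes(
    path: str | Path,
    format: str = "tsv-wide",
    map_path: str | Path | None = None,
    missing_codes: tuple[str, ...] = _DEFAULT_MISSING,
) -> GenotypeMatrix:
    """Read a genotype table into a :class:`GenotypeMatrix`.

    Formats:

    ``ped``
        PLINK .ped with a companion .map (``map_path`` or same stem).
    ``tsv-wide``
        One row per animal: first column animal id, remaining columns one
        SNP each with calls 0/1/2 or a missing code. The map comes from
        ``map_path`` (snp, chrom, pos).
    ``tsv-long``
        Columns (animal, snp, call); map from ``map_path``.
    """
    path = Path(path)
    if format == "ped":
        mpath = Path(map_path) if map_path else path.with_suffix(".map")
        map_df = _read_map(mpath)
        animal_ids, calls = _parse_ped(path, map_df)
        return GenotypeMatrix(animal_ids, list(map_df.index), calls, map_df)

    if map_path is None:
        raise ValueError(f"format {format!r} requires map_path")
    map_df = _read_map(Path(map_path))

    if format == "tsv-wide":
        df = pd.read_csv(path, sep="\t", dtype=str)
        animal_ids = df.iloc[:, 0].astype(str).tolist()
        snp_ids = list(df.columns[1:])
        calls = np.full((len(animal_ids), len(snp_ids)), -1, dtype=np.int8)
        for j, snp in enumerate(snp_ids):
            col = df[snp].tolist()
            for i, v in enumerate(col):
                calls[i, j] = _coerce_call(v, missing_codes, f"{path}: row {i + 2}, SNP {snp}")
        return GenotypeMatrix(animal_ids, snp_ids, calls, map_df)

    if format == "tsv-long":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise ValueError(f"{path}: tsv-long needs (animal, snp, call) columns")
        animal_ids = list(dict.fromkeys(df.iloc[:, 0].astype(str)))
        snp_ids = list(dict.fromkeys(df.iloc[:, 1].astype(str)))
        ai = {a: i for i, a in enumerate(animal_ids)}
        si = {s: i for i, s in enumerate(snp_ids)}
        calls = np.full((len(animal_ids), len(snp_ids)), -1, dtype=np.int8)
        for k, (a, s, v) in enumerate(df.iloc[:, :3].itertuples(index=False)):
            calls[ai[str(a)], si[str(s)]] = _coerce_call(
                v, missing_codes, f"{path}: row {k + 2}"
            )
        return GenotypeMatrix(animal_ids, snp_ids, calls, map_df)

    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Pair assembly


def extract_pair(
    genotypes: GenotypeMatrix,
    trios: TrioTable,
    snp_a: str,
    snp_b: str,
    het_mode: str = "either",
    allow_linked: bool = False,
) -> PairTrioData:
    """Assemble :class:`PairTrioData` for one SNP pair.

    Trios missing a call at either SNP in any member are excluded, as are
    trios whose offspring class has zero Mendelian probability under the
    parental mating (logged as inconsistent). ``het_mode`` controls the
    heterozygous-parent tallies: ``"either"`` (default) counts a distinct
    parent as heterozygous when heterozygous at at least one of the two
    loci; ``"both"`` requires heterozygosity at both.
    """
    if het_mode not in ("either", "both"):
        raise ValueError("het_mode must be 'either' or 'both'")
    ja, jb = genotypes.snp_index(snp_a), genotypes.snp_index(snp_b)
    if not allow_linked and genotypes.chrom(snp_a) == genotypes.chrom(snp_b):
        raise ValueError(
            f"SNPs {snp_a!r} and {snp_b!r} are on the same chromosome "
            f"({genotypes.chrom(snp_a)}); pass allow_linked=True to override"
        )

    tab = trios.table
    known = (
        tab["offspring"].isin(genotypes._animal_index)
        & tab["sire"].isin(genotypes._animal_index)
        & tab["dam"].isin(genotypes._animal_index)
    )
    tab = tab[known]
    o_idx = tab["offspring"].map(genotypes._animal_index).to_numpy()
    s_idx = tab["sire"].map(genotypes._animal_index).to_numpy()
    d_idx = tab["dam"].map(genotypes._animal_index).to_numpy()

    ga = genotypes.calls[:, ja].astype(np.int64)
    gb = genotypes.calls[:, jb].astype(np.int64)

    def cls(idx: np.ndarray) -> np.ndarray:
        da, db = ga[idx], gb[idx]
        out = 3 * (2 - db) + (2 - da)
        out[(da < 0) | (db < 0)] = -1
        return out

    oc, sc, dc = cls(o_idx), cls(s_idx), cls(d_idx)
    complete = (oc >= 0) & (sc >= 0) & (dc >= 0)
    n_missing = int((~complete).sum())

    mend = mendelian_table()
    mating = 9 * sc[complete] + dc[complete]
    off = oc[complete]
    consistent = mend[mating, off] > 0
    n_inconsistent = int((~consistent).sum())

    counts = np.zeros((N_MATINGS, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (mating[consistent], off[consistent]), 1)

    kept = tab[complete].loc[consistent]

    def n_het(parents: pd.Series) -> int:
        ids = parents.unique()
        idx = np.array([genotypes._animal_index[p] for p in ids], dtype=int)
        het_a = ga[idx] == 1
        het_b = gb[idx] == 1
        het = (het_a | het_b) if het_mode == "either" else (het_a & het_b)
        return int(het.sum())

    return PairTrioData(
        snp_a=snp_a,
        snp_b=snp_b,
        counts=counts,
        n_het_sires=n_het(kept["sire"]) if len(kept) else 0,
        n_het_dams=n_het(kept["dam"]) if len(kept) else 0,
        n_excluded=n_missing + n_inconsistent,
        exclusion_reasons={"missing": n_missing, "inconsistent": n_inconsistent},
    )
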