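"""Genome-wide SNP-pair scan: filter cascade, staging, selection, collapsing.

The cascade mirrors the two-stage design of the scan: cheap count-based
pre-filters first (informative-offspring and heterozygous-parent
minima, then a per-cell deviation screen against Mendelian expectation),
a preliminary short chain on the survivors, evidence filters on the
posterior (minimum epistatic Bayes factor, epistatic/direct BF ratio,
coefficient-of-variation cut), categorization by the strongest epistatic
effect, a top-fraction multiple-test selection per category, a longer
accurate chain for the selected pairs, and finally collapsing of pairs
that share one SNP whose partners are physically linked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .inference import ChainConfig, PosteriorResult, fit_allelic, fit_genotypic
from .trio_data import PairTrioData, mendelian_table

__all__ = [
    "ScanConfig",
    "ScanRow",
    "DeviationResult",
    "prefilter",
    "deviation_screen",
    "run_pair",
    "epistatic_filter",
    "categorize",
    "select_top",
    "collapse_linked",
    "scan_pairs",
    "CATEGORIES",
]

DIRECT_PARAMS = ("alpha_A", "alpha_B", "delta_A", "delta_B")
EPISTATIC_PARAMS = ("aa_e", "ad_e", "da_e", "dd_e")

CATEGORIES = (
    "additive_by_additive",
    "additive_by_dominance_or_reverse",
    "dominance_by_dominance",
)
_EFFECT_CATEGORY = {
    "aa_e": "additive_by_additive",
    "ad_e": "additive_by_dominance_or_reverse",
    "da_e": "additive_by_dominance_or_reverse",
    "dd_e": "dominance_by_dominance",
}


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the filter cascade.

    Defaults are the full-data settings: >=1,000 informative offspring
    and >=20 heterozygous sires or >=50 heterozygous dams to analyze a
    pair; a deviation of >=1,000 offspring and >=10% of expectation in
    some (mating, class) cell; Bayes factor >=1,000 for the strongest
    epistatic effect with an epistatic/direct BF ratio >1,000; CV <=20%
    for every significant epistatic effect; top 0.1% per category kept.
    ``desk_scale`` provides a preset for simulated datasets in the
    tens-of-thousands of trios, where the absolute deviation cut scales
    with the cell sizes such a dataset can produce.
    """

    min_informative_offspring: int = 1000
    min_het_sires: int = 20
    min_het_dams: int = 50
    min_abs_deviation: float = 1000.0
    min_rel_deviation: float = 0.10
    bf_threshold: float = 1000.0
    epi_direct_bf_ratio: float = 1000.0
    max_cv: float = 0.20
    top_fraction: float = 0.001
    linked_window_bp: int = 10_000_000

    def __post_init__(self) -> None:
        for name in (
            "min_informative_offspring", "min_het_sires", "min_het_dams",
            "min_abs_deviation", "min_rel_deviation", "bf_threshold",
            "epi_direct_bf_ratio", "max_cv", "top_fraction", "linked_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_scale(cls) -> "ScanConfig":
        """Preset for simulated scans of ~20,000 trios per pair."""
        return cls(min_abs_deviation=50.0)

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload.get("scan", payload))


@dataclass
class ScanRow:
    """One SNP pair's scan record."""

    snp_a: str
    snp_b: str
    genotypic: PosteriorResult | None = None
    allelic: PosteriorResult | None = None
    category: str | None = None
    passed_filters: dict = field(default_factory=dict)
    selected: bool = False

    @property
    def pair_id(self) -> tuple:
        return (self.snp_a, self.snp_b)

    def max_epistatic_bf(self) -> float:
        return max(
            self.genotypic.param(p)["log10_bf"] for p in EPISTATIC_PARAMS
        )

    def max_direct_bf(self) -> float:
        return max(self.genotypic.param(p)["log10_bf"] for p in DIRECT_PARAMS)


@dataclass
class DeviationResult:
    """Largest observed-vs-Mendelian deviation over (mating, class) cells.

    Percentage deviations are reported both relative to the expected and
    to the observed count of the extreme cell (the field convention
    varies, so both are given).
    """

    max_abs_deviation: float
    rel_deviation_vs_expected: float
    rel_deviation_vs_observed: float
    passed: bool


def cell_deviation(observed: float, expected: float) -> dict:
    """Deviation of one (mating, class) cell from Mendelian expectation.

    Returns the signed deviation and its magnitude as a percentage of
    both the observed and the expected count (conventions differ across
    reports, so both are given).
    """
    dev = observed - expected
    return {
        "deviation": dev,
        "pct_of_observed": 100.0 * abs(dev) / observed if observed > 0 else float("inf"),
        "pct_of_expected": 100.0 * abs(dev) / expected if expected > 0 else float("inf"),
    }


def prefilter(data: PairTrioData, cfg: ScanConfig) -> tuple[bool, list[str]]:
    """Informative-offspring and heterozygous-parent minima."""
    reasons = []
    if data.n_informative_offspring < cfg.min_informative_offspring:
        reasons.append(
            f"informative offspring {data.n_informative_offspring} < "
            f"{cfg.min_informative_offspring}"
        )
    if data.n_het_sires < cfg.min_het_sires and data.n_het_dams < cfg.min_het_dams:
        reasons.append(
            f"heterozygous parents below both minima "
            f"({data.n_het_sires} sires, {data.n_het_dams} dams)"
        )
    return (not reasons), reasons


def deviation_screen(
    data: PairTrioData,
    cfg: ScanConfig,
    mating_grouping: dict[int, int] | None = None,
) -> DeviationResult:
    """Per-cell deviation of observed counts from Mendelian expectation.

    Passes when some (mating, offspring-class) cell deviates by at least
    ``min_abs_deviation`` offspring and by at least ``min_rel_deviation``
    of the expected count. ``mating_grouping`` optionally pools the 81
    ordered mating configurations into user-defined groups (mating index
    -> group id) before computing expectations.
    """
    mend = mendelian_table()
    counts = data.counts.astype(float)
    if mating_grouping is not None:
        groups = sorted(set(mating_grouping.values()))
        gc = np.zeros((len(groups), counts.shape[1]))
        gm = np.zeros_like(gc)
        pos = {g: i for i, g in enumerate(groups)}
        for m_idx, g_id in mating_grouping.items():
            gc[pos[g_id]] += counts[m_idx]
            # pooled expectation: weight each mating's Mendelian vector
            # by its observed trio total
            gm[pos[g_id]] += counts[m_idx].sum() * mend[m_idx]
        expected = gm
        counts = gc
    else:
        expected = counts.sum(axis=1, keepdims=True) * mend

    dev = counts - expected
    ok_cells = (np.abs(dev) >= cfg.min_abs_deviation) & (
        np.abs(dev) >= cfg.min_rel_deviation * expected
    )
    flat = np.abs(dev).ravel()
    best = int(flat.argmax())
    i, j = divmod(best, counts.shape[1])
    max_abs = float(flat[best])
    exp_b, obs_b = float(expected[i, j]), float(counts[i, j])
    return DeviationResult(
        max_abs_deviation=max_abs,
        rel_deviation_vs_expected=(max_abs / exp_b) if exp_b > 0 else np.inf,
        rel_deviation_vs_observed=(max_abs / obs_b) if obs_b > 0 else np.inf,
        passed=bool(ok_cells.any()),
    )


def run_pair(
    data: PairTrioData,
    model: str = "genotypic",
    stage: str = "preliminary",
    chain_cfg: ChainConfig | None = None,
    seed: int = 0,
) -> ScanRow:
    """Fit the requested model(s) on one pair and categorize the result.

    ``stage`` selects the chain preset (``preliminary``: 11,000/1,000;
    ``accurate``: 550,000/50,000) unless an explicit ``chain_cfg`` is
    given. With ``model="both"`` the DIC of the two parameterizations
    can be compared on the same pair.
    """
    if model not in ("genotypic", "allelic", "both"):
        raise ValueError("model must be 'genotypic', 'allelic' or 'both'")
    if chain_cfg is None:
        if stage == "preliminary":
            chain_cfg = ChainConfig.preliminary(seed=seed)
        elif stage == "accurate":
            chain_cfg = ChainConfig.accurate(seed=seed)
        else:
            raise ValueError("stage must be 'preliminary' or 'accurate'")
    else:
        chain_cfg = replace(chain_cfg, seed=seed)

    row = ScanRow(snp_a=data.snp_a, snp_b=data.snp_b)
    try:
        if model in ("genotypic", "both"):
            row.genotypic = fit_genotypic(data, chain_cfg)
        if model in ("allelic", "both"):
            row.allelic = fit_allelic(data, chain_cfg)
    except ValueError as exc:
        raise ValueError(f"pair {data.snp_a} x {data.snp_b}: {exc}") from exc
    if row.genotypic is not None:
        row.category = categorize(row.genotypic)
    return row


def categorize(posterior: PosteriorResult) -> str:
    """Effect category of the epistatic parameter with the largest BF."""
    bfs = {p: posterior.param(p)["log10_bf"] for p in EPISTATIC_PARAMS}
    best = max(bfs, key=lambda p: (bfs[p], p))
    return _EFFECT_CATEGORY[best]


def epistatic_filter(row: ScanRow, cfg: ScanConfig) -> tuple[bool, list[str]]:
    """Evidence filters on the genotypic posterior.

    Requires the strongest epistatic Bayes factor to reach
    ``bf_threshold``, the epistatic/direct BF ratio to exceed
    ``epi_direct_bf_ratio`` (computed on the BF scale from the log10
    values; an underflowing direct BF passes by convention), and the CV
    of every significant epistatic parameter to stay within ``max_cv``.
    """
    log10_thr = math.log10(cfg.bf_threshold)
    log10_ratio = math.log10(cfg.epi_direct_bf_ratio)
    reasons = []
    max_epi = row.max_epistatic_bf()
    max_dir = row.max_direct_bf()
    if not max_epi >= log10_thr:
        reasons.append(f"max epistatic log10 BF {max_epi:.2f} < {log10_thr:.2f}")
    if np.isfinite(max_dir):
        if not (max_epi - max_dir) > log10_ratio:
            reasons.append(
                f"epistatic/direct log10 BF ratio {max_epi - max_dir:.2f} "
                f"<= {log10_ratio:.2f}"
            )
    # a direct BF of -inf means direct effects are absent: ratio passes
    for p in EPISTATIC_PARAMS:
        stats = row.genotypic.param(p)
        if stats["log10_bf"] >= log10_thr:
            cv = stats["cv"]
            if np.isfinite(cv) and cv > cfg.max_cv:
                reasons.append(f"{p} CV {cv:.2f} > {cfg.max_cv:.2f}")
    return (not reasons), reasons


def select_top(rows: list[ScanRow], cfg: ScanConfig) -> list[ScanRow]:
    """Top-fraction multiple-test selection within each effect category.

    Keeps ``ceil(top_fraction * n)`` rows per category ranked by the
    maximum epistatic BF; ties break toward the lexicographically
    smaller pair identifier. Marks and returns the selected rows.
    """
    selected: list[ScanRow] = []
    for cat in CATEGORIES:
        in_cat = [r for r in rows if r.category == cat]
        if not in_cat:
            continue
        n_keep = math.ceil(cfg.top_fraction * len(in_cat))
        ranked = sorted(in_cat, key=lambda r: (-r.max_epistatic_bf(), r.pair_id))
        for r in ranked[:n_keep]:
            r.selected = True
            selected.append(r)
    return selected


def collapse_linked(
    rows: list[ScanRow], snp_map: pd.DataFrame, cfg: ScanConfig
) -> list[ScanRow]:
    """Collapse pairs sharing one SNP whose partners are physically linked.

    Rows sharing an anchor SNP form a cluster when their partner SNPs
    lie on one chromosome within ``linked_window_bp`` of each other
    (chained single-linkage along positions); only the highest-BF row of
    each cluster survives.
    """
    dropped: set[int] = set()
    anchors: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        anchors.setdefault(r.snp_a, []).append(i)
        anchors.setdefault(r.snp_b, []).append(i)
    for anchor, idxs in anchors.items():
        if len(idxs) < 2:
            continue
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for i in idxs:
            r = rows[i]
            partner = r.snp_b if r.snp_a == anchor else r.snp_a
            chrom = str(snp_map.loc[partner, "chrom"])
            pos = int(snp_map.loc[partner, "pos"])
            per_chrom.setdefault(chrom, []).append((pos, i))
        for chrom, members in per_chrom.items():
            members.sort()
            cluster: list[int] = []
            prev_pos = None
            for pos, i in members + [(None, None)]:
                if prev_pos is not None and (
                    pos is None or pos - prev_pos > cfg.linked_window_bp
                ):
                    if len(cluster) > 1:
                        best = max(
                            cluster,
                            key=lambda k: (rows[k].max_epistatic_bf(), rows[k].pair_id),
                        )
                        dropped.update(k for k in cluster if k != best)
                    cluster = []
                if pos is None:
                    break
                cluster.append(i)
                prev_pos = pos
    return [r for i, r in enumerate(rows) if i not in dropped]


def scan_pairs(
    pairs: list[PairTrioData],
    snp_map: pd.DataFrame,
    cfg: ScanConfig,
    model: str = "genotypic",
    preliminary_cfg: ChainConfig | None = None,
    accurate_cfg: ChainConfig | None = None,
    seed: int = 0,
    log=None,
) -> tuple[list[ScanRow], dict]:
    """Run the full cascade over assembled pairs.

    Returns the surviving rows (selected, accurately re-estimated and
    collapsed) and a stage-by-stage survivor-count summary.
    """
    summary = {"input": len(pairs)}
    stage1 = [d for d in pairs if prefilter(d, cfg)[0]]
    summary["prefilter"] = len(stage1)
    stage2 = [d for d in stage1 if deviation_screen(d, cfg).passed]
    summary["deviation_screen"] = len(stage2)

    rows = []
    for k, d in enumerate(stage2):
        rows.append(
            run_pair(
                d, model=model, stage="preliminary",
                chain_cfg=preliminary_cfg, seed=seed + k,
            )
        )
    filtered = [r for r in rows if epistatic_filter(r, cfg)[0]]
    summary["epistatic_filter"] = len(filtered)
    selected = select_top(filtered, cfg)
    summary["selected"] = len(selected)

    # accurate re-estimation of the selected pairs overwrites the
    # preliminary statistics
    by_id = {d.snp_a + "\x00" + d.snp_b: d for d in stage2}
    accurate_rows = []
    for k, r in enumerate(selected):
        d = by_id[r.snp_a + "\x00" + r.snp_b]
        nr = run_pair(
            d, model=model, stage="accurate",
            chain_cfg=accurate_cfg, seed=seed + 10_000 + k,
        )
        nr.selected = True
        accurate_rows.append(nr)
    final = collapse_linked(accurate_rows, snp_map, cfg)
    summary["collapsed"] = len(final)
    if log is not None:
        for stage, n in summary.items():
            log(f"{stage}: {n} pairs")
    return final, summary


def rows_to_frame(rows: list[ScanRow]) -> pd.DataFrame:
    """Flatten scan rows into a TSV-ready table."""
    records = []
    for r in rows:
        rec = {"snp_a": r.snp_a, "snp_b": r.snp_b, "category": r.category,
               "selected": r.selected}
        for label, post in (("genotypic", r.genotypic), ("allelic", r.allelic)):
            if post is None:
                continue
            for i, p in enumerate(post.param_names):
                rec[f"{label}.{p}.mean"] = post.mean[i]
                rec[f"{label}.{p}.sd"] = post.sd[i]
                rec[f"{label}.{p}.log10_bf"] = post.log10_bf[i]
            rec[f"{label}.log10_lr"] = post.log10_lr
            rec[f"{label}.dic"] = post.dic
        records.append(rec)
    return pd.DataFrame(records)
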