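"""Filter cascade, categorization, top-fraction selection and collapsing."""

import numpy as np
import pandas as pd
import pytest

from epitrd.genotypic import PARAM_NAMES
from epitrd.inference import PosteriorResult
from epitrd.scan import (
    CATEGORIES,
    ScanConfig,
    ScanRow,
    categorize,
    collapse_linked,
    deviation_screen,
    epistatic_filter,
    prefilter,
    select_top,
)
from epitrd.trio_data import PairTrioData, TwoLocusGenotype, mendelian_table


def make_pair(n_informative=0, n_het_sires=0, n_het_dams=0):
    counts = np.zeros((81, 9), dtype=np.int64)
    m = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
    # spread counts Mendelian-proportionally over the double-het mating
    mend = mendelian_table()[m]
    counts[m] = np.floor(n_informative * mend).astype(np.int64)
    counts[m, 4] += n_informative - counts[m].sum()
    d = PairTrioData("a", "b", counts)
    d.n_het_sires = n_het_sires
    d.n_het_dams = n_het_dams
    return d


def make_posterior(means=None, sds=None, bfs=None):
    means = np.array(means if means is not None else np.zeros(8), dtype=float)
    sds = np.array(sds if sds is not None else np.full(8, 0.01), dtype=float)
    bfs = np.array(bfs if bfs is not None else np.full(8, -1.0), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / np.abs(means), np.nan)
    return PosteriorResult(
        param_names=PARAM_NAMES, mean=means, sd=sds, cv=cv, log10_bf=bfs,
        log10_lr=0.0, dic=0.0, acceptance_rate=0.3, n_kept=10_000,
    )


def make_row(snp_a, snp_b, epi_bfs, direct_bfs=(-1, -1, -1, -1),
             epi_means=(0.5, 0, 0, 0), epi_sds=(0.01, 0.01, 0.01, 0.01)):
    post = make_posterior(
        means=list((0.0,) * 4) + list(epi_means),
        sds=list((0.01,) * 4) + list(epi_sds),
        bfs=list(direct_bfs) + list(epi_bfs),
    )
    row = ScanRow(snp_a=snp_a, snp_b=snp_b, genotypic=post)
    row.category = categorize(post)
    return row


class TestPrefilter:
    def test_thresholds_as_printed(self):
        cfg = ScanConfig()
        ok, _ = prefilter(make_pair(1_000, 20, 0), cfg)
        assert ok
        ok, reasons = prefilter(make_pair(999, 100, 100), cfg)
        assert not ok and "informative" in reasons[0]
        ok, reasons = prefilter(make_pair(5_000, 19, 49), cfg)
        assert not ok and "parents" in reasons[0]


class TestDeviationScreen:
    def test_printed_deviation_arithmetic(self):
        # one cell observed 20,117 vs expected 12,063: |dev| = 8,054,
        # 40.04% of observed
        cfg = ScanConfig()
        counts = np.zeros((81, 9), dtype=np.int64)
        m = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
        mend = mendelian_table()[m]
        total = int(round(12_063 / mend[0]))
        counts[m] = np.round(total * mend).astype(np.int64)
        counts[m, 0] = 20_117  # AABB over-represented
        d = PairTrioData("a", "b", counts)
        res = deviation_screen(d, cfg)
        total_after = counts[m].sum()
        expected_aabb = total_after * mend[0]
        assert res.max_abs_deviation == pytest.approx(20_117 - expected_aabb)
        assert res.passed

    def test_no_deviation_fails(self):
        res = deviation_screen(make_pair(16_000), ScanConfig())
        assert res.max_abs_deviation < 1.0
        assert not res.passed

    def test_absolute_threshold_binds(self):
        cfg = ScanConfig()
        counts = np.zeros((81, 9), dtype=np.int64)
        m = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
        mend = mendelian_table()[m]
        counts[m] = np.round(16_000 * mend).astype(np.int64)
        # push AABB up by 900 (relative deviation >10% but absolute < 1000)
        counts[m, 0] += 900
        d = PairTrioData("a", "b", counts)
        res = deviation_screen(d, cfg)
        assert not res.passed

    def test_reports_both_percent_conventions(self):
        cfg = ScanConfig()
        counts = np.zeros((81, 9), dtype=np.int64)
        m = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
        counts[m] = np.round(16_000 * mendelian_table()[m]).astype(np.int64)
        counts[m, 0] += 2_000
        res = deviation_screen(PairTrioData("a", "b", counts), cfg)
        assert res.rel_deviation_vs_expected > res.rel_deviation_vs_observed


class TestEpistaticFilter:
    def test_ratio_pass_and_fail(self):
        cfg = ScanConfig()
        ok, _ = epistatic_filter(make_row("a", "b", epi_bfs=(6, 0, 0, 0), direct_bfs=(2, 0, 0, 0)), cfg)
        assert ok
        ok, reasons = epistatic_filter(make_row("a", "b", epi_bfs=(4, 0, 0, 0), direct_bfs=(2, 0, 0, 0)), cfg)
        assert not ok and "ratio" in reasons[0]

    def test_cv_cut(self):
        cfg = ScanConfig()
        row = make_row("a", "b", epi_bfs=(6, 0, 0, 0), epi_means=(0.5, 0, 0, 0),
                       epi_sds=(0.15, 0.01, 0.01, 0.01))
        ok, reasons = epistatic_filter(row, cfg)
        assert not ok and "CV" in reasons[0]

    def test_underflowing_direct_bf_passes_ratio(self):
        cfg = ScanConfig()
        row = make_row("a", "b", epi_bfs=(6, 0, 0, 0),
                       direct_bfs=(-np.inf, -np.inf, -np.inf, -np.inf))
        ok, _ = epistatic_filter(row, cfg)
        assert ok

    def test_monotone_in_thresholds(self):
        rows = [
            make_row("a", "b", epi_bfs=(6, 0, 0, 0), direct_bfs=(1, 0, 0, 0)),
            make_row("c", "d", epi_bfs=(4, 0, 0, 0), direct_bfs=(0, 0, 0, 0)),
            make_row("e", "f", epi_bfs=(8, 0, 0, 0), direct_bfs=(2, 0, 0, 0)),
        ]
        loose = ScanConfig(bf_threshold=100.0, epi_direct_bf_ratio=100.0)
        tight = ScanConfig(bf_threshold=10_000.0, epi_direct_bf_ratio=10_000.0)
        pass_loose = {r.pair_id for r in rows if epistatic_filter(r, loose)[0]}
        pass_tight = {r.pair_id for r in rows if epistatic_filter(r, tight)[0]}
        assert pass_tight <= pass_loose


class TestCategorize:
    @pytest.mark.parametrize(
        "bfs,expected",
        [
            ((9, 1, 1, 1), "additive_by_additive"),
            ((1, 9, 1, 1), "additive_by_dominance_or_reverse"),
            ((1, 1, 9, 1), "additive_by_dominance_or_reverse"),
            ((1, 1, 1, 9), "dominance_by_dominance"),
        ],
    )
    def test_strongest_effect_wins(self, bfs, expected):
        assert categorize(make_posterior(bfs=[0, 0, 0, 0] + list(bfs))) == expected


class TestSelectTop:
    def test_ceiling_rule(self):
        rows = [
            make_row(f"s{i:03d}", f"t{i:03d}", epi_bfs=(float(i + 1), 0, 0, 0))
            for i in range(500)
        ]
        kept = select_top(rows, ScanConfig())
        assert len(kept) == 1  # ceil(0.001 * 500)
        assert kept[0].snp_a == "s499"

    def test_ceiling_rule_at_genome_scan_scale(self):
        # 59,831 rows in a category at the default 0.1% -> 60 kept
        import math

        assert math.ceil(ScanConfig().top_fraction * 59_831) == 60

    def test_tie_breaks_to_lexicographically_smaller_pair(self):
        rows = [
            make_row("b", "z", epi_bfs=(5, 0, 0, 0)),
            make_row("a", "z", epi_bfs=(5, 0, 0, 0)),
        ]
        kept = select_top(rows, ScanConfig())
        assert len(kept) == 1 and kept[0].snp_a == "a"

    def test_per_category_selection(self):
        rows = [make_row("a", "b", epi_bfs=(9, 0, 0, 0)),
                make_row("c", "d", epi_bfs=(0, 0, 0, 9))]
        kept = select_top(rows, ScanConfig())
        assert {r.category for r in kept} == {
            "additive_by_additive", "dominance_by_dominance"
        }


class TestCollapseLinked:
    def _map(self, entries):
        return pd.DataFrame(
            {k: {"chrom": c, "pos": p} for k, (c, p) in entries.items()}
        ).T

    def test_linked_partners_collapse_to_best(self):
        # one anchor SNP paired with partners spanning ~8 Mb on one
        # chromosome: a single survivor
        snp_map = {"anchor": ("17", 39_696_262)}
        rows = []
        for i, pos in enumerate(range(4_197_354, 12_447_485, 330_000)):
            snp = f"p{i:02d}"
            snp_map[snp] = ("23", pos)
            rows.append(make_row("anchor", snp, epi_bfs=(float(i), 0, 0, 0)))
        out = collapse_linked(rows, self._map(snp_map), ScanConfig())
        assert len(out) == 1
        assert out[0].snp_b == rows[-1].snp_b

    def test_partners_on_different_chromosomes_not_collapsed(self):
        snp_map = {"anchor": ("1", 100), "x": ("2", 100), "y": ("3", 100)}
        rows = [make_row("anchor", "x", epi_bfs=(5, 0, 0, 0)),
                make_row("anchor", "y", epi_bfs=(6, 0, 0, 0))]
        out = collapse_linked(rows, self._map(snp_map), ScanConfig())
        assert len(out) == 2

    def test_single_row_unchanged(self):
        snp_map = {"a": ("1", 100), "b": ("2", 100)}
        rows = [make_row("a", "b", epi_bfs=(5, 0, 0, 0))]
        assert collapse_linked(rows, self._map(snp_map), ScanConfig()) == rows

    def test_distant_partners_form_separate_clusters(self):
        cfg = ScanConfig(linked_window_bp=1_000_000)
        snp_map = {"anchor": ("1", 100), "x": ("2", 1_000_000),
                   "y": ("2", 1_500_000), "z": ("2", 50_000_000)}
        rows = [make_row("anchor", "x", epi_bfs=(5, 0, 0, 0)),
                make_row("anchor", "y", epi_bfs=(6, 0, 0, 0)),
                make_row("anchor", "z", epi_bfs=(4, 0, 0, 0))]
        out = collapse_linked(rows, self._map(snp_map), cfg)
        assert {r.snp_b for r in out} == {"y", "z"}
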