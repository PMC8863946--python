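"""Methylome-stage checks: QC, tiling, DMR statistics and enrichment.

Fisher p-values are verified against an exact hypergeometric enumeration of
all 2x2 tables with the observed margins, and the chi-square statistic
against scipy's contingency implementation — both independent of the
package's closed-form code path.
"""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from cilseq import methylome
from cilseq.synthetic import SimConfig, simulate_methylomes, state_track


def meth_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "meth_count", "unmeth_count"])


class TestConversionRate:
    def test_definitional_example(self):
        calls = meth_table(
            [("chr1", i, "+", "CHH", 1 if i < 20 else 0, 0 if i < 20 else 1)
             for i in range(1000)])
        r, conv = methylome.conversion_rate(calls)
        assert r == pytest.approx(0.02)
        assert conv == pytest.approx(0.98)

    def test_fully_converted(self):
        calls = meth_table([("chr1", 1, "+", "CHH", 0, 10)])
        assert methylome.conversion_rate(calls)[1] == 1.0

    def test_no_noncpg_sites_is_an_error(self):
        calls = meth_table([("chr1", 1, "+", "CpG", 5, 5)])
        with pytest.raises(ValueError, match="non-CpG"):
            methylome.conversion_rate(calls)

    def test_simulated_98pct_recovered_within_0p3(self):
        cfg = SimConfig(seed=9, n_cpg=500, n_noncpg=50_000,
                        conversion_rate=0.98)
        meth = simulate_methylomes(cfg)
        _, conv = methylome.conversion_rate(meth["PL_M1"])
        assert abs(conv - 0.98) < 0.003


class TestBaseFilter:
    @pytest.mark.parametrize("cov,kept", [
        (2, False), (3, True), (500, True), (501, False)])
    def test_boundaries(self, cov, kept):
        calls = meth_table([("chr1", 1, "+", "CpG", cov, 0)])
        assert (len(methylome.filter_bases(calls)) == 1) is kept


class TestTiling:
    def test_three_cpgs_in_one_300bp_tile(self):
        calls = meth_table([
            ("chr1", 10, "+", "CpG", 5, 5),
            ("chr1", 150, "+", "CpG", 5, 5),
            ("chr1", 299, "+", "CpG", 5, 5),
        ])
        tiles = methylome.tile_windows({"s": calls}, "frozen")
        assert len(tiles) == 1
        t = tiles.iloc[0]
        assert (t["start"], t["end"], t["n_cpgs"]) == (0, 300, 3)
        assert t["level"] == pytest.approx(0.5)

    def test_tile_with_two_cpgs_dropped_for_that_sample(self):
        calls = meth_table([
            ("chr1", 10, "+", "CpG", 5, 5),
            ("chr1", 150, "+", "CpG", 5, 5),
        ])
        assert methylome.tile_windows({"s": calls}, "frozen").empty

    def test_ffpe_megabase_tiles(self):
        calls = meth_table([
            ("chr1", 10, "+", "CpG", 5, 5),
            ("chr1", 5_000, "+", "CpG", 5, 5),
            ("chr1", 999_999, "+", "CpG", 5, 5),
        ])
        tiles = methylome.tile_windows({"s": calls}, "ffpe")
        assert len(tiles) == 1
        assert tiles.iloc[0]["end"] == 1_000_000

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            methylome.tile_windows({}, "fresh")

    def test_dyad_strands_merge_to_one_site(self):
        calls = meth_table([
            ("chr1", 10, "+", "CpG", 3, 2),
            ("chr1", 11, "-", "CpG", 2, 3),
            ("chr1", 100, "+", "CpG", 5, 5),
            ("chr1", 200, "+", "CpG", 5, 5),
        ])
        tiles = methylome.tile_windows({"s": calls}, "frozen")
        assert tiles.iloc[0]["n_cpgs"] == 3           # dyad counts once
        assert tiles.iloc[0]["meth_count"] == 15      # 3+2+5+5


class TestGlobalLevel:
    def test_weighted_mean(self):
        calls = meth_table([
            ("chr1", 10, "+", "CpG", 5, 5),
            ("chr1", 20, "+", "CpG", 0, 10),
        ])
        assert methylome.global_level(calls) == pytest.approx(0.25)

    def test_fully_methylated(self):
        calls = meth_table([("chr1", 10, "+", "CpG", 10, 0)])
        assert methylome.global_level(calls) == 1.0

    def test_no_sites_is_an_error(self):
        with pytest.raises(ValueError):
            methylome.global_level(meth_table([]))

    def test_demethylated_tumor_below_normal(self):
        cfg = SimConfig(seed=9, n_cpg=4000, n_noncpg=500)
        meth = simulate_methylomes(cfg)
        assert methylome.global_level(meth["HCC_M1"]) < \
            methylome.global_level(meth["PL_M1"])


class TestCorrelationClustering:
    def _tiles(self, levels: dict[str, list[float]]):
        rows = []
        for s, vals in levels.items():
            for k, v in enumerate(vals):
                rows.append({"chrom": "chr1", "start": k * 300,
                             "end": (k + 1) * 300, "sample_id": s,
                             "n_cpgs": 3, "meth_count": int(v * 100),
                             "coverage": 100, "level": v})
        return pd.DataFrame(rows)

    def test_identical_vectors_correlate_perfectly(self):
        tiles = self._tiles({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9],
                             "c": [0.9, 0.5, 0.1]})
        corr, tree = methylome.correlate_and_cluster(tiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert tree.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors(self):
        tiles = self._tiles({"a": [0.1, 0.9], "b": [0.9, 0.1]})
        corr, _ = methylome.correlate_and_cluster(tiles)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_too_few_common_tiles_rejected(self):
        tiles = self._tiles({"a": [0.5], "b": [0.5]})
        with pytest.raises(ValueError, match="tiles"):
            methylome.correlate_and_cluster(tiles)


# ---------------------------------------------------------------------------
# chi-square and DMR calling
# ---------------------------------------------------------------------------

def test_chi2_matches_scipy_on_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c, d = rng.integers(1, 200, size=4)
        stat, p = methylome.chi2_2x2(int(a), int(b), int(c), int(d))
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-300)


def test_chi2_worked_value():
    stat, p = methylome.chi2_2x2(80, 20, 40, 60)
    assert stat == pytest.approx(33.33, abs=0.01)
    assert p == pytest.approx(7.7e-9, rel=0.05)


def _tiles_from_counts(counts: dict[str, list[tuple[int, int]]]):
    """counts: sample -> [(meth, cov), ...] per tile."""
    rows = []
    for s, pairs in counts.items():
        for k, (m, cov) in enumerate(pairs):
            rows.append({"chrom": "chr1", "start": k * 300,
                         "end": (k + 1) * 300, "sample_id": s, "n_cpgs": 3,
                         "meth_count": m, "coverage": cov, "level": m / cov})
    return pd.DataFrame(rows)


class TestCallDmrs:
    def test_hand_computed_2x2(self):
        # pooled A 80/100 methylated vs B 40/100: diff 0.4, chi2 33.33
        tiles = _tiles_from_counts({
            "a1": [(40, 50)], "a2": [(40, 50)],
            "b1": [(20, 50)], "b2": [(20, 50)],
        })
        out = methylome.call_dmrs(tiles, ["a1", "a2"], ["b1", "b2"])
        row = out.iloc[0]
        assert row["diff"] == pytest.approx(0.4)
        assert row["chi2"] == pytest.approx(33.33, abs=0.01)
        assert row["is_dmr"]
        assert row["direction"] == "hypo"   # B lower than A

    def test_identical_groups_not_dmr(self):
        tiles = _tiles_from_counts({
            "a1": [(30, 60)], "a2": [(30, 60)],
            "b1": [(30, 60)], "b2": [(30, 60)],
        })
        out = methylome.call_dmrs(tiles, ["a1", "a2"], ["b1", "b2"])
        assert out.iloc[0]["chi2"] == 0.0
        assert not out.iloc[0]["is_dmr"]

    def test_diff_exactly_quarter_not_dmr(self):
        # huge counts -> q tiny, but |diff| == 0.25 exactly fails the strict rule
        tiles = _tiles_from_counts({
            "a1": [(5000, 10000)], "a2": [(5000, 10000)],
            "b1": [(2500, 10000)], "b2": [(2500, 10000)],
        })
        out = methylome.call_dmrs(tiles, ["a1", "a2"], ["b1", "b2"])
        assert out.iloc[0]["q"] < 0.05
        assert out.iloc[0]["diff"] == pytest.approx(0.25)
        assert not out.iloc[0]["is_dmr"]

    def test_tiles_missing_a_sample_not_tested(self):
        tiles = _tiles_from_counts({
            "a1": [(40, 50), (40, 50)], "a2": [(40, 50)],
            "b1": [(20, 50), (20, 50)], "b2": [(20, 50), (20, 50)],
        })
        out = methylome.call_dmrs(tiles, ["a1", "a2"], ["b1", "b2"])
        assert len(out) == 1    # second tile covered by only one A sample
        assert out.iloc[0]["start"] == 0


# ---------------------------------------------------------------------------
# annotation and enrichment
# ---------------------------------------------------------------------------

def _annotation(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


class TestAnnotateStates:
    def test_containment_majority_and_none(self):
        ann = _annotation([
            ("chr1", 0, 600, "9_Het"),
            ("chr1", 600, 800, "15_Quies"),
            ("chr1", 800, 900, "1_TssA"),
        ])
        tiles = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 300},      # inside 9_Het
            {"chrom": "chr1", "start": 600, "end": 900},    # 200bp Quies,100 TssA
            {"chrom": "chr1", "start": 5000, "end": 5300},  # outside
        ])
        labels = methylome.annotate_states(tiles, ann)
        assert list(labels) == ["9_Het", "15_Quies", "none"]

    def test_tie_goes_to_lowest_state_number(self):
        ann = _annotation([
            ("chr1", 0, 150, "7_Enh"),
            ("chr1", 150, 300, "2_TssAFlnk"),
        ])
        tiles = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300}])
        assert methylome.annotate_states(tiles, ann)[0] == "2_TssAFlnk"

    def test_unknown_state_label_rejected(self):
        ann = _annotation([("chr1", 0, 100, "99_Nope")])
        tiles = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300}])
        with pytest.raises(ValueError, match="15-state"):
            methylome.annotate_states(tiles, ann)

    def test_every_tile_gets_exactly_one_label(self):
        cfg = SimConfig(seed=9, n_cpg=1000)
        track = state_track(cfg)
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 25_000, size=50) // 300 * 300
        tiles = pd.DataFrame({"chrom": "chrM1", "start": starts,
                              "end": starts + 300})
        labels = methylome.annotate_states(tiles, track)
        assert len(labels) == 50
        assert labels.ne("none").all()   # track covers the whole toy genome


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact two-sided Fisher p: sum of point probabilities <= observed."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (comb(r1, x) * comb(n - r1, c1 - x)) / comb(n, c1)

    obs = point(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1)
               if point(x) <= obs * (1 + 1e-9))


@settings(max_examples=80, deadline=None)
@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
       st.integers(0, 20))
def test_fisher_matches_exact_enumeration(a, b, c, d):
    from scipy.stats import fisher_exact
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d),
                              rel=1e-7, abs=1e-12)


class TestEnrichment:
    def _dmr_table(self, n_state, n_other, dmr_in_state, dmr_out):
        rows = []
        for k in range(n_state + n_other):
            in_state = k < n_state
            is_dmr = (k < dmr_in_state) if in_state else \
                (k - n_state < dmr_out)
            rows.append({"chrom": "chr1",
                         "start": k * 300 if in_state else 100_000 + k * 300,
                         "end": (k * 300 if in_state else 100_000 + k * 300)
                                + 300,
                         "is_dmr": is_dmr,
                         "direction": "hyper" if is_dmr else "none"})
        return pd.DataFrame(rows)

    def _ann(self, n_state):
        return _annotation([
            ("chr1", 0, n_state * 300, "10_TssBiv"),
            ("chr1", 100_000, 400_000, "4_Tx"),
        ])

    def test_worked_odds_ratio(self):
        # [[8, 2], [20, 70]] -> OR 14
        dmrs = self._dmr_table(n_state=28, n_other=72, dmr_in_state=8,
                               dmr_out=2)
        out = methylome.enrichment(dmrs, self._ann(28))
        row = out[(out["state"] == "10_TssBiv")
                  & (out["direction"] == "hyper")].iloc[0]
        assert (row["dmr_in_state"], row["dmr_out"]) == (8, 2)
        assert row["odds_ratio"] == pytest.approx(14.0)
        assert row["p"] == pytest.approx(
            fisher_two_sided_enumeration(8, 2, 20, 70), rel=1e-9)

    def test_null_distribution_not_significant(self):
        # DMRs spread proportionally: odds ratio ~= 1
        rows = []
        for k in range(200):
            rows.append({"chrom": "chr1", "start": k * 300,
                         "end": k * 300 + 300, "is_dmr": k % 10 == 0,
                         "direction": "hyper" if k % 10 == 0 else "none"})
        dmrs = pd.DataFrame(rows)
        ann = _annotation([("chr1", 0, 30_000, "10_TssBiv"),
                           ("chr1", 30_000, 60_000, "4_Tx")])
        out = methylome.enrichment(dmrs, ann)
        assert not out["significant"].any()

    def test_counts_partition_all_common_tiles(self):
        dmrs = self._dmr_table(n_state=30, n_other=70, dmr_in_state=5,
                               dmr_out=3)
        out = methylome.enrichment(dmrs, self._ann(30))
        for _, row in out.iterrows():
            total = (row["dmr_in_state"] + row["dmr_out"]
                     + row["nondmr_in_state"] + row["nondmr_out"])
            assert total == 100


class TestDmrFrequency:
    def _dmrs(self, n_dmr, n_total):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [k * 300 for k in range(n_total)],
            "end": [k * 300 + 300 for k in range(n_total)],
            "is_dmr": [k < n_dmr for k in range(n_total)],
            "direction": ["hypo" if k < n_dmr else "none"
                          for k in range(n_total)],
        })

    def test_definitional(self):
        assert methylome.dmr_frequency(self._dmrs(10, 200)) == pytest.approx(5.0)

    def test_zero_dmrs(self):
        assert methylome.dmr_frequency(self._dmrs(0, 50)) == 0.0

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ValueError):
            methylome.dmr_frequency(self._dmrs(0, 0))

    def test_monotone_in_dmr_set_and_bounded(self):
        prev = -1.0
        for n in (0, 5, 20, 50):
            f = methylome.dmr_frequency(self._dmrs(n, 50))
            assert 0.0 <= f <= 100.0
            assert f >= prev
            prev = f

    def test_state_restriction(self):
        dmrs = self._dmrs(10, 200)
        ann = _annotation([("chr1", 0, 1500, "10_TssBiv")])  # first 5 tiles
        f = methylome.dmr_frequency(dmrs, state="10_TssBiv", annotation=ann)
        assert f == pytest.approx(100.0 * 5 / 200)
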