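import numpy as np
import pandas as pd
import pytest

from eskor.occupancy import (
    add_eskor,
    build_occupancy_table,
    count_fragments,
    eskor,
    eskor_to_percent_shift,
    filter_genes,
    fit_trend,
    fpkm,
    rank_and_smooth,
    rna_log2fc,
    slope_drop_percent,
)

from conftest import make_fragments, make_gene


def brute_count(genes, fragments):
    """Per-fragment scan with the midpoint rule and the documented tie-break."""
    counts = {g.gene_id: 0 for g in genes.values()}
    for chrom, start, end in fragments:
        mid = (start + end) // 2
        containing = [
            g
            for g in genes.values()
            if g.chrom == chrom and g.tx_start <= mid < g.tx_end
        ]
        if containing:
            winner = min(containing, key=lambda g: (g.tx_start, g.gene_id))
            counts[winner.gene_id] += 1
    return counts


class TestCountFragments:
    def test_midpoint_containment(self):
        genes = {"A": make_gene("A", tx_start=100, tx_end=600)}
        frags = make_fragments([("chr1", 150, 350)])
        assert count_fragments(genes, frags) == {"A": 1}

    def test_midpoint_at_tx_end_not_counted(self):
        genes = {"A": make_gene("A", tx_start=100, tx_end=600)}
        frags = make_fragments([("chr1", 500, 700)])  # midpoint 600, half-open
        assert count_fragments(genes, frags) == {"A": 0}

    def test_missing_chromosome_counts_zero(self):
        genes = {"A": make_gene("A", chrom="chr9", tx_start=0, tx_end=500)}
        frags = make_fragments([("chr1", 0, 100)])
        assert count_fragments(genes, frags) == {"A": 0}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = {}
        for i in range(10):
            start = int(rng.integers(0, 8_000))
            genes[f"G{i}"] = make_gene(
                f"G{i}",
                chrom=f"chr{int(rng.integers(1, 3))}",
                tx_start=start,
                tx_end=start + int(rng.integers(500, 4_000)),
            )
        starts = rng.integers(0, 12_000, 1_000)
        frags = [
            (f"chr{int(rng.integers(1, 3))}", int(s), int(s) + int(rng.integers(1, 400)))
            for s in starts
        ]
        fset = make_fragments(frags)
        assert count_fragments(genes, fset) == brute_count(genes, fset.fragments)

    def test_count_conservation(self, rng):
        genes = {
            f"G{i}": make_gene(f"G{i}", tx_start=i * 1000, tx_end=i * 1000 + 800)
            for i in range(5)
        }
        frags = make_fragments(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 6_000, 500)]
        )
        counts = count_fragments(genes, frags)
        assert sum(counts.values()) <= len(frags)


class TestFpkm:
    def test_unit_case(self):
        assert fpkm(10, 10_000, 1_000_000) == pytest.approx(1.0)

    def test_zero_count(self):
        assert fpkm(0, 10_000, 1_000_000) == 0.0

    def test_arithmetic(self):
        assert fpkm(66, 2_500, 4_000_000) == pytest.approx(6.6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            fpkm(10, 1000, 0)

    def test_scale_invariance(self, rng):
        count, length, total = 37, 8_000, 2_000_000
        for factor in (2, 10, 1000):
            assert fpkm(count * factor, length, total * factor) == pytest.approx(
                fpkm(count, length, total)
            )


class TestEskor:
    def test_doubling_is_plus_one(self):
        assert eskor(2.0, 1.0) == pytest.approx(1.0)

    def test_no_difference_is_zero(self):
        assert eskor(1.0, 1.0) == 0.0

    def test_log2_evaluation(self):
        assert eskor(0.84, 1.0) == pytest.approx(np.log2(0.84))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            eskor(0.0, 1.0)

    def test_antisymmetry_under_condition_swap(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, 2)
            assert eskor(a, b) == pytest.approx(-eskor(b, a))


class TestPercentShift:
    def test_paper_values(self):
        assert eskor_to_percent_shift(-0.25) == -16
        assert eskor_to_percent_shift(0.24) == 18

    def test_zero_identity(self):
        assert eskor_to_percent_shift(0.0) == 0

    def test_monotone_in_eskor(self):
        grid = np.linspace(-2, 2, 41)
        shifts = [eskor_to_percent_shift(v) for v in grid]
        assert all(a <= b for a, b in zip(shifts, shifts[1:]))


class TestFilterGenes:
    def records(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_low_fpkm_removed(self):
        df = self.records(
            [
                {"gene_id": "A", "length": 8000, "fpkm_unt": 0.6, "fpkm_kd": 0.4},
                {"gene_id": "B", "length": 8000, "fpkm_unt": 0.6, "fpkm_kd": 0.6},
            ]
        )
        out, stages = filter_genes(df)
        assert list(out.index) == ["B"]
        assert stages == {"input": 2, "length": 2, "fpkm": 1, "expressed": 1}

    def test_short_gene_removed(self):
        df = self.records(
            [{"gene_id": "A", "length": 4_999, "fpkm_unt": 1.0, "fpkm_kd": 1.0}]
        )
        out, _ = filter_genes(df)
        assert out.empty

    def test_matches_predicate_oracle(self, rng):
        rows = [
            {
                "gene_id": f"G{i}",
                "length": int(rng.integers(1_000, 20_000)),
                "fpkm_unt": float(rng.uniform(0, 2)),
                "fpkm_kd": float(rng.uniform(0, 2)),
            }
            for i in range(200)
        ]
        expressed = {f"G{i}" for i in range(200) if rng.random() < 0.8}
        df = self.records(rows)
        out, _ = filter_genes(df, expressed=expressed)
        expected = {
            r["gene_id"]
            for r in rows
            if r["length"] >= 5000
            and r["fpkm_unt"] > 0.5
            and r["fpkm_kd"] > 0.5
            and r["gene_id"] in expressed
        }
        assert set(out.index) == expected


class TestTrendFit:
    def test_exact_line(self):
        df = pd.DataFrame({"gc": [40, 50, 60], "fpkm_unt": [1.0, 2.0, 3.0]})
        fit = fit_trend(df, "UNT")
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(-3.0)

    def test_constant_y_gives_zero_slope(self):
        df = pd.DataFrame({"gc": [40, 50, 60], "fpkm_kd": [2.0, 2.0, 2.0]})
        assert fit_trend(df, "KD").slope == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        df = pd.DataFrame({"gc": [50, 50, 50], "fpkm_unt": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_trend(df, "UNT")

    def test_matches_closed_form_least_squares(self, rng):
        x = rng.uniform(35, 65, 50)
        y = 0.05 * x + rng.normal(0, 0.5, 50)
        df = pd.DataFrame({"gc": x, "fpkm_unt": y})
        fit = fit_trend(df, "UNT")
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean())


class TestSlopeDrop:
    def test_printed_trendline_pair(self):
        unt = fit_trend(
            pd.DataFrame({"gc": [40.0, 50, 60], "fpkm_unt": [0.0502 * g for g in (40, 50, 60)]}),
            "UNT",
        )
        kd = fit_trend(
            pd.DataFrame({"gc": [40.0, 50, 60], "fpkm_kd": [0.0328 * g for g in (40, 50, 60)]}),
            "KD",
        )
        assert slope_drop_percent(unt, kd) == 35

    def test_equal_slopes_no_drop(self):
        from eskor.occupancy import TrendFit

        fit = TrendFit(0.05, 0.0, "UNT")
        assert slope_drop_percent(fit, TrendFit(0.05, 1.0, "KD")) == 0
        assert slope_drop_percent(TrendFit(0.10, 0, "UNT"), TrendFit(0.05, 0, "KD")) == 50

    def test_zero_unt_slope_rejected(self):
        from eskor.occupancy import TrendFit

        with pytest.raises(ValueError):
            slope_drop_percent(TrendFit(0.0, 0, "UNT"), TrendFit(0.05, 0, "KD"))


class TestRankAndSmooth:
    def test_three_gene_window(self):
        df = pd.DataFrame(
            {"eskor": [2.0, 1.0, 0.0], "gc": [60.0, 50.0, 40.0]},
            index=pd.Index(["A", "B", "C"], name="gene_id"),
        )
        out, _ = rank_and_smooth(df, window=3)
        assert list(out.index) == ["A", "B", "C"]
        assert out["eskor_rank"].tolist() == [1, 2, 3]
        assert out["gc_moving_avg"].tolist() == [60.0, 50.0, 40.0]
        # the centered window covers all three genes only in the middle
        assert out["gc_moving_avg"].iloc[1] == pytest.approx(np.mean([60, 50, 40]))

    def test_constant_gc_correlation_missing(self, caplog):
        df = pd.DataFrame(
            {"eskor": [2.0, 1.0, 0.0], "gc": [50.0, 50.0, 50.0]},
            index=pd.Index(["A", "B", "C"], name="gene_id"),
        )
        with caplog.at_level("WARNING"):
            _, r = rank_and_smooth(df, window=3)
        assert np.isnan(r)
        assert "undefined" in caplog.text

    def test_correlation_matches_product_moment_formula(self, rng):
        esk = rng.normal(0, 1, 300)
        gc = -0.5 * esk + rng.normal(0, 1, 300)
        df = pd.DataFrame(
            {"eskor": esk, "gc": gc},
            index=pd.Index([f"G{i}" for i in range(300)], name="gene_id"),
        )
        _, r = rank_and_smooth(df)
        num = np.sum((esk - esk.mean()) * (gc - gc.mean()))
        den = np.sqrt(np.sum((esk - esk.mean()) ** 2) * np.sum((gc - gc.mean()) ** 2))
        assert r == pytest.approx(num / den)


class TestRnaLog2fc:
    def expr(self, unt, kd):
        return pd.DataFrame({"fpkm_unt": unt, "fpkm_kd": kd})

    def test_knockdown_mrna_fold_change(self):
        # Supt4h mRNA dropping from FPKM 66.78 to 12.05 leaves 18% of the
        # initial concentration
        fc = rna_log2fc(self.expr([66.78], [12.05]))
        assert fc.iloc[0] == pytest.approx(np.log2(12.06 / 66.79), abs=1e-4)
        assert round(100 * 12.05 / 66.78) == 18

    def test_equal_fpkm_is_zero(self):
        assert rna_log2fc(self.expr([5.0], [5.0])).iloc[0] == 0.0

    def test_zero_zero_guarded_by_pseudocount(self):
        assert rna_log2fc(self.expr([0.0], [0.0])).iloc[0] == 0.0


class TestBuildTable:
    def test_fpkm_and_eskor_columns_consistent(self, rng):
        genes = {
            f"G{i}": make_gene(f"G{i}", tx_start=i * 3000, tx_end=i * 3000 + 2000)
            for i in range(4)
        }
        frags_u = make_fragments(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 12_000, 400)],
            total_mapped=1_000_000,
        )
        frags_k = make_fragments(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 12_000, 400)],
            "KD",
            total_mapped=1_000_000,
        )
        gc = pd.Series(
            rng.uniform(40, 60, 4), index=pd.Index(genes.keys(), name="gene_id"), name="gc"
        )
        table = build_occupancy_table(genes, frags_u, frags_k, gc)
        for gid, row in table.iterrows():
            assert row["fpkm_unt"] == pytest.approx(
                fpkm(int(row["count_unt"]), int(row["length"]), 1_000_000)
            )
        positive = table[(table["fpkm_unt"] > 0) & (table["fpkm_kd"] > 0)]
        with_eskor = add_eskor(positive)
        np.testing.assert_allclose(
            with_eskor["eskor"],
            np.log2(positive["fpkm_kd"] / positive["fpkm_unt"]),
        )
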