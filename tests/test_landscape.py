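"""Peak assignment and ohnolog/homeoblock divergence statistics."""

import numpy as np
import pandas as pd
import pytest

from wgdreg.landscape import (
    assign_peaks,
    homeoblock_divergence,
    ohnolog_divergence,
    peak_expression_association,
)


def make_peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestAssignPeaks:
    def test_promoter_window_rule(self):
        genes = make_genes([("g1", "chr1", 10_000, "+")])
        # centers at +50 (promoter), +101 (proximal), -1000 (promoter edge)
        peaks = make_peaks(
            [
                ("chr1", 10_000, 10_100, "p_down50"),
                ("chr1", 10_051, 10_151, "p_down101"),
                ("chr1", 8_950, 9_050, "p_up1000"),
            ]
        )
        out = assign_peaks(peaks, genes).set_index("peak_id")
        assert out.loc["p_down50", "peak_class"] == "promoter"
        assert out.loc["p_down50", "distance"] == 50
        assert out.loc["p_down101", "peak_class"] == "proximal"
        assert out.loc["p_up1000", "peak_class"] == "promoter"
        assert out.loc["p_up1000", "distance"] == -1000

    def test_strand_symmetry(self):
        plus = make_genes([("g1", "chr1", 10_000, "+")])
        minus = make_genes([("g1", "chr1", 10_000, "-")])
        up_for_plus = make_peaks([("chr1", 9_450, 9_550, "p")])  # center 9500
        down_for_minus = make_peaks([("chr1", 10_450, 10_550, "p")])  # center 10500
        a = assign_peaks(up_for_plus, plus)
        b = assign_peaks(down_for_minus, minus)
        assert a.loc[0, "distance"] == b.loc[0, "distance"] == -500
        assert a.loc[0, "peak_class"] == b.loc[0, "peak_class"] == "promoter"

    def test_matches_brute_force_nearest_tss(self, rng):
        genes = make_genes(
            [
                (f"g{k:02d}", "chr1", int(p), "+" if k % 2 else "-")
                for k, p in enumerate(np.sort(rng.choice(500_000, 40, replace=False)))
            ]
        )
        starts = rng.choice(499_000, 100, replace=False)
        peaks = make_peaks(
            [("chr1", int(s), int(s) + 300, f"p{j}") for j, s in enumerate(starts)]
        )
        out = assign_peaks(peaks, genes)
        tss = genes["tss"].to_numpy()
        for row in out.itertuples(index=False):
            dmin = np.abs(tss - row.center).min()
            candidates = genes.loc[np.abs(tss - row.center) == dmin, "gene_id"]
            assert row.gene_id == sorted(candidates)[0]

    def test_translation_invariance(self):
        genes = make_genes([("g1", "chr1", 5_000, "+"), ("g2", "chr1", 40_000, "-")])
        peaks = make_peaks([("chr1", 6_000, 6_500, "p1"), ("chr1", 39_000, 39_400, "p2")])
        base = assign_peaks(peaks, genes)
        shift = 10_000
        g2 = genes.assign(tss=genes["tss"] + shift)
        p2 = peaks.assign(start=peaks["start"] + shift, end=peaks["end"] + shift)
        moved = assign_peaks(p2, g2)
        assert base["gene_id"].tolist() == moved["gene_id"].tolist()
        assert base["distance"].tolist() == moved["distance"].tolist()

    def test_contig_without_genes_counted_unassigned(self):
        genes = make_genes([("g1", "chr1", 1_000, "+")])
        peaks = make_peaks([("chr2", 0, 100, "p1"), ("chr1", 0, 100, "p2")])
        out = assign_peaks(peaks, genes)
        assert len(out) == 1
        assert out.attrs["n_unassigned"] == 1


class TestExpressionAssociation:
    def test_planted_monotone_gives_rho_one(self):
        genes = [f"g{k}" for k in range(10)]
        assignments = pd.DataFrame(
            [
                {"peak_id": f"p{k}{j}", "chrom": "chr1", "center": 0,
                 "gene_id": g, "distance": 5_000, "peak_class": "proximal"}
                for k, g in enumerate(genes)
                for j in range(k)
            ]
        )
        expr = pd.DataFrame({"gene_id": genes, "expr": np.arange(10) * 2.0})
        res = peak_expression_association(assignments, expr)
        assert res["proximal"]["rho"] == pytest.approx(1.0)

    def test_permuted_labels_near_zero(self, rng):
        genes = [f"g{k}" for k in range(60)]
        counts = rng.integers(0, 6, size=60)
        assignments = pd.DataFrame(
            [
                {"peak_id": f"p{k}{j}", "chrom": "c", "center": 0, "gene_id": g,
                 "distance": 5_000, "peak_class": "proximal"}
                for k, g in enumerate(genes)
                for j in range(counts[k])
            ]
        )
        rhos = []
        for t in range(40):
            expr = pd.DataFrame(
                {"gene_id": genes, "expr": rng.permutation(np.arange(60.0))}
            )
            rhos.append(peak_expression_association(assignments, expr)["proximal"]["rho"])
        assert abs(np.mean(rhos)) < 0.08

    def test_constant_input_reported_missing(self):
        assignments = pd.DataFrame(
            columns=["peak_id", "chrom", "center", "gene_id", "distance", "peak_class"]
        )
        expr = pd.DataFrame({"gene_id": ["a", "b", "c"], "expr": [1.0, 2.0, 3.0]})
        res = peak_expression_association(assignments, expr)
        assert np.isnan(res["promoter"]["rho"])


class TestOhnologDivergence:
    def _assignments(self, spec):
        rows = []
        for gene, (n_prom, n_prox) in spec.items():
            for j in range(n_prom):
                rows.append({"peak_id": f"{gene}m{j}", "chrom": "c", "center": 0,
                             "gene_id": gene, "distance": 0, "peak_class": "promoter"})
            for j in range(n_prox):
                rows.append({"peak_id": f"{gene}x{j}", "chrom": "c", "center": 0,
                             "gene_id": gene, "distance": 9_999, "peak_class": "proximal"})
        return pd.DataFrame(
            rows, columns=["peak_id", "chrom", "center", "gene_id", "distance", "peak_class"]
        )

    def test_identical_ohnologs_zero_divergence(self):
        pairs = pd.DataFrame({"gene1": ["a"], "gene2": ["b"],
                              "expr1": [5.0], "expr2": [5.0]})
        out = ohnolog_divergence(pairs, self._assignments({"a": (1, 2), "b": (1, 2)}))
        assert out.loc[0, ["d_promoter", "d_proximal", "d_expr"]].tolist() == [0, 0, 0.0]

    def test_planted_linear_relation_recovered(self, rng):
        spec, rows = {}, []
        for k in range(30):
            g1, g2 = f"a{k}", f"b{k}"
            dp = k % 6
            spec[g1] = (0, 5 + dp)
            spec[g2] = (0, 5)
            e1 = 2.0 ** (dp * 0.5) * 10 - 1  # |log2 expr difference| == 0.5*dp
            rows.append({"gene1": g1, "gene2": g2, "expr1": e1, "expr2": 9.0})
        out = ohnolog_divergence(pd.DataFrame(rows), self._assignments(spec))
        trend = out.attrs["trend"]["proximal"]
        assert trend["slope"] > 0
        assert trend["slope_p"] < 1e-6

    def test_constant_promoter_deltas_reported_missing(self):
        spec = {f"a{k}": (1, k) for k in range(6)} | {f"b{k}": (1, 0) for k in range(6)}
        rows = [{"gene1": f"a{k}", "gene2": f"b{k}", "expr1": 10.0 + k, "expr2": 5.0}
                for k in range(6)]
        out = ohnolog_divergence(pd.DataFrame(rows), self._assignments(spec))
        assert np.isnan(out.attrs["trend"]["promoter"]["rho"])
        assert np.isfinite(out.attrs["trend"]["proximal"]["rho"])

    def test_missing_expression_dropped_and_counted(self):
        rows = [
            {"gene1": "a", "gene2": "b", "expr1": 1.0, "expr2": np.nan},
            {"gene1": "c", "gene2": "d", "expr1": 1.0, "expr2": 2.0},
        ]
        out = ohnolog_divergence(pd.DataFrame(rows), self._assignments({}))
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1


def _blocks(rows):
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "age_ma", "p1", "p2"],
    )


class TestHomeoblockDivergence:
    def test_equal_densities_zero(self):
        df = _blocks([("b0", "c1", 0, 100_000, "c2", 0, 200_000, 50.0, 10, 20)])
        res = homeoblock_divergence(df)
        assert res.divergence.loc[0, "divergence"] == 0.0
        assert res.divergence.loc[0, "residual"] == 0.0

    def test_density_scale_invariance(self):
        base = _blocks([("b0", "c1", 0, 100_000, "c2", 0, 100_000, 50.0, 10, 30)])
        doubled = _blocks([("b0", "c1", 0, 200_000, "c2", 0, 200_000, 50.0, 20, 60)])
        d1 = homeoblock_divergence(base).divergence.loc[0, "divergence"]
        d2 = homeoblock_divergence(doubled).divergence.loc[0, "divergence"]
        assert d1 == pytest.approx(d2)
        assert d1 > 0

    def test_planted_young_conserved_contrast(self, rng):
        rows = []
        for k in range(12):  # young blocks: nearly equal densities
            p = int(rng.integers(20, 40))
            rows.append((f"y{k}", "c1", 0, 100_000, "c2", 0, 100_000, 20.0, p, p + 1))
        for k in range(12):  # old blocks: strongly diverged densities
            p = int(rng.integers(20, 40))
            rows.append((f"o{k}", "c1", 0, 100_000, "c2", 0, 100_000, 70.0, p, p + 25))
        res = homeoblock_divergence(_blocks(rows), age_threshold=40.0)
        assert res.young_median < res.old_median
        assert res.rank_sum_p < 0.01

    def test_counts_peaks_by_center_when_not_given(self):
        peaks = pd.DataFrame(
            {"chrom": ["c1"] * 3 + ["c2"], "start": [10, 500, 5_000, 100],
             "end": [110, 600, 5_100, 200], "name": list("abcd")}
        )
        df = _blocks([("b0", "c1", 0, 1_000, "c2", 0, 1_000, 50.0, None, None)]).drop(
            columns=["p1", "p2"]
        )
        res = homeoblock_divergence(df, peaks=peaks)
        assert res.divergence.loc[0, "p1"] == 2  # centers 60 and 550
        assert res.divergence.loc[0, "p2"] == 1

    def test_divergence_correlates_with_short_length(self, rng):
        rows = []
        for k in range(20):
            L = 20_000 + 15_000 * k
            # same absolute peak-count noise hits short blocks harder
            p = int(L / 5_000)
            rows.append((f"b{k}", "c1", 0, L, "c2", 0, L, 50.0, p, p + 4))
        res = homeoblock_divergence(_blocks(rows))
        assert res.length_rho < -0.9
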