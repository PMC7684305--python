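"""Tests of community statistics: CSS, Bray-Curtis, PCoA, permutation tests,
depth profiles and congruence — with skbio cross-checks where it implements
the same statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sedaforam.stats import (
    aggregate_warm,
    bray_curtis,
    css_normalize,
    congruence_report,
    dispersion_test,
    mantel,
    pcoa,
    permanova,
    planktonic_fraction_profile,
)


def table(data, samples=None, taxa=None):
    data = np.asarray(data)
    samples = samples or [f"s{i}" for i in range(data.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(data.shape[1])]
    return pd.DataFrame(data, index=samples, columns=taxa)


class TestAggregateWarm:
    def test_conservation(self):
        t = table([[3, 4, 5]], taxa=["Globorotalia menardii", "Trilobatus sacculifer", "other"])
        out = aggregate_warm(t)
        assert out.loc["s0", "WARM"] == 7
        assert out.sum(axis=1).iloc[0] == t.sum(axis=1).iloc[0]

    def test_empty_list_identity(self):
        t = table([[1, 2]])
        assert aggregate_warm(t, []).equals(t)

    def test_all_warm_single_column(self):
        t = table([[1, 2], [3, 4]])
        out = aggregate_warm(t, list(t.columns))
        assert list(out.columns) == ["WARM"]
        assert list(out["WARM"]) == [3, 7]


class TestCss:
    def test_hand_computed_uniform_sample(self):
        t = table([[10, 10, 10, 10]])
        norm, factors = css_normalize(t, percentile=0.5)
        assert factors.iloc[0] == 40  # median of nonzero counts is 10; all <= 10
        assert np.allclose(norm.to_numpy(), 10 / 40 * 1000)

    def test_hand_computed_mixed_sample(self):
        # counts 1,2,3,100: median of nonzero = 2.5 -> factor = 1 + 2 = 3
        t = table([[1, 2, 3, 100]])
        _, factors = css_normalize(t, percentile=0.5)
        assert factors.iloc[0] == 3

    def test_scale_invariance(self):
        t = table([[1, 2, 3, 100], [5, 10, 15, 500]])
        norm, factors = css_normalize(t)
        assert factors.iloc[1] == 5 * factors.iloc[0]
        assert np.allclose(norm.iloc[0], norm.iloc[1])

    @given(
        arrays(np.int64, (3, 6), elements=st.integers(0, 50)).filter(
            lambda x: (x.sum(axis=1) > 0).all()
        ),
        st.integers(2, 7),
    )
    def test_scale_invariance_randomized(self, data, c):
        t = table(data)
        scaled = t.copy()
        scaled.iloc[0] = scaled.iloc[0] * c
        n1, f1 = css_normalize(t)
        n2, f2 = css_normalize(scaled)
        assert f2.iloc[0] == pytest.approx(c * f1.iloc[0])
        assert np.allclose(n1.iloc[0], n2.iloc[0])

    def test_all_zero_sample_excluded(self):
        t = table([[0, 0], [1, 2]])
        norm, factors = css_normalize(t)
        assert list(norm.index) == ["s1"]


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(table([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(table([[5, 0], [0, 7]]))
        assert d.iloc[0, 1] == 1.0

    def test_printed_example(self):
        d = bray_curtis(table([[1, 2, 3], [3, 2, 1]]))
        assert d.iloc[0, 1] == pytest.approx(4 / 12)

    @given(arrays(np.int64, (4, 5), elements=st.integers(0, 30)).filter(
        lambda x: (x.sum(axis=1) > 0).all()
    ))
    def test_distance_axioms(self, data):
        d = bray_curtis(table(data)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_two_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(table([[0, 0], [0, 0], [1, 1]]))


class TestPcoa:
    def test_collinear_points_recovered(self):
        # three points on a line with distances 1, 1, 2
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        res = pcoa(D)
        coords = res.coordinates.to_numpy()[:, 0]
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, D.to_numpy(), atol=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_configuration_roundtrip(self, rng):
        X = rng.normal(size=(6, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = pd.DataFrame(D, index=[f"s{i}" for i in range(6)], columns=[f"s{i}" for i in range(6)])
        res = pcoa(dm)
        C = res.coordinates.to_numpy()[:, res.eigenvalues > 1e-9]
        rec = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-10)

    def test_duplicate_samples_coincident(self):
        t = table([[1, 2, 3], [1, 2, 3], [9, 1, 0]])
        res = pcoa(bray_curtis(t))
        c = res.coordinates.to_numpy()[:, np.abs(res.eigenvalues) > 1e-9]
        assert np.allclose(c[0], c[1], atol=1e-10)

    def test_asymmetric_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            pcoa(D)

    def test_matches_skbio(self, rng):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        t = table(rng.integers(0, 50, size=(7, 5)))
        dm = bray_curtis(t)
        ours = pcoa(dm)
        theirs = skbio_pcoa(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
        # skbio clamps negative eigenvalues; compare the positive spectrum
        mine = sorted([v for v in ours.eigenvalues if v > 1e-9], reverse=True)
        ref = sorted([v for v in theirs.eigvals.to_numpy() if v > 1e-9], reverse=True)
        np.testing.assert_allclose(mine, ref, atol=1e-8)


class TestPermanova:
    def test_statistic_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        t = table(rng.integers(0, 50, size=(10, 6)))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.index)
        ours = permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio_stats.permanova(
            DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            grouping=groups.to_numpy(),
            permutations=99,
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_label_order_invariance(self, rng):
        t = table(rng.integers(0, 50, size=(8, 5)))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.index)
        perm = rng.permutation(8)
        dm2 = dm.iloc[perm, perm]
        r1 = permanova(dm, groups, n_perm=49, seed=1)
        r2 = permanova(dm2, groups.iloc[perm], n_perm=49, seed=1)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_disjoint_clouds_significant(self, rng):
        a = rng.normal(0, 0.05, size=(6, 4)) + np.array([10, 0, 0, 0])
        b = rng.normal(0, 0.05, size=(6, 4)) + np.array([0, 10, 0, 0])
        t = table(np.abs(np.vstack([a, b])))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.index)
        assert permanova(dm, groups, n_perm=999, seed=3).p_value <= 0.01


class TestDispersion:
    def test_observed_labels_p_at_least_min(self, rng):
        t = table(rng.integers(1, 50, size=(10, 6)))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.index)
        res = dispersion_test(dm, groups, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_strong_dispersion_contrast_detected(self, rng):
        center = np.full(5, 50.0)
        tight = np.abs(center + rng.normal(0, 0.5, size=(8, 5)))
        loose = np.abs(center + rng.normal(0, 25, size=(8, 5)))
        t = table(np.vstack([tight, loose]))
        dm = bray_curtis(t)
        groups = pd.Series(["tight"] * 8 + ["loose"] * 8, index=dm.index)
        assert dispersion_test(dm, groups, n_perm=999, seed=1).p_value <= 0.01

    def test_singleton_group_excluded(self, rng):
        t = table(rng.integers(1, 50, size=(6, 4)))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 3 + ["b"] * 2 + ["c"], index=dm.index)
        res = dispersion_test(dm, groups, n_perm=49, seed=0)
        assert np.isfinite(res.statistic)

    def test_statistic_matches_vegan_betadisper(self, rng):
        """Cross-check the dispersion F statistic against vegan::betadisper."""
        import shutil
        import subprocess
        import tempfile

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        t = table(rng.integers(1, 60, size=(9, 5)))
        dm = bray_curtis(t)
        groups = pd.Series(["a"] * 5 + ["b"] * 4, index=dm.index)
        ours = dispersion_test(dm, groups, n_perm=9, seed=0)
        with tempfile.TemporaryDirectory() as d:
            dm.to_csv(f"{d}/dm.tsv", sep="\t")
            script = f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.table("{d}/dm.tsv", sep="\\t", header=TRUE, row.names=1))
            bd <- betadisper(as.dist(m), c(rep("a",5), rep("b",4)), type="centroid")
            cat(anova(bd)$`F value`[1])
            """
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
            f_vegan = float(out.stdout.strip().split()[-1])
        assert ours.statistic == pytest.approx(f_vegan, rel=1e-6)


class TestMantel:
    def test_identical_tables_correlation_one(self, rng):
        t = table(rng.integers(0, 50, size=(6, 5)))
        dm = bray_curtis(t)
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        a = bray_curtis(table(rng.integers(0, 50, size=(7, 5))))
        b = bray_curtis(table(rng.integers(0, 50, size=(7, 5))))
        ours = mantel(a, b, n_perm=99, seed=0)
        r, _, _ = skbio_stats.mantel(
            DistanceMatrix(a.to_numpy(), ids=list(a.index)),
            DistanceMatrix(b.to_numpy(), ids=list(b.index)),
            method="pearson",
            permutations=0,
        )
        assert ours.statistic == pytest.approx(r, rel=1e-10)

    def test_independent_tables_p_not_extreme(self, rng):
        a = bray_curtis(table(rng.integers(1, 50, size=(8, 5))))
        b = bray_curtis(table(rng.integers(1, 50, size=(8, 5))))
        res = mantel(a, b, n_perm=199, seed=0)
        assert 0 < res.p_value <= 1

    def test_null_calibration(self, rng):
        """Mantel p-values are uniform for independent random tables:
        rejection rate at alpha=0.05 within 2 binomial SE over 500 runs."""
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a = bray_curtis(table(rng.integers(1, 50, size=(7, 5))))
            b = bray_curtis(table(rng.integers(1, 50, size=(7, 5))))
            res = mantel(a, b, n_perm=199, seed=int(rng.integers(2**31)))
            if res.p_value <= 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) <= 2 * se


class TestFractionProfile:
    def make_inputs(self):
        counts = pd.DataFrame(
            {
                "a_0-2.rep1": [1, 99],
                "a_0-2.rep2": [1, 99],
                "a_12-14.rep1": [80, 20],
                "a_12-14.rep2": [60, 40],
                "a_24-26.rep1": [30, 70],
                "a_24-26.rep2": [30, 70],
            },
            index=["otu1", "otu2"],
        )
        habitat = pd.Series(["planktonic", "benthic"], index=counts.index)
        meta = pd.DataFrame(
            {
                "site": ["a"] * 6,
                "depth_cm_top": [0, 0, 12, 12, 24, 24],
                "depth_cm_bottom": [2, 2, 14, 14, 26, 26],
                "zone": ["LC"] * 6,
            },
            index=counts.columns,
        )
        return counts, habitat, meta

    def test_fractions_and_binned_means(self):
        counts, habitat, meta = self.make_inputs()
        fr, summary = planktonic_fraction_profile(counts, habitat, meta)
        assert fr["a_0-2"] == pytest.approx(0.01)
        assert fr["a_12-14"] == pytest.approx(140 / 200)
        assert summary["[0,10)"] == pytest.approx(0.01)
        assert summary["[10,20)"] == pytest.approx(0.7)
        assert summary["[20,30)"] == pytest.approx(0.3)

    def test_all_planktonic_fraction_one(self):
        counts, habitat, meta = self.make_inputs()
        habitat[:] = "planktonic"
        fr, _ = planktonic_fraction_profile(counts, habitat, meta)
        assert (fr == 1.0).all()

    def test_reads_conserved(self):
        counts, habitat, meta = self.make_inputs()
        fr, _ = planktonic_fraction_profile(counts, habitat, meta)
        plank = counts.loc[habitat == "planktonic"].sum().groupby(
            counts.columns.str.replace(r"\.rep\d+$", "", regex=True)
        ).sum()
        total = counts.sum().groupby(
            counts.columns.str.replace(r"\.rep\d+$", "", regex=True)
        ).sum()
        assert np.allclose(fr * total, plank)


class TestCongruence:
    def test_identical_tables(self, rng):
        t = table(rng.integers(1, 50, size=(8, 5)))
        meta = pd.DataFrame(
            {
                "site": ["x"] * 4 + ["y"] * 4,
                "zone": ["LC"] * 4 + ["NAC"] * 4,
                "depth_cm_top": 0.0,
                "depth_cm_bottom": 2.0,
            },
            index=t.index,
        )
        rep = congruence_report(t, t, meta, n_perm=99, seed=0)
        assert rep["mantel"].statistic == pytest.approx(1.0)

    def test_spinose_removed_from_fossil(self, rng):
        t = table(rng.integers(1, 50, size=(6, 3)), taxa=["Globigerina bulloides", "a", "b"])
        meta = pd.DataFrame(
            {
                "site": ["x"] * 3 + ["y"] * 3,
                "zone": ["LC"] * 3 + ["NAC"] * 3,
                "depth_cm_top": 0.0,
                "depth_cm_bottom": 2.0,
            },
            index=t.index,
        )
        mol = t.drop(columns=["Globigerina bulloides"])
        rep = congruence_report(t, mol, meta, spinose_taxa=["Globigerina bulloides"], n_perm=49, seed=0)
        assert rep["mantel"].statistic == pytest.approx(1.0)

    def test_too_few_samples_rejected(self, rng):
        t = table(rng.integers(1, 50, size=(2, 3)))
        meta = pd.DataFrame(
            {"site": ["x", "y"], "zone": ["LC", "NAC"], "depth_cm_top": 0.0, "depth_cm_bottom": 2.0},
            index=t.index,
        )
        with pytest.raises(ValueError):
            congruence_report(t, t, meta)
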