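import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from feralscan import synthetic_data as sd
from feralscan.expression import (
    CountMatrix,
    by_fdr,
    call_degs,
    deg_test,
    read_counts,
    region_specific_degs,
    rpkm,
)


def _cm(counts, lengths=None, lib=None):
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    sheet = pd.DataFrame(
        {"sample": samples, "region": "R", "stage": 1}
    )
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(lengths if lengths is not None else 1000, index=genes),
        sheet,
        library_size=pd.Series(lib, index=samples) if lib is not None else None,
        enforce_library_floor=False,
    )


class TestRpkm:
    def test_worked_example(self):
        # 1,000 reads on a 1 kb gene in a 10-million-read library -> 100
        cm = _cm(np.array([[1000]]), lengths=[1000], lib=[1e7])
        assert rpkm(cm).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_zero_rpkm(self):
        cm = _cm(np.array([[0], [10]]), lib=[1e6])
        assert rpkm(cm).iloc[0, 0] == 0.0

    def test_scale_invariance(self):
        c = np.array([[100, 30], [5, 800]])
        a = rpkm(_cm(c, lib=[1e6, 2e6]))
        b = rpkm(_cm(2 * c, lib=[2e6, 4e6]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(_cm(np.array([[0]]), lib=[0.0]))


def brute_force_binomial_p(c1, c2, n1, n2):
    """Exact two-sided p by explicit pmf summation (tail doubling with the
    observed point included)."""
    n = c1 + c2
    pr = n1 / (n1 + n2)
    pmf = [stats.binom.pmf(k, n, pr) for k in range(n + 1)]
    lower = sum(pmf[: c1 + 1])
    upper = sum(pmf[c1:])
    return min(1.0, 2 * min(lower, upper))


class TestDegTest:
    def test_perfect_null(self):
        p, r = deg_test([50], [50], 1e6, 1e6)
        assert p[0] == pytest.approx(1.0)
        assert r[0] == 0.0

    def test_pseudocount_on_zero(self):
        p, r = deg_test([10], [0], 1e6, 1e6)
        assert r[0] == pytest.approx(np.log2(10.5 / 0.5))

    def test_both_zero_is_ns(self):
        p, r = deg_test([0], [0], 1e6, 1e6)
        assert p[0] == 1.0 and r[0] == 0.0

    def test_matches_brute_force_tail_summation(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            c1 = int(rng.integers(0, 60))
            c2 = int(rng.integers(0, 60))
            n1 = float(rng.integers(5, 20)) * 1e5
            n2 = float(rng.integers(5, 20)) * 1e5
            p, _ = deg_test([c1], [c2], n1, n2)
            if c1 + c2 == 0:
                assert p[0] == 1.0
            else:
                assert p[0] == pytest.approx(
                    brute_force_binomial_p(c1, c2, n1, n2), rel=1e-9
                )

    def test_null_pvalues_super_uniform(self):
        # discrete exact test: empirical size must not exceed alpha by much
        rng = np.random.default_rng(10)
        lam = rng.uniform(50, 500, 4000)
        c1 = rng.poisson(lam)
        c2 = rng.poisson(lam)
        p, _ = deg_test(c1, c2, 1e6, 1e6)
        assert 0.02 <= (p < 0.05).mean() <= 0.06


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_expanded_three_values(self):
        # m = 3, c(3) = 1 + 1/2 + 1/3 = 11/6; raw step values
        # p_(i) * m * c(m) / i = (0.055, 0.055, 0.055); step-up keeps 0.055
        q = by_fdr([0.01, 0.02, 0.03])
        np.testing.assert_allclose(q, [0.055, 0.055, 0.055], rtol=1e-12)

    def test_hand_expanded_step_up_minimum(self):
        # p = (0.001, 0.5): raw = (0.001*2*1.5/1, 0.5*2*1.5/2) = (0.003, 0.75)
        q = by_fdr([0.001, 0.5])
        np.testing.assert_allclose(q, [0.003, 0.75], rtol=1e-12)

    def test_dominates_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(200)
            q_by = by_fdr(p)
            q_bh = multipletests(p, method="fdr_bh")[1]
            assert (q_by >= q_bh - 1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.1, np.nan])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    def test_permutation_equivariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        q = by_fdr(p)
        perm = np.argsort(p)[::-1]
        np.testing.assert_allclose(by_fdr(p[perm]), q[perm], atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _design_cm(planted=None, overdispersion=0.0, seed=2, n_genes=400,
               lib=300_000.0):
    design = sd.ExpressionDesign(
        n_genes=n_genes,
        library_size=lib,
        planted_degs=planted,
        overdispersion=overdispersion,
        seed=seed,
    )
    return sd.simulate_counts(design)


class TestCallDegs:
    def test_null_data_yields_no_calls(self):
        cm, _ = _design_cm()
        deg = call_degs(cm)
        assert (deg["call"] == "ns").mean() > 0.999

    def test_planted_fourfold_recovered_with_direction(self):
        planted = pd.DataFrame(
            {"gene_id": [f"gene{i:05d}" for i in range(20)],
             "stage": 1, "fold": 4.0}
        )
        cm, truth = _design_cm(planted=planted)
        deg = call_degs(cm)
        hit = deg[(deg["stage"] == 1) & deg["gene_id"].isin(truth["gene_id"])]
        assert (hit["call"] == "up").mean() >= 0.9

    def test_dual_threshold_blocks_small_ratio(self):
        # hugely significant but ratio below 1 -> ns
        cm = CountMatrix(
            pd.DataFrame(
                {"a_s1": [150_000, 50_000], "b_s1": [100_000, 100_000]},
                index=pd.Index(["g0", "g1"], name="gene_id"),
            ),
            pd.Series([1000, 1000], index=["g0", "g1"]),
            pd.DataFrame({"sample": ["a_s1", "b_s1"], "region": ["NE", "E"],
                          "stage": [1, 1]}),
        )
        deg = call_degs(cm, e_region="E")
        row = deg.set_index("gene_id").loc["g0"]
        assert row["q"] < 0.001 and abs(row["log2_ratio"]) < 1
        assert row["call"] == "ns"

    def test_missing_stage_library_rejected(self):
        cm, _ = _design_cm()
        with pytest.raises(ValueError):
            cm.sample_for("NE_a", 99)

    def test_roundtrip_tsv(self, tmp_path):
        cm, _ = _design_cm(n_genes=50)
        cm.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        pd.testing.assert_series_equal(
            back.lengths, cm.lengths, check_names=False
        )


class TestRegionSpecificSets:
    def _deg_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "region", "stage", "call"]
        ).assign(rpkm_ne=1.0, rpkm_e=1.0, log2_ratio=0.0, p=0.5, q=1.0)

    def test_single_region_up_excluded(self):
        rows = [("g1", "NE_a", s, "up") for s in (1, 2, 3)]
        rows += [("g1", "NE_b", s, "ns") for s in (1, 2, 3)]
        sets = region_specific_degs(self._deg_frame(rows))
        assert all(not sets.common_up[s] for s in (1, 2, 3))

    def test_set_logic_enumeration(self):
        rows = []
        # g_both: up in both regions at stages 1, 2; down at 3
        for s, call in ((1, "up"), (2, "up"), (3, "down")):
            rows += [("g_both", r, s, call) for r in ("NE_a", "NE_b")]
        # g_const: up everywhere
        rows += [("g_const", r, s, "up") for r in ("NE_a", "NE_b")
                 for s in (1, 2, 3)]
        sets = region_specific_degs(self._deg_frame(rows))
        assert sets.common_up[1] == {"g_both", "g_const"}
        assert sets.common_up[2] == {"g_both", "g_const"}
        assert sets.common_up[3] == {"g_const"}
        assert sets.common_down[3] == {"g_both"}
        assert sets.constant_up == {"g_const"}
        assert sets.constant_down == set()

    def test_intersections_match_brute_force(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        rows = [
            (g, r, s, rng.choice(["up", "down", "ns"], p=[0.3, 0.3, 0.4]))
            for g in genes for r in ("NE_a", "NE_b") for s in (1, 2, 3)
        ]
        df = self._deg_frame(rows)
        sets = region_specific_degs(df)
        lookup = df.set_index(["gene_id", "region", "stage"])["call"]
        for s in (1, 2, 3):
            expected = {
                g for g in genes
                if lookup[(g, "NE_a", s)] == "up" and lookup[(g, "NE_b", s)] == "up"
            }
            assert sets.common_up[s] == expected
        assert sets.constant_up == set.intersection(
            *(sets.common_up[s] for s in (1, 2, 3))
        )

    def test_planted_persistent_genes_recovered(self):
        planted = pd.DataFrame(
            [(f"gene{i:05d}", s, 4.0) for i in range(10) for s in (1, 2, 3)],
            columns=["gene_id", "stage", "fold"],
        )
        cm, _ = _design_cm(planted=planted)
        sets = region_specific_degs(call_degs(cm))
        assert sets.constant_up == set(planted["gene_id"].unique())
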