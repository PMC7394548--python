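"""CPM filter, NB Wald test, BH, DEG calling, intersections, synergy, ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeoscreen import NBExpressionModel, bh_adjust, ddct, deg_call
from homeoscreen.degs import (
    _irls_nb,
    cpm_filter,
    per_gene_test,
    size_factors,
    synergy_select,
    upset_intersections,
)
from homeoscreen.errors import DomainError, SchemaError
from homeoscreen.params import CountSimSpec
from homeoscreen.simulate import simulate_counts

SAMPLES = tuple((f"{g}{i}", g, f"b{i % 2}") for g in ("wt", "mut") for i in range(4))


def null_counts(seed, n_genes=1000, samples=SAMPLES):
    spec = CountSimSpec(n_genes=n_genes, samples=samples, control_genotype="wt")
    return simulate_counts(spec, np.random.default_rng(seed))


class TestCPMFilter:
    def test_hand_computed_example(self):
        counts = pd.DataFrame(
            {"s1": [10, 4, 0], "s2": [0, 4, 0]},
            index=["gene1", "gene2", "gene3"],
        )
        # make library sizes 1e6 without touching the tested genes
        counts.loc["filler"] = [10**6 - 14, 10**6 - 4]
        kept = cpm_filter(counts, threshold=5.0)
        assert "gene1" in kept.index  # CPM 10 in s1
        assert "gene2" not in kept.index  # CPM 4 in all samples
        assert "gene3" not in kept.index

    def test_threshold_zero_keeps_nonzero_genes(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [2, 0]}, index=["a", "b"])
        kept = cpm_filter(counts, threshold=0.0)
        assert list(kept.index) == ["a"]

    def test_nothing_passing_warns_not_raises(self):
        counts = pd.DataFrame({"s1": [1, 1], "s2": [10**6, 10**6]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            kept = cpm_filter(counts, threshold=10**7)
        assert kept.empty

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["a"])
        with pytest.raises(SchemaError, match="empty"):
            cpm_filter(counts)


class TestPerGeneTest:
    def test_identical_counts_null_result(self):
        """Every sample carries the same column of counts: nothing to find."""
        col = np.arange(50, 70) * 10
        counts = pd.DataFrame(
            {s: col for s, _, _ in SAMPLES},
            index=[f"g{i}" for i in range(20)],
        )
        design = pd.DataFrame(
            [{"sample": s, "genotype": g, "batch": b} for s, g, b in SAMPLES]
        )
        res = per_gene_test(counts, design, ("mut", "wt"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-9)
        assert (res["p"] > 0.99).all()

    def test_planted_effect_detected(self):
        genes = CountSimSpec(n_genes=500, samples=SAMPLES).gene_ids
        spec = CountSimSpec(
            n_genes=500,
            samples=SAMPLES,
            de_spec={"mut": ([genes[0]], 2.0)},
            control_genotype="wt",
        )
        counts, design, _ = simulate_counts(spec, np.random.default_rng(3))
        res = per_gene_test(counts, design, ("mut", "wt"))
        assert res.iloc[0]["p"] < 0.01
        assert res.iloc[0]["log2fc"] == pytest.approx(2.0, abs=0.5)

    def test_type_one_error_calibrated(self):
        """Global null over 200 seeds: rejection rate at alpha=0.05 in
        [0.03, 0.07]."""
        rates = []
        for seed in range(200):
            counts, design, _ = null_counts(10_000 + seed, n_genes=1000)
            res = per_gene_test(counts, design, ("mut", "wt"))
            rates.append((res["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_confounded_design_rejected(self):
        samples = tuple(
            (f"{g}{i}", g, "batchA" if g == "wt" else "batchB")
            for g in ("wt", "mut")
            for i in range(3)
        )
        counts, design, _ = null_counts(1, n_genes=20, samples=samples)
        with pytest.raises(DomainError, match="confound"):
            per_gene_test(counts, design, ("mut", "wt"))

    def test_irls_matches_statsmodels_glm(self):
        """Coefficients agree with statsmodels' NB GLM at fixed dispersion."""
        import statsmodels.api as sm

        counts, design, _ = null_counts(4, n_genes=5)
        sub = design[design["genotype"].isin(["mut", "wt"])]
        y = counts[sub["sample"]].to_numpy(float)
        sf = size_factors(counts[sub["sample"]]).to_numpy()
        X = np.column_stack(
            [
                np.ones(len(sub)),
                (sub["genotype"] == "mut").to_numpy(float),
                pd.get_dummies(sub["batch"], drop_first=True, dtype=float),
            ]
        )
        alpha = np.full(5, 0.05)
        beta, _ = _irls_nb(y, X, np.log(sf), alpha)
        for i in range(5):
            glm = sm.GLM(
                y[i],
                X,
                family=sm.families.NegativeBinomial(alpha=0.05),
                offset=np.log(sf),
            ).fit()
            np.testing.assert_allclose(beta[i], glm.params, atol=1e-4)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = bh_adjust(pvals)
        shuffled = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([base[i] for i in perm], shuffled, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


class TestDegCall:
    def make(self, fdr, log2fc):
        return pd.DataFrame({"log2fc": [log2fc], "p": [fdr], "fdr": [fdr]})

    @pytest.mark.parametrize(
        "fdr,log2fc,expected",
        [
            (0.01, 0.3, False),  # fold 1.23 below the 1.5x cut
            (0.01, np.log2(1.5), True),  # boundary fold passes
            (0.01, -np.log2(1.5), True),
            (0.05, 1.0, False),  # FDR boundary fails (strict <)
            (0.049, 1.0, True),
        ],
    )
    def test_thresholds(self, fdr, log2fc, expected):
        out = deg_call(self.make(fdr, log2fc))
        assert bool(out["is_deg"].iloc[0]) is expected

    def test_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 200), "p": rng.uniform(0, 1, 200)}
        )
        df["fdr"] = bh_adjust(df["p"])
        loose = deg_call(df, fdr_cut=0.2, fc_cut=1.2)["is_deg"].sum()
        tight_fdr = deg_call(df, fdr_cut=0.05, fc_cut=1.2)["is_deg"].sum()
        tight_fc = deg_call(df, fdr_cut=0.2, fc_cut=2.0)["is_deg"].sum()
        assert tight_fdr <= loose and tight_fc <= loose


class TestUpsetIntersections:
    def test_enumerable_example(self):
        sets = {"A": {"1", "2"}, "B": {"2", "3"}}
        by_sig = {s.signature: set(s.genes) for s in upset_intersections(sets)}
        assert by_sig == {("A",): {"1"}, ("B",): {"3"}, ("A", "B"): {"2"}}

    def test_disjoint_sets_only_singletons(self):
        sets = {"A": {"1"}, "B": {"2"}, "C": {"3"}}
        sigs = {s.signature for s in upset_intersections(sets)}
        assert sigs == {("A",), ("B",), ("C",)}

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_partition_of_union(self, k):
        """Exclusive sizes sum to the union; each gene in exactly one set
        (brute-force per-gene membership oracle)."""
        rng = np.random.default_rng(k)
        genes = [f"g{i}" for i in range(100)]
        sets = {
            f"S{j}": {g for g in genes if rng.random() < 0.3} for j in range(k)
        }
        inter = upset_intersections(sets)
        union = set().union(*sets.values())
        assert sum(s.size for s in inter) == len(union)
        for g in union:
            oracle_sig = tuple(n for n in sets if g in sets[n])
            holders = [s for s in inter if g in s.genes]
            assert len(holders) == 1
            assert holders[0].signature == oracle_sig


class TestSynergySelect:
    def fit_three(self, seed=0):
        samples = tuple(
            (f"{g}{i}", g, f"b{i % 2}")
            for g in ("wt", "hetA", "hetB", "double")
            for i in range(4)
        )
        genes = CountSimSpec(n_genes=600, samples=samples).gene_ids
        spec = CountSimSpec(
            n_genes=600,
            samples=samples,
            de_spec={"hetA": (genes[0:10], 2.0)},  # shared het effect
            synergy_spec=(genes[10:20], 2.0),  # double-specific
            double_genotype="double",
            control_genotype="wt",
        )
        counts, design, _ = simulate_counts(spec, np.random.default_rng(seed))
        model = NBExpressionModel(counts, design)
        fits = {c: model.fit(("double", c)) for c in ("wt", "hetA", "hetB")}
        return genes, fits

    def test_planted_synergy_recovered_shared_excluded(self):
        genes, fits = self.fit_three(seed=1)
        sel = synergy_select(
            fits["wt"].table, fits["hetA"].table, fits["hetB"].table
        )
        planted = set(genes[10:20])
        assert len(planted & set(sel.index)) >= 8
        # genes DE in hetA and double alike do not pass the vs-hetA contrast
        assert not (set(genes[0:10]) & set(sel.index))

    def test_no_degs_empty_selection(self):
        counts, design, _ = null_counts(9, n_genes=100)
        model = NBExpressionModel(counts, design)
        fit = model.fit(("mut", "wt"))
        sel = synergy_select(fit.table, fit.table, fit.table)
        assert len(sel) <= 2  # at FDR < 0.05 on a null, essentially nothing

    def test_sign_conflict_excluded(self):
        idx = pd.Index(["g1"], name="gene_id")
        up = pd.DataFrame({"log2fc": [1.0], "is_deg": [True]}, index=idx)
        down = pd.DataFrame({"log2fc": [-1.0], "is_deg": [True]}, index=idx)
        assert synergy_select(up, up, down).empty

    def test_subset_of_vs_wt_degs(self):
        genes, fits = self.fit_three(seed=2)
        sel = synergy_select(
            fits["wt"].table, fits["hetA"].table, fits["hetB"].table
        )
        assert set(sel.index) <= set(fits["wt"].degs)

    def test_mismatched_universe_rejected(self):
        a = pd.DataFrame(
            {"log2fc": [1.0], "is_deg": [True]}, index=pd.Index(["g1"])
        )
        b = pd.DataFrame(
            {"log2fc": [1.0], "is_deg": [True]}, index=pd.Index(["g2"])
        )
        with pytest.raises(DomainError):
            synergy_select(a, a, b)


class TestDdct:
    def make(self, ctrl_dct, test_dct):
        rows = []
        for i, d in enumerate(ctrl_dct):
            rows.append(
                {"sample": f"c{i}", "group": "control", "ct_target": 20 + d,
                 "ct_reference": 20.0}
            )
        for i, d in enumerate(test_dct):
            rows.append(
                {"sample": f"t{i}", "group": "mut", "ct_target": 20 + d,
                 "ct_reference": 20.0}
            )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "ctrl,test,fold", [([5.0], [4.0], 2.0), ([5.0], [5.0], 1.0), ([5.0], [6.0], 0.5)]
    )
    def test_closed_forms(self, ctrl, test, fold):
        out = ddct(self.make(ctrl, test), control_group="control")
        assert out["fold_change"].iloc[0] == pytest.approx(fold)

    def test_missing_ct_rejected(self):
        df = self.make([5.0], [4.0])
        df.loc[0, "ct_reference"] = np.nan
        with pytest.raises(SchemaError):
            ddct(df)
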