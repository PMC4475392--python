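import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from soilscape.community import (
    CommunityTable,
    DistanceMatrix,
    OrdinationResult,
    aggregate_taxonomy,
    fit_vectors,
    nmds,
    pca_soil,
    rarefy_counts,
    weighted_unifrac,
)
from soilscape.errors import SchemaError, ValidationError
from soilscape.synthetic import random_coalescent_tree


# ---------------------------------------------------------------------------
# rarefaction

class TestRarefy:
    def test_site_at_exact_depth_unchanged(self, tiny_community):
        out = rarefy_counts(tiny_community, 100, seed=0)
        pd.testing.assert_series_equal(
            out.data["s1"].astype(float), tiny_community.data["s1"], check_names=True
        )

    def test_all_columns_sum_to_depth(self, tiny_community):
        out = rarefy_counts(tiny_community, 60, seed=1)
        assert (out.data.sum(axis=0) == 60).all()

    def test_hypergeometric_mean_oracle(self):
        # oracle: E[count] = depth * K / N for subsampling without replacement
        col = np.array([300, 100, 600])
        data = pd.DataFrame({"s": col}, index=["a", "b", "c"], dtype=float)
        table = CommunityTable(data, pd.Series({"a": "x", "b": "x", "c": "x"}))
        depth = 200
        draws = np.array(
            [rarefy_counts(table, depth, seed=s).data["s"].to_numpy() for s in range(1000)]
        )
        expected = depth * col / col.sum()
        np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.03)

    def test_shallow_sites_dropped_with_warning(self, tiny_community):
        tbl = CommunityTable(
            tiny_community.data.assign(s4=[1.0, 0, 0, 0]),
            tiny_community.lineages,
        )
        with pytest.warns(UserWarning, match="dropped"):
            out = rarefy_counts(tbl, 60, seed=0)
        assert "s4" not in out.sites

    def test_determinism(self, tiny_community):
        a = rarefy_counts(tiny_community, 50, seed=3)
        b = rarefy_counts(tiny_community, 50, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_bad_depth_rejected(self, tiny_community):
        with pytest.raises(ValidationError):
            rarefy_counts(tiny_community, 0)


# ---------------------------------------------------------------------------
# taxonomy aggregation

class TestAggregate:
    def test_grand_total_conserved(self, tiny_community):
        out = aggregate_taxonomy(tiny_community, "phylum")
        assert out.data.to_numpy().sum() == tiny_community.data.to_numpy().sum()

    def test_shared_phylum_rows_summed(self, tiny_community):
        out = aggregate_taxonomy(tiny_community, "phylum")
        expected = tiny_community.data.loc[["otu3", "otu4"]].sum()
        pd.testing.assert_series_equal(
            out.data.loc["Acidobacteria"], expected, check_names=False
        )

    def test_proteobacteria_split_at_class(self, tiny_community):
        out = aggregate_taxonomy(tiny_community, "phylum_with_proteobacteria_classes")
        assert set(out.taxa) == {
            "Alphaproteobacteria",
            "Betaproteobacteria",
            "Acidobacteria",
        }

    def test_unparseable_pooled_as_unclassified(self):
        data = pd.DataFrame({"s": [5.0, 7.0]}, index=["a", "b"])
        table = CommunityTable(data, pd.Series({"a": "Bacteria", "b": ""}))
        out = aggregate_taxonomy(table, "phylum")
        assert out.taxa == ["unclassified"]
        assert out.data.loc["unclassified", "s"] == 12.0

    def test_generator_closed_loop_phylum_proportions(self, small_design):
        # taxa with fixed baseline logits -> known expected phylum proportions
        from soilscape.geostat import VariogramModel
        from soilscape.synthetic import (
            CommunitySpec,
            FieldSpec,
            TaxonSpec,
            attach_soil_and_management,
            simulate_community,
        )

        vg = VariogramModel(0.1, 0.9, 150.0, 0.5)
        sites = attach_soil_and_management(
            small_design, [FieldSpec("pH", vg, 7.7)], {"A": 55}, seed=0
        )
        spec = CommunitySpec(
            [
                TaxonSpec("o1", "Bacteria;P1", baseline_logit=np.log(6)),
                TaxonSpec("o2", "Bacteria;P2", baseline_logit=np.log(3)),
                TaxonSpec("o3", "Bacteria;P2", baseline_logit=np.log(1)),
            ],
            library_size=20_000,
        )
        ct = simulate_community(sites, spec, seed=1)
        agg = aggregate_taxonomy(ct, "phylum")
        props = agg.data.sum(axis=1) / agg.data.to_numpy().sum()
        assert props["P1"] == pytest.approx(0.6, abs=0.02)
        assert props["P2"] == pytest.approx(0.4, abs=0.02)

    def test_empty_table_rejected(self):
        table = CommunityTable(pd.DataFrame(), pd.Series(dtype=object))
        with pytest.raises(ValidationError):
            aggregate_taxonomy(table, "phylum")


# ---------------------------------------------------------------------------
# weighted UniFrac

def _brute_force_unifrac(newick, table):
    """Independent oracle: recursive branch enumeration on the parsed tree."""
    from soilscape.io import read_tree_newick

    tree = read_tree_newick(newick)
    props = table.data.to_numpy(dtype=float)
    props = props / props.sum(axis=0)
    taxa = table.taxa
    branches = []  # (length, set of descendant leaf names)
    for node in tree.postorder(include_self=False):
        leafset = {t.name for t in node.tips(include_self=True)}
        branches.append((node.length or 0.0, leafset))
    n = props.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for length, leafset in branches:
                idx = [k for k, t in enumerate(taxa) if t in leafset]
                pa = props[idx, i].sum()
                pb = props[idx, j].sum()
                num += length * abs(pa - pb)
                den += length * (pa + pb)
            out[i, j] = num / den if den > 0 else 0.0
    return out


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        data = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["L1", "L2"])
        t = CommunityTable(data, pd.Series({"L1": "x", "L2": "x"}))
        d = weighted_unifrac(t, "(L1:1,L2:1);")
        assert d.values[0, 1] == 0.0

    def test_two_leaf_star_hand_oracle(self):
        # disjoint samples on a unit star: raw 2 / normalizer 2 = 1
        data = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["L1", "L2"])
        t = CommunityTable(data, pd.Series({"L1": "x", "L2": "x"}))
        d = weighted_unifrac(t, "(L1:1,L2:1);")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_metric_axioms(self):
        rng = np.random.default_rng(3)
        names = [f"T{i}" for i in range(6)]
        nwk = random_coalescent_tree(names, seed=3)
        counts = rng.integers(1, 40, (6, 4)).astype(float)
        t = CommunityTable(
            pd.DataFrame(counts, index=names, columns=list("wxyz")),
            pd.Series({n: "x" for n in names}),
        )
        d = weighted_unifrac(t.to_proportions(), nwk)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)
        assert d.values.min() >= 0 and d.values.max() <= 1 + 1e-12

    @pytest.mark.parametrize("seed", [11, 23, 37])
    def test_brute_force_oracle_random_8_leaf_trees(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"T{i}" for i in range(8)]
        nwk = random_coalescent_tree(names, seed=seed)
        counts = rng.integers(0, 30, (8, 5)).astype(float)
        counts[0] += 1  # no empty site
        t = CommunityTable(
            pd.DataFrame(counts, index=names, columns=list("abcde")),
            pd.Series({n: "x" for n in names}),
        ).to_proportions()
        ours = weighted_unifrac(t, nwk)
        oracle = _brute_force_unifrac(nwk, t)
        np.testing.assert_allclose(ours.values, oracle, atol=1e-12)

    def test_matches_skbio_reference(self):
        import skbio
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(5)
        names = [f"T{i}" for i in range(8)]
        nwk = random_coalescent_tree(names, seed=7)
        counts = rng.integers(0, 50, (8, 5))
        counts[0] += 1
        t = CommunityTable(
            pd.DataFrame(counts.astype(float), index=names, columns=list("abcde")),
            pd.Series({n: "x" for n in names}),
        ).to_proportions()
        ours = weighted_unifrac(t, nwk)
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        ref = beta_diversity(
            "weighted_unifrac", counts.T, ids=list("abcde"),
            taxa=names, tree=tree, normalized=True,
        )
        np.testing.assert_allclose(ours.values, ref.data, atol=1e-10)

    def test_missing_taxon_error_lists_names(self):
        data = pd.DataFrame({"a": [1.0, 1.0]}, index=["L1", "LX"])
        t = CommunityTable(data, pd.Series({"L1": "x", "LX": "x"}))
        with pytest.raises(SchemaError, match="LX"):
            weighted_unifrac(t.to_proportions(), "(L1:1,L2:1);")


# ---------------------------------------------------------------------------
# NMDS

def _random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 4))
    return DistanceMatrix([str(i) for i in range(n)], squareform(pdist(pts)))


class TestNMDS:
    def test_exact_2d_configuration_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((25, 2))
        d = DistanceMatrix([str(i) for i in range(25)], squareform(pdist(pts)))
        res = nmds(d, k=2, restarts=4, seed=0)
        assert res.stress < 0.01

    def test_stress_bounded(self):
        res = nmds(_random_distance_matrix(20, 1), k=2, restarts=4, seed=0)
        assert 0.0 <= res.stress <= 1.0

    def test_stress_nonincreasing_with_dimensions(self):
        d = _random_distance_matrix(25, 2)
        s2 = nmds(d, k=2, restarts=6, seed=0).stress
        s3 = nmds(d, k=3, restarts=6, seed=0).stress
        assert s3 <= s2 + 1e-6

    def test_restart_stability_across_master_seeds(self):
        d = _random_distance_matrix(30, 3)
        a = nmds(d, k=2, restarts=10, seed=101).stress
        b = nmds(d, k=2, restarts=10, seed=202).stress
        assert abs(a - b) < 1e-3

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValidationError):
            nmds(_random_distance_matrix(3, 0), k=2)


# ---------------------------------------------------------------------------
# soil PCA

class TestPCA:
    def test_component_scores_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((100, 5)), columns=list("abcde"))
        df["site_id"] = [str(i) for i in range(100)]
        res = pca_soil(df, list("abcde"))
        c = np.corrcoef(res.scores.T)
        assert np.abs(c[~np.eye(5, dtype=bool)]).max() < 1e-8

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        res = pca_soil(df, list("abcd"))
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_two_variable_eigenvalue_oracle(self):
        # 2x2 correlation matrix eigenvalues are 1 +/- r
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.standard_normal(500)
        df = pd.DataFrame({"a": x, "b": y})
        res = pca_soil(df, ["a", "b"])
        r = abs(np.corrcoef(x, y)[0, 1])
        assert res.explained[0] == pytest.approx((1 + r) / 2, abs=1e-10)

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.standard_normal(30), "b": rng.standard_normal(30),
                           "c": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_soil(df, ["a", "b", "c"])
        assert res.loadings.shape[0] == 2


# ---------------------------------------------------------------------------
# vector fitting

class TestFitVectors:
    def _ordination(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return OrdinationResult(
            [str(i) for i in range(n)], rng.standard_normal((n, 2)), "nmds", stress=0.1
        )

    def test_self_fit(self):
        ordn = self._ordination()
        vars_ = pd.DataFrame({"ax1": ordn.scores[:, 0]})
        (v,) = fit_vectors(ordn, vars_, n_perm=999, seed=0)
        assert v.r2 == pytest.approx(1.0, abs=1e-10)
        assert v.p_value == pytest.approx(1.0 / 1000.0)
        np.testing.assert_allclose(np.abs(v.direction), [1.0, 0.0], atol=1e-8)
        assert v.retained

    def test_r2_just_below_threshold_never_retained(self):
        # construct a variable with R^2 exactly 0.19 against the axes
        ordn = self._ordination(n=200, seed=1)
        rng = np.random.default_rng(2)
        S = ordn.scores - ordn.scores.mean(axis=0)
        s1 = S[:, 0] / np.linalg.norm(S[:, 0])
        e = rng.standard_normal(200)
        e = e - S @ np.linalg.lstsq(S, e, rcond=None)[0]
        e -= e.mean()
        e /= np.linalg.norm(e)
        y = np.sqrt(0.19) * s1 + np.sqrt(0.81) * e
        (v,) = fit_vectors(ordn, pd.DataFrame({"v": y}), n_perm=999, seed=3)
        assert v.r2 == pytest.approx(0.19, abs=1e-10)
        assert not v.retained
        # same construction at 0.21 is retained (p is tiny at n=200)
        y2 = np.sqrt(0.21) * s1 + np.sqrt(0.79) * e
        (v2,) = fit_vectors(ordn, pd.DataFrame({"v": y2}), n_perm=999, seed=3)
        assert v2.retained

    def test_constant_variable_skipped(self):
        ordn = self._ordination()
        with pytest.warns(UserWarning, match="constant"):
            out = fit_vectors(ordn, pd.DataFrame({"c": np.ones(60)}), n_perm=99, seed=0)
        assert out == []

    def test_direction_unit_norm(self):
        ordn = self._ordination(seed=5)
        rng = np.random.default_rng(6)
        vars_ = pd.DataFrame({"a": rng.standard_normal(60), "b": rng.standard_normal(60)})
        for v in fit_vectors(ordn, vars_, n_perm=99, seed=0):
            assert np.linalg.norm(v.direction) == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# property tests

@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_unifrac_bounded_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    names = [f"T{i}" for i in range(5)]
    nwk = random_coalescent_tree(names, seed=seed)
    counts = rng.integers(0, 20, (5, 3)).astype(float) + 0.01
    t = CommunityTable(
        pd.DataFrame(counts, index=names, columns=list("abc")),
        pd.Series({n: "x" for n in names}),
    ).to_proportions()
    d = weighted_unifrac(t, nwk)
    assert d.values.min() >= 0 and d.values.max() <= 1 + 1e-9


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=3, max_value=30), st.integers(min_value=0, max_value=10**6))
def test_rarefaction_closure_property(depth, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, (4, 3)).astype(float)
    counts[0] += depth  # guarantee every site reaches the depth
    t = CommunityTable(
        pd.DataFrame(counts, index=list("wxyz"), columns=list("abc")),
        pd.Series({k: "x" for k in "wxyz"}),
    )
    out = rarefy_counts(t, depth, seed=seed)
    assert (out.data.sum(axis=0) == depth).all()
    out2 = rarefy_counts(t, depth, seed=seed)
    pd.testing.assert_frame_equal(out.data, out2.data)
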