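import numpy as np
import pandas as pd
import pytest

from coexnet.module_detection import ModuleAssignment, compute_eigengenes
from coexnet.module_stats import (
    hub_genes,
    module_membership,
    module_trait_correlation,
    summarize_eigengene_by_category,
)
from coexnet.network import build_network
from coexnet.simulation import SimulationDesign, TraitLink, simulate_expression

from conftest import make_dataset
from oracles import t_sf_numeric


def eigengene_fixture(rng, n_samples=20, n_features=10):
    ds = make_dataset(rng.standard_normal((n_samples, n_features)))
    a = ModuleAssignment(labels=pd.Series([1] * n_features, index=ds.feature_ids))
    return ds, a, compute_eigengenes(ds, a)


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene(self, rng):
        ds, _, eig = eigengene_fixture(rng)
        meta = pd.DataFrame({"t": eig.eigengene(1)}, index=ds.sample_ids)
        out = module_trait_correlation(eig, meta).table
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p_value"].iloc[0] == pytest.approx(0.0, abs=1e-30)

    def test_orthogonal_trait_p_is_one(self, rng):
        ds, _, eig = eigengene_fixture(rng)
        e = eig.eigengene(1)
        raw = rng.standard_normal(len(e))
        ec = e - e.mean()
        ortho = raw - ec * (raw @ ec) / (ec @ ec)  # exactly uncorrelated
        meta = pd.DataFrame({"t": ortho}, index=ds.sample_ids)
        out = module_trait_correlation(eig, meta).table
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_p_value_against_numeric_t_oracle(self, rng):
        # r=0.5, n=20 -> t = 0.5*sqrt(18/0.75) = 2.4495, p ~ 0.0249
        ds, _, eig = eigengene_fixture(rng, n_samples=20)
        e = eig.eigengene(1)
        ec = (e - e.mean()) / np.linalg.norm(e - e.mean())
        raw = rng.standard_normal(20)
        ortho = raw - ec * (raw @ ec)
        ortho -= ortho.mean()  # keep orthogonality to ec after centering
        ortho = ortho - ec * (ortho @ ec)
        ortho /= np.linalg.norm(ortho)
        r = 0.5
        trait = r * ec + np.sqrt(1 - r**2) * ortho  # exact correlation 0.5
        out = module_trait_correlation(
            eig, pd.DataFrame({"t": trait}, index=ds.sample_ids)
        ).table
        assert out["r"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        t_stat = 0.5 * np.sqrt(18 / 0.75)
        expected = 2 * t_sf_numeric(t_stat, 18)
        assert expected == pytest.approx(0.0249, abs=5e-4)  # sanity of the oracle
        assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_categorical_one_hot_and_bh(self, rng):
        ds, _, eig = eigengene_fixture(rng)
        meta = pd.DataFrame(
            {"geno": ["wt"] * 10 + ["mut"] * 10, "age": rng.integers(4, 19, 20).astype(float)},
            index=ds.sample_ids,
        )
        res = module_trait_correlation(eig, meta)
        assert set(res.trait_encoding) == {"geno"}
        assert set(res.table["trait"]) == {"geno=wt", "geno=mut", "age"}
        ok = res.table.dropna()
        assert (ok["p_adjusted"] >= ok["p_value"] - 1e-15).all()
        assert ok["p_value"].between(0, 1).all()

    def test_constant_trait_undefined_with_warning(self, rng, caplog):
        ds, _, eig = eigengene_fixture(rng)
        meta = pd.DataFrame({"c": np.ones(20)}, index=ds.sample_ids)
        with caplog.at_level("WARNING"):
            out = module_trait_correlation(eig, meta).table
        assert np.isnan(out["r"].iloc[0])
        assert any("constant" in r.message for r in caplog.records)


class TestSummarizeEigengene:
    def test_single_level_mean_is_zero(self, rng):
        ds, _, eig = eigengene_fixture(rng)
        meta = pd.DataFrame({"grp": ["all"] * 20}, index=ds.sample_ids)
        out = summarize_eigengene_by_category(eig, meta, "grp")
        assert out["level_mean"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert out["level_n"].iloc[0] == 20

    def test_two_level_plus_minus_one(self):
        # craft a dataset whose single-module eigengene is +-1 by level
        e = np.array([1.0, 1, 1, -1, -1, -1]) * 1.0
        X = np.column_stack([e, e * 2, e * 3])
        ds = make_dataset(X + 0.0)
        a = ModuleAssignment(labels=pd.Series([1, 1, 1], index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        meta = pd.DataFrame({"g": ["hi"] * 3 + ["lo"] * 3}, index=ds.sample_ids)
        out = summarize_eigengene_by_category(eig, meta, "g")
        means = out.drop_duplicates(["module_label", "level"]).set_index("level")["level_mean"]
        assert means["hi"] == pytest.approx(-means["lo"])
        # a +-1 pattern scaled to unit sample variance is +-sqrt((n-1)/n)
        assert abs(means["hi"]) == pytest.approx(np.sqrt(5 / 6), rel=1e-6)

    def test_unknown_category_error(self, rng):
        ds, _, eig = eigengene_fixture(rng)
        with pytest.raises(ValueError, match="unknown"):
            summarize_eigengene_by_category(eig, ds.sample_meta, "nope")

    def test_trait_linked_module_separates_levels(self):
        design = SimulationDesign(
            module_sizes=(60,), n_background=0,
            trait_links=[TraitLink(0, "geno", 0.9, binary=True)], seed=4,
        )
        ds, truth, _ = simulate_expression(design)
        a = ModuleAssignment(labels=truth)
        eig = compute_eigengenes(ds, a)
        out = summarize_eigengene_by_category(eig, ds.sample_meta, "geno")
        means = out.drop_duplicates(["level"]).set_index("level")["level_mean"]
        assert abs(means["case"] - means["control"]) > 0.5


class TestMembershipAndHubs:
    def test_single_feature_module_kme_one(self, rng):
        X = rng.standard_normal((20, 3))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1, 2, 2], index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        assert abs(mem.kme.loc["g1", 1]) == pytest.approx(1.0)

    def test_kme_matches_direct_recomputation(self, rng):
        X = rng.standard_normal((25, 10))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1] * 5 + [2] * 5, index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        for label in (1, 2):
            e = eig.eigengene(label)
            for j, fid in enumerate(ds.feature_ids):
                direct = np.corrcoef(X[:, j], e)[0, 1]
                assert mem.kme.loc[fid, label] == pytest.approx(direct, abs=1e-12)

    def test_intramodular_connectivity_restricted_to_module(self, rng):
        X = rng.standard_normal((20, 6))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1, 1, 1, 2, 2, 2], index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        net = build_network(ds, power=2)
        mem = module_membership(ds, eig, net, a)
        adj = net.adjacency
        expected = adj[0, 1] + adj[0, 2]
        assert mem.intramodular_connectivity["g1"] == pytest.approx(expected, abs=1e-12)

    def test_planted_hub_ranked_first(self):
        design = SimulationDesign(
            module_sizes=(40,), n_background=0, within_module_cor=0.5,
            first_feature_loading_scale=2.0, seed=9,
        )
        ds, truth, _ = simulate_expression(design)
        a = ModuleAssignment(labels=truth)
        eig = compute_eigengenes(ds, a)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        hubs = hub_genes(mem, a, top_n=5)
        assert hubs[1].index[0] == "g00001"

    def test_tie_broken_lexicographically(self, rng):
        profile = rng.standard_normal(15)
        X = np.column_stack([profile, profile, profile])  # identical features
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1, 1, 1], index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        hubs = hub_genes(mem, a, top_n=3)
        assert hubs[1].index.tolist() == ["g1", "g2", "g3"]

    def test_small_module_returns_all_without_error(self, rng):
        ds, a, eig = eigengene_fixture(rng, n_features=4)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        hubs = hub_genes(mem, a, top_n=50)
        assert len(hubs[1]) == 4

    def test_top_n_validation(self, rng):
        ds, a, eig = eigengene_fixture(rng)
        net = build_network(ds, power=6)
        mem = module_membership(ds, eig, net, a)
        with pytest.raises(ValueError, match="top_n"):
            hub_genes(mem, a, top_n=0)
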