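"""Co-expression network construction: filtering, pseudobulk, power, TOM, modules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plaquenet.networks import (
    UNASSIGNED,
    adjacency_matrix,
    consensus_tom,
    detect_modules,
    merge_modules,
    filter_expressed_genes,
    make_metaspots,
    module_eigengenes,
    module_kme,
    project_modules,
    pseudobulk_log2cpm,
    select_soft_power,
    tom_matrix,
)
from plaquenet.simulate import SimulationConfig, make_hex_grid, simulate_sample, combine_samples
from plaquenet.types import CountsTable


def counts_from_matrix(values, regions_per_spot, sample="S1"):
    values = np.asarray(values)
    genes = pd.Index([f"g{i}" for i in range(values.shape[0])])
    spots = pd.Index([f"s{i}" for i in range(values.shape[1])])
    counts = CountsTable(genes, spots, values, np.array([sample] * values.shape[1]))
    return counts, pd.Series(regions_per_spot, index=spots)


def planted_block_expression(n_obs=80, block_sizes=(60, 60), n_noise=20,
                             factor_cor=0.0, seed=0, noise_sd=0.3):
    """Two latent factors (optionally correlated), one per gene block."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, factor_cor], [factor_cor, 1.0]])
    f = rng.multivariate_normal([0, 0], cov, size=n_obs)
    cols, names, truth = [], [], []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            cols.append(f[:, b] + rng.normal(0, noise_sd, n_obs))
            names.append(f"blk{b}_g{i}")
            truth.append(b)
    for i in range(n_noise):
        cols.append(rng.normal(0, 1, n_obs))
        names.append(f"noise_g{i}")
        truth.append(-1)
    expr = pd.DataFrame(np.column_stack(cols), columns=names)
    return expr, pd.Series(truth, index=names)


class TestFilter:
    def _counts(self, frac_by_region):
        # 1 gene, 100 spots per region, expressed in the given fractions
        n = 100
        rows = []
        regions = []
        vals = []
        for region, frac in frac_by_region.items():
            v = np.zeros(n, dtype=int)
            v[: int(round(frac * n))] = 1
            vals.append(v)
            regions.extend([region] * n)
        return counts_from_matrix(np.concatenate(vals)[None, :], regions)

    def test_below_threshold_everywhere_dropped(self):
        counts, regions = self._counts({"L1": 0.04, "WM": 0.04})
        assert filter_expressed_genes(counts, regions) == []

    def test_exactly_five_percent_kept(self):
        counts, regions = self._counts({"L1": 0.05, "WM": 0.0})
        assert filter_expressed_genes(counts, regions) == ["g0"]

    def test_zero_threshold_keeps_everything(self):
        counts, regions = self._counts({"L1": 0.0})
        assert filter_expressed_genes(counts, regions, min_frac=0.0) == ["g0"]


class TestPseudobulk:
    def test_worked_cpm_example(self):
        counts, regions = counts_from_matrix([[90], [10]], ["L1"])
        pb = pseudobulk_log2cpm(counts, regions)
        assert pb.iloc[0, 0] == pytest.approx(np.log2(900000 + 1))
        assert pb.iloc[0, 1] == pytest.approx(np.log2(100000 + 1))

    def test_cpm_scale_invariance(self):
        c1, r1 = counts_from_matrix([[90, 0], [10, 0]], ["L1", "L2"])
        c2, r2 = counts_from_matrix([[180, 0], [20, 0]], ["L1", "L2"])
        pb1 = pseudobulk_log2cpm(c1, r1)
        pb2 = pseudobulk_log2cpm(c2, r2)
        assert np.allclose(pb1.loc[("S1", "L1")], pb2.loc[("S1", "L1")])

    def test_cpm_rows_sum_to_1e6_pre_log(self, default_sample):
        counts, regions, _ = combine_samples([default_sample])
        pb = pseudobulk_log2cpm(counts, regions)
        cpm = 2.0 ** pb.to_numpy() - 1.0
        assert np.allclose(cpm.sum(axis=1), 1e6, rtol=1e-6)

    def test_empty_region_yields_no_row(self):
        counts, regions = counts_from_matrix([[0, 5], [0, 5]], ["L1", "L2"])
        with pytest.warns(UserWarning, match="zero total UMI"):
            pb = pseudobulk_log2cpm(counts, regions)
        assert ("S1", "L1") not in pb.index


class TestSoftPower:
    def test_scale_free_generator_passes(self):
        # exact construction: gene i = r_i * e + noise with r_i = (i/n)^(gamma/beta),
        # so unsigned connectivity at power beta is a power law in rank
        rng = np.random.default_rng(7)
        n_genes, n_obs = 80, 4000
        r = (np.arange(1, n_genes + 1) / n_genes) ** (2.0 / 6.0)
        e = rng.normal(size=n_obs)
        X = np.outer(e, r) + rng.normal(size=(n_obs, n_genes)) * np.sqrt(1 - r**2)
        cfg = select_soft_power(pd.DataFrame(X), network_type="unsigned")
        assert cfg.passed
        assert cfg.fit_by_power[cfg.chosen_power] > 0.8

    def test_iid_noise_does_not_pass(self):
        rng = np.random.default_rng(8)
        noise = pd.DataFrame(rng.normal(size=(60, 40)))
        assert not select_soft_power(noise, network_type="unsigned").passed
        assert not select_soft_power(noise, network_type="signed").passed

    def test_chosen_power_is_smallest_passing(self):
        rng = np.random.default_rng(9)
        n_genes, n_obs = 60, 2000
        r = (np.arange(1, n_genes + 1) / n_genes) ** (2.0 / 6.0)
        e = rng.normal(size=n_obs)
        X = np.outer(e, r) + rng.normal(size=(n_obs, n_genes)) * np.sqrt(1 - r**2)
        cfg = select_soft_power(pd.DataFrame(X), network_type="unsigned")
        smaller = [p for p in cfg.candidate_powers if p < cfg.chosen_power]
        assert all(cfg.fit_by_power[p] <= 0.8 or not p for p in smaller)


class TestTom:
    def test_two_gene_closed_form(self):
        # for 2 genes TOM_12 reduces to a_12 exactly
        rng = np.random.default_rng(1)
        e = rng.normal(size=(30, 2))
        e[:, 1] = 0.7 * e[:, 0] + 0.3 * e[:, 1]
        expr = pd.DataFrame(e, columns=["a", "b"])
        adj = adjacency_matrix(expr, 6).to_numpy()
        tom = tom_matrix(expr, 6)
        assert tom.loc["a", "b"] == pytest.approx(adj[0, 1], abs=1e-12)

    def test_duplicated_gene_tom_one(self):
        # two identical genes: a_12 = 1 and TOM_12 = a_12 exactly
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        expr = pd.DataFrame({"a": x, "b": x})
        tom = tom_matrix(expr, 6)
        assert tom.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("power", [2, 6])
    def test_matches_triple_loop_oracle(self, power, tom_oracle):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(25, 10)),
                            columns=[f"g{i}" for i in range(10)])
        adj = adjacency_matrix(expr, power).to_numpy()
        tom = tom_matrix(expr, power).to_numpy()
        assert np.max(np.abs(tom - tom_oracle(adj))) < 1e-12

    def test_entries_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(30, 20)))
        expr.columns = [f"g{i}" for i in range(20)]
        tom = tom_matrix(expr, 6).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, truth = planted_block_expression(n_noise=0, seed=10)
        tom = tom_matrix(expr, 6)
        # static cut placed between within-block (~0.3) and between-block
        # (~0.95) average dissimilarity
        labels = detect_modules(tom, expr, min_module_size=50, cut_height=0.9)
        planted = truth[truth >= 0]
        ari = adjusted_rand_score(planted, labels[planted.index])
        assert ari == 1.0
        assert labels[planted.index].nunique() == 2
        assert (labels != UNASSIGNED).all()

    def test_block_below_min_size_unassigned(self):
        expr, truth = planted_block_expression(block_sizes=(60, 30), seed=11)
        tom = tom_matrix(expr, 6)
        labels = detect_modules(tom, expr, min_module_size=50, cut_height=0.9)
        small_block = truth[truth == 1].index
        assert (labels[small_block] == UNASSIGNED).all()

    def test_highly_correlated_blocks_merge(self):
        # one pipeline check: blocks whose factors correlate 0.95 collapse to
        # a single module (0.95 > 1 - merge_height = 0.9), whether the tree
        # cut or the eigengene merge does it
        expr, truth = planted_block_expression(factor_cor=0.95, n_noise=0, seed=12)
        tom = tom_matrix(expr, 6)
        labels = detect_modules(tom, expr, min_module_size=50, merge_height=0.1,
                                cut_height=0.9)
        planted = truth[truth >= 0]
        assert labels[planted.index].nunique() == 1

    def test_merge_rule_joins_correlated_partition(self):
        # start from an artificial split of one block: the two halves' MEs
        # correlate ~0.99 > 0.9, so the merge loop must reunite them, while
        # an independent block stays separate
        expr, truth = planted_block_expression(n_noise=0, seed=13)
        blk0 = list(truth[truth == 0].index)
        blk1 = list(truth[truth == 1].index)
        init = pd.Series(-1, index=expr.columns, dtype=int)
        init[blk0[:30]] = 1
        init[blk0[30:]] = 2
        init[blk1] = 3
        merged = merge_modules(init, expr, merge_height=0.1)
        assert merged[blk0].nunique() == 1
        assert merged[blk1].nunique() == 1
        assert merged[blk0[0]] != merged[blk1[0]]

    def test_uncorrelated_modules_not_merged(self):
        expr, truth = planted_block_expression(n_noise=0, seed=14)
        init = pd.Series(-1, index=expr.columns, dtype=int)
        init[truth[truth == 0].index] = 1
        init[truth[truth == 1].index] = 2
        merged = merge_modules(init, expr, merge_height=0.1)
        assert merged.nunique() == 2


class TestEigengenes:
    def test_rank_one_module_correlates_perfectly_with_genes(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=50)
        expr = pd.DataFrame({"a": 2 * x + 1, "b": -3 * x})
        me = module_eigengenes(expr, {"M1": ["a", "b"]})
        # two perfectly correlated genes (up to sign): |cor| = 1, sign fix
        # aligns the eigengene with the mean standardized expression
        r = np.corrcoef(me["M1"], expr["a"])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_sign_rule_positive_on_aligned_module(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=50)
        expr = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.1, 50)})
        me = module_eigengenes(expr, {"M1": ["a", "b"]})
        assert np.corrcoef(me["M1"], expr["a"])[0, 1] > 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(22)
        expr = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        me = module_eigengenes(expr, {"M1": list("abcd")})
        perm = rng.permutation(30)
        me_perm = module_eigengenes(expr.iloc[perm], {"M1": list("abcd")})
        assert np.allclose(me["M1"].to_numpy()[perm], me_perm["M1"].to_numpy())

    def test_pc1_beats_random_projections(self):
        rng = np.random.default_rng(23)
        expr = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        me = module_eigengenes(expr, {"M1": list(expr.columns)})
        z = (expr - expr.mean()) / expr.std(ddof=0)
        var_me = np.var((z.to_numpy() @ np.linalg.lstsq(
            z.to_numpy(), me["M1"].to_numpy(), rcond=None)[0]))
        explained = []
        for _ in range(200):
            w = rng.normal(size=6)
            w /= np.linalg.norm(w)
            explained.append(np.var(z.to_numpy() @ w))
        # ME is the first PC: no random unit projection explains more variance
        me_var = np.var(z.to_numpy() @ (np.linalg.svd(z.to_numpy())[2][0]))
        assert me_var >= max(explained) - 1e-9


class TestKme:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=50)
        expr = pd.DataFrame({"a": x, "b": x})
        me = module_eigengenes(expr, {"M1": ["a", "b"]})
        kme = module_kme(expr, me)
        assert kme.loc["a", "M1"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_gene_near_zero(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=2000)
        expr = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=2000)})
        me = module_eigengenes(expr, {"M1": ["a", "b"]})
        kme = module_kme(expr, me)
        assert abs(kme.loc["c", "M1"]) < 0.1

    def test_bounded(self):
        rng = np.random.default_rng(32)
        expr = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        me = module_eigengenes(expr, {"M1": list("abc"), "M2": list("de")})
        kme = module_kme(expr, me).to_numpy()
        assert (np.abs(kme) <= 1 + 1e-12).all()


class TestProjection:
    def test_self_projection_reproduces_me(self):
        expr, truth = planted_block_expression(seed=40)
        modules = {"M1": list(truth[truth == 0].index), "M2": list(truth[truth == 1].index)}
        me = module_eigengenes(expr, modules)
        projected, skipped = project_modules(modules, expr)
        assert skipped == []
        for m in modules:
            assert abs(np.corrcoef(me[m], projected[m])[0, 1]) > 0.999

    def test_half_missing_genes_still_tracks_factor(self):
        rng = np.random.default_rng(41)
        expr, truth = planted_block_expression(seed=41)
        modules = {"M1": list(truth[truth == 0].index)}
        me_full = module_eigengenes(expr, modules)
        kept = list(rng.choice(modules["M1"], size=30, replace=False))
        projected, _ = project_modules(modules, expr[kept + ["noise_g0"]])
        assert np.corrcoef(me_full["M1"], projected["M1"])[0, 1] > 0.8

    def test_module_absent_from_query_is_listed(self):
        expr, truth = planted_block_expression(seed=42)
        modules = {"M1": list(truth[truth == 0].index), "Mx": ["not_there1", "not_there2"]}
        projected, skipped = project_modules(modules, expr)
        assert skipped == ["Mx"]
        assert list(projected.columns) == ["M1"]


class TestMetaspots:
    def test_identity_at_bin_one(self, default_sample):
        grid, counts = default_sample.grid, default_sample.counts
        mgrid, mcounts = make_metaspots(grid, counts, bin_width_spots=1)
        assert len(mgrid) == len(grid)
        assert mcounts.values.sum() == counts.values.sum()

    def test_total_umi_conserved(self, default_sample):
        _, mcounts = make_metaspots(default_sample.grid, default_sample.counts, 2)
        assert mcounts.values.sum() == default_sample.counts.values.sum()

    def test_4x4_lattice_bins_to_four(self):
        cfg = SimulationConfig(seed=0, n_rows=4, n_cols=4, n_genes=10, n_modules=1,
                               module_size=2, region_layout=("L1",))
        s = simulate_sample(cfg)
        mgrid, mcounts = make_metaspots(s.grid, s.counts, 2)
        assert len(mgrid) == 4
        assert mcounts.n_spots == 4


class TestConsensusTom:
    def _toms(self, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(3):
            expr = pd.DataFrame(rng.normal(size=(30, 12)),
                                columns=[f"g{i}" for i in range(12)])
            out.append(tom_matrix(expr, 6))
        return out

    def test_identical_inputs_pass_through(self):
        t = self._toms(1)[0]
        cons = consensus_tom([t, t.copy()])
        assert np.allclose(cons.to_numpy(), t.to_numpy(), atol=1e-12)

    def test_consensus_below_each_scaled_input(self):
        toms = self._toms(2)
        cons = consensus_tom(toms)
        # min property holds for the first (unscaled reference) TOM
        assert (cons.to_numpy() <= toms[0].to_numpy() + 1e-12).all()

    def test_symmetric_output(self):
        cons = consensus_tom(self._toms(3)).to_numpy()
        assert np.allclose(cons, cons.T)
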