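import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from rps12evo.dating import pl_date
from rps12evo.likelihood import fit_mg94
from rps12evo.phylo import Tree
from rps12evo.rate_tests import (
    DegenerateSampleError,
    absolute_rates,
    classify_branches,
    compare_type_rates,
    region_pairwise,
    region_tests,
    type_lrt,
    wilcoxon_rank_sum,
)
from rps12evo.synthetic_data import (
    SimConfig,
    simulate_bundle,
    tip_type_map,
)


class TestClassifyBranches:
    def test_all_type_I(self):
        tree = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        labeled = classify_branches(tree, {t: "I" for t in "abcd"})
        assert all(n.klass == "typeI" for n in labeled.postorder())

    def test_single_clade_with_stem(self):
        tree = Tree.from_newick(
            "(((a:1,b:1):1,c:1):1,((d:1,e:1):1,f:1):1);"
        )
        types = {t: "II" if t in "de" else "I" for t in "abcdef"}
        labeled = classify_branches(tree, types)
        type2 = [n for n in labeled.branches() if n.klass == "typeII"]
        # two terminals plus the stem of the (d,e) cherry
        assert len(type2) == 3
        keys = {labeled.clade_key(n) for n in type2}
        assert frozenset({"d", "e"}) in keys

    def test_three_tip_clade_has_five_typeII_branches(self):
        tree = Tree.from_newick(
            "(((a:1,b:1):1,c:1):1,((d:1,e:1):1,f:1):1);"
        )
        types = {t: "II" if t in "def" else "I" for t in "abcdef"}
        labeled = classify_branches(tree, types)
        type2 = [n for n in labeled.branches() if n.klass == "typeII"]
        assert len(type2) == 5  # 3 terminal + 1 internal + 1 stem

    def test_two_independent_clades_disjoint(self, default_bundle):
        tree = default_bundle.tree
        types = tip_type_map(tree)
        labeled = classify_branches(tree, types)
        type2_keys = [
            labeled.clade_key(n)
            for n in labeled.branches()
            if n.klass == "typeII"
        ]
        maximal = [
            k for k in type2_keys
            if not any(k < other for other in type2_keys)
        ]
        assert len(maximal) == 2
        assert not (maximal[0] & maximal[1])

    def test_unlabeled_tip_rejected(self):
        tree = Tree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="without a gene-type"):
            classify_branches(tree, {"a": "I"})


class TestAbsoluteRates:
    def _trees(self):
        nwk = "((a:{0},b:{0}):{0},c:{0});"
        ds = Tree.from_newick(nwk.format(0.02))
        dn = Tree.from_newick(nwk.format(0.004))
        chron = Tree.from_newick(nwk.format(10.0))
        chron.set_ages_from_lengths()
        return ds, dn, chron

    def test_simple_arithmetic(self):
        ds, dn, chron = self._trees()
        table = absolute_rates(ds, dn, chron)
        assert np.allclose(table.R_S, 0.002)
        assert np.allclose(table.R_N, 0.0004)
        assert not table.flagged.any()

    def test_zero_dn_gives_zero_rate(self):
        ds, dn, chron = self._trees()
        for n in dn.branches():
            n.length = 0.0
        table = absolute_rates(ds, dn, chron)
        assert np.allclose(table.R_N, 0.0)

    def test_short_duration_flagged(self):
        ds, dn, chron = self._trees()
        leaf = next(n for n in chron.branches() if n.is_leaf and n.name == "c")
        leaf.age = chron.root.age - 0.01  # dt = 0.01 My < floor
        table = absolute_rates(ds, dn, chron)
        assert table.flagged.sum() == 1
        assert table.loc[table.flagged, "R_S"].isna().all()

    def test_topology_mismatch_rejected(self):
        ds, dn, chron = self._trees()
        other = Tree.from_newick("((a:1,c:1):1,b:1);")
        other.set_ages_from_lengths()
        with pytest.raises(ValueError, match="topology mismatch"):
            absolute_rates(ds, dn, other)


class TestWilcoxon:
    def test_exact_enumeration_reference(self):
        rep = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert rep.method == "wilcoxon_exact"
        assert rep.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        rep = wilcoxon_rank_sum([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])
        assert rep.p_value <= 1.0
        rep2 = wilcoxon_rank_sum([1, 3, 5], [2, 4, 6])
        assert rep2.p_value > 0.5

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            mine = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_close_to_exact_at_boundary(self):
        # a draw whose p sits near the 5% decision region
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = rng.normal(0.5, size=8)
        exact = wilcoxon_rank_sum(x, y)  # n+m=16 -> exact
        asym = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        assert exact.method == "wilcoxon_exact"
        assert exact.p_value == pytest.approx(float(asym.pvalue), abs=0.01)

    def test_ties_fall_back_to_normal(self):
        rep = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert rep.method == "wilcoxon_normal"
        assert 0 <= rep.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(
        nx=st.integers(2, 6),
        ny=st.integers(2, 6),
        seed=st.integers(0, 500),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_one_sided_tails_sum(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=nx)
        y = rng.normal(size=ny)
        lo = wilcoxon_rank_sum(x, y, alternative="less").p_value
        hi = wilcoxon_rank_sum(x, y, alternative="greater").p_value
        two = wilcoxon_rank_sum(x, y, alternative="two-sided").p_value
        # exact tails overlap in exactly the observed value's probability,
        # and the two-sided p doubles the smaller tail (capped at 1)
        assert lo + hi >= 1.0
        assert two == pytest.approx(min(1.0, 2.0 * min(lo, hi)), abs=1e-12)


class TestCompareTypeRates:
    def _table(self, rng, shift=0.0):
        rows = []
        for i in range(10):
            rows.append(
                dict(branch_class="typeI", R_S=rng.lognormal(0, 0.3),
                     R_N=rng.lognormal(-2, 0.3), TI=rng.lognormal(0, 0.3),
                     TV=rng.lognormal(-1, 0.3), flagged=False)
            )
        for i in range(8):
            rows.append(
                dict(branch_class="typeII", R_S=rng.lognormal(shift, 0.3),
                     R_N=rng.lognormal(-2, 0.3), TI=rng.lognormal(0, 0.3),
                     TV=rng.lognormal(-1, 0.3), flagged=False)
            )
        return pd.DataFrame(rows)

    def test_four_reports(self, rng):
        reports = compare_type_rates(self._table(rng))
        assert len(reports) == 4
        assert [r.comparison.split(":")[0] for r in reports] == [
            "R_S", "R_N", "TI", "TV",
        ]

    def test_planted_rs_shift_detected(self, rng):
        hits = 0
        for rep in range(40):
            table = self._table(rng, shift=np.log(3.0))
            reports = compare_type_rates(table)
            rs = reports[0]
            if rs.p_value < 0.05 and rs.direction == "x>y":
                hits += 1
        assert hits >= 36  # >= 90% power at a 3x shift

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        n = 200
        for rep in range(n):
            table = self._table(rng, shift=0.0)
            rs = compare_type_rates(table, quantities=("R_S",))[0]
            rejections += rs.p_value < 0.05
        assert 0.02 <= rejections / n <= 0.09

    def test_holm_adjustment_never_smaller_and_monotone(self, rng):
        table = self._table(rng, shift=np.log(2.0))
        raw = compare_type_rates(table)
        adj = compare_type_rates(table, adjust="holm")
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15
            assert a.p_value <= 1.0
            assert a.method.endswith("+holm")
        # Holm preserves the ordering of evidence
        raw_order = np.argsort([r.p_value for r in raw])
        adj_sorted = np.array([a.p_value for a in adj])[raw_order]
        assert np.all(np.diff(adj_sorted) >= -1e-15)

    def test_degenerate_class_rejected(self, rng):
        table = self._table(rng)
        table = table[table.branch_class != "typeII"].copy()
        table.loc[len(table)] = dict(
            branch_class="typeII", R_S=1.0, R_N=0.1, TI=1.0, TV=0.5,
            flagged=False,
        )
        with pytest.raises(DegenerateSampleError):
            compare_type_rates(table)


class TestTypeLRT:
    def test_statistic_definition_and_df(self, small_bundle):
        b = small_bundle
        types = tip_type_map(b.tree)
        res, f0, f1 = type_lrt(b.alignment, b.tree, types, quantity="titv")
        assert res.df == 1
        assert res.statistic == pytest.approx(2 * (f1.lnL - f0.lnL), abs=1e-9)
        assert 0 <= res.p_value <= 1


class TestRegionAnalysis:
    def test_identical_outgroup_zero_ds(self, small_bundle):
        aln = small_bundle.alignment
        t0 = aln.taxa[0]
        fern = {t0: aln.row(t0)}
        og = {"og": list(aln.row(t0))}
        table = region_pairwise(fern, og, aln.partition)
        assert len(table) == 2
        assert np.allclose(table.dS, 0.0)
        assert np.allclose(table.TI, 0.0)

    def test_row_count_contract(self, small_bundle):
        aln = small_bundle.alignment
        ferns = {t: aln.row(t) for t in aln.taxa[:3]}
        ogs = {t: aln.row(t) for t in aln.taxa[3:5]}
        table = region_pairwise(ferns, ogs, aln.partition)
        assert len(table) == 3 * 2 * 2

    def test_small_region_warns(self, small_bundle):
        aln = small_bundle.alignment
        part = ["SC"] * 5 + ["IR"] * (aln.ncodons - 5)
        with pytest.warns(UserWarning, match="region SC"):
            region_pairwise(
                {aln.taxa[0]: aln.row(aln.taxa[0])},
                {aln.taxa[1]: aln.row(aln.taxa[1])},
                part,
            )

    def test_paired_signed_rank_option(self, small_bundle):
        aln = small_bundle.alignment
        ferns = {t: aln.row(t) for t in aln.taxa[:4]}
        ogs = {t: aln.row(t) for t in aln.taxa[6:8]}
        table = region_pairwise(ferns, ogs, aln.partition)
        out = region_tests(table, paired=True)
        for rep in out["wilcoxon"]:
            assert rep.method == "wilcoxon_signed_rank"
            assert 0 <= rep.p_value <= 1
            assert rep.n_x == 4 * 2  # one difference per (taxon, outgroup)

    def test_region_tests_structure(self, small_bundle):
        b = small_bundle
        aln = b.alignment
        ferns = {t: aln.row(t) for t in aln.taxa[:4]}
        ogs = {t: aln.row(t) for t in aln.taxa[6:7]}
        table = region_pairwise(ferns, ogs, aln.partition)
        labeled = classify_branches(b.tree, tip_type_map(b.tree))
        out = region_tests(table, alignment=aln, tree=labeled)
        assert {r.comparison.split(":")[0] for r in out["wilcoxon"]} == {
            "dS", "TI", "TV",
        }
        assert out["lrt"]["omega_region"].df == 1
        assert out["lrt"]["titv_region"].df == 1
        for res in out["lrt"].values():
            assert 0 <= res.p_value <= 1


class TestEndToEndRecovery:
    def test_planted_typeII_rate_ratio(self):
        """R_S(typeII)/R_S(typeI) recovered within 25% from the pipeline."""
        cfg = SimConfig(
            seed=31, n_taxa=10, n_codons=668, typeII_clades=[4],
            rate_by_class={"typeI": 1.0, "typeII": 2.0},
        )
        b = simulate_bundle(cfg)
        fit = fit_mg94(b.tree, b.alignment, omega_mode="global")
        from rps12evo.subst_models import decompose_sn

        ds = fit.tree.copy()
        dn = fit.tree.copy()
        for node_s, node_n in zip(ds.branches(), dn.branches()):
            s, nn = decompose_sn(fit.model, "typeI" if "typeI" in fit.model.omega_by_class else "all", node_s.length)
            node_s.length, node_n.length = s, nn
        chron = pl_date(fit.tree, 354.0, 1.0, nsites=3 * b.alignment.ncodons, seed=0)
        table = absolute_rates(ds, dn, chron)
        med2 = table.loc[table.branch_class == "typeII", "R_S"].median()
        med1 = table.loc[table.branch_class == "typeI", "R_S"].median()
        assert med2 / med1 == pytest.approx(2.0, rel=0.25)
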