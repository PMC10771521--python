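"""Aesthetic phenotypes: agreement, UR pairs, mm2, bias, PCA, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from twintaste import metrics as me
from twintaste.qc import RatingMatrix
from twintaste.stats import fisher_z


def _matrix(values, families, orders, sexes=None, ages=None, domain="toy"):
    n = len(values)
    ids = [f"I{f}_{o}" for f, o in zip(families, orders)]
    vals = pd.DataFrame(np.asarray(values, dtype=float),
                        index=pd.Index(ids, name="individual_id"),
                        columns=[f"img{j}" for j in range(len(values[0]))])
    meta = pd.DataFrame({
        "family_id": families,
        "twin_order": orders,
        "zygosity": ["MZ"] * n,
        "sex": sexes or ["F"] * n,
        "age": ages or [30.0] * n,
    }, index=vals.index)
    return RatingMatrix(domain, vals, meta)


class TestPairwiseAgreement:
    def test_extremes_and_formula(self, toy_matrix):
        m = _matrix([[1, 2, 3], [1, 2, 3], [3, 2, 1], [1, 1, 1]],
                    [0, 0, 1, 1], [1, 2, 1, 2])
        rec = me.pairwise_agreement(m, "I0_1", "I0_2")
        assert rec.r_inter == pytest.approx(1.0)
        assert rec.clipped and np.isfinite(rec.z_inter)
        assert rec.pair_class == "MZ"
        rec2 = me.pairwise_agreement(m, "I0_1", "I1_1")
        assert rec2.r_inter == pytest.approx(-1.0)
        assert rec2.pair_class == "UR"
        with pytest.raises(ValueError, match="constant"):
            me.pairwise_agreement(m, "I0_1", "I1_2")
        # brute-force Pearson on a random pair
        a, b = toy_matrix.row("I0_1"), toy_matrix.row("I1_2")
        expected = np.corrcoef(a, b)[0, 1]
        got = me.pairwise_agreement(toy_matrix, "I0_1", "I1_2").r_inter
        assert got == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance_of_agreement(self, toy_matrix):
        shifted = RatingMatrix(toy_matrix.domain, toy_matrix.values.copy(),
                               toy_matrix.meta)
        shifted.values.loc["I0_1"] += 2.5
        r0 = me.pairwise_agreement(toy_matrix, "I0_1", "I1_1").r_inter
        r1 = me.pairwise_agreement(shifted, "I0_1", "I1_1").r_inter
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestUnrelatedPairs:
    def test_two_families_cross_pairing(self):
        m = _matrix(np.random.default_rng(0).normal(4, 1, (4, 5)),
                    [0, 0, 1, 1], [1, 2, 1, 2])
        recs, unpaired = me.make_unrelated_pairs(m, seed=1)
        assert len(recs) == 2 and not unpaired
        for r in recs:
            f1 = m.meta.loc[r.member1, "family_id"]
            f2 = m.meta.loc[r.member2, "family_id"]
            assert f1 != f2
            assert r.pair_class == "UR"

    def test_sex_matching_leaves_odd_member_unpaired(self):
        m = _matrix(np.random.default_rng(1).normal(4, 1, (6, 5)),
                    [0, 0, 1, 1, 2, 2], [1, 2, 1, 2, 1, 2],
                    sexes=["M", "M", "M", "M", "F", "F"])
        recs, unpaired = me.make_unrelated_pairs(m, seed=2)
        # the lone female second member cannot be paired outside her family
        assert len(recs) == 2
        assert set(unpaired) == {"I2_2", "I2_1"}

    def test_greedy_matches_exhaustive_on_separated_ages(self):
        """With well-separated ages the greedy assignment is the optimum."""
        ages = [20.0, 20.0, 35.0, 35.0, 50.0, 50.0, 21.0, 21.0, 36.0, 36.0,
                51.0, 51.0]
        fams = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        orders = [1, 2] * 6
        m = _matrix(np.random.default_rng(2).normal(4, 1, (12, 5)),
                    fams, orders, ages=ages)
        recs, unpaired = me.make_unrelated_pairs(m, seed=3)
        assert not unpaired
        total = sum(abs(m.meta.loc[r.member1, "age"] - m.meta.loc[r.member2, "age"])
                    for r in recs)
        # exhaustive assignment over all second->first bijections
        seconds = [i for i in m.individuals if m.meta.loc[i, "twin_order"] == 2]
        firsts = [i for i in m.individuals if m.meta.loc[i, "twin_order"] == 1]
        best = np.inf
        for perm in itertools.permutations(firsts):
            if any(m.meta.loc[s, "family_id"] == m.meta.loc[f, "family_id"]
                   for s, f in zip(seconds, perm)):
                continue
            cost = sum(abs(m.meta.loc[s, "age"] - m.meta.loc[f, "age"])
                       for s, f in zip(seconds, perm))
            best = min(best, cost)
        assert total == pytest.approx(best)

    def test_deterministic_given_seed(self):
        m = _matrix(np.random.default_rng(4).normal(4, 1, (8, 5)),
                    [0, 0, 1, 1, 2, 2, 3, 3], [1, 2] * 4,
                    ages=[20, 20, 21, 21, 22, 22, 23, 23])
        r1, _ = me.make_unrelated_pairs(m, seed=5)
        r2, _ = me.make_unrelated_pairs(m, seed=5)
        assert [(r.member1, r.member2) for r in r1] == \
               [(r.member1, r.member2) for r in r2]


class TestIndividualMetrics:
    def test_mm2_brute_force_and_perfect_typicality(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(4, 1, (6, 8))
        m = _matrix(vals, [0, 0, 1, 1, 2, 2], [1, 2] * 3)
        # brute-force leave-two-out mean for I0_1: exclude family 0
        ref = vals[2:].mean(axis=0)
        expected = np.corrcoef(vals[0], ref)[0, 1]
        r, z = me.taste_typicality_mm2(m, "I0_1")
        assert r == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(fisher_z(expected), abs=1e-12)
        # an individual equal to the leave-two-out mean has mm2 = 1
        vals2 = vals.copy()
        vals2[0] = ref
        m2 = _matrix(vals2, [0, 0, 1, 1, 2, 2], [1, 2] * 3)
        r2, _ = me.taste_typicality_mm2(m2, "I0_1")
        assert r2 == pytest.approx(1.0)

    def test_mm2_shift_invariance_bias_shifts_exactly(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(4, 1, (6, 8))
        m = _matrix(vals, [0, 0, 1, 1, 2, 2], [1, 2] * 3)
        r0, _ = me.taste_typicality_mm2(m, "I0_1")
        b0 = me.evaluation_bias(m, "I0_1")
        vals_shift = vals.copy()
        vals_shift[0] += 1.7
        ms = _matrix(vals_shift, [0, 0, 1, 1, 2, 2], [1, 2] * 3)
        r1, _ = me.taste_typicality_mm2(ms, "I0_1")
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert me.evaluation_bias(ms, "I0_1") == pytest.approx(b0 + 1.7, abs=1e-12)

    def test_evaluation_bias_is_row_mean(self, toy_matrix):
        assert me.evaluation_bias(toy_matrix, "I1_1") == pytest.approx(
            toy_matrix.values.loc["I1_1"].mean())
        m = _matrix([[7, 7, 7], [1, 3, 5], [2, 2, 2], [4, 4, 4]],
                    [0, 0, 1, 1], [1, 2, 1, 2])
        assert me.evaluation_bias(m, "I0_1") == 7.0
        assert me.evaluation_bias(m, "I0_2") == 3.0


class TestPrincipalAxes:
    def test_rank_one_bias_matrix(self):
        # pure bias differences: every row is a constant offset of a base row
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        offs = np.array([0.0, 1.0, -1.0, 2.0])
        vals = base[None, :] + offs[:, None]
        m = _matrix(vals, [0, 0, 1, 1], [1, 2, 1, 2])
        pa = me.principal_axes(m, n_axes=2)
        assert pa.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_axes_orthogonal_and_sign_alignment(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(4, 1, (20, 10))
        fams = np.repeat(np.arange(10), 2)
        m = _matrix(vals, list(fams), [1, 2] * 10)
        bias = vals.mean(axis=1)
        pa = me.principal_axes(m, n_axes=3, align_bias=bias)
        s = pa.scores.to_numpy()
        assert abs(s[:, 0] @ s[:, 1]) < 1e-8
        assert abs(s[:, 1] @ s[:, 2]) < 1e-8
        assert np.corrcoef(s[:, 0], bias)[0, 1] >= 0


class TestAgreementAnova:
    @staticmethod
    def _records(rng, means, n=40):
        rows = []
        for (cls, dom), mu in means.items():
            for _ in range(n):
                z = rng.normal(mu, 0.3)
                rows.append(dict(pair_class=cls, member1="a", member2="b",
                                 domain=dom, sex="F", mean_age=30.0,
                                 r_inter=np.tanh(z), z_inter=z, clipped=False))
        return pd.DataFrame(rows)

    def test_equal_cell_means_give_null_f(self):
        rng = np.random.default_rng(8)
        means = {(c, d): 0.5 for c in ("MZ", "DZ", "UR") for d in ("x", "y", "w")}
        res = me.agreement_anova(self._records(rng, means, n=200))
        f_class = res.anova_table.loc["C(pair_class, Sum)", "F"]
        assert f_class < 3.0
        assert res.effect_sizes.loc["C(pair_class, Sum)", "partial_eta_sq"] < 0.01

    def test_one_way_reduction_matches_closed_form(self):
        """Single-domain design reproduces hand-computed one-way sums of squares."""
        groups = {"MZ": [0.9, 1.1, 1.0], "DZ": [0.5, 0.7, 0.6],
                  "UR": [0.1, 0.3, 0.2]}
        rows = []
        for cls, zs in groups.items():
            for z in zs:
                rows.append(dict(pair_class=cls, member1="a", member2="b",
                                 domain="only", sex="F", mean_age=30.0,
                                 r_inter=np.tanh(z), z_inter=z, clipped=False))
        df = pd.DataFrame(rows)
        import statsmodels.formula.api as smf
        model = smf.ols("z_inter ~ C(pair_class, Sum)", data=df).fit()
        # closed form: SS_between = 3 * sum (group mean - grand)^2, MS_within = 0.01
        grand = np.mean([z for zs in groups.values() for z in zs])
        ss_b = 3 * sum((np.mean(zs) - grand) ** 2 for zs in groups.values())
        f_expected = (ss_b / 2) / 0.01
        assert model.fvalue == pytest.approx(f_expected, rel=1e-10)
        # marginal means on the z scale back-transform to r
        res = me.agreement_anova(df)
        mm = res.marginal_means.loc["pair_class"]
        assert mm.loc["MZ", "z"] == pytest.approx(1.0)
        assert mm.loc["MZ", "r"] == pytest.approx(np.tanh(1.0))

    def test_balanced_type_iii_equals_type_i(self):
        rng = np.random.default_rng(9)
        means = {("MZ", "x"): 0.8, ("MZ", "y"): 0.7, ("DZ", "x"): 0.6,
                 ("DZ", "y"): 0.5, ("UR", "x"): 0.4, ("UR", "y"): 0.3}
        df = self._records(rng, means, n=30)
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf
        model = smf.ols("z_inter ~ C(pair_class, Sum) * C(domain, Sum)", data=df).fit()
        t1 = smapi.stats.anova_lm(model, typ=1)
        t3 = smapi.stats.anova_lm(model, typ=3)
        assert t3.loc["C(pair_class, Sum)", "sum_sq"] == pytest.approx(
            t1.loc["C(pair_class, Sum)", "sum_sq"], rel=1e-8)

    def test_marginal_ordering_and_contrasts_under_genetic_signal(self):
        rng = np.random.default_rng(10)
        means = {}
        for d in ("x", "y"):
            means[("MZ", d)] = 0.8
            means[("DZ", d)] = 0.65
            means[("UR", d)] = 0.5
        res = me.agreement_anova(self._records(rng, means, n=500))
        mm = res.marginal_means.loc["pair_class"]["z"]
        assert mm["MZ"] > mm["DZ"] > mm["UR"]
        p = res.contrasts.loc["DZ - MZ", "p_bonferroni"]
        assert p < 0.001
        d = res.contrasts.loc["DZ - MZ", "cohens_d"]
        lo, hi = res.contrasts.loc["DZ - MZ", ["d_ci_low", "d_ci_high"]]
        assert lo < d < hi

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(11)
        means = {("MZ", "x"): 0.5, ("DZ", "x"): 0.5, ("UR", "x"): 0.5,
                 ("MZ", "y"): 0.5, ("DZ", "y"): 0.5}
        with pytest.raises(ValueError, match="empty cells"):
            me.agreement_anova(self._records(rng, means, n=5))
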