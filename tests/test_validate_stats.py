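"""Two-way ANOVA against closed-form sums of squares, and Mann-Whitney U
against a full-enumeration oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mavenpy import mann_whitney_u, two_way_anova
from mavenpy.errors import ValidationError


# ---------------------------------------------------------------------------
# closed-form balanced two-way ANOVA oracle


def balanced_anova_oracle(y, A, B):
    """Textbook sums-of-squares decomposition for a balanced two-way design."""
    y = np.asarray(y, dtype=float)
    A = np.asarray(A)
    B = np.asarray(B)
    grand = y.mean()
    a_levels = np.unique(A)
    b_levels = np.unique(B)
    n_cell = len(y) / (len(a_levels) * len(b_levels))
    ss_a = sum(
        (y[A == a].mean() - grand) ** 2 * (y[A == a]).size for a in a_levels
    )
    ss_b = sum(
        (y[B == b].mean() - grand) ** 2 * (y[B == b]).size for b in b_levels
    )
    ss_cells = sum(
        (y[(A == a) & (B == b)].mean() - grand) ** 2 * n_cell
        for a in a_levels
        for b in b_levels
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - grand) ** 2).sum()
    ss_res = ss_tot - ss_cells
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = len(y) - len(a_levels) * len(b_levels)
    return {
        "A": (ss_a, df_a),
        "B": (ss_b, df_b),
        "AB": (ss_ab, df_ab),
        "res": (ss_res, df_res),
        "total": ss_tot,
    }


def balanced_design(rng, n_cell=4, effect_a=0.0, effect_b=0.0, noise=1.0):
    phen, geno, y = [], [], []
    for a in (0, 1):
        for b in ("wt", "het", "hom"):
            for _ in range(n_cell):
                phen.append(a)
                geno.append(b)
                y.append(
                    effect_a * a
                    + effect_b * {"wt": 0, "het": 1, "hom": 2}[b]
                    + noise * rng.normal()
                )
    return np.array(y), np.array(phen), np.array(geno)


class TestTwoWayAnova:
    def test_balanced_matches_closed_form(self, rng):
        y, phen, geno = balanced_design(rng, n_cell=5, effect_a=1.2, effect_b=0.5)
        res = two_way_anova(y, phen, geno)
        want = balanced_anova_oracle(y, phen, geno)
        assert res.effects["phenotype"].ss == pytest.approx(want["A"][0], abs=1e-10)
        assert res.effects["genotype"].ss == pytest.approx(want["B"][0], abs=1e-10)
        assert res.effects["interaction"].ss == pytest.approx(want["AB"][0], abs=1e-10)
        assert res.effects["residual"].ss == pytest.approx(want["res"][0], abs=1e-10)
        assert res.effects["phenotype"].df == want["A"][1]
        assert res.effects["interaction"].df == want["AB"][1]
        # F from the oracle decomposition
        f_want = (want["A"][0] / want["A"][1]) / (want["res"][0] / want["res"][1])
        assert res.effects["phenotype"].F == pytest.approx(f_want, rel=1e-10)
        # SS_total additivity on the balanced design
        ss_sum = sum(
            res.effects[k].ss
            for k in ("phenotype", "genotype", "interaction", "residual")
        )
        assert ss_sum == pytest.approx(res.ss_total, rel=1e-10)

    def test_scale_equivariance(self, rng):
        y, phen, geno = balanced_design(rng, n_cell=4, effect_a=0.8)
        r1 = two_way_anova(y, phen, geno)
        r2 = two_way_anova(2.0 * y, phen, geno)
        for k in ("phenotype", "genotype", "interaction"):
            assert r2.effects[k].ss == pytest.approx(4.0 * r1.effects[k].ss, rel=1e-9)
            assert r2.effects[k].F == pytest.approx(r1.effects[k].F, rel=1e-9)
            assert r2.effects[k].p == pytest.approx(r1.effects[k].p, rel=1e-9)

    def test_identical_values_everywhere_p_one(self):
        y = np.full(12, 3.3)
        phen = np.array([0, 1] * 6)
        geno = np.array(["wt", "wt", "het", "het", "hom", "hom"] * 2)
        res = two_way_anova(y, phen, geno)
        assert res.effects["phenotype"].p == 1.0
        assert res.effects["genotype"].p == 1.0

    def test_null_data_f_near_one(self):
        rng = np.random.default_rng(0)
        fs = []
        for _ in range(200):
            y, phen, geno = balanced_design(rng, n_cell=4)
            fs.append(two_way_anova(y, phen, geno).effects["phenotype"].F)
        # E[F] = df_res/(df_res-2) under the null
        df_res = 4 * 6 - 6
        assert np.mean(fs) == pytest.approx(df_res / (df_res - 2), abs=0.25)

    def test_factor_label_permutation_preserves_p_set(self, rng):
        y, phen, geno = balanced_design(rng, n_cell=4, effect_a=1.0, effect_b=0.3)
        r1 = two_way_anova(y, phen, geno)
        remap = {"wt": "z_wt", "het": "a_het", "hom": "m_hom"}
        r2 = two_way_anova(y, phen, np.array([remap[g] for g in geno]))
        for k in ("phenotype", "genotype", "interaction"):
            assert r2.effects[k].p == pytest.approx(r1.effects[k].p, rel=1e-9)

    def test_unbalanced_type3_runs_and_posthoc_adjusted(self, rng):
        y, phen, geno = balanced_design(rng, n_cell=6, effect_a=2.0)
        keep = np.ones(len(y), dtype=bool)
        keep[:4] = False  # unbalance one cell
        res = two_way_anova(y[keep], phen[keep], geno[keep])
        assert res.effects["phenotype"].p < 0.01
        assert set(res.posthoc) == {"wt", "het", "hom"}
        for d in res.posthoc.values():
            assert d["p_adj"] >= d["p_raw"] - 1e-15

    def test_empty_cell_degrades_with_warning(self, rng):
        y, phen, geno = balanced_design(rng, n_cell=3)
        keep = ~((phen == 1) & (geno == "hom"))
        with pytest.warns(UserWarning, match="interaction dropped"):
            res = two_way_anova(y[keep], phen[keep], geno[keep])
        assert not res.interaction_estimable
        assert "interaction" not in res.effects

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError):
            two_way_anova(np.arange(4.0), [0, 0, 0, 0], ["a", "a", "b", "b"])


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_of(sel):
        sa = pooled[list(sel)]
        sb = np.delete(pooled, list(sel))
        u = sum((x > yv).sum() + 0.5 * (x == yv).sum() for x in sa for yv in [sb])
        return float(np.asarray(u))

    u_obs = u_of(range(n_a))
    mid = n_a * (len(b)) / 2.0
    us = [u_of(sel) for sel in itertools.combinations(range(len(pooled)), n_a)]
    # two-sided: as or more extreme in distance from the mean
    d_obs = abs(u_obs - mid) - 1e-12
    return sum(abs(u - mid) >= d_obs for u in us) / len(us)


class TestMannWhitney:
    def test_complete_separation_exact(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert U == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        U, p = mann_whitney_u(a, list(a))
        assert U == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_matches_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        a = rng.normal(size=n_a)
        b = rng.normal(loc=0.8, size=n_b)
        _, p = mann_whitney_u(a, b, mode="exact")
        want = mwu_enumeration_oracle(a, b)
        assert p == pytest.approx(want, abs=1e-10)

    def test_normal_approx_close_to_enumeration(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=8)
        b = rng.normal(loc=0.5, size=8)
        _, p_approx = mann_whitney_u(a, b, mode="normal_approx")
        want = mwu_enumeration_oracle(a, b)
        assert abs(p_approx - want) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 2, size=6)
        b = rng.uniform(0.3, 2.5, size=7)
        _, p1 = mann_whitney_u(a, b)
        for f in (np.log, np.sqrt, lambda v: v**3 + v):
            _, p2 = mann_whitney_u(f(a), f(b))
            assert p2 == pytest.approx(p1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_null_type_one_error_exact(self):
        """At alpha=0.05 with n=6 per group, the exact test's rejection rate
        over null simulations stays within 0.05 +/- 0.01."""
        rate = simulate_mwu_type_one_error(
            n_per_group=6, n_sim=50_000, seed=2024
        )
        assert abs(rate - 0.05) < 0.01


def simulate_mwu_type_one_error(n_per_group: int, n_sim: int, seed: int) -> float:
    """Empirical rejection rate of the exact Mann-Whitney test on null data.

    Because tie-free p-values depend on the data only through U, the
    implementation's p is tabulated once per attainable U (from constructed
    exemplar samples) and looked up per simulated draw, which makes large
    simulation counts cheap without bypassing the implementation.
    """
    rng = np.random.default_rng(seed)
    n = n_per_group
    pooled_ranks = np.arange(1.0, 2 * n + 1)
    p_of_u = {}
    for sel in itertools.combinations(range(2 * n), n):
        a = pooled_ranks[list(sel)]
        b = np.delete(pooled_ranks, list(sel))
        u = float((a[:, None] > b[None, :]).sum())
        if u not in p_of_u:
            _, p_of_u[u] = mann_whitney_u(a, b, mode="exact")
    draws = rng.normal(size=(n_sim, 2 * n))
    order = draws.argsort(axis=1).argsort(axis=1)  # ranks 0..2n-1, no ties a.s.
    # U_a = R_a - n(n+1)/2 with R_a the 1-based rank sum of the first group
    u_a = (order[:, :n] + 1).sum(axis=1) - n * (n + 1) / 2
    rejected = np.fromiter(
        (p_of_u[float(u)] <= 0.05 for u in u_a), dtype=bool, count=n_sim
    )
    return float(rejected.mean())
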