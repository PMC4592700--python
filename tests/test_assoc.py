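import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as ss

from lohscan.assoc import (
    ContingencyTable2x2,
    GroupingRule,
    association_report,
    default_rules,
    dichotomize,
    fal_association,
    fisher_exact,
    fisher_exact_2x2,
    fisher_table_log_probs,
    kruskal_wallis,
    linear_regression,
    loh_contingency,
    mann_whitney_u,
    spearman_rho,
)
from lohscan.calls import LOH, NG, NI, CallMatrix
from lohscan.simdata import SimulationConfig, simulate_cohort


def random_2x2(rng, max_total=60):
    while True:
        t = rng.integers(0, max_total // 4 + 1, size=4)
        if t.sum() > 0:
            return np.array(t).reshape(2, 2)


def brute_force_fisher_2x2(table):
    """Independent oracle: enumerate k with scipy's hypergeometric pmf."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = ss.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return float(np.sum(rv.pmf(ks)[rv.pmf(ks) <= p_obs * (1 + 1e-7)]))


class TestFisherExact:
    def test_reference_table_value(self):
        assert fisher_exact_2x2([[6, 2], [17, 15]]) == pytest.approx(0.4284, abs=5e-4)

    def test_degenerate_zero_column_is_one(self):
        assert fisher_exact_2x2([[0, 5], [0, 7]]) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            t = random_2x2(rng)
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T), rel=1e-10)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            t = random_2x2(rng)
            assert fisher_exact_2x2(t) == pytest.approx(
                brute_force_fisher_2x2(t), rel=1e-9, abs=1e-12
            )

    def test_matches_scipy_two_sided(self, rng):
        for _ in range(100):
            t = random_2x2(rng)
            assert fisher_exact_2x2(t) == pytest.approx(
                ss.fisher_exact(t)[1], rel=1e-8, abs=1e-12
            )

    def test_point_probabilities_sum_to_one(self, rng):
        for _ in range(100):
            t = random_2x2(rng)
            _, lps = fisher_table_log_probs(t)
            assert math.fsum(math.exp(lp) for lp in lps) == pytest.approx(1.0, abs=1e-12)

    def test_freeman_halton_3x2_sums_to_one_and_bounds(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(3, 2))
            if t.sum() == 0:
                continue
            _, lps = fisher_table_log_probs(t)
            assert math.fsum(math.exp(lp) for lp in lps) == pytest.approx(1.0, abs=1e-12)
            p = fisher_exact(t)
            assert 0 < p <= 1

    def test_freeman_halton_agrees_with_collapsed_2x2_when_row_empty(self):
        # an all-zero middle stratum must not change the test
        t3 = np.array([[6, 2], [0, 0], [17, 15]])
        assert fisher_exact(t3) == pytest.approx(fisher_exact_2x2([[6, 2], [17, 15]]), rel=1e-12)

    def test_contingency_dataclass_roundtrip(self):
        t = ContingencyTable2x2(6, 2, 17, 15)
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.as_array()))
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


def brute_force_mw_two_sided(x, y):
    """Oracle: complete enumeration of which ranks group A occupies."""
    nx = len(x)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    u_lo = min(u_obs, nx * len(y) - u_obs)
    u_hi = nx * len(y) - u_lo
    n = nx + len(y)
    total = extreme = 0
    for subset in combinations(range(1, n + 1), nx):
        u = sum(subset) - nx * (nx + 1) / 2
        total += 1
        extreme += u <= u_lo or u >= u_hi
    return min(1.0, extreme / total)


class TestMannWhitney:
    def test_small_separated_groups(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_degenerate(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            nx = int(rng.integers(1, n))
            vals = rng.permutation(np.arange(1, n + 1) * 1.0)
            x, y = list(vals[:nx]), list(vals[nx:])
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(brute_force_mw_two_sided(x, y), rel=1e-12)

    def test_exact_path_matches_scipy_exact(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            nx = int(rng.integers(1, n))
            vals = rng.permutation(np.arange(1, n + 1) * 1.0)
            x, y = vals[:nx], vals[nx:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(
                ss.mannwhitneyu(x, y, method="exact").pvalue, rel=1e-12
            )

    def test_exact_p_symmetric_in_group_exchange(self, rng):
        vals = rng.permutation(np.arange(1, 9) * 1.0)
        x, y = list(vals[:3]), list(vals[3:])
        assert mann_whitney_u(x, y) == mann_whitney_u(y, x)

    def test_large_sample_approximation_close_to_exact_subsample(self, rng):
        x = sorted(rng.normal(0, 1, 120))
        y = sorted(rng.normal(0.2, 1, 80))
        _, p_large = mann_whitney_u(x, y)
        assert 0 < p_large <= 1
        # the approximate path on an exact-eligible input stays close to exact
        xs, ys = [1.0, 4.0, 6.0, 7.0], [2.0, 3.0, 5.0, 8.0]
        _, p_exact = mann_whitney_u(xs, ys)
        _, p_approx = mann_whitney_u(xs, ys, exact_max_n=0)
        assert p_approx == pytest.approx(p_exact, abs=0.08)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_fully_separated_groups_hand_formula(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # rank sums 6, 15, 24; H = 12/(9*10) * (36+225+576)/3 - 3*10
        assert h == pytest.approx(12 / 90 * (36 + 225 + 576) / 3 - 30)
        assert p == pytest.approx(ss.kruskal(*[[1, 2, 3], [4, 5, 6], [7, 8, 9]]).pvalue)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [list(rng.integers(0, 6, size=int(rng.integers(2, 8)))) for _ in range(3)]
            if len({v for g in groups for v in g}) == 1:
                continue
            h, p = kruskal_wallis(groups)
            ref = ss.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_h_equals_z_squared(self, rng):
        """For k=2 the rank-sum H statistic is the square of the normal
        Mann–Whitney deviate (no continuity correction)."""
        x = list(rng.normal(size=9))
        y = list(rng.normal(0.5, 1, size=7))
        h, _ = kruskal_wallis([x, y])
        nx, ny, n = len(x), len(y), len(x) + len(y)
        ranks = ss.rankdata(x + y)
        u = float(np.sum(ranks[:nx]) - nx * (nx + 1) / 2)
        z = (u - nx * ny / 2) / math.sqrt(nx * ny * (n + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho_up, p_up = spearman_rho(x, [2.0, 5.0, 9.0, 11.0])
        rho_dn, _ = spearman_rho(x, [4.0, 3.0, 1.0, 0.5])
        assert rho_up == 1.0 and p_up == 0.0
        assert rho_dn == -1.0

    def test_tied_data_matches_midrank_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)
            y = rng.integers(0, 5, size=15).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, p = spearman_rho(x, y)
            rx, ry = ss.rankdata(x), ss.rankdata(y)
            oracle = float(np.corrcoef(rx, ry)[0, 1])
            assert rho == pytest.approx(oracle, rel=1e-12)
            ref = ss.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinearRegression:
    def test_collinear_points_exact(self):
        slope, intercept, p = linear_regression([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert p == 0.0

    def test_joint_permutation_invariance(self, rng):
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        perm = rng.permutation(20)
        assert linear_regression(x, y) == pytest.approx(linear_regression(x[perm], y[perm]))

    def test_matches_scipy_linregress(self, rng):
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(size=25)
        slope, intercept, p = linear_regression(x, y)
        ref = ss.linregress(x, y)
        assert slope == pytest.approx(ref.slope, rel=1e-10)
        assert intercept == pytest.approx(ref.intercept, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestGrouping:
    def test_boundary_goes_to_upper_group_for_geq_labels(self):
        rules = {r.variable: r for r in default_rules()}
        assert rules["psad"].assign(0.15) == ">=0.15"
        assert rules["age"].assign(71) == "<72"
        assert rules["gleason"].assign(7) == ">=7"

    def test_psat_boundary_goes_to_lower_stratum(self):
        rule = {r.variable: r for r in default_rules()}["psat"]
        assert rule.assign(10) == "4-10"
        assert rule.assign(10.01) == ">10-20"
        assert rule.assign(20) == ">10-20"

    def test_stage_mapping(self):
        rule = {r.variable: r for r in default_rules()}["stage"]
        import pandas as pd

        clinical = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "stage": ["T1", "T2", "T4"]}
        )
        groups = dichotomize(clinical, rule)
        assert groups == {"a": "T1-T2", "b": "T1-T2", "c": "T3-T4"}

    def test_missing_values_excluded(self):
        import pandas as pd

        rule = {r.variable: r for r in default_rules()}["psad"]
        clinical = pd.DataFrame({"sample_id": ["a", "b"], "psad": [0.2, None]})
        assert dichotomize(clinical, rule) == {"a": ">=0.15"}

    def test_unknown_variable_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="unknown variable"):
            dichotomize(pd.DataFrame({"sample_id": ["a"]}), GroupingRule("psad", (0.15,), ("lo", "hi")))

    def test_rule_invariants(self):
        with pytest.raises(ValueError):
            GroupingRule("x", (2, 1), ("a", "b", "c"))
        with pytest.raises(ValueError):
            GroupingRule("x", (1,), ("a", "a"))


class TestContingency:
    def test_toy_2x2(self, panel):
        grid = [
            [LOH, NI, NI, NI, NI, NI, NI],
            [NG, NI, NI, NI, NI, NI, NI],
            [LOH, NI, NI, NI, NI, NI, NI],
            [NG, NI, NI, NI, NI, NI, NI],
        ]
        matrix = CallMatrix.from_status_grid(["a", "b", "c", "d"], panel.marker_names, grid)
        groups = {"a": "lo", "b": "lo", "c": "hi", "d": "hi"}
        table = loh_contingency(matrix, panel, "15q14-21.1", groups, labels=["lo", "hi"])
        assert table.loc["lo"].tolist() == [1, 1]
        assert table.loc["hi"].tolist() == [1, 1]

    def test_single_stratum_gives_zero_row(self, panel):
        grid = [[LOH] + [NI] * 6, [NG] + [NI] * 6]
        matrix = CallMatrix.from_status_grid(["a", "b"], panel.marker_names, grid)
        table = loh_contingency(matrix, panel, "15q14-21.1", {"a": "lo", "b": "lo"}, labels=["lo", "hi"])
        assert table.loc["hi"].sum() == 0
        assert fisher_exact(table.to_numpy()) == 1.0

    def test_matches_brute_force_recount(self, panel, rng):
        cohort = simulate_cohort(SimulationConfig(n_patients=40, rng_seed=17), panel)
        groups = {sid: ("hi" if rng.random() < 0.5 else "lo") for sid in cohort.truth.sample_ids}
        table = loh_contingency(cohort.truth, panel, "13q12.3-13.1", groups, labels=["lo", "hi"])
        names = panel.markers_in_region("13q12.3-13.1")
        for lab in ("lo", "hi"):
            loh = ng = 0
            for sid, g in groups.items():
                if g != lab:
                    continue
                cells = [cohort.truth.get(sid, m).status for m in names]
                if not any(c in (LOH, NG) for c in cells):
                    continue
                if any(c == LOH for c in cells):
                    loh += 1
                else:
                    ng += 1
            assert table.loc[lab].tolist() == [loh, ng]

    def test_informative_margin_identity(self, panel):
        cohort = simulate_cohort(SimulationConfig(n_patients=30, rng_seed=19), panel)
        groups = {sid: ("hi" if i % 2 else "lo") for i, sid in enumerate(cohort.truth.sample_ids)}
        table = loh_contingency(cohort.truth, panel, "15q14-21.1", groups)
        from lohscan.summarize import region_summary

        s = region_summary(cohort.truth, panel, "15q14-21.1")
        assert int(table.to_numpy().sum()) == s.n_informative


class TestAssociationReport:
    def test_strong_psad_effect_is_flagged(self, panel):
        cohort = simulate_cohort(
            SimulationConfig(n_patients=120, psad_odds_ratio=30.0, psad_high_prob=0.4, rng_seed=23),
            panel,
        )
        report = association_report(cohort.truth, panel, cohort.clinical)
        psad_15q = report[(report.region == "15q14-21.1") & (report.variable == "psad")]
        assert psad_15q["significant"].all()

    def test_layout_mirrors_strata(self, panel):
        cohort = simulate_cohort(SimulationConfig(n_patients=25, rng_seed=29), panel)
        report = association_report(cohort.truth, panel, cohort.clinical)
        assert len(report) == 3 * (6 * 2 + 3)  # 3 regions x (6 two-level + 1 three-level)
        assert (report["I"] == report["N"] + report["LOH"]).all()

    def test_sample_reordering_invariance(self, panel):
        cohort = simulate_cohort(SimulationConfig(n_patients=30, rng_seed=31), panel)
        report1 = association_report(cohort.truth, panel, cohort.clinical)
        shuffled = cohort.clinical.sample(frac=1, random_state=0).reset_index(drop=True)
        report2 = association_report(cohort.truth, panel, shuffled)
        assert report1.equals(report2)

    def test_null_flag_rate_does_not_exceed_nominal(self, panel):
        """A valid exact test never rejects a true null more often than
        its level (up to Monte Carlo error). Discreteness keeps the rate
        at or below nominal, so only the upper bound is a law."""
        n_rep = 120
        flags = 0
        cells = 0
        for i in range(n_rep):
            cohort = simulate_cohort(SimulationConfig(n_patients=50, rng_seed=40_000 + i), panel)
            report = association_report(cohort.truth, panel, cohort.clinical)
            per_test = report.drop_duplicates(subset=["region", "variable"])
            flags += int((per_test["p"] < 0.05).sum())
            cells += len(per_test)
        rate = flags / cells
        # pooled over 21 cells x 120 reps; 99.9% upper binomial bound on 0.05
        bound = 0.05 + 3.29 * math.sqrt(0.05 * 0.95 / cells)
        assert rate <= bound

    def test_fdr_column_optional(self, panel):
        cohort = simulate_cohort(SimulationConfig(n_patients=25, rng_seed=37), panel)
        plain = association_report(cohort.truth, panel, cohort.clinical)
        with_q = association_report(cohort.truth, panel, cohort.clinical, fdr=True)
        assert "q" not in plain.columns and "q" in with_q.columns
        assert (with_q["q"] >= with_q["p"] - 1e-12).all()


class TestFalAssociation:
    def test_two_level_uses_mann_whitney(self, panel):
        cohort = simulate_cohort(SimulationConfig(n_patients=40, rng_seed=41), panel)
        table = fal_association(cohort.truth, cohort.clinical)
        by_var = table.set_index("variable")
        assert by_var.loc["psad", "test"] == "mann-whitney"
        assert by_var.loc["psat", "test"] == "kruskal-wallis"
        assert ((table["p"].dropna() > 0) & (table["p"].dropna() <= 1)).all()
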