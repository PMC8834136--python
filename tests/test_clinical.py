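"""PFS derivation, stratification, Kaplan-Meier, exact tests, qPCR, IHC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aberex.clinical import (
    EARLY,
    LATE,
    UNCLASSIFIABLE,
    IRSScore,
    PatientRecord,
    QPCRMeasurement,
    SurvivalObservation,
    compare_groups,
    count_tables_with_margins,
    delta_ct,
    delta_delta_ct,
    derive_pfs,
    fisher_exact_rxc,
    irs,
    kaplan_meier,
    percentage_class,
    stratify,
    student_t_from_stats,
    wilcoxon_rank_sum,
)


class TestDerivePFS:
    def test_metastasis_is_event(self):
        r = PatientRecord("p", metastasis=True, time_to_metastasis=40.1,
                          followup_months=80.0)
        assert derive_pfs(r) == SurvivalObservation(40.1, 1)

    def test_alive_censored_at_last_followup(self):
        r = PatientRecord("p", followup_months=97.8)
        assert derive_pfs(r) == SurvivalObservation(97.8, 0)

    def test_death_unknown_cause_censored(self):
        r = PatientRecord("p", death_cause="unknown", time_to_death=30.0)
        assert derive_pfs(r) == SurvivalObservation(30.0, 0)

    def test_death_due_disease_is_event(self):
        r = PatientRecord("p", death_cause="UM", time_to_death=50.0,
                          followup_months=50.0)
        assert derive_pfs(r) == SurvivalObservation(50.0, 1)

    def test_earliest_of_metastasis_and_death(self):
        r = PatientRecord("p", metastasis=True, time_to_metastasis=35.0,
                          death_cause="UM", time_to_death=48.0)
        assert derive_pfs(r) == SurvivalObservation(35.0, 1)

    def test_no_usable_time_rejected(self):
        with pytest.raises(ValueError, match="no usable time"):
            derive_pfs(PatientRecord("p"))


class TestStratify:
    @pytest.mark.parametrize(
        "months,event,want",
        [(40, 1, EARLY), (70, 0, LATE), (70, 1, LATE), (30, 0, UNCLASSIFIABLE),
         (60, 0, LATE), (59.9, 1, EARLY)],
    )
    def test_examples(self, months, event, want):
        assert stratify(SurvivalObservation(months, event)) == want

    def test_partition_property(self, rng):
        obs = [
            SurvivalObservation(float(rng.uniform(0, 200)), int(rng.random() < 0.5))
            for _ in range(200)
        ]
        labels = [stratify(o) for o in obs]
        assert all(l in (EARLY, LATE, UNCLASSIFIABLE) for l in labels)
        for o, l in zip(obs, labels):
            if l == EARLY:
                assert o.event == 1 and o.pfs_months < 60
            elif l == LATE:
                assert o.pfs_months >= 60
            else:
                assert o.event == 0 and o.pfs_months < 60


class TestKaplanMeier:
    def test_hand_example(self):
        obs = [
            SurvivalObservation(1, 1),
            SurvivalObservation(2, 0),
            SurvivalObservation(3, 1),
        ]
        km = kaplan_meier(obs)
        surv = km["survival"]["estimate"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)
        assert km["median"] == pytest.approx(3.0)

    def test_all_censored_flat(self):
        obs = [SurvivalObservation(t, 0) for t in (5, 10, 20)]
        km = kaplan_meier(obs)
        assert (km["survival"]["estimate"] == 1.0).all()
        assert np.isnan(km["median"])

    def test_curve_monotone_from_one(self, rng):
        obs = [
            SurvivalObservation(float(rng.exponential(50)), int(rng.random() < 0.7))
            for _ in range(100)
        ]
        km = kaplan_meier(obs)
        est = km["survival"]["estimate"].values
        assert est[0] <= 1.0 + 1e-12
        assert (np.diff(est) <= 1e-12).all()

    def test_exponential_median_recovered(self, rng):
        lam = 1 / 80.0
        obs = [
            SurvivalObservation(float(rng.exponential(1 / lam)), 1)
            for _ in range(4000)
        ]
        km = kaplan_meier(obs)
        want = np.log(2) / lam
        assert abs(km["median"] - want) / want < 0.05
        lo, hi = km["median_ci"]
        assert lo < km["median"] < hi


class TestFisherRxC:
    def test_published_3x2_table(self):
        # metastatic location, early vs late strata, "not reported" excluded
        p = fisher_exact_rxc([[11, 9], [2, 4], [1, 0]])
        assert p == pytest.approx(0.510, abs=1e-3)

    def test_extreme_2x2_analytic(self):
        # (5,0),(0,5): two-sided p = 2/C(10,5) = 2/252
        assert fisher_exact_rxc([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_reduces_to_hypergeometric_2x2(self, rng):
        for _ in range(50):
            tab = rng.integers(0, 10, size=(2, 2))
            if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or (
                tab.sum(axis=1) == 0
            ).any():
                continue
            want = sps.fisher_exact(tab)[1]
            assert fisher_exact_rxc(tab) == pytest.approx(want, rel=1e-9)

    def test_enumeration_count_matches_combinatorics(self):
        # number of tables with margins equals the direct combinatorial count
        assert count_tables_with_margins([3, 2], [2, 2, 1]) == sum(
            1
            for a in range(4) for b in range(4) for c in range(4)
            if a + b + c == 3 and a <= 2 and b <= 2 and c <= 1
        )

    def test_degenerate_single_column(self):
        assert fisher_exact_rxc([[3], [4]]) == 1.0


class TestTTest:
    def test_equal_groups_give_p_one(self):
        t, p = student_t_from_stats(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_ltd_direction(self):
        # LTD summary statistics of the stratified cohort: the early group's
        # tumors are larger; p is small at these group sizes
        t, p = student_t_from_stats(17.7, 2.8, 17, 14.7, 3.7, 49)
        assert t > 0
        assert p < 0.01


class TestCompareGroups:
    def test_not_reported_rows_excluded(self):
        tab = pd.DataFrame(
            {
                "stratum": [EARLY] * 14 + [LATE] * 13 + [EARLY] * 5 + [LATE] * 39,
                "metastatic_location": (
                    ["Liver"] * 11 + ["Liver and other site"] * 2 + ["Ossal"]
                    + ["Liver"] * 9 + ["Liver and other site"] * 4
                    + ["Data not reported"] * 44
                ),
            }
        )
        out = compare_groups(tab, "metastatic_location")
        assert out["test"] == "fisher"
        assert out["p"] == pytest.approx(0.510, abs=1e-3)

    def test_continuous_uses_t(self, rng):
        tab = pd.DataFrame(
            {
                "stratum": [EARLY] * 20 + [LATE] * 20,
                "ltd_mm": np.concatenate(
                    [rng.normal(17.7, 2.8, 20), rng.normal(14.7, 3.7, 20)]
                ),
            }
        )
        out = compare_groups(tab, "ltd_mm")
        assert out["test"] == "t"
        assert out["p"] < 0.05

    def test_empty_group_warns(self):
        tab = pd.DataFrame({"stratum": [EARLY] * 3, "x": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="empty"):
            out = compare_groups(tab, "x")
        assert np.isnan(out["p"])


class TestWilcoxon:
    def test_singletons(self):
        assert wilcoxon_rank_sum([1.0], [2.0]) == 1.0

    def test_fully_separated_n3(self):
        # exact two-sided tail: 2 * 1/C(6,3) = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_values(self):
        assert wilcoxon_rank_sum([2, 2], [2, 2]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            vals = rng.permutation(100)[: nx + ny].astype(float)
            x, y = vals[:nx], vals[ny:][:ny] if False else (vals[:nx], vals[nx:])
            x, y = vals[:nx], vals[nx:]
            got = wilcoxon_rank_sum(x, y)
            # enumerate all assignments of ranks to the x-group
            combined = np.concatenate([x, y])
            ranks = sps.rankdata(combined)
            u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
            n = nx + ny
            us = []
            for comb in itertools.combinations(range(n), nx):
                u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
                us.append(u)
            us = np.array(us)
            mean_u = nx * ny / 2
            want = (np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9).mean()
            assert got == pytest.approx(want, rel=1e-9)


class TestQPCR:
    def _m(self, target, ref, sample="s1"):
        return QPCRMeasurement(sample, "ABHD6", tuple(target), tuple(ref))

    def test_delta_ct_sign_convention(self):
        # target amplifying 5 cycles later than the reference -> dCt = -5
        m = self._m([25, 25, 25], [20, 20, 20])
        assert delta_ct(m) == pytest.approx(-5.0)

    def test_sample_equal_control_fold_one(self):
        a = self._m([24, 25, 26], [20, 20, 20])
        ddct, fold = delta_delta_ct(a, a)
        assert ddct == pytest.approx(0.0)
        assert fold == pytest.approx(1.0)

    def test_replicate_shuffle_invariant(self, rng):
        t = rng.normal(25, 0.1, 3)
        r = rng.normal(20, 0.1, 3)
        m1 = self._m(t, r)
        m2 = self._m(t[::-1], r[[1, 0, 2]])
        assert delta_ct(m1) == pytest.approx(delta_ct(m2))
        assert delta_ct(m1) == pytest.approx(r.mean() - t.mean())

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            QPCRMeasurement("s", "g", (25.0,), (20.0, 20.1))


class TestIRS:
    def test_max_product(self):
        assert irs(3, 90.0).irs == 12

    def test_zero_intensity(self):
        assert irs(0, 4).irs == 0

    @pytest.mark.parametrize(
        "pct,want", [(0.0, 0), (5.0, 1), (10.0, 2), (50.0, 2), (55.0, 3),
                     (80.0, 3), (81.0, 4)],
    )
    def test_percentage_bins(self, pct, want):
        assert percentage_class(pct) == want

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            irs(4, 2)
        with pytest.raises(ValueError):
            percentage_class(101.0)
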