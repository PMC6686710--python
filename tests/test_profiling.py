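"""Herd means, |Hm - Ca| deviations, best-of-three clustering, cross-tabs."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import herdsense as hs
from herdsense.profiling import ClusterAssignment
from herdsense.synthetic_herd import ActivityDay, CowState

DAY = dt.date(2017, 5, 1)
WINDOW = (DAY, DAY)


def _activity(rows):
    return pd.DataFrame(
        [{"cow_id": c, "date": DAY, "steps": s, "lying_hours": l,
          "swaps_per_hour": w} for c, s, l, w in rows])


class TestHerdBaseline:
    def test_arithmetic_mean(self):
        act = _activity([("a", 4000, 10.0, 1.0), ("b", 6000, 12.0, 2.0)])
        base = hs.compute_herd_baseline(act, DAY)
        assert base.mean_steps == 5000
        assert base.mean_lying == 11.0
        assert base.herd_size == 2

    def test_single_cow_baseline_is_that_cow(self):
        act = _activity([("a", 4100, 9.5, 1.25)])
        base = hs.compute_herd_baseline(act, DAY)
        assert (base.mean_steps, base.mean_lying, base.mean_swaps) \
            == (4100, 9.5, 1.25)

    def test_empty_day_errors_with_date(self):
        act = _activity([("a", 4000, 10.0, 1.0)])
        with pytest.raises(ValueError, match="2017-06-01"):
            hs.compute_herd_baseline(act, dt.date(2017, 6, 1))

    def test_zero_noise_simulated_baseline_equals_config(self):
        cfg = hs.HerdConfig(
            noise_sd={"steps": 0.0, "lying_hours": 0.0, "swaps_per_hour": 0.0})
        roster = hs.generate_herd(cfg)
        act, _ = hs.simulate_activity(roster, 1, cfg, events=False)
        base = hs.compute_herd_baseline(act, cfg.start_date)
        assert base.mean_steps == pytest.approx(cfg.baseline_steps)
        assert base.mean_lying == pytest.approx(cfg.baseline_lying)
        assert base.mean_swaps == pytest.approx(cfg.baseline_swaps)
        assert base.herd_size == 147


class TestDeviation:
    def _baseline(self, steps=5000, lying=11.0, swaps=1.5):
        return hs.HerdBaseline(DAY, steps, lying, swaps, herd_size=10)

    def test_cow_at_herd_mean(self):
        day = ActivityDay("a", DAY, 5000, 11.0, 1.5)
        prof = hs.compute_deviation(self._baseline(), day)
        assert prof.ad_steps == 0 and prof.sign_steps == "at"
        assert prof.ad_lying == 0 and prof.ad_swaps == 0

    def test_below_mean(self):
        day = ActivityDay("a", DAY, 4200, 11.0, 1.5)
        prof = hs.compute_deviation(self._baseline(steps=6000), day)
        assert prof.ad_steps == 1800
        assert prof.sign_steps == "below"

    def test_symmetry_swaps_sign_not_magnitude(self):
        prof_lo = hs.compute_deviation(
            self._baseline(steps=6000), ActivityDay("a", DAY, 4200, 11.0, 1.5))
        prof_hi = hs.compute_deviation(
            self._baseline(steps=4200), ActivityDay("a", DAY, 6000, 11.0, 1.5))
        assert prof_lo.ad_steps == prof_hi.ad_steps == 1800
        assert (prof_lo.sign_steps, prof_hi.sign_steps) == ("below", "above")

    def test_date_mismatch_rejected(self):
        day = ActivityDay("a", dt.date(2017, 6, 2), 5000, 11.0, 1.5)
        with pytest.raises(ValueError):
            hs.compute_deviation(self._baseline(), day)

    def test_table_matches_direct_recompute(self, sim14, profiles14):
        """Every row of the bulk deviation table equals a direct |Hm - Ca|
        recomputation through the per-day operation."""
        act, _ = sim14
        merged = profiles14.sample(n=200, random_state=0)
        act = act.set_index(["cow_id", "date"])
        for _, row in merged.iterrows():
            base = hs.compute_herd_baseline(
                act.reset_index(), row["date"])
            cow = act.loc[(row["cow_id"], row["date"])]
            prof = hs.compute_deviation(
                base, ActivityDay(row["cow_id"], row["date"], int(cow["steps"]),
                                  float(cow["lying_hours"]),
                                  float(cow["swaps_per_hour"])))
            assert prof.ad_steps == pytest.approx(row["ad_steps"])
            assert prof.ad_lying == pytest.approx(row["ad_lying"])
            assert prof.ad_swaps == pytest.approx(row["ad_swaps"])
            assert prof.sign_steps == row["sign_steps"]


def _profiles_from_devs(rows):
    """rows: (cow_id, dev_steps, dev_lying, dev_swaps)"""
    return pd.DataFrame([
        {"cow_id": c, "date": DAY,
         "dev_steps": s, "ad_steps": abs(s), "sign_steps": "above" if s > 0 else "below" if s < 0 else "at",
         "dev_lying": l, "ad_lying": abs(l), "sign_lying": "above" if l > 0 else "below" if l < 0 else "at",
         "dev_swaps": w, "ad_swaps": abs(w), "sign_swaps": "above" if w > 0 else "below" if w < 0 else "at"}
        for c, s, l, w in rows])


UNIT_DISPERSION = {"steps": 100.0, "lying_hours": 1.0, "swaps_per_hour": 0.1}


class TestAssignClusters:
    def test_two_high_activity_votes_make_active(self):
        # steps well above, lying well below (both high-activity), swaps near
        profs = _profiles_from_devs([("a", 500.0, -3.0, 0.0)])
        [a] = hs.assign_clusters(profs, UNIT_DISPERSION, WINDOW, tau=1.0)
        assert a.label == "active"
        assert a.votes == {"steps": "high", "lying_hours": "high",
                           "swaps_per_hour": "near"}

    def test_all_near_is_normal(self):
        profs = _profiles_from_devs([("a", 50.0, -0.5, 0.05)])
        [a] = hs.assign_clusters(profs, UNIT_DISPERSION, WINDOW, tau=1.0)
        assert a.label == "normal"

    def test_two_low_activity_votes_make_dormant(self):
        profs = _profiles_from_devs([("a", -400.0, 5.0, 0.0)])
        [a] = hs.assign_clusters(profs, UNIT_DISPERSION, WINDOW, tau=1.0)
        assert a.label == "dormant"

    def test_split_vote_is_normal(self):
        # steps high-activity, lying low-activity, swaps near
        profs = _profiles_from_devs([("a", 500.0, 4.0, 0.0)])
        [a] = hs.assign_clusters(profs, UNIT_DISPERSION, WINDOW, tau=1.0)
        assert a.label == "normal"

    def test_empty_window_rejected(self):
        profs = _profiles_from_devs([("a", 0.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            hs.assign_clusters(profs, UNIT_DISPERSION,
                               (dt.date(2018, 1, 1), dt.date(2018, 1, 7)))
        with pytest.raises(ValueError):
            hs.assign_clusters(profs, UNIT_DISPERSION, WINDOW, tau=0.0)

    def test_recovers_planted_structure(self, roster, profiles14):
        """14-day window over the default simulated herd recovers the planted
        54/83/10 cluster structure for >= 95% of cows."""
        disp = hs.compute_herd_dispersion(profiles14)
        dates = sorted(profiles14["date"].unique())
        assignments = hs.assign_clusters(
            profiles14, disp, (dates[0], dates[-1]))
        labels = {a.cow_id: a.label for a in assignments}
        truth = {c.cow_id: c.latent_cluster for c in roster}
        hit = np.mean([labels[c] == truth[c] for c in labels])
        assert hit >= 0.95
        totals = pd.Series(list(labels.values())).value_counts()
        assert totals["active"] == 54
        assert totals["normal"] == 83
        assert totals["dormant"] == 10


def _table3_assignments_and_roster():
    counts = hs.synthetic_herd.DEFAULT_CLUSTER_COUNTS
    roster, assignments, i = [], [], 0
    for age, row in counts.items():
        for cluster, n in row.items():
            for _ in range(n):
                i += 1
                cow = CowState(f"cow_{i:03d}", age, cluster)
                roster.append(cow)
                assignments.append(ClusterAssignment(
                    cow.cow_id, WINDOW, cluster, {}))
    return assignments, roster


class TestCrossTabulate:
    def test_herd_percentage_bullets(self):
        assignments, roster = _table3_assignments_and_roster()
        table = hs.cross_tabulate(assignments, roster)
        pct = table.pct_of_herd
        assert pct[("young", "active")] == 30
        assert pct[("old", "active")] == 7
        assert pct[("young", "normal")] == 45
        assert pct[("old", "normal")] == 12
        assert pct[("old", "dormant")] == 6
        # 1/147 rounds to 1% under nearest-percent rounding
        assert pct[("young", "dormant")] == 1

    def test_conservation(self):
        assignments, roster = _table3_assignments_and_roster()
        table = hs.cross_tabulate(assignments, roster)
        assert table.herd_size == 147
        assert table.totals == {"active": 54, "normal": 83, "dormant": 10}
        age_counts = hs.synthetic_herd.DEFAULT_AGE_COUNTS
        for age in table.counts.index:
            assert int(table.counts.loc[age].sum()) == age_counts[age]
        for cluster, total in table.totals.items():
            assert int(table.counts[cluster].sum()) == total

    def test_single_cow_herd(self):
        roster = [CowState("solo", 4, "active")]
        table = hs.cross_tabulate(
            [ClusterAssignment("solo", WINDOW, "active", {})], roster)
        assert int(table.counts.loc[4, "active"]) == 1
        assert table.pct_of_herd[("young", "active")] == 100

    def test_unknown_cow_rejected(self):
        roster = [CowState("solo", 4, "active")]
        with pytest.raises(KeyError, match="ghost"):
            hs.cross_tabulate(
                [ClusterAssignment("ghost", WINDOW, "active", {})], roster)


class TestZeroNoiseLimit:
    def test_normal_cows_have_zero_deviations(self):
        cfg = hs.HerdConfig(
            noise_sd={"steps": 0.0, "lying_hours": 0.0, "swaps_per_hour": 0.0})
        roster = hs.generate_herd(cfg)
        act, _ = hs.simulate_activity(roster, 2, cfg, events=False)
        profiles = hs.compute_deviation_table(act)
        normal = {c.cow_id for c in roster if c.latent_cluster == "normal"}
        sub = profiles[profiles["cow_id"].isin(normal)]
        assert (sub[["ad_steps", "ad_lying", "ad_swaps"]].to_numpy() == 0).all()
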