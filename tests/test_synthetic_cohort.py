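"""Synthetic cohort generator: determinism, band placement, null behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cafkit import (
    CohortParams,
    MarkerReference,
    enrich_cohort,
    generate_cohort,
    sample_marker_hscores,
)
from cafkit.stats import km_logrank
from cafkit.subtyping import MARKERS, SUBSETS, MarkerPanel, bin_marker, default_profiles


class TestSampleMarkerHScores:
    def test_s1_profile_bins(self, marker_reference):
        panel = sample_marker_hscores("CAF-S1", marker_reference, 0)
        th = marker_reference.thresholds
        assert bin_marker(panel.fap, th["fap"]) == "Hi"
        assert bin_marker(panel.sma, th["sma"]) == "Hi"

    def test_s2_profile_bins(self, marker_reference):
        panel = sample_marker_hscores("CAF-S2", marker_reference, 1)
        th = marker_reference.thresholds
        assert bin_marker(panel.fap, th["fap"]) == "Neg"
        assert bin_marker(panel.sma, th["sma"]) == "Neg"

    def test_bounds_over_many_draws(self, marker_reference):
        rng = np.random.default_rng(5)
        for subset in SUBSETS:
            vals = np.array(
                [
                    list(
                        sample_marker_hscores(subset, marker_reference, rng)
                        .markers()
                        .values()
                    )
                    for _ in range(500)
                ]
            )
            assert vals.min() >= 0.0 and vals.max() <= 300.0

    def test_band_placement_against_realized_quartiles(self, marker_reference):
        """>= 95% of draws bin into a profile-permitted band."""
        rng = np.random.default_rng(6)
        profiles = default_profiles()
        th = marker_reference.thresholds
        for subset in SUBSETS:
            hits = total = 0
            for _ in range(300):
                panel = sample_marker_hscores(subset, marker_reference, rng)
                for m, v in panel.markers().items():
                    total += 1
                    hits += bin_marker(v, th[m]) in profiles[subset][m]
            assert hits / total >= 0.95

    def test_unknown_subset_rejected(self, marker_reference):
        with pytest.raises(ValueError, match="subset"):
            sample_marker_hscores("CAF-S9", marker_reference, 0)


class TestGenerateCohort:
    def test_deterministic_per_seed(self):
        params = CohortParams(n_cases=10, n_controls_pool=60, seed=9)
        c1, t1 = generate_cohort(params)
        c2, t2 = generate_cohort(params)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_zero_cases_still_generates_pool(self):
        params = CohortParams(n_cases=0, n_controls_pool=40, seed=2)
        cohort, truth = generate_cohort(params)
        assert cohort["case"].sum() == 0
        assert len(cohort) == 40 and len(truth) == 40

    def test_cases_have_realized_distant_events(self):
        params = CohortParams(n_cases=15, n_controls_pool=50, seed=3)
        cohort, _ = generate_cohort(params)
        cases = cohort[cohort["case"]]
        assert len(cases) == 15
        assert cases["distant_event"].all()
        assert (cases["time_to_event"] < params.censor_time).all()

    def test_cd4_depressed_in_cases(self):
        params = CohortParams(
            n_cases=150, n_controls_pool=600, baseline_hazard=0.004, seed=4
        )
        cohort, _ = generate_cohort(params)
        cd4_cases = cohort.loc[cohort["case"], "cd4_density"].median()
        cd4_ctrl = cohort.loc[~cohort["case"], "cd4_density"].median()
        assert cd4_cases < cd4_ctrl

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(subset_prevalence=(0.5, 0.5, 0.5, 0.5))

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(baseline_hazard=0.0)


class TestNullBehavior:
    def test_null_hr_gives_equal_s1_fractions(self, marker_reference):
        """With HR = 1, conditioning on the event does not enrich CAF-S1."""
        diffs = []
        for i in range(150):
            params = CohortParams(
                n_cases=20,
                n_controls_pool=80,
                caf_s1_hr=1.0,
                baseline_hazard=0.004,
                seed=50_000 + i,
            )
            cohort, truth = generate_cohort(params, reference=marker_reference)
            s1 = truth.set_index("id")["latent_subset"] == "CAF-S1"
            cases = cohort.loc[cohort["case"], "id"]
            ctrls = cohort.loc[~cohort["case"], "id"]
            diffs.append(s1.loc[cases].mean() - s1.loc[ctrls].mean())
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * mc_se + 1e-12

    def test_null_logrank_pvalues_uniform(self, marker_reference):
        """Log-rank p over replicate null cohorts is uniform (KS)."""
        ps = []
        for i in range(200):
            params = CohortParams(
                n_cases=0,
                n_controls_pool=120,
                caf_s1_hr=1.0,
                baseline_hazard=0.005,
                seed=80_000 + i,
            )
            cohort, truth = generate_cohort(params, reference=marker_reference)
            s1 = (truth.set_index("id")["latent_subset"] == "CAF-S1").reindex(
                cohort["id"]
            )
            df = cohort.rename(
                columns={"time_to_event": "time", "distant_event": "event"}
            )
            g1, g0 = df[s1.to_numpy()], df[~s1.to_numpy()]
            if len(g1) == 0 or not df["event"].any():
                continue
            ps.append(km_logrank({"s1": g1, "rest": g0}).pvalue)
        assert len(ps) > 150
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPrevalenceRecovery:
    def test_enrichment_recovers_generating_prevalence(self, marker_reference):
        """Classification with the generating thresholds recovers the
        subset mix within 2 binomial SE at n = 4000."""
        rng = np.random.default_rng(17)
        prev = np.array([0.144, 0.423, 0.135, 0.298])
        n = 4000
        latent = rng.choice(SUBSETS, size=n, p=prev)
        panels = [
            sample_marker_hscores(s, marker_reference, rng) for s in latent
        ]
        labels, dist = enrich_cohort(
            panels, thresholds=marker_reference.thresholds, mode="tree"
        )
        # With the generating thresholds the call is exact per tumor.
        assert (np.asarray(labels) == latent).mean() > 0.999
        for s, p in zip(SUBSETS, prev):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(dist[s] / 100.0 - p) <= 2 * se + 2.0 / n
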