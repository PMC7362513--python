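"""Quartile binning and CAF-subset classification."""

import itertools

import numpy as np
import pytest

from cafkit import (
    MarkerPanel,
    classify_subset,
    default_profiles,
    default_tree,
    enrich_cohort,
    fit_quantile_thresholds,
)
from cafkit.subtyping import (
    LEVELS,
    MARKERS,
    SUBSETS,
    MarkerThresholds,
    QuantileThresholds,
    bin_marker,
    bin_panel,
)

from conftest import BAND_CENTER

# The four archetype bin-vectors, one per subset profile.
ARCHETYPES = {
    "CAF-S1": {"fap": "Hi", "cd29": "Med", "sma": "Hi", "fsp1": "Low", "pdgfrb": "Hi"},
    "CAF-S2": {"fap": "Neg", "cd29": "Low", "sma": "Neg", "fsp1": "Neg", "pdgfrb": "Neg"},
    "CAF-S3": {"fap": "Neg", "cd29": "Med", "sma": "Neg", "fsp1": "Med", "pdgfrb": "Med"},
    "CAF-S4": {"fap": "Neg", "cd29": "Hi", "sma": "Hi", "fsp1": "Low", "pdgfrb": "Low"},
}


def panel_from_bins(bins: dict) -> MarkerPanel:
    return MarkerPanel(**{m: BAND_CENTER[b] for m, b in bins.items()})


class TestQuantileThresholds:
    def test_linear_interpolation_quantiles(self):
        th = fit_quantile_thresholds({"fap": np.arange(1, 9)})["fap"]
        assert (th.q1, th.med, th.q3) == (2.75, 4.5, 6.25)

    def test_constant_vector_collapses(self):
        th = fit_quantile_thresholds({"fap": [7.0] * 5})["fap"]
        assert th.q1 == th.med == th.q3 == 7.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_quantile_thresholds({"fap": [1.0, np.nan, 3.0, 4.0]})

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_quantile_thresholds({"fap": [1.0, 2.0, 3.0]})

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            MarkerThresholds(10.0, 5.0, 20.0)


class TestBinning:
    def test_boundaries(self):
        th = MarkerThresholds(75, 150, 225)
        assert bin_marker(74.999, th) == "Neg"
        assert bin_marker(75, th) == "Low"
        assert bin_marker(150, th) == "Med"
        assert bin_marker(225, th) == "Hi"
        assert bin_marker(300, th) == "Hi"

    def test_degenerate_thresholds(self):
        th = MarkerThresholds(5.0, 5.0, 5.0)
        assert bin_marker(5.0, th) == "Hi"
        assert bin_marker(4.9, th) == "Neg"


class TestClassification:
    @pytest.mark.parametrize("subset", SUBSETS)
    @pytest.mark.parametrize("mode", ["tree", "archetype"])
    def test_archetypes_reach_their_own_subset(self, subset, mode, even_thresholds):
        panel = panel_from_bins(ARCHETYPES[subset])
        assert classify_subset(panel, even_thresholds, mode=mode) == subset

    def test_every_panel_gets_exactly_one_subset(self, even_thresholds, rng):
        for _ in range(200):
            panel = MarkerPanel(**{m: rng.uniform(0, 300) for m in MARKERS})
            for mode in ("tree", "archetype"):
                assert classify_subset(panel, even_thresholds, mode=mode) in SUBSETS

    def test_monotone_transform_equivariance(self, even_thresholds, rng):
        """Jointly transforming values and thresholds preserves the label."""

        def f(x):  # strictly increasing
            return np.expm1(x / 80.0)

        for _ in range(100):
            vals = {m: rng.uniform(0, 300) for m in MARKERS}
            panel = MarkerPanel(**vals)
            t_panel = MarkerPanel(**{m: f(v) for m, v in vals.items()})
            t_th = QuantileThresholds(
                {
                    m: MarkerThresholds(f(t.q1), f(t.med), f(t.q3))
                    for m, t in even_thresholds.items()
                }
            )
            for mode in ("tree", "archetype"):
                assert classify_subset(panel, even_thresholds, mode=mode) == \
                    classify_subset(t_panel, t_th, mode=mode)

    def test_tree_and_archetype_agree_on_unique_profile_matches(
        self, even_thresholds
    ):
        """Enumerate all 4^5 bin-vectors; on exact unique matches the two
        classification modes must agree with the matched profile."""
        profiles = default_profiles()
        checked = 0
        for bins_tuple in itertools.product(LEVELS, repeat=5):
            bins = dict(zip(MARKERS, bins_tuple))
            matches = [
                s
                for s in SUBSETS
                if all(bins[m] in profiles[s][m] for m in MARKERS)
            ]
            if len(matches) != 1:
                continue
            panel = panel_from_bins(bins)
            assert classify_subset(panel, even_thresholds, mode="tree") == matches[0]
            assert (
                classify_subset(panel, even_thresholds, mode="archetype")
                == matches[0]
            )
            checked += 1
        assert checked >= 4  # at least the four archetypes are unique

    def test_tree_missing_marker_is_config_error(self, even_thresholds):
        panel = MarkerPanel(cd29=10.0, fsp1=10.0)  # tree needs fap/sma
        with pytest.raises(KeyError, match="fap"):
            classify_subset(panel, even_thresholds, mode="tree")

    def test_bin_panel_covers_measured_markers(self, even_thresholds):
        bins = bin_panel(MarkerPanel(fap=260, cd29=100), even_thresholds)
        assert bins == {"fap": "Hi", "cd29": "Low"}


class TestEnrichCohort:
    def test_symmetric_cohort_splits_evenly(self, even_thresholds):
        panels = [
            panel_from_bins(ARCHETYPES[s]) for s in SUBSETS for _ in range(26)
        ]
        labels, dist = enrich_cohort(panels, thresholds=even_thresholds)
        assert sorted(set(labels)) == sorted(SUBSETS)
        assert np.allclose(dist.to_numpy(), 25.0)
        assert dist.sum() == pytest.approx(100.0)

    def test_single_subset_cohort(self, even_thresholds):
        panels = [panel_from_bins(ARCHETYPES["CAF-S2"])] * 10
        _, dist = enrich_cohort(panels, thresholds=even_thresholds)
        assert dist["CAF-S2"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            enrich_cohort([])

    def test_default_tree_provenance_is_declared(self):
        assert default_tree().provenance == "profile-consistent-default"
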