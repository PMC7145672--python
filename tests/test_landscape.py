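"""Window tiling, pericentromere calls, correlations, and activity models."""

import numpy as np
import pandas as pd
import pytest

from retroscape import chronos, landscape
from retroscape.landscape import (
    ages_by_gene_bin,
    assign_to_windows,
    call_pericentromeres,
    classify_activity_pattern,
    correlate,
    gene_content_bin,
    genic_fraction,
    ltr_count_metrics,
    make_windows,
)


class TestWindows:
    def test_large_scaffold_tiles_with_trailing_partial(self):
        w = make_windows({"s": 2_500_000})
        assert [(r.start, r.end) for r in w.itertuples(index=False)] == [
            (0, 1_000_000), (1_000_000, 2_000_000), (2_000_000, 2_500_000)
        ]

    def test_short_scaffold_discarded(self):
        assert make_windows({"s": 99_000}).empty

    def test_mid_size_scaffold_is_single_window(self):
        w = make_windows({"s": 300_000})
        assert len(w) == 1 and (w.iloc[0]["start"], w.iloc[0]["end"]) == (0, 300_000)

    def test_tiling_partitions_each_retained_scaffold(self):
        lengths = {"a": 3_456_789, "b": 150_000, "c": 50_000}
        w = make_windows(lengths)
        for scaffold, sub in w.groupby("scaffold"):
            sub = sub.sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == lengths[scaffold]
            assert (sub["end"].to_numpy()[:-1] == sub["start"].to_numpy()[1:]).all()
        assert "c" not in set(w["scaffold"])

    def test_feature_assignment_by_start_position(self):
        w = make_windows({"s": 2_000_000})
        assigned = assign_to_windows(
            w, [("s", 0), ("s", 999_999), ("s", 1_000_000), ("x", 5)]
        )
        assert assigned == ["W0001", "W0001", "W0002", None]

    def test_genic_fraction_clips_and_unions(self):
        w = make_windows({"s": 1_000_000})
        genes = [("s", 0, 100_000), ("s", 50_000, 150_000), ("s", 900_000, 1_100_000)]
        frac = genic_fraction(w, genes)
        assert frac.iloc[0] == pytest.approx(0.25)


class TestPericentromeres:
    def test_uniform_genic_content_flags_nothing(self):
        w = make_windows({"s": 5_000_000})
        genic = pd.Series(0.3, index=w["window_id"])
        flagged, candidates = call_pericentromeres(w, genic)
        assert flagged == [] and candidates == {}

    def test_planted_low_gene_valley_is_the_maximal_run(self):
        w = make_windows({"s": 10_000_000})
        values = [0.4] * 10
        for i in (4, 5, 6):
            values[i] = 0.05
        genic = pd.Series(values, index=w["window_id"])
        flagged, candidates = call_pericentromeres(w, genic)
        assert flagged == [w["window_id"].iloc[i] for i in (4, 5, 6)]
        assert candidates["s"] == flagged

    def test_default_threshold_is_the_median(self):
        w = make_windows({"s": 4_000_000})
        genic = pd.Series([0.1, 0.2, 0.3, 0.4], index=w["window_id"])
        flagged, _ = call_pericentromeres(w, genic)
        # median 0.25: strictly-below windows only
        assert flagged == list(w["window_id"].iloc[:2])


class TestCorrelation:
    def test_perfect_negative_correlation(self):
        frame = pd.DataFrame({"x": range(20), "y": [-v for v in range(20)]})
        rho, p = correlate(frame, "x", "y")
        assert rho == pytest.approx(-1.0)

    def test_constant_field_rejected(self):
        frame = pd.DataFrame({"x": range(10), "y": [1.0] * 10})
        with pytest.raises(ValueError):
            correlate(frame, "x", "y")

    def test_planted_anticorrelated_elements(self):
        """Element density planted inversely proportional to gene density
        yields a significant negative correlation."""
        rng = np.random.default_rng(2)
        genic = np.linspace(0.05, 0.55, 40)
        elements = np.array([rng.poisson(30 * (0.6 - g)) for g in genic])
        frame = pd.DataFrame({"genic": genic, "elements": elements})
        rho, p = correlate(frame, "genic", "elements")
        assert rho < 0 and p < 0.05

    def test_permuted_labels_lose_the_signal(self):
        rng = np.random.default_rng(4)
        genic = np.linspace(0.05, 0.55, 40)
        elements = np.array([rng.poisson(30 * (0.6 - g)) for g in genic])
        rhos = []
        for _ in range(30):
            perm = rng.permutation(elements)
            frame = pd.DataFrame({"genic": genic, "elements": perm})
            rhos.append(correlate(frame, "genic", "elements")[0])
        assert abs(np.mean(rhos)) < 0.15


class TestAgesByGeneBin:
    def test_bins_are_left_closed_and_sixty_percent_excluded(self):
        assert gene_content_bin(0.0) == 0
        assert gene_content_bin(0.1) == 1
        assert gene_content_bin(0.599) == 5
        assert gene_content_bin(0.6) is None

    def test_elements_pool_by_window_bin_and_normalise(self):
        w = make_windows({"s": 3_000_000})
        genic = pd.Series([0.05, 0.25, 0.65], index=w["window_id"])
        wins = ["W0001"] * 5 + ["W0002"] * 3 + ["W0003"] * 2 + [None]
        ages = [0.01] * 5 + [0.11] * 3 + [0.2] * 2 + [0.0]
        hist = ages_by_gene_bin(w, genic, wins, ages)
        groups = set(hist["group"])
        assert groups == {"bin0", "bin2"}  # the 65% window is excluded
        for _, sub in hist.groupby("group"):
            assert sub["proportion"].sum() == pytest.approx(1.0)
        bin0 = hist[(hist["group"] == "bin0") & (hist["count"] > 0)]
        assert bin0["bin_left"].tolist() == [0.01]

    def test_age_separation_by_gene_content_profile(self):
        """Old elements confined to gene-poor windows: the recent-age peak
        sharpens as genic content rises."""
        rng = np.random.default_rng(6)
        w = make_windows({"s": 6_000_000})
        genic = pd.Series([0.05, 0.15, 0.25, 0.35, 0.45, 0.55], index=w["window_id"])
        wins, ages = [], []
        for wid, g in genic.items():
            for _ in range(300):
                if rng.random() < 0.5:
                    age = float(rng.uniform(0, 0.02))  # young: everywhere
                    wins.append(wid)
                    ages.append(age)
                elif g < 0.2:  # old: only gene-poor windows
                    wins.append(wid)
                    ages.append(float(rng.uniform(0.05, 0.2)))
        hist = ages_by_gene_bin(w, genic, wins, ages)
        recent_mass = {
            g: sub[sub["bin_left"] < 0.02]["proportion"].sum()
            for g, sub in hist.groupby("group")
        }
        assert recent_mass["bin5"] > recent_mass["bin0"]


class TestActivityPatterns:
    BINS = np.arange(0.0, 0.20, 0.01)

    def _hist(self, counts):
        return pd.DataFrame({"bin_left": self.BINS, "count": counts})

    def _shape(self, model):
        """Counts per bin; bin 0 is the present, bin 19 the oldest."""
        c = [int(10 * 1.3 ** (19 - i)) for i in range(20)]  # growth to present
        if model in ("b", "c"):
            peak = c[6]
            for i in range(6):  # decline after the 0.06 changepoint
                c[i] = max(1, int(peak * 0.5 ** (6 - i)))
        if model == "c":
            c[0] = c[6] * 3  # recent burst at d ~ 0
            c[1] = c[6] * 2
        return c

    def test_clean_shapes_classified_perfectly(self):
        for truth in "abc":
            pattern = classify_activity_pattern(self._hist(self._shape(truth)))
            assert pattern.model == truth

    def test_low_count_histograms_flagged(self):
        hist = self._hist([4] * 20)  # 80 elements, below the 100 floor
        assert classify_activity_pattern(hist).low_confidence
        assert not classify_activity_pattern(self._hist([5] * 20)).low_confidence

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            classify_activity_pattern(self._hist([0] * 20))

    def test_simulated_cohorts_type_as_planted(self):
        """Histograms simulated from the three generative shapes (with
        sampling noise) are recovered perfectly."""
        rng = np.random.default_rng(12)
        confusion = np.zeros((3, 3), dtype=int)
        order = {m: i for i, m in enumerate("abc")}
        for rep in range(5):
            for truth in "abc":
                weights = np.array(self._shape(truth), dtype=float)
                weights /= weights.sum()
                draws = rng.multinomial(2_000, weights)
                got = classify_activity_pattern(self._hist(draws.tolist())).model
                confusion[order[truth], order[got]] += 1
        assert np.trace(confusion) == confusion.sum()


class TestCountMetrics:
    def test_definitions(self):
        assert ltr_count_metrics(10, 5, 5) == (20, 30)

    def test_published_stack_total(self):
        stack, _ = ltr_count_metrics(9_826, 15_471, 5_924)
        assert stack == 31_221

    def test_uniform_planting_is_flat(self, small_pipeline):
        stats = small_pipeline.window_stats
        assert (stats["total_ltr"] == stats["paired"] + stats["solo"] + stats["nonsolo"]).all()
        assert (
            stats["insertion_equivalent"]
            == stats["paired"] + 2 * (stats["solo"] + stats["nonsolo"])
        ).all()
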