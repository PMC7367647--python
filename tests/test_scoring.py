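import numpy as np
import pytest
from scipy import stats

import plasmacin as pc
from plasmacin.scoring import (DEFAULT_CUTOFF, UncallableSegmentError,
                               category_of, track_longitudinal)


def _profile(grid, z, mask=None):
    mask = np.ones(grid.n_bins, bool) if mask is None else mask
    zz = np.asarray(z, float).copy()
    zz[~mask] = np.nan
    return pc.NormalizedProfile("s", grid, zz, mask)


class TestSegmentZ:
    def test_zero_bins_give_zero_z(self, mini_grid, mini_panel):
        prof = _profile(mini_grid, np.zeros(mini_grid.n_bins))
        sz = pc.segment_z(prof, mini_panel[0].interval)
        assert sz.seg_mean == 0.0 and sz.z == 0.0

    def test_stouffer_scaling_with_bin_count(self, mini_grid):
        prof = _profile(mini_grid, np.full(mini_grid.n_bins, 0.5))
        iv = pc.GenomicInterval("c1", 0, 20_000_000)  # 100 bins
        sz = pc.segment_z(prof, iv)
        assert sz.n_bins == 100
        assert sz.seg_mean == pytest.approx(0.5)
        assert sz.z == pytest.approx(5.0)

    def test_fully_masked_segment_is_uncallable(self, mini_grid):
        mask = np.ones(mini_grid.n_bins, bool)
        mask[:20] = False
        prof = _profile(mini_grid, np.zeros(mini_grid.n_bins), mask)
        with pytest.raises(UncallableSegmentError):
            pc.segment_z(prof, pc.GenomicInterval("c1", 0, 4_000_000))

    def test_null_segment_z_is_standard_normal(self, mini_grid):
        rng = np.random.default_rng(17)
        iv = pc.GenomicInterval("c1", 0, 10_000_000)  # 50 bins
        zs = []
        for _ in range(1000):
            prof = _profile(mini_grid, rng.normal(size=mini_grid.n_bins))
            zs.append(pc.segment_z(prof, iv).z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.9 < zs.std() < 1.1


class TestScorePanel:
    def test_all_null_scores_zero_category(self, mini_grid, mini_panel):
        prof = _profile(mini_grid, np.zeros(mini_grid.n_bins))
        score = pc.score_panel(prof, mini_panel)
        assert score.altered_count == 0
        assert score.category == "0"

    def test_cutoff_is_inclusive(self, mini_grid):
        # one-bin segment so the aggregated Z is exactly the bin Z
        seg = pc.PanelSegment(
            name="one+", direction="gain",
            interval=pc.GenomicInterval("c1", 0, 200_000))
        for value, expected in [(DEFAULT_CUTOFF, True),
                                (-DEFAULT_CUTOFF, True),
                                (np.nextafter(DEFAULT_CUTOFF, 0), False)]:
            z = np.zeros(mini_grid.n_bins)
            z[0] = value
            score = pc.score_panel(_profile(mini_grid, z), [seg])
            assert score.calls["one+"] is expected

    def test_matched_mode_ignores_wrong_direction(self, mini_grid, mini_panel):
        z = np.zeros(mini_grid.n_bins)
        seg = mini_panel[0]  # a gain segment
        bins = mini_grid.bins_in_interval(seg.interval)
        z[bins.start:bins.stop] = -1.0  # strong loss: |z| = sqrt(20)
        prof = _profile(mini_grid, z)
        assert pc.score_panel(prof, mini_panel,
                              direction_mode="absolute").altered_count == 1
        assert pc.score_panel(prof, mini_panel,
                              direction_mode="matched").altered_count == 0

    def test_null_call_rate_matches_two_sided_gaussian_tail(self, mini_grid,
                                                            mini_panel):
        rng = np.random.default_rng(23)
        calls = trials = 0
        for _ in range(1000):
            prof = _profile(mini_grid, rng.normal(size=mini_grid.n_bins))
            score = pc.score_panel(prof, mini_panel)
            calls += score.altered_count
            trials += len(score.segment_scores)
        expected = 2 * (1 - stats.norm.cdf(DEFAULT_CUTOFF))  # ~0.69%
        # 3-sigma band: the test draws this statistic once, from a fixed
        # seed, so it must not fail on ordinary binomial fluctuation
        ci = 3 * np.sqrt(expected * (1 - expected) / trials)
        assert abs(calls / trials - expected) <= ci

    def test_uncallable_segments_listed_not_counted(self, mini_grid,
                                                    mini_panel):
        mask = np.ones(mini_grid.n_bins, bool)
        first = mini_grid.bins_in_interval(mini_panel[0].interval)
        mask[first.start:first.stop] = False
        prof = _profile(mini_grid, np.zeros(mini_grid.n_bins), mask)
        score = pc.score_panel(prof, mini_panel)
        assert score.uncallable == [mini_panel[0].name]
        assert len(score.segment_scores) == len(mini_panel) - 1

    def test_screen_invariant_to_panel_order(self, mini_grid, mini_panel):
        rng = np.random.default_rng(5)
        prof = _profile(mini_grid, rng.normal(size=mini_grid.n_bins) * 2)
        a = pc.screen(pc.score_panel(prof, mini_panel))
        b = pc.screen(pc.score_panel(prof, mini_panel[::-1]))
        assert (a.positive, a.altered_count) == (b.positive, b.altered_count)


class TestScreen:
    @pytest.mark.parametrize("count,positive,category", [
        (0, False, "0"), (1, True, "1"), (2, True, "2"), (11, True, ">=3"),
    ])
    def test_positivity_rule_and_category(self, count, positive, category):
        score = pc.PanelScore(sample_id="s", segment_scores=[], calls={},
                              altered_count=count,
                              category=category_of(count),
                              cutoff=DEFAULT_CUTOFF,
                              direction_mode="absolute")
        call = pc.screen(score)
        assert call.positive is positive
        assert score.category == category


class TestTumorFractionMonotonicity:
    def test_expected_segment_z_grows_with_tumor_fraction(self, mini_grid,
                                                          mini_panel):
        seg = mini_panel[0]
        means = []
        for tf in (0.0, 0.05, 0.1, 0.2, 0.3):
            zs = []
            for rep in range(20):
                params = pc.SimulationParams(
                    grid=mini_grid, depth=2_000_000, tumor_fraction=tf,
                    events=(pc.CNVEvent(seg.interval, 3.0),),
                    seed=1000 * rep + int(tf * 100))
                prof, _ = pc.simulate_profile(params)
                controls = [pc.simulate_profile(
                    pc.SimulationParams(grid=mini_grid, depth=2_000_000,
                                        seed=50_000 + 97 * rep + c))[0]
                    for c in range(8)]
                ref = pc.build_reference(controls)
                nz = pc.normalize(prof, ref)
                zs.append(abs(pc.segment_z(nz, seg.interval).z))
            means.append(np.mean(zs))
        # monotone in expectation, up to Monte-Carlo noise of the batch means
        assert all(b >= a - 0.75 for a, b in zip(means[:-1], means[1:]))
        assert means[-1] > 2 * means[0]


class TestTrackLongitudinal:
    def _score(self, z_value, name="8q+"):
        sz = pc.SegmentZ(name=name, interval=None, n_bins=10,
                         seg_mean=z_value / np.sqrt(10), z=z_value)
        altered = abs(z_value) >= DEFAULT_CUTOFF
        return pc.PanelScore(sample_id="pt", segment_scores=[sz],
                             calls={name: altered},
                             altered_count=int(altered),
                             category=category_of(int(altered)),
                             cutoff=DEFAULT_CUTOFF, direction_mode="absolute")

    def test_single_timepoint(self):
        traj = track_longitudinal([self._score(6.63)])
        assert len(traj["8q+"]) == 1

    def test_relapse_series_flags_follow_cutoff(self):
        # published 8q trajectory of a relapsing patient, used as fixture
        series = [6.63, 2.46, 6.58, 11.8]
        traj = track_longitudinal([self._score(z) for z in series])
        flags = [altered for _, _, altered in traj["8q+"]]
        assert flags == [True, False, True, True]
        zs = [z for _, z, _ in traj["8q+"]]
        assert zs == pytest.approx(series)
        screens = [call.positive for _, call in traj["__screen__"]]
        assert screens == flags

    def test_all_below_cutoff_is_all_negative(self):
        traj = track_longitudinal([self._score(z) for z in (1.0, 0.5, 2.0)])
        assert not any(a for _, _, a in traj["8q+"])

    def test_mixed_panels_rejected(self):
        with pytest.raises(ValueError, match="panels"):
            track_longitudinal([self._score(1.0, "8q+"),
                                self._score(1.0, "1q+")])
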