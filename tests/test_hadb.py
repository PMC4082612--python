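"""Enrichment-zone heuristic: bins, allowance line, score threshold, labels."""

import numpy as np
import pandas as pd
import pytest

from peaktopo import hadb, synthetic
from peaktopo.hadb import DistanceBins, EnrichmentZone, ScoreBins


def make_bins(proportions, bin_width=5, max_distance=500):
    n = max_distance // bin_width
    props = np.asarray(proportions, dtype=float)
    assert props.size == n
    return DistanceBins(bin_width, max_distance, bin_width * np.arange(1, n + 1), props, n_peaks=1000)


class TestDistanceBins:
    def _hits(self, dists):
        return pd.DataFrame({"dist": dists})

    def test_all_hits_proximal(self):
        bins = hadb.compute_distance_bins(self._hits([0, 2, -3, 5, -5]), n_peaks=5)
        assert bins.proportions[0] == pytest.approx(1.0)
        assert bins.proportions[1:].sum() == 0

    def test_boundary_hit_in_inclusive_upper_bin(self):
        bins = hadb.compute_distance_bins(self._hits([5]), n_peaks=1)
        assert bins.upper_limits[0] == 5 and bins.proportions[0] == 1.0
        bins = hadb.compute_distance_bins(self._hits([6]), n_peaks=1)
        assert bins.proportions[1] == 1.0  # bin (5, 10]

    def test_uniform_distances_give_uniform_bins(self, rng):
        d = rng.uniform(0, 500, size=200_000)
        bins = hadb.compute_distance_bins(self._hits(d), n_peaks=200_000)
        assert np.allclose(bins.proportions, 0.01, atol=0.002)

    def test_denominator_is_all_peaks(self):
        bins = hadb.compute_distance_bins(self._hits([3, 700]), n_peaks=10)
        assert bins.proportions.sum() == pytest.approx(0.1)  # distant hit ignored

    def test_zero_peaks_rejected(self):
        with pytest.raises(ValueError):
            hadb.compute_distance_bins(self._hits([1]), n_peaks=0)


class TestBackgroundFit:
    def test_flat_background_zero_slope_zero_allowance(self):
        bins = make_bins([0.02] * 100)
        fit = hadb.fit_background_line(bins)
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(0.02)
        assert np.allclose(fit.residuals, 0.0)
        assert fit.allowance_offset == 0.0

    def test_known_line_with_spike_recovered(self):
        """Construct y = a + b x on the background range plus one spike."""
        uppers = 5.0 * np.arange(1, 101)
        props = 0.03 - 2e-5 * uppers
        props[80] += 0.01  # spike inside background range (upper = 405)
        bins = make_bins(props)
        fit = hadb.fit_background_line(bins)
        # oracle: closed-form least squares on the 60 background bins
        mask = bins.background_mask
        x, y = uppers[mask], props[mask]
        b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        a = y.mean() - b * x.mean()
        assert fit.slope == pytest.approx(b)
        assert fit.intercept == pytest.approx(a)
        # the spike is the largest residual, hence omitted from the allowance
        assert fit.residuals.max() == pytest.approx(0.01, rel=0.05)
        assert fit.allowance_offset < 0.01

    def test_allowance_is_twice_third_largest_residual(self):
        """Residuals (5,4,3,2,1)e-4: omit the two largest, take 2 x 3e-4."""
        uppers = 5.0 * np.arange(1, 101)
        props = np.full(100, 0.02)
        mask = (uppers > 200) & (uppers <= 500)
        idx = np.flatnonzero(mask)
        bumps = np.array([5, 4, 3, 2, 1]) * 1e-4
        props[idx[10:15]] += bumps
        bins = make_bins(props)
        fit = hadb.fit_background_line(bins)
        # the two largest bumps are omitted; the offset doubles the 3rd largest
        r = np.sort(fit.residuals)[::-1]
        assert fit.allowance_offset == pytest.approx(2 * r[2])
        assert fit.allowance_offset < 2 * r[1] < 2 * r[0]
        # 3rd-largest residual tracks the injected 3e-4 bump (minus the OLS shift)
        assert 4e-4 < fit.allowance_offset < 6e-4

    def test_fewer_than_five_background_bins_rejected(self):
        bins = hadb.compute_distance_bins(pd.DataFrame({"dist": [1]}), n_peaks=1,
                                          bin_width=5, max_distance=220)
        with pytest.raises(ValueError):
            hadb.fit_background_line(bins)


class TestEnrichmentZone:
    def test_worked_example_threshold_105(self):
        """Enrichment out to the 100-105 bp bin puts the threshold at 105."""
        props = np.full(100, 0.002)
        uppers = 5 * np.arange(1, 101)
        props[uppers <= 105] = 0.02  # enriched bins 5..105
        bins = make_bins(props)
        fit = hadb.fit_background_line(bins)
        zone = hadb.find_enrichment_zone(bins, fit)
        assert zone.enriched and zone.distance_threshold == 105
        assert zone.width == 210

    def test_no_bin_above_allowance_not_enriched(self):
        bins = make_bins([0.002] * 100)
        zone = hadb.find_enrichment_zone(bins, hadb.fit_background_line(bins))
        assert not zone.enriched and zone.distance_threshold == 0 and zone.width == 0

    def test_threshold_never_exceeds_background_low(self):
        props = np.full(100, 0.05)  # everything "enriched"
        bins = make_bins(props)
        fit = hadb.BackgroundFit(0.0, 0.0, np.zeros(60), 0.0)
        zone = hadb.find_enrichment_zone(bins, fit)
        assert zone.distance_threshold <= 200


class TestScoreBins:
    def test_bin81_convention(self):
        """Scores 80.5 and 81.0 fall in bin 81 (range 80 < s <= 81)."""
        assert hadb._score_to_bin(np.array([80.5, 81.0, 81.0001])).tolist() == [81, 81, 82]

    def test_central_count_conservation(self, syn_pfm, syn_pwm):
        _, seqs, _ = synthetic.make_peak_dataset(300, syn_pfm, f=0.5, seed=3)
        profile = hadb.ScanProfile.from_sequences(seqs, syn_pwm)
        zone = EnrichmentZone(100, True)
        sb = hadb.build_score_bins(profile, zone)
        top = profile.top_hits()
        assert sb.central.sum() == (np.abs(top["dist"]) <= 100).sum()
        assert sb.control.sum() == len(profile)  # every peak has a best control hit

    def test_unenriched_zone_rejected(self, syn_pfm, syn_pwm):
        _, seqs, _ = synthetic.make_peak_dataset(20, syn_pfm, f=0.0, seed=3)
        profile = hadb.ScanProfile.from_sequences(seqs, syn_pwm)
        with pytest.raises(ValueError, match="zone"):
            hadb.build_score_bins(profile, EnrichmentZone(0, False))


def step_score_bins(lo=86, boost=500, base=20):
    """Central = control everywhere except bins lo..100 boosted by a constant."""
    labels = np.arange(1, 101)
    control = np.full(100, base)
    central = control.copy()
    central[lo - 1 :] += boost
    return ScoreBins(labels, central, control)


class TestScoreThreshold:
    def test_central_equals_control_gives_no_threshold(self):
        sb = ScoreBins(np.arange(1, 101), np.full(100, 7), np.full(100, 7))
        assert hadb.find_score_threshold(sb) is None

    def test_step_function_flags_bin86_threshold_87(self):
        """Direct transcription of the scan rule on a constructed step."""
        assert hadb.find_score_threshold(step_score_bins(lo=86)) == 87

    def test_monotone_in_signal_fraction(self):
        """A stricter signal requirement never lowers the threshold."""
        rng = np.random.default_rng(5)
        control = rng.integers(0, 50, size=100)
        central = control + rng.integers(0, 30, size=100)
        central[70:] += 40
        sb = ScoreBins(np.arange(1, 101), central, control)
        t20 = hadb.find_score_threshold(sb, 0.20)
        t05 = hadb.find_score_threshold(sb, 0.05)
        assert t05 is not None and t20 is not None and t05 <= t20

    def test_isolated_passing_bin_not_flagged(self):
        control = np.full(100, 20)
        central = control.copy()
        central[49] += 500  # lone spike at bin 50
        central[90:] += 500  # well-supported block at the top
        sb = ScoreBins(np.arange(1, 101), central, control)
        assert hadb.find_score_threshold(sb) == 92  # flags bin 91, not the spike


class TestClassification:
    def test_all_planted_at_summit_nearly_all_direct(self, syn_pfm, syn_pwm):
        _, seqs, _ = synthetic.make_peak_dataset(
            400, syn_pfm, f=1.0, placement=("uniform", 0), min_site_score=90, seed=8
        )
        res = hadb.run_hadb(seqs, syn_pwm, seed=8)
        assert res.zone.enriched
        assert res.direct_fraction > 0.85

    def test_unenriched_zone_all_undetermined(self, syn_pfm, syn_pwm):
        _, seqs, _ = synthetic.make_peak_dataset(300, syn_pfm, f=0.0, seed=9)
        profile = hadb.ScanProfile.from_sequences(seqs, syn_pwm)
        labels, frac = hadb.classify_peaks(profile, EnrichmentZone(0, False), None)
        assert frac == 0.0 and (labels == "undetermined").all()

    def test_score_boundary_is_strictly_above_flagged_bin(self, syn_pfm, syn_pwm):
        _, seqs, _ = synthetic.make_peak_dataset(500, syn_pfm, f=0.7, seed=10)
        res = hadb.run_hadb(seqs, syn_pwm, seed=10)
        assert res.score_threshold is not None
        profile = hadb.ScanProfile.from_sequences(seqs, syn_pwm)
        best = profile.best_in_distance_window(np.abs(profile.dist) <= res.zone.distance_threshold)
        expected = best["rel_score"].to_numpy() > res.score_threshold - 1
        assert (res.per_peak_label.to_numpy() == np.where(expected, "direct", "undetermined")).all()


class TestReplicateConcordance:
    def _pooling(self, rng, n=200, p_direct_given_rep=0.9, p_direct_given_uniq=0.5):
        from peaktopo import peaks as pk

        regions, labels = [], {}
        pos = 1000
        for i in range(n):
            replicated = i % 2 == 0
            p = p_direct_given_rep if replicated else p_direct_given_uniq
            direct = rng.random() < p
            members = [("A", pk.Peak("chr1", pos - 50, pos + 51, peak_max=pos, id=f"a{i}"))]
            if replicated:
                members.append(("B", pk.Peak("chr1", pos - 40, pos + 61, peak_max=pos + 10, id=f"b{i}")))
            for rep, peak in members:
                labels[peak.id] = "direct" if direct else "undetermined"
            regions.append(pk.PooledRegion("chr1", members))
            pos += 5000
        return pk.ReplicatePooling(regions, 500), labels

    def test_p_matches_hypergeometric_oracle(self, rng):
        from test_overrep import hypergeom_tail_oracle

        pooling, labels = self._pooling(rng)
        p, table = hadb.replicate_concordance(pooling, labels)
        a, b = table[0]
        c, d = table[1]
        assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), abs=1e-12)
        assert p < 0.001  # strong planted association

    def test_discordant_regions_omitted(self, rng):
        from peaktopo import peaks as pk

        members = [
            ("A", pk.Peak("chr1", 950, 1151, peak_max=1050, id="a0")),
            ("B", pk.Peak("chr1", 960, 1161, peak_max=1060, id="b0")),
        ]
        pooling = pk.ReplicatePooling([pk.PooledRegion("chr1", members)], 500)
        labels = {"a0": "direct", "b0": "undetermined"}
        with pytest.warns(UserWarning):  # only region omitted -> degenerate margin
            p, table = hadb.replicate_concordance(pooling, labels)
        assert pooling.discordant_count == 1
        assert table.sum() == 0

    def test_degenerate_margin_returns_nan(self, rng):
        pooling, labels = self._pooling(rng, n=10, p_direct_given_rep=1.0, p_direct_given_uniq=1.0)
        with pytest.warns(UserWarning):
            p, _ = hadb.replicate_concordance(pooling, labels)
        assert np.isnan(p)


class TestAggregateByTf:
    def _result(self, width, threshold, frac):
        return hadb.HadbResult(
            zone=EnrichmentZone(width // 2, True),
            score_threshold=threshold,
            signal_fraction=0.2,
            per_peak_label=pd.Series(dtype=object),
            direct_fraction=frac,
        )

    def test_single_dataset_zero_dispersion(self):
        out = hadb.aggregate_by_tf({"d1": self._result(200, 85, 0.5)}, {"d1": "TFA"})
        row = out.iloc[0]
        assert row["mean_width"] == 200 and row["mean_pairwise_dwidth"] == 0.0

    def test_mean_pairwise_difference_example(self):
        """Widths 200/210/220 -> mean 210, mean pairwise |d| = 40/3."""
        results = {f"d{i}": self._result(w, 80 + i, 0.5) for i, w in enumerate([200, 210, 220])}
        out = hadb.aggregate_by_tf(results, {d: "TFA" for d in results})
        row = out.iloc[0]
        assert row["mean_width"] == pytest.approx(210)
        assert row["mean_pairwise_dwidth"] == pytest.approx((10 + 20 + 10) / 3)

    def test_matches_brute_force_pair_enumeration(self, rng):
        widths = rng.integers(100, 300, size=6).tolist()
        results = {f"d{i}": self._result(int(w) * 2 // 2 * 2, 80, 0.5) for i, w in enumerate(widths)}
        out = hadb.aggregate_by_tf(results, {d: "TFB" for d in results})
        ws = [r.zone.width for r in results.values()]
        pairs = [abs(a - b) for i, a in enumerate(ws) for b in ws[i + 1 :]]
        assert out.iloc[0]["mean_pairwise_dwidth"] == pytest.approx(np.mean(pairs))
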