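"""GFP, spatial correlation, GEV, AAHC clustering, fitting, window choice."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from evtopo import (
    CONDITIONS,
    EvokedDataset,
    aahc_cluster,
    fit_templates,
    gev,
    gfp,
    select_n_maps,
    select_window,
    spatial_correlation,
)
from evtopo.containers import average_reference


class TestGfp:
    def test_constant_map_has_zero_gfp(self):
        assert gfp(np.full(8, 3.3)) == 0.0

    def test_two_channel_closed_form(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0, abs=1e-15)

    def test_matches_population_sd_oracle(self, rng):
        for _ in range(100):
            v = rng.standard_normal(64)
            mean = v.sum() / 64
            oracle = np.sqrt(sum((x - mean) ** 2 for x in v) / 64)
            assert gfp(v) == pytest.approx(oracle, rel=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.array([1.0]))

    @given(
        arrays(float, 16, elements=st.floats(-100, 100)),
        st.floats(-50, 50),
        st.floats(0.1, 10),
    )
    def test_gfp_shift_invariant_scale_equivariant(self, v, shift, scale):
        """GFP ignores the reference (additive shifts) and scales linearly
        with field strength."""
        assert gfp(v + shift) == pytest.approx(gfp(v), abs=1e-9)
        assert gfp(scale * v) == pytest.approx(scale * gfp(v), rel=1e-9, abs=1e-9)


class TestSpatialCorrelationProperties:
    @given(
        arrays(float, 12, elements=st.floats(-10, 10)),
        arrays(float, 12, elements=st.floats(-10, 10)),
        st.floats(0.1, 5),
        st.floats(-20, 20),
    )
    def test_invariant_to_gain_and_reference(self, a, b, gain, offset):
        """Correlation between topographies ignores per-map gain and
        reference shifts; flipping one map's sign flips the sign."""
        if np.std(a) < 1e-6 or np.std(b) < 1e-6:
            return
        r = spatial_correlation(a, b)
        assert spatial_correlation(gain * a + offset, b) == pytest.approx(r, abs=1e-7)
        assert spatial_correlation(a, -b) == pytest.approx(-r, abs=1e-9)


class TestSpatialCorrelation:
    def test_self_and_inverse(self, rng):
        a = rng.standard_normal(32)
        assert spatial_correlation(a, a) == pytest.approx(1.0, abs=1e-12)
        assert spatial_correlation(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson_oracle(self, rng):
        for _ in range(100):
            a, b = rng.standard_normal((2, 16))
            r, _ = scipy.stats.pearsonr(a, b)
            assert spatial_correlation(a, b) == pytest.approx(r, rel=1e-10, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            spatial_correlation(np.ones(8), rng.standard_normal(8))


class TestGev:
    def test_perfect_templates_give_unity(self, rng):
        X = average_reference(rng.standard_normal((6, 4)), axis=1)
        labels = np.arange(6)
        assert gev(X, X.copy(), labels) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_map_gives_zero(self):
        X = np.tile([1.0, -1.0, 1.0, -1.0], (5, 1))
        ortho = np.array([[1.0, 1.0, -1.0, -1.0]])
        assert gev(X, ortho, np.zeros(5, int)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_summation(self, rng):
        """6-point, 4-channel instance against the literal per-timepoint
        (GFP * corr)^2 summation."""
        X = average_reference(rng.standard_normal((6, 4)), axis=1)
        maps = average_reference(rng.standard_normal((2, 4)), axis=1)
        labels = np.array([0, 1, 0, 1, 1, 0])
        num = 0.0
        den = 0.0
        for t in range(6):
            g = np.std(X[t])
            r = scipy.stats.pearsonr(X[t], maps[labels[t]])[0]
            num += (g * r) ** 2
            den += g**2
        assert gev(X, maps, labels) == pytest.approx(num / den, rel=1e-10)


# ---------------------------------------------------------------------------
# independent step-by-step AAHC oracle (plain loops, no shared code)


def aahc_oracle(X, q_wanted):
    """Brute-force AAHC: returns member partition (set of frozensets) and
    total GEV for the requested cluster count."""
    X = np.asarray(X, float)
    T = X.shape[0]
    Xc = [x - x.mean() for x in X]
    g = [np.std(x) for x in X]

    def unit(v):
        v = v - v.mean()
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    clusters = [[t] for t in range(T)]
    templates = [unit(X[t]) for t in range(T)]

    def corr(a, b):
        return float(np.dot(unit(a), unit(b)))

    while len(clusters) > q_wanted:
        contribs = []
        for members, tpl in zip(clusters, templates):
            c = 0.0
            for t in members:
                c += (g[t] * corr(Xc[t], tpl)) ** 2
            contribs.append(c)
        k = int(np.argmin(contribs))
        freed = clusters.pop(k)
        templates.pop(k)
        for t in freed:
            rs = [corr(Xc[t], tpl) for tpl in templates]
            best = int(np.argmax(rs))
            clusters[best].append(t)
        for j, members in enumerate(clusters):
            s = np.zeros(X.shape[1])
            for t in members:
                s += g[t] * Xc[t]
            templates[j] = unit(s)
    num = 0.0
    den = sum(gg**2 for gg in g)
    for members, tpl in zip(clusters, templates):
        for t in members:
            num += (g[t] * corr(Xc[t], tpl)) ** 2
    return {frozenset(m) for m in clusters}, num / den


class TestAahc:
    def test_two_alternating_maps_recovered_exactly(self):
        a = np.array([1.0, -1.0, 0.5, -0.5])
        b = np.array([-0.2, 0.8, -1.0, 0.4])
        X = average_reference(np.array([a, b, a, b, a, b] * 2), axis=1)
        sets = aahc_cluster(X, [1, 2, 3])
        two = sets[2]
        assert two.gev_total == pytest.approx(1.0, abs=1e-12)
        for planted in (a, b):
            rs = [abs(spatial_correlation(planted, m)) for m in two.maps]
            assert max(rs) == pytest.approx(1.0, abs=1e-10)

    def test_identical_maps_collapse_to_one(self):
        X = np.tile([2.0, -1.0, -1.0], (7, 1))
        one = aahc_cluster(X, [1])[1]
        assert one.q == 1 and one.gev_total == pytest.approx(1.0, abs=1e-12)

    def test_greedy_steps_match_bruteforce_oracle(self, rng):
        """Every atomize/reassign level of an 8-point, 4-channel run agrees
        with an independent loop-based re-implementation."""
        for trial in range(20):
            X = average_reference(rng.standard_normal((8, 4)), axis=1)
            sets = aahc_cluster(X, [2, 3, 4, 5])
            for q in (5, 4, 3, 2):
                partition_o, gev_o = aahc_oracle(X, q)
                lab = sets[q].labels
                partition_i = {
                    frozenset(np.flatnonzero(lab == k)) for k in range(q)
                }
                assert partition_i == partition_o, f"trial {trial} q={q}"
                assert sets[q].gev_total == pytest.approx(gev_o, rel=1e-10)

    def test_gev_nondecreasing_in_q(self, rng):
        X = average_reference(rng.standard_normal((40, 8)), axis=1)
        sets = aahc_cluster(X, range(1, 11))
        gevs = [sets[q].gev_total for q in sorted(sets)]
        assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            aahc_cluster(np.empty((0, 4)))


class TestSelectNMaps:
    def test_planted_two_map_data_selects_two(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        X = average_reference(np.array([a, a, b, b, a, b, a, a]), axis=1)
        hierarchy = aahc_cluster(X, range(1, 5))
        q_star, _ = select_n_maps(hierarchy, 0.90)
        assert q_star == 2

    def test_selector_unique_and_threshold_consistent(self, rng):
        protos = average_reference(rng.standard_normal((3, 8)), axis=1)
        X = protos[rng.integers(0, 3, 30)] + 0.15 * rng.standard_normal((30, 8))
        X = average_reference(X, axis=1)
        hierarchy = aahc_cluster(X, range(1, 11))
        q_star, kl = select_n_maps(hierarchy, 0.90)
        assert hierarchy[q_star].gev_total >= 0.90
        assert all(
            hierarchy[q].gev_total < 0.90 for q in hierarchy if q < q_star
        )
        assert all(v >= 0 for v in kl.values())


def _evoked_from_maps(montage4, seq, sfreq=1000.0):
    """Evoked dataset whose every cell equals the given topography series."""
    wave = average_reference(np.array(seq).T, axis=0)
    data = {("S01", c): wave for c in CONDITIONS}
    return EvokedDataset(
        evoked=data, sfreq=sfreq, t0_offset=0.0, montage=montage4
    )


class TestFitTemplates:
    def test_pure_template_data_takes_full_window(self, montage4):
        A = np.array([1.0, -1.0, 0.5, -0.5])
        B = np.array([-1.0, 0.3, 1.0, -0.3])
        ev = _evoked_from_maps(montage4, [A] * 35, sfreq=1000.0)
        fit = fit_templates(ev, np.stack([A, B]), (0.0, 35.0))
        tab = fit.table.set_index(["condition", "map"])
        for c in CONDITIONS:
            assert tab.loc[(c, 0), "duration_ms"] == pytest.approx(35.0)
            assert tab.loc[(c, 1), "duration_ms"] == 0.0
            assert np.isnan(tab.loc[(c, 1), "mean_gfp_uv"])

    def test_durations_sum_to_window_exactly(self, montage4, rng):
        maps = average_reference(rng.standard_normal((3, 4)), axis=1)
        seq = [rng.standard_normal(4) for _ in range(50)]
        ev = _evoked_from_maps(montage4, seq, sfreq=1000.0)
        fit = fit_templates(ev, maps, (10.0, 42.0))
        sums = fit.table.groupby(["subject", "condition"])["duration_ms"].sum()
        assert (sums == 32.0).all()

    def test_tie_breaks_to_lowest_map_index(self, montage4):
        A = np.array([1.0, -1.0, 1.0, -1.0])
        ev = _evoked_from_maps(montage4, [A] * 10, sfreq=1000.0)
        fit = fit_templates(ev, np.stack([A, A.copy()]), (0.0, 10.0))
        tab = fit.table.set_index(["condition", "map"])
        assert tab.loc[(CONDITIONS[0], 0), "duration_ms"] == pytest.approx(10.0)
        assert tab.loc[(CONDITIONS[0], 1), "duration_ms"] == 0.0

    def test_window_outside_epoch_rejected(self, montage4, rng):
        ev = _evoked_from_maps(montage4, [rng.standard_normal(4)] * 10, sfreq=1000.0)
        with pytest.raises(ValueError, match="outside the epoch"):
            fit_templates(ev, np.eye(4)[:2] - 0.25, (500.0, 600.0))


class TestSelectWindow:
    times = np.arange(0.0, 100.0, 10.0)

    def test_single_fully_consistent_segment_returned(self):
        labels = {c: np.zeros(10, int) for c in CONDITIONS}
        pvals = {c: np.full(10, 0.001) for c in CONDITIONS}
        g = np.linspace(0, 1, 10)
        sel = select_window(labels, pvals, g, self.times)
        assert sel.window_ms == (0.0, 100.0)
        assert sel.eligible_ms == [(0.0, 100.0)]

    def test_no_consistent_sample_warns_and_returns_none(self):
        labels = {c: np.zeros(10, int) for c in CONDITIONS}
        pvals = {c: np.full(10, 0.5) for c in CONDITIONS}
        pvals[CONDITIONS[0]] = np.full(10, 0.001)  # one condition alone
        with pytest.warns(UserWarning, match="no clustering segment"):
            sel = select_window(labels, pvals, np.ones(10), self.times)
        assert sel.window_ms is None and sel.eligible_ms == []

    def test_window_is_consistent_overlap_of_peak_segment(self):
        """A label change splits the series; within the GFP-peak segment only
        the consistent run around the peak is returned."""
        lab = np.array([0] * 5 + [1] * 5)
        labels = {c: lab for c in CONDITIONS}
        p = np.full(10, 0.001)
        p[1] = 0.8  # inconsistent sample inside the first segment
        pvals = {c: p for c in CONDITIONS}
        g = np.zeros(10)
        g[3] = 5.0  # peak in the first segment, after the bad sample
        sel = select_window(labels, pvals, g, self.times)
        assert sel.window_ms == (20.0, 50.0)
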