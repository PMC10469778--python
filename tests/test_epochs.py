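"""Trial rules, canonical grid, resampling, z-scoring, grand averaging."""

import numpy as np
import pytest

from speechbeta.epochs import (
    assemble_timecourse,
    build_trials,
    canonical_grid,
    derive_isp_intervals,
    grand_average,
    resample_interval,
    zscore_session,
)
from speechbeta.session_io import Annotation


from tests_helpers import session_from_gaps


class TestIspIntervals:
    def test_adjacent_end_start_pairs(self):
        anns = [
            Annotation(0.5, 0.6, 1.0, "bi"),
            Annotation(1.8, 1.9, 2.5, "di"),
            Annotation(3.0, 3.1, 3.5, "ti"),
        ]
        assert derive_isp_intervals(anns) == [(1.0, 1.8), (2.5, 3.0)]

    def test_single_utterance_no_intervals(self):
        assert derive_isp_intervals([Annotation(0.5, 0.6, 1.0, "bi")]) == []

    def test_overlap_rejected(self):
        anns = [Annotation(0.5, 0.6, 2.0, "bi"), Annotation(1.9, 2.1, 2.5, "di")]
        with pytest.raises(ValueError):
            derive_isp_intervals(anns)


class TestBuildTrials:
    def test_only_boundary_exclusion(self):
        ts = build_trials(session_from_gaps([900] * 5))
        assert len(ts.included) == 4
        assert ts.tally == {"boundary": 2}

    def test_hand_enumerated_five_utterance_set(self):
        # gaps 700/400/900/600 ms: only the trial flanked by 900 and 600 survives
        ts = build_trials(session_from_gaps([700, 400, 900, 600]))
        assert len(ts.included) == 1
        survivor = ts.included[0]
        assert survivor.isp1_len_s == pytest.approx(0.9)
        assert survivor.isp2_len_s == pytest.approx(0.6)
        assert ts.tally == {"boundary": 2, "short_isp": 2}

    def test_vowel_filter_excludes_all(self):
        ts = build_trials(session_from_gaps([900] * 4, labels=["ba"] * 5))
        assert len(ts.included) == 0
        assert ts.tally == {"boundary": 2, "vowel": 3}

    def test_invalid_interval_overlap_excluded_first(self):
        # middle trial overlaps an invalid span; tally goes to 'invalid'
        # even though its label would also fail the vowel filter
        labels = ["bi", "bi", "ba", "bi", "bi"]
        sess = session_from_gaps([900] * 4, labels=labels, invalid=[(3.0, 3.3)])
        ts = build_trials(sess)
        assert ts.tally["invalid"] >= 1
        assert ts.check_conservation()

    def test_conservation_of_counts(self):
        ts = build_trials(
            session_from_gaps([700, 400, 900, 600, 300, 1000], invalid=[(4.0, 4.2)])
        )
        assert ts.check_conservation()


class TestResampleInterval:
    def test_constant_preserved_exactly(self):
        out = resample_interval(np.full(13, 2.5), 327)
        assert len(out) == 327
        assert np.max(np.abs(out - 2.5)) < 1e-9

    def test_identity_when_lengths_equal(self):
        x = np.sin(np.arange(50))
        out = resample_interval(x, 50)
        assert np.array_equal(out, x)

    def test_round_trip_of_periodic_oversampled_sinusoid(self):
        # integer number of cycles: band-limited round trip is near exact
        t = np.arange(200) / 200.0
        x = np.sin(2 * np.pi * 5 * t)
        back = resample_interval(resample_interval(x, 600), 200)
        assert np.max(np.abs(back - x)) < 1e-6

    def test_degenerate_lengths_rejected(self):
        with pytest.raises(ValueError):
            resample_interval(np.ones(1), 10)
        with pytest.raises(ValueError):
            resample_interval(np.ones(10), 1)


class TestCanonicalGrid:
    def test_grid_at_deposited_sample_rate(self):
        lengths, boundaries = canonical_grid(3052.0)
        assert lengths == (1526, 327, 1184, 1526)
        assert boundaries == (1526, 1853, 3037)
        assert sum(lengths) == 4563

    def test_grid_at_test_sample_rate(self):
        lengths, boundaries = canonical_grid(1000.0)
        assert lengths == (500, 107, 388, 500)
        assert boundaries == (500, 607, 995)


class TestAssembleTimecourse:
    def test_piecewise_constant_segments_preserved(self):
        fs = 1000.0
        (isp_n, c_t, v_t, _), bounds = canonical_grid(fs)
        pad, c_len, v_len = 500, 93, 401
        window = np.concatenate(
            [
                np.full(pad, 9.0),
                np.full(isp_n, 1.0),
                np.full(c_len, 2.0),
                np.full(v_len, 3.0),
                np.full(isp_n, 4.0),
                np.full(pad, 9.0),
            ]
        )
        tc = assemble_timecourse(window, fs, c_len, v_len, pad)
        assert len(tc.values) == sum((isp_n, c_t, v_t, isp_n))
        assert tc.boundaries == bounds
        b1, b2, b3 = bounds
        assert np.allclose(tc.values[:b1], 1.0)
        assert np.allclose(tc.values[b1:b2], 2.0, atol=1e-9)
        assert np.allclose(tc.values[b2:b3], 3.0, atol=1e-9)
        assert np.allclose(tc.values[b3:], 4.0)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            assemble_timecourse(np.zeros(100), 1000.0, 93, 401, 500)


class TestZScore:
    def test_pooled_moments_identity(self, rng):
        z, _, _ = zscore_session(rng.gamma(2.0, size=(20, 300)))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_affine_invariance_to_session_scale(self, rng):
        x = rng.gamma(2.0, size=(10, 100))
        z1, _, _ = zscore_session(x)
        z2, _, _ = zscore_session(10.0 * x)
        assert np.allclose(z1, z2)

    def test_constant_session_rejected(self):
        with pytest.raises(ValueError):
            zscore_session(np.full((5, 50), 3.0))


class TestGrandAverage:
    def test_identical_sessions_zero_se(self):
        fs = 1000.0
        n = sum(canonical_grid(fs)[0])
        x = np.tile(np.sin(np.arange(n) / 50.0), (5, 1))
        g = grand_average(x, fs, band="beta")
        assert np.allclose(g.values, x[0])
        assert np.allclose(g.se, 0.0)
        assert g.n_units == 5

    def test_two_constant_sessions(self):
        fs = 1000.0
        n = sum(canonical_grid(fs)[0])
        x = np.vstack([np.full(n, 1.0), np.full(n, 3.0)])
        g = grand_average(x, fs)
        assert np.allclose(g.values, 2.0)
        assert np.allclose(g.se, 1.0)  # sample SD sqrt(2) / sqrt(2)

    def test_sigma_over_n_option(self):
        fs = 1000.0
        n = sum(canonical_grid(fs)[0])
        x = np.vstack([np.full(n, 1.0), np.full(n, 3.0)])
        g = grand_average(x, fs, se_mode="sd_over_n")
        assert np.allclose(g.se, np.sqrt(2.0) / 2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grand_average(np.zeros((3, 100)), 1000.0)
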