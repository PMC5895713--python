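"""Step-1 tests: spectrogram, signatures, candidates, association, editing."""

import itertools
import math

import numpy as np
import pytest

import efishgrid as eg
from efishgrid.frequency_tracker import (
    Candidate,
    Signature,
    _assign,
    _gated_cost,
    cluster_candidates,
)
from efishgrid.simulator import DEFAULT_KA


FS = 20_000.0


def tone(f, amp=1.0, duration=2.0, fs=FS, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.cos(2 * np.pi * f * t + phase)


def eod_like(f, amp=1.0, gamma=0.25, duration=2.0, fs=FS):
    return tone(f, amp, duration, fs) + tone(2 * f, gamma * amp, duration, fs)


def make_candidate(t, f0, amps, n_elec=9, amp2_ratio=0.25, phases=None):
    """Synthetic candidate with given per-electrode fundamental amplitudes."""
    amps = np.asarray(amps, float)
    mask = ~np.isnan(amps)
    phase1 = np.where(
        mask, 0.0 if phases is None else np.asarray(phases, float), np.nan
    )
    members = [
        Signature(int(e), t, f0, float(amps[e]), float(phase1[e]),
                  float(amps[e] * amp2_ratio), 0.0)
        for e in np.flatnonzero(mask)
    ]
    return Candidate(
        t=t, f0=f0, members=members, amp1=amps, phase1=phase1,
        amp2=amps * amp2_ratio, phase2=np.where(mask, 0.0, np.nan), mask=mask,
    )


class TestSpectrogram:
    def test_pure_tone_peaks_at_nearest_bin(self):
        cfg = eg.TrackerConfig()
        stack = eg.compute_spectrogram(tone(400.0)[:, None], FS, cfg)
        mag = np.abs(stack.coeffs[0, :, 0])
        assert stack.freqs[int(np.argmax(mag))] == pytest.approx(400.0, abs=stack.df)
        # amplitude scaling: bin-centered unit cosine has unit magnitude
        assert mag.max() == pytest.approx(1.0, rel=1e-3)

    def test_dc_only_input_has_no_band_signatures(self):
        cfg = eg.TrackerConfig(tau1=0.01)
        stack = eg.compute_spectrogram(np.ones((40_000, 2)), FS, cfg)
        sigs = eg.detect_signatures(stack, cfg)
        assert all(not s for s in sigs)

    def test_harmonic_magnitude_ratio_preserved(self):
        cfg = eg.TrackerConfig()
        stack = eg.compute_spectrogram(eod_like(400.0, gamma=1 / 8)[:, None], FS, cfg)
        mag = np.abs(stack.coeffs[0, :, 0])
        k1 = int(np.argmin(np.abs(stack.freqs - 400.0)))
        k2 = int(np.argmin(np.abs(stack.freqs - 800.0)))
        assert mag[k2] / mag[k1] == pytest.approx(1 / 8, rel=1e-3)

    def test_too_short_recording_names_the_window(self):
        cfg = eg.TrackerConfig()
        with pytest.raises(ValueError, match="analysis window"):
            eg.compute_spectrogram(np.zeros((1000, 2)), FS, cfg)

    def test_low_sample_rate_names_the_constraint(self):
        cfg = eg.TrackerConfig()
        with pytest.raises(ValueError, match="second harmonic"):
            eg.compute_spectrogram(np.zeros((5000, 2)), 2000.0, cfg)


class TestSignatures:
    def test_out_of_band_peak_rejected(self):
        cfg = eg.TrackerConfig(tau1=0.01)
        stack = eg.compute_spectrogram(
            (tone(150.0) + tone(300.0, 0.05))[:, None], FS, cfg
        )
        sigs = [s for w in eg.detect_signatures(stack, cfg) for s in w]
        assert all(s.f0 >= 200.0 for s in sigs)

    def test_missing_second_harmonic_rejected(self):
        cfg = eg.TrackerConfig(tau1=0.01)
        stack = eg.compute_spectrogram(tone(400.0)[:, None], FS, cfg)
        sigs = [s for w in eg.detect_signatures(stack, cfg) for s in w]
        assert not sigs

    def test_thresholds_are_inclusive_at_ratio_one_eighth(self):
        tau1 = 0.05
        cfg = eg.TrackerConfig(tau1=tau1)
        x = eod_like(400.0, amp=2 * tau1, gamma=1 / 8)
        stack = eg.compute_spectrogram(x[:, None], FS, cfg)
        sigs = [s for w in eg.detect_signatures(stack, cfg) for s in w]
        assert sigs
        assert all(abs(s.f0 - 400.0) < 0.1 for s in sigs)

    def test_emitted_signatures_respect_band_and_thresholds(self, rng):
        cfg = eg.TrackerConfig(tau1=0.02)
        x = rng.normal(0, 0.05, (40_000, 3))
        for f, amp in ((250.0, 0.4), (430.0, 0.6), (660.0, 0.3)):
            x += eod_like(f, amp, 0.3)[:, None]
        stack = eg.compute_spectrogram(x, FS, cfg)
        sigs = [s for w in eg.detect_signatures(stack, cfg) for s in w]
        assert sigs
        for s in sigs:
            assert cfg.band_low <= s.f0 <= cfg.band_high
            assert s.amp1 >= cfg.tau1
            assert s.amp2 >= cfg.tau_ratio * cfg.tau1

    def test_harmonic_image_of_lower_fundamental_vetoed(self):
        # 340 Hz fundamental whose second harmonic at 680 Hz is in-band
        cfg = eg.TrackerConfig(tau1=0.01)
        x = eod_like(340.0, amp=1.0, gamma=0.4) + tone(1360.0, 0.06)
        stack = eg.compute_spectrogram(x[:, None], FS, cfg)
        sigs = [s for w in eg.detect_signatures(stack, cfg) for s in w]
        assert sigs
        assert all(abs(s.f0 - 340.0) < 1.0 for s in sigs)


class TestCandidates:
    def test_three_electrode_agreement_forms_one_candidate(self):
        sigs = [
            Signature(e, 1.0, 400.0 + 0.01 * e, 1.0, 0.0, 0.2, 0.0)
            for e in range(3)
        ]
        cands = cluster_candidates(sigs, 9, eg.TrackerConfig())
        assert len(cands) == 1
        assert cands[0].n_votes == 3
        assert cands[0].f0 == pytest.approx(400.01, abs=0.02)

    def test_single_electrode_signature_eliminated(self):
        sigs = [Signature(4, 1.0, 512.0, 1.0, 0.0, 0.2, 0.0)]
        assert cluster_candidates(sigs, 9, eg.TrackerConfig()) == []

    def test_distant_frequencies_stay_separate(self):
        sigs = [
            Signature(e, 0.0, f, 1.0, 0.0, 0.2, 0.0)
            for f in (400.0, 405.0)
            for e in range(2)
        ]
        cands = cluster_candidates(sigs, 9, eg.TrackerConfig(cluster_tol=0.5))
        assert [round(c.f0) for c in cands] == [400, 405]

    def test_mixed_times_rejected(self):
        sigs = [
            Signature(0, 0.0, 400.0, 1.0, 0.0, 0.2, 0.0),
            Signature(1, 1.0, 400.0, 1.0, 0.0, 0.2, 0.0),
        ]
        with pytest.raises(ValueError, match="one time"):
            cluster_candidates(sigs, 9, eg.TrackerConfig())

    def test_weighted_consensus_favors_strong_electrodes(self):
        sigs = [
            Signature(0, 0.0, 400.0, 10.0, 0.0, 2.0, 0.0),
            Signature(1, 0.0, 400.4, 0.1, 0.0, 0.02, 0.0),
        ]
        cands = cluster_candidates(sigs, 9, eg.TrackerConfig())
        assert cands[0].f0 == pytest.approx(400.004, abs=1e-3)


class TestAssociation:
    def cands_two_sources(self, n_windows=30, hop=0.25):
        out = []
        for k in range(n_windows):
            t = 0.25 + k * hop
            out.append(make_candidate(t, 400.0, [5, 4, 3, 2, 1, 1, 1, 1, 1]))
            out.append(make_candidate(t, 430.0, [1, 1, 1, 1, 1, 2, 3, 4, 5]))
        return out

    def test_two_constant_sources_give_two_full_tracks(self):
        cfg = eg.TrackerConfig()
        tracks = eg.associate_tracks(self.cands_two_sources(), cfg)
        assert len(tracks) == 2
        assert all(len(t.candidates) == 30 for t in tracks)
        for t in tracks:
            t.validate(cfg)

    def test_six_second_silence_starts_new_track(self):
        cfg = eg.TrackerConfig(min_track_windows=5)
        cands = []
        for k in range(20):
            cands.append(make_candidate(0.25 + k * 0.25, 400.0, [3] * 9))
        for k in range(20):
            cands.append(make_candidate(0.25 + (k + 44) * 0.25, 400.0, [3] * 9))
        tracks = eg.associate_tracks(cands, cfg)
        assert len(tracks) == 2  # 6 s > the 5 s maximum gap

    def test_gap_within_five_seconds_is_bridged(self):
        cfg = eg.TrackerConfig(min_track_windows=5)
        cands = []
        for k in range(20):
            cands.append(make_candidate(0.25 + k * 0.25, 400.0, [3] * 9))
        for k in range(20):
            cands.append(make_candidate(0.25 + (k + 36) * 0.25, 400.0, [3] * 9))
        tracks = eg.associate_tracks(cands, cfg)
        assert len(tracks) == 1  # 4 s gap closed by the multi-pass association

    def test_frequency_gate_blocks_jumps(self):
        cfg = eg.TrackerConfig(min_track_windows=1)
        cands = [
            make_candidate(0.25, 400.0, [3] * 9),
            make_candidate(0.50, 402.0, [3] * 9),
        ]
        tracks = eg.associate_tracks(cands, cfg)
        assert len(tracks) == 2  # 2 Hz jump exceeds the 1 Hz gate

    def test_crossing_resolved_by_amplitude_profiles(self):
        # at the crossing window both assignments satisfy the frequency
        # gate; the Hungarian optimum must pick the amplitude-consistent one
        cfg = eg.TrackerConfig()
        tail_a = make_candidate(1.0, 440.0, [9, 9, 9, 1, 1, 1, 1, 1, 1])
        tail_b = make_candidate(1.0, 440.4, [1, 1, 1, 1, 1, 1, 9, 9, 9])
        new_a = make_candidate(1.25, 440.4, [9, 9, 9, 1, 1, 1, 1, 1, 1])
        new_b = make_candidate(1.25, 440.0, [1, 1, 1, 1, 1, 1, 9, 9, 9])
        cost = _gated_cost([tail_a, tail_b], [new_a, new_b], 3.0, cfg)
        pairs = dict(_assign(cost))
        assert pairs == {0: 0, 1: 1}  # identity carried, frequencies swapped
        # and the Hungarian cost equals the brute-force minimum
        brute = min(
            cost[0, p[0]] + cost[1, p[1]]
            for p in itertools.permutations(range(2))
        )
        assert cost[0, 0] + cost[1, 1] == pytest.approx(brute)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_hungarian_equals_brute_force(self, n, rng):
        cfg = eg.TrackerConfig()
        for _ in range(10):
            f0 = 400.0
            rows = [
                make_candidate(1.0, f0 + rng.uniform(-0.3, 0.3),
                               rng.uniform(0.5, 5.0, 9))
                for _ in range(n)
            ]
            cols = [
                make_candidate(1.25, f0 + rng.uniform(-0.3, 0.3),
                               rng.uniform(0.5, 5.0, 9))
                for _ in range(n)
            ]
            cost = _gated_cost(rows, cols, 1.0, cfg)
            pairs = _assign(cost)
            hung = sum(cost[i, j] for i, j in pairs)
            brute = min(
                sum(cost[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert hung == pytest.approx(brute, rel=1e-12)

    def test_track_continuity_invariants_hold(self, rng):
        cfg = eg.TrackerConfig(min_track_windows=1)
        cands = []
        for k in range(40):
            t = 0.25 * (k + 1)
            f = 400.0 + 0.8 * math.sin(k / 5)
            cands.append(make_candidate(t, f, rng.uniform(1, 4, 9)))
            if k % 7 == 0:
                cands.append(make_candidate(t, 500.0, [2] * 9))
        for tr in eg.associate_tracks(cands, cfg):
            tr.validate(cfg)


class TestEditTracks:
    def base_tracks(self):
        cfg = eg.TrackerConfig(min_track_windows=1)
        cands = [make_candidate(0.25 * (k + 1), 400.0, [3] * 9) for k in range(10)]
        more = [make_candidate(0.25 * (k + 1), 430.0, [2] * 9) for k in range(10)]
        return eg.associate_tracks(cands + more, cfg), cfg

    def test_split_partitions_candidates(self):
        tracks, cfg = self.base_tracks()
        out = eg.edit_tracks(tracks, "split", cfg, track_id=0, at_time=1.3)
        assert len(out) == 3
        parts = [t for t in out if t.provenance == "edited"]
        assert sum(len(t.candidates) for t in parts) == 10

    def test_delete_removes_track(self):
        tracks, cfg = self.base_tracks()
        out = eg.edit_tracks(tracks, "delete", cfg, track_id=1)
        assert [t.track_id for t in out] == [0]
        with pytest.raises(KeyError):
            eg.edit_tracks(out, "delete", cfg, track_id=99)

    def test_join_respects_gates(self):
        tracks, cfg = self.base_tracks()
        a = eg.edit_tracks(tracks, "split", cfg, track_id=0, at_time=1.3)
        ids = sorted(t.track_id for t in a)
        # splitting leaves adjacent halves: joining them back is legal
        rejoined = eg.edit_tracks(a, "join", cfg, track_id=0, other_id=ids[-1])
        assert len(rejoined) == 2
        # joining across 30 Hz is blocked without force
        cands_a = [make_candidate(0.25 * (k + 1), 400.0, [3] * 9) for k in range(4)]
        cands_b = [make_candidate(2.0 + 0.25 * k, 430.0, [3] * 9) for k in range(4)]
        two = [eg.FrequencyTrack(0, cands_a), eg.FrequencyTrack(1, cands_b)]
        with pytest.raises(ValueError, match="force"):
            eg.edit_tracks(two, "join", cfg, track_id=0, other_id=1)
        forced = eg.edit_tracks(
            two, "join", cfg, track_id=0, other_id=1, force=True
        )
        assert len(forced) == 1
        # overlapping tracks can never be joined
        with pytest.raises(ValueError, match="overlap"):
            eg.edit_tracks(tracks, "join", cfg, track_id=0, other_id=1)

    def test_join_within_gates_merges(self):
        cfg = eg.TrackerConfig(min_track_windows=1)
        first = [make_candidate(0.25 * (k + 1), 400.0, [3] * 9) for k in range(8)]
        second = [
            make_candidate(0.25 * (k + 1) + 4.0, 400.4, [3] * 9) for k in range(8)
        ]
        tracks = [
            eg.FrequencyTrack(0, first),
            eg.FrequencyTrack(1, second),
        ]
        out = eg.edit_tracks(tracks, "join", cfg, track_id=0, other_id=1)
        assert len(out) == 1
        assert len(out[0].candidates) == 16

    def test_reassign_moves_candidate(self):
        cfg = eg.TrackerConfig(min_track_windows=1)
        first = [make_candidate(0.25 * (k + 1), 400.0, [3] * 9) for k in range(8)]
        later = [make_candidate(2.25 + 0.25 * k, 400.3, [2] * 9) for k in range(4)]
        tracks = [eg.FrequencyTrack(0, first), eg.FrequencyTrack(1, later)]
        out = eg.edit_tracks(
            tracks, "reassign", cfg, track_id=1, at_time=2.25, to_id=0
        )
        dst = [t for t in out if t.track_id == 0][0]
        src = [t for t in out if t.track_id == 1][0]
        assert len(dst.candidates) == 9 and dst.provenance == "edited"
        assert len(src.candidates) == 3


class TestMeasuredObservation:
    def test_antiphase_groups_get_opposite_signs(self, lab_grid):
        phases = [0.1] * 5 + [0.1 + math.pi] * 4
        cand = make_candidate(1.0, 400.0, [3, 3, 3, 3, 3, 2, 2, 2, 2],
                              phases=phases)
        track = eg.FrequencyTrack(0, [cand])
        obs = eg.measured_observation(track, 1.0, lab_grid, eg.TrackerConfig())
        assert obs.valid
        signed = obs.values  # components: s_i - s_ref, ref in antiphase group
        # reconstruct signs: electrodes 0-4 positive, 5-8 negative vs anchor
        s = np.array([3, 3, 3, 3, 3, -2, -2, -2, -2], float)
        expected = s[:8] - s[8]
        np.testing.assert_allclose(
            signed, expected / np.linalg.norm(expected), atol=1e-12
        )

    def test_too_few_electrodes_invalid(self, lab_grid):
        amps = [np.nan] * 9
        amps[0], amps[8] = 3.0, 2.0
        cand = make_candidate(1.0, 400.0, amps, phases=[0.0] * 9)
        track = eg.FrequencyTrack(0, [cand])
        obs = eg.measured_observation(track, 1.0, lab_grid, eg.TrackerConfig())
        assert not obs.valid

    def test_missing_reference_invalid(self, lab_grid):
        amps = [3.0] * 8 + [np.nan]
        cand = make_candidate(1.0, 400.0, amps, phases=[0.0] * 9)
        track = eg.FrequencyTrack(0, [cand])
        obs = eg.measured_observation(track, 1.0, lab_grid, eg.TrackerConfig())
        assert not obs.valid

    def test_forward_inverse_consistency_noiseless(self, lab_grid):
        from efishgrid.dipole_model import DipoleSource, EODWaveform
        from efishgrid.simulator import make_trajectory

        pose = (68.0, 52.0, 9.0, 1.1)
        times, states = make_trajectory("static", 4.0, start=pose)
        src = DipoleSource(
            "f1", DEFAULT_KA,
            EODWaveform(f=412.0, gamma=0.3, psi=0.7, xi=2.1), times, states,
        )
        scene = eg.Scene(grid=lab_grid, sources=[src], duration=4.0,
                         sensor_std=0.0, seed=0)
        samples, _ = eg.synthesize_recording(scene)
        cfg = eg.TrackerConfig()
        tracks = eg.track_frequencies(samples, scene.fs, 9, cfg)
        assert len(tracks) == 1
        h = eg.observation_map(eg.DipoleState(*pose), lab_grid).values
        for c in tracks[0].candidates:
            obs = eg.measured_observation(tracks[0], c.t, lab_grid, cfg)
            assert obs.valid and obs.valid_mask.all()
            err = min(
                np.abs(obs.values - h).max(), np.abs(obs.values + h).max()
            )
            assert err < 1e-3
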