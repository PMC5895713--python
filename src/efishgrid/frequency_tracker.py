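"""Frequency-domain identification of individual fish (Step 1).

Each wave-type fish broadcasts a quasi-sinusoidal discharge whose fundamental
frequency is (except during brief social interactions) unique to the
individual.  This module turns a multichannel grid recording into per-fish
*frequency tracks*:

(a) a short-time Fourier transform per electrode; spectral peaks whose
    fundamental lies in the species band and exceeds a magnitude threshold
    tau1, and whose second harmonic exceeds tau2 = tau1/8, become
    "signatures";
(b) signatures at one time window are clustered by fundamental frequency;
    clusters seen on at least ``min_votes`` distinct electrodes become
    "candidates" (the voting suppresses single-electrode noise);
(c) candidates are associated across time with the Hungarian algorithm,
    using Euclidean distance over the candidates' fundamental and second
    harmonic amplitudes, gated at 1 Hz of frequency difference; unmatched
    candidates two windows apart are linked next, and so on up to a 5 s gap.

The module also converts a track's per-electrode amplitudes and phases into
the differenced, unit-normalized observation vector the spatial tracker
consumes: the electrodes split into two antiphase groups — those nearer the
dipole's positive pole versus the negative pole — so each electrode's
amplitude is signed by comparing its fundamental phase against the
largest-amplitude electrode in the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.optimize import linear_sum_assignment
from scipy.signal.windows import hann

from .dipole_model import DEGENERATE_NORM, GridGeometry, ObservationVector

__all__ = [
    "TrackerConfig",
    "SpectrogramStack",
    "Signature",
    "Candidate",
    "FrequencyTrack",
    "compute_spectrogram",
    "detect_signatures",
    "cluster_candidates",
    "associate_tracks",
    "edit_tracks",
    "measured_observation",
    "track_frequencies",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Step-1 parameters.

    ``tau1`` is the fundamental magnitude threshold; ``None`` selects it
    per window and electrode as ``tau1_auto_factor`` times the median in-band
    magnitude (a robust noise floor; the original procedure set it manually
    per recording).  ``tau_ratio`` is the second-to-fundamental threshold
    ratio tau2/tau1.  ``freq_weight`` scales Hz against (normalized)
    amplitude units in the association metric.

    ``min_track_windows`` prunes assembled tracks shorter than this many
    candidate windows (default 12, i.e. 3 s at the default hop) — confidence
    pruning that discards fragments thrown off by movement-induced spectral
    sidebands of a strong carrier.  Set to 1 to keep everything.
    """

    band_low: float = 200.0
    band_high: float = 700.0
    tau1: float | None = None
    tau1_auto_factor: float = 8.0
    tau_ratio: float = 1.0 / 8.0
    min_votes: int = 2
    cluster_tol: float = 0.5
    max_gap: float = 5.0
    max_df: float = 1.0
    window_length: float = 0.5
    hop: float = 0.25
    zero_pad: int = 4
    freq_weight: float = 1.0
    min_track_windows: int = 12

    def __post_init__(self) -> None:
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")
        if self.tau1 is not None and self.tau1 <= 0:
            raise ValueError("tau1 must be positive")
        if not 0 < self.tau_ratio <= 1:
            raise ValueError("tau_ratio must be in (0, 1]")
        if self.min_votes < 2:
            raise ValueError("min_votes must be at least 2")
        if self.hop <= 0 or self.window_length < self.hop:
            raise ValueError("need 0 < hop <= window_length")

    @property
    def max_gap_windows(self) -> int:
        return int(math.floor(self.max_gap / self.hop + 1e-9))


@dataclass
class SpectrogramStack:
    """Complex STFT coefficients on a shared lattice, [time, freq, electrode].

    Coefficients are scaled so that a full-scale cosine of amplitude ``A``
    whose frequency sits on a bin center has magnitude ``A`` at that bin.
    Only frequencies up to slightly above twice the detection band are kept.
    """

    times: np.ndarray
    freqs: np.ndarray
    coeffs: np.ndarray
    window_length: float
    hop: float
    fs: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_electrodes(self) -> int:
        return self.coeffs.shape[2]


@dataclass(frozen=True)
class Signature:
    """One harmonic spectral peak at one electrode and time window."""

    electrode: int
    t: float
    f0: float
    amp1: float
    phase1: float
    amp2: float
    phase2: float


@dataclass
class Candidate:
    """Same-frequency signatures across electrodes at one window: one fish's
    footprint at that instant."""

    t: float
    f0: float
    members: list[Signature]
    amp1: np.ndarray      # per electrode, NaN where absent
    phase1: np.ndarray
    amp2: np.ndarray
    phase2: np.ndarray
    mask: np.ndarray      # bool per electrode

    @property
    def n_votes(self) -> int:
        return int(self.mask.sum())

    @property
    def mean_amp1(self) -> float:
        return float(np.nanmean(self.amp1))

    @property
    def mean_amp2(self) -> float:
        return float(np.nanmean(self.amp2))


@dataclass
class FrequencyTrack:
    """A time-linked chain of candidates: one individual's EOD trajectory."""

    track_id: int
    candidates: list[Candidate]
    provenance: str = "auto"

    @property
    def times(self) -> np.ndarray:
        return np.array([c.t for c in self.candidates])

    @property
    def freqs(self) -> np.ndarray:
        return np.array([c.f0 for c in self.candidates])

    def validate(self, config: TrackerConfig) -> None:
        """Raise if any adjacent pair violates the gap or frequency gates."""
        for a, b in zip(self.candidates, self.candidates[1:]):
            if b.t - a.t <= 0:
                raise ValueError(f"track {self.track_id}: non-increasing times")
            if b.t - a.t > config.max_gap + 1e-9:
                raise ValueError(
                    f"track {self.track_id}: gap {b.t - a.t:.2f} s exceeds "
                    f"{config.max_gap} s"
                )
            if abs(b.f0 - a.f0) > config.max_df + 1e-9:
                raise ValueError(
                    f"track {self.track_id}: frequency jump "
                    f"{abs(b.f0 - a.f0):.2f} Hz exceeds {config.max_df} Hz"
                )


# ---------------------------------------------------------------------------
# (a) spectrogram and signatures
# ---------------------------------------------------------------------------

def compute_spectrogram(
    samples: np.ndarray, fs: float, config: TrackerConfig
) -> SpectrogramStack:
    """Hann-windowed, zero-padded STFT of every channel on one lattice.

    Only full windows are used (no edge padding), so window-center times run
    from ``window_length/2`` inward.  Zero-padding by ``config.zero_pad``
    refines the bin spacing to support sub-bin peak interpolation.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[0] < samples.shape[1]:
        raise ValueError("samples must be (n_samples, n_channels), long axis first")
    nperseg = int(round(config.window_length * fs))
    hop_n = int(round(config.hop * fs))
    if samples.shape[0] < nperseg:
        raise ValueError(
            f"recording of {samples.shape[0] / fs:.3f} s is shorter than one "
            f"{config.window_length} s analysis window"
        )
    if fs <= 4 * config.band_high:
        raise ValueError(
            f"fs={fs} Hz cannot resolve second harmonics up to "
            f"{2 * config.band_high} Hz; need fs > {4 * config.band_high} Hz"
        )
    win = hann(nperseg, sym=False)
    mfft = config.zero_pad * nperseg
    freqs = np.fft.rfftfreq(mfft, 1.0 / fs)
    keep = freqs <= 2.1 * config.band_high + 50.0
    n_windows = (samples.shape[0] - nperseg) // hop_n + 1
    starts = np.arange(n_windows) * hop_n
    times = (starts + nperseg / 2) / fs
    scale = 2.0 / win.sum()

    coeffs = np.empty((n_windows, int(keep.sum()), samples.shape[1]), complex)
    for k, s0 in enumerate(starts):
        frame = samples[s0 : s0 + nperseg] * win[:, None]
        spec = scipy.fft.rfft(frame, n=mfft, axis=0)
        coeffs[k] = spec[keep] * scale
    return SpectrogramStack(
        times=times, freqs=freqs[keep], coeffs=coeffs,
        window_length=config.window_length, hop=config.hop, fs=fs,
    )


def _parabolic_peak(logmag: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-bin offset and refined log-magnitude around interior bin k."""
    a, b, c = logmag[k - 1], logmag[k], logmag[k + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # flat or degenerate — keep the bin itself
        return 0.0, b
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return delta, b - 0.25 * (a - c) * delta


def detect_signatures(
    stack: SpectrogramStack, config: TrackerConfig
) -> list[list[Signature]]:
    """Harmonic signatures per time window (outer list indexed like times).

    A signature is a local magnitude maximum with parabolic-interpolated
    fundamental in [band_low, band_high], interpolated magnitude >= tau1, and
    interpolated magnitude at twice the fundamental >= tau2.  Both thresholds
    are inclusive.

    Two vetoes keep the peak list clean without human review: a peak must
    dominate its neighbourhood out to two pre-padding bins (suppresses the
    analysis window's sidelobes), and a peak whose half frequency carries at
    least as much magnitude is rejected as the second-harmonic image of a
    lower fundamental (a fish's second harmonic can itself fall inside the
    species band).
    """
    df = stack.df
    band = (stack.freqs >= config.band_low) & (stack.freqs <= config.band_high)
    band_idx = np.flatnonzero(band)
    out: list[list[Signature]] = []
    tiny = 1e-300
    for k, t in enumerate(stack.times):
        sigs_t: list[Signature] = []
        for e in range(stack.n_electrodes):
            mag = np.abs(stack.coeffs[k, :, e])
            if config.tau1 is not None:
                tau1 = config.tau1
            else:
                med = float(np.median(mag[band_idx]))
                tau1 = config.tau1_auto_factor * max(med, tiny)
            tau2 = config.tau_ratio * tau1
            logmag = np.log(mag + tiny)
            nb = 2 * config.zero_pad  # two pre-padding bins
            # interior local maxima within the band
            cand = band_idx[(band_idx > 0) & (band_idx < mag.size - 1)]
            is_peak = (mag[cand] > mag[cand - 1]) & (mag[cand] >= mag[cand + 1])
            for kb in cand[is_peak]:
                lo, hi = max(kb - nb, 0), min(kb + nb + 1, mag.size)
                if mag[kb] < mag[lo:hi].max():
                    continue  # sidelobe of a stronger neighbour
                delta, logamp = _parabolic_peak(logmag, kb)
                f0 = stack.freqs[kb] + delta * df
                amp1 = math.exp(logamp)
                if not (config.band_low <= f0 <= config.band_high):
                    continue
                if amp1 < tau1:
                    continue
                kh = int(round((f0 / 2 - stack.freqs[0]) / df))
                if kh >= 1:
                    half = mag[max(kh - nb, 0) : kh + nb + 1].max()
                    if half >= amp1:
                        continue  # harmonic image of a lower fundamental
                k2 = int(round((2 * f0 - stack.freqs[0]) / df))
                if not 1 <= k2 < mag.size - 1:
                    continue
                # second harmonic: refine around the nearest bin to 2*f0
                k2 += int(np.argmax(mag[k2 - 1 : k2 + 2])) - 1
                if not 1 <= k2 < mag.size - 1:
                    continue
                _, logamp2 = _parabolic_peak(logmag, k2)
                amp2 = math.exp(logamp2)
                if amp2 < tau2:
                    continue
                sigs_t.append(
                    Signature(
                        electrode=e, t=float(t), f0=float(f0), amp1=amp1,
                        phase1=float(np.angle(stack.coeffs[k, kb, e])),
                        amp2=amp2,
                        phase2=float(np.angle(stack.coeffs[k, k2, e])),
                    )
                )
        out.append(sigs_t)
    return out


# ---------------------------------------------------------------------------
# (b) candidates
# ---------------------------------------------------------------------------

def cluster_candidates(
    signatures: list[Signature], n_electrodes: int, config: TrackerConfig
) -> list[Candidate]:
    """Greedy frequency clustering of one window's signatures into candidates.

    Signatures are processed in descending fundamental amplitude and
    first-fit into the existing cluster whose amplitude-weighted mean
    frequency is within ``cluster_tol``; a weaker duplicate from an electrode
    already in the cluster is discarded as a sidelobe.  Clusters backed by at
    least ``min_votes`` distinct electrodes become candidates.
    """
    if not signatures:
        return []
    t = signatures[0].t
    if any(abs(s.t - t) > 1e-9 for s in signatures):
        raise ValueError("cluster_candidates expects signatures at one time")
    order = sorted(signatures, key=lambda s: -s.amp1)
    clusters: list[list[Signature]] = []
    centers: list[float] = []
    for sig in order:
        for ci, center in enumerate(centers):
            if abs(sig.f0 - center) <= config.cluster_tol:
                if any(m.electrode == sig.electrode for m in clusters[ci]):
                    break  # weaker duplicate on the same electrode
                clusters[ci].append(sig)
                w = np.array([m.amp1 for m in clusters[ci]])
                f = np.array([m.f0 for m in clusters[ci]])
                centers[ci] = float(np.average(f, weights=w))
                break
        else:
            clusters.append([sig])
            centers.append(sig.f0)

    out = []
    for members, center in zip(clusters, centers):
        elecs = {m.electrode for m in members}
        if len(elecs) < config.min_votes:
            continue
        amp1 = np.full(n_electrodes, np.nan)
        phase1 = np.full(n_electrodes, np.nan)
        amp2 = np.full(n_electrodes, np.nan)
        phase2 = np.full(n_electrodes, np.nan)
        mask = np.zeros(n_electrodes, bool)
        for m in members:
            amp1[m.electrode] = m.amp1
            phase1[m.electrode] = m.phase1
            amp2[m.electrode] = m.amp2
            phase2[m.electrode] = m.phase2
            mask[m.electrode] = True
        out.append(
            Candidate(t=t, f0=center, members=members, amp1=amp1,
                      phase1=phase1, amp2=amp2, phase2=phase2, mask=mask)
        )
    out.sort(key=lambda c: c.f0)
    return out


# ---------------------------------------------------------------------------
# (c) association across time
# ---------------------------------------------------------------------------

_BIG = 1e12


def _features(c: Candidate, amp_scale: float, config: TrackerConfig) -> np.ndarray:
    """Association feature vector: weighted frequency plus the per-electrode
    fundamental and second-harmonic amplitude profiles (missing electrodes
    contribute zero).  The amplitude *profiles*, not their totals, are what
    distinguish two fish whose frequencies cross."""
    a1 = np.nan_to_num(c.amp1) / amp_scale
    a2 = np.nan_to_num(c.amp2) / amp_scale
    return np.concatenate(([config.freq_weight * c.f0], a1, a2))


def _gated_cost(
    rows: list[Candidate], cols: list[Candidate], amp_scale: float,
    config: TrackerConfig,
) -> np.ndarray:
    cost = np.full((len(rows), len(cols)), _BIG)
    for i, a in enumerate(rows):
        fa = _features(a, amp_scale, config)
        for j, b in enumerate(cols):
            if abs(a.f0 - b.f0) > config.max_df:
                continue
            cost[i, j] = float(np.linalg.norm(fa - _features(b, amp_scale, config)))
    return cost


def _assign(cost: np.ndarray) -> list[tuple[int, int]]:
    """Hungarian assignment; pairs whose cost carries the gate sentinel are
    dropped."""
    if cost.size == 0:
        return []
    ri, ci = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(ri, ci) if cost[i, j] < _BIG / 2]


def associate_tracks(
    candidates: list[Candidate], config: TrackerConfig
) -> list[FrequencyTrack]:
    """Link candidates over time into frequency tracks.

    A forward sweep first associates candidates in neighbouring windows
    (Hungarian assignment per window under the gated amplitude metric), every
    unmatched candidate seeding a new track.  Remaining track ends and track
    starts two windows apart are then linked, and so on, up to the maximum
    gap — the multi-pass closure that rides out frequency crossings and
    dropped windows.  Tracks shorter than ``min_track_windows`` windows are
    pruned at the end.
    """
    if not candidates:
        return []
    # group candidates by window index on the hop lattice
    tmin = min(c.t for c in candidates)
    by_win: dict[int, list[Candidate]] = {}
    for c in candidates:
        by_win.setdefault(int(round((c.t - tmin) / config.hop)), []).append(c)
    amps = [c.mean_amp1 for c in candidates]
    amp_scale = float(np.median(amps)) or 1.0

    # pass at gap 1: forward sweep
    tracks: list[list[Candidate]] = []
    tails: dict[int, int] = {}  # window index -> track indices via list below
    open_at: dict[int, list[int]] = {}  # tail window -> track list indices
    for w in sorted(by_win):
        cands = sorted(by_win[w], key=lambda c: c.f0)
        prev = open_at.pop(w - 1, [])
        rows = [tracks[ti][-1] for ti in prev]
        pairs = _assign(_gated_cost(rows, cands, amp_scale, config))
        matched_c = set()
        for i, j in pairs:
            tracks[prev[i]].append(cands[j])
            open_at.setdefault(w, []).append(prev[i])
            matched_c.add(j)
        for i, ti in enumerate(prev):
            if i not in {p[0] for p in pairs}:
                tails[ti] = w - 1
        for j, c in enumerate(cands):
            if j not in matched_c:
                tracks.append([c])
                open_at.setdefault(w, []).append(len(tracks) - 1)
    for w, tis in open_at.items():
        for ti in tis:
            tails[ti] = w

    # passes at gap 2..G: stitch track fragments end-to-start
    heads = {ti: int(round((tr[0].t - tmin) / config.hop)) for ti, tr in enumerate(tracks)}
    alive = set(range(len(tracks)))
    for g in range(2, config.max_gap_windows + 1):
        merged = True
        while merged:
            merged = False
            ends = sorted(alive)
            starts = sorted(alive)
            pair_rows, pair_cols = [], []
            for a in ends:
                for b in starts:
                    if a != b and heads[b] - tails[a] == g:
                        pair_rows.append(a)
                        pair_cols.append(b)
            if not pair_rows:
                break
            rows = sorted(set(pair_rows))
            cols = sorted(set(pair_cols))
            cost = np.full((len(rows), len(cols)), _BIG)
            for a, b in zip(pair_rows, pair_cols):
                i, j = rows.index(a), cols.index(b)
                sub = _gated_cost(
                    [tracks[a][-1]], [tracks[b][0]], amp_scale, config
                )
                cost[i, j] = sub[0, 0]
            for i, j in _assign(cost):
                a, b = rows[i], cols[j]
                if a not in alive or b not in alive:
                    continue
                tracks[a].extend(tracks[b])
                tails[a] = tails[b]
                alive.discard(b)
                merged = True

    kept = [
        ti
        for ti in sorted(alive, key=lambda ti: tracks[ti][0].t)
        if len(tracks[ti]) >= config.min_track_windows
    ]
    out = [
        FrequencyTrack(track_id=k, candidates=tracks[ti])
        for k, ti in enumerate(kept)
    ]
    for tr in out:
        tr.validate(config)
    return out


def track_frequencies(
    samples: np.ndarray, fs: float, n_electrodes: int, config: TrackerConfig
) -> list[FrequencyTrack]:
    """Full Step 1: recording -> spectrogram -> signatures -> candidates ->
    tracks."""
    stack = compute_spectrogram(samples, fs, config)
    sigs = detect_signatures(stack, config)
    cands: list[Candidate] = []
    for sigs_t in sigs:
        cands.extend(cluster_candidates(sigs_t, n_electrodes, config))
    return associate_tracks(cands, config)


# ---------------------------------------------------------------------------
# track editing (programmatic replacement for the interactive review step)
# ---------------------------------------------------------------------------

def edit_tracks(
    tracks: list[FrequencyTrack],
    edit: str,
    config: TrackerConfig,
    *,
    track_id: int | None = None,
    other_id: int | None = None,
    at_time: float | None = None,
    to_id: int | None = None,
    force: bool = False,
) -> list[FrequencyTrack]:
    """Split, join, delete, or reassign tracks; returns a new track list.

    ``split`` divides ``track_id`` at ``at_time`` (candidates with t >=
    at_time go to a new track).  ``join`` concatenates ``track_id`` and
    ``other_id`` provided the junction respects the gap and frequency gates
    (override with ``force``).  ``reassign`` moves the candidate of
    ``track_id`` at ``at_time`` to track ``to_id``.
    """
    index = {tr.track_id: tr for tr in tracks}

    def need(tid) -> FrequencyTrack:
        if tid not in index:
            raise KeyError(f"no track with id {tid}")
        return index[tid]

    next_id = max(index, default=-1) + 1
    if edit == "delete":
        need(track_id)
        return [tr for tr in tracks if tr.track_id != track_id]
    if edit == "split":
        tr = need(track_id)
        if at_time is None:
            raise ValueError("split requires at_time")
        first = [c for c in tr.candidates if c.t < at_time]
        second = [c for c in tr.candidates if c.t >= at_time]
        if not first or not second:
            raise ValueError("split time does not partition the track")
        out = [t for t in tracks if t.track_id != track_id]
        out.append(FrequencyTrack(tr.track_id, first, "edited"))
        out.append(FrequencyTrack(next_id, second, "edited"))
        return sorted(out, key=lambda t: t.track_id)
    if edit == "join":
        a, b = need(track_id), need(other_id)
        first, second = (a, b) if a.candidates[-1].t <= b.candidates[0].t else (b, a)
        gap = second.candidates[0].t - first.candidates[-1].t
        df = abs(second.candidates[0].f0 - first.candidates[-1].f0)
        if gap <= 0:
            raise ValueError("tracks overlap in time; cannot join")
        if not force and (gap > config.max_gap or df > config.max_df):
            raise ValueError(
                f"junction gap {gap:.2f} s / df {df:.2f} Hz violates the "
                "continuity gates (use force=True to override)"
            )
        out = [t for t in tracks if t.track_id not in (a.track_id, b.track_id)]
        out.append(
            FrequencyTrack(first.track_id,
                           first.candidates + second.candidates, "edited")
        )
        return sorted(out, key=lambda t: t.track_id)
    if edit == "reassign":
        src, dst = need(track_id), need(to_id)
        if at_time is None:
            raise ValueError("reassign requires at_time")
        moved = [c for c in src.candidates if abs(c.t - at_time) < 1e-9]
        if not moved:
            raise ValueError(f"track {track_id} has no candidate at t={at_time}")
        if any(abs(c.t - at_time) < 1e-9 for c in dst.candidates):
            raise ValueError(f"track {to_id} already has a candidate at t={at_time}")
        out = [t for t in tracks if t.track_id not in (src.track_id, dst.track_id)]
        remaining = [c for c in src.candidates if abs(c.t - at_time) >= 1e-9]
        if remaining:
            out.append(FrequencyTrack(src.track_id, remaining, "edited"))
        merged = sorted(dst.candidates + moved, key=lambda c: c.t)
        new_dst = FrequencyTrack(dst.track_id, merged, "edited")
        if not force:
            new_dst.validate(config)
        out.append(new_dst)
        return sorted(out, key=lambda t: t.track_id)
    raise ValueError(f"unknown edit {edit!r}")


# ---------------------------------------------------------------------------
# measured observation vector
# ---------------------------------------------------------------------------

def measured_observation(
    track: FrequencyTrack,
    t: float,
    grid: GridGeometry,
    config: TrackerConfig,
) -> ObservationVector:
    """Signed, differenced, unit-normalized amplitudes at one window.

    Per reporting electrode i the signed amplitude is ``amp1_i * sign_i``
    where ``sign_i`` is +1 when the fundamental phase at i lies within pi/2
    of the phase at the window's largest-amplitude electrode, else -1 (the
    two antiphase groups sit on either side of the dipole midline).  The
    global sign is thereby anchored arbitrarily per window, so downstream
    consumers must treat the observation as known only up to +-1.
    """
    sel = [c for c in track.candidates if abs(c.t - t) <= config.hop / 2 + 1e-9]
    if not sel:
        return ObservationVector(
            t=t, values=np.zeros(grid.n_electrodes - 1),
            valid_mask=np.zeros(grid.n_electrodes - 1, bool), valid=False,
        )
    cand = min(sel, key=lambda c: abs(c.t - t))
    mask_e = cand.mask.copy()
    sig = grid.signal_indices
    ref = grid.reference_index
    if mask_e.sum() < 3 or not mask_e[ref]:
        return ObservationVector(
            t=cand.t, values=np.zeros(sig.size),
            valid_mask=mask_e[sig], valid=False,
        )
    anchor = int(np.nanargmax(np.where(mask_e, cand.amp1, -np.inf)))
    dphi = cand.phase1 - cand.phase1[anchor]
    signs = np.where(np.cos(dphi) >= 0, 1.0, -1.0)
    s = np.where(mask_e, cand.amp1 * signs, 0.0)
    values = np.where(mask_e[sig], s[sig] - s[ref], 0.0)
    norm = float(np.linalg.norm(values))
    if norm < DEGENERATE_NORM:
        return ObservationVector(t=cand.t, values=values,
                                 valid_mask=mask_e[sig], valid=False)
    return ObservationVector(
        t=cand.t, values=values / norm, valid_mask=mask_e[sig], valid=True
    )
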