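"""Synthetic stereo-EEG cohorts with known ground truth.

The generator emulates what the detection and validation stages consume:
bipolar channels carrying 1/f ("pink") background activity, with hann- or
gaussian-windowed oscillatory bursts superimposed in the ripple (80-250 Hz)
and fast-ripple (250-500 Hz) bands at controlled Poisson rates, amplitudes,
frequencies and durations. Co-occurring ripple+FR pairs — the HFO events the
pipeline counts — are synthesized as simultaneous bursts sharing a centre
time. Channel-level anatomy (MTL vs Neocortex) and resection flags, NREM
interval lists and ILAE outcomes complete a patient, and cohorts can be
constructed to realize a requested TP/TN/FP/FN confusion table exactly when
the HFO-area rule is applied to the ground-truth rates.

Synthesis happens directly at the bipolar-channel level: the analysis
operates on bipolar signals, so no referential-to-bipolar subtraction is
simulated. Optional mains interference (50 Hz and harmonics) is available
but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import gaussian, hann

from hfopipe.iobase import BipolarData

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Requested event rates are too high to place bursts without overlap."""


@dataclass(frozen=True)
class SimChannelSpec:
    """Ground-truth event statistics for one synthetic bipolar channel.

    Rates are events/minute: ``ripple_rate`` and ``fr_rate`` are solitary
    (unpaired) bursts, ``hfo_rate`` is co-occurring ripple+FR pairs.
    Amplitudes are burst peak values in microvolts; ``dur_ms`` is the ripple
    burst duration, and FR bursts default to a shorter duration so the pair
    passes the detector's 50 ms FR bound.
    """

    channel_id: str
    electrode_id: str
    region: str = "MTL"
    resected: bool = False
    ripple_rate: float = 0.0
    fr_rate: float = 0.0
    hfo_rate: float = 0.0
    amp_ripple_uv: float = 15.0
    amp_fr_uv: float = 10.0
    freq_ripple_hz: float = 140.0
    freq_fr_hz: float = 350.0
    dur_ms: float = 70.0
    fr_dur_ms: float | None = None

    def __post_init__(self) -> None:
        if not 80.0 <= self.freq_ripple_hz <= 250.0:
            raise ValueError("freq_ripple_hz must lie in [80, 250]")
        if not 250.0 <= self.freq_fr_hz <= 500.0:
            raise ValueError("freq_fr_hz must lie in [250, 500]")
        for r in (self.ripple_rate, self.fr_rate, self.hfo_rate):
            if not np.isfinite(r) or r < 0:
                raise ValueError("rates must be finite and non-negative")
        if self.amp_ripple_uv <= 0 or self.amp_fr_uv <= 0 or self.dur_ms <= 0:
            raise ValueError("amplitudes and duration must be positive")

    @property
    def fr_duration_ms(self) -> float:
        if self.fr_dur_ms is not None:
            return self.fr_dur_ms
        return min(0.45 * self.dur_ms, 40.0)


@dataclass(frozen=True)
class SimPatientSpec:
    patient_id: str
    channel_specs: tuple[SimChannelSpec, ...]
    n_intervals: int = 6
    interval_len_s: float = 300.0
    fs: float = 2000.0
    noise_rms_uv: float = 5.0
    ilae: int = 1
    seed: int = 0
    line_noise_uv: float = 0.0

    def __post_init__(self) -> None:
        if not 4 <= self.n_intervals <= 14:
            raise ValueError("n_intervals must lie in [4, 14]")
        if self.fs not in (2000.0, 2048.0):
            raise ValueError("fs must be 2000 or 2048 Hz")
        if self.noise_rms_uv <= 0:
            raise ValueError("noise_rms_uv must be positive")
        if not 1 <= self.ilae <= 6:
            raise ValueError("ilae must be in 1..6")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        L = self.interval_len_s
        return [(i * L, (i + 1) * L) for i in range(self.n_intervals)]


@dataclass(frozen=True)
class GroundTruthEvent:
    channel_id: str
    kind: str  # "ripple" | "FR" | "HFO-pair"
    onset_s: float
    offset_s: float
    amplitude_uv: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")


def generate_background(n_samples: int, fs: float, rms: float, seed: int, beta: float = 1.0) -> np.ndarray:
    """1/f^beta background noise scaled to an exact sample RMS (microvolts)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if rms <= 0:
        raise ValueError("rms must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(X * shape, n=n_samples)
    x -= x.mean()
    return x * (rms / np.sqrt(np.mean(x**2)))


def inject_burst(
    signal: np.ndarray,
    fs: float,
    onset_s: float,
    freq_hz: float,
    peak_amp_uv: float,
    dur_ms: float,
    envelope: str = "hann",
) -> tuple[np.ndarray, GroundTruthEvent]:
    """Add an amplitude-modulated sinusoidal burst; returns (signal', truth).

    The carrier phase is aligned with the envelope maximum so the peak of the
    added waveform equals ``peak_amp_uv`` exactly.
    """
    if freq_hz >= fs / 2:
        raise ValueError("burst frequency must be below Nyquist")
    n = int(round(dur_ms / 1000.0 * fs))
    i0 = int(round(onset_s * fs))
    if i0 < 0 or i0 + n > len(signal) or n < 2:
        raise ValueError("burst does not fit inside the signal")
    if envelope == "hann":
        env = hann(n, sym=True)
    elif envelope == "gauss":
        env = gaussian(n, std=n / 6.0, sym=True)
    else:
        raise ValueError(f"unknown envelope: {envelope!r}")
    t = np.arange(n) / fs
    burst = env * np.cos(2 * np.pi * freq_hz * (t - t[n // 2]))
    burst *= peak_amp_uv / np.abs(burst).max()
    out = signal.copy()
    out[i0 : i0 + n] += burst
    truth = GroundTruthEvent(
        channel_id="",
        kind="ripple" if freq_hz <= 250 else "FR",
        onset_s=i0 / fs,
        offset_s=(i0 + n) / fs,
        amplitude_uv=peak_amp_uv,
        frequency_hz=freq_hz,
    )
    return out, truth


def _place_centres(
    rng: np.random.Generator,
    count: int,
    start_s: float,
    stop_s: float,
    half_width_s: float,
    occupied: list[tuple[float, float]],
    guard_s: float = 0.15,
    max_tries_per_event: int = 200,
) -> list[float]:
    """Draw burst centre times uniformly, rejecting overlap with occupied spans."""
    centres = []
    lo = start_s + half_width_s + guard_s
    hi = stop_s - half_width_s - guard_s
    if hi <= lo:
        raise PlacementError("interval too short for the requested burst duration")
    for _ in range(count):
        for _ in range(max_tries_per_event):
            c = rng.uniform(lo, hi)
            span = (c - half_width_s - guard_s, c + half_width_s + guard_s)
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                occupied.append(span)
                centres.append(c)
                break
        else:
            raise PlacementError(
                "could not place burst without overlap; rates too high for interval"
            )
    return centres


def _round_to_sample(t: float, fs: float) -> float:
    return round(t * fs) / fs


def _channel_truth(ch: SimChannelSpec, spec: SimPatientSpec, rng: np.random.Generator):
    """Poisson placement of one channel's events; returns (truth, bg_seed).

    The background seed is drawn first so that the truth stream is identical
    whether or not signals are rendered afterwards.
    """
    bg_seed = int(rng.integers(2**31))
    line_phases = rng.uniform(0, 2 * np.pi, 3) if spec.line_noise_uv > 0 else None
    half_r = ch.dur_ms / 2000.0
    half_f = ch.fr_duration_ms / 2000.0
    minutes = spec.interval_len_s / 60.0
    fs = spec.fs
    truth: list[GroundTruthEvent] = []
    for start, stop in spec.intervals:
        occupied: list[tuple[float, float]] = []
        n_pair = rng.poisson(ch.hfo_rate * minutes)
        n_rip = rng.poisson(ch.ripple_rate * minutes)
        n_fr = rng.poisson(ch.fr_rate * minutes)
        pair_c = _place_centres(rng, n_pair, start, stop, half_r, occupied)
        rip_c = _place_centres(rng, n_rip, start, stop, half_r, occupied)
        fr_c = _place_centres(rng, n_fr, start, stop, half_f, occupied)
        for c in pair_c:
            r0 = _round_to_sample(c - half_r, fs)
            f0 = _round_to_sample(c - half_f, fs)
            ev_r = GroundTruthEvent(ch.channel_id, "ripple", r0, r0 + 2 * half_r, ch.amp_ripple_uv, ch.freq_ripple_hz)
            ev_f = GroundTruthEvent(ch.channel_id, "FR", f0, f0 + 2 * half_f, ch.amp_fr_uv, ch.freq_fr_hz)
            truth += [
                ev_r,
                ev_f,
                GroundTruthEvent(
                    ch.channel_id,
                    "HFO-pair",
                    min(ev_r.onset_s, ev_f.onset_s),
                    max(ev_r.offset_s, ev_f.offset_s),
                    ch.amp_ripple_uv,
                    ch.freq_ripple_hz,
                ),
            ]
        for c in rip_c:
            r0 = _round_to_sample(c - half_r, fs)
            truth.append(GroundTruthEvent(ch.channel_id, "ripple", r0, r0 + 2 * half_r, ch.amp_ripple_uv, ch.freq_ripple_hz))
        for c in fr_c:
            f0 = _round_to_sample(c - half_f, fs)
            truth.append(GroundTruthEvent(ch.channel_id, "FR", f0, f0 + 2 * half_f, ch.amp_fr_uv, ch.freq_fr_hz))
    return truth, bg_seed, line_phases


def generate_truth(spec: SimPatientSpec) -> list[GroundTruthEvent]:
    """Ground-truth event stream only, without waveform synthesis.

    Identical to the truth list ``generate_patient`` returns for the same
    spec: useful when a test needs event counts or rate vectors but not
    signals.
    """
    ss = np.random.SeedSequence(spec.seed)
    truth: list[GroundTruthEvent] = []
    for ch, cseed in zip(spec.channel_specs, ss.spawn(len(spec.channel_specs))):
        truth += _channel_truth(ch, spec, np.random.default_rng(cseed))[0]
    truth.sort(key=lambda e: (e.channel_id, e.onset_s))
    return truth


def generate_patient(spec: SimPatientSpec) -> tuple[BipolarData, list[GroundTruthEvent], pd.DataFrame]:
    """Synthesize one patient: signals, ground-truth events and channel table.

    Per channel, solitary ripples, solitary FR and co-occurring pairs are
    placed by independent Poisson processes at the spec rates within each
    NREM interval. Pairs share a centre time, the FR burst lying entirely
    inside the ripple burst (temporal overlap well above 50%). Deterministic
    given ``spec.seed``.
    """
    n_samples = int(round(spec.n_intervals * spec.interval_len_s * spec.fs))
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(len(spec.channel_specs))
    signals = np.empty((len(spec.channel_specs), n_samples))
    truth: list[GroundTruthEvent] = []
    rows = []
    for ci, (ch, cseed) in enumerate(zip(spec.channel_specs, child_seeds)):
        rng = np.random.default_rng(cseed)
        ch_truth, bg_seed, line_phases = _channel_truth(ch, spec, rng)
        sig = generate_background(n_samples, spec.fs, spec.noise_rms_uv, seed=bg_seed)
        if spec.line_noise_uv > 0:
            t = np.arange(n_samples) / spec.fs
            for (h, w), phase in zip(((50.0, 1.0), (100.0, 0.4), (150.0, 0.2)), line_phases):
                sig += spec.line_noise_uv * w * np.sin(2 * np.pi * h * t + phase)
        for ev in ch_truth:
            if ev.kind == "HFO-pair":
                continue
            sig, _ = inject_burst(
                sig,
                spec.fs,
                ev.onset_s,
                ev.frequency_hz,
                ev.amplitude_uv,
                (ev.offset_s - ev.onset_s) * 1000.0,
            )
        truth += ch_truth
        signals[ci] = sig
        rows.append(
            {
                "channel": ch.channel_id,
                "electrode": ch.electrode_id,
                "region": ch.region,
                "resected": ch.resected,
                "ripple_rate": ch.ripple_rate,
                "fr_rate": ch.fr_rate,
                "hfo_rate": ch.hfo_rate,
            }
        )
    meta = pd.DataFrame(rows)
    data = BipolarData(
        patient_id=spec.patient_id,
        signals=signals,
        fs=spec.fs,
        channels=meta[["channel", "electrode", "region", "resected"]],
        intervals=spec.intervals,
        ilae=spec.ilae,
    )
    truth.sort(key=lambda e: (e.channel_id, e.onset_s))
    return data, truth, meta


def ground_truth_rates(spec: SimPatientSpec) -> pd.Series:
    """Expected HFO (pair) rate per channel, events/min, in channel order."""
    return pd.Series(
        {ch.channel_id: ch.hfo_rate for ch in spec.channel_specs},
        name="hfo_rate",
    )


#: realistic location/scale for the five morphology features
#: (uV, uV, Hz, Hz, ms): FR peak-to-peak, ripple peak-to-peak, FR central
#: frequency, ripple central frequency, paired-event duration
FEATURE_SCALES = {
    "am_fr": (10.0, 3.0),
    "am_ripples": (30.0, 10.0),
    "fr_fr": (375.0, 12.0),
    "fr_ripples": (168.0, 11.0),
    "d_hfo": (72.0, 25.0),
}


def generate_feature_table(
    n_class1: int,
    n_class2: int,
    seed: int,
    am_fr_shift_sd: float = 0.0,
    n_patients: int = 5,
) -> pd.DataFrame:
    """Synthetic morphology-feature table with an optional planted effect.

    Features are Gaussian at realistic locations/scales (FEATURE_SCALES);
    ``am_fr_shift_sd`` shifts the Class-1 FR amplitude by that many pooled
    standard deviations, emulating larger FR amplitude in epileptogenic
    tissue. Patients and regions are assigned round-robin so both
    stratifications are populated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n, shift in (("Class-1", n_class1, am_fr_shift_sd), ("Class-2", n_class2, 0.0)):
        for i in range(n):
            row = {
                name: mu + sd * rng.standard_normal()
                for name, (mu, sd) in FEATURE_SCALES.items()
            }
            row["am_fr"] += shift * FEATURE_SCALES["am_fr"][1]
            row.update(
                patient_id=f"p{i % n_patients}",
                channel=f"ch{i % 8}",
                region="MTL" if i % 2 == 0 else "Neocortex",
                **{"class": cls},
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort construction to hit a requested confusion table


def _default_channel_grid(
    hot: set[str], resected: set[str], hot_rate: float = 2.5, cold_rate: float = 0.05
) -> tuple[SimChannelSpec, ...]:
    """40 bipolar channels on five 9-contact electrodes; A/B are MTL."""
    specs = []
    for e, electrode in enumerate("ABCDE"):
        region = "MTL" if electrode in ("A", "B") else "Neocortex"
        for i in range(1, 9):
            name = f"{electrode}{i}-{electrode}{i + 1}"
            specs.append(
                SimChannelSpec(
                    channel_id=name,
                    electrode_id=electrode,
                    region=region,
                    resected=name in resected,
                    hfo_rate=hot_rate if name in hot else cold_rate,
                    ripple_rate=1.0 if name in hot else 0.2,
                    fr_rate=0.5 if name in hot else 0.05,
                )
            )
    return tuple(specs)


def generate_cohort(
    n_patients: int,
    confusion_targets: dict[str, int],
    seed: int,
    n_intervals: int = 6,
    interval_len_s: float = 300.0,
) -> list[tuple[SimPatientSpec, str]]:
    """Build patient specs realizing an exact TP/TN/FP/FN confusion table.

    The returned expected status holds when the pipeline's HFO-area rule
    (rate >= 1/min and above the 95th percentile of the channel-rate
    distribution) is applied to the ground-truth rates: high-rate channels
    fully resected with ILAE 1 gives TN, not fully resected with poor
    outcome gives TP, and so on.
    """
    targets = {k: int(confusion_targets.get(k, 0)) for k in ("TP", "TN", "FP", "FN")}
    if any(v < 0 for v in targets.values()):
        raise ValueError("confusion counts must be non-negative")
    if sum(targets.values()) != n_patients:
        raise ValueError("confusion counts must sum to n_patients")
    rng = np.random.default_rng(seed)
    cohort = []
    pid = 0
    for status, count in targets.items():
        for _ in range(count):
            pid += 1
            hot = {"A3-A4", "B5-B6"}
            if status in ("TN", "FN"):
                resected = hot | {"A2-A3", "A4-A5"}  # area fully inside resection
            else:  # TP / FP leave one hot channel out of the resection
                resected = {"A3-A4", "A2-A3", "A4-A5"}
            ilae = 1 if status in ("TN", "FP") else int(rng.integers(2, 7))
            cohort.append(
                (
                    SimPatientSpec(
                        patient_id=f"sim{pid:03d}",
                        channel_specs=_default_channel_grid(hot, resected),
                        n_intervals=n_intervals,
                        interval_len_s=interval_len_s,
                        ilae=ilae,
                        seed=int(rng.integers(2**31)),
                    ),
                    status,
                )
            )
    return cohort
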