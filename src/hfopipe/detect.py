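"""Two-stage automated ripple / fast-ripple detector.

Stage 1 finds events of interest whose band-limited amplitude envelope
exceeds a baseline threshold. The baseline is estimated from time segments
with high Stockwell-spectrum entropy: a flat (high-entropy) short-time
spectrum means no sustained oscillation, i.e. background. The threshold is a
high quantile of the Hilbert-envelope distribution within those background
segments, so channels with frequent oscillatory events still yield a
baseline uncontaminated by the events themselves.

Stage 2 rejects candidates on morphology: ripples with peak amplitude above
30 uV or duration above 150 ms, and FR above 20 uV or 50 ms, are discarded
as artifacts (sharp transients and filter ringing reach the high bands with
much larger amplitude than genuine HFO).

An HFO proper is the co-occurrence of a ripple and a fast ripple on the same
channel with temporal overlap; the paired event spans the union of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt


class DegenerateBaselineError(ValueError):
    """Signal has no amplitude structure; no baseline threshold exists."""


@dataclass(frozen=True)
class DetectorConfig:
    ripple_band: tuple[float, float] = (80.0, 250.0)
    fr_band: tuple[float, float] = (250.0, 500.0)
    ripple_amp_reject_uv: float = 30.0
    fr_amp_reject_uv: float = 20.0
    ripple_max_dur_ms: float = 150.0
    fr_max_dur_ms: float = 50.0
    min_peaks: int = 4
    entropy_window_ms: float = 50.0
    entropy_quantile: float = 0.9
    envelope_cdf_quantile: float = 0.99
    merge_gap_ms: float = 10.0
    filter_order: int = 5
    baseline_scope: str = "interval"  # or "recording"
    pair_extent: str = "union"  # or "intersection"

    def __post_init__(self) -> None:
        if not (self.ripple_band[0] < self.ripple_band[1] <= self.fr_band[0] < self.fr_band[1]):
            raise ValueError("bands must be ordered and non-overlapping at the boundary")
        for v in (self.ripple_amp_reject_uv, self.fr_amp_reject_uv):
            if v <= 0:
                raise ValueError("rejection thresholds must be positive")

    def band(self, kind: str) -> tuple[float, float]:
        return self.ripple_band if kind == "ripple" else self.fr_band


@dataclass
class HFOEvent:
    """A detected ripple, FR, or paired (co-occurring) HFO event."""

    channel: str
    kind: str  # "ripple" | "FR" | "HFO"
    onset_s: float
    offset_s: float
    peak_amp_uv: float
    band: tuple[float, float] | None = None
    interval_index: int | None = None
    patient_id: str | None = None
    # for kind == "HFO": the member sub-events
    ripple: "HFOEvent | None" = field(default=None, repr=False)
    fr: "HFOEvent | None" = field(default=None, repr=False)

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0

    def overlap_s(self, other: "HFOEvent") -> float:
        return max(0.0, min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s))


def bandpass(signal: np.ndarray, fs: float, band: tuple[float, float], order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, signal)


def _stockwell_band_spectra(windows: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Time-averaged Stockwell power spectrum of each window, in-band bins only.

    The S-transform of an N-point window at frequency bin k is the inverse
    FFT of X[k+n] * G_k[n] with the Gaussian voice G_k[n] = exp(-2 pi^2 n^2 /
    k^2). By Parseval the power averaged over the window's time axis is
    (1/N) sum_n |X[k+n]|^2 G_k[n]^2, which needs only one FFT per window and
    a matrix product over windows. Returns (n_windows, n_band_bins).
    """
    n_win, n = windows.shape
    X2 = np.abs(np.fft.fft(windows, axis=1)) ** 2
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    kbins = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0))
    shifts = np.arange(n)
    shifts_sym = np.where(shifts <= n // 2, shifts, shifts - n)  # signed freq offsets
    M = np.empty((n, len(kbins)))
    for j, k in enumerate(kbins):
        g2 = np.exp(-4.0 * np.pi**2 * shifts_sym**2 / k**2)  # G_k[n]^2
        M[:, j] = np.roll(g2, k)  # M[m, j] = G_k[(m - k) mod N]^2
    return (X2 @ M) / n


def _window_entropies(filtered: np.ndarray, fs: float, band: tuple[float, float], window_ms: float):
    win = int(round(window_ms / 1000.0 * fs))
    n_win = len(filtered) // win
    if n_win < 2:
        raise ValueError("segment too short for entropy windowing")
    windows = filtered[: n_win * win].reshape(n_win, win)
    P = _stockwell_band_spectra(windows, fs, band)
    tot = P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = P / tot
        H = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    H[tot.ravel() == 0] = np.nan
    return H, win, n_win


def envelope(filtered: np.ndarray) -> np.ndarray:
    """Amplitude envelope as the magnitude of the analytic (Hilbert) signal."""
    return np.abs(hilbert(filtered))


def entropy_baseline_threshold(
    filtered: np.ndarray, fs: float, config: DetectorConfig, band: tuple[float, float]
) -> float:
    """Amplitude threshold from the envelope CDF of high-entropy segments.

    Windows whose Stockwell-spectrum entropy is at or above the
    ``entropy_quantile`` of the window-entropy distribution are treated as
    background; the threshold is the ``envelope_cdf_quantile`` of the Hilbert
    envelope restricted to those windows.
    """
    if len(filtered) < 10 * fs:
        raise ValueError("baseline estimation needs at least 10 s of signal")
    if np.ptp(filtered) == 0:
        raise DegenerateBaselineError("constant signal has no amplitude distribution")
    H, win, n_win = _window_entropies(filtered, fs, band, config.entropy_window_ms)
    finite = H[np.isfinite(H)]
    if finite.size == 0:
        raise DegenerateBaselineError("no finite-entropy windows")
    cutoff = np.quantile(finite, config.entropy_quantile)
    keep = np.flatnonzero(np.isfinite(H) & (H >= cutoff))
    env = envelope(filtered[: n_win * win]).reshape(n_win, win)
    values = env[keep].ravel()
    thr = float(np.quantile(values, config.envelope_cdf_quantile))
    if not np.isfinite(thr) or thr <= 0:
        raise DegenerateBaselineError("degenerate baseline threshold")
    return thr


def detect_band_events(
    filtered: np.ndarray,
    fs: float,
    threshold: float,
    band: tuple[float, float],
    config: DetectorConfig,
    channel: str = "",
    t0: float = 0.0,
) -> list[HFOEvent]:
    """Segment candidate events where the envelope exceeds the threshold.

    Contiguous supra-threshold runs closer than ``merge_gap_ms`` are merged;
    a run is kept only if the rectified band signal shows at least
    ``min_peaks`` local maxima above the threshold itself (a sustained
    oscillation, not an isolated transient). Onset/offset sit at the
    threshold crossings; peak amplitude is max |filtered| within the run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    env = envelope(filtered)
    above = env > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    gap = int(round(config.merge_gap_ms / 1000.0 * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kind = "ripple" if band == config.ripple_band else "FR"
    events = []
    for s, e in merged:
        seg = np.abs(filtered[s:e])
        peaks, _ = find_peaks(seg, height=threshold)
        if len(peaks) < config.min_peaks:
            continue
        events.append(
            HFOEvent(
                channel=channel,
                kind=kind,
                onset_s=t0 + s / fs,
                offset_s=t0 + e / fs,
                peak_amp_uv=float(seg.max()),
                band=band,
            )
        )
    return events


def morphology_filter(candidates: list[HFOEvent], kind: str, config: DetectorConfig) -> list[HFOEvent]:
    """Reject artifactual candidates on amplitude and duration bounds."""
    if kind == "ripple":
        amp_max, dur_max = config.ripple_amp_reject_uv, config.ripple_max_dur_ms
    elif kind == "FR":
        amp_max, dur_max = config.fr_amp_reject_uv, config.fr_max_dur_ms
    else:
        raise ValueError(f"unknown event kind: {kind!r}")
    tol = 1e-9  # float slack so boundary-duration events are kept
    return [
        c for c in candidates if c.peak_amp_uv <= amp_max and c.duration_ms <= dur_max + tol
    ]


def pair_cooccurrence(
    ripples: list[HFOEvent], frs: list[HFOEvent], extent: str = "union"
) -> list[HFOEvent]:
    """Pair ripples with temporally overlapping FR into HFO events.

    Any overlap of at least one sample qualifies. Each ripple and each FR
    joins at most one pair: candidate pairs are taken greedily by decreasing
    overlap length, ties broken by earlier ripple onset. The paired event
    spans the union of the two sub-events (or their intersection when
    ``extent="intersection"``).
    """
    pairs = []
    for i, r in enumerate(ripples):
        for j, f in enumerate(frs):
            ov = r.overlap_s(f)
            if ov > 0:
                pairs.append((ov, r.onset_s, f.onset_s, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_r: set[int] = set()
    used_f: set[int] = set()
    events = []
    for ov, _, _, i, j in pairs:
        if i in used_r or j in used_f:
            continue
        used_r.add(i)
        used_f.add(j)
        r, f = ripples[i], frs[j]
        if extent == "union":
            onset, offset = min(r.onset_s, f.onset_s), max(r.offset_s, f.offset_s)
        else:
            onset, offset = max(r.onset_s, f.onset_s), min(r.offset_s, f.offset_s)
        events.append(
            HFOEvent(
                channel=r.channel,
                kind="HFO",
                onset_s=onset,
                offset_s=offset,
                peak_amp_uv=max(r.peak_amp_uv, f.peak_amp_uv),
                interval_index=r.interval_index,
                patient_id=r.patient_id,
                ripple=r,
                fr=f,
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


def detect_channel_interval(
    signal: np.ndarray,
    fs: float,
    config: DetectorConfig,
    channel: str = "",
    t0: float = 0.0,
    interval_index: int | None = None,
    patient_id: str | None = None,
) -> dict[str, list[HFOEvent]]:
    """Run the full two-stage detector on one channel over one interval.

    Returns accepted ripples, FR, and their co-occurrence pairs. A channel
    whose baseline is degenerate (flat signal) yields no events.
    """
    out: dict[str, list[HFOEvent]] = {"ripple": [], "FR": [], "HFO": []}
    per_band: dict[str, list[HFOEvent]] = {}
    for kind in ("ripple", "FR"):
        band = config.band(kind)
        filtered = bandpass(signal, fs, band, config.filter_order)
        try:
            thr = entropy_baseline_threshold(filtered, fs, config, band)
        except DegenerateBaselineError:
            per_band[kind] = []
            continue
        cands = detect_band_events(filtered, fs, thr, band, config, channel=channel, t0=t0)
        accepted = morphology_filter(cands, kind, config)
        for ev in accepted:
            ev.interval_index = interval_index
            ev.patient_id = patient_id
        per_band[kind] = accepted
    out["ripple"] = per_band.get("ripple", [])
    out["FR"] = per_band.get("FR", [])
    out["HFO"] = pair_cooccurrence(out["ripple"], out["FR"], extent=config.pair_extent)
    return out
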