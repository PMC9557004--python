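"""Morphological features of HFO events and the labelled feature table.

Five features per co-occurring event: peak-to-peak amplitude on the
ripple-band signal (Am-ripples, uV) and on the FR-band signal (Am-FR, uV),
central frequency in each band as the inverse of the mean distance between
consecutive positive local maxima (Fr-ripples, Fr-FR, Hz), and the duration
of the paired event from onset to offset (D-HFO, ms).

For tissue characterization only true-negative patients are informative:
their resected HFO-area channels are operationally epileptogenic (Class-1,
resection led to seizure freedom) and their non-resected channels
non-epileptogenic (Class-2). Events of TP, FP and FN patients are excluded
because their epileptogenicity cannot be established.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from hfopipe.detect import HFOEvent

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("am_fr", "am_ripples", "fr_fr", "fr_ripples", "d_hfo")


def peak_to_peak(segment: np.ndarray) -> float:
    """Max minus min of the band-filtered samples within the event."""
    segment = np.asarray(segment)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.ptp(segment))


def central_frequency(segment: np.ndarray, fs: float) -> float | None:
    """Inverse of the mean interval between consecutive positive local maxima.

    For a sinusoid the interpeak distance is one period, so this recovers
    the oscillation frequency. Returns None (undefined) for segments with
    fewer than two peaks.
    """
    segment = np.asarray(segment)
    peaks, _ = find_peaks(segment)
    if len(peaks) < 2:
        return None
    return float(fs / np.mean(np.diff(peaks)))


def event_duration(event: HFOEvent) -> float:
    """Onset-to-offset duration in milliseconds."""
    return event.duration_ms


def extract_event_features(
    event: HFOEvent,
    ripple_filtered: np.ndarray,
    fr_filtered: np.ndarray,
    fs: float,
    t0: float = 0.0,
) -> dict | None:
    """Feature vector for one paired event, or None when undefined.

    Amplitude and frequency in each band are measured on that band's
    filtered signal over the corresponding sub-event window; the duration is
    the paired event's extent. ``t0`` is the signal's start time in seconds.
    """
    if event.kind != "HFO" or event.ripple is None or event.fr is None:
        raise ValueError("features are defined for paired (kind='HFO') events")

    def window(sig, sub):
        i0 = int(round((sub.onset_s - t0) * fs))
        i1 = int(round((sub.offset_s - t0) * fs))
        return sig[max(i0, 0) : i1]

    rip_seg = window(ripple_filtered, event.ripple)
    fr_seg = window(fr_filtered, event.fr)
    if rip_seg.size == 0 or fr_seg.size == 0:
        return None
    fr_rip = central_frequency(rip_seg, fs)
    fr_fr = central_frequency(fr_seg, fs)
    am_rip = peak_to_peak(rip_seg)
    am_fr = peak_to_peak(fr_seg)
    if fr_rip is None or fr_fr is None or am_rip == 0 or am_fr == 0:
        return None
    return {
        "am_fr": am_fr,
        "am_ripples": am_rip,
        "fr_fr": fr_fr,
        "fr_ripples": fr_rip,
        "d_hfo": event_duration(event),
    }


def build_feature_table(
    events_with_features: list[tuple[HFOEvent, dict]],
    validations: dict[str, "object"],
    channel_metadata: dict[str, pd.DataFrame],
    areas: dict[str, set[str]],
) -> pd.DataFrame:
    """Assemble the labelled event x feature table over TN patients.

    ``validations`` maps patient_id -> PatientValidation, ``channel_metadata``
    maps patient_id -> channel table (channel, region, resected), ``areas``
    maps patient_id -> HFO-area channel set. Class-1 rows are events on
    resected HFO-area channels; Class-2 rows events on non-resected
    channels; events on resected channels outside the area are dropped
    (their epileptogenic status is ambiguous). Non-TN patients contribute
    nothing.
    """
    rows = []
    n_dropped = 0
    for event, feats in events_with_features:
        pid = event.patient_id
        val = validations.get(pid)
        if val is None or val.status != "TN":
            continue
        meta = channel_metadata[pid]
        hit = meta[meta["channel"] == event.channel]
        if hit.empty:
            raise ValueError(f"event on unknown channel {event.channel!r} (patient {pid})")
        resected = bool(hit["resected"].iloc[0])
        in_area = event.channel in areas.get(pid, set())
        if resected and in_area:
            cls = "Class-1"
        elif not resected:
            cls = "Class-2"
        else:  # resected but outside the area
            n_dropped += 1
            continue
        if feats is None:
            n_dropped += 1
            continue
        rows.append(
            {
                **feats,
                "patient_id": pid,
                "channel": event.channel,
                "region": hit["region"].iloc[0],
                "class": cls,
            }
        )
    if n_dropped:
        logger.info("feature table: dropped %d events (undefined features or ambiguous channel)", n_dropped)
    return pd.DataFrame(
        rows, columns=list(FEATURE_COLUMNS) + ["patient_id", "channel", "region", "class"]
    )
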