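"""Recording containers, bipolar montage derivation and NREM interval slicing.

Stereo-EEG is recorded from depth electrodes carrying several contacts each.
Analysis operates on the bipolar montage: the difference between physically
adjacent contacts on the same electrode shaft, which suppresses volume-
conducted far-field activity. Contacts flagged noisy are excluded before
pairing, so a noisy contact removes the bipolar channels it would anchor.

Recordings travel as flat float64 binary plus a JSON sidecar and a TSV
contact table, all human-inspectable apart from the raw samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("MTL", "Neocortex")

#: columns required in a contact metadata table
CONTACT_COLUMNS = ("contact", "electrode", "index", "region", "resected", "noisy")


@dataclass
class Recording:
    """Contact-level (referential) multichannel recording.

    signals is contacts x samples in microvolts; contacts is a DataFrame with
    the CONTACT_COLUMNS (``index`` is the within-electrode contact number,
    1 = deepest).
    """

    patient_id: str
    signals: np.ndarray
    fs: float
    contacts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (contacts x samples)")
        if len(self.contacts) != self.signals.shape[0]:
            raise ValueError("contact table length does not match signal rows")
        missing = set(CONTACT_COLUMNS) - set(self.contacts.columns)
        if missing:
            raise ValueError(f"contact table missing columns: {sorted(missing)}")
        if self.contacts["contact"].duplicated().any():
            raise ValueError("contact labels must be unique")
        bad = set(self.contacts["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BipolarData:
    """Bipolar-montage signals plus per-channel metadata and NREM intervals.

    channels is a DataFrame with columns (channel, electrode, region,
    resected); intervals is a list of half-open (start_s, stop_s) pairs.
    """

    patient_id: str
    signals: np.ndarray
    fs: float
    channels: pd.DataFrame
    intervals: list[tuple[float, float]] = field(default_factory=list)
    ilae: int | None = None

    def __post_init__(self) -> None:
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError("channel table length does not match signal rows")
        validate_intervals(self.intervals, self.signals.shape[1] / self.fs)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels["channel"])

    def resected_channels(self) -> set[str]:
        return set(self.channels.loc[self.channels["resected"].astype(bool), "channel"])

    def total_minutes(self) -> float:
        return sum(b - a for a, b in self.intervals) / 60.0


def validate_intervals(intervals, duration_s: float | None = None) -> None:
    """Check half-open intervals are ordered, positive and non-overlapping."""
    prev_stop = -np.inf
    for start, stop in sorted(intervals):
        if stop <= start:
            raise ValueError(f"empty or inverted interval [{start}, {stop})")
        if start < prev_stop:
            raise ValueError(f"overlapping interval [{start}, {stop})")
        if duration_s is not None and stop > duration_s + 1e-9:
            raise ValueError(
                f"interval [{start}, {stop}) exceeds recording duration {duration_s:.3f} s"
            )
        prev_stop = stop


def derive_bipolar(
    recording: Recording,
    resect_rule: str = "both",
    intervals: list[tuple[float, float]] | None = None,
    ilae: int | None = None,
) -> BipolarData:
    """Derive the bipolar montage along consecutive contacts of each electrode.

    For each electrode the usable (non-noisy) contacts are sorted by their
    within-electrode index and every physically adjacent pair (index step of
    one) yields a bipolar channel anode-minus-cathode, named "A1-A2".
    Electrodes contributing fewer than two usable contacts emit nothing.

    The bipolar ``resected`` flag is True when both member contacts are
    resected (``resect_rule="both"``, the conservative default) or when at
    least one is (``"either"``). The region label is taken from the deeper
    (lower-index) contact.
    """
    if resect_rule not in ("both", "either"):
        raise ValueError("resect_rule must be 'both' or 'either'")
    rows = []
    sig_rows = []
    contacts = recording.contacts
    for electrode, grp in contacts.groupby("electrode", sort=True):
        usable = grp.loc[~grp["noisy"].astype(bool)].sort_values("index")
        if len(usable) < 2:
            logger.info("electrode %s: <2 usable contacts, no bipolar channels", electrode)
            continue
        recs = usable.to_dict("records")
        for a, b in zip(recs[:-1], recs[1:]):
            if b["index"] - a["index"] != 1:
                continue  # a noisy contact broke physical adjacency
            # positional rows of anode/cathode in the signal array
            ia = int(np.flatnonzero(contacts["contact"].values == a["contact"])[0])
            ib = int(np.flatnonzero(contacts["contact"].values == b["contact"])[0])
            sig_rows.append(recording.signals[ia] - recording.signals[ib])
            if resect_rule == "both":
                resected = bool(a["resected"]) and bool(b["resected"])
            else:
                resected = bool(a["resected"]) or bool(b["resected"])
            rows.append(
                {
                    "channel": f"{a['contact']}-{b['contact']}",
                    "electrode": electrode,
                    "region": a["region"],
                    "resected": resected,
                }
            )
    signals = np.vstack(sig_rows) if sig_rows else np.empty((0, recording.n_samples))
    return BipolarData(
        patient_id=recording.patient_id,
        signals=signals,
        fs=recording.fs,
        channels=pd.DataFrame(rows, columns=["channel", "electrode", "region", "resected"]),
        intervals=intervals or [],
        ilae=ilae,
    )


def slice_intervals(
    signals: np.ndarray, fs: float, intervals: list[tuple[float, float]]
) -> list[np.ndarray]:
    """Cut channels x samples into per-interval blocks, half-open in time.

    The sample at ``round(start*fs)`` is included, the one at
    ``round(stop*fs)`` excluded, so adjoining intervals share no sample.
    """
    n = signals.shape[-1]
    blocks = []
    for start, stop in intervals:
        i0 = int(round(start * fs))
        i1 = int(round(stop * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(
                f"interval [{start}, {stop}) s is outside the recording "
                f"({n / fs:.3f} s long)"
            )
        blocks.append(signals[..., i0:i1])
    return blocks


# ---------------------------------------------------------------------------
# on-disk formats: flat binary + JSON sidecar, TSV metadata, CSV intervals


def save_bipolar(data: BipolarData, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = outdir / f"{data.patient_id}.dat"
    data.signals.astype("<f8").tofile(raw)
    sidecar = {
        "patient_id": data.patient_id,
        "fs": data.fs,
        "n_channels": int(data.signals.shape[0]),
        "n_samples": int(data.signals.shape[1]),
        "dtype": "<f8",
        "ilae": data.ilae,
        "intervals": [[float(a), float(b)] for a, b in data.intervals],
    }
    (outdir / f"{data.patient_id}.json").write_text(json.dumps(sidecar, indent=2))
    data.channels.to_csv(outdir / f"{data.patient_id}.channels.tsv", sep="\t", index=False)
    return raw


def load_bipolar(outdir: str | Path, patient_id: str) -> BipolarData:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{patient_id}.json").read_text())
    signals = np.fromfile(outdir / f"{patient_id}.dat", dtype=sidecar["dtype"]).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    channels = pd.read_csv(outdir / f"{patient_id}.channels.tsv", sep="\t")
    return BipolarData(
        patient_id=patient_id,
        signals=signals,
        fs=sidecar["fs"],
        channels=channels,
        intervals=[tuple(iv) for iv in sidecar["intervals"]],
        ilae=sidecar["ilae"],
    )


def read_contact_table(path: str | Path) -> pd.DataFrame:
    """Read a contact metadata TSV (contact, electrode, index, region, resected, noisy)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CONTACT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_interval_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    intervals = [(float(r.start_s), float(r.stop_s)) for r in df.itertuples()]
    validate_intervals(intervals)
    return intervals
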