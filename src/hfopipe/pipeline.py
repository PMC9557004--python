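"""End-to-end orchestration: detect -> rates/area -> validate -> features.

``run_patient`` drives the detector stage-by-stage over every bipolar
channel and NREM interval of one patient (keeping the band-filtered signals
so morphology features come for free), then computes pooled and
per-interval rate vectors, the HFO area, the permutation test-retest
report, and the outcome classification. ``run_cohort`` aggregates patients
into the confusion table, predictive metrics, the TN-patient feature table
and the statistical contrasts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hfopipe import __version__
from hfopipe.detect import (
    DegenerateBaselineError,
    DetectorConfig,
    HFOEvent,
    bandpass,
    detect_band_events,
    entropy_baseline_threshold,
    morphology_filter,
    pair_cooccurrence,
)
from hfopipe.features import build_feature_table, extract_event_features
from hfopipe.iobase import BipolarData, slice_intervals
from hfopipe.rates import compute_rates, hfo_area, test_retest_summary
from hfopipe.validation import classify_patient, compute_metrics

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    area_percentile: float = 95.0
    area_min_rate: float = 1.0
    n_perm: int = 5000
    perm_alpha_percentile: float = 97.5
    cv_scheme: str = "nested-5x5"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in raw.pop("detector", {}).items()})
        return cls(detector=det, **raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def detect_patient(data: BipolarData, config: RunConfig):
    """Run the two-stage detector over all channels and intervals.

    Returns (events, filtered) where events is a flat list of accepted
    ripple, FR and paired HFO events and filtered maps channel ->
    {"ripple": array, "FR": array} full-length band-filtered signals.
    """
    cfg = config.detector
    events: list[HFOEvent] = []
    filtered: dict[str, dict[str, np.ndarray]] = {}
    for row, sig in zip(data.channels.itertuples(), data.signals):
        ch = row.channel
        bands = {
            "ripple": bandpass(sig, data.fs, cfg.ripple_band, cfg.filter_order),
            "FR": bandpass(sig, data.fs, cfg.fr_band, cfg.filter_order),
        }
        filtered[ch] = bands
        recording_thr = {}
        if cfg.baseline_scope == "recording":
            for kind in ("ripple", "FR"):
                try:
                    recording_thr[kind] = entropy_baseline_threshold(
                        bands[kind], data.fs, cfg, cfg.band(kind)
                    )
                except DegenerateBaselineError:
                    recording_thr[kind] = None
        for k, (start, stop) in enumerate(data.intervals):
            per_band: dict[str, list[HFOEvent]] = {}
            for kind in ("ripple", "FR"):
                band = cfg.band(kind)
                block = slice_intervals(bands[kind], data.fs, [(start, stop)])[0]
                if cfg.baseline_scope == "recording":
                    thr = recording_thr[kind]
                else:
                    try:
                        thr = entropy_baseline_threshold(block, data.fs, cfg, band)
                    except DegenerateBaselineError:
                        thr = None
                if thr is None:
                    per_band[kind] = []
                    continue
                cands = detect_band_events(
                    block, data.fs, thr, band, cfg, channel=ch, t0=start
                )
                accepted = morphology_filter(cands, kind, cfg)
                for ev in accepted:
                    ev.interval_index = k
                    ev.patient_id = data.patient_id
                per_band[kind] = accepted
            pairs = pair_cooccurrence(per_band["ripple"], per_band["FR"], extent=cfg.pair_extent)
            for ev in pairs:
                ev.interval_index = k
                ev.patient_id = data.patient_id
            events.extend(per_band["ripple"])
            events.extend(per_band["FR"])
            events.extend(pairs)
    return events, filtered


def events_to_frame(events: list[HFOEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "channel": e.channel,
                "kind": e.kind,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "peak_amp_uv": e.peak_amp_uv,
                "interval_index": e.interval_index,
            }
            for e in events
        ],
        columns=["patient_id", "channel", "kind", "onset_s", "offset_s", "peak_amp_uv", "interval_index"],
    )


def run_patient(data: BipolarData, config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full single-patient analysis; optionally writes the report files."""
    events, filtered = detect_patient(data, config)
    channels = data.channel_names
    pooled = compute_rates(events, data.intervals, channels, kind="HFO")
    per_interval = compute_rates(events, data.intervals, channels, kind="HFO", per_interval=True)
    area = hfo_area(pooled, percentile=config.area_percentile, min_rate=config.area_min_rate)
    reliability = test_retest_summary(per_interval.values, n_perm=config.n_perm, seed=config.seed)
    validation = None
    if data.ilae is not None:
        validation = classify_patient(area, data.resected_channels(), data.ilae, data.patient_id)
    feats = []
    for ev in events:
        if ev.kind != "HFO":
            continue
        f = extract_event_features(
            ev, filtered[ev.channel]["ripple"], filtered[ev.channel]["FR"], data.fs
        )
        feats.append((ev, f))
    report = {
        "patient_id": data.patient_id,
        "events": events,
        "event_features": feats,
        "rates_pooled": pooled,
        "rates_per_interval": per_interval,
        "area": sorted(area),
        "reliability": reliability,
        "validation": validation,
    }
    if outdir is not None:
        _write_patient_report(report, data, config, Path(outdir))
    return report


def _write_patient_report(report: dict, data: BipolarData, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pid = report["patient_id"]
    events_to_frame(report["events"]).to_csv(outdir / f"{pid}.events.csv", index=False)
    report["rates_pooled"].rename("rate_per_min").rename_axis("channel").to_csv(
        outdir / f"{pid}.rates.csv"
    )
    (outdir / f"{pid}.area.json").write_text(json.dumps({"patient_id": pid, "area": report["area"]}, indent=2))
    (outdir / f"{pid}.reliability.json").write_text(json.dumps(report["reliability"], indent=2))
    val = report["validation"]
    payload = dataclasses.asdict(val) if val is not None else None
    (outdir / f"{pid}.validation.json").write_text(json.dumps(payload, indent=2))


def run_cohort(
    patients: list[BipolarData],
    config: RunConfig,
    outdir: str | Path | None = None,
    classify: bool = False,
) -> dict:
    """Analyse every patient, aggregate metrics, features and contrasts.

    A failing patient is recorded and the cohort continues; the report's
    ``failures`` list carries (patient_id, error).
    """
    if not patients:
        raise ValueError("empty cohort")
    from hfopipe.stats import remove_outliers, run_contrasts, zscore_features

    reports, failures = [], []
    for data in patients:
        try:
            reports.append(run_patient(data, config, outdir=outdir))
        except Exception as exc:  # noqa: BLE001 — cohort continues past one bad patient
            logger.error("patient %s failed: %s", data.patient_id, exc)
            failures.append({"patient_id": data.patient_id, "error": str(exc)})
    validations = {r["patient_id"]: r["validation"] for r in reports if r["validation"]}
    statuses = [v.status for v in validations.values() if v.status is not None]
    metrics = compute_metrics(statuses) if statuses else None
    events_feats = [ef for r in reports for ef in r["event_features"]]
    meta = {p.patient_id: p.channels for p in patients}
    areas = {r["patient_id"]: set(r["area"]) for r in reports}
    table = build_feature_table(events_feats, validations, meta, areas)
    tests, clf_reports = [], []
    if len(table) and table["class"].nunique() == 2:
        table = remove_outliers(table, seed=config.seed)
        table, _scaler = zscore_features(table)
        tests, clf_reports = run_contrasts(table, seed=config.seed, classify=classify)
    cohort_report = {
        "n_patients": len(patients),
        "failures": failures,
        "metrics": metrics,
        "feature_table": table,
        "median_tests": tests,
        "classifier_reports": clf_reports,
        "reliability_mean_pct": float(
            np.mean([r["reliability"]["mean_pct"] for r in reports])
        )
        if reports
        else float("nan"),
        "manifest": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {
            k: v
            for k, v in cohort_report.items()
            if k not in ("feature_table", "median_tests")
        }
        serializable["median_tests"] = [dataclasses.asdict(t) for t in tests]
        (outdir / "cohort.json").write_text(json.dumps(serializable, indent=2, default=str))
        table.to_csv(outdir / "features.csv", index=False)
    return cohort_report
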