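"""Simulate a small stereo-EEG cohort with known ground truth.

Generates four synthetic patients (2 TN, 1 TP, 1 FP by construction: 40
bipolar channels each, two high-rate HFO channels, four 5-min NREM
intervals) and writes the raw recordings, ground-truth event list and
expected statuses under scratch/sim (flat binary + sidecars + CSV).
Runtime is a few minutes; rerun with a different --seed for a new cohort.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from hfopipe.iobase import save_bipolar
from hfopipe.synthetic import generate_cohort, generate_patient

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "sim")
    args = parser.parse_args()

    cohort = generate_cohort(
        4, {"TP": 1, "TN": 2, "FP": 1, "FN": 0}, seed=args.seed, n_intervals=4
    )
    truth_rows, manifest = [], []
    for spec, status in cohort:
        data, truth, _ = generate_patient(spec)
        save_bipolar(data, args.outdir)
        manifest.append({"patient_id": spec.patient_id, "expected_status": status})
        truth_rows += [
            {"patient_id": spec.patient_id, **dataclasses.asdict(ev)} for ev in truth
        ]
        print(f"{spec.patient_id}: {sum(e.kind == 'HFO-pair' for e in truth)} truth pairs, "
              f"expected {status}")
    (args.outdir / "cohort.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(truth_rows).to_csv(args.outdir / "truth_events.csv", index=False)
    print(f"recordings and truth table in {args.outdir}")


if __name__ == "__main__":
    main()
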