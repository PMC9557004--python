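"""Outcome validation on the published 20-patient cohort rows.

Applies the four-category rule (full HFO-area resection x good/poor ILAE
outcome) to the bundled cohort summary and prints the confusion table and
predictive metrics with exact binomial 95% confidence intervals, writing
the report to results/validation_metrics.json.
"""

import json
from pathlib import Path

from hfopipe.datasets import classify_cohort_rows, published_cohort
from hfopipe.validation import compute_metrics

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    statuses = classify_cohort_rows(published_cohort())
    m = compute_metrics(statuses)
    print("counts:", m["counts"])
    for name in ("specificity", "sensitivity", "npv", "ppv", "accuracy"):
        r = m[name]
        print(f"{name:>12}: {r['display']:3d}% CI [{r['ci_display'][0]} {r['ci_display'][1]}]"
              f"  ({r['numerator']}/{r['denominator']})")
    out = ROOT / "results" / "validation_metrics.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(m, indent=2))
    print(f"written to {out}")


if __name__ == "__main__":
    main()
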