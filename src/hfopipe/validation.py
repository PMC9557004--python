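"""Patient-level validation of the HFO area against seizure outcome.

A patient whose HFO area was fully resected and who became seizure-free
(ILAE 1) is a true negative; fully resected with persisting seizures (ILAE
2-6) a false negative; not fully resected with good outcome a false
positive; not fully resected with poor outcome a true positive. From the
cohort confusion table the standard predictive metrics follow, with exact
binomial (Clopper-Pearson) 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import beta

logger = logging.getLogger(__name__)

STATUSES = ("TP", "TN", "FP", "FN")


@dataclass(frozen=True)
class PatientValidation:
    patient_id: str
    area_fully_resected: bool
    ilae: int
    status: str | None  # None when the patient has no HFO area


def status_from_flags(area_fully_resected: bool, ilae: int) -> str:
    """The four-category rule over {fully resected} x {good/poor outcome}."""
    if not 1 <= ilae <= 6:
        raise ValueError(f"ILAE outcome must be in 1..6, got {ilae!r}")
    good = ilae == 1
    return {
        (True, True): "TN",
        (True, False): "FN",
        (False, True): "FP",
        (False, False): "TP",
    }[(area_fully_resected, good)]


def classify_patient(
    hfo_area: set[str], resected_channels: set[str], ilae: int, patient_id: str = ""
) -> PatientValidation:
    """Cross full-resection of the HFO area with good/poor ILAE outcome.

    A patient with an empty HFO area cannot be classified; flagged with
    status None and excluded from cohort metrics.
    """
    if not isinstance(ilae, int) or not 1 <= ilae <= 6:
        raise ValueError(f"ILAE outcome must be an integer in 1..6, got {ilae!r}")
    if not hfo_area:
        logger.warning("patient %s: empty HFO area, excluded from metrics", patient_id)
        return PatientValidation(patient_id, False, ilae, None)
    fully = hfo_area <= set(resected_channels)
    return PatientValidation(patient_id, fully, ilae, status_from_flags(fully, ilae))


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles (proportions)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def compute_metrics(statuses: list[str], conf: float = 0.95) -> dict:
    """Cohort predictive metrics with exact binomial CIs.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/N. Each is reported in percent at
    full precision together with a half-up-rounded integer display value and
    its Clopper-Pearson interval; an undefined ratio (0/0) is reported as
    None ("not applicable").
    """
    if not statuses:
        raise ValueError("empty status list")
    bad = set(statuses) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown statuses: {sorted(bad)}")
    counts = {s: statuses.count(s) for s in STATUSES}
    n = len(statuses)
    defs = {
        "sensitivity": (counts["TP"], counts["TP"] + counts["FN"]),
        "specificity": (counts["TN"], counts["TN"] + counts["FP"]),
        "ppv": (counts["TP"], counts["TP"] + counts["FP"]),
        "npv": (counts["TN"], counts["TN"] + counts["FN"]),
        "accuracy": (counts["TP"] + counts["TN"], n),
    }
    report: dict = {"counts": counts, "n": n}
    for name, (x, d) in defs.items():
        if d == 0:
            report[name] = None
            continue
        lo, hi = clopper_pearson(x, d, conf)
        report[name] = {
            "percent": 100.0 * x / d,
            "display": _round_half_up(100.0 * x / d),
            "ci_percent": (100.0 * lo, 100.0 * hi),
            "ci_display": (_round_half_up(100.0 * lo), _round_half_up(100.0 * hi)),
            "numerator": x,
            "denominator": d,
        }
    return report
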