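"""Bundled reference data.

``published_cohort`` returns the per-patient summary of a published
20-patient stereo-EEG cohort: whether each patient's HFO area was fully
contained in the resection, and the ILAE seizure outcome. These two columns
are all the four-category outcome rule needs, so the cohort's confusion
table and predictive metrics can be recomputed from scratch.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from hfopipe.validation import status_from_flags


def published_cohort() -> pd.DataFrame:
    """20-patient cohort summary: patient_id, area_fully_resected, ilae."""
    path = files("hfopipe.data").joinpath("published_cohort.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    df["area_fully_resected"] = df["area_fully_resected"].astype(bool)
    return df


def classify_cohort_rows(df: pd.DataFrame) -> list[str]:
    """Apply the four-category outcome rule to each cohort row."""
    return [
        status_from_flags(bool(r.area_fully_resected), int(r.ilae))
        for r in df.itertuples()
    ]
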