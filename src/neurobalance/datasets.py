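"""Packaged reference data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stroke_cohort"]


def load_stroke_cohort() -> pd.DataFrame:
    """Feature table of the eight-patient stroke cohort.

    One row per patient: AGE (years), ERD (mean negative normalized beta
    power at Cz during the first second of dorsiflexion, power units),
    HBO (peak of the trial-averaged oxygenated-hemoglobin curve over the
    sensorimotor channels), and BBS (Berg Balance Scale, 0-56 points).
    """
    ref = resources.files("neurobalance.data") / "stroke_cohort.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
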