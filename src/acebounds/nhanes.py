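"""Adapter for NHANES SAS transport (XPT) files.

Builds the case-study baseline SBP cohort from the National Health and
Nutrition Examination Survey 2017-2018 public-use files:

* ``BPX_J.XPT`` — examination blood pressure; first systolic reading
  ``BPXSY1``;
* ``DEMO_J.XPT`` — demographics; age ``RIDAGEYR`` and the two-year
  examination weight ``WTMEC2YR``.

Inclusion: age >= 18 and first SBP >= 140 mm Hg (the support constraint of
the case-study context), positive examination weight, nonmissing SBP.
Records failing these are dropped and counted in the log.  The survey names
the cohort, not the exact variable mapping, so this mapping is a
reconstruction and every name can be overridden.

This module is optional: the rest of the package builds and tests without
any NHANES download.  Files are read with :func:`pandas.read_sas`.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .distributions import WeightedCohort, build_cohort

__all__ = ["load_nhanes_cohort", "DEFAULT_VARIABLES"]

logger = logging.getLogger(__name__)

DEFAULT_VARIABLES = {
    "bp_file": "BPX_J.XPT",
    "demo_file": "DEMO_J.XPT",
    "id": "SEQN",
    "sbp": "BPXSY1",
    "age": "RIDAGEYR",
    "weight": "WTMEC2YR",
}


def load_nhanes_cohort(
    directory,
    min_age: float = 18.0,
    support_min: float = 140.0,
    variables: dict | None = None,
) -> WeightedCohort:
    """Load and filter the NHANES 2017-2018 SBP cohort from XPT files.

    Parameters
    ----------
    directory
        Folder containing the blood-pressure and demographics XPT files.
    min_age, support_min
        Inclusion thresholds: age >= ``min_age`` and first SBP >=
        ``support_min`` mm Hg.
    variables
        Overrides for :data:`DEFAULT_VARIABLES` (file and column names).
    """
    var = dict(DEFAULT_VARIABLES)
    if variables:
        var.update(variables)
    directory = Path(directory)
    bp_path = directory / var["bp_file"]
    demo_path = directory / var["demo_file"]
    for path in (bp_path, demo_path):
        if not path.exists():
            raise FileNotFoundError(
                f"NHANES file not found: {path}. Download the 2017-2018 "
                "examination and demographics XPT files into this directory."
            )

    bp = pd.read_sas(bp_path, format="xport")[[var["id"], var["sbp"]]]
    demo = pd.read_sas(demo_path, format="xport")[
        [var["id"], var["age"], var["weight"]]
    ]
    df = bp.merge(demo, on=var["id"], how="inner")
    n0 = len(df)

    df = df.dropna(subset=[var["sbp"], var["age"], var["weight"]])
    n_missing = n0 - len(df)
    df = df[df[var["weight"]] > 0]
    df = df[df[var["age"]] >= min_age]
    n_kept_pre_sbp = len(df)

    cohort = build_cohort(
        df[var["sbp"]].to_numpy(float),
        df[var["weight"]].to_numpy(float),
        support_min=support_min,
    )
    logger.info(
        "NHANES cohort: %d merged records, %d dropped for missingness, "
        "%d adults with positive weight, %d with SBP >= %g",
        n0,
        n_missing,
        n_kept_pre_sbp,
        cohort.n,
        support_min,
    )
    return cohort
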