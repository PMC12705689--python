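"""Clinical derived variables and classification flags.

HOMA-IR, FIB-4, BMI and the steatosis/prediabetes classifications used
throughout the trial analysis.  FIB-4 is offered in two variants: the
standard definition age*ASAT / (platelets*sqrt(ALAT)) with
aminotransferases in U/L, and an ``as_printed`` variant without the
square root that treats the units as given (some clinical reports state
the formula this way).  The standard form is the default because it is
the one whose values land on the familiar 1.3/2.67 interpretive scale.
Aminotransferase conversion: 1 ukat/L = 60 U/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from triarm.errors import DomainError

__all__ = [
    "ClassificationThresholds",
    "UKAT_TO_UL",
    "homa_ir",
    "fib4",
    "bmi",
    "classify_status",
    "remission_rates",
]

#: 1 microkatal per litre expressed in U/L (1 U = 1 umol/min).
UKAT_TO_UL = 60.0


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs for steatosis and prediabetes classification.

    nafld_liver_fat_pct: liver fat (%) above which steatosis is present
        (strictly greater than).
    prediabetes_glucose: fasting plasma glucose (mmol/L), at-or-above.
    prediabetes_hba1c: HbA1c (mmol/mol), at-or-above.
    homa_denominator: the 22.5 normalising constant of HOMA-IR.
    """

    nafld_liver_fat_pct: float = 5.6
    prediabetes_glucose: float = 5.6
    prediabetes_hba1c: float = 39.0
    homa_denominator: float = 22.5

    def __post_init__(self) -> None:
        for f in ("nafld_liver_fat_pct", "prediabetes_glucose",
                  "prediabetes_hba1c", "homa_denominator"):
            if getattr(self, f) <= 0:
                raise DomainError(f"{f} must be strictly positive")


def homa_ir(insulin: float, glucose: float,
            denominator: float = 22.5) -> float:
    """HOMA insulin-resistance index: insulin (mE/L) x glucose (mmol/L) / 22.5."""
    if insulin < 0 or glucose < 0:
        raise DomainError("insulin and glucose must be non-negative")
    return insulin * glucose / denominator


def fib4(age: float, asat: float, alat: float, platelets: float,
         mode: str = "standard") -> float:
    """FIB-4 liver-fibrosis index.

    Parameters
    ----------
    age : years
    asat, alat : aminotransferases; U/L for ``standard`` mode, any single
        consistent unit for ``as_printed``.
    platelets : platelet count, 10^9/L.
    mode : ``"standard"`` uses age*ASAT / (platelets*sqrt(ALAT));
        ``"as_printed"`` omits the square root.
    """
    if min(age, asat, alat, platelets) <= 0:
        raise DomainError("all FIB-4 inputs must be strictly positive")
    if mode == "standard":
        return age * asat / (platelets * sqrt(alat))
    if mode == "as_printed":
        return age * asat / (platelets * alat)
    raise DomainError(f"unknown FIB-4 mode {mode!r}")


def bmi(weight: float, height: float) -> float:
    """Body-mass index, weight (kg) / height (m) squared."""
    if height <= 0:
        raise DomainError("height must be strictly positive")
    if weight < 0:
        raise DomainError("weight must be non-negative")
    return weight / height**2


def classify_status(record: Mapping[str, float],
                    thresholds: ClassificationThresholds | None = None,
                    ) -> dict[str, bool]:
    """Steatosis / prediabetes flags for one subject record.

    Steatosis requires liver fat strictly *exceeding* the cutoff;
    prediabetes is at-or-above on either glucose or HbA1c.  Keys absent
    from the record are treated as not contributing (e.g. a record with
    only ``liver_fat`` yields a steatosis flag and ``prediabetes=False``).
    """
    th = thresholds or ClassificationThresholds()
    flags = {"nafld": False, "prediabetes": False}
    lf = record.get("liver_fat")
    if lf is not None and not pd.isna(lf):
        if not 0 <= lf <= 100:
            raise DomainError(f"liver fat {lf} outside [0, 100]%")
        flags["nafld"] = lf > th.nafld_liver_fat_pct
    glu = record.get("glucose")
    hba = record.get("hba1c")
    for v, name in ((glu, "glucose"), (hba, "hba1c")):
        if v is not None and not pd.isna(v) and v < 0:
            raise DomainError(f"{name} must be non-negative")
    pre = False
    if glu is not None and not pd.isna(glu):
        pre = pre or glu >= th.prediabetes_glucose
    if hba is not None and not pd.isna(hba):
        pre = pre or hba >= th.prediabetes_hba1c
    flags["prediabetes"] = pre
    return flags


def remission_rates(table: pd.DataFrame, baseline_col: str,
                    followup_col: str, arm_col: str = "arm",
                    ) -> pd.DataFrame:
    """Per-arm remission fractions among baseline-positive completers.

    A subject contributes to the denominator when both boolean flags are
    observed and the baseline flag is true; remission means the follow-up
    flag is false.  Arms with an empty denominator get a NaN rate rather
    than raising.

    Returns a frame indexed by arm with columns ``n_baseline``,
    ``n_remitted`` and ``pct`` (percentage, 0-100).
    """
    rows = []
    for arm, grp in table.groupby(arm_col, observed=True):
        complete = grp[[baseline_col, followup_col]].notna().all(axis=1)
        base_pos = complete & grp[baseline_col].astype("boolean").fillna(False).astype(bool)
        denom = int(base_pos.sum())
        remit = int((base_pos & ~grp[followup_col].astype(bool)).sum())
        pct = 100.0 * remit / denom if denom > 0 else np.nan
        rows.append({"arm": arm, "n_baseline": denom,
                     "n_remitted": remit, "pct": pct})
    return pd.DataFrame(rows).set_index("arm")
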