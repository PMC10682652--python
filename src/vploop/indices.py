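"""Conventional hemodynamic comparator indices and pre/post change metrics.

These are the standard bedside quantities the loop-derived slope index is
compared against: valvuloarterial impedance Zva, total arterial
distensibility SVi/PP, and the proportional pre-to-post variation used for
change tables.

SVi is stored in ml/m^2 (stroke volume indexed to body surface area), the
unit under which Zva values around 4-5 mmHg.m^2/ml are dimensionally
coherent.  Missing fields are carried as missing (None/NaN); index functions
never impute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EchoPanel",
    "zva",
    "arterial_distensibility",
    "proportional_variation",
    "append_indices",
]


@dataclass(frozen=True)
class EchoPanel:
    """Echocardiographic / hemodynamic numbers for one patient.

    All fields optional; units: pressures mmHg, SVi ml/m^2, LVEF %,
    energy_loss_index and indexed_AVA cm^2/m^2.
    """

    SBP: Optional[float] = None
    DBP: Optional[float] = None
    MAP: Optional[float] = None
    PP: Optional[float] = None
    SVi: Optional[float] = None
    LVEF: Optional[float] = None
    max_gradient: Optional[float] = None
    mean_gradient: Optional[float] = None
    energy_loss_index: Optional[float] = None
    indexed_AVA: Optional[float] = None

    def __post_init__(self):
        for name in ("SBP", "MAP", "PP", "SVi", "max_gradient", "mean_gradient",
                     "energy_loss_index", "indexed_AVA"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.LVEF is not None and not (0 < self.LVEF <= 100):
            raise ValueError(f"LVEF must be in (0, 100], got {self.LVEF}")
        if self.PP is not None and self.SBP is not None and self.DBP is not None:
            if not np.isclose(self.PP, self.SBP - self.DBP):
                raise ValueError(
                    f"PP={self.PP} inconsistent with SBP-DBP="
                    f"{self.SBP - self.DBP}"
                )


def zva(SBP: float, mean_gradient: float, SVi: float) -> float:
    """Valvuloarterial impedance (SBP + mean aortic gradient) / SVi.

    Global left-ventricular afterload estimate, mmHg.m^2/ml; SVi in ml/m^2.
    """
    if SVi <= 0:
        raise ValueError("SVi must be positive")
    return (SBP + mean_gradient) / SVi


def arterial_distensibility(SVi: float, PP: float) -> float:
    """Total arterial distensibility surrogate SVi/PP (ml/mmHg per m^2)."""
    if PP <= 0:
        raise ValueError("pulse pressure must be positive")
    return SVi / PP


def proportional_variation(pre_value: float, post_value: float) -> float:
    """Relative change (post - pre) / pre; undefined for pre == 0."""
    if pre_value == 0:
        raise ValueError("proportional variation undefined for pre_value == 0")
    return (post_value - pre_value) / pre_value


def append_indices(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append zva and svi_pp columns to a cohort table.

    Expects columns ``sbp``, ``mean_gradient``, ``svi`` and ``pp`` where
    available; rows with missing inputs get NaN.
    """
    out = cohort.copy()
    if {"sbp", "mean_gradient", "svi"} <= set(out.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            out["zva"] = (out["sbp"] + out["mean_gradient"]) / out["svi"]
    if {"svi", "pp"} <= set(out.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            out["svi_pp"] = out["svi"] / out["pp"]
    return out
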