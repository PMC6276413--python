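"""Lipid-panel derivations, dyslipidemia classification, and cohort summaries.

The four phenotypes handled throughout the package are total cholesterol
(TC), LDL cholesterol (LDL-c), HDL cholesterol (HDL-c) and triglycerides
(TG), all in mg/dl.  LDL-c is normally not measured directly but derived
from the other three with the Friedewald formula::

    LDL-c = TC - HDL-c - TG / 5          (mg/dl, valid for TG < 400 mg/dl)

Dyslipidemia flags use the standard clinical cutoffs: hypercholesterolemia
TC >= 200, high LDL-c >= 130, hypertriglyceridemia TG >= 150, and low HDL-c
("hypoalphalipoproteinemia") < 40 mg/dl in men and < 50 mg/dl in women.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: TG above this bound makes the Friedewald VLDL approximation unreliable.
FRIEDEWALD_TG_LIMIT = 400.0

#: mg/dl per mmol/l conversion factors.
CHOLESTEROL_MGDL_PER_MMOL = 38.67
TG_MGDL_PER_MMOL = 88.57

LIPIDS = ("tc", "ldl", "hdl", "tg")


def friedewald_ldl(tc, hdl, tg):
    """Derive LDL-c (mg/dl) from TC, HDL-c and TG via the Friedewald formula.

    Accepts scalars or array-likes (broadcast).  All inputs must be positive;
    applicability (TG < 400 mg/dl) is *not* enforced here -- use
    :func:`friedewald_valid` or :func:`derive_ldl` when a validity mask is
    needed.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc <= 0) or np.any(hdl <= 0) or np.any(tg <= 0):
        raise ValueError("TC, HDL-c and TG must all be positive (mg/dl)")
    out = tc - hdl - tg / 5.0
    if out.ndim == 0:
        return float(out)
    return out


def friedewald_valid(tg) -> np.ndarray:
    """Boolean mask: True where the Friedewald derivation is applicable."""
    return np.asarray(tg, dtype=float) < FRIEDEWALD_TG_LIMIT


def derive_ldl(cohort: pd.DataFrame, *, tg_limit: float = FRIEDEWALD_TG_LIMIT,
               prefer_derived: bool = True) -> pd.DataFrame:
    """Add/refresh the ``ldl`` column of a cohort table.

    Parameters
    ----------
    cohort
        Table with ``tc``, ``hdl`` and ``tg`` columns in mg/dl.  An existing
        ``ldl`` column is overwritten unless ``prefer_derived=False``.
    tg_limit
        TG bound above which the derived value is set to NaN and flagged in
        the added ``ldl_valid`` column.
    """
    out = cohort.copy()
    derived = out["tc"] - out["hdl"] - out["tg"] / 5.0
    valid = out["tg"] < tg_limit
    if prefer_derived or "ldl" not in out.columns:
        out["ldl"] = derived.where(valid)
    out["ldl_valid"] = valid
    return out


def classify_dyslipidemia(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject dyslipidemia flags from a lipid panel.

    Expects columns ``tc``, ``ldl``, ``hdl``, ``tg`` (mg/dl) and ``sex``
    (coded ``"F"``/``"M"``).  Returns a boolean frame with columns
    ``hypercholesterolemia``, ``high_ldl``, ``low_hdl`` and
    ``hypertriglyceridemia``; ``low_hdl`` is NA where sex is missing because
    its cutoff is sex-specific.
    """
    sex = cohort["sex"].astype("string")
    hdl_cut = pd.Series(np.nan, index=cohort.index)
    hdl_cut[sex == "M"] = 40.0
    hdl_cut[sex == "F"] = 50.0
    low_hdl = pd.array(cohort["hdl"] < hdl_cut, dtype="boolean")
    low_hdl[hdl_cut.isna()] = pd.NA
    return pd.DataFrame(
        {
            "hypercholesterolemia": cohort["tc"] >= 200.0,
            "high_ldl": cohort["ldl"] >= 130.0,
            "low_hdl": low_hdl,
            "hypertriglyceridemia": cohort["tg"] >= 150.0,
        },
        index=cohort.index,
    )


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (the convention of clinical percent tables;
    numpy's default rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def prevalence_report(flags: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per dyslipidemia condition over a cohort.

    Missing flags (e.g. ``low_hdl`` with unknown sex) are excluded from both
    numerator and denominator of that condition.
    """
    if len(flags) == 0:
        raise ValueError("empty cohort: prevalence undefined")
    rows = []
    for cond in flags.columns:
        col = flags[cond]
        n = int(col.notna().sum())
        count = int((col == True).sum())  # noqa: E712  (nullable boolean)
        pct = 100.0 * count / n if n else np.nan
        rows.append(
            {
                "condition": cond,
                "count": count,
                "n": n,
                "percent": pct,
                "percent_rounded": int(round_half_away(pct)) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def mgdl_to_mmol(value, lipid: str):
    """Convert a cholesterol (tc/ldl/hdl) or TG value from mg/dl to mmol/l."""
    factor = TG_MGDL_PER_MMOL if lipid == "tg" else CHOLESTEROL_MGDL_PER_MMOL
    return np.asarray(value, dtype=float) / factor


def mmol_to_mgdl(value, lipid: str):
    factor = TG_MGDL_PER_MMOL if lipid == "tg" else CHOLESTEROL_MGDL_PER_MMOL
    return np.asarray(value, dtype=float) * factor


_SUMMARY_CONTINUOUS: Mapping[str, str] = {
    "age": "Age (years)",
    "weight": "Weight (kg)",
    "bmi": "BMI (kg/m2)",
    "tfat": "TFAT (kg)",
    "vfat": "VFAT (kg)",
    "glucose": "Glucose (mg/dl)",
    "tc": "TC (mg/dl)",
    "hdl": "HDL-c (mg/dl)",
    "ldl": "LDL-c (mg/dl)",
    "tg": "TG (mg/dl)",
    "energy": "Energy (kcal)",
    "carb_pct": "Carbohydrates (%E)",
    "prot_pct": "Protein (%E)",
    "fat_pct": "Fat (%E)",
    "chol_intake": "Cholesterol intake (mg)",
    "mets": "METs",
}
_SUMMARY_BINARY: Mapping[str, str] = {
    "smoker": "Smokers (%)",
    "drinker": "Drinkers (%)",
}


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics table: mean +/- SD for continuous variables,
    count and percent for binary ones."""
    rows = []
    for col, label in _SUMMARY_CONTINUOUS.items():
        if col not in cohort.columns:
            continue
        x = cohort[col].dropna()
        rows.append({"variable": label, "mean": x.mean(), "sd": x.std(ddof=1),
                     "count": np.nan, "percent": np.nan})
    if "sex" in cohort.columns:
        n_f = int((cohort["sex"] == "F").sum())
        n_m = int((cohort["sex"] == "M").sum())
        rows.append({"variable": "Sex (F/M)", "mean": np.nan, "sd": np.nan,
                     "count": n_f, "percent": 100.0 * n_f / max(n_f + n_m, 1)})
    for col, label in _SUMMARY_BINARY.items():
        if col not in cohort.columns:
            continue
        x = cohort[col].dropna().astype(bool)
        rows.append({"variable": label, "mean": np.nan, "sd": np.nan,
                     "count": int(x.sum()),
                     "percent": 100.0 * x.mean() if len(x) else np.nan})
    return pd.DataFrame(rows).set_index("variable")


def summary_to_markdown(summary: pd.DataFrame) -> str:
    lines = ["| Variable | Value |", "| --- | --- |"]
    for var, row in summary.iterrows():
        if np.isfinite(row["mean"]):
            val = f"{row['mean']:.1f} +/- {row['sd']:.1f}"
        else:
            val = f"n = {int(row['count'])} ({row['percent']:.1f}%)"
        lines.append(f"| {var} | {val} |")
    return "\n".join(lines) + "\n"
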