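"""GC-MS internal-standard relative quantification.

Analyte peak areas are divided by the ribitol internal-standard area
(20 nmol spiked per sample) to give dimensionless relative quantities;
norvaline and camphorsulfonic acid are carried as QC columns only.
Condition means over three biological replicates are compared to the
control by a classic two-sided pooled-variance Student's t-test, with
strict p < 0.05 significance marking, producing a table of per-metabolite
means and p values for each stress.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("control", "NaCl", "sucrose")


def relative_quant(analyte_area: float, ribitol_area: float) -> float:
    """Analyte peak area relative to the ribitol internal-standard area."""
    if ribitol_area <= 0:
        raise ValueError("ribitol area must be > 0 (invalid sample)")
    if analyte_area < 0:
        raise ValueError("analyte area must be >= 0")
    return analyte_area / ribitol_area


def ttest_vs_control(
    stress: np.ndarray | list[float],
    control: np.ndarray | list[float],
    welch: bool = False,
) -> float:
    """Two-sided two-sample Student's t-test p value.

    Pooled-variance by default (``welch=True`` switches to the unequal-
    variance variant).  Degenerate zero-pooled-variance groups yield p = 1
    when the means agree and p = 0 when they differ.
    """
    a = np.asarray(stress, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    # constant groups: mean subtraction leaves no exact zero variance in
    # floating point, so detect degeneracy by all-values-equal
    if a.max() == a.min() and b.max() == b.min():
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def build_metabolite_table(
    peaks: pd.DataFrame, alpha: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Per-metabolite condition means and stress-vs-control t-tests.

    ``peaks`` is a long-format table with columns condition, replicate,
    analyte, analyte_area, ribitol_area.  Returns one row per analyte
    (sorted by analyte name) with mean relative quantities per condition,
    p values for each stress vs control, and strict p < alpha significance
    flags.  Analytes missing a condition are skipped with a warning.
    """
    empty = pd.DataFrame(
        columns=[
            "control", "NaCl", "sucrose",
            "p_NaCl", "p_sucrose", "sig_NaCl", "sig_sucrose",
        ],
        index=pd.Index([], name="analyte"),
    )
    if len(peaks) == 0:
        return empty
    peaks = peaks.copy()
    peaks["ratio"] = peaks.apply(
        lambda r: relative_quant(r["analyte_area"], r["ribitol_area"]), axis=1
    )
    rows = []
    for analyte in sorted(peaks["analyte"].unique()):
        sub = peaks[peaks["analyte"] == analyte]
        groups = {
            cond: sub.loc[sub["condition"] == cond, "ratio"].to_numpy()
            for cond in CONDITIONS
        }
        if any(len(v) == 0 for v in groups.values()):
            warnings.warn(
                f"analyte {analyte!r} lacks a condition; skipped", stacklevel=2
            )
            continue
        row = {"analyte": analyte}
        for cond in CONDITIONS:
            row[cond] = float(groups[cond].mean())
        for cond in ("NaCl", "sucrose"):
            p = ttest_vs_control(groups[cond], groups["control"], welch=welch)
            row[f"p_{cond}"] = p
            row[f"sig_{cond}"] = bool(p < alpha)
        rows.append(row)
    if not rows:
        return empty
    return pd.DataFrame(rows).set_index("analyte")
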