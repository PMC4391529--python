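"""2D-gel spot quantification statistics.

Spot volumes (grey-level integrals inside matched spot boundaries) are
normalized per gel to 100% of the detected overall gel quantity, spots
below a 0.02% abundance floor on every image are eliminated, relative
volumes are standardized (mean-centred, unit sample SD) per spot, and a
one-factorial ANOVA across the three conditions (control, NaCl, sucrose)
tests each spot at alpha = 0.1.  Changes of the condition means exceeding
two-fold in either direction are flagged substantial, and the per-condition
RSD (100 * sd / mean) serves as the replicate-reproducibility QC.  The
mass-spectrometry identification acceptance rule (at least two Mowse
scores >= 50 and sequence coverage >= 30%) is applied to externally
produced evidence; spectrum processing itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ACCEPTED = "accepted"
NEEDS_MSMS = "needs_msms"
REJECTED = "rejected"


@dataclass
class SpotConfig:
    alpha: float = 0.1
    fold: float = 2.0
    min_volume: float = 0.02  # percent of gel total
    rsd_limit: float = 35.0  # percent


def normalize_spots(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw volumes to percent of each gel's total quantity.

    Adds a ``normalized`` column: 100 * raw / (sum of raw on that gel).
    A gel whose volumes are all zero has no reference quantity and is an
    error.
    """
    sums = table.groupby("gel_id")["raw_volume"].transform("sum")
    zero_gels = table.loc[sums == 0, "gel_id"].unique()
    if len(zero_gels):
        raise ValueError(f"gel(s) with zero total volume: {list(zero_gels)}")
    out = table.copy()
    out["normalized"] = 100.0 * table["raw_volume"] / sums
    return out


def low_abundance_filter(
    normalized: pd.DataFrame, min_volume: float = 0.02
) -> pd.Series:
    """Spots to eliminate: normalized volume < min_volume on *every* image.

    Returns a boolean Series indexed by spot_id (True = eliminated).
    """
    return (
        normalized.groupby("spot_id")["normalized"]
        .max()
        .lt(min_volume)
        .rename("eliminated")
    )


def standardize(values: np.ndarray | list[float]) -> np.ndarray:
    """Mean-centre and scale to unit sample (n−1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


def anova_per_spot(
    groups: list[np.ndarray | list[float]], alpha: float = 0.1
) -> tuple[float, float, bool]:
    """One-way ANOVA over condition groups: F = MS_between / MS_within.

    p comes from the F distribution with (k−1, N−k) degrees of freedom;
    significant iff p < alpha.  Conditions with fewer than 2 replicates
    cannot contribute a within-group variance estimate.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    f_stat, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f_stat), float(p), bool(p < alpha)


def fold_change_call(
    mean_stress: float, mean_control: float, fold: float = 2.0
) -> tuple[float, bool]:
    """Stress/control ratio of condition means with the substantial flag.

    Substantial iff the ratio strictly exceeds ``fold`` up- or
    down-regulation (ratio > fold or ratio < 1/fold).
    """
    if mean_control <= 0:
        raise ValueError("control mean must be > 0 for a fold change")
    ratio = mean_stress / mean_control
    return ratio, bool(ratio > fold or ratio < 1.0 / fold)


def rsd(values: np.ndarray | list[float]) -> float:
    """Relative standard deviation: 100 * sample sd / mean (percent).

    Undefined (NaN) for a zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs >= 2 replicates")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def identification_filter(
    mowse_scores: list[float], coverage: float
) -> str:
    """Apply the peptide-mass-fingerprint acceptance rule.

    accepted iff at least two Mowse scores >= 50 and sequence coverage
    >= 30%; needs_msms iff the score criterion is met but coverage falls
    short (the spot goes to MALDI-MS/MS); rejected otherwise.
    """
    if not mowse_scores:
        raise ValueError("at least one spectrum score required")
    if not (0 <= coverage <= 100):
        raise ValueError("coverage must be a percentage in [0, 100]")
    qualifying = sum(s >= 50 for s in mowse_scores)
    if qualifying >= 2:
        return ACCEPTED if coverage >= 30 else NEEDS_MSMS
    return REJECTED


def spot_stats(
    table: pd.DataFrame, cfg: SpotConfig | None = None
) -> pd.DataFrame:
    """Full per-spot statistics over a long-format spot-volume table.

    Expects columns gel_id, condition, replicate, spot_id, raw_volume with
    conditions control/NaCl/sucrose.  Returns one row per spot with the
    low-abundance flag, ANOVA F/p/significance (computed on normalized
    volumes; F is scale- and shift-invariant so standardization does not
    change it), fold changes and substantial flags per stress, and RSD per
    condition.  Eliminated spots carry NaN statistics.
    """
    cfg = cfg or SpotConfig()
    norm = normalize_spots(table)
    eliminated = low_abundance_filter(norm, cfg.min_volume)

    rows = []
    for spot_id, sub in norm.groupby("spot_id"):
        row: dict = {"spot_id": spot_id,
                     "low_abundance": bool(eliminated[spot_id])}
        by_cond = {
            cond: g["normalized"].to_numpy()
            for cond, g in sub.groupby("condition")
        }
        for cond, vals in by_cond.items():
            row[f"rsd_{cond}"] = rsd(vals) if len(vals) >= 2 else float("nan")
        if eliminated[spot_id]:
            row.update(
                F=float("nan"), p=float("nan"), significant=False,
                fold_NaCl=float("nan"), fold_sucrose=float("nan"),
                substantial_NaCl=False, substantial_sucrose=False,
            )
        else:
            f_stat, p, sig = anova_per_spot(
                [by_cond[c] for c in ("control", "NaCl", "sucrose")],
                cfg.alpha,
            )
            row.update(F=f_stat, p=p, significant=sig)
            control_mean = by_cond["control"].mean()
            for cond in ("NaCl", "sucrose"):
                ratio, substantial = fold_change_call(
                    by_cond[cond].mean(), control_mean, cfg.fold
                )
                row[f"fold_{cond}"] = ratio
                row[f"substantial_{cond}"] = substantial
        rows.append(row)
    out = pd.DataFrame(rows).set_index("spot_id").sort_index()
    return out


def rsd_qc_summary(
    stats_table: pd.DataFrame, rsd_limit: float = 35.0
) -> pd.DataFrame:
    """Fraction of spots whose per-condition RSD falls below the limit.

    NaN RSDs (zero-mean spots) are excluded from the denominator.
    """
    rows = []
    for col in [c for c in stats_table.columns if c.startswith("rsd_")]:
        vals = stats_table[col].dropna()
        rows.append(
            {
                "condition": col[len("rsd_"):],
                "n_spots": len(vals),
                "fraction_below_limit": float((vals < rsd_limit).mean())
                if len(vals)
                else float("nan"),
                "median_rsd": float(vals.median()) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("condition")
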