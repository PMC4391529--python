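"""Probe-level microarray differential-expression calling.

Two-color arrays tile 9–11 probes per gene across a (−300, +200) window
around the translational start (+1 = first base).  The caller applies the
positional filter (only probes downstream of the start, offset >= +1,
contribute), averages probe log2 ratios per gene and replicate, and calls a
gene differentially expressed only when the per-replicate mean exceeds the
threshold in the same direction in *all three* biological replicates —
replicate-consistent fold change, no p-value, no multiple-testing
correction.  The same rule applied to the direct sucrose-vs-NaCl ratios
drives the G1–G4 stress-comparison grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
NOT_EVALUATED = "not_evaluated"


@dataclass
class DEConfig:
    """Replicate-consistency DE rule parameters.

    ``threshold`` is in log2 units (default 1.0, i.e. two-fold); the
    comparison is strict (> +threshold / < −threshold).  ``require_all``
    demands the rule hold in every replicate.
    """

    threshold: float = 1.0
    n_replicates: int = 3
    require_all: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def filter_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Keep only probes downstream of the translational start (offset >= +1).

    Probe coordinates are midpoint offsets relative to the start (+1 =
    first base, negative = upstream).  Row order is preserved.
    """
    return probes[probes["offset"] >= 1]


def gene_ratio(probe_ratios: np.ndarray | list[float]) -> float:
    """Arithmetic mean of the probe log2 ratios of one gene, one replicate."""
    arr = np.asarray(probe_ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("no probes passed the positional filter")
    return float(arr.mean())


def call_de(replicate_means: list[float] | np.ndarray,
            cfg: DEConfig | None = None) -> str:
    """Apply the replicate-consistent threshold rule to per-replicate means.

    up iff every replicate mean > +threshold; down iff every mean
    < −threshold; otherwise unchanged.  Missing (NaN) replicates make the
    gene not_evaluated.
    """
    cfg = cfg or DEConfig()
    arr = np.asarray(replicate_means, dtype=float)
    if arr.size < cfg.n_replicates or np.isnan(arr).any():
        return NOT_EVALUATED
    if np.all(arr > cfg.threshold):
        return UP
    if np.all(arr < -cfg.threshold):
        return DOWN
    return UNCHANGED


def de_table(
    probes: pd.DataFrame, contrast: str, cfg: DEConfig | None = None
) -> pd.DataFrame:
    """Per-gene replicate means and DE status for one contrast.

    ``probes`` is the probe-level table with columns gene_id, offset and
    ``{contrast}_rep{r}``.  Genes whose probes all lie upstream of +1 are
    reported not_evaluated with NaN means.  Returns a DataFrame indexed by
    gene_id with columns rep1..repN, status.
    """
    cfg = cfg or DEConfig()
    rep_cols = [f"{contrast}_rep{r}" for r in range(1, cfg.n_replicates + 1)]
    missing = [c for c in rep_cols if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table lacks columns {missing}")
    all_genes = probes["gene_id"].unique()
    passing = filter_probes(probes)
    means = passing.groupby("gene_id")[rep_cols].mean()

    rows = []
    for gene in all_genes:
        if gene in means.index:
            m = means.loc[gene].to_numpy(dtype=float)
            status = call_de(m, cfg)
        else:
            m = np.full(cfg.n_replicates, np.nan)
            status = NOT_EVALUATED
        rows.append({"gene_id": gene, **{
            f"rep{r + 1}": m[r] for r in range(cfg.n_replicates)
        }, "status": status})
    out = pd.DataFrame(rows).set_index("gene_id")
    return out


def assign_groups(
    status_nacl: pd.Series,
    status_sucrose: pd.Series,
    status_direct: pd.Series,
) -> pd.Series:
    """Assign each gene to at most one of the stress-comparison groups.

    G1: higher expression under sucrose in the direct comparison, or
    up-regulated only under sucrose; G2: down-regulated only under
    sucrose; G3: higher under NaCl in the direct comparison, or
    up-regulated only under NaCl; G4: down-regulated only under NaCl.
    The direct-contrast routes take precedence, so each gene lands in
    exactly one group or none.
    """
    genes = status_nacl.index
    out = pd.Series("none", index=genes, name="group")
    for gene in genes:
        nacl = status_nacl.get(gene, NOT_EVALUATED)
        suc = status_sucrose.get(gene, NOT_EVALUATED)
        direct = status_direct.get(gene, NOT_EVALUATED)
        if direct == UP:  # sucrose > NaCl
            out[gene] = "G1"
        elif direct == DOWN:  # NaCl > sucrose
            out[gene] = "G3"
        elif suc == UP and nacl != UP:
            out[gene] = "G1"
        elif suc == DOWN and nacl != DOWN:
            out[gene] = "G2"
        elif nacl == UP and suc != UP:
            out[gene] = "G3"
        elif nacl == DOWN and suc != DOWN:
            out[gene] = "G4"
    return out


def category_summary(
    calls: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Count regulated genes per functional category and condition.

    ``calls`` has columns gene_id, condition, status; genes missing from
    the annotation fall into the "unknown" category.  Returns a table
    indexed by main_role with one column per (condition, direction),
    e.g. ``NaCl_up`` — including all-zero rows/columns so the shape is
    stable across call sets.
    """
    ann = annotation.set_index("gene_id")["main_role"]
    conditions = sorted(calls["condition"].unique()) if len(calls) else []
    roles = sorted(set(ann.unique()) | (
        {"unknown"} if len(calls) and (~calls["gene_id"].isin(ann.index)).any()
        else set()
    ))
    out = pd.DataFrame(
        0,
        index=pd.Index(roles, name="main_role"),
        columns=[f"{c}_{d}" for c in conditions for d in (UP, DOWN)],
        dtype=int,
    )
    for _, row in calls.iterrows():
        if row["status"] not in (UP, DOWN):
            continue
        role = ann.get(row["gene_id"], "unknown")
        out.loc[role, f"{row['condition']}_{row['status']}"] += 1
    return out


def run_de_analysis(
    probes: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    cfg: DEConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Full DE workflow over the three contrasts.

    Returns per-contrast call tables, the G1–G4 group assignment and, when
    an annotation is supplied, the per-category summary of the two
    stress-vs-control contrasts.
    """
    cfg = cfg or DEConfig()
    tables = {c: de_table(probes, c, cfg) for c in ("NaCl", "sucrose", "direct")}
    groups = assign_groups(
        tables["NaCl"]["status"],
        tables["sucrose"]["status"],
        tables["direct"]["status"],
    )
    result = {"calls": tables, "groups": groups.to_frame()}
    if annotation is not None:
        long_calls = pd.concat(
            [
                tables[c][["status"]]
                .reset_index()
                .assign(condition=c)
                for c in ("NaCl", "sucrose")
            ],
            ignore_index=True,
        )
        result["category_summary"] = category_summary(long_calls, annotation)
    return result
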