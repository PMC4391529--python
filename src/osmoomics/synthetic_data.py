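"""Synthetic input generators for every pipeline stage.

Each generator emulates the *post-extraction* tables a hyperosmotic-stress
study produces — protein complements of two genomes with planted orthologs,
probe-level two-color log2 ratios with planted differentially expressed
genes, 2D-gel spot volumes with planted fold changes, and GC-MS peak areas
normalized to a ribitol internal standard — with the statistical structure
the downstream analysis assumes.  Nothing upstream of those tables (scanner
images, spectra, chromatograms) is simulated.

All generators are deterministic under a fixed seed: the same
:class:`SimulationConfig` produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CONDITIONS = ("control", "NaCl", "sucrose")
#: Contrast labels used throughout: stress/control log2 ratios for each
#: stress, plus the direct sucrose-vs-NaCl comparison.
CONTRASTS = ("NaCl", "sucrose", "direct")

#: Published mean relative quantities (analyte peak area / ribitol peak
#: area, dimensionless) of the six metabolites whose levels change under
#: hyperosmotic stress in C. crescentus, as (control, NaCl, sucrose).
#: These serve as the default target means of :func:`simulate_peak_table`.
OSMOSTRESS_METABOLITE_MEANS: dict[str, tuple[float, float, float]] = {
    "Glucose": (11.85, 53.15, 64.55),
    "L-glutamate": (17.12, 78.54, 57.92),
    "L-phenylalanine": (0.06, 0.14, 0.15),
    "L-isoleucine": (0.20, 0.21, 0.59),
    "L-leucine": (0.38, 0.64, 0.86),
    "L-proline": (0.20, 0.36, 0.48),
}


@dataclass
class SimulationConfig:
    """Parameters of all synthetic-data generators.

    The defaults reflect the study conditions the pipeline was designed
    for: three biological replicates, 9–11 probes per gene tiled across a
    (−300, +200) window around the translational start, a two-fold (log2
    effect 2.0) planted expression shift, and lognormal multiplicative
    noise on volumes and areas.
    """

    seed: int = 0
    # -- transcriptome --
    n_genes: int = 200
    n_probes_min: int = 9
    n_probes_max: int = 11
    probe_window: tuple[int, int] = (-300, 200)
    n_replicates: int = 3
    de_fraction_up: float = 0.1
    de_fraction_down: float = 0.075
    de_effect: float = 2.0
    probe_noise_sd: float = 0.2
    # -- proteome --
    n_spots: int = 200
    spot_cv: float = 0.1
    planted_spot_fold: float = 3.0
    planted_spot_fraction: float = 0.1
    faint_spot_count: int = 5
    # -- metabolome --
    peak_cv: float = 0.1
    ribitol_area: float = 20000.0
    # -- genome pair --
    ortholog_identity_levels: tuple[float, ...] = tuple(
        np.round(np.linspace(0.4, 1.0, 25), 3)
    )
    protein_length: int = 300
    decoy_count: int = 20

    def __post_init__(self) -> None:
        if self.de_fraction_up + self.de_fraction_down > 1:
            raise ValueError("de_fraction_up + de_fraction_down must be <= 1")
        if not (0 < self.n_probes_min <= self.n_probes_max):
            raise ValueError("invalid probe count bounds")
        lo, hi = self.probe_window
        if lo >= hi:
            raise ValueError("probe_window must be a nonempty interval")
        for ident in self.ortholog_identity_levels:
            if not (0 < ident <= 1):
                raise ValueError(
                    f"ortholog identity level {ident} outside (0, 1]"
                )
        for name in ("spot_cv", "peak_cv", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_spot_fold <= 0:
            raise ValueError("planted_spot_fold must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML or JSON, filling unspecified defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        for key in ("probe_window", "ortholog_identity_levels"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probe_window"] = list(self.probe_window)
        d["ortholog_identity_levels"] = [
            float(x) for x in self.ortholog_identity_levels
        ]
        return d


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV.

    sigma is chosen so that sd/mean of the factor equals ``cv``; the factor
    has expectation exactly 1, so noiseless settings (cv=0) are exact.
    """
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# genome pair with planted orthologs
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_to_identity(
    rng: np.random.Generator, residues: str, identity: float
) -> tuple[str, float]:
    """Point-mutate ``residues`` so the fraction of unchanged positions is
    as close as possible to ``identity``.  Substitutions only — no indels —
    so the realized identity is exactly ``1 - n_mut/len``."""
    length = len(residues)
    n_mut = int(round((1.0 - identity) * length))
    positions = rng.choice(length, size=n_mut, replace=False)
    out = list(residues)
    for pos in positions:
        choices = [a for a in AA20 if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out), 1.0 - n_mut / length


def simulate_genome_pair(config: SimulationConfig):
    """Generate a source/target proteome pair with planted orthologs.

    One ortholog is planted per entry of ``config.ortholog_identity_levels``
    by point-mutating a random source protein down to the requested percent
    identity.  ``config.decoy_count`` unrelated random-residue decoys are
    added to each proteome and never appear in the truth table.

    Returns
    -------
    (source, target, truth) where source/target are lists of
    ``(id, organism, residues)`` tuples understood by the ortholog screen,
    and truth is a DataFrame with columns source_id, target_id,
    target_identity (requested) and realized_identity.
    """
    from .ortholog_screen import ProteinSequence

    rng = np.random.default_rng(config.seed)
    source, target, rows = [], [], []
    for i, ident in enumerate(config.ortholog_identity_levels):
        if not (0 < ident <= 1):
            raise ValueError(f"identity level {ident} outside (0, 1]")
        sid, tid = f"SRC_{i:04d}", f"TGT_{i:04d}"
        res = _random_protein(rng, config.protein_length)
        mutated, realized = _mutate_to_identity(rng, res, ident)
        source.append(ProteinSequence(sid, "src", res))
        target.append(ProteinSequence(tid, "tgt", mutated))
        rows.append(
            {
                "source_id": sid,
                "target_id": tid,
                "target_identity": float(ident),
                "realized_identity": realized,
            }
        )
    for i in range(config.decoy_count):
        source.append(
            ProteinSequence(
                f"SRCDECOY_{i:04d}", "src",
                _random_protein(rng, config.protein_length),
            )
        )
        target.append(
            ProteinSequence(
                f"TGTDECOY_{i:04d}", "tgt",
                _random_protein(rng, config.protein_length),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=["source_id", "target_id", "target_identity",
                 "realized_identity"],
    )
    return source, target, truth


# ---------------------------------------------------------------------------
# probe-level two-color log2 ratio table
# ---------------------------------------------------------------------------

def simulate_probe_table(config: SimulationConfig):
    """Generate a probe-level log2-ratio table plus a DE truth table.

    Each gene carries 9–11 probes whose midpoint offsets are drawn
    uniformly from the design window around the translational start
    (+1 = first base; offset 0 does not exist).  Per-gene true log2 levels
    are 0 for unchanged genes and ±``de_effect`` for planted genes, drawn
    independently for the NaCl and sucrose contrasts; the direct
    sucrose-vs-NaCl ratio is their difference.  Probe-level Normal noise of
    sd ``probe_noise_sd`` (log2 units) is added independently per probe,
    replicate and contrast.

    Returns
    -------
    (table, truth): ``table`` has columns probe_id, gene_id, offset and
    ``{contrast}_rep{r}``; ``truth`` has columns gene_id, contrast,
    direction ("up"/"down").
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]

    n_up = int(round(config.de_fraction_up * config.n_genes))
    n_down = int(round(config.de_fraction_down * config.n_genes))
    mu = {c: np.zeros(config.n_genes) for c in ("NaCl", "sucrose")}
    truth_rows = []
    for contrast in ("NaCl", "sucrose"):
        chosen = rng.choice(config.n_genes, size=n_up + n_down, replace=False)
        for g in chosen[:n_up]:
            mu[contrast][g] = config.de_effect
            truth_rows.append(
                {"gene_id": genes[g], "contrast": contrast, "direction": "up"}
            )
        for g in chosen[n_up:]:
            mu[contrast][g] = -config.de_effect
            truth_rows.append(
                {"gene_id": genes[g], "contrast": contrast,
                 "direction": "down"}
            )
    mu["direct"] = mu["sucrose"] - mu["NaCl"]
    for g in np.nonzero(mu["direct"])[0]:
        truth_rows.append(
            {
                "gene_id": genes[g],
                "contrast": "direct",
                "direction": "up" if mu["direct"][g] > 0 else "down",
            }
        )

    lo, hi = config.probe_window
    # valid midpoint offsets: the window minus the nonexistent position 0
    offsets_pool = np.array(
        [o for o in range(lo, hi + 1) if o != 0], dtype=int
    )
    rows = []
    for g, gene in enumerate(genes):
        n_probes = int(
            rng.integers(config.n_probes_min, config.n_probes_max + 1)
        )
        offs = rng.choice(offsets_pool, size=n_probes, replace=False)
        for j, off in enumerate(offs):
            row = {
                "probe_id": f"{gene}_p{j:02d}",
                "gene_id": gene,
                "offset": int(off),
            }
            for contrast in CONTRASTS:
                noise = rng.normal(
                    0.0, config.probe_noise_sd, size=config.n_replicates
                )
                for r in range(config.n_replicates):
                    row[f"{contrast}_rep{r + 1}"] = mu[contrast][g] + noise[r]
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "contrast", "direction"]
    ).sort_values(["contrast", "gene_id"], ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# functional annotation / operon structure
# ---------------------------------------------------------------------------

_MAIN_ROLES: dict[str, tuple[str, ...]] = {
    "Transport and binding proteins": (
        "Cations and iron carrying compounds",
        "Carbohydrates, organic alcohols, and acids",
        "Amino acids, peptides and amines",
    ),
    "Energy metabolism": ("Glycolysis", "TCA cycle", "Electron transport"),
    "Protein synthesis": ("Ribosomal proteins", "tRNA aminoacylation"),
    "Regulatory functions": ("DNA interactions", "Small molecule interactions"),
    "Cell envelope": ("Biosynthesis of murein sacculus", "Surface structures"),
    "Unknown function": ("General", "Conserved hypothetical"),
}


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Generate a TIGR-style two-level functional annotation with operons.

    Genes are laid out in genome order and grouped into operons of 1–5
    consecutive genes; all members of an operon share a (main role,
    sub-role) pair, mirroring the co-functional structure of real operons.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]
    roles = list(_MAIN_ROLES)
    rows: list[dict] = []
    i = 0
    operon = 0
    while i < config.n_genes:
        size = min(int(rng.integers(1, 6)), config.n_genes - i)
        main = roles[rng.integers(len(roles))]
        sub = _MAIN_ROLES[main][rng.integers(len(_MAIN_ROLES[main]))]
        for j in range(size):
            rows.append(
                {
                    "gene_id": genes[i + j],
                    "main_role": main,
                    "sub_role": sub,
                    "operon_id": f"operon_{operon:04d}",
                    "genome_order_index": i + j,
                }
            )
        i += size
        operon += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D-gel spot volumes
# ---------------------------------------------------------------------------

def simulate_spot_table(config: SimulationConfig):
    """Generate a long-format spot-volume table plus a fold-change truth.

    Spot abundances are planted in compositional space: each gel's spot
    *shares* sum to 1 before noise, as densitometric normalization to 100%
    of the detected gel quantity enforces downstream.  Planted spots have
    their share multiplied by ``planted_spot_fold`` in both stress
    conditions, with the remaining spots uniformly rescaled to keep the
    composition closed; at ``spot_cv = 0`` the downstream normalized ratio
    of a planted spot is therefore exactly the planted fold.  A few faint
    spots are planted below the 0.02% abundance floor on every gel to
    exercise the low-abundance filter.

    Returns
    -------
    (table, truth): ``table`` has columns gel_id, condition, replicate,
    spot_id, raw_volume; ``truth`` has columns spot_id, planted_fold,
    faint (bool).
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_spots
    spot_ids = [f"spot_{i:04d}" for i in range(n)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    faint = np.zeros(n, dtype=bool)
    n_faint = min(config.faint_spot_count, n)
    faint_idx = rng.choice(n, size=n_faint, replace=False)
    faint[faint_idx] = True
    # push faint spots well below 0.02% of the gel total
    base[faint_idx] = base.sum() * 5e-5

    n_planted = int(round(config.planted_spot_fraction * n))
    # plant only on below-median-abundance spots: regulated synthesis spots
    # are rarely the dominant housekeeping spots, and keeping the planted
    # mass small keeps the compositional closure shift of the remaining
    # spots well inside the two-fold window
    plantable = np.setdiff1d(np.arange(n), faint_idx)
    plantable = plantable[base[plantable] <= np.median(base[plantable])]
    planted_idx = rng.choice(
        plantable, size=min(n_planted, len(plantable)), replace=False
    )
    fold = np.ones(n)
    fold[planted_idx] = config.planted_spot_fold

    shares = {"control": base / base.sum()}
    for cond in ("NaCl", "sucrose"):
        s = shares["control"].copy()
        planted_mass = s[planted_idx].sum()
        rest = 1.0 - planted_mass
        scale = (1.0 - config.planted_spot_fold * planted_mass) / rest
        s = s * scale
        s[planted_idx] = shares["control"][planted_idx] * config.planted_spot_fold
        shares[cond] = s

    gel_total = 1e6
    rows = []
    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            noise = _lognoise(rng, config.spot_cv, n)
            vols = shares[cond] * gel_total * noise
            gel_id = f"{cond}_{rep}"
            for sid, v in zip(spot_ids, vols):
                rows.append(
                    {
                        "gel_id": gel_id,
                        "condition": cond,
                        "replicate": rep,
                        "spot_id": sid,
                        "raw_volume": float(v),
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"spot_id": spot_ids, "planted_fold": fold, "faint": faint}
    )
    return table, truth


# ---------------------------------------------------------------------------
# GC-MS peak areas
# ---------------------------------------------------------------------------

def simulate_peak_table(
    config: SimulationConfig,
    target_means: dict[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Generate a GC-MS peak-area table with a ribitol internal standard.

    The ribitol area is fixed per sample; each analyte area is constructed
    so its expected area ratio to ribitol equals the target mean for the
    sample's condition, with mean-one multiplicative lognormal noise at
    ``peak_cv``.  The norvaline and camphorsulfonic-acid standards are
    carried as constant QC columns (they are spiked but unused by the
    ribitol-based quantification).
    """
    if target_means is None:
        target_means = OSMOSTRESS_METABOLITE_MEANS
    for analyte, means in target_means.items():
        if any(m <= 0 for m in means):
            raise ValueError(
                f"target means must be positive (analyte {analyte!r})"
            )
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    for cond_idx, cond in enumerate(CONDITIONS):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_{rep}"
            for analyte, means in target_means.items():
                noise = float(_lognoise(rng, config.peak_cv, 1)[0])
                area = config.ribitol_area * means[cond_idx] * noise
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": cond,
                        "replicate": rep,
                        "analyte": analyte,
                        "analyte_area": area,
                        "ribitol_area": config.ribitol_area,
                        "norvaline_area": config.ribitol_area,
                        "camphorsulfonic_area": config.ribitol_area / 8.0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator and write all pipeline inputs under ``outdir``.

    Writes FASTA proteomes, tab-separated probe/spot/peak/annotation
    tables and JSON truth tables; returns a manifest of paths.
    """
    from .ortholog_screen import write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    source, target, ortho_truth = simulate_genome_pair(config)
    write_fasta(source, out / "proteome_source.faa")
    write_fasta(target, out / "proteome_target.faa")
    ortho_truth.to_json(out / "truth_orthologs.json", orient="records", indent=2)

    probes, de_truth = simulate_probe_table(config)
    probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    de_truth.to_json(out / "truth_de.json", orient="records", indent=2)

    annotation = simulate_annotation(config)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)

    spots, spot_truth = simulate_spot_table(config)
    spots.to_csv(out / "spots.tsv", sep="\t", index=False)
    spot_truth.to_json(out / "truth_spots.json", orient="records", indent=2)

    peaks = simulate_peak_table(config)
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return {
        "proteome_source": str(out / "proteome_source.faa"),
        "proteome_target": str(out / "proteome_target.faa"),
        "probes": str(out / "probes.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "spots": str(out / "spots.tsv"),
        "peaks": str(out / "peaks.tsv"),
    }
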