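"""Reciprocal best-hit screen for osmolyte-related genes.

Seed proteins (the E. coli osmolyte panel: potassium uptake, glutamate
synthesis, glycine betaine synthesis/transport, proline synthesis/transport,
trehalose synthesis) are searched against each target proteome by local
Smith–Waterman alignment under affine gap penalties.  A gene is called
*present* in a target organism when the forward best hit, ranked by percent
identity among alignments passing the score and overlap thresholds, finds
the seed again as its own best hit in the source proteome.  The result is a
seed × organism presence/identity matrix, serializable as TSV and as an
identity-shaded SVG heatmap (blue intensity = identity, white = absent).

Alignment is protein-level only and delegates to Biopython's pairwise
aligner in local mode; gap penalties follow the convention that a gap of
length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Gene symbols of the classical osmolyte panel used as the default seed
#: set: potassium transport (kup, trkAHG, kdpABCDEF), glutamate synthesis
#: (glnA, gltBD, gdhA), glycine betaine synthesis (betABCI) and transport
#: (betS), glycine betaine/proline/carnitine transport (proP, proVWZ),
#: proline synthesis (proABC) and trehalose synthesis (ostAB).
OSMOLYTE_SEED_PANEL: tuple[str, ...] = (
    "kup",
    "trkA", "trkH", "trkG",
    "kdpA", "kdpB", "kdpC", "kdpD", "kdpE", "kdpF",
    "glnA", "gltB", "gltD", "gdhA",
    "betA", "betB", "betC", "betI", "betS",
    "proP", "proV", "proW", "proZ",
    "proA", "proB", "proC",
    "ostA", "ostB",
)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid record: locus tag, organism code, residues."""

    id: str
    organism: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty residues for {self.id}")


@dataclass
class ScreenConfig:
    """Alignment scoring and hit-acceptance thresholds.

    ``min_score`` and ``min_overlap`` are the screen's acceptance cutoffs
    (Smith–Waterman score >= 100, subject coverage >= 75% of the hit's
    length).  The substitution matrix and gap penalties are configurable;
    BLOSUM62 with gap open 11 / extend 1 are the standard defaults.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 100.0
    min_overlap: float = 0.75

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must be in (0, 1]")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix
        )
        # first gap residue costs open+extend, each further residue extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class AlignmentResult:
    """A scored local alignment between a query and a subject."""

    score: float
    identity: float  # identical columns / all columns incl. gap columns
    query_span: tuple[int, int]  # half-open residue interval
    subject_span: tuple[int, int]
    overlap_fraction: float  # subject-aligned length / subject full length


@dataclass
class PresenceCall:
    seed_id: str
    organism: str
    status: str  # "present" | "absent"
    identity: float | None = None

    def __post_init__(self) -> None:
        if (self.status == "present") != (self.identity is not None):
            raise ValueError("identity populated iff status is present")


def _validate_alphabet(seq: ProteinSequence, alphabet: str) -> None:
    bad = set(seq.residues) - set(alphabet)
    if bad:
        raise ValueError(
            f"{seq.id}: residues {sorted(bad)} outside matrix alphabet"
        )


def smith_waterman(
    a: ProteinSequence, b: ProteinSequence, cfg: ScreenConfig | None = None
) -> AlignmentResult:
    """Optimal local alignment of ``a`` (query) vs ``b`` (subject).

    Returns the Smith–Waterman score under affine gaps together with the
    identity (identical columns over all alignment columns, gap columns
    included) and the residue spans of the traceback.  A pair with no
    positive-scoring alignment scores 0 with empty spans.
    """
    cfg = cfg or ScreenConfig()
    aligner = cfg.aligner()
    alphabet = str(aligner.substitution_matrix.alphabet)
    _validate_alphabet(a, alphabet)
    _validate_alphabet(b, alphabet)

    score = aligner.score(a.residues, b.residues)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0), 0.0)

    aln = aligner.align(a.residues, b.residues)[0]
    qa, sa = aln[0], aln[1]  # aligned strings with gaps
    n_cols = len(qa)
    n_ident = sum(x == y and x != "-" for x, y in zip(qa, sa))
    (qstart, qend) = (
        int(aln.aligned[0][0][0]),
        int(aln.aligned[0][-1][1]),
    )
    (sstart, send) = (
        int(aln.aligned[1][0][0]),
        int(aln.aligned[1][-1][1]),
    )
    return AlignmentResult(
        score=float(score),
        identity=n_ident / n_cols,
        query_span=(qstart, qend),
        subject_span=(sstart, send),
        overlap_fraction=(send - sstart) / len(b.residues),
    )


def best_hit(
    query: ProteinSequence,
    proteome: list[ProteinSequence],
    cfg: ScreenConfig | None = None,
) -> tuple[str, AlignmentResult] | None:
    """Best hit of ``query`` in ``proteome``, ranked by percent identity.

    Only subjects whose alignment passes both ``min_score`` and
    ``min_overlap`` are candidates.  Ties on identity are broken by higher
    score, then lexicographically smallest subject id, so the result is
    deterministic.  Returns ``None`` when no subject qualifies.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    cfg = cfg or ScreenConfig()
    aligner = cfg.aligner()
    best: tuple[float, float, str, AlignmentResult] | None = None
    for subject in sorted(proteome, key=lambda s: s.id):
        # cheap score-only pass first; traceback only for passing subjects
        if aligner.score(query.residues, subject.residues) < cfg.min_score:
            continue
        result = smith_waterman(query, subject, cfg)
        if result.score < cfg.min_score:
            continue
        if result.overlap_fraction < cfg.min_overlap:
            continue
        key = (result.identity, result.score)
        if best is None or key > (best[0], best[1]):
            best = (result.identity, result.score, subject.id, result)
    if best is None:
        return None
    return best[2], best[3]


def reciprocal_best_hit(
    seed: ProteinSequence,
    source_proteome: list[ProteinSequence],
    target_proteome: list[ProteinSequence],
    cfg: ScreenConfig | None = None,
) -> PresenceCall:
    """Reciprocal best-hit presence call for one seed gene.

    Present iff the forward best hit ``t`` in the target proteome exists
    and the back-search from ``t`` returns the seed itself (exact id
    match); a paralog capturing the back-search yields absent.  Identity is
    reported from the forward alignment.
    """
    cfg = cfg or ScreenConfig()
    if all(s.id != seed.id for s in source_proteome):
        raise ValueError(f"seed {seed.id} not in source proteome")
    forward = best_hit(seed, target_proteome, cfg)
    if forward is None:
        return PresenceCall(seed.id, _org(target_proteome), "absent")
    subject_id, fwd_aln = forward
    subject = next(s for s in target_proteome if s.id == subject_id)
    back = best_hit(subject, source_proteome, cfg)
    if back is None or back[0] != seed.id:
        return PresenceCall(seed.id, _org(target_proteome), "absent")
    return PresenceCall(
        seed.id, _org(target_proteome), "present", identity=fwd_aln.identity
    )


def _org(proteome: list[ProteinSequence]) -> str:
    return proteome[0].organism if proteome else ""


@dataclass
class PresenceMatrix:
    """Complete seed × organism grid of presence/identity calls."""

    seeds: list[str]
    organisms: list[str]
    calls: dict[tuple[str, str], PresenceCall]

    def to_frame(self) -> pd.DataFrame:
        """Identity values with NaN for absent, seeds as rows."""
        data = {
            org: [
                self.calls[(s, org)].identity
                if self.calls[(s, org)].status == "present"
                else float("nan")
                for s in self.seeds
            ]
            for org in self.organisms
        }
        return pd.DataFrame(data, index=pd.Index(self.seeds, name="seed_id"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    def to_svg(self, path: str | Path, cell: int = 28) -> None:
        """Identity-shaded heatmap: blue intensity = identity, white = absent."""
        frame = self.to_frame()
        label_w, label_h = 120, 70
        width = label_w + cell * len(self.organisms)
        height = label_h + cell * len(self.seeds)
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{width}" height="{height}">'
        ]
        for j, org in enumerate(self.organisms):
            parts.append(
                f'<text x="{label_w + j * cell + cell / 2:.1f}" y="{label_h - 6}" '
                f'text-anchor="middle" font-size="10">{org}</text>'
            )
        for i, seed in enumerate(self.seeds):
            y = label_h + i * cell
            parts.append(
                f'<text x="{label_w - 6}" y="{y + cell / 2 + 3:.1f}" '
                f'text-anchor="end" font-size="10">{seed}</text>'
            )
            for j, org in enumerate(self.organisms):
                ident = frame.iloc[i, j]
                if ident != ident:  # NaN -> absent -> white box
                    fill = "#ffffff"
                else:
                    # white (identity 0) to saturated blue (identity 1)
                    chan = int(round(255 * (1 - ident)))
                    fill = f"#{chan:02x}{chan:02x}ff"
                parts.append(
                    f'<rect class="call" x="{label_w + j * cell}" y="{y}" '
                    f'width="{cell}" height="{cell}" fill="{fill}" '
                    f'stroke="#333333"/>'
                )
        parts.append("</svg>")
        Path(path).write_text("\n".join(parts))


def build_presence_matrix(
    seeds: list[ProteinSequence],
    organisms: dict[str, list[ProteinSequence]],
    source_proteome: list[ProteinSequence],
    cfg: ScreenConfig | None = None,
) -> PresenceMatrix:
    """Run the reciprocal search for every (seed, organism) pair.

    ``source_proteome`` is the seed organism's full protein complement,
    used for the back-search.  Every cell of the matrix is filled.
    """
    if not seeds:
        raise ValueError("seed panel must be non-empty")
    for org, proteome in organisms.items():
        if not proteome:
            raise ValueError(f"organism {org!r} has an empty proteome")
    cfg = cfg or ScreenConfig()
    calls: dict[tuple[str, str], PresenceCall] = {}
    for seed in seeds:
        for org, proteome in organisms.items():
            call = reciprocal_best_hit(seed, source_proteome, proteome, cfg)
            calls[(seed.id, org)] = PresenceCall(
                call.seed_id, org, call.status, call.identity
            )
    return PresenceMatrix(
        seeds=[s.id for s in seeds],
        organisms=list(organisms),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# FASTA / seed-panel I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, organism: str) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, organism, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteome: list[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.id, description=p.organism)
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_seed_panel(path: str | Path) -> pd.DataFrame:
    """Seed panel TSV with columns seed_id, organism, gene_symbol."""
    panel = pd.read_csv(path, sep="\t")
    required = {"seed_id", "organism", "gene_symbol"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"seed panel missing columns {sorted(missing)}")
    return panel
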