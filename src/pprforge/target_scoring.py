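"""PPR-code scoring of RNA windows and genome scans for C-to-U editing sites.

A designed array is scored against an RNA window by summing, motif by
motif, the score its (fifth, last) residue pair assigns to the aligned
base.  Scanning a genome emits one candidate per cytidine (both strands)
whose upstream bound window is fully inside the sequence, using the
editing-factor geometry: for an n-motif array the designable S motifs
occupy positions -(n+6)..-7 relative to the edited C at 0, positions
-6..-2 face the C-terminal P2-L2-S2-E1-E2 motifs (unscored by default)
and position -1 is unbound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .motif_design import PPRArraySpec, PPR_CODE, normalize_rna

__all__ = [
    "ScoringTable",
    "ScoreResult",
    "CandidateSite",
    "unit_table",
    "load_scoring_table",
    "score_window",
    "scan_for_edit_sites",
    "read_fasta_sequences",
    "candidates_to_frame",
    "minus_to_plus_coordinate",
]

BASES = ("A", "C", "G", "U")

#: Gap between the last designable S motif and the edited C: five bases
#: facing P2-L2-S2-E1-E2 plus one unbound base adjacent to the edit site.
DEFAULT_SPACER = 6


@dataclass
class ScoringTable:
    """Per-base affinity scores keyed by (fifth, last) residue pair."""

    scores: dict[tuple[str, str], dict[str, float]]
    name: str = ""

    def __post_init__(self) -> None:
        for key, row in self.scores.items():
            missing = set(BASES) - set(row)
            if missing:
                raise ValueError(f"table row {key} missing bases {sorted(missing)}")
            for b in BASES:
                if not math.isfinite(row[b]):
                    raise ValueError(f"non-finite score at {key}/{b}")

    def get(self, pair: tuple[str, str]) -> dict[str, float] | None:
        return self.scores.get(tuple(pair))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [
                {"fifth": f, "last": l, **{b: row[b] for b in BASES}}
                for (f, l), row in sorted(self.scores.items())
            ]
        )
        df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.scores)


def load_scoring_table(path, name: str | None = None) -> ScoringTable:
    """Read a scoring table TSV with header ``fifth last A C G U``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["fifth", "last", *BASES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"scoring table missing columns {missing}")
    for b in BASES:
        if not pd.api.types.is_numeric_dtype(df[b]):
            raise ValueError(f"non-numeric scores in column {b}")
    keys = list(zip(df["fifth"], df["last"]))
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ValueError(f"duplicate (fifth,last) rows: {sorted(dupes)}")
    scores = {
        (r.fifth, r.last): {b: float(getattr(r, b)) for b in BASES}
        for r in df.itertuples()
    }
    return ScoringTable(scores, name=name or str(path))


def unit_table() -> ScoringTable:
    """The canonical unit table: cognate base scores 1, all others 0."""
    scores = {
        pair: {b: 1.0 if b == base else 0.0 for b in BASES}
        for base, pair in PPR_CODE.items()
    }
    return ScoringTable(scores, name="unit")


@dataclass
class ScoreResult:
    raw_score: float
    mean_score: float
    misses: int  # motifs whose residue pair is absent from the table


def score_window(array: PPRArraySpec, window: str, table: ScoringTable) -> ScoreResult:
    """Sum per-motif scores over an RNA window of length n_motifs.

    Residue pairs absent from the table contribute 0 and are tallied in
    ``misses`` so partial (e.g. canonical-only) tables stay usable.
    """
    w = normalize_rna(window)
    if len(w) != array.n_motifs:
        raise ValueError(
            f"window length {len(w)} != number of motifs {array.n_motifs}"
        )
    raw = 0.0
    misses = 0
    for motif, base in zip(array.motifs, w):
        row = table.get((motif.fifth, motif.last))
        if row is None:
            misses += 1
            continue
        raw += row[base]
    return ScoreResult(raw_score=raw, mean_score=raw / array.n_motifs, misses=misses)


@dataclass(frozen=True)
class CandidateSite:
    """A cytidine with its predicted upstream binding window and score.

    ``edited_c_position`` is 0-based on the reported strand's own
    coordinate system (use :func:`minus_to_plus_coordinate` to convert).
    """

    sequence_id: str
    edited_c_position: int
    strand: str
    bound_window: str
    raw_score: float
    mean_score: float


def minus_to_plus_coordinate(pos: int, seq_length: int) -> int:
    """Convert a minus-strand-local 0-based position to the plus strand."""
    return seq_length - 1 - pos


def read_fasta_sequences(path) -> dict[str, str]:
    """Read DNA/RNA FASTA into {id: uppercase DNA string} (U -> T)."""
    seqs = {
        r.id: str(r.seq).upper().replace("U", "T")
        for r in SeqIO.parse(str(path), "fasta")
    }
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def _scan_one_strand(array, seq_rna, seq_id, strand, table, spacer, out):
    n = array.n_motifs
    offset = n + spacer  # window start = c - offset
    for c_pos in range(offset, len(seq_rna)):
        if seq_rna[c_pos] != "C":
            continue
        window = seq_rna[c_pos - offset : c_pos - spacer]
        res = score_window(array, window, table)
        out.append(
            CandidateSite(
                sequence_id=seq_id,
                edited_c_position=c_pos,
                strand=strand,
                bound_window=window,
                raw_score=res.raw_score,
                mean_score=res.mean_score,
            )
        )


def scan_for_edit_sites(
    array: PPRArraySpec,
    sequences: Mapping[str, str],
    table: ScoringTable | None = None,
    spacer: int = DEFAULT_SPACER,
    min_score: float | None = None,
) -> list[CandidateSite]:
    """Scan sequences (both strands) for candidate C-to-U editing sites.

    Every C with a full upstream window is emitted, sorted by raw score
    descending with ties broken by (sequence_id, position, strand).
    ``min_score`` optionally filters the returned list.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    if table is None:
        table = unit_table()
    out: list[CandidateSite] = []
    for seq_id, dna in sequences.items():
        plus = dna.upper().replace("U", "T").replace("T", "U")
        minus = str(Seq(dna.upper().replace("U", "T")).reverse_complement()).replace(
            "T", "U"
        )
        _scan_one_strand(array, plus, seq_id, "+", table, spacer, out)
        _scan_one_strand(array, minus, seq_id, "-", table, spacer, out)
    out.sort(
        key=lambda s: (-s.raw_score, s.sequence_id, s.edited_c_position, s.strand)
    )
    if min_score is not None:
        out = [s for s in out if s.raw_score >= min_score]
    return out


def candidates_to_frame(candidates: Iterable[CandidateSite]) -> pd.DataFrame:
    """Tabulate candidate sites (columns match the candidate TSV contract)."""
    return pd.DataFrame(
        [
            {
                "seq_id": c.sequence_id,
                "pos0": c.edited_c_position,
                "strand": c.strand,
                "window": c.bound_window,
                "raw_score": c.raw_score,
                "mean_score": c.mean_score,
            }
            for c in candidates
        ],
        columns=["seq_id", "pos0", "strand", "window", "raw_score", "mean_score"],
    )
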