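"""Consensus building, PPR-code array design and degenerate-codon libraries.

PPR (pentatricopeptide repeat) proteins bind single-stranded RNA one base
per ~31-36 aa helix-turn-helix motif.  Two residues per motif — the fifth
and the last — determine the bound base via the "PPR code":

    N/D -> U,  N/S -> C,  T/D -> G,  T/N -> A

This module builds consensus backbones from motif alignments, designs
S-type PPR arrays against an RNA target by splicing code residues into
those backbones, and enumerates the residue-pair content of partially
degenerate codon libraries of the NDT/VMA/ATG/TGG kind used to randomise
a single motif during a binding screen.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "PPR_CODE",
    "DEFAULT_LIBRARY_CODONS",
    "MotifAlignment",
    "Motif",
    "PPRArraySpec",
    "CodonLibraryDesign",
    "build_consensus",
    "design_array",
    "target_from_pairs",
    "normalize_rna",
    "load_backbones",
    "splice_protein_sequence",
    "expand_degenerate_codon",
    "enumerate_library",
    "library_sampling_stats",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: The canonical PPR code: target base -> (fifth residue, last residue).
PPR_CODE: dict[str, tuple[str, str]] = {
    "U": ("N", "D"),
    "C": ("N", "S"),
    "G": ("T", "D"),
    "A": ("T", "N"),
}

#: Degenerate codon sets and mixing weights used to randomise one codon
#: position while covering all 20 residues with near-uniform frequency.
DEFAULT_LIBRARY_CODONS: list[tuple[str, float]] = [
    ("NDT", 12.0),
    ("VMA", 6.0),
    ("ATG", 1.0),
    ("TGG", 1.0),
]


def normalize_rna(seq: str) -> str:
    """Uppercase an RNA/DNA string and convert T to U.

    Raises ``ValueError`` on any letter outside {A, C, G, U, T}; IUPAC
    ambiguity codes are deliberately rejected for design targets.
    """
    out = seq.upper().replace("T", "U")
    bad = set(out) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return out


@dataclass
class MotifAlignment:
    """A gapped alignment of same-length PPR motif sequences."""

    sequences: list[str]
    motif_class: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        width = len(self.sequences[0])
        if width == 0:
            raise ValueError("alignment has zero columns")
        for i, s in enumerate(self.sequences):
            if len(s) != width:
                raise ValueError(
                    f"ragged alignment: record {i} has length {len(s)}, expected {width}"
                )
            bad = set(s.upper()) - AMINO_ACIDS - {GAP}
            if bad:
                raise ValueError(f"record {i} contains invalid letters: {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, motif_class: str = "") -> "MotifAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([str(r.seq) for r in records], motif_class=motif_class)


def build_consensus(alignment: MotifAlignment, plurality: float = 0.0) -> str:
    """Column-wise plurality consensus of a gapped motif alignment.

    At each column the most frequent non-gap residue wins, provided its
    count reaches ``plurality``; ties break to the alphabetically first
    residue.  Columns where no residue qualifies (all gaps, or the top
    count is below the plurality threshold) are dropped from the output.
    """
    if plurality < 0:
        raise ValueError("plurality must be non-negative")
    out = []
    for col in range(alignment.width):
        counts = Counter(
            s[col] for s in alignment.sequences if s[col] != GAP
        )
        if not counts:
            continue
        # deterministic tie-break: highest count, then alphabetical
        top = max(counts.values())
        best = min(r for r in counts if counts[r] == top)
        if counts[best] >= plurality:
            out.append(best)
    return "".join(out)


@dataclass(frozen=True)
class Motif:
    """One designed S-type motif: positional variant plus code residues."""

    variant_class: str
    fifth: str
    last: str


@dataclass
class PPRArraySpec:
    """A designed PPR array: ordered motifs against a 5'->3' RNA target.

    Motif order is N- to C-terminal and matches the target 5'->3', one
    motif per base.
    """

    motifs: list[Motif]
    scaffold_name: str
    target_rna: str

    def __post_init__(self) -> None:
        if len(self.motifs) != len(self.target_rna):
            raise ValueError("number of motifs must equal target length")

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(m.fifth, m.last) for m in self.motifs]


_SCHEMES = ("dsnS_abcd", "dsnSc_uniform")


def _variant_classes(n: int, scaffold: str) -> list[str]:
    if scaffold == "dsnSc_uniform":
        return ["dsnSc"] * n
    if scaffold != "dsnS_abcd":
        raise ValueError(f"unknown scaffold scheme {scaffold!r}; choose from {_SCHEMES}")
    classes = []
    for i in range(n):
        if i == 0:
            classes.append("dsnSa")
        elif i == 1 and n > 2:
            classes.append("dsnSb")
        elif i == n - 1:
            classes.append("dsnSd")
        else:
            classes.append("dsnSc")
    return classes


def design_array(
    target_rna: str,
    scaffold: str = "dsnS_abcd",
    code: Mapping[str, tuple[str, str]] = PPR_CODE,
) -> PPRArraySpec:
    """Design an S-type PPR array against an RNA target via the PPR code.

    Motif i carries the (fifth, last) residue pair coding for target base
    i; positional variant classes follow the scaffold scheme (first motif
    dsnSa, second dsnSb, internal dsnSc, last dsnSd — or all dsnSc).
    """
    target = normalize_rna(target_rna)
    if not target:
        raise ValueError("empty RNA target")
    missing = set("ACGU") - set(code)
    if missing:
        raise ValueError(f"code does not cover bases {sorted(missing)}")
    classes = _variant_classes(len(target), scaffold)
    motifs = [
        Motif(cls, *code[base]) for cls, base in zip(classes, target)
    ]
    return PPRArraySpec(motifs=motifs, scaffold_name=scaffold, target_rna=target)


def target_from_pairs(
    pairs: Iterable[tuple[str, str]],
    code: Mapping[str, tuple[str, str]] = PPR_CODE,
) -> str:
    """Reverse-lookup an RNA target from (fifth, last) pairs (round trip)."""
    inverse = {v: k for k, v in code.items()}
    out = []
    for pair in pairs:
        pair = tuple(pair)
        if pair not in inverse:
            raise KeyError(f"residue pair {pair} not in code")
        out.append(inverse[pair])
    return "".join(out)


def load_backbones(path=None) -> dict[str, str]:
    """Load consensus motif backbones from FASTA (bundled synthetic set by default).

    The bundled file carries synthetic stand-in backbones with the
    correct motif lengths; real consensus sequences can be dropped in by
    pointing ``path`` at an edited FASTA.
    """
    if path is None:
        ref = resources.files("pprforge.data") / "backbones_synthetic.fasta"
        with resources.as_file(ref) as p:
            records = list(SeqIO.parse(str(p), "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return {r.id: str(r.seq).upper() for r in records}


def splice_protein_sequence(
    array: PPRArraySpec,
    backbones: Mapping[str, str] | None = None,
    c_terminal_modules: Sequence[str] = (),
) -> str:
    """Splice code residues into variant backbones to get the full array sequence.

    The fifth residue replaces backbone position 5 and the last residue
    the final backbone position (1-based within each motif).  Optional
    C-terminal modules (e.g. P2, L2, S2, E1, E2, DYW) are appended
    unmodified.
    """
    if backbones is None:
        backbones = load_backbones()
    parts = []
    for m in array.motifs:
        try:
            bb = backbones[m.variant_class]
        except KeyError:
            raise KeyError(f"no backbone for variant class {m.variant_class!r}")
        if len(bb) < 5:
            raise ValueError(f"backbone {m.variant_class} shorter than 5 residues")
        spliced = bb[:4] + m.fifth + bb[5:-1] + m.last
        parts.append(spliced)
    for name in c_terminal_modules:
        parts.append(backbones[name])
    return "".join(parts)


@dataclass
class CodonLibraryDesign:
    """Degenerate-codon sets (with mixing weights) used at both randomised
    codon positions (fifth and last) of the variable motif."""

    position_codon_sets: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_LIBRARY_CODONS)
    )
    n_positions: int = 2

    def __post_init__(self) -> None:
        for codon, weight in self.position_codon_sets:
            if weight <= 0:
                raise ValueError(f"non-positive weight for codon set {codon}")
            if len(codon) != 3:
                raise ValueError(f"degenerate codon {codon!r} is not a triplet")


def expand_degenerate_codon(codon: str) -> list[str]:
    """Expand an IUPAC degenerate codon to all concrete DNA codons."""
    options = []
    for letter in codon.upper():
        try:
            options.append(ambiguous_dna_values[letter])
        except KeyError:
            raise ValueError(f"invalid IUPAC nucleotide code {letter!r} in {codon!r}")
    return [a + b + c for a in options[0] for b in options[1] for c in options[2]]


def _residue_probs(codon_sets: list[tuple[str, float]]) -> dict[str, float]:
    total_weight = sum(w for _, w in codon_sets)
    probs: dict[str, float] = {}
    for codon, weight in codon_sets:
        concrete = expand_degenerate_codon(codon)
        for c in concrete:
            aa = str(Seq(c).translate())
            if aa == "*":
                raise ValueError(f"degenerate codon {codon} expands to stop codon {c}")
            probs[aa] = probs.get(aa, 0.0) + (weight / total_weight) / len(concrete)
    return probs


def enumerate_library(design: CodonLibraryDesign | None = None):
    """Enumerate (fifth, last) residue pairs and their expected frequencies.

    Per-position residue probability sums each codon set's weight share
    uniformly over its concrete codons; pair frequency is the product
    across the two positions.  Returns a DataFrame with columns
    ``fifth``, ``last``, ``frequency`` summing to 1.
    """
    import pandas as pd

    if design is None:
        design = CodonLibraryDesign()
    probs = _residue_probs(design.position_codon_sets)
    rows = [
        {"fifth": f, "last": l, "frequency": pf * pl}
        for f, pf in sorted(probs.items())
        for l, pl in sorted(probs.items())
    ]
    return pd.DataFrame(rows)


def library_sampling_stats(n_clones: int, n_pairs: int) -> tuple[float, float]:
    """Sampling ratio and expected distinct pairs for uniform clone picking.

    ``expected_distinct = n_pairs * (1 - (1 - 1/n_pairs)**n_clones)`` —
    the mean coverage of a uniform occupancy process.
    """
    if n_clones < 1 or n_pairs < 1:
        raise ValueError("n_clones and n_pairs must be >= 1")
    ratio = n_clones / n_pairs
    expected = n_pairs * (1.0 - (1.0 - 1.0 / n_pairs) ** n_clones)
    return ratio, expected
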