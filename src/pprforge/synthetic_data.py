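"""Synthetic inputs with the statistical structure the pipeline assumes.

Every wet-lab input the analysis consumes can be generated here: a random
genome with planted editing-target contexts, per-site strand-specific
nucleotide counts with binomial editing at programmed fractions,
saturation binding curves from known Kd values, and clone draws from a
degenerate-codon library.  All generators are driven by a single integer
seed through an explicit numpy Generator and are byte-deterministic; the
seed is echoed into every output file header.

The planted editing context mirrors the editing-factor geometry: a 9-nt
bound region (the designable S motifs), then CAAAA (facing the
P2-L2-S2-E1-E2 motifs), one unbound nucleotide, then the edited C — 16 nt
in total, e.g. TTACACGTGCAAAATC for the rpoA-derived target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .binding_quant import CONCENTRATION_SERIES_NM, fraction_bound
from .motif_design import CodonLibraryDesign, PPRArraySpec, enumerate_library

__all__ = [
    "TUFB_LIKE_MISMATCHES",
    "PlantedSite",
    "SimTruth",
    "make_genome",
    "simulate_counts",
    "simulate_binding",
    "simulate_clones",
    "write_genome_fasta",
    "write_truth_tsv",
]

DNA = np.array(list("ACGT"))

#: The off-target-like mismatch pattern: two purine swaps (A->G, G->A)
#: and one purine/pyrimidine swap (C->A) within the 9-nt bound window.
TUFB_LIKE_MISMATCHES = {2: "G", 3: "A", 8: "A"}

SPACER = "CAAAA"  # bases facing the C-terminal P2-L2-S2-E1-E2 motifs


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    pos0: int  # 0-based position of the edited C, plus strand
    strand: str
    fraction_treat: float
    fraction_ctrl: float


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    genome: dict[str, str]
    planted: list[PlantedSite]
    background_error: float
    mean_depth: float
    seed: int


def _context_dna(array: PPRArraySpec, mismatches: dict[int, str] | None) -> str:
    window = array.target_rna.replace("U", "T")
    if mismatches:
        chars = list(window)
        for pos, base in mismatches.items():
            if not 0 <= pos < len(chars):
                raise ValueError(f"mismatch position {pos} outside the bound window")
            chars[pos] = base.upper().replace("U", "T")
        window = "".join(chars)
    return window


def make_genome(
    length: int,
    n_planted: int,
    array: PPRArraySpec,
    seed: int,
    mismatch_spec: dict[int, str] | None = None,
    fraction_treat: float = 0.5,
    fraction_ctrl: float = 0.0,
    background_error: float = 0.001,
    mean_depth: float = 5000.0,
    unbound_base: str = "T",
    seq_id: str = "sim_genome",
) -> SimTruth:
    """Random genome with planted 16-nt editing contexts and a truth table.

    The background is i.i.d. uniform DNA.  Planted contexts are the bound
    window (with the requested mismatches applied), then CAAAA, one
    unbound base and the edited C.  The draw is rejected and retried if
    the exact cognate bound window occurs anywhere else on either strand
    — a chance second perfect-score site would make planted-site ranking
    ambiguous.
    """
    context = _context_dna(array, mismatch_spec) + SPACER + unbound_base + "C"
    clen = len(context)
    if length < n_planted * clen * 10:
        raise ValueError(
            f"genome length {length} too short to plant {n_planted} contexts sparsely"
        )
    cognate = array.target_rna.replace("U", "T")
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        genome = rng.choice(DNA, size=length)
        # non-overlapping plant positions on a coarse grid
        slot = length // n_planted
        starts = []
        for i in range(n_planted):
            lo = i * slot
            hi = min((i + 1) * slot, length) - clen
            if hi <= lo:
                raise ValueError("infeasible planting density")
            starts.append(int(rng.integers(lo, hi)))
        for s in starts:
            genome[s : s + clen] = list(context)
        text = "".join(genome)
        rc = str(Seq(text).reverse_complement())
        hits = _count_occurrences(text, cognate) + _count_occurrences(rc, cognate)
        planted_hits = sum(
            1 for s in starts if text[s : s + len(cognate)] == cognate
        )
        if hits == planted_hits:
            planted = [
                PlantedSite(seq_id, s + clen - 1, "+", fraction_treat, fraction_ctrl)
                for s in starts
            ]
            return SimTruth(
                genome={seq_id: text},
                planted=planted,
                background_error=background_error,
                mean_depth=mean_depth,
                seed=seed,
            )
    raise RuntimeError("could not place contexts without accidental cognate windows")


def _count_occurrences(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def simulate_counts(
    truth: SimTruth,
    condition: str,
    seed: int | None = None,
    include_non_c: bool = False,
) -> pd.DataFrame:
    """Strand-specific per-site nucleotide counts for one condition.

    At every reference-C site (both strands) the edited-read count is
    Binomial(depth, f) with f the planted fraction (at planted sites, in
    their condition) or the background error rate; per-site depth is
    Poisson(mean depth) floored at 1.  Remaining reads carry the
    reference base apart from rare A/G errors at the same background
    rate.  ``condition`` is "treat" or "ctrl".
    """
    if condition not in ("treat", "ctrl"):
        raise ValueError("condition must be 'treat' or 'ctrl'")
    # distinct default streams per condition, both derived from the truth seed
    if seed is None:
        rng = np.random.default_rng([truth.seed, 0 if condition == "treat" else 1])
    else:
        rng = np.random.default_rng(seed)
    planted = {
        (p.seq_id, p.pos0, p.strand): (
            p.fraction_treat if condition == "treat" else p.fraction_ctrl
        )
        for p in truth.planted
    }
    err = truth.background_error
    rows = []
    for seq_id, dna in truth.genome.items():
        rc = str(Seq(dna).reverse_complement())
        L = len(dna)
        for strand, text in (("+", dna), ("-", rc)):
            for i, ref in enumerate(text):
                pos = i if strand == "+" else L - 1 - i
                if ref != "C" and not include_non_c:
                    continue
                depth = max(1, int(rng.poisson(truth.mean_depth)))
                counts = {b: 0 for b in "ACGT"}
                if ref == "C":
                    f = planted.get((seq_id, pos, strand), err)
                    edited = int(rng.binomial(depth, f))
                    rest = depth - edited
                    misc = int(rng.binomial(rest, err)) if rest else 0
                    counts["T"] = edited
                    counts["A"] = int(rng.binomial(misc, 0.5)) if misc else 0
                    counts["G"] = misc - counts["A"]
                    counts["C"] = rest - misc
                else:
                    misc = int(rng.binomial(depth, err))
                    others = [b for b in "ACGT" if b != ref]
                    alloc = rng.multinomial(misc, [1 / 3] * 3) if misc else [0, 0, 0]
                    for b, k in zip(others, alloc):
                        counts[b] = int(k)
                    counts[ref] = depth - misc
                rows.append(
                    {
                        "seq_id": seq_id,
                        "pos0": pos,
                        "strand": strand,
                        "ref": ref,
                        "nA": counts["A"],
                        "nC": counts["C"],
                        "nG": counts["G"],
                        "nT": counts["T"],
                    }
                )
    return pd.DataFrame(rows, columns=["seq_id", "pos0", "strand", "ref",
                                       "nA", "nC", "nG", "nT"])


def simulate_binding(
    kd: float,
    probe_nM: float = 2.0,
    concentrations=CONCENTRATION_SERIES_NM,
    noise_sd_frac: float = 0.0,
    replicates: int = 1,
    smax: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy saturation-binding curves from a known Kd.

    signal = smax * fraction_bound(P, L, kd) * (1 + eps),
    eps ~ Normal(0, noise_sd_frac).  Default grid is the standard
    12-point dilution series.  Returns the curve-TSV layout
    (protein_nM, signal, replicate, probe_nM).
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if noise_sd_frac < 0:
        raise ValueError("noise fraction must be non-negative")
    rng = np.random.default_rng(seed)
    P = np.asarray(concentrations, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        clean = smax * fraction_bound(P, probe_nM, kd)
        noise = rng.normal(0.0, noise_sd_frac, size=P.shape) if noise_sd_frac else 0.0
        signal = clean * (1.0 + noise)
        for p, s in zip(P, signal):
            rows.append(
                {"protein_nM": p, "signal": float(s), "replicate": rep,
                 "probe_nM": probe_nM}
            )
    return pd.DataFrame(rows)


def simulate_clones(
    n_clones: int,
    design: CodonLibraryDesign | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """I.i.d. clone draws of (fifth, last) pairs from the library frequencies."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    lib = enumerate_library(design)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), size=n_clones, p=lib["frequency"].to_numpy())
    return [(lib["fifth"].iat[i], lib["last"].iat[i]) for i in idx]


def write_genome_fasta(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in truth.genome.items():
            fh.write(f">{seq_id} seed={truth.seed}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed} background_error={truth.background_error} "
                 f"mean_depth={truth.mean_depth}\n")
        fh.write("seq_id\tpos0\tstrand\tfraction_treat\tfraction_ctrl\n")
        for p in truth.planted:
            fh.write(
                f"{p.seq_id}\t{p.pos0}\t{p.strand}\t{p.fraction_treat}\t{p.fraction_ctrl}\n"
            )
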