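# Methods

`pprforge` implements the computational side of designing and validating
a synthetic S-type PPR (pentatricopeptide repeat) C-to-U RNA editing
factor: array design via the PPR code, binding-screen quantification,
genome scans for candidate editing sites, and editing-site detection
from strand-specific RNA-seq nucleotide counts. This note records the
models, the parameter choices and the places where the design was
genuinely open.

## The PPR code and array design

Each S-type motif (31 aa) recognises one RNA base through the residues
at its fifth and last positions. The canonical code used for design is
N/D → U, N/S → C, T/D → G, T/N → A. `design_array` maps a 5'→3' RNA
target, base by base, onto an N-to-C ordered motif list and assigns
positional variant classes: the first motif `dsnSa`, second `dsnSb`,
internal motifs `dsnSc`, last `dsnSd` (scheme `dsnS_abcd`), or uniformly
`dsnSc` (`dsnSc_uniform`). The full amino-acid sequence is produced by
splicing the fifth residue into backbone position 5 and the last residue
into the final backbone position of each motif's consensus backbone.

Backbones ship in `data/backbones_synthetic.fasta`. These are
**synthetic stand-ins** with the correct motif lengths (S motifs 31 aa;
P2 35, L2 36, S2 32) and typical PPR helix-turn-helix character; they
exercise the splicing logic but are not measured consensus sequences.
Real consensus backbones can be substituted by passing a FASTA path to
`load_backbones`.

### Consensus building

`build_consensus` is a plurality consensus: per column, the most
frequent non-gap residue wins if its count reaches the plurality
threshold (default 0). The tie-break is a repo convention chosen for
determinism: among equally frequent non-gap residues the alphabetically
first is taken; gaps never win a column; columns whose consensus would
be a gap (all-gap, or below plurality) are dropped. Other consensus
tools may resolve ties differently, so consensus sequences built here
can differ from published ones at tied columns.

### Degenerate-codon libraries

`enumerate_library` expands each degenerate codon set (IUPAC codes) to
concrete codons, translates with the standard genetic code, and computes
per-position residue probabilities as the weight-share of each set
spread uniformly over its codons; pair frequencies are products across
the two randomised positions. The default design — NDT, VMA, ATG, TGG
mixed 12:6:1:1 — encodes each of the 20 residues at exactly 1/20 per
position (NDT's 12 codons cover 12 distinct residues, VMA's 6 cover 6,
ATG and TGG add M and W), giving 400 equally likely pairs and no stops.
`library_sampling_stats` gives the expected number of distinct pairs
among n uniform clone draws, `n_pairs·(1 − (1 − 1/n_pairs)^n)`; for 644
clones over 400 pairs this is 320.2 with a sampling ratio of 1.61.

## Binding quantification

Screens run with the labelled RNA probe at a concentration (L, nM)
comparable to Kd, so the fraction of probe bound uses the quadratic
ligand-depletion isotherm

    f(P) = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·L)

rather than the hyperbolic approximation P/(P+Kd) (recovered in the
dilute-probe limit). The functional form is the standard reading of
"fitting taking the probe concentration into account"; alternative
depletion corrections exist but are not implemented.

`fit_kd` fits `signal = baseline + (smax − baseline)·f(P)` by bounded
nonlinear least squares (`scipy.optimize.least_squares`): Kd ∈ [1e-3,
1e5] nM, smax ∈ [0, 10·max signal], baseline ∈ [0, max signal];
initialisation baseline = min signal, smax = max signal, Kd = the
protein concentration nearest half-maximal signal. The optimizer is
deterministic. A fit is flagged `unreliable` when Kd lands within 1% of
a box bound or when the residual sum of squares exceeds half the total
signal variance (rss/TSS > 0.5 — the fraction-of-variance-unexplained
reading of the reliability rule); flat or all-zero curves short-circuit
to an unreliable estimate rather than failing silently.

Kd estimates above the assay's reliable ceiling are capped: 200 nM for
this screen's lysate assays, 900 nM when re-scaling external comparison
datasets. **Relative binding strength** is −log(Kd) min-max scaled to
[0, 1] *after* capping, over whichever dataset is being compared (one
specificity matrix, or a pooled set for cross-scaffold comparisons).
Log base 10 is used; since min-max scaling absorbs the base, the choice
is recorded only for reproducibility. All-equal Kd sets are degenerate
and return 0.5 everywhere with a warning.

`build_specificity_matrix` caps per-base Kds, scales strengths jointly
across every measured (variant, base) cell so rows are comparable, and
assigns each variant its preferred base (argmax strength); ties are
flagged `ambiguous`, single-measurement rows `low_evidence`.

## Target scoring and the scan geometry

`score_window` sums per-motif scores from a table keyed by (fifth, last)
pairs; pairs absent from the table contribute 0 and increment a miss
counter, so partial (canonical-only) tables remain usable. The bundled
default is the canonical unit table (cognate base 1, else 0);
empirically derived tables are user-supplied TSVs.

The scan geometry follows the editing-factor layout, checked against the
target context `UUACACGUGCAAAAUC`: with the edited C at position 0, the
n designable S motifs bind positions −(n+6)…−7, the five bases at
−6…−2 (CAAAA in the intended target) face the C-terminal
P2-L2-S2-E1-E2 motifs and are unscored by default, and position −1 is
unbound. `scan_for_edit_sites` emits every C on both strands with a
full upstream window, sorted by raw score descending (ties by sequence,
position, strand). Coordinates are 0-based and strand-local;
`minus_to_plus_coordinate` converts minus-strand positions. Which sites
constitute the testable universe (coverage, transcribed strand) is left
to the caller's filters.

## Editing-site statistics

Input is one strand-specific count table per sample (TSV: seq_id, pos0,
strand, ref, nA, nC, nG, nT). At each reference-C site, edited = T
count and unedited = C count on that strand; A/G reads reflect other
error modes and are excluded from the 2×2 table. Replicate cultures, if
any, are pooled into one table per condition upstream.

Each site is tested with a two-sided Fisher exact test
(`scipy.stats.fisher_exact`; one-sided configurable), adjusted across
**all** tested C sites with the Simes–Hochberg step-up procedure
(`statsmodels.stats.multitest.multipletests`), and summarised by an odds
ratio with a pseudocount of 0.5 added to all four cells, which keeps the
ratio finite and positive for any table. A site is called when adjusted
p < α (default 0.05) **and** the natural-log odds ratio exceeds the
threshold (default 2; base and threshold configurable). Candidate-scan
scores join the report by (seq_id, pos0, strand).

The test suite verifies the Fisher p against a full hypergeometric
enumeration oracle on every 2×2 table with margins ≤ 30 (tolerance
1e-12, tie handling by the standard relative-epsilon convention), and
the Hochberg adjustment against a hand-coded step-up recursion.

## Synthetic data: what it emulates, and what it does not

Generators are all driven by one integer seed through explicit numpy
`Generator` objects and are byte-deterministic; seeds are echoed into
output headers. Defaults mirror the study conditions: editing fraction
0.5 at the target in treatment, 0 in control; background C→T error
0.001; mean depth 5000; the 12-point titration series 0–800 nM with
probe at 2 nM; 644 clones over the 400-pair library.

`make_genome` plants 16-nt contexts — bound window (with optional
mismatches, e.g. the off-target-like two-purine-plus-one-A/C pattern)
+ CAAAA + one unbound base + the edited C — into i.i.d. uniform
background DNA. The draw is rejected if the exact cognate 9-mer occurs
anywhere else on either strand: a chance second perfect-score window
(~8% per 10 kb) would otherwise make planted-site ranking ambiguous.
`simulate_counts` draws per-site depth ~ Poisson(mean), floored at 1,
and edited reads ~ Binomial(depth, f); treatment and control use
distinct seed streams derived from the truth seed.

What passing on this data does **not** show: real transcriptomes have
non-uniform composition and expression (depth varies over orders of
magnitude), strand-bias and mapping artefacts, position-dependent error
profiles, and duplicated sequence (the paralog effect) — none of which
are modelled. Recovery of a 50% planted site here demonstrates the
statistical machinery, not performance on real RNA-seq.

## Pipeline and problem sizes

`RunConfig` (YAML, unknown keys rejected) drives
simulate → design → scan → call; every report carries the package
version, seed and a config hash (output paths excluded from the hash so
re-runs are byte-identical wherever they land). The default end-to-end
problem size — a 10-kb genome, one planted site, depth 5000 — keeps a
full run around five seconds while preserving every statistical feature
of the method; the transcriptome-scale analysis is the same code over a
larger site universe.

## Known limitations

- The canonical code covers four residue pairs; scoring with richer
  empirical tables requires a user-supplied TSV (none is bundled, since
  measured values are dataset-specific).
- The quadratic isotherm assumes one binding site and no cooperativity.
- No read-level simulation (FASTQ, quality, duplicates) and no
  alignment: the contract input is the per-site count table.
- L-motif-containing (PLS-type) arrays and A-to-I editing are out of
  scope.
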