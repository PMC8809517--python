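"""End to end: simulate an editing experiment and call edited sites.

A genome with one site edited at 50% in treatment (background error
0.1%) is sequenced to depth ~5000; every reference-C site is tested with
a Fisher exact test against control, adjusted with Simes-Hochberg, and a
site is called when adjusted p < 0.05 and the pseudocounted log odds
ratio exceeds 2.
"""

from pprforge import call_editing, design_array, scan_for_edit_sites
from pprforge.synthetic_data import make_genome, simulate_counts

array = design_array("UUACACGUG")
truth = make_genome(10_000, 1, array, seed=1, mean_depth=5000)
treat = simulate_counts(truth, "treat")
ctrl = simulate_counts(truth, "ctrl")

sites = scan_for_edit_sites(array, truth.genome)
scores = {(s.sequence_id, s.edited_c_position, s.strand): s.raw_score
          for s in sites}
report = call_editing(treat, ctrl, alpha=0.05, log_or_threshold=2.0,
                      scores=scores)

print(f"tested {len(report.tests)} C sites; {len(report.calls)} call(s):")
cols = ["pos0", "strand", "editing_percent_treat", "p_adjusted",
        "log_odds_ratio", "raw_score"]
print(report.calls[cols].to_string(index=False))
print(f"\nplanted site: pos {truth.planted[0].pos0} (+), edited at "
      f"{100 * truth.planted[0].fraction_treat:.0f}% in truth — the call "
      "matches it, its editing percent sits near 50 and its binding score "
      "9/9 marks it as the intended target rather than an off-target")
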