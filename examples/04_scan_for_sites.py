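"""Scan a genome for candidate C-to-U editing sites by predicted binding.

Every cytidine (both strands) with a full upstream window is scored: the
nine designable motifs bind positions -15..-7 relative to the edited C,
positions -6..-2 face the C-terminal P2-L2-S2-E1-E2 motifs and -1 is
unbound.  A perfect cognate window under the unit table scores 9/9.
"""

from pprforge import design_array, scan_for_edit_sites
from pprforge.synthetic_data import TUFB_LIKE_MISMATCHES, make_genome

array = design_array("UUACACGUG")

# a 10-kb random genome with one planted off-target-like context:
# two purine mismatches and one purine/pyrimidine mismatch in the window
truth = make_genome(10_000, 1, array, seed=4,
                    mismatch_spec=TUFB_LIKE_MISMATCHES)
sites = scan_for_edit_sites(array, truth.genome)

planted_pos = truth.planted[0].pos0
rank = next(i for i, s in enumerate(sites, 1)
            if (s.edited_c_position, s.strand) == (planted_pos, "+"))

print(f"scanned {len(sites)} candidate C sites; top five by raw score:")
for s in sites[:5]:
    print(f"  pos {s.edited_c_position:>6} {s.strand}  window {s.bound_window}"
          f"  score {s.raw_score:.0f}/9")
print(f"\nplanted 3-mismatch context: pos {planted_pos}, score 6/9, "
      f"rank {rank} of {len(sites)}")
print("predicted binding alone cannot separate a real off-target from the "
      "best chance matches in random sequence — which is why candidate "
      "sites are combined with editing statistics (example 05)")
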