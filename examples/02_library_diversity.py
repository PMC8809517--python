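"""Enumerate the degenerate-codon randomisation library and its sampling.

One motif's fifth and last codons are randomised with a 12:6:1:1 mix of
NDT, VMA, ATG and TGG primers.  That mix encodes each of the 20 amino
acids with probability exactly 1/20 per position, i.e. 400 equally
likely residue pairs with no stop codons.
"""

from pprforge import enumerate_library, library_sampling_stats
from pprforge.synthetic_data import simulate_clones

lib = enumerate_library()
print(f"residue pairs: {len(lib)}; "
      f"per-pair frequency: {lib['frequency'].iloc[0]:.6f} (uniform 1/400)")

n_clones = 644
ratio, expected = library_sampling_stats(n_clones, len(lib))
print(f"sequencing {n_clones} clones = {ratio:.2f}x the library diversity;"
      f" expected distinct pairs {expected:.1f}")

pairs = simulate_clones(n_clones, seed=1)
print(f"one simulated screen of {n_clones} clones observed "
      f"{len(set(pairs))} distinct pairs "
      "(a real screen can observe fewer: cloning biases are not modelled)")
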