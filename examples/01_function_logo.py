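"""Estimate a function logo and extract Class-Informative Features (CIFs).

Builds a small synthetic taxon set with one planted clade CIF, estimates the
function logo (empirical class background, Monte-Carlo sample-size
correction), and prints the strongest letters.  Each letter's height (bits)
says how informative that nucleotide-at-a-Sprinzl-position is about tRNA
functional class, and how over-represented it is in the printed class.
"""

from trnacif import build_logo, extract_cifs
from trnacif.benchmark import default_benchmark_config, training_partition
from trnacif.synth import generate

cfg = default_benchmark_config(seed=1, n_clades=2)
dataset, truth, planted = generate(cfg)
clade1 = training_partition(dataset, truth)["clade1"]

logo = build_logo(clade1, correction="mc", mc_reps=500, seed=1)
cifs = extract_cifs(logo, threshold_bits=1.0)

print(f"clade1: {len(clade1.records)} tDNAs, {len(logo.info)} distinct features")
print(f"planted CIFs: {[(str(f), c) for f, c in planted['clade1']]}")
print(f"\ntop letters with height >= 1 bit ({len(cifs)} total):")
for f, c, h in sorted(cifs.members, key=lambda x: -x[2])[:8]:
    print(f"  {str(f):>10s}  class {c}  height {h:.2f} bits "
          f"(n = {logo.sample_sizes[f]})")
print("\nThe planted letters rank at the top: a feature carried almost only")
print("by one class's tRNAs concentrates nearly the full class information.")
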