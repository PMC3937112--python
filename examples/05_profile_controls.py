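"""The four missing-data treatments of the total-sequence profile control.

A genome is scored by mean log-odds of its tDNA features under class-specific
sequence profiles from two taxon sets.  The methods differ in how they treat
features unobserved in one or both training sets: "zero" ignores them,
"skip" averages only over scoreable features, "pseudo" Laplace-smooths, and
"small" substitutes a sample-size-tied epsilon.
"""

from trnacif import build_profiles, score_profile
from trnacif.benchmark import default_benchmark_config, training_partition
from trnacif.synth import converge, generate

cfg = default_benchmark_config(seed=5, n_clades=2, n_genomes=6)
dataset, truth, _ = generate(cfg)
parts = training_partition(dataset, truth)
profA = build_profiles(parts["clade1"], "clade1")
profB = build_profiles(parts["clade2"], "clade2")

genome = dataset.restrict(["clade1_g1"])
novel = converge(genome, ["clade1_g1"], at_shift=0.7, seed=5)

print("scores (bits per tDNA, positive = clade1 side):")
print(f"{'method':>8s} {'clade1 genome':>14s} {'A+T-rewritten':>14s}")
for method in ("zero", "skip", "pseudo", "small"):
    s1 = score_profile(genome, profA, profB, method)
    s2 = score_profile(novel, profA, profB, method)
    print(f"{method:>8s} {s1:>+14.2f} {s2:>+14.2f}")
print("\nAll methods place the unmodified genome firmly on its own side.")
print("Rewriting most of its G/C sites to A/T creates features rare or")
print("absent in both training sets: the methods then disagree, which is")
print("why missing-data treatment matters for total-sequence classifiers.")
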