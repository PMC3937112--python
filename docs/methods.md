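# Methods

## Data model

The unit of analysis is the tRNA **gene** (tDNA): a gap-containing DNA string
over the columns of a structural alignment indexed by Sprinzl coordinate
labels (strings "-1", "1".."76", with insertion labels allowed).  Columns are
always addressed by label, never by integer offset.  Each tDNA carries a
functional class from the 22-letter alphabet: the 20 IUPAC amino-acid letters
(aminoacylation classes), `X` (initiator), and `J` (the CAU-anticodon
isoleucine class).  A genome is the multiset of its tDNAs; a taxon set is a
set of genomes pooled for estimation.

Readers accept `U` (normalized to `T`), `.` (normalized to `-`), and
lower-case input; IUPAC ambiguity codes are accepted but yield no features,
like gaps, because the feature space is defined over {A, C, G, T}.  The
default Sprinzl map ships the standard 77 columns (-1, 1..76) and the
canonical acceptor-, D-, anticodon- and T-stem pair list; a table header can
override it.  Both the tDNA table (TSV) and Stockholm 1.0 (with a
`#=GC SPRINZL` comma-separated coordinate line) round-trip bit-exactly.

## Function logos and CIFs

Features are single nucleotides at a column, plus ordered nucleotide pairs at
the canonical stem pairings (counted only when both member columns are
ungapped; optional via `use_pairs`, default on).  With class background
*p(c)* = empirical class frequencies of the taxon set — empirical rather than
uniform, so that biased sampling of tRNA classes is corrected — and
feature-conditional distribution *P(c|f)*, the corrected stack information is

    I(f) = max(0, H(p) − H(P(·|f)) − e(n_f))        [bits]

and letter heights split *I(f)* by the normalized odds ratio
*w(c|f) ∝ P(c|f)/p(c)* (classes with *p(c) = 0* excluded).  Heights are
non-negative and sum exactly to *I(f)* per feature; *I* is bounded by
log2(number of classes present).

**Sample-size correction.**  *e(n)* is the expected apparent information of a
feature observed *n* times under the null that its class labels are i.i.d.
draws from the background: estimated by Monte Carlo (default 1000 replicates
per distinct *n*, multinomial draws, plug-in entropy), cached per *n*, with
an independent child RNG per *n* so the cache is order-independent and
deterministic given the seed.  At *n = 1* the correction saturates
(*e(1) = H(p)*), so singleton features carry no corrected information.  The
correction subtracts the *mean* apparent information; upward fluctuations
remain, so very small-sample letters can retain modest positive heights —
the benchmark's recovery protocol (below) and the permutation test are the
tools for separating those from signal.

**Significance.**  `permutation_pvalue` permutes class labels across tDNAs
and reports `(1 + #{permuted height ≥ observed}) / (reps + 1)`.  Heights are
compared uncorrected: *e(n_f)* depends only on *n_f*, which label permutation
preserves, so corrected and uncorrected orderings coincide.

**CIF sets.**  `extract_cifs(logo, t)` keeps letters with height ≥ *t*
(strictly positive at *t* = 0).  The threshold is a free parameter: 0
reproduces "all letters", 0.5 bits reproduces the reduced models used for
support re-estimation.  Purine/pyrimidine aggregates are reporting sugar
only, never part of the estimation alphabet.

## Classifiers

**Binary.**  A genome's score against taxon sets A and B is the mean over
its tDNAs of the summed height differences of the tDNA's features at the
tDNA's own class.  The per-genome mean (not the raw sum) is canonical, so
the score is invariant to duplicating the multiset.  Features absent from a
logo contribute zero on that side; no correction is applied for unequal
training-set sizes.  LOOCV rebuilds the scored genome's own side's logo
without its tDNAs; external query genomes are scored against full logos.
`class_breakout` averages each class's per-tDNA sums over that class's tDNA
count, so count-weighted contributions reproduce the genome total exactly.

**Profile controls.**  Class-specific sequence profiles hold
*q(c, f)* = frequency of *f* among class-*c* tDNAs and class priors *r(c)*.
A tDNA's score is `log2 rA(c) − log2 rB(c)` plus per-feature log-odds terms;
the genome score is the per-tDNA mean; logs are base 2 throughout so all
scores share the logo's bit units.  The four missing-data treatments are
isolated behind one switch:

* `zero` — a feature term contributes only when both *q* values are positive;
* `skip` — unscoreable features are omitted and the feature sum is divided by
  the number of scored features (per-feature mean);
* `pseudo` — Laplace smoothing `(count + k)/(n_class + |alphabet|·k)` with
  default pseudocount 1 (alphabet 4 for single features, 16 for pairs);
* `small` — zero frequencies replaced by ε, default `1/(2·max class count
  over both sets)`, smaller than any observable nonzero frequency.

Class priors absent from a profile are zeroed with a warning under
`zero`/`skip` and smoothed under `pseudo`/`small`.  All four are exactly
antisymmetric under swapping the taxon sets (the `small` ε is computed over
both sets jointly).

**Multiway.**  Each genome gets one CIF-match score per candidate clade
(the binary score's A-side sum against that clade's logo), in a fixed sorted
clade order.  The classifier is a one-hidden-layer perceptron mirroring the
common default configuration of such models: hidden units
⌈(inputs + classes)/2⌉, logistic activations, SGD with learning rate 0.3 and
momentum 0.2, 500 epochs, per-input mean/sd standardization; fitted via
scikit-learn, serialized as documented JSON (clade order, scaler, weights,
hyperparameters), with a self-contained forward pass for prediction.
Training reports stratified ten-fold cross-validation (folds shrink when a
clade has fewer than ten genomes); the fold predictions provide the
validation accuracy for LOOCV vectors.  Argmax ties break by clade order.

*Training-set augmentation.*  Site-bootstrap support (below) presents the
model with score vectors whose common-mode level fluctuates far outside the
spread of the plain training vectors, and a perceptron extrapolates
arbitrarily there.  Training therefore augments the labeled vectors with
site-resampled replicates of each training genome's vector (default 50 per
genome).  Augmented replicates join only the training side of each fit —
never a validation fold, and a fold's fit only sees replicates of genomes in
its training split — so reported CV accuracy is still measured on the plain
vectors.

**Bootstrap support.**  Each replicate draws alignment columns uniformly
with replacement from the shared Sprinzl labels; every feature is counted at
its column's sampled multiplicity (paired features ride their 5′ member
column), the score vector is recomputed via a precomputed per-column
contribution matrix, and the replicate is classified; support for a clade is
the percentage of replicates predicting it.  With a height filter set, the
logos are truncated to CIFs at or above the filter and the perceptron is
retrained on the filtered vectors before bootstrapping — the filter acts on
logo letters, never on genomes.

**Class deletion.**  For each functional class, all its tDNAs are removed
from every clade's training set, logos and perceptron are retrained
(non-LOOCV vectors, for speed), and all queries are reclassified; output is
the prediction table plus per-class counts of changed classifications.  If a
deletion empties every clade but one, predictions fall back to the raw
best-scoring clade.

## Composition diagnostics

Base counts over ungapped residues, aggregated by clade (via the dataset's
taxon map) or genome; zero counts are smoothed by +0.5 before proportions so
the centered log-ratio is defined (real tDNA sets never hit zero; synthetic
edge cases can).  CLR uses natural log — any base scales all distances by a
constant, leaving UPGMA topology unchanged; the base is recorded in output
metadata.  Distances are Euclidean on CLR vectors (Aitchison), invariant to
scaling any group's counts.  UPGMA is average-linkage clustering (scipy)
with labels pre-sorted so ties break deterministically by label order, and
an ultrametric Newick output (node height = half the merge distance;
children ordered by smallest contained leaf label).

## Synthetic data generator

The generator emulates the data structure the CIF machinery exploits, at
desk scale:

* **Class templates** share one gap pattern (position -1 gapped) and differ
  at four *diagnostic sites* (anticodon triplet analog 34-36 plus
  discriminator 73), whose class-specific states are shared across clades —
  the analog of universal identity elements.
* **Body sites** (all columns where the 22 templates agree) are drawn
  i.i.d. per gene from the clade's compositional equilibrium
  (P(G) = P(C) = gc_bias/2).  Being identically distributed across classes
  they carry zero class information — function logos ignore them — while
  giving the clade its G+C content and giving class profiles soft,
  composition-reflecting frequencies, as within-clade sequence variation
  does in real data.
* **Planted clade CIFs** are (feature, class) pairs imposed on the clade's
  genes of that class with probability `cif_fidelity` (imposed after noise,
  so fidelity is exact).  At a clade's own planted columns the body
  equilibrium excludes the planted state, keeping it the class's marker.
* **Noise**: i.i.d. substitution at `background_noise` per template-retained
  site, replacement bases drawn at the clade's G+C bias.

`converge` rewrites G/C to A/T (equiprobably) with probability `at_shift`
at unprotected, ungapped sites of chosen genomes — the synthetic analog of
mutational A+T drift.  The `protect` argument takes a CIF set or position
labels; the convergence experiment protects the CIFs of the converged
genomes' *own* lineage, modeling the observation that sites under
class-specific selection in a lineage resist the compositional drift of the
tRNA body around them, while other clades' CIF positions — unconstrained in
this lineage — drift freely.

**Reference benchmark** (`default_benchmark_config`): 7 clades × 10 genomes,
2 genes per class × 22 classes (44 tDNAs per genome, within the range
observed in real bacterial genomes), 3 planted CIFs per clade at fidelity
0.95, noise 0.02.  Six clades sit at G+C 0.60 and the last at 0.45, the
A+T-rich (Rickettsiales-analog) lineage.  Planted CIFs occupy 3′-side stem
positions, three distinct classes per clade, so each also surfaces as a
paired feature anchored at the 5′ partner column — spreading each clade's
signature over about six alignment columns, as real base-pair CIFs do, which
is what gives site-bootstrap support its stability.

**What the generator does not emulate**: phylogenetic structure within and
between clades (no tree-based substitution process — genomes within a clade
are exchangeable samples), isoacceptor/isodecoder structure within classes,
alignment or annotation error, and length variation in the variable arm.
Passing tests therefore demonstrate the estimators' and classifiers'
correctness and their differential robustness to compositional convergence —
not performance under real phylogenetic autocorrelation, which can only be
assessed on real data.

## Evaluation protocols

* **Oracle equivalence**: uncorrected logo heights match a direct-enumeration
  brute-force implementation to 1e-9 on randomized small alignments.
* **Planted-CIF recovery**: per clade, letters of the 0.3-bit CIF set are
  counted as *clade-specific* if (i) they reach half that threshold in no
  other clade (universal letters cancel, including ones straddling the
  threshold) and (ii) their feature is carried by at least half of the
  class's tDNAs in the clade — class-typical, as identity elements are,
  which screens sporadic low-count letters whose corrected heights fluctuate
  above threshold.  A recovered paired letter whose member matches a planted
  single of the same class is the planted CIF seen through its stem partner
  and is counted neither for nor against precision; recall is over the
  planted singles themselves.
* **Multiway benchmark**: LOOCV score vectors, ten-fold CV accuracy,
  bootstrap support (100 replicates per genome) for each genome's true
  clade.
* **Convergence experiment**: ten fresh genomes of a G+C-rich clade
  (generated from the same clade process beyond the training genomes) are
  converged at `at_shift` 0.5 with own-lineage CIFs protected, then
  evaluated three ways: sisterhood with the A+T-rich clade in the UPGMA
  composition tree, CIF multiway accuracy versus the "zero" profile control,
  and the sign of binary CIF scores contrasting the true clade with the
  A+T-rich clade.

Problem sizes throughout (10 genomes per clade, 100 bootstrap replicates,
1000 Monte-Carlo correction replicates) are the package's reference study
conditions; they keep a full pipeline run to a couple of minutes on one CPU
while leaving comfortable statistical margins on every protocol.

## Numerical and degenerate-input choices

Negative corrected information clamps to zero (heights are defined
non-negative).  Empty taxon sets yield an explicitly empty logo whose
heights are all zero (a single-genome side under LOOCV reduces to scoring
against the other side alone).  Duplicate (genome, gene) identifiers are
rejected; strict parsing rejects malformed rows with their row number,
non-strict parsing skips them with a logged warning.  All stochastic stages
(Monte-Carlo correction, permutation test, generator, convergence, MLP
training, bootstrap) are seeded, and a fixed seed reproduces results
bit-exactly; derived child seeds stay below 2^31.
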