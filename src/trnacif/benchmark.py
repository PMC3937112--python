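"""The package's reference synthetic benchmark and its evaluation protocols.

The default benchmark emulates, at desk scale, the study design the CIF
method targets: seven clades of ten genomes each, every genome carrying two
genes for each of the 22 tRNA functional classes, with three clade-specific
CIFs planted per clade (fidelity 0.95, substitution noise 0.02).  Six clades
have G+C-rich tRNAs (0.60) and one — the analog of an A+T-drifted lineage
such as the Rickettsiales — sits at 0.45.

Protocols defined here:

* :func:`cif_recovery` — precision/recall of planted clade-specific CIFs.
  Recovered clade-specific CIFs are letters of a clade's thresholded CIF set
  that (i) reach at least half the threshold in no other clade (universal,
  identity-element-like letters cancel, including ones that straddle the
  threshold) and (ii) are carried by at least half of their class's
  tDNAs in the clade — class-typical, as identity elements are, which screens
  out sporadic low-count letters whose corrected heights fluctuate above
  threshold.
* :func:`multiway_benchmark` — leave-one-out multiway classification accuracy
  and site-bootstrap support on the benchmark.
* :func:`convergence_experiment` — the compositional-convergence contrast:
  fresh genomes of one G+C-rich clade are driven A+T-rich at non-CIF sites,
  then classified by the CIF multiway model, the binary CIF score and the
  total-sequence "zero" profile score, while their base composition is
  clustered by UPGMA.  Sites that are CIFs of the queries' own lineage are
  protected during convergence, modeling the observation that the sites
  selection preserves in a lineage resist the compositional drift of the tRNA
  bodies around them.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .binary import score_binary
from .composition import composition, distance_matrix, upgma
from .dataset import TDNADataset
from .logo import (
    Feature,
    build_logo,
    count_features,
    extract_cifs,
)
from .multiway import (
    bootstrap_augmented_vectors,
    bootstrap_support,
    clade_score_vector,
    classify,
    build_clade_logos,
    train_mlp,
    training_score_vectors,
)
from .profiles import build_profiles, score_profile
from .sprinzl import default_sprinzl_map
from .synth import (
    DIAGNOSTIC_SITES,
    CladeSpec,
    GeneratorConfig,
    build_class_templates,
    converge,
    generate,
)

__all__ = [
    "default_benchmark_config",
    "training_partition",
    "cif_recovery",
    "multiway_benchmark",
    "convergence_experiment",
]

_CLASSES = tuple(sorted("ACDEFGHIKLMNPQRSTVWY") + ["X", "J"])


def _plantable_positions(sprinzl) -> List[str]:
    """3'-side stem positions, in stem order.

    Planting a clade CIF at a 3' stem member makes the clade's signature show
    both as the single feature at that column and as a paired feature with
    the clade's 5' partner state, anchored at the partner column — spreading
    the clade signal over two alignment columns per planted CIF, as real
    base-pair CIFs do.
    """
    return [b for _, b in sprinzl.pair_list]


def default_benchmark_config(
    seed: int = 0,
    n_clades: int = 7,
    n_genomes: int = 10,
    genes_per_class: int = 2,
    cifs_per_clade: int = 3,
    gc_bias: float = 0.60,
    at_clade_gc: float = 0.45,
    background_noise: float = 0.02,
    cif_fidelity: float = 0.95,
    extra_genomes: Optional[Dict[str, int]] = None,
) -> GeneratorConfig:
    """The default seven-clade benchmark configuration.

    The last clade is the A+T-rich analog (``at_clade_gc``).  Planted CIFs are
    single-nucleotide features at 3'-side stem positions, three per clade in
    three distinct classes, with states differing from the master template.
    ``extra_genomes`` adds genomes to named clades (used to draw
    fresh query genomes from the same clade processes: for a fixed seed, the
    first ``n_genomes`` genomes of each clade are identical regardless).
    """
    sprinzl = default_sprinzl_map()
    templates = build_class_templates(sprinzl, _CLASSES, seed)
    positions = _plantable_positions(sprinzl)
    need = n_clades * cifs_per_clade
    if need > len(positions):
        raise ValueError("too many planted CIFs for the available positions")
    clades = []
    for i in range(n_clades):
        name = f"clade{i + 1}"
        planted: List[Tuple[Feature, str]] = []
        for k in range(cifs_per_clade):
            pos = positions[i * cifs_per_clade + k]
            cls = _CLASSES[(i * cifs_per_clade + k) % len(_CLASSES)]
            tmpl_state = templates[cls][sprinzl.column(pos)]
            state = "ACGT"[("ACGT".index(tmpl_state) + 1) % 4]
            planted.append((Feature("single", pos, state), cls))
        n_g = n_genomes + (extra_genomes or {}).get(name, 0)
        clades.append(
            CladeSpec(
                name=name,
                n_genomes=n_g,
                genes_per_class={c: genes_per_class for c in _CLASSES},
                gc_bias=at_clade_gc if i == n_clades - 1 else gc_bias,
                planted_cifs=planted,
                cif_fidelity=cif_fidelity,
            )
        )
    return GeneratorConfig(sprinzl, clades, templates, background_noise, seed)


def training_partition(
    dataset: TDNADataset, truth: Dict[str, str]
) -> Dict[str, TDNADataset]:
    """Split a generated dataset into per-clade training sets."""
    out: Dict[str, TDNADataset] = {}
    for clade in sorted(set(truth.values())):
        out[clade] = dataset.restrict([g for g, c in truth.items() if c == clade])
    return out


def cif_recovery(
    training: Dict[str, TDNADataset],
    planted: Dict[str, List[Tuple[Feature, str]]],
    threshold: float = 0.3,
    min_class_fraction: float = 0.5,
    use_pairs: bool = True,
    correction: str = "mc",
    mc_reps: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Precision and recall of planted clade-specific CIFs (see module
    docstring for the recovered-CIF definition)."""
    logo_kw = dict(use_pairs=use_pairs, correction=correction, mc_reps=mc_reps, seed=seed)
    cif_sets = {}
    exclusion_sets = {}  # letters at half threshold: a clade-specific letter
    # must be near-absent elsewhere, not merely just under the threshold
    class_fraction = {}
    for clade, data in training.items():
        logo = build_logo(data, **logo_kw)
        cif_sets[clade] = {(f, c) for f, c, _ in extract_cifs(logo, threshold).members}
        exclusion_sets[clade] = {
            (f, c) for f, c, _ in extract_cifs(logo, threshold / 2).members
        }
        counts = count_features(data, use_pairs)
        class_fraction[clade] = {
            (f, c): n / counts.n_class[c] for (f, c), n in counts.n_feat_class.items()
        }
    def _consistent(fc, truth_set) -> bool:
        # a paired letter whose member matches a planted single (same class)
        # is the planted CIF seen through its stem partner, not a false call
        f, c = fc
        if fc in truth_set:
            return True
        if f.kind != "paired":
            return False
        members = set(zip(f.positions(), f.state))
        return any(
            tc == c and tf.kind == "single" and (tf.pos, tf.state) in members
            for tf, tc in truth_set
        )

    tp = fp = fn = 0
    for clade in training:
        others = set().union(*(exclusion_sets[o] for o in training if o != clade))
        recovered = {
            fc
            for fc in cif_sets[clade] - others
            if class_fraction[clade].get(fc, 0.0) >= min_class_fraction
        }
        truth_set = set(planted.get(clade, []))
        consistent = {fc for fc in recovered if _consistent(fc, truth_set)}
        tp += len(consistent & truth_set)
        fp += len(recovered - consistent)
        fn += len(truth_set - recovered)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn}


def multiway_benchmark(
    seed: int = 0,
    replicates: int = 100,
    height_filter: Optional[float] = None,
    mc_reps: int = 1000,
    config: Optional[GeneratorConfig] = None,
) -> Dict[str, object]:
    """LOOCV multiway accuracy and site-bootstrap support on the benchmark.

    Every training genome's score vector is computed with its own tDNAs left
    out of its clade's logo; ten-fold stratified CV reports the validation
    accuracy; bootstrap support (per genome, for its true clade) uses the
    all-data model.
    """
    cfg = config or default_benchmark_config(seed)
    dataset, truth, _ = generate(cfg)
    training = training_partition(dataset, truth)
    logo_kw = dict(correction="mc", mc_reps=mc_reps, seed=seed)
    logos = build_clade_logos(training, use_pairs=True, **logo_kw)
    vectors = training_score_vectors(
        training, loocv=True, use_pairs=True, clade_logos=logos, **logo_kw
    )
    augmented = bootstrap_augmented_vectors(training, logos, n_aug=50, seed=seed)
    model, report = train_mlp(vectors, seed=seed, augmented=augmented)

    supports = []
    parts = dataset.by_genome()
    for gid, clade in truth.items():
        res = bootstrap_support(
            parts[gid],
            logos,
            model,
            replicates=replicates,
            seed=int(np.random.default_rng([seed, hash(gid) % (2**31)]).integers(2**31)),
            height_filter=height_filter,
            training=training if height_filter is not None else None,
            mlp_seed=seed,
        )
        supports.append(res.bootstrap_support.get(clade, 0.0))
    return {
        "loocv_accuracy": report["accuracy"],
        "cv_report": report,
        "median_correct_support": float(np.median(supports)),
        "supports": supports,
        "model": model,
        "logos": logos,
        "training": training,
        "vectors": vectors,
    }


def convergence_experiment(
    seed: int = 0,
    at_shift: float = 0.5,
    n_queries: int = 10,
    protect_threshold: float = 0.3,
    mc_reps: int = 1000,
) -> Dict[str, object]:
    """The compositional-convergence contrast on the default benchmark.

    Fresh genomes of clade1 (G+C-rich) are converged A+T-ward at non-CIF
    sites, then (a) their base compositions are clustered against the clade
    compositions by UPGMA, (b) they are classified by the CIF multiway model
    and by the binary CIF and "zero" profile classifiers contrasting clade1
    with the A+T-rich clade.
    """
    base_cfg = default_benchmark_config(seed)
    n_train = base_cfg.clades[0].n_genomes
    cfg = default_benchmark_config(seed, extra_genomes={"clade1": n_queries})
    dataset, truth, planted = generate(cfg)
    at_clade = cfg.clades[-1].name

    clade1_genomes = sorted(
        (g for g, c in truth.items() if c == "clade1"),
        key=lambda s: int(s.rsplit("_g", 1)[1]),
    )
    train_g1 = clade1_genomes[:n_train]
    query_ids = clade1_genomes[n_train:]
    train_truth = {g: c for g, c in truth.items() if g not in set(query_ids)}
    training = training_partition(dataset.exclude(query_ids), train_truth)
    queries = dataset.restrict(query_ids)

    # sites that are CIFs of the queries' own lineage resist the drift: they
    # are the sites selection preserves in that lineage; everything else (the
    # tRNA "body") converges
    logo_kw = dict(correction="mc", mc_reps=mc_reps, seed=seed)
    own_logo = build_logo(training["clade1"], use_pairs=True, **logo_kw)
    protect = extract_cifs(own_logo, protect_threshold)
    converged = converge(queries, query_ids, at_shift, protect=protect, seed=seed + 1)

    # (a) composition clustering: clade groups + the converged query group
    comp_data = TDNADataset(
        dataset.sprinzl,
        [r for d in training.values() for r in d.records] + list(converged.records),
        {**{g: c for g, c in train_truth.items()}, **{g: "converged" for g in query_ids}},
    )
    comps = composition(comp_data, group_by="clade")
    D = distance_matrix(comps)
    labels = [v.group for v in comps]
    tree = upgma(D, labels)
    sister = _upgma_sister(D, labels, "converged")

    # (b) multiway CIF classification of converged queries
    logos = build_clade_logos(training, use_pairs=True, **logo_kw)
    vectors = training_score_vectors(
        training, loocv=True, use_pairs=True, clade_logos=logos, **logo_kw
    )
    augmented = bootstrap_augmented_vectors(training, logos, n_aug=50, seed=seed)
    model, _ = train_mlp(vectors, seed=seed, augmented=augmented)
    preds = {}
    for gid, part in converged.by_genome().items():
        preds[gid] = classify(model, clade_score_vector(part, logos)).predicted
    multiway_acc = float(np.mean([preds[g] == "clade1" for g in query_ids]))

    # (c) binary CIF and "zero" profile contrasts: clade1 vs the A+T clade
    logoA, logoB = logos["clade1"], logos[at_clade]
    profA = build_profiles(training["clade1"], "clade1")
    profB = build_profiles(training[at_clade], at_clade)
    cif_scores, prof_scores = [], []
    for gid, part in converged.by_genome().items():
        cif_scores.append(score_binary(part, logoA, logoB))
        prof_scores.append(score_profile(part, profA, profB, method="zero"))
    binary_sign_acc = float(np.mean([s > 0 for s in cif_scores]))
    profile_acc = float(np.mean([s > 0 for s in prof_scores]))

    return {
        "tree": tree,
        "sister_of_converged": sister,
        "at_clade": at_clade,
        "converged_joins_at_clade": sister == at_clade,
        "multiway_accuracy_converged": multiway_acc,
        "profile_zero_accuracy_converged": profile_acc,
        "binary_sign_accuracy_converged": binary_sign_acc,
        "binary_scores": cif_scores,
        "profile_scores": prof_scores,
        "predictions": preds,
        "planted": planted,
    }


def _upgma_sister(D: np.ndarray, labels: Sequence[str], target: str) -> Optional[str]:
    """The leaf label joined with ``target`` in its first UPGMA merge, or None
    if the target first merges with an internal cluster."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    order = sorted(range(len(labels)), key=lambda i: str(labels[i]))
    labs = [str(labels[i]) for i in order]
    Z = linkage(squareform(D[np.ix_(order, order)], checks=False), method="average")
    t = labs.index(target)
    n = len(labs)
    for a, b, _, _ in Z:
        a, b = int(a), int(b)
        if t in (a, b):
            other = b if a == t else a
            return labs[other] if other < n else None
    return None
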