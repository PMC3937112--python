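"""k-way CIF-based phyloclassification with a small multilayer perceptron.

Each genome is summarized by a vector of per-clade CIF-match scores: for each
candidate clade, the mean over the genome's tDNAs of the summed letter
heights its features attain in that clade's function logo (bits per tDNA).
A one-hidden-layer perceptron with logistic activations, trained on labeled
score vectors of reference genomes (with ten-fold stratified cross-validation
reported), turns a score vector into clade membership probabilities.
Statistical support is estimated by bootstrap resampling of alignment
columns: each replicate draws Sprinzl columns with replacement, recomputes
the genome's score vector with features weighted by their column's sampled
multiplicity (paired features ride their 5' member column), and reclassifies;
support for a clade is the percentage of replicates predicting it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .dataset import TDNADataset
from .logo import FunctionLogo, build_logo, features_of, filter_logo

__all__ = [
    "ScoreVector",
    "MLPModel",
    "ClassificationResult",
    "clade_score_vector",
    "build_clade_logos",
    "training_score_vectors",
    "bootstrap_augmented_vectors",
    "train_mlp",
    "classify",
    "bootstrap_support",
    "class_deletion_analysis",
]

DEFAULT_HYPERPARAMETERS = {
    "hidden_units": None,  # None -> ceil((inputs + classes) / 2)
    "learning_rate": 0.3,
    "momentum": 0.2,
    "epochs": 500,
}


@dataclass
class ScoreVector:
    """Per-genome vector of clade CIF-match scores (bits per tDNA), in a fixed
    clade order."""

    genome_id: str
    scores: Dict[str, float]
    loocv: bool = False

    def as_array(self, clade_order: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[k] for k in clade_order], dtype=float)


@dataclass
class ClassificationResult:
    """Clade membership probabilities for one genome, with optional bootstrap
    support per clade (percentages over replicates)."""

    genome_id: str
    probabilities: Dict[str, float]
    predicted: str
    bootstrap_support: Optional[Dict[str, float]] = None
    replicates: int = 0


def _genome_score(genome: TDNADataset, logo: FunctionLogo, use_pairs: bool) -> float:
    total = 0.0
    for rec in genome.records:
        for f in features_of(rec.seq, genome.sprinzl, use_pairs):
            total += logo.height(f, rec.cls)
    return total / len(genome.records)


def clade_score_vector(
    genome: TDNADataset,
    clade_logos: Dict[str, FunctionLogo],
    loocv_exclude: Optional[str] = None,
    training: Optional[Dict[str, TDNADataset]] = None,
    use_pairs: bool = True,
    logo_kwargs: Optional[dict] = None,
) -> ScoreVector:
    """Score one genome against every clade's function logo.

    With ``loocv_exclude`` set to the genome's own id and ``training``
    supplied, the clade containing that genome has its logo rebuilt without
    the genome's tDNAs before scoring.
    """
    if len(clade_logos) < 2:
        raise ValueError("need at least 2 clades")
    if not genome.records:
        raise ValueError("empty genome")
    logos = dict(clade_logos)
    loocv = False
    if loocv_exclude is not None and training is not None:
        for clade, data in training.items():
            if loocv_exclude in set(data.genome_ids):
                rest = data.exclude([loocv_exclude])
                logos[clade] = (
                    build_logo(rest, use_pairs=use_pairs, **(logo_kwargs or {}))
                    if rest.records
                    else FunctionLogo.empty(use_pairs)
                )
                loocv = True
    gid = genome.records[0].genome_id
    scores = {k: _genome_score(genome, logos[k], use_pairs) for k in sorted(logos)}
    return ScoreVector(gid, scores, loocv)


def build_clade_logos(
    training: Dict[str, TDNADataset], use_pairs: bool = True, **logo_kwargs
) -> Dict[str, FunctionLogo]:
    """One function logo per training clade."""
    return {
        clade: build_logo(data, use_pairs=use_pairs, **logo_kwargs)
        for clade, data in training.items()
    }


def training_score_vectors(
    training: Dict[str, TDNADataset],
    loocv: bool = True,
    use_pairs: bool = True,
    clade_logos: Optional[Dict[str, FunctionLogo]] = None,
    **logo_kwargs,
) -> List[Tuple[ScoreVector, str]]:
    """Labeled score vectors for every training genome.

    With ``loocv`` (default), each genome's own clade logo is rebuilt without
    its tDNAs before scoring, so no genome sees its own data.
    """
    if clade_logos is None:
        clade_logos = build_clade_logos(training, use_pairs, **logo_kwargs)
    out: List[Tuple[ScoreVector, str]] = []
    for clade, data in training.items():
        for gid, part in data.by_genome().items():
            vec = clade_score_vector(
                part,
                clade_logos,
                loocv_exclude=gid if loocv else None,
                training=training if loocv else None,
                use_pairs=use_pairs,
                logo_kwargs=logo_kwargs,
            )
            out.append((vec, clade))
    return out


@dataclass
class MLPModel:
    """A trained one-hidden-layer perceptron over clade score vectors.

    Inputs are standardized by the stored per-input mean/sd; the hidden layer
    uses logistic activations; outputs are normalized to a probability vector
    over ``clade_labels``.
    """

    clade_labels: List[str]
    input_mean: np.ndarray
    input_sd: np.ndarray
    weights: List[np.ndarray]       # [W_hidden, W_out]
    intercepts: List[np.ndarray]    # [b_hidden, b_out]
    hyperparameters: dict = field(default_factory=dict)
    class_order: Optional[List[str]] = None  # output-unit order (training label order)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities in ``clade_labels`` order for an (n, k) score array."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.clade_labels):
            raise ValueError(
                f"expected {len(self.clade_labels)} inputs, got {X.shape[1]}"
            )
        Z = (X - self.input_mean) / self.input_sd
        H = 1.0 / (1.0 + np.exp(-(Z @ self.weights[0] + self.intercepts[0])))
        O = H @ self.weights[1] + self.intercepts[1]
        order = self.class_order or self.clade_labels
        if O.shape[1] == 1:  # binary case: single logistic output
            p1 = 1.0 / (1.0 + np.exp(-O[:, 0]))
            probs_in_order = np.column_stack([1.0 - p1, p1])
        else:
            O = O - O.max(axis=1, keepdims=True)
            E = np.exp(O)
            probs_in_order = E / E.sum(axis=1, keepdims=True)
        # reorder output units into clade_labels order
        idx = [order.index(k) for k in self.clade_labels]
        return probs_in_order[:, idx]

    def to_json(self, path) -> None:
        obj = {
            "clade_labels": self.clade_labels,
            "input_mean": self.input_mean.tolist(),
            "input_sd": self.input_sd.tolist(),
            "weights": [w.tolist() for w in self.weights],
            "intercepts": [b.tolist() for b in self.intercepts],
            "hyperparameters": self.hyperparameters,
            "class_order": self.class_order,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    @staticmethod
    def from_json(path) -> "MLPModel":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return MLPModel(
            obj["clade_labels"],
            np.array(obj["input_mean"], dtype=float),
            np.array(obj["input_sd"], dtype=float),
            [np.array(w, dtype=float) for w in obj["weights"]],
            [np.array(b, dtype=float) for b in obj["intercepts"]],
            obj.get("hyperparameters", {}),
            obj.get("class_order"),
        )


def bootstrap_augmented_vectors(
    training: Dict[str, TDNADataset],
    clade_logos: Dict[str, FunctionLogo],
    n_aug: int = 25,
    seed: int = 0,
    use_pairs: bool = True,
) -> List[Tuple[ScoreVector, str]]:
    """Site-resampled replicates of the training genomes' score vectors.

    Used to augment perceptron training so the classifier is exposed to the
    same column-resampling variation that the bootstrap support procedure
    applies at classification time; each replicate keeps its source genome's
    id and clade label.
    """
    clades = sorted(clade_logos)
    rng = np.random.default_rng(seed)
    out: List[Tuple[ScoreVector, str]] = []
    for clade in sorted(training):
        for gid, part in training[clade].by_genome().items():
            C, _ = _column_contributions(part, clade_logos, use_pairs)
            n_cols = C.shape[0]
            n = len(part.records)
            for _ in range(n_aug):
                mult = np.bincount(
                    rng.integers(0, n_cols, n_cols), minlength=n_cols
                ).astype(float)
                s = (mult @ C) / n
                out.append((ScoreVector(gid, dict(zip(clades, s))), clade))
    return out


def train_mlp(
    vectors: Sequence[Tuple[ScoreVector, str]],
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
    augmented: Optional[Sequence[Tuple[ScoreVector, str]]] = None,
) -> Tuple[MLPModel, dict]:
    """Train the perceptron on labeled score vectors.

    Returns the fitted model and a stratified ten-fold cross-validation
    report (fold sizes adapt when a clade has fewer than ten genomes).
    ``augmented`` vectors (e.g. from :func:`bootstrap_augmented_vectors`)
    join the training side of every fit; they never enter a validation fold,
    and a fold's fit only sees augmented vectors whose source genome is in
    that fold's training split.  Training is deterministic given the seed.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS)
    hp.update(hyperparameters or {})
    labels = [lab for _, lab in vectors]
    clade_order = sorted(set(labels))
    if len(clade_order) < 2:
        raise ValueError("need vectors from at least 2 clades")
    counts = {c: labels.count(c) for c in clade_order}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"clade(s) with zero vectors: {missing}")
    for vec, _ in vectors:
        if sorted(vec.scores) != clade_order:
            raise ValueError(
                f"vector {vec.genome_id} clades do not match training clades"
            )

    X = np.array([vec.as_array(clade_order) for vec, _ in vectors], dtype=float)
    y = np.array(labels)
    if augmented:
        Xa = np.array([vec.as_array(clade_order) for vec, _ in augmented], dtype=float)
        ya = np.array([lab for _, lab in augmented])
        gids_a = np.array([vec.genome_id for vec, _ in augmented])
        Xall = np.vstack([X, Xa])
    else:
        Xa = ya = gids_a = None
        Xall = X
    mean = Xall.mean(axis=0)
    sd = Xall.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    Za = (Xa - mean) / sd if Xa is not None else None

    n_in = len(clade_order)
    hidden = hp["hidden_units"] or math.ceil((n_in + len(clade_order)) / 2)

    def _fit(Ztr, ytr) -> MLPClassifier:
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="sgd",
            alpha=0.0,
            batch_size=min(200, len(ytr)),
            learning_rate="constant",
            learning_rate_init=hp["learning_rate"],
            momentum=hp["momentum"],
            nesterovs_momentum=False,
            max_iter=hp["epochs"],
            n_iter_no_change=hp["epochs"],
            tol=0.0,
            shuffle=True,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Ztr, ytr)
        return clf

    # ten-fold stratified cross-validation report
    n_splits = min(10, min(counts.values()), len(y))
    fold_pred: Dict[str, str] = {}
    fold_acc: List[float] = []
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for tr_idx, te_idx in skf.split(Z, y):
            Ztr, ytr = Z[tr_idx], y[tr_idx]
            if Za is not None:
                tr_gids = {vectors[i][0].genome_id for i in tr_idx}
                keep = np.array([g in tr_gids for g in gids_a])
                Ztr = np.vstack([Ztr, Za[keep]])
                ytr = np.concatenate([ytr, ya[keep]])
            clf = _fit(Ztr, ytr)
            pred = clf.predict(Z[te_idx])
            fold_acc.append(float((pred == y[te_idx]).mean()))
            for i, p in zip(te_idx, pred):
                fold_pred[vectors[i][0].genome_id] = str(p)
        cv_accuracy = float(
            np.mean([fold_pred[v.genome_id] == lab for v, lab in vectors])
        )
    else:
        cv_accuracy = float("nan")
    report = {
        "n_splits": n_splits,
        "fold_accuracies": fold_acc,
        "accuracy": cv_accuracy,
        "fold_predictions": fold_pred,
    }

    if Za is not None:
        clf = _fit(np.vstack([Z, Za]), np.concatenate([y, ya]))
    else:
        clf = _fit(Z, y)
    model = MLPModel(
        clade_labels=clade_order,
        input_mean=mean,
        input_sd=sd,
        weights=[np.array(w) for w in clf.coefs_],
        intercepts=[np.array(b) for b in clf.intercepts_],
        hyperparameters={**hp, "hidden_units": hidden, "seed": seed},
        class_order=[str(c) for c in clf.classes_],
    )
    return model, report


def classify(model: MLPModel, vector: ScoreVector) -> ClassificationResult:
    """Clade probabilities for one score vector; the predicted clade is the
    argmax, ties broken by clade order."""
    x = vector.as_array(model.clade_labels)
    p = model.predict_proba(x)[0]
    best = int(np.argmax(p))  # argmax returns the first (clade-order) maximum
    return ClassificationResult(
        vector.genome_id,
        {k: float(pi) for k, pi in zip(model.clade_labels, p)},
        model.clade_labels[best],
    )


def _column_contributions(
    genome: TDNADataset, clade_logos: Dict[str, FunctionLogo], use_pairs: bool
) -> Tuple[np.ndarray, List[str]]:
    """(n_columns, n_clades) matrix of per-column summed letter heights over
    the genome's tDNAs; paired features are attributed to their 5' column."""
    clades = sorted(clade_logos)
    labels = genome.sprinzl.labels
    col_index = {lab: j for j, lab in enumerate(labels)}
    C = np.zeros((len(labels), len(clades)))
    for rec in genome.records:
        for f in features_of(rec.seq, genome.sprinzl, use_pairs):
            j = col_index[f.anchor()]
            for k, clade in enumerate(clades):
                C[j, k] += clade_logos[clade].height(f, rec.cls)
    return C, clades


def bootstrap_support(
    genome: TDNADataset,
    clade_logos: Dict[str, FunctionLogo],
    model: MLPModel,
    replicates: int = 100,
    seed: int = 0,
    height_filter: Optional[float] = None,
    training: Optional[Dict[str, TDNADataset]] = None,
    use_pairs: bool = True,
    mlp_seed: Optional[int] = None,
) -> ClassificationResult:
    """Site-bootstrap support for one genome's classification.

    Each replicate resamples the shared Sprinzl columns with replacement and
    recomputes the score vector with features counted at their sampled
    column's multiplicity.  With ``height_filter`` set, logos are first
    truncated to CIFs at or above the filter and the perceptron is retrained
    on the (supplied) training data before bootstrapping.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not genome.records:
        raise ValueError("empty genome")
    if height_filter is not None:
        clade_logos = {
            k: filter_logo(v, height_filter) for k, v in clade_logos.items()
        }
        if training is None:
            raise ValueError("height_filter requires the training datasets")
        vectors = training_score_vectors(
            training, loocv=False, use_pairs=use_pairs, clade_logos=clade_logos
        )
        model, _ = train_mlp(
            vectors, model.hyperparameters, mlp_seed if mlp_seed is not None else seed
        )

    C, clades = _column_contributions(genome, clade_logos, use_pairs)
    n_cols = C.shape[0]
    n = len(genome.records)
    point_scores = C.sum(axis=0) / n
    point = classify(model, ScoreVector(genome.records[0].genome_id, dict(zip(clades, point_scores))))

    rng = np.random.default_rng(seed)
    cols = rng.integers(0, n_cols, size=(replicates, n_cols))
    mult = np.zeros((replicates, n_cols))
    for i in range(replicates):
        np.add.at(mult[i], cols[i], 1.0)
    rep_scores = (mult @ C) / n
    probs = model.predict_proba(rep_scores)
    # per-replicate argmax with first-maximum (clade-order) tie-break
    pred_idx = np.argmax(probs, axis=1)
    support = {
        k: 100.0 * float((pred_idx == i).sum()) / replicates
        for i, k in enumerate(model.clade_labels)
    }
    return ClassificationResult(
        point.genome_id, point.probabilities, point.predicted, support, replicates
    )


def class_deletion_analysis(
    training: Dict[str, TDNADataset],
    queries: TDNADataset,
    classes_to_delete: Sequence[str],
    use_pairs: bool = True,
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
    **logo_kwargs,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Robustness of query classifications to deletion of whole tRNA
    functional classes from the training data.

    For each class, all tDNAs of that class are removed from every clade's
    training set, logos and perceptron retrained, and every query genome
    reclassified.  Returns the (genome x deleted class) prediction table
    (deleted_class "none" is the baseline) and the per-class count of queries
    whose classification changed from baseline.
    """

    def _run(train: Dict[str, TDNADataset]) -> Dict[str, str]:
        logos = {}
        for clade, data in train.items():
            if not data.records:
                warnings.warn(
                    f"clade {clade!r} has no tDNAs after deletion; empty logo kept",
                    stacklevel=2,
                )
                logos[clade] = FunctionLogo.empty(use_pairs)
            else:
                logos[clade] = build_logo(data, use_pairs=use_pairs, **logo_kwargs)
        trainable = {k: d for k, d in train.items() if d.records}
        model = None
        if len(trainable) >= 2:
            vectors = training_score_vectors(
                trainable, loocv=False, use_pairs=use_pairs, clade_logos=logos
            )
            model, _ = train_mlp(vectors, hyperparameters, seed)
        out = {}
        clade_order = sorted(logos)
        for gid, part in queries.by_genome().items():
            vec = clade_score_vector(part, logos, use_pairs=use_pairs)
            if model is not None:
                out[gid] = classify(model, vec).predicted
            else:
                # degenerate deletion: fall back to the raw best-scoring clade
                out[gid] = max(clade_order, key=lambda k: vec.scores[k])
        return out

    baseline = _run(training)
    rows = [
        {"genome_id": g, "deleted_class": "none", "predicted": p}
        for g, p in baseline.items()
    ]
    changed: Dict[str, int] = {}
    for cls in classes_to_delete:
        reduced = {
            clade: TDNADataset(
                data.sprinzl,
                [r for r in data.records if r.cls != cls],
                dict(data.taxon_of),
            )
            for clade, data in training.items()
        }
        preds = _run(reduced)
        changed[cls] = sum(preds[g] != baseline[g] for g in baseline)
        rows.extend(
            {"genome_id": g, "deleted_class": cls, "predicted": p}
            for g, p in preds.items()
        )
    return pd.DataFrame(rows, columns=["genome_id", "deleted_class", "predicted"]), changed
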