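import numpy as np
import pytest

from trnacif.dataset import TDNADataset
from trnacif.logo import Feature, FunctionLogo
from trnacif.multiway import (
    MLPModel,
    ScoreVector,
    bootstrap_support,
    clade_score_vector,
    class_deletion_analysis,
    classify,
    train_mlp,
)
from trnacif.sprinzl import SprinzlMap

from conftest import make_dataset


def S(pos, state):
    return Feature("single", pos, state)


def hand_logo(heights):
    info = {}
    for (f, c), h in heights.items():
        info[f] = info.get(f, 0.0) + h
    return FunctionLogo({}, info, dict(heights), {f: 1 for f in info}, "none", False)


def toy_vectors(rng, n_per_clade=8, clades=("X", "Y", "Z"), margin=1.0):
    """Linearly separable score vectors: own-clade score exceeds others."""
    out = []
    i = 0
    for c in clades:
        for _ in range(n_per_clade):
            scores = {k: rng.normal(1.0, 0.1) for k in clades}
            scores[c] += margin
            out.append((ScoreVector(f"g{i}", scores), c))
            i += 1
    return out


class TestCladeScoreVector:
    def test_features_missing_everywhere_give_zero_vector(self, map2):
        genome = make_dataset(map2, [("g", "t", "F", "AA")])
        logos = {"X": hand_logo({(S("1", "G"), "F"): 1.0}), "Y": hand_logo({})}
        vec = clade_score_vector(genome, logos)
        assert vec.scores == {"X": 0.0, "Y": 0.0}

    def test_single_clade_rejected(self, map2):
        genome = make_dataset(map2, [("g", "t", "F", "AA")])
        with pytest.raises(ValueError):
            clade_score_vector(genome, {"X": hand_logo({})})

    def test_hand_built_two_clade_sums(self, map2):
        genome = make_dataset(map2, [("g", "t", "F", "AC")])
        logos = {
            "X": hand_logo({(S("1", "A"), "F"): 1.0, (S("2", "C"), "F"): 0.25}),
            "Y": hand_logo({(S("2", "C"), "F"): 0.5}),
        }
        vec = clade_score_vector(genome, logos, use_pairs=False)
        assert vec.scores == pytest.approx({"X": 1.25, "Y": 0.5})

    def test_empty_genome_rejected(self, map2):
        with pytest.raises(ValueError):
            clade_score_vector(TDNADataset(map2, []), {"X": hand_logo({}), "Y": hand_logo({})})


class TestTrainMLP:
    def test_separable_vectors_reach_full_training_accuracy(self):
        rng = np.random.default_rng(0)
        vectors = toy_vectors(rng)
        model, report = train_mlp(vectors, seed=0)
        preds = [classify(model, v).predicted for v, _ in vectors]
        assert preds == [lab for _, lab in vectors]

    def test_conflicting_labels_limit_cv_to_majority_rate(self):
        # identical vectors, labels 2:1 -> irreducible error floor
        vecs = []
        for i in range(12):
            lab = "X" if i % 3 else "Y"
            vecs.append((ScoreVector(f"g{i}", {"X": 1.0, "Y": 1.0}), lab))
        _, report = train_mlp(vecs, seed=0)
        majority = 8 / 12
        assert report["accuracy"] <= majority + 0.25

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        vectors = toy_vectors(rng)
        m1, _ = train_mlp(vectors, seed=5)
        m2, _ = train_mlp(vectors, seed=5)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_clade_with_zero_vectors_rejected(self):
        with pytest.raises(ValueError):
            train_mlp([(ScoreVector("g", {"X": 1.0}), "X")])

    def test_cv_folds_partition_all_genomes(self):
        rng = np.random.default_rng(2)
        vectors = toy_vectors(rng, n_per_clade=10)
        _, report = train_mlp(vectors, seed=0)
        assert report["n_splits"] == 10
        assert sorted(report["fold_predictions"]) == sorted(v.genome_id for v, _ in vectors)


class TestClassify:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        vectors = toy_vectors(rng)
        model, _ = train_mlp(vectors, seed=0)
        res = classify(model, ScoreVector("q", {"X": 2.0, "Y": 1.0, "Z": 1.0}))
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_vector_inside_training_cloud_classified_confidently(self):
        rng = np.random.default_rng(4)
        vectors = toy_vectors(rng, margin=2.0)
        model, _ = train_mlp(vectors, seed=0)
        res = classify(model, ScoreVector("q", {"X": 3.0, "Y": 1.0, "Z": 1.0}))
        assert res.predicted == "X"
        assert res.probabilities["X"] > 0.9

    def test_arity_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        model, _ = train_mlp(toy_vectors(rng), seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(np.array([1.0, 2.0]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        model, _ = train_mlp(toy_vectors(rng), seed=0)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = MLPModel.from_json(p)
        x = np.array([[2.0, 1.0, 0.5]])
        assert back.predict_proba(x) == pytest.approx(model.predict_proba(x))


def _sep_training():
    """Two clades with three class-linked marker columns each (columns 1, 5, 9
    mark clade X in classes F, K, W; columns 4, 8, 12 mark clade Y)."""
    m = SprinzlMap([str(i) for i in range(1, 13)])
    block = {"F": 0, "K": 4, "W": 8}  # each class occupies its own 4 columns
    rows_x, rows_y = [], []
    for g in range(4):
        for cls in "FKW":
            for copy in range(2):
                x = ["-"] * 12
                y = ["-"] * 12
                b = block[cls]
                x[b : b + 4] = list("GAAC")
                y[b : b + 4] = list("CAAT")
                rows_x.append((f"X_g{g}", f"t{cls}{copy}", cls, "".join(x)))
                rows_y.append((f"Y_g{g}", f"t{cls}{copy}", cls, "".join(y)))
    return {"X": make_dataset(m, rows_x), "Y": make_dataset(m, rows_y)}


def _conflict_training():
    """Both clades' only distinguishing letters live in class F, so deleting F
    collapses the clades onto identical data."""
    m = SprinzlMap(["1", "2", "3", "4"])
    rows_x, rows_y = [], []
    for g in range(4):
        for cls in ("F", "K", "W"):
            x = "GCAA" if cls == "F" else "ACAA"
            y = "TCAA" if cls == "F" else "ACAA"
            rows_x.append((f"X_g{g}", f"t{cls}", cls, x))
            rows_y.append((f"Y_g{g}", f"t{cls}", cls, y))
    return {"X": make_dataset(m, rows_x), "Y": make_dataset(m, rows_y)}


class TestBootstrapSupport:
    def _setup(self):
        training = _sep_training()
        from trnacif.multiway import (
            bootstrap_augmented_vectors,
            build_clade_logos,
            training_score_vectors,
        )

        logos = build_clade_logos(training, use_pairs=True, correction="none")
        vectors = training_score_vectors(
            training, loocv=False, use_pairs=True, clade_logos=logos
        )
        aug = bootstrap_augmented_vectors(training, logos, n_aug=25, seed=0)
        model, _ = train_mlp(vectors, seed=0, augmented=aug)
        return training, logos, model

    def test_single_replicate_gives_one_full_support(self):
        training, logos, model = self._setup()
        genome = training["X"].restrict(["X_g0"])
        res = bootstrap_support(genome, logos, model, replicates=1, seed=0)
        assert sorted(res.bootstrap_support.values()) == [0.0, 100.0]

    def test_supports_sum_to_100(self):
        training, logos, model = self._setup()
        genome = training["Y"].restrict(["Y_g1"])
        res = bootstrap_support(genome, logos, model, replicates=37, seed=1)
        assert sum(res.bootstrap_support.values()) == pytest.approx(100.0)

    def test_well_separated_genome_strongly_supported(self):
        training, logos, model = self._setup()
        genome = training["X"].restrict(["X_g2"])
        res = bootstrap_support(genome, logos, model, replicates=100, seed=2)
        assert res.predicted == "X"
        assert res.bootstrap_support["X"] >= 95

    def test_zero_replicates_rejected(self):
        training, logos, model = self._setup()
        with pytest.raises(ValueError):
            bootstrap_support(training["X"].restrict(["X_g0"]), logos, model, replicates=0)


class TestClassDeletion:
    def test_deleting_absent_class_changes_nothing(self):
        training = _sep_training()
        queries = training["X"].restrict(["X_g0"])
        table, changed = class_deletion_analysis(
            training, queries, ["M"], correction="none", seed=0
        )
        base = table[table.deleted_class == "none"].set_index("genome_id").predicted
        after = table[table.deleted_class == "M"].set_index("genome_id").predicted
        assert (base == after).all()
        assert changed["M"] == 0

    def test_deleting_the_marker_class_degrades_classification(self):
        # both clades' only distinguishing letters live in class F, so its
        # deletion collapses the clades and one side's self-classification
        # must flip to the constant prediction
        training = _conflict_training()
        queries = TDNADataset(
            training["X"].sprinzl,
            training["X"].records + training["Y"].records,
        )
        table, changed = class_deletion_analysis(
            training, queries, ["F"], correction="none", seed=0
        )
        base = table[table.deleted_class == "none"].set_index("genome_id").predicted
        assert (base[[g.startswith("X") for g in base.index]] == "X").all()
        assert (base[[g.startswith("Y") for g in base.index]] == "Y").all()
        assert changed["F"] >= 1

    def test_changed_counts_bounded_by_query_count(self):
        training = _sep_training()
        queries = training["X"]
        n_queries = len(queries.by_genome())
        _, changed = class_deletion_analysis(
            training, queries, ["F", "K", "M"], correction="none", seed=0
        )
        assert all(0 <= v <= n_queries for v in changed.values())

    def test_emptied_clade_warns_and_is_retained(self):
        m = SprinzlMap(["1", "2"])
        training = {
            "X": make_dataset(m, [(f"X_g{i}", "tF", "F", "GA") for i in range(3)]),
            "Y": make_dataset(
                m,
                [(f"Y_g{i}", "tF", "F", "TA") for i in range(3)]
                + [(f"Y_g{i}", "tK", "K", "CA") for i in range(3)],
            ),
        }
        queries = training["X"].restrict(["X_g0"])
        with pytest.warns(UserWarning, match="empty logo"):
            table, _ = class_deletion_analysis(
                training, queries, ["F"], correction="none", seed=0
            )
        assert set(table.deleted_class) == {"none", "F"}
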