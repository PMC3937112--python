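import math

import numpy as np
import pytest

from trnacif.dataset import AlignedTDNA, TDNADataset
from trnacif.logo import (
    Feature,
    SampleSizeCorrection,
    background_distribution,
    build_logo,
    count_features,
    export_logo_table,
    extract_cifs,
    feature_information,
    filter_logo,
    import_logo_table,
    permutation_pvalue,
)
from trnacif.sprinzl import SprinzlMap

from conftest import make_dataset
from oracles import brute_force_logo


def S(pos, state):
    return Feature("single", pos, state)


class TestCountFeatures:
    def test_gap_yields_no_feature(self, map3):
        ds = make_dataset(map3, [("g", "t", "F", "AC-")])
        c = count_features(ds, use_pairs=False)
        assert c.n_feat == {S("1", "A"): 1, S("2", "C"): 1}

    def test_class_counts(self, two_class_ds):
        c = count_features(two_class_ds)
        assert c.n_feat[S("2", "A")] == 1
        assert c.n_feat_class[(S("2", "A"), "F")] == 1
        assert c.n_class == {"F": 1, "K": 1}
        assert sum(c.n_class.values()) == c.n_total

    def test_paired_feature_requires_both_ungapped(self, map3):
        ds = make_dataset(map3, [("g", "t1", "F", "AC-"), ("g", "t2", "F", "ACG")])
        c = count_features(ds, use_pairs=True)
        assert c.n_feat[Feature("paired", ("1", "3"), "AG")] == 1
        assert not any(
            f.kind == "paired" and c.n_feat[f] > 1 for f in c.n_feat
        )

    def test_ambiguity_yields_no_feature(self, map3):
        ds = make_dataset(map3, [("g", "t", "F", "ANG")])
        c = count_features(ds, use_pairs=True)
        assert S("2", "N") not in c.n_feat
        assert c.n_feat[S("1", "A")] == 1

    def test_empty_dataset_rejected(self, map3):
        with pytest.raises(ValueError):
            count_features(TDNADataset(map3, []))


class TestBackground:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"F": 3, "K": 1}, {"F": 0.75, "K": 0.25}),
            ({"W": 7}, {"W": 1.0}),
        ],
    )
    def test_empirical_frequencies(self, map2, counts, expected):
        rows = [
            (f"g", f"t{c}{i}", c, "AA") for c, n in counts.items() for i in range(n)
        ]
        bg = background_distribution(count_features(make_dataset(map2, rows)))
        assert bg == pytest.approx(expected)
        assert sum(bg.values()) == pytest.approx(1.0)


class TestFeatureInformation:
    def test_exclusive_feature_uniform_background(self, map2):
        # 10 F carrying A1, 10 K carrying C1: H(bg)=1, H(post)=0
        rows = [("g", f"f{i}", "F", "AA") for i in range(10)] + [
            ("g", f"k{i}", "K", "CA") for i in range(10)
        ]
        c = count_features(make_dataset(map2, rows))
        assert feature_information(c, S("1", "A"), correction="none") == pytest.approx(1.0)

    def test_negative_raw_information_clamped(self, map2):
        # bg {F:.75,K:.25}; feature seen once in each class: post (.5,.5)
        rows = [("g", f"f{i}", "F", "AA") for i in range(3)] + [("g", "k", "K", "AA")]
        rows[1] = ("g", "f1", "F", "CA")
        rows[2] = ("g", "f2", "F", "CA")
        c = count_features(make_dataset(map2, rows))
        # feature A1 carried by 1 F and 1 K
        assert c.n_feat[S("1", "A")] == 2
        assert feature_information(c, S("1", "A"), correction="none") == 0.0

    def test_mc_correction_saturates_at_n1(self, map2):
        rows = [("g", "f", "F", "AA"), ("g", "k", "K", "CC")]
        c = count_features(make_dataset(map2, rows))
        v = feature_information(c, S("1", "A"), correction="mc", mc_reps=2000, seed=0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_unseen_feature_rejected(self, two_class_ds):
        with pytest.raises(KeyError):
            feature_information(count_features(two_class_ds), S("1", "G"))


class TestSampleSizeCorrection:
    def test_matches_closed_form_at_n1(self):
        corr = SampleSizeCorrection({"F": 0.5, "K": 0.5}, mc_reps=500, seed=1)
        assert corr(1) == pytest.approx(1.0)  # e(1) = H(bg) exactly

    def test_cache_order_independent(self):
        a = SampleSizeCorrection({"F": 0.5, "K": 0.5}, mc_reps=500, seed=1)
        b = SampleSizeCorrection({"F": 0.5, "K": 0.5}, mc_reps=500, seed=1)
        x = a(5)
        _ = b(17)
        assert b(5) == x

    def test_decreases_with_sample_size(self):
        corr = SampleSizeCorrection({"F": 0.5, "K": 0.5}, mc_reps=2000, seed=0)
        vals = [corr(n) for n in (2, 4, 8, 16, 64)]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestBuildLogo:
    def test_exclusive_feature_splits_all_height_to_class(self, map2):
        rows = [("g", f"f{i}", "F", "AA") for i in range(5)] + [
            ("g", f"k{i}", "K", "CA") for i in range(5)
        ]
        logo = build_logo(make_dataset(map2, rows), correction="none")
        assert logo.height(S("1", "A"), "F") == pytest.approx(1.0)
        assert logo.height(S("1", "A"), "K") == 0.0

    def test_posterior_equal_background_gives_zero(self, map2):
        rows = [("g", "f", "F", "AA"), ("g", "k", "K", "AA")]
        logo = build_logo(make_dataset(map2, rows), correction="none")
        assert logo.info[S("1", "A")] == 0.0
        assert logo.height(S("1", "A"), "F") == 0.0

    def test_skewed_background_hand_values(self, map2):
        # bg {F:0.8, K:0.2}; feature G1 only in the K record
        rows = [("g", f"f{i}", "F", "AA") for i in range(4)] + [("g", "k", "K", "GA")]
        logo = build_logo(make_dataset(map2, rows), correction="none")
        h_bg = -(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2))
        assert logo.info[S("1", "G")] == pytest.approx(h_bg)  # 0.7219
        assert logo.height(S("1", "G"), "K") == pytest.approx(h_bg)
        assert logo.height(S("1", "G"), "F") == 0.0

    def test_stack_conservation(self, map3):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rows = [
                (
                    "g",
                    f"t{i}",
                    rng.choice(list("FKDE")),
                    "".join(rng.choice(list("ACGT-"), 3)),
                )
                for i in range(rng.integers(2, 15))
            ]
            try:
                logo = build_logo(make_dataset(map3, rows), correction="mc",
                                  mc_reps=100, seed=3)
            except ValueError:
                continue
            for f, info in logo.info.items():
                total = sum(h for (ff, _), h in logo.heights.items() if ff == f)
                assert total == pytest.approx(info, abs=1e-9)

    def test_matches_brute_force_oracle(self, map3):
        rng = np.random.default_rng(11)
        for _ in range(25):
            rows = [
                (
                    "g",
                    f"t{i}",
                    rng.choice(list("FKDEL")),
                    "".join(rng.choice(list("ACGT-"), 3)),
                )
                for i in range(rng.integers(2, 20))
            ]
            ds = make_dataset(map3, rows)
            logo = build_logo(ds, correction="none")
            _, heights = brute_force_logo(
                [(r.cls, r.seq) for r in ds.records],
                list(map3.labels),
                list(map3.pair_list),
            )
            ours = {
                ((f.kind, f.pos, f.state), c): h for (f, c), h in logo.heights.items()
            }
            assert set(ours) == set(heights)
            for k in heights:
                assert ours[k] == pytest.approx(heights[k], abs=1e-9)


class TestExtractCIFs:
    def _logo(self, map2):
        rows = [("g", f"f{i}", "F", "AA") for i in range(5)] + [
            ("g", f"k{i}", "K", "CG") for i in range(5)
        ]
        return build_logo(make_dataset(map2, rows), correction="none")

    def test_threshold_zero_keeps_positive_letters(self, map2):
        logo = self._logo(map2)
        cifs = extract_cifs(logo, 0.0)
        assert all(h > 0 for _, _, h in cifs.members)
        assert len(cifs) == len([h for h in logo.heights.values() if h > 0])

    def test_above_max_height_empty(self, map2):
        assert len(extract_cifs(self._logo(map2), 99.0)) == 0

    def test_members_at_or_above_threshold(self, map2):
        cifs = extract_cifs(self._logo(map2), 0.5)
        assert all(h >= 0.5 for _, _, h in cifs.members)

    def test_negative_threshold_rejected(self, map2):
        with pytest.raises(ValueError):
            extract_cifs(self._logo(map2), -0.1)

    def test_filter_logo_truncates(self, map2):
        logo = self._logo(map2)
        cut = filter_logo(logo, 0.5)
        assert all(h >= 0.5 for h in cut.heights.values())
        assert set(cut.info) == {f for f, _ in cut.heights}


class TestPermutationPvalue:
    def test_exclusive_feature_significant(self, map2):
        rows = [("g", f"f{i}", "F", "AA") for i in range(10)] + [
            ("g", f"k{i}", "K", "CA") for i in range(10)
        ]
        p = permutation_pvalue(make_dataset(map2, rows), S("1", "A"), "F",
                               reps=999, seed=0)
        assert p <= 0.01

    def test_independent_feature_not_significant(self, map2):
        # A2 carried by everyone: height 0 regardless of labels
        rows = [("g", f"f{i}", "F", "CA") for i in range(10)] + [
            ("g", f"k{i}", "K", "GA") for i in range(10)
        ]
        p = permutation_pvalue(make_dataset(map2, rows), S("2", "A"), "F",
                               reps=199, seed=0)
        assert p >= 0.05

    def test_zero_reps_rejected(self, two_class_ds):
        with pytest.raises(ValueError):
            permutation_pvalue(two_class_ds, S("1", "A"), "F", reps=0)


class TestLogoTable:
    def test_round_trip(self, map2, tmp_path):
        rows = [("g", f"f{i}", "F", "AA") for i in range(5)] + [
            ("g", f"k{i}", "K", "CG") for i in range(5)
        ]
        logo = build_logo(make_dataset(map2, rows), correction="none")
        p = tmp_path / "logo.tsv"
        export_logo_table(logo, p)
        df = import_logo_table(p)
        assert len(df) == len(logo.heights)
        export_logo_table(logo, tmp_path / "logo2.tsv")
        assert (tmp_path / "logo2.tsv").read_text() == p.read_text()

    def test_empty_logo_header_only(self, map2, tmp_path):
        rows = [("g", "f", "F", "AA"), ("g", "k", "K", "AA")]
        logo = build_logo(make_dataset(map2, rows), correction="none")
        logo.heights = {}
        p = tmp_path / "empty.tsv"
        export_logo_table(logo, p)
        assert len(import_logo_table(p)) == 0
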