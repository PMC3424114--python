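"""Bi-profile posterior fitting, encoding and feature fusion."""

from collections import Counter

import numpy as np
import pytest

from atpbind import encode_biprofile, fit_biprofile, fuse_features
from atpbind.biprofile import ENCODER_ALPHABETS, build_feature_matrix
from atpbind.windowing import PAD

from conftest import make_window


def brute_force_tables(windows, track_kind, pseudocount):
    """Independent tally: dict-of-Counters recount of the posterior tables."""
    alphabet = ENCODER_ALPHABETS[track_kind]
    w = windows[0].width
    table = np.zeros((w, len(alphabet)))
    for i in range(w):
        counts = Counter(
            win.track_slices[track_kind][i] if track_kind != "aa" else win.aa_slice[i]
            for win in windows
        )
        for j, a in enumerate(alphabet):
            table[i, j] = (counts.get(a, 0) + pseudocount) / (
                len(windows) + pseudocount * len(alphabet)
            )
    return table


class TestFitBiprofile:
    def test_hand_counted_pseudocount_zero(self):
        pos = [make_window("HEC"), make_window("HEE")]
        neg = [make_window("CCC"), make_window("ECC")]
        model = fit_biprofile(pos, neg, "ss3", pseudocount=0.0)
        a = model.alphabet
        # position 1 of positives: always H
        assert model.pos_table[0, a.index("H")] == 1.0
        assert model.pos_table[0, a.index("E")] == 0.0
        # position 3 of positives: C and E each once
        assert model.pos_table[2, a.index("C")] == 0.5
        assert model.pos_table[2, a.index("E")] == 0.5
        # negatives, position 1: C and E each once
        assert model.neg_table[0, a.index("C")] == 0.5

    def test_hand_counted_pseudocount_one(self):
        pos = [make_window("HEC"), make_window("HEE")]
        neg = [make_window("CCC")]
        model = fit_biprofile(pos, neg, "ss3", pseudocount=1.0)
        a = model.alphabet  # (H, E, C, PAD) -> size 4
        assert model.pos_table[0, a.index("H")] == pytest.approx((2 + 1) / (2 + 4))
        assert model.pos_table[0, a.index("C")] == pytest.approx(1 / 6)
        assert model.neg_table[0, a.index("C")] == pytest.approx((1 + 1) / (1 + 4))

    @pytest.mark.parametrize("pseudocount", [0.0, 1.0, 2.5])
    @pytest.mark.parametrize("track_kind", ["ss3", "disorder2", "access2", "aa"])
    def test_matches_brute_force_tally(self, rng, track_kind, pseudocount):
        alphabet = [a for a in ENCODER_ALPHABETS[track_kind] if a != PAD][:4]
        def draw(n):
            return [
                make_window(
                    "".join(rng.choice(alphabet, size=5)), kind=track_kind
                )
                for _ in range(n)
            ]
        pos, neg = draw(7), draw(9)
        model = fit_biprofile(pos, neg, track_kind, pseudocount=pseudocount)
        np.testing.assert_array_almost_equal(
            model.pos_table, brute_force_tables(pos, track_kind, pseudocount), decimal=12
        )
        np.testing.assert_array_almost_equal(
            model.neg_table, brute_force_tables(neg, track_kind, pseudocount), decimal=12
        )

    def test_identical_sets_give_identical_tables(self):
        wins = [make_window("HEC"), make_window("CEH")]
        model = fit_biprofile(wins, wins, "ss3")
        np.testing.assert_array_equal(model.pos_table, model.neg_table)

    def test_rows_sum_to_one(self, rng):
        wins = [make_window("".join(rng.choice(list("HEC"), size=7))) for _ in range(20)]
        for pc in (0.5, 1.0, 3.0):
            model = fit_biprofile(wins[:10], wins[10:], "ss3", pseudocount=pc)
            np.testing.assert_allclose(model.pos_table.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(model.neg_table.sum(axis=1), 1.0, atol=1e-9)

    def test_center_rate_recovery(self, rng):
        # center symbol drawn D with probability p: fitted posterior within 3 SE
        p, n = 0.3, 500
        pos = [
            make_window(
                "O" + ("D" if rng.random() < p else "O") + "O", kind="disorder2"
            )
            for _ in range(n)
        ]
        neg = [make_window("OOO", kind="disorder2") for _ in range(50)]
        model = fit_biprofile(pos, neg, "disorder2", pseudocount=0.0)
        est = model.pos_table[1, model.alphabet.index("D")]
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_monotone_contrast(self):
        neg = [make_window("CCC") for _ in range(4)]
        pos_lo = [make_window("HCC"), make_window("CCC"), make_window("CCC")]
        pos_hi = [make_window("HCC"), make_window("HCC"), make_window("CCC")]
        lo = fit_biprofile(pos_lo, neg, "ss3", pseudocount=1.0)
        hi = fit_biprofile(pos_hi, neg, "ss3", pseudocount=1.0)
        h = lo.alphabet.index("H")
        assert hi.pos_table[0, h] > lo.pos_table[0, h]

    def test_empty_or_mixed_width_rejected(self):
        wins = [make_window("HEC")]
        with pytest.raises(ValueError, match="nonempty"):
            fit_biprofile([], wins, "ss3")
        with pytest.raises(ValueError, match="width"):
            fit_biprofile(wins, [make_window("HECEC")], "ss3")


class TestEncodeBiprofile:
    def test_toy_lookup(self):
        pos = [make_window("HEC"), make_window("HEE")]
        neg = [make_window("CCC"), make_window("ECC")]
        model = fit_biprofile(pos, neg, "ss3", pseudocount=0.0)
        v = encode_biprofile(make_window("HEC"), model)
        a = model.alphabet
        expected = [
            model.pos_table[0, a.index("H")],
            model.pos_table[1, a.index("E")],
            model.pos_table[2, a.index("C")],
            model.neg_table[0, a.index("H")],
            model.neg_table[1, a.index("E")],
            model.neg_table[2, a.index("C")],
        ]
        np.testing.assert_array_equal(v, expected)

    def test_width17_gives_34(self, rng):
        wins = [make_window("".join(rng.choice(list("HEC"), size=17))) for _ in range(6)]
        model = fit_biprofile(wins[:3], wins[3:], "ss3")
        assert encode_biprofile(wins[0], model).shape == (34,)

    def test_uniform_tables_give_constant_vector(self):
        model = fit_biprofile(
            [make_window("HEC")], [make_window("CEH")], "ss3", pseudocount=0.0
        )
        k = len(model.alphabet)
        model.pos_table[:] = 1.0 / k
        model.neg_table[:] = 1.0 / k
        v = encode_biprofile(make_window("EEE"), model)
        np.testing.assert_allclose(v, 1.0 / k)

    def test_width_mismatch_and_unknown_symbol(self):
        model = fit_biprofile([make_window("HEC")], [make_window("CEH")], "ss3")
        with pytest.raises(ValueError, match="width"):
            encode_biprofile(make_window("HECEC"), model)
        bad = make_window("HEC")
        bad.track_slices["ss3"] = "HZC"
        with pytest.raises(ValueError, match="alphabet"):
            encode_biprofile(bad, model)


class TestFuseFeatures:
    @pytest.mark.parametrize(
        "blocks,total",
        [
            ([("LogisticPSSM", 340), ("Bipro-ss", 34)], 374),
            (
                [
                    ("LogisticPSSM", 340),
                    ("Bipro-aa", 34),
                    ("Bipro-ss", 34),
                    ("Bipro-dis", 34),
                    ("Bipro-sa", 34),
                ],
                476,
            ),
            ([("LogisticPSSM", 340)], 340),
        ],
    )
    def test_total_dims(self, blocks, total):
        fv = fuse_features([(n, np.zeros(d)) for n, d in blocks])
        assert fv.total_dim == total

    def test_canonical_order(self):
        fv = fuse_features(
            [("Bipro-ss", np.ones(2)), ("LogisticPSSM", np.zeros(3)), ("Bipro-aa", 2 * np.ones(2))]
        )
        assert [n for n, _ in fv.blocks] == ["LogisticPSSM", "Bipro-aa", "Bipro-ss"]
        np.testing.assert_array_equal(fv.values, [0, 0, 0, 2, 2, 1, 1])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fuse_features([("Bipro-ss", np.ones(2)), ("Bipro-ss", np.ones(2))])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fuse_features([])


def test_build_feature_matrix_requires_encoders(rng):
    wins = [make_window("".join(rng.choice(list("HEC"), size=5))) for _ in range(4)]
    with pytest.raises(ValueError, match="no fitted bi-profile model"):
        build_feature_matrix(wins, ["Bipro-ss"], {})
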