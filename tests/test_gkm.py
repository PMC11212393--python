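"""Gapped k-mer featurization, training, CV metrics and deltaSVM."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from asbqtl._util import AsbqtlError, InputError
from asbqtl.gkm import (
    GkmConfig,
    GkmModel,
    consensus_peaks,
    cross_validate,
    delta_svm,
    featurize,
    normalized_inner_product,
    null_sequences,
    train,
)

RNG = np.random.default_rng(2024)
BASES = list("ACGT")


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, n))


# --- independent enumeration oracle -----------------------------------------

def naive_features(seq, l=10, k=6):
    feats = {}
    for i in range(len(seq) - l + 1):
        win = seq[i:i + l]
        for mask in combinations(range(l), k):
            key = (mask, "".join(win[j] for j in mask))
            feats[key] = feats.get(key, 0) + 1
    return feats


def naive_cosine(a, b):
    fa, fb = naive_features(a), naive_features(b)
    dot = sum(v * fb.get(key, 0) for key, v in fa.items())
    na = sum(v * v for v in fa.values()) ** 0.5
    nb = sum(v * v for v in fb.values()) ** 0.5
    return dot / (na * nb)


NO_RC = GkmConfig(include_revcomp=False)


class TestFeaturize:
    def test_single_window_has_210_unit_features(self):
        f = featurize(rand_seq(10), NO_RC)
        assert len(f) == 210
        assert set(f.values()) == {1}

    def test_revcomp_symmetry(self):
        cfg = GkmConfig(include_revcomp=True)
        assert featurize("A" * 10, cfg) == featurize("T" * 10, cfg)

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            featurize(rand_seq(9), NO_RC)

    def test_windows_with_n_are_skipped(self):
        f = featurize("N" + rand_seq(9), NO_RC)
        assert f == {}

    def test_counts_match_enumeration_oracle(self):
        seq = rand_seq(25)
        f = featurize(seq, NO_RC)
        naive = naive_features(seq)
        assert sum(f.values()) == sum(naive.values())
        assert sorted(f.values()) == sorted(naive.values())

    def test_normalized_inner_product_matches_oracle(self):
        for _ in range(10):
            a, b = rand_seq(20), rand_seq(20)
            assert normalized_inner_product(a, b, NO_RC) == pytest.approx(
                naive_cosine(a, b), abs=1e-9)


class TestConsensusPeaks:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start",
                                           "end", "neglog10p"])

    def test_single_sample_passthrough(self):
        df = self._peaks([("s1", "chr1", 100, 400, 250.0),
                          ("s1", "chr1", 900, 1200, 150.0)])  # 2nd not sig
        cons = consensus_peaks(df, n_samples=1)
        assert len(cons) == 1
        assert (cons.start.iat[0], cons.end.iat[0]) == (100, 400)

    @pytest.mark.parametrize("n_support,kept", [(48, False), (49, True)])
    def test_half_of_samples_voting_boundary(self, n_support, kept):
        rows = [(f"s{i}", "chr1", 100, 400, 250.0) for i in range(n_support)]
        cons = consensus_peaks(self._peaks(rows), n_samples=98)
        assert (len(cons) == 1) == kept

    def test_overlong_region_excluded(self):
        rows = [("s1", "chr1", 0, 2001, 250.0)]
        assert len(consensus_peaks(self._peaks(rows), n_samples=1)) == 0
        rows = [("s1", "chr1", 0, 2000, 250.0)]
        assert len(consensus_peaks(self._peaks(rows), n_samples=1)) == 1

    def test_non_autosome_excluded(self):
        rows = [("s1", "chrX", 100, 400, 250.0)]
        assert len(consensus_peaks(self._peaks(rows), n_samples=1)) == 0

    def test_inconsistent_chromosome_names_raise(self):
        rows = [("s1", "chr1", 100, 400, 250.0), ("s2", "1", 100, 400, 250.0)]
        with pytest.raises(InputError):
            consensus_peaks(self._peaks(rows))

    def test_overlapping_peaks_merge(self):
        rows = [("s1", "chr1", 100, 400, 250.0), ("s2", "chr1", 300, 600, 250.0)]
        cons = consensus_peaks(self._peaks(rows), n_samples=2)
        assert len(cons) == 1
        assert (cons.start.iat[0], cons.end.iat[0]) == (100, 600)
        assert cons.n_samples.iat[0] == 2


class TestNullSequences:
    def test_contract_instance(self):
        rng = np.random.default_rng(8)
        genome = {"chr1": rand_seq(50_000, rng)}
        pos = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1300]})
        cfg = GkmConfig(neg_ratio=5)
        neg = null_sequences(genome, pos, cfg, rng=np.random.default_rng(1))
        assert len(neg) == 5
        assert ((neg.end - neg.start) == 300).all()
        pos_gc = (genome["chr1"][1000:1300].count("G")
                  + genome["chr1"][1000:1300].count("C")) / 300
        assert (abs(neg.gc - pos_gc) <= 0.1 + 1e-9).all()
        # never overlapping the positive
        assert ((neg.end <= 1000) | (neg.start >= 1300)).all()

    def test_deterministic_under_seed(self):
        genome = {"chr1": rand_seq(50_000)}
        pos = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1300]})
        a = null_sequences(genome, pos, rng=np.random.default_rng(5))
        b = null_sequences(genome, pos, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_no_negative_space_raises(self):
        genome = {"chr1": rand_seq(300)}
        pos = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300]})
        with pytest.raises(AsbqtlError):
            null_sequences(genome, pos, GkmConfig(),
                           rng=np.random.default_rng(0), retries_per_level=20)


MOTIF = "GATTACAGAT"


def motif_seqs(n, length=40, rng=None):
    rng = rng or np.random.default_rng(99)
    out = []
    for _ in range(n):
        s = rand_seq(length, rng)
        i = int(rng.integers(0, length - 10))
        out.append(s[:i] + MOTIF + s[i + 10:])
    return out


def background_seqs(n, length=40, rng=None):
    rng = rng or np.random.default_rng(100)
    out = []
    while len(out) < n:
        s = rand_seq(length, rng)
        if MOTIF not in s:
            out.append(s)
    return out


class TestTrain:
    def test_separable_training_accuracy(self):
        pos = motif_seqs(50)
        neg = background_seqs(50)
        model = train(pos, neg, GkmConfig(seed=1))
        dv = model.decision_values(pos + neg)
        assert (dv[:50] > 0).all() and (dv[50:] < 0).all()

    def test_retrain_same_seed_identical(self):
        pos, neg = motif_seqs(20), background_seqs(20)
        m1 = train(pos, neg, GkmConfig(seed=3))
        m2 = train(pos, neg, GkmConfig(seed=3))
        assert np.array_equal(m1.weights, m2.weights)

    def test_empty_class_raises(self):
        with pytest.raises(InputError):
            train([], background_seqs(5), GkmConfig())

    def test_kernel_and_explicit_routes_agree(self):
        pos, neg = motif_seqs(30), background_seqs(30)
        mk = train(pos, neg, GkmConfig(seed=1), method="kernel")
        ml = train(pos, neg, GkmConfig(seed=1), method="linear")
        probes = [rand_seq(10) for _ in range(100)] + [MOTIF]
        sk = np.array([mk.score_lmer(p) for p in probes])
        sl = np.array([ml.score_lmer(p) for p in probes])
        from scipy.stats import spearmanr
        assert spearmanr(sk, sl).statistic > 0.9

    def test_score_linearity_over_windows(self):
        pos, neg = motif_seqs(20), background_seqs(20)
        model = train(pos, neg, GkmConfig(seed=2))
        l = model.config.word_length
        for _ in range(5):
            seq = rand_seq(30)
            total = sum(model.score_lmer(seq[i:i + l])
                        for i in range(len(seq) - l + 1))
            assert model.score_sequence(seq) == pytest.approx(total, rel=1e-9)


class TestCrossValidate:
    def test_separable_classes_perfect_auroc(self):
        cv = cross_validate(motif_seqs(50), background_seqs(50), GkmConfig(seed=4))
        assert cv[cv.fold == "mean"].auroc.iat[0] == 1.0

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(17)
        pos = motif_seqs(100, rng=rng)
        neg = background_seqs(500, rng=rng)
        seqs = pos + neg
        labels = np.array([1] * 100 + [0] * 500)
        rng.shuffle(labels)
        sh_pos = [s for s, t in zip(seqs, labels) if t == 1]
        sh_neg = [s for s, t in zip(seqs, labels) if t == 0]
        cv = cross_validate(sh_pos, sh_neg, GkmConfig(seed=4))
        mean = cv[cv.fold == "mean"].iloc[0]
        assert abs(mean.auroc - 0.5) <= 0.05

    def test_random_scorer_auprc_matches_prevalence(self):
        # the analytic baseline for the metric used by cross_validate: a
        # random scorer's average precision equals class prevalence (1/6 at
        # neg_ratio 5) for large n
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(21)
        labels = np.array([1] * 1000 + [0] * 5000)
        ap = average_precision_score(labels, rng.normal(size=6000))
        assert abs(ap - 1 / 6) <= 0.02

    def test_class_smaller_than_folds_raises(self):
        with pytest.raises(InputError):
            cross_validate(motif_seqs(3), background_seqs(50), GkmConfig())


class TestDeltaSvm:
    def _trained(self):
        return train(motif_seqs(30), background_seqs(30), GkmConfig(seed=6))

    @staticmethod
    def _site(chrom, pos, ref, alt):
        class S:
            pass
        s = S()
        s.chrom, s.pos, s.ref_allele, s.alt_allele = chrom, pos, ref, alt
        return s

    def test_identical_alleles_score_zero(self):
        model = self._trained()
        genome = {"chr1": rand_seq(100)}
        base = genome["chr1"][49]
        assert delta_svm(model, self._site("chr1", 50, base, base), genome) == 0.0

    def test_allele_swap_negates_score(self):
        model = self._trained()
        genome = {"chr1": rand_seq(100)}
        fwd = delta_svm(model, self._site("chr1", 50, "A", "G"), genome)
        rev = delta_svm(model, self._site("chr1", 50, "G", "A"), genome)
        assert fwd == pytest.approx(-rev, abs=1e-12)
        assert fwd != 0.0

    def test_missing_context_is_nan(self):
        model = self._trained()
        genome = {"chr1": rand_seq(100)}
        assert np.isnan(delta_svm(model, self._site("chr1", 5, "A", "G"), genome))

    def test_one_feature_model_matches_hand_count(self):
        # weight on a single gapped k-mer: mask (0..5), letters "ACGTAC"
        cfg = GkmConfig(include_revcomp=False)
        weights = np.zeros(cfg.n_features)
        code = ((0 * 4 + 1) * 4 + 2) * 4 ** 3 + (3 * 16 + 0 * 4 + 1)  # ACGTAC
        weights[code] = 2.5
        model = GkmModel(config=cfg, weights=weights, intercept=0.0,
                         n_pos=1, n_neg=1)
        genome = {"chr1": "TTTTTTTTTACGTACGTTTTTTTTTT"}
        #                    ctx of pos 14 (1-based) = positions 5..23
        site = self._site("chr1", 14, "T", "A")
        ctx = genome["chr1"][4:23]
        l = 10

        def count(seq):
            return sum(seq[i:i + 6] == "ACGTAC" for i in range(l))

        seq_ref = ctx[:9] + "T" + ctx[10:]
        seq_alt = ctx[:9] + "A" + ctx[10:]
        expected = 2.5 * (count(seq_alt) - count(seq_ref))
        got = delta_svm(model, site, genome)
        assert got == pytest.approx(expected)
        assert got != 0.0
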