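"""Gapped k-mer classifier of peak sequence and deltaSVM variant scoring.

A gapped k-mer is an l-length pattern with k informative positions and l-k
wildcards. Every l-bp window of a sequence contributes one count to each of
the C(l, k) (mask, letters) features it realizes; with reverse-complement
counting on, the window's reverse complement is counted too. Sequences under
consensus ChIP-seq peaks (positives) are separated from GC-matched background
segments (negatives, ``neg_ratio`` per positive) by a linear max-margin
classifier on unit-norm feature vectors.

The trained model assigns a weight to every possible l-mer; a variant's
deltaSVM is the sum, over the l windows of its (2l-1)-bp context that cover
the variant, of the alt-window weight minus the ref-window weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from asbqtl._util import AsbqtlError, ConfigError, InputError, is_autosome, substream

_CODE = np.full(128, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_RC = np.array([3, 2, 1, 0, -1], dtype=np.int8)  # complement of base codes; N stays invalid


@dataclass
class GkmConfig:
    word_length: int = 10          # l: window length scored by the classifier
    informative_columns: int = 6   # k: non-wildcard positions per gapped k-mer
    C: float = 1.0                 # soft-margin penalty
    neg_ratio: int = 5             # negatives sampled per positive
    consensus_fraction: float = 0.5
    peak_sig_threshold: float = 200.0  # -log10 P cutoff for per-sample peaks
    max_peak_length: int = 2000
    include_revcomp: bool = True
    folds: int = 5
    seed: int = 0
    #: training-set preparation at desk scale: cap on positive sequences
    #: (deterministic subsample; None = use all) and central crop applied to
    #: training sequences (None = full length). Peaks concentrate motif
    #: signal at their summit, so the center crop keeps most of it.
    max_train_pos: int | None = 150
    train_crop_bp: int | None = 150

    def __post_init__(self) -> None:
        if not 0 < self.informative_columns <= self.word_length:
            raise ConfigError("need 0 < k <= l")
        if self.neg_ratio < 1:
            raise ConfigError("neg_ratio must be >= 1")
        if not 0 < self.consensus_fraction <= 1:
            raise ConfigError("consensus_fraction must be in (0, 1]")

    @property
    def n_masks(self) -> int:
        from math import comb
        return comb(self.word_length, self.informative_columns)

    @property
    def n_features(self) -> int:
        return self.n_masks * 4 ** self.informative_columns


def _masks(config: GkmConfig) -> np.ndarray:
    return np.array(list(combinations(range(config.word_length),
                                      config.informative_columns)), dtype=np.int64)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, config: GkmConfig,
                  masks: np.ndarray) -> np.ndarray:
    """Feature codes of every valid (N-free) window x mask, flattened.

    A feature's global code is mask_index * 4^k + base-4 value of the letters
    at the mask's positions.
    """
    l = config.word_length
    k = config.informative_columns
    if codes.size < l:
        raise InputError(f"sequence shorter than word length {l}")
    win = np.lib.stride_tricks.sliding_window_view(codes, l)
    valid = (win >= 0).all(axis=1)
    win = win[valid].astype(np.int64)
    if win.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    offsets = np.arange(len(masks), dtype=np.int64) * 4 ** k
    vals = win[:, masks] @ pow4  # (n_windows, n_masks)
    vals += offsets[None, :]
    return vals.ravel()


def _seq_codes(seq: str, config: GkmConfig, masks: np.ndarray) -> np.ndarray:
    codes = _encode(seq)
    parts = [_window_codes(codes, config, masks)]
    if config.include_revcomp:
        rc = _RC[codes[::-1]]
        parts.append(_window_codes(rc, config, masks))
    return np.concatenate(parts)


def featurize(seq: str, config: GkmConfig | None = None) -> dict[int, int]:
    """Exact multiset count of gapped k-mer features as {code: count}."""
    config = config or GkmConfig()
    flat = _seq_codes(seq, config, _masks(config))
    codes, counts = np.unique(flat, return_counts=True)
    return dict(zip(codes.tolist(), counts.tolist()))


def featurize_matrix(seqs: Sequence[str], config: GkmConfig) -> sparse.csr_matrix:
    """CSR count matrix, one row per sequence, over the full feature space."""
    masks = _masks(config)
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for seq in seqs:
        codes, counts = np.unique(_seq_codes(seq, config, masks), return_counts=True)
        indices.append(codes.astype(np.int32))
        data.append(counts.astype(np.float64))
        indptr.append(indptr[-1] + len(codes))
    return sparse.csr_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(indices) if indices else np.empty(0, np.int32),
         np.asarray(indptr, dtype=np.int64)),
        shape=(len(seqs), config.n_features),
    )


def _normalize_rows(x: sparse.csr_matrix) -> sparse.csr_matrix:
    """Scale each row to unit Euclidean norm, in place on the CSR data."""
    row_nnz = np.diff(x.indptr)
    rows = np.repeat(np.arange(x.shape[0]), row_nnz)
    norms = np.sqrt(np.bincount(rows, weights=x.data * x.data,
                                minlength=x.shape[0]))
    norms[norms == 0] = 1.0
    x.data /= np.repeat(norms, row_nnz)
    return x


def normalized_inner_product(seq_a: str, seq_b: str,
                             config: GkmConfig | None = None) -> float:
    """Cosine similarity of two sequences' gapped k-mer count vectors."""
    config = config or GkmConfig()
    fa = featurize(seq_a, config)
    fb = featurize(seq_b, config)
    dot = sum(c * fb.get(code, 0) for code, c in fa.items())
    na = np.sqrt(sum(c * c for c in fa.values()))
    nb = np.sqrt(sum(c * c for c in fb.values()))
    return dot / (na * nb)


@dataclass
class GkmModel:
    """Trained linear classifier in gapped k-mer space.

    ``weights`` is dense over the full feature space, so the score of any
    l-mer is the sum of its feature weights — linear in the feature vector.
    """

    config: GkmConfig
    weights: np.ndarray
    intercept: float
    n_pos: int
    n_neg: int
    method: str = "linear"
    _masks_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _get_masks(self) -> np.ndarray:
        if self._masks_cache is None:
            self._masks_cache = _masks(self.config)
        return self._masks_cache

    def score_lmer(self, lmer: str) -> float:
        """Raw weight of one l-bp word (no intercept, no normalization)."""
        if len(lmer) != self.config.word_length:
            raise InputError(f"l-mer must be {self.config.word_length} bp")
        codes = _seq_codes(lmer, self.config, self._get_masks())
        return float(self.weights[codes].sum())

    def score_sequence(self, seq: str) -> float:
        """Sum of window scores; equals weights . features(seq) by linearity."""
        codes = _seq_codes(seq, self.config, self._get_masks())
        return float(self.weights[codes].sum())

    def decision_values(self, seqs: Sequence[str]) -> np.ndarray:
        """Classifier decision values on unit-normalized feature vectors."""
        x = _normalize_rows(featurize_matrix(seqs, self.config))
        return np.asarray(x @ self.weights).ravel() + self.intercept


def consensus_peaks(sample_peaks: pd.DataFrame, n_samples: int | None = None,
                    config: GkmConfig | None = None) -> pd.DataFrame:
    """Merge significant per-sample peaks into consensus regions.

    Per-sample peaks with -log10 P <= threshold are discarded; the rest are
    merged by overlap, and a merged region is kept iff peaks from at least
    ``consensus_fraction`` of samples contribute, it lies on an autosome, and
    it is no longer than ``max_peak_length``.
    """
    config = config or GkmConfig()
    req = {"sample_id", "chrom", "start", "end", "neglog10p"}
    if not req <= set(sample_peaks.columns):
        raise InputError(f"sample peaks need columns {sorted(req)}")
    prefixes = sample_peaks.chrom.astype(str).str.startswith("chr").unique()
    if len(prefixes) > 1:
        raise InputError("inconsistent chromosome naming across samples")
    if n_samples is None:
        n_samples = sample_peaks.sample_id.nunique()
    if n_samples < 1:
        raise InputError("need at least one sample")

    sig = sample_peaks[sample_peaks.neglog10p > config.peak_sig_threshold]
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        members: set[str] = set()
        for r in grp.itertuples():
            if cur_s is None:
                cur_s, cur_e, members = r.start, r.end, {r.sample_id}
            elif r.start < cur_e:
                cur_e = max(cur_e, r.end)
                members.add(r.sample_id)
            else:
                rows.append((chrom, cur_s, cur_e, len(members)))
                cur_s, cur_e, members = r.start, r.end, {r.sample_id}
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, len(members)))
    cons = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_samples"])
    if len(cons) == 0:
        return cons
    keep = (
        (cons.n_samples >= config.consensus_fraction * n_samples)
        & (cons.end - cons.start <= config.max_peak_length)
        & cons.chrom.map(is_autosome)
    )
    return cons[keep].reset_index(drop=True)


def _gc(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / max(1, len(seq))


def null_sequences(genome: Mapping[str, str], positives: pd.DataFrame,
                   config: GkmConfig | None = None,
                   rng: np.random.Generator | None = None,
                   gc_tolerance: float = 0.02,
                   max_tolerance: float = 0.10,
                   retries_per_level: int = 200) -> pd.DataFrame:
    """GC-matched background segments: ``neg_ratio`` per positive.

    Each negative has the positive's exact length, lies outside every
    positive region, contains no N, and matches the positive's GC within the
    tolerance (widened in 0.02 steps with a warning, up to ``max_tolerance``).
    """
    config = config or GkmConfig()
    if rng is None:
        rng = substream(config.seed, "nullseqs")
    excl = {c: grp[["start", "end"]].to_numpy()
            for c, grp in positives.groupby("chrom")}
    chroms = [c for c in genome if c in set(positives.chrom)] or list(genome)
    failures = []
    rows = []
    widened = False
    for prow in positives.itertuples():
        length = int(prow.end - prow.start)
        pos_gc = _gc(str(genome[prow.chrom][prow.start:prow.end]))
        found = 0
        tol = gc_tolerance
        while found < config.neg_ratio and tol <= max_tolerance + 1e-12:
            for _ in range(retries_per_level):
                chrom = chroms[int(rng.integers(len(chroms)))]
                limit = len(genome[chrom]) - length
                if limit <= 0:
                    continue
                s = int(rng.integers(0, limit + 1))
                iv = excl.get(chrom)
                if iv is not None and bool(((iv[:, 0] < s + length) & (s < iv[:, 1])).any()):
                    continue
                seq = str(genome[chrom][s:s + length]).upper()
                if "N" in seq:
                    continue
                if abs(_gc(seq) - pos_gc) <= tol:
                    rows.append((chrom, s, s + length, _gc(seq)))
                    found += 1
                    if found == config.neg_ratio:
                        break
            else:
                tol += 0.02
                widened = True
                continue
            break
        if found < config.neg_ratio:
            failures.append(f"{prow.chrom}:{prow.start}-{prow.end}")
    if widened:
        warnings.warn("GC tolerance widened while sampling null sequences")
    if failures:
        raise AsbqtlError("could not GC-match null sequences for positives: "
                          + ", ".join(failures[:10]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def fetch_sequences(genome: Mapping[str, str], intervals: pd.DataFrame) -> list[str]:
    return [str(genome[r.chrom][r.start:r.end]).upper() for r in intervals.itertuples()]


def _fit_weight_vector(x_norm: sparse.csr_matrix, y: np.ndarray,
                       config: GkmConfig, method: str) -> tuple[np.ndarray, float, str]:
    n = x_norm.shape[0]
    if method == "auto":
        method = "kernel" if n <= 600 else "linear"
    if method == "kernel":
        gram = np.asarray((x_norm @ x_norm.T).todense())
        clf = SVC(kernel="precomputed", C=config.C)
        clf.fit(gram, y)
        w = np.asarray(clf.dual_coef_ @ x_norm[clf.support_]).ravel()
        return w, float(clf.intercept_[0]), "kernel"
    clf = LinearSVC(loss="hinge", C=config.C, random_state=config.seed,
                    max_iter=20000, tol=1e-4)
    clf.fit(x_norm, y)
    return clf.coef_.ravel(), float(clf.intercept_[0]), "linear"


def train(pos: Sequence[str], neg: Sequence[str], config: GkmConfig | None = None,
          method: str = "auto") -> GkmModel:
    """Train the max-margin classifier on unit-norm gapped k-mer vectors.

    ``method="kernel"`` solves the dual with a precomputed normalized gram;
    ``method="linear"`` solves the same hinge-loss problem on the explicit
    sparse features (scales to larger training sets). Both represent the
    model as one dense weight vector over the feature space, so any l-mer's
    score is a plain feature-weight sum.
    """
    config = config or GkmConfig()
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both training classes must be nonempty")
    ratio = max(len(pos), len(neg)) / min(len(pos), len(neg))
    if ratio > 100:
        warnings.warn(f"extreme class imbalance ({ratio:.0f}:1)")
    x = _normalize_rows(featurize_matrix(list(pos) + list(neg), config))
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    w, b, used = _fit_weight_vector(x, y, config, method)
    return GkmModel(config=config, weights=w, intercept=b,
                    n_pos=len(pos), n_neg=len(neg), method=used)


def cross_validate(pos: Sequence[str], neg: Sequence[str],
                   config: GkmConfig | None = None,
                   method: str = "auto") -> pd.DataFrame:
    """Stratified k-fold CV; returns per-fold and mean auROC / auPRC."""
    config = config or GkmConfig()
    if len(pos) < config.folds or len(neg) < config.folds:
        raise InputError("each class needs at least `folds` members")
    seqs = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    x = _normalize_rows(featurize_matrix(seqs, config))
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise AsbqtlError(f"fold {fold} contains a single class")
        w, b, _ = _fit_weight_vector(x[tr], y[tr], config, method)
        scores = np.asarray(x[te] @ w).ravel() + b
        rows.append((fold,
                     roc_auc_score(y[te] > 0, scores),
                     average_precision_score(y[te] > 0, scores)))
    df = pd.DataFrame(rows, columns=["fold", "auroc", "auprc"])
    df.loc[len(df)] = ("mean", df.auroc.mean(), df.auprc.mean())
    return df


def variant_context(genome: Mapping[str, str], chrom: str, pos: int,
                    l: int) -> str | None:
    """(2l-1)-bp plus-strand context centered on a 1-based site; None if the
    context runs off the contig or contains N."""
    half = l - 1
    seq = genome[chrom]
    if pos - half < 1 or pos + half > len(seq):
        return None
    ctx = str(seq[pos - 1 - half:pos + half]).upper()
    if "N" in ctx:
        return None
    return ctx


def delta_svm(model: GkmModel, site, genome: Mapping[str, str]) -> float:
    """deltaSVM of one variant: build the (2l-1)-bp context, mask the middle
    base, fill with ref and alt, and sum alt-minus-ref scores over the l
    sliding windows covering the variant. NaN when context is unavailable."""
    l = model.config.word_length
    ctx = variant_context(genome, site.chrom, site.pos, l)
    if ctx is None:
        return float("nan")
    mid = l - 1
    seq_ref = ctx[:mid] + site.ref_allele.upper() + ctx[mid + 1:]
    seq_alt = ctx[:mid] + site.alt_allele.upper() + ctx[mid + 1:]
    total = 0.0
    for i in range(l):
        total += model.score_lmer(seq_alt[i:i + l]) - model.score_lmer(seq_ref[i:i + l])
    return total


def delta_svm_table(model: GkmModel, sites, genome: Mapping[str, str]) -> pd.DataFrame:
    rows = [(s.site_id, delta_svm(model, s, genome)) for s in sites]
    return pd.DataFrame(rows, columns=["site_id", "delta_svm"])
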