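"""Gapped k-mer sequence model for chromatin accessibility.

A sequence is represented in the explicit gapped k-mer feature space: every
length-``l`` window contributes one count to each of the C(l, k) position
masks, indexed by the k informative letters at the masked positions.  A
linear soft-margin classifier trained on accessible (summit-centered) versus
matched background sequences then assigns every sequence a real-valued
accessibility score — the dot product of its feature counts with the learned
weights plus a bias.  Scoring is exact (no kernel truncation), which keeps
every score reproducible and auditable against brute-force k-mer counting.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space


@dataclass(frozen=True)
class GkmParams:
    """Hyper-parameters of the gapped k-mer feature map and classifier.

    ``l`` is the window (word) length, ``k`` the number of informative
    columns, ``d`` the maximum mismatch parameter of approximate gkm kernels
    — accepted for interface parity but inert here, since the feature space
    is realized exactly.  ``C`` is the SVM regularization strength.
    ``normalize`` applies the usual cosine (unit-norm) kernel normalization
    to feature vectors before the SVM, so sequence length and low-complexity
    content do not dominate the margin.
    """

    l: int = 10
    k: int = 6
    d: int = 3
    C: float = 1.0
    collapse_revcomp: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.l):
            raise ValueError(f"require 1 <= k <= l, got k={self.k}, l={self.l}")
        if self.l > 12:
            raise ValueError(f"l={self.l} > 12 exceeds the explicit-feature limit")


@dataclass
class TrainingSet:
    """Equal-length positive (summit-centered) and background sequences."""

    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.positives} | {len(s) for s in self.negatives}
        if len(lengths) > 1:
            raise ValueError(f"training sequences have mixed lengths: {sorted(lengths)}")


class FeatureSpace:
    """Explicit index of gapped k-mer features for fixed (l, k).

    Raw features are pairs (position mask, k-letter word); there are
    C(l, k) * 4**k of them.  With reverse-complement collapsing, each raw
    feature is mapped to the canonical member (smallest raw id) of its
    strand-equivalence class.
    """

    def __init__(self, params: GkmParams):
        self.params = params
        l, k = params.l, params.k
        self.masks = list(itertools.combinations(range(l), k))
        self.n_masks = len(self.masks)
        self.n_words = 4**k
        self.n_raw = self.n_masks * self.n_words
        self._mask_index = {m: i for i, m in enumerate(self.masks)}
        if params.collapse_revcomp:
            self._canon_raw, self._raw_to_feature, self.n_features = self._collapse()
        else:
            self._canon_raw = None
            self._raw_to_feature = None
            self.n_features = self.n_raw

    # -- reverse-complement algebra -------------------------------------

    def _rc_raw_ids(self) -> np.ndarray:
        """Raw id of the reverse complement of every raw feature."""
        l, k = self.params.l, self.params.k
        n_words = self.n_words
        # words enumerated base-4, most significant digit = first masked position
        powers = 4 ** np.arange(k - 1, -1, -1)
        words = np.arange(n_words)
        digits = (words[:, None] // powers[None, :]) % 4  # (n_words, k)
        rc_digits = _COMPLEMENT_IDX[digits[:, ::-1]]
        rc_words = rc_digits @ powers
        rc = np.empty(self.n_raw, dtype=np.int64)
        for mi, mask in enumerate(self.masks):
            rc_mask = tuple(sorted(l - 1 - p for p in mask))
            rmi = self._mask_index[rc_mask]
            rc[mi * n_words : (mi + 1) * n_words] = rmi * n_words + rc_words
        return rc

    def _collapse(self):
        rc = self._rc_raw_ids()
        canon = np.minimum(np.arange(self.n_raw), rc)
        reps = np.unique(canon)
        raw_to_feature = np.empty(self.n_raw, dtype=np.int64)
        raw_to_feature[reps] = np.arange(reps.size)
        raw_to_feature = raw_to_feature[canon]
        return canon, raw_to_feature, reps.size

    # -- featurization ---------------------------------------------------

    def encode(self, seq: str) -> np.ndarray:
        """Map a DNA string to base indices; anything not ACGT becomes -1."""
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        out = np.full(arr.size, -1, dtype=np.int8)
        for base, idx in _BASE_INDEX.items():
            out[arr == ord(base)] = idx
        return out

    def raw_feature_ids(self, seq: str) -> np.ndarray:
        """Raw feature id of every (valid window, mask) pair, with multiplicity."""
        l, k = self.params.l, self.params.k
        enc = self.encode(seq)
        if enc.size < l:
            raise ValueError(f"sequence length {enc.size} < word length l={l}")
        n_win = enc.size - l + 1
        # windows containing N (or any non-ACGT base) are skipped entirely
        bad = enc < 0
        valid = ~np.array(
            [bad[s : s + l].any() for s in range(n_win)]
        ) if bad.any() else np.ones(n_win, dtype=bool)
        starts = np.nonzero(valid)[0]
        if starts.size == 0:
            raise ValueError("no valid l-length window (sequence is all ambiguous)")
        powers = 4 ** np.arange(k - 1, -1, -1)
        ids = np.empty(starts.size * self.n_masks, dtype=np.int64)
        for mi, mask in enumerate(self.masks):
            word = np.zeros(starts.size, dtype=np.int64)
            for j, p in enumerate(mask):
                word += enc[starts + p].astype(np.int64) * powers[j]
            ids[mi * starts.size : (mi + 1) * starts.size] = mi * self.n_words + word
        return ids

    def featurize(self, seq: str) -> sp.csr_matrix:
        """Sparse (1 x n_features) count vector of gapped k-mers in ``seq``."""
        ids = self.raw_feature_ids(seq)
        if self._raw_to_feature is not None:
            ids = self._raw_to_feature[ids]
        cols, counts = np.unique(ids, return_counts=True)
        return sp.csr_matrix(
            (counts.astype(np.float64), (np.zeros_like(cols), cols)),
            shape=(1, self.n_features),
        )

    def featurize_many(self, seqs) -> sp.csr_matrix:
        return sp.vstack([self.featurize(s) for s in seqs], format="csr")


def enumerate_feature_space(params: GkmParams) -> FeatureSpace:
    """Build the explicit feature index for ``params``.

    The raw cardinality is C(l, k) * 4**k; with reverse-complement collapsing
    strand-equivalent features are merged (``n_features`` <= ``n_raw``).
    """
    return FeatureSpace(params)


def featurize(seq: str, params: GkmParams | FeatureSpace) -> sp.csr_matrix:
    space = params if isinstance(params, FeatureSpace) else FeatureSpace(params)
    return space.featurize(seq)


def gapped_pair_count(x: str, y: str, params: GkmParams) -> int:
    """Brute-force count of matching gapped k-mer pairs between two sequences.

    For every pair of l-windows (u from x, v from y) and every k-position
    mask, count 1 if u and v agree at the masked positions.  Equals the dot
    product of the explicit (non-collapsed) feature vectors; O(|x||y|C(l,k)l)
    — an independent oracle, kept deliberately naive.
    """
    if params.collapse_revcomp:
        raise ValueError("pair-count oracle is defined on the non-collapsed space")
    l = params.l
    masks = list(itertools.combinations(range(l), params.k))
    total = 0
    for i in range(len(x) - l + 1):
        u = x[i : i + l].upper()
        if any(c not in _BASE_INDEX for c in u):
            continue
        for j in range(len(y) - l + 1):
            v = y[j : j + l].upper()
            if any(c not in _BASE_INDEX for c in v):
                continue
            for mask in masks:
                if all(u[p] == v[p] for p in mask):
                    total += 1
    return total


# -- training-set construction ------------------------------------------


def _gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def _repeat_fraction(seq: str) -> float:
    """Lowercase (soft-masked repeat) proportion of a sequence."""
    return sum(c.islower() for c in seq) / max(len(seq), 1)


def _bin_index(value: float, n_bins: int) -> int:
    return min(int(value * n_bins), n_bins - 1)


def extract_positive_set(genome, peaks, width: int = 100) -> list[str]:
    """Summit-centered ``width``-bp sequences, the positive training set."""
    from .io import fetch_sequence

    half = width // 2
    out = []
    for pk in peaks:
        seq = fetch_sequence(genome, pk.chrom, pk.summit - half, pk.summit - half + width)
        if len(seq) == width:
            out.append(seq)
    return out


def build_negative_set(
    genome,
    positives: list[str],
    excluded_regions,
    n_ratio: int = 1,
    n_bins: int = 10,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> list[str]:
    """Sample background sequences matched to the positives.

    Positives are binned on a fixed (GC decile x repeat-fraction decile)
    grid; negatives are drawn uniformly from the genome, rejected if they
    overlap ``excluded_regions`` (the relaxed accessibility set — by default
    callers pass the peaks padded +/-500 bp) or contain ambiguous bases, and
    accepted into a bin until every bin holds ``n_ratio`` times its positive
    count.
    """
    from .io import contig_lengths, fetch_sequence

    rng = np.random.default_rng(seed)
    width = len(positives[0])
    need: dict[tuple[int, int], int] = {}
    for seq in positives:
        b = (_bin_index(_gc_fraction(seq), n_bins), _bin_index(_repeat_fraction(seq), n_bins))
        need[b] = need.get(b, 0) + n_ratio

    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in excluded_regions:
        excl.setdefault(chrom, []).append((int(start), int(end)))

    lengths = contig_lengths(genome)
    chroms = sorted(lengths)
    sizes = np.array([lengths[c] - width for c in chroms], dtype=np.float64)
    if (sizes <= 0).any():
        raise ValueError("a contig is shorter than the training-sequence width")
    probs = sizes / sizes.sum()

    negatives: list[str] = []
    remaining = dict(need)
    for _ in range(max_attempts):
        if not remaining:
            break
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        start = int(rng.integers(0, lengths[chrom] - width))
        if any(start < e and start + width > s for s, e in excl.get(chrom, ())):
            continue
        seq = fetch_sequence(genome, chrom, start, start + width)
        if any(c.upper() not in _BASE_INDEX for c in seq):
            continue
        b = (_bin_index(_gc_fraction(seq), n_bins), _bin_index(_repeat_fraction(seq), n_bins))
        if remaining.get(b, 0) > 0:
            negatives.append(seq)
            remaining[b] -= 1
            if remaining[b] == 0:
                del remaining[b]
    if remaining:
        worst = max(remaining.items(), key=lambda kv: kv[1])
        raise RuntimeError(
            f"negative sampling exhausted: bin (gc_decile={worst[0][0]}, "
            f"repeat_decile={worst[0][1]}) still needs {worst[1]} sequences"
        )
    return negatives


# -- the trained model ---------------------------------------------------


@dataclass
class SequenceModel:
    """Linear accessibility scorer in the explicit gapped k-mer space."""

    params: GkmParams
    weights: np.ndarray
    bias: float
    cv_auc: float = float("nan")
    space: FeatureSpace = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.space is None:
            self.space = FeatureSpace(self.params)
        if self.weights.shape != (self.space.n_features,):
            raise ValueError("weight vector does not match the feature space")

    def score(self, seq: str) -> float:
        """Decision value dot(weights, features(seq)) + bias.

        With ``params.normalize`` the feature vector is unit-L2-normalized
        first (cosine kernel convention).
        """
        x = _maybe_normalize(self.space.featurize(seq), self.params)
        return float((x @ self.weights)[0]) + self.bias

    def score_many(self, seqs) -> np.ndarray:
        X = _maybe_normalize(self.space.featurize_many(seqs), self.params)
        return np.asarray(X @ self.weights).ravel() + self.bias

    # -- persistence: TSV of nonzero weights + JSON header ---------------

    def save(self, weights_path, header_path) -> None:
        nz = np.nonzero(self.weights)[0]
        with open(weights_path, "w") as fh:
            fh.write("feature_id\tweight\n")
            for i in nz:
                fh.write(f"{i}\t{float(self.weights[i])!r}\n")
        header = {
            "format_version": 1,
            "l": self.params.l,
            "k": self.params.k,
            "d": self.params.d,
            "C": self.params.C,
            "collapse_revcomp": self.params.collapse_revcomp,
            "normalize": self.params.normalize,
            "bias": self.bias,
            "cv_auc": self.cv_auc,
            "n_features": int(self.space.n_features),
        }
        with open(header_path, "w") as fh:
            json.dump(header, fh, indent=2)

    @classmethod
    def load(cls, weights_path, header_path) -> "SequenceModel":
        with open(header_path) as fh:
            h = json.load(fh)
        params = GkmParams(
            l=h["l"], k=h["k"], d=h["d"], C=h["C"],
            collapse_revcomp=h["collapse_revcomp"],
            normalize=h.get("normalize", True),
        )
        space = FeatureSpace(params)
        w = np.zeros(space.n_features)
        with open(weights_path) as fh:
            next(fh)
            for line in fh:
                i, v = line.split("\t")
                w[int(i)] = float(v)
        return cls(params=params, weights=w, bias=h["bias"], cv_auc=h["cv_auc"], space=space)


def train_classifier(
    training: TrainingSet,
    params_grid=None,
    folds: int = 3,
    seed: int = 0,
) -> SequenceModel:
    """Cross-validated linear SVM over the gapped k-mer feature space.

    Each grid point (default: C in {0.1, 1, 10} at the base parameters) is
    scored by mean ROC AUC over ``folds`` stratified folds; the best point is
    refit on all data.  Hinge loss with balanced class weights; deterministic
    given ``seed``.
    """
    if params_grid is None:
        params_grid = [GkmParams()]
    if isinstance(params_grid, GkmParams):
        params_grid = [replace(params_grid, C=c) for c in (0.1, 1.0, 10.0)]
    n_pos, n_neg = len(training.positives), len(training.negatives)
    if min(n_pos, n_neg) < 10 * folds:
        raise ValueError(
            f"need >= {10 * folds} sequences per class for {folds}-fold CV, "
            f"got {n_pos} positives / {n_neg} negatives"
        )
    seqs = list(training.positives) + list(training.negatives)
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)]

    spaces: dict[tuple, FeatureSpace] = {}
    feats: dict[tuple, sp.csr_matrix] = {}
    best = None
    for params in params_grid:
        key = (params.l, params.k, params.collapse_revcomp, params.normalize)
        if key not in spaces:
            spaces[key] = FeatureSpace(params)
            feats[key] = _maybe_normalize(spaces[key].featurize_many(seqs), params)
        X = feats[key]
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in cv.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError("degenerate labels in a cross-validation fold")
            clf = _svc(params.C, seed)
            clf.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        mean_auc = float(np.mean(aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, key)

    cv_auc, params, key = best
    clf = _svc(params.C, seed)
    clf.fit(feats[key], y)
    return SequenceModel(
        params=params,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        cv_auc=cv_auc,
        space=spaces[key],
    )


def _maybe_normalize(X: sp.csr_matrix, params: GkmParams) -> sp.csr_matrix:
    if not params.normalize:
        return X
    from sklearn.preprocessing import normalize as _l2

    return _l2(X)


def _svc(C: float, seed: int) -> LinearSVC:
    return LinearSVC(
        C=C,
        loss="hinge",
        class_weight="balanced",
        dual=True,
        tol=1e-6,
        max_iter=20000,
        random_state=seed,
    )


def score_sequence(model: SequenceModel, seq: str) -> float:
    return model.score(seq)
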