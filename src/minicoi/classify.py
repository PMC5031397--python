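"""Taxonomic assignment of mini-barcode sequences.

Two classifiers, both sklearn-style estimators (``fit`` / ``predict`` /
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) so they compose with sklearn model selection:

``NaiveBayesKmerClassifier``
    A bootstrap naive-Bayes word classifier.  Training records each
    species' set of overlapping k-mers (word *presence*, not frequency).
    With N training sequences of which n(w) contain word w, the word prior
    is P(w) = (n(w) + 0.5) / (N + 1), and the per-species conditional is
    P(w|S) = (m(w,S) + P(w)) / (M(S) + 1) where m(w,S) of the M(S) sequences
    of species S contain w.  A query is scored by the product of P(w|S) over
    its distinct words; confidence at each rank is estimated by bootstrap:
    each trial re-scores a with-replacement sample of ceil(W * fraction) of
    the query's W distinct words and the confidence is the fraction of
    trials whose winning species agrees with the full-data candidate at that
    rank.  Confidence is therefore non-decreasing from species toward order.

``TopHitClassifier``
    Best-identity assignment against the reference set: the tie set of
    references within ``tie_epsilon`` of the best global-alignment identity
    determines the call, assigned at the deepest rank unanimous across the
    tie set.

Training is at the species level with rank rollup for shallower ranks;
genus-or-shallower labels can be used directly by supplying them as ``y``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .reflib import ReferenceLibrary, sequence_identity
from .seqcore import RANKS, TaxonLineage

__all__ = [
    "ClassifierParams",
    "Call",
    "TopHitResult",
    "NaiveBayesKmerClassifier",
    "TopHitClassifier",
    "train_bayes",
    "classify_bayes",
    "classify_tophit",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Bootstrap naive-Bayes parameters (threading convenience for the
    pipeline-facing wrappers)."""

    confidence: float = 0.8
    n_bootstrap: int = 100
    word_fraction: float = 0.125
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.word_fraction <= 1:
            raise ValueError("word_fraction must be in (0, 1]")


@dataclass
class Call:
    """A per-rank classification with bootstrap confidences.

    ``assignments`` maps rank -> (taxon, confidence); confidence is
    non-decreasing from species toward order.  ``accepted(c)`` returns the
    deepest rank whose confidence reaches the threshold.
    """

    query_id: str
    candidate_species: str
    assignments: dict  # rank -> (taxon or None, confidence)

    def confidence(self, rank: str) -> float:
        return self.assignments[rank][1]

    def taxon(self, rank: str) -> Optional[str]:
        return self.assignments[rank][0]

    def accepted(self, c: float):
        """(rank, taxon) of the deepest rank with confidence >= c, or
        ("unclassified", None)."""
        for rank in RANKS:
            taxon, conf = self.assignments[rank]
            if taxon is not None and conf >= c:
                return rank, taxon
        return "unclassified", None


@dataclass
class TopHitResult:
    query_id: str
    best_identity: float
    tie_species: list            # species of the tie-set references, sorted
    assigned_rank: str           # deepest unanimous rank or "unclassified"
    assigned_taxon: Optional[str]


def _kmers(seq: str, k: int) -> list:
    return sorted({seq[i:i + k] for i in range(len(seq) - k + 1)})


class NaiveBayesKmerClassifier(BaseEstimator):
    """Bootstrap naive-Bayes k-mer classifier (see module docstring).

    Parameters
    ----------
    k : word size (default 8).
    confidence : acceptance threshold applied by :meth:`predict_calls`
        consumers; the working default of 0.8 trades correctly classified
        sequences against the risk of false positives.
    n_bootstrap : bootstrap trials per query (default 100).
    word_fraction : fraction of the query's distinct words drawn (with
        replacement) per trial (default 1/8).
    random_state : seed for the bootstrap RNG; classification is
        bit-reproducible for a fixed seed.
    """

    def __init__(self, k: int = 8, confidence: float = 0.8,
                 n_bootstrap: int = 100, word_fraction: float = 0.125,
                 random_state: int = 1):
        self.k = k
        self.confidence = confidence
        self.n_bootstrap = n_bootstrap
        self.word_fraction = word_fraction
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def fit(self, X: Sequence[str], y: Sequence[str],
            lineages: Optional[Mapping[str, TaxonLineage]] = None):
        """Train on sequences ``X`` labelled with species names ``y``.

        ``lineages`` maps species -> TaxonLineage for rank rollup; species
        without an entry roll up through the first token of their binomial
        as genus.  Sequences shorter than ``k`` are rejected and listed in
        ``rejected_``.
        """
        X, y = list(X), list(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.rejected_ = [i for i, s in enumerate(X) if len(s) < self.k]
        keep = [i for i in range(len(X)) if i not in set(self.rejected_)]
        if not keep:
            raise ValueError("no training sequence is at least k long")
        X = [X[i] for i in keep]
        y = [y[i] for i in keep]

        self.species_ = np.array(sorted(set(y)))
        sidx = {s: i for i, s in enumerate(self.species_)}
        self.vocab_ = {}
        rows, cols = [], []
        M = np.zeros(len(self.species_), dtype=np.int64)
        for seq, sp in zip(X, y):
            j = sidx[sp]
            M[j] += 1
            for w in _kmers(seq, self.k):
                wi = self.vocab_.setdefault(w, len(self.vocab_))
                rows.append(wi)
                cols.append(j)
        data = np.ones(len(rows), dtype=np.int64)
        self.m_ = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.vocab_), len(self.species_)))
        self.M_ = M
        self.N_ = int(M.sum())
        self.n_ = np.asarray(self.m_.sum(axis=1)).ravel()
        self.prior_ = (self.n_ + 0.5) / (self.N_ + 1)
        self.log_M1_ = np.log(self.M_ + 1.0)

        lineages = dict(lineages or {})
        self.lineage_map_ = {}
        for sp in self.species_:
            lin = lineages.get(sp)
            if lin is None:
                genus = sp.split()[0] if " " in sp else None
                lin = TaxonLineage(genus=genus, species=sp if genus else None,
                                   order=None, family=None)
                if genus is None:
                    lin = TaxonLineage()
            self.lineage_map_[sp] = lin
        # taxon-at-rank lookup tables for fast bootstrap agreement counting
        self._rank_labels_ = {}
        for rank in RANKS:
            if rank == "species":
                self._rank_labels_[rank] = np.array(
                    [sp for sp in self.species_], dtype=object)
            else:
                self._rank_labels_[rank] = np.array(
                    [self.lineage_map_[sp].get(rank) for sp in self.species_],
                    dtype=object)
        return self

    # -- scoring -----------------------------------------------------------

    def _query_matrix(self, seq: str):
        """Per-word log P(w|S) numerators for the query's distinct words.

        Returns (A, n_unseen) where A is (n_seen_words, n_species) of
        log(m(w,S) + P(w)); words absent from training contribute the
        species-independent numerator log(0.5 / (N+1)) and the shared
        denominator, so only their count matters.
        """
        words = _kmers(seq, self.k)
        idx = [self.vocab_[w] for w in words if w in self.vocab_]
        n_unseen = len(words) - len(idx)
        if idx:
            sub = self.m_[idx].toarray().astype(float)
            A = np.log(sub + self.prior_[idx][:, None])
        else:
            A = np.zeros((0, len(self.species_)))
        return A, n_unseen

    def _full_scores(self, A: np.ndarray, n_unseen: int) -> np.ndarray:
        W = A.shape[0] + n_unseen
        const = n_unseen * math.log(0.5 / (self.N_ + 1))
        return A.sum(axis=0) + const - W * self.log_M1_

    def predict_call(self, seq: str, query_id: str = "",
                     rng: Optional[np.random.Generator] = None) -> Call:
        """Classify one query: full-word candidate plus bootstrap
        confidences at every rank."""
        if len(seq) < self.k:
            raise ValueError(f"query shorter than k={self.k}")
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        A, n_unseen = self._query_matrix(seq)
        full = self._full_scores(A, n_unseen)
        cand = int(np.argmax(full))  # argmax takes the first = lexicographic
        W = A.shape[0] + n_unseen
        n_sub = max(1, math.ceil(W * self.word_fraction))
        # counts over the W distinct words, seen words first
        counts = rng.multinomial(n_sub, np.full(W, 1.0 / W),
                                 size=self.n_bootstrap)
        seen = counts[:, :A.shape[0]].astype(float)
        unseen_ct = counts[:, A.shape[0]:].sum(axis=1).astype(float)
        scores = seen @ A + unseen_ct[:, None] * math.log(0.5 / (self.N_ + 1))
        scores -= n_sub * self.log_M1_[None, :]
        winners = np.argmax(scores, axis=1)

        assignments = {}
        for rank in RANKS:
            labels = self._rank_labels_[rank]
            taxon = labels[cand]
            if taxon is None:
                assignments[rank] = (None, 0.0)
                continue
            agree = np.mean(labels[winners] == taxon)
            assignments[rank] = (taxon, float(agree))
        return Call(query_id=query_id, candidate_species=str(self.species_[cand]),
                    assignments=assignments)

    def predict_calls(self, X: Sequence[str],
                      ids: Optional[Sequence[str]] = None) -> list:
        """Classify queries; one bootstrap RNG stream seeded by
        ``random_state`` covers the batch (bit-reproducible)."""
        rng = np.random.default_rng(self.random_state)
        ids = list(ids) if ids is not None else [f"q{i}" for i in range(len(X))]
        return [self.predict_call(s, query_id=i, rng=rng)
                for s, i in zip(X, ids)]

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Maximum-likelihood species per query (unthresholded; use
        :meth:`predict_calls` + ``Call.accepted`` for confidence-filtered
        assignments)."""
        out = []
        for seq in X:
            A, n_unseen = self._query_matrix(seq)
            out.append(self.species_[int(np.argmax(self._full_scores(A, n_unseen)))])
        return np.array(out, dtype=object)


class TopHitClassifier(BaseEstimator):
    """Top-hit identity classifier over a reference set.

    The tie set comprises references within ``tie_epsilon`` of the best
    identity; the assignment is the deepest rank unanimous across the tie
    set's lineages.
    """

    def __init__(self, tie_epsilon: float = 0.0):
        self.tie_epsilon = tie_epsilon

    def fit(self, X: Sequence[str], y: Sequence[str],
            lineages: Optional[Mapping[str, TaxonLineage]] = None):
        X, y = list(X), list(y)
        if not X:
            raise ValueError("empty reference set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.sequences_ = X
        self.labels_ = y
        lineages = dict(lineages or {})
        self.lineage_map_ = {}
        for sp in set(y):
            lin = lineages.get(sp)
            if lin is None:
                genus = sp.split()[0] if " " in sp else None
                lin = TaxonLineage(genus=genus, species=sp) if genus else TaxonLineage()
            self.lineage_map_[sp] = lin
        return self

    def predict_tophit(self, seq: str, query_id: str = "",
                       exclude: Optional[set] = None) -> TopHitResult:
        """Best-identity call for one query; ``exclude`` drops reference
        indices (used for leave-self-out panel evaluation)."""
        ident = np.array([
            -1.0 if (exclude and i in exclude)
            else sequence_identity(seq, ref)
            for i, ref in enumerate(self.sequences_)
        ])
        best = float(ident.max())
        if best < 0:
            raise ValueError("all references excluded")
        tie = [self.labels_[i] for i in np.flatnonzero(ident >= best - self.tie_epsilon)]
        tie_species = sorted(set(tie))
        lins = [self.lineage_map_[s] for s in tie_species]
        rank_taxon = ("unclassified", None)
        for rank in RANKS:
            names = {lin.get(rank) for lin in lins}
            if len(names) == 1 and None not in names:
                rank_taxon = (rank, names.pop())
                break
        return TopHitResult(query_id=query_id, best_identity=best,
                            tie_species=tie_species,
                            assigned_rank=rank_taxon[0],
                            assigned_taxon=rank_taxon[1])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.array([self.predict_tophit(s).assigned_taxon for s in X],
                        dtype=object)


# ---------------------------------------------------------------------------
# Pipeline-facing wrappers and serialization
# ---------------------------------------------------------------------------

def train_bayes(library: Iterable, k: int = 8,
                params: ClassifierParams = ClassifierParams()) -> NaiveBayesKmerClassifier:
    """Train a naive-Bayes classifier from a reference library (RefRecords
    trimmed to the amplicon region, species-level lineages)."""
    records = list(library)
    X, y, lineages = [], [], {}
    clf = NaiveBayesKmerClassifier(
        k=k, confidence=params.confidence, n_bootstrap=params.n_bootstrap,
        word_fraction=params.word_fraction, random_state=params.seed)
    for rec in records:
        sp = rec.lineage.species
        if not sp:
            raise ValueError(f"{rec.id}: species-level lineage required for training")
        X.append(rec.sequence)
        y.append(sp)
        lineages[sp] = rec.lineage
    clf.fit(X, y, lineages=lineages)
    return clf


def classify_bayes(model: NaiveBayesKmerClassifier, query: str,
                   params: Optional[ClassifierParams] = None) -> Call:
    if params is not None:
        model.set_params(confidence=params.confidence,
                         n_bootstrap=params.n_bootstrap,
                         word_fraction=params.word_fraction,
                         random_state=params.seed)
    return model.predict_call(query)


def classify_tophit(library: Iterable, query: str,
                    tie_epsilon: float = 0.0) -> TopHitResult:
    records = list(library)
    clf = TopHitClassifier(tie_epsilon=tie_epsilon)
    clf.fit([r.sequence for r in records],
            [r.lineage.species or r.id for r in records],
            lineages={r.lineage.species: r.lineage for r in records
                      if r.lineage.species})
    return clf.predict_tophit(query)


_MODEL_FORMAT = "minicoi-bayes/1"


def save_model(model: NaiveBayesKmerClassifier, path) -> None:
    """Serialize a fitted model as versioned JSON-lines word counts."""
    with open(path, "w") as fh:
        header = {
            "format": _MODEL_FORMAT, "k": model.k,
            "confidence": model.confidence, "n_bootstrap": model.n_bootstrap,
            "word_fraction": model.word_fraction,
            "random_state": model.random_state,
            "species": list(map(str, model.species_)),
            "M": model.M_.tolist(),
            "lineages": {sp: model.lineage_map_[sp].to_string()
                         for sp in model.species_},
        }
        fh.write(json.dumps(header) + "\n")
        coo = model.m_.tocoo()
        by_word: dict = {}
        for wi, si, c in zip(coo.row, coo.col, coo.data):
            by_word.setdefault(int(wi), {})[int(si)] = int(c)
        inv = {i: w for w, i in model.vocab_.items()}
        for wi in sorted(by_word):
            fh.write(json.dumps({"w": inv[wi], "c": by_word[wi]}) + "\n")


def load_model(path) -> NaiveBayesKmerClassifier:
    from .seqcore import parse_bold_lineage

    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != _MODEL_FORMAT:
            raise ValueError(f"unknown model format {header.get('format')!r}")
        model = NaiveBayesKmerClassifier(
            k=header["k"], confidence=header["confidence"],
            n_bootstrap=header["n_bootstrap"],
            word_fraction=header["word_fraction"],
            random_state=header["random_state"])
        model.species_ = np.array(header["species"])
        model.M_ = np.array(header["M"], dtype=np.int64)
        model.N_ = int(model.M_.sum())
        model.log_M1_ = np.log(model.M_ + 1.0)
        model.lineage_map_ = {
            sp: parse_bold_lineage(lin)
            for sp, lin in header["lineages"].items()}
        model.vocab_ = {}
        rows, cols, data = [], [], []
        for line in fh:
            obj = json.loads(line)
            wi = model.vocab_.setdefault(obj["w"], len(model.vocab_))
            for si, c in obj["c"].items():
                rows.append(wi)
                cols.append(int(si))
                data.append(int(c))
        model.m_ = sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(model.vocab_), len(model.species_)))
        model.n_ = np.asarray(model.m_.sum(axis=1)).ravel()
        model.prior_ = (model.n_ + 0.5) / (model.N_ + 1)
        model.rejected_ = []
        model._rank_labels_ = {}
        for rank in RANKS:
            if rank == "species":
                model._rank_labels_[rank] = np.array(
                    list(model.species_), dtype=object)
            else:
                model._rank_labels_[rank] = np.array(
                    [model.lineage_map_[sp].get(rank) for sp in model.species_],
                    dtype=object)
    return model
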