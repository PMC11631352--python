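"""Taxonomy classification of amplicon sequences against a ReferenceDB.

Two in-repo classifiers are provided as scikit-learn-style estimators:

* :class:`ConsensusTaxonomyClassifier` — alignment-based top-hit consensus
  (VSEARCH-style): accepted hits above an identity threshold vote rank by
  rank; the lineage is truncated at the first rank where the plurality
  label's fraction drops below ``min_consensus``.
* :class:`NaiveBayesTaxonomyClassifier` — multinomial naive Bayes over
  overlapping k-mers with additive smoothing and uniform class priors
  (classify-sklearn-style); per-rank confidence is the posterior mass of
  classes sharing the label path, and the lineage is truncated at the
  deepest rank whose confidence clears ``confidence``.

A ``positive_filter`` screen (identity/coverage against a trusted rRNA set,
the Deblur-style "positive filter") is also provided. Module-level
``classify_consensus`` / ``train_naive_bayes`` / ``classify_naive_bayes``
functions are thin wrappers over the estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .align import AlignmentHit, semiglobal_align
from .io import SequenceRecord
from .lineage import (N_RANKS, Lineage, format_lineage, parse_lineage,
                      unassigned_lineage)
from .refdb import ReferenceDB

logger = logging.getLogger(__name__)


@dataclass
class ClassifyParams:
    """Shared knobs for search, consensus, naive Bayes, and the screen."""

    perc_identity: float = 0.80
    maxaccepts: int = 10
    min_consensus: float = 0.51
    k: int = 7
    alpha: float = 0.001
    confidence: float = 0.70
    filter_identity: float = 0.65
    filter_coverage: float = 0.50
    prefilter_k: int = 8
    prefilter_candidates: int = 50

    def __post_init__(self):
        for name in ("perc_identity", "min_consensus", "filter_identity",
                     "filter_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.confidence <= 0:
            # deliberately allowed to exceed 1 (makes every call Unassigned)
            raise ValueError("confidence must be positive")
        if self.maxaccepts < 1:
            raise ValueError("maxaccepts must be >= 1")
        if self.k < 4:
            raise ValueError("k must be >= 4")


@dataclass
class Classification:
    """A per-feature taxonomy call with its score and method tag."""

    feature_id: str
    lineage: Lineage
    score: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


# ---------------------------------------------------------------------------
# k-mer machinery

def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of overlapping k-mers over the 4^k vocabulary (as-written
    orientation, no reverse complement); k-mers touching a non-ACGT base
    are skipped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    out = np.zeros(4 ** k, dtype=np.int64)
    if n <= 0:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return out
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (windows[valid] * powers).sum(axis=1)
    np.add.at(out, idx, 1)
    return out


# ---------------------------------------------------------------------------
# alignment search

def _prefilter(query_seq: str, db: ReferenceDB, params: ClassifyParams,
               kmer_index: dict | None = None) -> list[str]:
    """Top candidate ref ids by shared prefilter_k-mer count (ties: id asc)."""
    k = params.prefilter_k
    q = _kmer_set(query_seq, k)
    if kmer_index is None:
        kmer_index = {fid: _kmer_set(db.record(fid).seq, k) for fid in db.ids()}
    scored = sorted(((len(q & ref_kmers), fid) for fid, ref_kmers in kmer_index.items()),
                    key=lambda t: (-t[0], t[1]))
    return [fid for _, fid in scored[:params.prefilter_candidates]]


def search(query: SequenceRecord, db: ReferenceDB, params: ClassifyParams,
           kmer_index: dict | None = None, apply_identity_cutoff: bool = True,
           query_global: bool = True) -> list[AlignmentHit]:
    """Ranked alignment hits for a query: prefilter, align, sort by identity
    descending then ref id ascending, keep identity >= perc_identity (when
    the cutoff applies), truncate to maxaccepts.

    Classification searches align the query end to end (vsearch-style
    global search); the positive filter passes ``query_global=False`` so
    partial overlaps can satisfy its explicit coverage threshold."""
    if len(db) == 0:
        return []
    hits = []
    for fid in _prefilter(query.seq, db, params, kmer_index):
        hit = semiglobal_align(query.seq, db.record(fid).seq,
                               query_id=query.id, ref_id=fid,
                               query_global=query_global)
        hits.append(hit)
    hits.sort(key=lambda h: (-h.identity, h.ref_id))
    if apply_identity_cutoff:
        hits = [h for h in hits if h.identity >= params.perc_identity]
        hits = hits[:params.maxaccepts]
    return hits


def _consensus_from_hits(feature_id: str, hits: list[AlignmentHit],
                         db: ReferenceDB, min_consensus: float) -> Classification:
    if not hits:
        return Classification(feature_id, unassigned_lineage(db.dialect), 0.0,
                              "consensus")
    lineages = [db.lineage(h.ref_id) for h in hits]
    n = len(lineages)
    kept: list[str] = []
    score = 0.0
    for r in range(N_RANKS):
        labels = [lin.labels[r] for lin in lineages]
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        # plurality ties or an empty winner fail the rank (conservative)
        if len(winners) != 1 or winners[0] == "":
            break
        frac = best / n
        if frac < min_consensus:
            break
        kept.append(winners[0])
        score = frac
    if not kept:
        return Classification(feature_id, unassigned_lineage(db.dialect), 0.0,
                              "consensus")
    return Classification(feature_id, Lineage(tuple(kept), db.dialect), score,
                          "consensus")


class ConsensusTaxonomyClassifier(BaseEstimator, ClassifierMixin):
    """Alignment-based top-hit consensus taxonomy classifier.

    Parameters mirror the classify-consensus defaults of the wrapped-style
    method: hits with identity >= ``perc_identity`` (up to ``maxaccepts``)
    vote per rank; ranks are kept while the plurality fraction stays at or
    above ``min_consensus``.
    """

    def __init__(self, perc_identity: float = 0.80, maxaccepts: int = 10,
                 min_consensus: float = 0.51, prefilter_k: int = 8,
                 prefilter_candidates: int = 50):
        self.perc_identity = perc_identity
        self.maxaccepts = maxaccepts
        self.min_consensus = min_consensus
        self.prefilter_k = prefilter_k
        self.prefilter_candidates = prefilter_candidates

    def _params(self) -> ClassifyParams:
        return ClassifyParams(perc_identity=self.perc_identity,
                              maxaccepts=self.maxaccepts,
                              min_consensus=self.min_consensus,
                              prefilter_k=self.prefilter_k,
                              prefilter_candidates=self.prefilter_candidates)

    def fit(self, X, y=None):
        """Index a reference. X may be a ReferenceDB, or a list of
        SequenceRecord with ``y`` the matching lineage strings."""
        if isinstance(X, ReferenceDB):
            db = X
        else:
            if y is None:
                raise ValueError("y (lineage strings) required when X is a sequence list")
            db = ReferenceDB("silva")
            for rec, lin in zip(X, y):
                db.add(rec, parse_lineage(lin, "silva"))
        self.db_ = db
        self.kmer_index_ = {fid: _kmer_set(db.record(fid).seq, self.prefilter_k)
                            for fid in db.ids()}
        return self

    def predict_classifications(self, records) -> list[Classification]:
        params = self._params()
        out = []
        for rec in records:
            hits = search(rec, self.db_, params, kmer_index=self.kmer_index_)
            out.append(_consensus_from_hits(rec.id, hits, self.db_,
                                            self.min_consensus))
        return out

    def predict(self, X) -> list[str]:
        """Formatted lineage strings for a list of SequenceRecord."""
        return [format_lineage(c.lineage) for c in self.predict_classifications(X)]


# ---------------------------------------------------------------------------
# naive Bayes

class NaiveBayesTaxonomyClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial naive Bayes over k-mer counts with rank-wise confidence.

    Classes are the distinct full lineages of the training reference; class
    likelihoods pool the k-mer counts of the class's sequences with additive
    (``alpha``) smoothing over the 4^k vocabulary; priors are uniform.
    Confidence at a rank is the total posterior of classes sharing the
    maximal label path to that rank (a deterministic, closed-form analogue
    of bootstrap confidence); the reported lineage stops at the deepest rank
    with confidence >= ``confidence``.
    """

    def __init__(self, k: int = 7, alpha: float = 0.001, confidence: float = 0.70):
        self.k = k
        self.alpha = alpha
        self.confidence = confidence

    def fit(self, X, y=None):
        if isinstance(X, ReferenceDB):
            seqs = [X.record(fid).seq for fid in X.ids()]
            lineages = [format_lineage(X.lineage(fid)) for fid in X.ids()]
            self.dialect_ = X.dialect
        else:
            if y is None:
                raise ValueError("y (lineage strings) required when X is a sequence list")
            seqs = [r.seq if isinstance(r, SequenceRecord) else str(r) for r in X]
            lineages = list(y)
            self.dialect_ = "silva"
        if not seqs:
            raise ValueError("cannot train on an empty reference")
        class_counts: dict[str, np.ndarray] = {}
        n_skipped = 0
        for seq, lin in zip(seqs, lineages):
            if len(seq) < self.k:
                n_skipped += 1
                logger.warning("training sequence shorter than k=%d skipped", self.k)
                continue
            vec = kmer_counts(seq, self.k)
            if lin in class_counts:
                class_counts[lin] += vec
            else:
                class_counts[lin] = vec.astype(np.float64)
        if not class_counts:
            raise ValueError("all training sequences shorter than k; nothing to train on")
        self.classes_ = np.array(sorted(class_counts))
        counts = np.stack([class_counts[c] for c in self.classes_])
        smoothed = counts + self.alpha
        self.feature_log_prob_ = np.log(smoothed) - np.log(smoothed.sum(axis=1,
                                                                        keepdims=True))
        self.class_log_prior_ = np.full(len(self.classes_),
                                        -np.log(len(self.classes_)))
        self.class_lineages_ = [parse_lineage(c, self.dialect_) for c in self.classes_]
        return self

    def posteriors(self, seq: str) -> np.ndarray:
        """Normalized class posteriors for one sequence."""
        vec = kmer_counts(seq, self.k)
        idx = np.nonzero(vec)[0]
        logp = self.class_log_prior_ + self.feature_log_prob_[:, idx] @ vec[idx]
        return np.exp(logp - logsumexp(logp))

    def _classify_one(self, rec: SequenceRecord) -> Classification:
        if len(rec.seq) < self.k:
            logger.warning("query %r shorter than k=%d; Unassigned", rec.id, self.k)
            return Classification(rec.id, unassigned_lineage(self.dialect_), 0.0,
                                  "naive_bayes")
        post = self.posteriors(rec.seq)
        active = np.arange(len(self.classes_))
        kept: list[str] = []
        score = 0.0
        for r in range(N_RANKS):
            groups: dict[str, float] = {}
            members: dict[str, list[int]] = {}
            for ci in active:
                lab = self.class_lineages_[ci].labels[r]
                groups[lab] = groups.get(lab, 0.0) + post[ci]
                members.setdefault(lab, []).append(ci)
            best_lab = max(groups, key=lambda lab: (groups[lab], lab))
            if best_lab == "":
                break
            conf = groups[best_lab]
            if conf < self.confidence:
                break
            kept.append(best_lab)
            score = min(conf, 1.0)
            active = np.array(members[best_lab])
        if not kept:
            return Classification(rec.id, unassigned_lineage(self.dialect_), 0.0,
                                  "naive_bayes")
        return Classification(rec.id, Lineage(tuple(kept), self.dialect_), score,
                              "naive_bayes")

    def predict_classifications(self, records) -> list[Classification]:
        return [self._classify_one(rec) for rec in records]

    def predict(self, X) -> list[str]:
        return [format_lineage(c.lineage) for c in self.predict_classifications(X)]


# ---------------------------------------------------------------------------
# positive filter

def positive_filter(queries, screen_db, params: ClassifyParams | None = None):
    """Deblur-style positive screen: keep a query iff some screen sequence
    reaches ``filter_identity`` identity and ``filter_coverage`` coverage
    (both boundaries inclusive). Returns (kept, discarded), input order."""
    params = params or ClassifyParams()
    if not screen_db:
        raise ValueError("screen_db must be non-empty")
    db = ReferenceDB("silva")
    for rec in screen_db:
        db.add(rec, unassigned_lineage("silva"))
    kmer_index = {fid: _kmer_set(db.record(fid).seq, params.prefilter_k)
                  for fid in db.ids()}
    kept, discarded = [], []
    for q in queries:
        hits = search(q, db, params, kmer_index=kmer_index,
                      apply_identity_cutoff=False, query_global=False)
        ok = any(h.identity >= params.filter_identity and
                 h.coverage >= params.filter_coverage for h in hits)
        (kept if ok else discarded).append(q)
    return kept, discarded


# ---------------------------------------------------------------------------
# spec-surface wrappers

def classify_consensus(query: SequenceRecord, db: ReferenceDB,
                       params: ClassifyParams | None = None) -> Classification:
    params = params or ClassifyParams()
    clf = ConsensusTaxonomyClassifier(
        perc_identity=params.perc_identity, maxaccepts=params.maxaccepts,
        min_consensus=params.min_consensus, prefilter_k=params.prefilter_k,
        prefilter_candidates=params.prefilter_candidates).fit(db)
    return clf.predict_classifications([query])[0]


def train_naive_bayes(db: ReferenceDB,
                      params: ClassifyParams | None = None) -> NaiveBayesTaxonomyClassifier:
    params = params or ClassifyParams()
    return NaiveBayesTaxonomyClassifier(k=params.k, alpha=params.alpha,
                                        confidence=params.confidence).fit(db)

def classify_naive_bayes(model: NaiveBayesTaxonomyClassifier, query: SequenceRecord,
                         params: ClassifyParams | None = None) -> Classification:
    if params is not None:
        model.confidence = params.confidence
    return model.predict_classifications([query])[0]
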