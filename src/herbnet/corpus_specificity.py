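"""Corpus-based TF-IDF specificity scoring of herbs.

A prescription corpus plays the role of a document collection: every
prescription is a document and every herb a term.  A designated subset of
*representative* prescriptions (the disease-specific formulas) is pooled into
a single document; the term frequency of an herb is its relative frequency in
that pooled document, and the inverse document frequency is computed over the
whole corpus.  The specificity score

    tfidf(h) = tf(h) * idf(h) * 100

is thresholded (strictly) to select disease-specific herbs.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PrescriptionCorpus",
    "SpecificityScore",
    "term_frequency",
    "inverse_document_frequency",
    "tfidf_scores",
    "read_corpus",
    "write_scores",
]


def _normalize_herb(herb: str) -> str:
    """Canonical herb id: trimmed and case-folded. Synonyms are not resolved."""
    return herb.strip().casefold()


@dataclass(frozen=True)
class PrescriptionCorpus:
    """A collection of prescriptions plus the representative (disease) subset.

    Parameters
    ----------
    prescriptions
        Map prescription-id -> multiset (Counter) of herb ids.  Plain
        iterables of herb ids are accepted and coerced; prescriptions list
        each herb once in practice, but multiset input is supported.
    representative_ids
        Ordered ids of the prescriptions designated as disease-specific.
    """

    prescriptions: dict[str, Counter] = field(default_factory=dict)
    representative_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coerced: dict[str, Counter] = {}
        for pid, herbs in self.prescriptions.items():
            if isinstance(herbs, Counter):
                counter = Counter({_normalize_herb(h): c for h, c in herbs.items()})
            else:
                counter = Counter(_normalize_herb(h) for h in herbs)
            if not counter:
                raise ValueError(f"prescription {pid!r} is empty")
            if any(not h for h in counter):
                raise ValueError(f"prescription {pid!r} contains an empty herb id")
            coerced[pid] = counter
        object.__setattr__(self, "prescriptions", coerced)
        object.__setattr__(self, "representative_ids", tuple(self.representative_ids))
        missing = [r for r in self.representative_ids if r not in coerced]
        if missing:
            raise ValueError(f"representative ids not in corpus: {missing}")

    @property
    def n_prescriptions(self) -> int:
        return len(self.prescriptions)

    def representative_pool(self) -> Counter:
        """All representative prescriptions pooled into one document."""
        pool: Counter = Counter()
        for rid in self.representative_ids:
            pool.update(self.prescriptions[rid])
        return pool

    def document_frequency(self, herb: str) -> int:
        h = _normalize_herb(herb)
        return sum(1 for p in self.prescriptions.values() if h in p)


@dataclass(frozen=True)
class SpecificityScore:
    herb: str
    tf: float
    idf: float
    tfidf: float
    selected: bool


def term_frequency(herb: str, corpus: PrescriptionCorpus) -> float:
    """Relative frequency of `herb` in the pooled representative document.

    Returns 0 for herbs absent from every representative prescription.
    Values over all herbs sum to 1.
    """
    if not corpus.representative_ids:
        raise ValueError("no representative prescriptions")
    pool = corpus.representative_pool()
    total = sum(pool.values())
    return pool.get(_normalize_herb(herb), 0) / total


def inverse_document_frequency(herb: str, corpus: PrescriptionCorpus) -> float:
    """ln(|P| / df) where df counts corpus prescriptions containing the herb."""
    df = corpus.document_frequency(herb)
    if df == 0:
        raise ValueError(f"herb not in corpus: {herb!r}")
    return math.log(corpus.n_prescriptions / df)


def tfidf_scores(
    corpus: PrescriptionCorpus, threshold: float = 10.0
) -> list[SpecificityScore]:
    """Score every herb of the representative subset; select by strict threshold.

    Output is sorted by tfidf descending with alphabetical tie-break.
    """
    if not corpus.representative_ids:
        raise ValueError("no representative prescriptions")
    pool = corpus.representative_pool()
    total = sum(pool.values())
    missing = sorted(h for h in pool if corpus.document_frequency(h) == 0)
    if missing:  # unreachable when reps are part of the corpus, guards split inputs
        raise ValueError(f"representative herbs absent from corpus: {missing}")
    scores = []
    for herb, count in pool.items():
        tf = count / total
        idf = math.log(corpus.n_prescriptions / corpus.document_frequency(herb))
        tfidf = tf * idf * 100.0
        scores.append(
            SpecificityScore(
                herb=herb, tf=tf, idf=idf, tfidf=tfidf, selected=tfidf > threshold
            )
        )
    scores.sort(key=lambda s: (-s.tfidf, s.herb))
    logger.info(
        "tfidf: %d herbs scored, %d selected at threshold %g",
        len(scores),
        sum(s.selected for s in scores),
        threshold,
    )
    return scores


# ---------------------------------------------------------------------------
# I/O


def read_corpus(corpus_tsv: str, representative_txt: str) -> PrescriptionCorpus:
    """Read a membership TSV (prescription_id, herb_id) and a representative-id list."""
    df = pd.read_csv(corpus_tsv, sep="\t", dtype=str)
    if not {"prescription_id", "herb_id"} <= set(df.columns):
        raise ValueError("corpus TSV needs columns prescription_id, herb_id")
    prescriptions: dict[str, list[str]] = {}
    for pid, herb in zip(df["prescription_id"], df["herb_id"]):
        prescriptions.setdefault(pid, []).append(herb)
    with open(representative_txt) as fh:
        rep_ids = [line.strip() for line in fh if line.strip()]
    return PrescriptionCorpus(prescriptions=prescriptions, representative_ids=rep_ids)


def write_scores(scores: list[SpecificityScore], path: str) -> None:
    pd.DataFrame(
        [
            {
                "herb_id": s.herb,
                "tf": s.tf,
                "idf": s.idf,
                "tfidf": s.tfidf,
                "selected": s.selected,
            }
            for s in scores
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
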