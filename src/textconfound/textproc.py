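"""Turn raw clinical note text into the interpretable term covariate block.

The pipeline mirrors standard clinical-NLP preprocessing for bag-of-words
survival covariates: sentence segmentation on clinical field labels, removal
of boilerplate (document head/tail, clinic locations, physician signatures),
a short-negated-sentence filter so conditions a patient does *not* have are
not counted, dictionary-based biomedical entity extraction with rule-based
lemmatization and synonym folding, and finally a TF-IDF matrix restricted to
the top-K most frequent terms below a document-frequency ceiling.

Entity recognition is a dictionary matcher over a configurable term list:
the interpretability of the resulting covariates rests on surface terms, and
the shipped dictionary is deliberately small and user-replaceable.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

from .matrix import TEXT_PREFIX, CovariateMatrix

logger = logging.getLogger(__name__)

# Small general-English stopword list plus clinical units/time/boilerplate
# terms that are frequent but uninformative as covariates.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been by for from had has have he her his i in is
    it its of on or she that the their they this to was were will with would
    not no nor do does did done am we you your our us than then there here
    also very more most much such per each both all any some these those
    lb oz kg mg ml mmhg bpm cm mm
    day days week weeks month months year years today yesterday
    patient doctor clinic hospital md dr note visit exam
    """.split()
)

# Lexical variations that suffix rules do not reduce, plus common clinical
# abbreviations; user configs extend or replace this.
DEFAULT_SYNONYMS: dict[str, str] = {
    "hx": "history",
    "fu": "follow-up",
    "abnormality": "abnormal",
    "abnormalities": "abnormal",
    "consult": "consultation",
    "assistance": "service",
    "action": "movement",
}

DEFAULT_NEGATION_TERMS = ("no", "denies", "does not", "none")

DEFAULT_BOILERPLATE_PATTERNS = (
    r"medical center",
    r"\bm\.?d\.?\b",
    r"\bclinic\b",
    r"electronically signed",
)

_LEMMA_EXCEPTIONS: dict[str, str] = {
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "biopsies": "biopsy",
    "metastases": "metastasis",
    "diagnoses": "diagnosis",
}

_FIELD_LABEL_RE = re.compile(r"\b[A-Z][A-Z/\- ]*[A-Z]:|\b[A-Z]{2,}:")
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


@dataclass
class NoteDocument:
    """One clinical note: free text with its day offset from diagnosis."""

    patient_id: str
    date: float  # days since diagnosis
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"empty note text for patient {self.patient_id}")


@dataclass
class TextFeatureConfig:
    """Knobs for the note-to-covariate pipeline.

    ``top_k`` and ``ngram_max`` follow the two study presets: 500 unigram
    features, or 1000 features with unigrams and bigrams under a document
    frequency ceiling of 0.7.
    """

    negation_terms: tuple[str, ...] = DEFAULT_NEGATION_TERMS
    negation_word_cap: int = 15
    boilerplate_trim: int = 2
    boilerplate_patterns: tuple[str, ...] = DEFAULT_BOILERPLATE_PATTERNS
    entity_dictionary: frozenset[str] = frozenset()
    synonym_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    ngram_max: int = 1
    top_k: int = 500
    max_document_frequency: float = 0.7

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.ngram_max not in (1, 2):
            raise ValueError("ngram_max must be 1 or 2")
        if not (0.0 < self.max_document_frequency <= 1.0):
            raise ValueError("max_document_frequency must lie in (0, 1]")
        self.entity_dictionary = frozenset(t.lower() for t in self.entity_dictionary)


# ---------------------------------------------------------------------------
# sentence-level preprocessing


def segment_sentences(doc: NoteDocument | str) -> list[str]:
    """Split a note into sentences on field labels, tab runs, and punctuation.

    Clinical field labels (ALL-CAPS token(s) followed by a colon, e.g.
    ``IMPRESSION:``) delimit segments and are removed from the output.
    """
    text = doc.text if isinstance(doc, NoteDocument) else doc
    if not text.strip():
        return []
    # field labels and tab runs both act as hard segment boundaries
    text = _FIELD_LABEL_RE.sub("\n", text)
    segments = re.split(r"[\t\n]+", text)
    sentences: list[str] = []
    for seg in segments:
        seg = seg.strip()
        if not seg:
            continue
        sentences.extend(s.strip() for s in _SENTENCE_SPLIT_RE.split(seg) if s.strip())
    return sentences


def strip_boilerplate(sentences: Sequence[str], config: TextFeatureConfig) -> list[str]:
    """Drop head/tail sentences and location / physician-signature lines."""
    k = config.boilerplate_trim
    if k < 0:
        raise ValueError("boilerplate_trim must be >= 0")
    body = list(sentences[k: len(sentences) - k]) if k else list(sentences)
    if not config.boilerplate_patterns:
        return body
    pattern = re.compile("|".join(config.boilerplate_patterns), re.IGNORECASE)
    return [s for s in body if not pattern.search(s)]


def _strip_punct_tokens(sentence: str) -> list[str]:
    return [t for t in (w.translate(_PUNCT_TABLE) for w in sentence.split()) if t]


def filter_negated(sentences: Sequence[str], config: TextFeatureConfig) -> list[str]:
    """Drop short sentences that contain a negation term.

    A sentence is removed iff it has fewer than ``negation_word_cap`` words
    (whitespace tokens after punctuation stripping) *and* contains at least
    one negation term as a case-insensitive token or phrase match.  Long
    sentences are kept even when negated: the negated concept is usually a
    minor clause rather than the sentence topic.
    """
    single = {t.lower() for t in config.negation_terms if " " not in t}
    phrases = [t.lower().split() for t in config.negation_terms if " " in t]
    kept = []
    for s in sentences:
        tokens = [t.lower() for t in _strip_punct_tokens(s)]
        if len(tokens) < config.negation_word_cap:
            has_neg = any(t in single for t in tokens) or any(
                tokens[i: i + len(p)] == p
                for p in phrases
                for i in range(len(tokens) - len(p) + 1)
            )
            if has_neg:
                continue
        kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# term extraction


def lemmatize(token: str, vocabulary: frozenset[str] | set[str]) -> str:
    """Rule/lookup lemmatizer: plural folding plus -ing/-ed stripping.

    Suffix stripping is accepted only when the candidate stem (with or
    without a restored final 'e') is a known vocabulary entry, so ordinary
    words like "bleeding" reduce to "bleed" only if "bleed" is in the
    dictionary while opaque tokens pass through unchanged.
    """
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    if token in vocabulary:
        return token
    if token.endswith("ies") and len(token) > 4:
        cand = token[:-3] + "y"
        if cand in vocabulary:
            return cand
    if token.endswith("es") and len(token) > 3:
        cand = token[:-2]
        if cand in vocabulary:
            return cand
    if token.endswith("s") and not token.endswith("ss") and len(token) > 2:
        cand = token[:-1]
        if cand in vocabulary:
            return cand
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            stem = token[: -len(suffix)]
            for cand in (stem, stem + "e"):
                if cand in vocabulary:
                    return cand
    return token


def extract_terms(sentences: Sequence[str], config: TextFeatureConfig) -> list[str]:
    """Normalize tokens and keep those in the entity dictionary, in text order."""
    if not config.entity_dictionary:
        raise ValueError("entity_dictionary must be non-empty")
    vocab = config.entity_dictionary
    lemma_vocab = set(vocab) | set(config.synonym_map)
    out: list[str] = []
    for s in sentences:
        for raw in _strip_punct_tokens(s.lower()):
            term = lemmatize(raw, lemma_vocab)
            term = config.synonym_map.get(term, term)
            if term in config.stopwords:
                continue
            if term in vocab:
                out.append(term)
    return out


# ---------------------------------------------------------------------------
# TF-IDF matrix


def build_tfidf(
    term_documents: Mapping[str, Sequence[str]],
    config: TextFeatureConfig,
) -> CovariateMatrix:
    """Build the TF-IDF covariate block from per-patient term documents.

    Candidate n-grams (up to ``ngram_max``) are ranked by total corpus
    frequency; n-grams whose document frequency reaches
    ``max_document_frequency`` are excluded; the ``top_k`` survivors form
    the vocabulary.  Cells are tf x idf with the smoothed idf
    ``ln((1+N)/(1+df)) + 1`` and per-patient L2 normalization.
    """
    if len(term_documents) == 0:
        raise ValueError("no documents to featurize")
    patient_ids = list(term_documents.keys())
    docs = [" ".join(term_documents[p]) for p in patient_ids]

    counter = CountVectorizer(
        analyzer="word",
        tokenizer=str.split,
        preprocessor=lambda x: x,
        token_pattern=None,
        lowercase=False,
        ngram_range=(1, config.ngram_max),
    )
    counts = counter.fit_transform(docs)
    terms = counter.get_feature_names_out()
    n_docs = len(docs)

    doc_freq = np.asarray((counts > 0).sum(axis=0)).ravel() / n_docs
    # strict ceiling: a term reaching the threshold is excluded; a ceiling of
    # exactly 1.0 disables the filter
    if config.max_document_frequency < 1.0:
        below_ceiling = doc_freq < config.max_document_frequency
    else:
        below_ceiling = np.ones_like(doc_freq, dtype=bool)
    corpus_freq = np.asarray(counts.sum(axis=0)).ravel()

    candidates = np.flatnonzero(below_ceiling)
    if candidates.size < config.top_k:
        logger.warning(
            "only %d candidate terms available for top_k=%d; keeping all",
            candidates.size, config.top_k,
        )
    # rank by corpus frequency, alphabetical tie-break for determinism
    order = sorted(candidates, key=lambda j: (-corpus_freq[j], terms[j]))
    keep = sorted(order[: config.top_k], key=lambda j: terms[j])

    tfidf = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    values = tfidf.fit_transform(counts[:, keep]).toarray()
    columns = [TEXT_PREFIX + terms[j] for j in keep]
    return CovariateMatrix(patient_ids, columns, values)


# ---------------------------------------------------------------------------
# note windowing and the assembled pipeline


def window_notes(
    docs: Iterable[NoteDocument], treatment_start: float, window_days: float
) -> list[NoteDocument]:
    """Keep notes dated at least ``window_days`` before treatment start.

    The boundary is inclusive: a note exactly ``window_days`` before the
    treatment start date is retained.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    cutoff = treatment_start - window_days
    return [d for d in docs if d.date <= cutoff]


def featurize_notes(
    notes_by_patient: Mapping[str, Sequence[NoteDocument]],
    config: TextFeatureConfig,
) -> CovariateMatrix:
    """Full note pipeline: segment, strip, negation-filter, extract, TF-IDF."""
    term_docs: dict[str, list[str]] = {}
    for pid, docs in notes_by_patient.items():
        terms: list[str] = []
        for doc in docs:
            sentences = segment_sentences(doc)
            sentences = strip_boilerplate(sentences, config)
            sentences = filter_negated(sentences, config)
            terms.extend(extract_terms(sentences, config))
        term_docs[pid] = terms
    return build_tfidf(term_docs, config)
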