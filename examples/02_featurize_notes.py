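"""Turn raw note text into interpretable TF-IDF term covariates.

Walks the preprocessing stages on a tiny hand-written corpus: field-label
segmentation, boilerplate stripping, the short-negated-sentence filter,
dictionary entity extraction, and the TF-IDF matrix.
"""

import textconfound as tc

config = tc.TextFeatureConfig(
    entity_dictionary=frozenset({"bladder", "obstruction", "smoking", "copd"}),
    top_k=10,
)

note = (
    "Example Medical Center, Urology Clinic. Seen by Jane Roe, M.D. "
    "HISTORY: Severe bladder outlet obstruction noted. No history of smoking. "
    "IMPRESSION:\tChronic obstruction stable. Return to clinic as scheduled. "
    "Electronically signed by Jane Roe, M.D."
)

sentences = tc.segment_sentences(note)
print("sentences:", sentences)

sentences = tc.strip_boilerplate(sentences, config)
print("after boilerplate stripping:", sentences)

sentences = tc.filter_negated(sentences, config)
print("after negation filter:", sentences)  # the smoking sentence is gone

terms = tc.extract_terms(sentences, config)
print("extracted terms:", terms)

matrix = tc.build_tfidf(
    {"p1": terms, "p2": ["copd", "copd"], "p3": ["bladder"]}, config
)
print("\nTF-IDF covariates (rows L2-normalized):")
print(matrix.to_dataframe().round(3))
# Each column is an interpretable candidate covariate named after its term;
# "smoking" is absent because its only mention was a short negated sentence.
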