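"""Normalize text into stemmed tokens and build the TF-IDF encoding.

Shows the full normalization chain (tokenize, stop words, lemma table,
Porter stemming), the sparse document-term matrix, and the IDF weighting
idf(i) = ln(N / df(i)): tokens present everywhere get weight 0.
"""

import numpy as np

import litscreen as ls

tokens = ls.normalize_and_tokenize(
    "HIV-1 prevalence among female sex workers, 2006!", "", ls.load_stopwords()
)
print("tokens after stripping/stop words:", tokens)
stemmed = [ls.porter_stem(t) for t in ls.lemmatize(tokens, ls.load_lemma_table())]
print("after lemmatization + Porter:     ", stemmed)

records = ls.tiny_corpus()
dtm = ls.build_dtm(ls.tokenize_records(records))
print(f"DTM: {dtm.shape[0]} documents x {dtm.shape[1]} tokens")

model = ls.fit_tfidf(dtm)
weights = ls.transform_tfidf(model, dtm)
j = model.vocabulary.index("hiv")
print(f"'hiv' document frequency {model.df[j]} of {model.n_docs}; "
      f"idf = ln({model.n_docs}/{model.df[j]}) = {model.idf[j]:.3f}")
print("per-document 'hiv' TF-IDF:", np.round(weights.toarray()[:, j], 3))
# Documents repeating "hiv" get proportionally larger weights; documents
# without it get 0.
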