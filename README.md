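# medrelex

Medical relation extraction with a pre-trained transformer encoder
fine-tuned through a multi-filter 1d-CNN head.

Corpora that annotate biomedical relations — chemical-induced disease
(CID) pairs in PubMed abstracts, herb/formula/syndrome/disease relations
in traditional Chinese medicine (TCM) literature, temporal relations in
clinical notes — are small: hundreds to a few thousand labeled examples
per category, far below what a deep classifier trained from scratch
needs. `medrelex` implements the remedy of pre-training a bidirectional
transformer encoder on unlabeled text and then *fine-tuning* it: a
convolutional classification head is placed on the encoder's token
states and its training error back-propagates all the way into the
encoder, instead of treating pre-trained representations as frozen
features.

## The model

A relation instance is a sentence pair: sentence A is the two entity
names (e.g. `"cocaine myocardial infarction"`), sentence B the document
they co-occur in (title + abstract). The pair is encoded as
`[CLS] A [SEP] B [SEP]` with WordPiece sub-word tokens, and the input
representation of token *i* is the exact sum

    v_input(i) = v_token(i) + v_segment(i) + v_position(i)

of its learned token, segment (A vs B) and position embeddings. The
encoder is a stack of L transformer layers — multi-head scaled
dot-product self-attention, softmax(QKᵀ/√d)·V over unpadded positions,
each sub-layer with residual connection and layer normalization — from
miniature (L=2, H=64) up to the base geometry (L=12, H=768, A=12,
~110M parameters).

Pre-training minimizes two cross-entropies on unlabeled text: a masked
language model (15% of tokens hidden; 80% → `[MASK]`, 10% → random
token, 10% unchanged) and next-sentence prediction (IsNext/NotNext,
balanced 50/50).

For classification, filters of window lengths 3/4/5 (100 feature maps
each) convolve along the token axis of the final hidden states; after
ReLU and max-over-time pooling the 300 features feed a dropout(0.5) +
softmax classifier. Binary tasks train with the margin ranking loss

    Σ max{ 0, 1 − g(d) + g(d′) }

over positive/negative document pairs, where g is the softmax score of
the positive class; multi-class tasks use cross-entropy. Performance is
reported as precision TP/(TP+FP), recall TP/(TP+FN) and their harmonic
mean F1, micro-averaged across classes for multi-class tasks.

Balanced training data are built from abstract-level annotations:
every annotated pair is a positive sample and unannotated
chemical × disease pairs are drawn uniformly at a 1:1 ratio as
negatives. TCM-style tables instead get their context attached by
co-occurrence search over a literature file.

The neural machinery (reverse-mode autodiff, Adam, the encoder and the
CNN head) is implemented in the package on NumPy — no deep-learning
framework is required.

## Worked example

```python
import numpy as np
from medrelex import fixture_1601297, make_positive_samples
from medrelex.samples import GenerationConfig, make_negative_samples

doc = fixture_1601297()           # the cocaine ECG abstract, PMID 1601297
doc.concept_ids("Chemical"), doc.concept_ids("Disease")
# ('D003042',) ('D009202', 'D012559', 'D009203', 'D007511', 'D002037')

[s.sentence_a for s in make_positive_samples(doc)]
# ['cocaine myocardial infarction', 'cocaine bundle branch block']

neg = make_negative_samples(doc, 2, GenerationConfig(), np.random.default_rng(0))
[s.sentence_a for s in neg]
# ['cocaine schizophrenic', 'cocaine ischemia']
```

One chemical and five diseases give two positive samples (the two
annotated CID pairs) and two negatives drawn from the three unannotated
pairs. Fine-tuning the miniature pre-trained encoder on synthetic
planted-signal instances:

```python
from medrelex.benchmark import build_benchmark, pretrain_miniature, finetune_config
from medrelex.model import RelationModel

data = build_benchmark(seed=1, n_train=300, n_test=100)
encoder, _ = pretrain_miniature(data, seed=1, epochs=15)
results = RelationModel(data.train, data.test, encoder, data.vocab,
                        finetune_config(1, epochs=3)).fit()
print(results.summary())
```

```
Relation extraction fine-tuning results
=======================================================
encoder geometry      L=2 H=64 A=2
head / loss           cnn / ranking
encoder frozen        False
learning rate         0.001
batch size / max len  20 / 48
epochs                3
train / dev samples   300 / 100
label set             0, 1
-------------------------------------------------------
epoch  0  loss   0.9822  dev P 0.7333 R 0.4074 F1 0.5238
epoch  1  loss   0.7990  dev P 0.9600 R 0.8889 F1 0.9231
epoch  2  loss   0.1090  dev P 1.0000 R 1.0000 F1 1.0000
-------------------------------------------------------
class                  P       R      F1  support
1                 1.0000  1.0000  1.0000       54
micro             1.0000  1.0000  1.0000       54
```

The held-out F1 of 1.0 says the fine-tuned encoder recovered the
planted lexical trigger signal ("chemX **induced** disY") that defines
a relation in the synthetic corpus.

There is also a CLI mirroring the pipeline stages:

```bash
medrelex synth --seed 5 --out data/
medrelex prepare --corpus data/corpus.pubtator --out prep/
medrelex pretrain --corpus data/pretrain.txt --out ckpt/
medrelex finetune --checkpoint ckpt/ --train prep/instances.tsv \
                  --dev prep/instances.tsv --out model/
medrelex evaluate --gold prep/instances.tsv --pred model/pred.tsv
```

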