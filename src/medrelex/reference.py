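"""Published summary statistics of the three evaluation corpora.

These are the printed corpus summaries (not the corpora themselves,
which require separate download or a data-use agreement); they serve as
inputs for corpus-statistics computations and as expectations for users
who obtain the corpora.
"""

from __future__ import annotations

__all__ = [
    "BC5CDR_SUMMARY",
    "I2B2_TEMPORAL_TRAINING_COUNTS",
    "I2B2_TEMPORAL_TEST_COUNTS",
    "TCM_LABELED_RELATIONS",
    "mean_per_category",
]

#: BC5CDR split -> (articles, chemical mentions, distinct chemical ids,
#: disease mentions, distinct disease ids, CID relations)
BC5CDR_SUMMARY = {
    "training": (500, 5203, 1467, 4182, 1965, 1038),
    "dev": (500, 5347, 1507, 4244, 1865, 1012),
    "test": (500, 5385, 1435, 4424, 1988, 1066),
}

#: i2b2 2012 temporal relation counts, training split (plus unlabeled rows)
I2B2_TEMPORAL_TRAINING_COUNTS = {
    "BEFORE": 13467,
    "AFTER": 2211,
    "SIMULTANEOUS": 4725,
    "OVERLAP": 7061,
    "BEGUN_BY": 996,
    "ENDED_BY": 797,
    "DURING": 1037,
    "BEFORE_OVERLAP": 3249,
    "unlabeled": 92,
}

I2B2_TEMPORAL_TEST_COUNTS = {
    "BEFORE": 10789,
    "AFTER": 1941,
    "SIMULTANEOUS": 4142,
    "OVERLAP": 4877,
    "BEGUN_BY": 788,
    "ENDED_BY": 688,
    "DURING": 875,
    "BEFORE_OVERLAP": 3636,
    "unlabeled": 0,
}

#: TCM corpus relation type -> (positive, negative) labeled relations
TCM_LABELED_RELATIONS = {
    "herb-syndrome": (538, 582),
    "herb-disease": (534, 642),
    "formula-syndrome": (392, 574),
    "formula-disease": (377, 411),
    "syndrome-disease": (431, 532),
}


def mean_per_category(counts: dict[str, int], n_categories: int | None = None) -> float:
    """Average annotated samples per relation category.

    The total includes every annotated sample (also rows not assigned a
    category label); the denominator is the number of defined categories.
    """
    if n_categories is None:
        n_categories = sum(1 for k in counts if k != "unlabeled")
    total = sum(counts.values())
    return total / n_categories
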