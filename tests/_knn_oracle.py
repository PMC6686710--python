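"""Independent exhaustive-search K-NN reference used by the test suite."""

from collections import Counter

import numpy as np

from herdsense.classify import NEGATIVE, POSITIVE


def knn_oracle(train, queries, k):
    """Nearest-neighbor vote by sorting every (distance, index) pair."""
    X = np.stack([e.features for e in train]).astype(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    labels = []
    for q in np.atleast_2d(queries):
        qz = (q - mu) / sd
        scored = sorted(
            (float(((((e.features - mu) / sd) - qz) ** 2).sum()), i)
            for i, e in enumerate(train))
        votes = Counter(train[i].label for _, i in scored[:k])
        if votes[NEGATIVE] > votes[POSITIVE]:
            labels.append(NEGATIVE)
        else:
            labels.append(POSITIVE)
    return labels
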