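"""Published benchmark confusion matrices for the crowdsourced
bovid-tooth experiment.

The original study reports leave-one-out confusion matrices for three
tracing conditions on its 38 second-lower-molar specimens (rows are the
actual tribe, columns the predicted tribe; classes in order
Alcelaphini, Hippotragini, Neotragini).  They are reproduced here as
data so the summary statistics derived from them — classification
rates and the share of errors confused between Alcelaphini and
Hippotragini — can be recomputed by this package's scoring code.
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix

__all__ = ["TRIBE_CLASSES", "benchmark_confusions"]

TRIBE_CLASSES = ("Alcelaphini", "Hippotragini", "Neotragini")

_TABLES = {
    # expert tracings only
    "expert": [[11, 3, 1],
               [3, 11, 1],
               [0, 0, 8]],
    # mean of worker tracings, rejects beyond distance 0.2 removed
    "worker_consensus": [[10, 2, 3],
                         [4, 11, 0],
                         [1, 0, 7]],
    # mean of worker tracings and the expert tracing together
    "consensus_plus_expert": [[11, 3, 1],
                              [5, 8, 2],
                              [1, 0, 7]],
}


def benchmark_confusions() -> dict[str, ConfusionMatrix]:
    """The three published confusion matrices, keyed by condition."""
    return {name: ConfusionMatrix(classes=TRIBE_CLASSES,
                                  counts=np.array(counts))
            for name, counts in _TABLES.items()}
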