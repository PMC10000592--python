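"""Reference contingency tables bundled for agreement analysis.

A published intrapartum-CTG benchmark compared four standard
classifiers (MLP, random forest, SVM, bagging) against the majority
vote of six clinicians on 399 first-stage records, reporting the 3x3
actual-vs-predicted contingency table for each classifier over
{Normal=1, Suspicious=2, Pathological=3}. Those printed tables are
reproduced here as inputs for the evaluation battery: chi-squared
independence, accuracy/kappa, and Bland–Altman limits of agreement
can all be recomputed from the counts alone.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix3

__all__ = ["benchmark_confusion_matrices", "BENCHMARK_N"]

BENCHMARK_N = 399

_TABLES = {
    "mlp": [[128, 1, 8], [0, 151, 3], [9, 8, 91]],
    "rf": [[131, 0, 6], [0, 151, 3], [3, 1, 104]],
    "svm": [[132, 0, 4], [1, 152, 3], [4, 0, 103]],
    "bagging": [[129, 0, 6], [2, 145, 7], [4, 6, 100]],
}


def benchmark_confusion_matrices() -> dict[str, ConfusionMatrix3]:
    """The four benchmark contingency tables, keyed by classifier name.

    Rows are the clinicians' majority annotation (actual), columns the
    classifier prediction; every table sums to 399 records.
    """
    return {
        name: ConfusionMatrix3(np.array(counts))
        for name, counts in _TABLES.items()
    }
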