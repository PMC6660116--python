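"""From-scratch classifiers on small real-valued feature vectors.

All classifiers share the same surface: ``fit(dataset)``,
``decision_function(X) -> scores`` and ``predict(X) -> labels`` with
``label = +1 if score >= 0 else -1`` (a score of exactly 0 resolves to +1).
"""

from .knn import KNNClassifier, knn_predict, minkowski_distance
from .ld import LinearDiscriminant, ld_fit, ld_predict
from .svm import LinearSVM, svm_fit, svm_predict
from .elm import (
    ELMClassifier,
    OPELMClassifier,
    elm_fit,
    elm_predict,
    op_elm_fit,
    press_loo_error,
)

__all__ = [
    "KNNClassifier",
    "LinearDiscriminant",
    "LinearSVM",
    "ELMClassifier",
    "OPELMClassifier",
    "minkowski_distance",
    "knn_predict",
    "ld_fit",
    "ld_predict",
    "svm_fit",
    "svm_predict",
    "elm_fit",
    "elm_predict",
    "op_elm_fit",
    "press_loo_error",
]


def sign_label(score: float) -> int:
    """Decision rule shared by every classifier: 0 ties break toward +1."""
    return 1 if score >= 0 else -1
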