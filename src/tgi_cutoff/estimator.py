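"""Scikit-learn style estimator for threshold selection on a 1-d score.

`CutoffClassifier` wraps the ROC machinery in :mod:`tgi_cutoff.roc` as a
binary classifier: ``fit`` selects the operating threshold from training
scores and states, ``predict`` applies the inclusive ``score >= threshold``
rule.  It composes with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .roc import delong_variance, empirical_roc, select_optimal_cutoff

__all__ = ["CutoffClassifier"]


class CutoffClassifier(BaseEstimator, ClassifierMixin):
    """Select and apply an optimal diagnostic cutoff on a single score.

    Parameters
    ----------
    policy : {"combined", "max_youden", "min_distance"}, default="combined"
        Threshold-selection rule: maximize the Youden index, minimize the
        distance to the perfect (Se=1, Sp=1) ROC corner, or rank by Youden
        with distance and LR+ tie-breaks.

    Attributes
    ----------
    threshold_ : float
        Selected cutoff; a subject is predicted positive iff
        ``score >= threshold_``.
    sensitivity_, specificity_ : float
        Operating characteristics at the selected threshold on the
        training sample.
    youden_, roc_distance_, lr_positive_, lr_negative_ : float
        Diagnostic indices at the selected threshold.
    auc_, auc_se_, auc_ci_ : float, float, (float, float)
        Training AUC with its DeLong standard error and Wald 95% CI.
    roc_curve_ : RocCurve
        The full empirical curve.
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the positive (disease) class.

    Examples
    --------
    >>> import numpy as np
    >>> clf = CutoffClassifier(policy="max_youden")
    >>> clf = clf.fit(np.array([1., 2., 3., 4.]), np.array([0, 0, 1, 1]))
    >>> float(clf.threshold_)
    3.0
    >>> clf.predict([[2.5], [3.5]]).tolist()
    [0, 1]
    """

    def __init__(self, policy: str = "combined"):
        self.policy = policy

    @staticmethod
    def _as_scores(X) -> np.ndarray:
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("CutoffClassifier expects a single score column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        """Select the threshold from scores ``X`` and binary state ``y``.

        ``X`` may be a 1-d array of scores or an ``(n, 1)`` column.
        ``y`` needs exactly two classes; the larger label (or "positive")
        is the disease state.
        """
        scores = self._as_scores(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must contain exactly two classes")
        if set(classes.tolist()) == {"negative", "positive"}:
            classes = np.array(["negative", "positive"], dtype=classes.dtype)
        self.classes_ = classes
        states = y == classes[1]
        curve = empirical_roc(scores, states)
        auc = delong_variance(scores, states)
        report = select_optimal_cutoff(curve, policy=self.policy, auc=auc)
        self.roc_curve_ = curve
        self.report_ = report
        self.threshold_ = report.threshold
        self.sensitivity_ = report.sensitivity
        self.specificity_ = report.specificity
        self.youden_ = report.indices.youden_j
        self.roc_distance_ = report.indices.roc_distance
        self.lr_positive_ = report.indices.lr_positive
        self.lr_negative_ = report.indices.lr_negative
        self.auc_ = auc.auc
        self.auc_se_ = auc.se
        self.auc_ci_ = (auc.ci_low, auc.ci_high)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        return self._as_scores(X) - self.threshold_

    def predict(self, X):
        """Label scores: positive class iff ``score >= threshold_``."""
        check_is_fitted(self, "threshold_")
        scores = self._as_scores(X)
        return np.where(scores >= self.threshold_, self.classes_[1], self.classes_[0])
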