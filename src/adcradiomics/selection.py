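"""Two-stage feature selection for the four-feature radiomic signature.

Stage one screens the 132 min-max-normalized features with a class-weighted
logistic LASSO under 10-fold stratified cross-validation at the
minimum-CV-error rule.  Stage two trains one linear SVM per 4-combination
of the screened features, tests the separation of its decision values
between classes with a two-sided Wilcoxon rank-sum test (Holm-Bonferroni
corrected over all combinations, alpha 1e-3) and picks, among the
significant combinations, the one with the highest informedness
(SN + SP - 1 at the SVM's native zero threshold).  Ties break on smaller
p, then lexicographic feature names.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .ggstats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

SIGNATURE_SIZE = 4
DEFAULT_ALPHA = 1e-3


@dataclass
class NormalizationParams:
    """Per-feature min/max of the fitting cohort, for linear [0,1] scaling."""

    feature_min: pd.Series
    feature_max: pd.Series
    dropped: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.feature_min.index
        out = (table[cols] - self.feature_min) / (self.feature_max - self.feature_min)
        return out  # new rows may fall outside [0, 1]; deliberately not clipped

    def to_dict(self) -> dict:
        return {
            "min": self.feature_min.to_dict(),
            "max": self.feature_max.to_dict(),
            "dropped": self.dropped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(pd.Series(d["min"]), pd.Series(d["max"]), list(d["dropped"]))


def minmax_normalize(
    table: pd.DataFrame, params: NormalizationParams | None = None
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Linear min-max normalization of a feature table.

    Without ``params`` the scaling is fitted on the table itself (features
    with zero range are dropped and logged); with ``params`` the stored
    affine map is reused, so values of new rows may fall outside [0, 1].
    """
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("non-finite feature values")
    if params is None:
        lo, hi = table.min(axis=0), table.max(axis=0)
        constant = list(table.columns[hi <= lo])
        if constant:
            logger.warning("dropping %d zero-range feature(s): %s", len(constant), constant)
        keep = [c for c in table.columns if c not in constant]
        params = NormalizationParams(lo[keep], hi[keep], dropped=constant)
    return params.transform(table), params


def lasso_screen(
    table: pd.DataFrame,
    labels: Sequence[int],
    *,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    class_weight: str | dict | None = "balanced",
    max_features: int | None = None,
) -> list[str]:
    """LASSO screening stage: features with nonzero coefficients at the
    regularization strength minimizing 10-fold CV deviance.

    The binary csPCa target makes this a binomial (logistic) LASSO; samples
    are weighted per class (``"balanced"`` inverse-frequency weights by
    default, or pass explicit priors).  Returns feature names ordered by
    descending ``|coefficient|``; empty when the fit is degenerate.
    """
    y = np.asarray(labels, dtype=int)
    if len(table) != len(y):
        raise ValueError("table and labels length mismatch")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    # grid capped at C = 1e2: beyond that the l1 fit is effectively
    # unregularized and the solver can stall on separable noise
    model = LogisticRegressionCV(
        Cs=np.logspace(-4, 2, n_lambdas),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",  # minimum CV deviance rule
        class_weight=class_weight,
        max_iter=2000,
        random_state=seed,
    )
    model.fit(table.to_numpy(dtype=float), y)
    coefs = model.coef_.ravel()
    nonzero = np.flatnonzero(coefs != 0)
    if nonzero.size == 0:
        logger.warning("LASSO screen degenerate: all coefficients zero")
        return []
    order = nonzero[np.argsort(-np.abs(coefs[nonzero]), kind="stable")]
    names = [table.columns[i] for i in order]
    return names[:max_features] if max_features else names


def informedness_from_counts(tp: int, fn: int, tn: int, fp: int) -> float:
    """Youden's J = SN + SP - 1."""
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    return sn + sp - 1.0


def _combo_informedness(decision: np.ndarray, y: np.ndarray) -> float:
    pred = (decision > 0).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    return informedness_from_counts(tp, fn, tn, fp)


def holm_bonferroni(p_values: Sequence[float], alpha: float) -> list[bool]:
    """Holm's step-down multiple-testing decisions at family level ``alpha``.

    Rejections are monotone: rejecting a p-value implies rejecting every
    smaller one.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break  # step-down stops at the first failure
    return reject.tolist()


@dataclass
class ComboResult:
    features: tuple[str, ...]
    wilcoxon_p: float
    significant: bool
    informedness: float


@dataclass
class SelectionResult:
    """Outcome of the exhaustive 4-feature search."""

    lasso_subset: list[str]
    combos: list[ComboResult]
    chosen: ComboResult
    alpha: float = DEFAULT_ALPHA

    @property
    def chosen_features(self) -> list[str]:
        return list(self.chosen.features)

    def combos_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "features": ["|".join(c.features) for c in self.combos],
                "wilcoxon_p": [c.wilcoxon_p for c in self.combos],
                "significant": [c.significant for c in self.combos],
                "informedness": [c.informedness for c in self.combos],
            }
        )

    def to_json(self, path: str | Path | None = None, top: int = 100) -> str:
        ranked = sorted(self.combos, key=lambda c: c.wilcoxon_p)[:top]
        payload = {
            "lasso_subset": self.lasso_subset,
            "alpha": self.alpha,
            "n_combos": len(self.combos),
            "chosen": {
                "features": list(self.chosen.features),
                "wilcoxon_p": self.chosen.wilcoxon_p,
                "informedness": self.chosen.informedness,
            },
            "top_combos": [
                {
                    "features": list(c.features),
                    "wilcoxon_p": c.wilcoxon_p,
                    "significant": c.significant,
                    "informedness": c.informedness,
                }
                for c in ranked
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def pick_winner(significant: list[ComboResult]) -> ComboResult:
    """Winner among significant combos: highest informedness, ties broken by
    smaller Wilcoxon p, then lexicographic feature names."""
    return min(significant, key=lambda c: (-c.informedness, c.wilcoxon_p, c.features))


class NoSignificantComboError(RuntimeError):
    """No 4-feature combination survived the Holm-Bonferroni correction."""

    def __init__(self, best_p: float, alpha: float):
        super().__init__(
            f"no significant 4-feature combination (best p = {best_p:.3g}, alpha = {alpha:g})"
        )
        self.best_p = best_p


def exhaustive_quadruple_search(
    table: pd.DataFrame,
    labels: Sequence[int],
    *,
    alpha: float = DEFAULT_ALPHA,
    svm_c: float = 1.0,
) -> SelectionResult:
    """Train one linear SVM per 4-combination of screened features and pick
    the most informative significantly discriminant combination.

    ``table`` must already be restricted to the LASSO-screened features and
    min-max normalized.
    """
    y = np.asarray(labels, dtype=int)
    names = list(table.columns)
    if len(names) < SIGNATURE_SIZE:
        raise ValueError(
            f"need at least {SIGNATURE_SIZE} screened features, got {len(names)}"
        )
    X = table.to_numpy(dtype=float)
    combos: list[ComboResult] = []
    index = {n: i for i, n in enumerate(names)}
    for quad in itertools.combinations(sorted(names), SIGNATURE_SIZE):
        cols = [index[n] for n in quad]
        svm = SVC(kernel="linear", C=svm_c, max_iter=200_000)
        svm.fit(X[:, cols], y)
        decision = svm.decision_function(X[:, cols])
        p = wilcoxon_rank_sum(decision[y == 1], decision[y == 0], tail="two-sided")
        combos.append(ComboResult(quad, p, False, _combo_informedness(decision, y)))

    rejects = holm_bonferroni([c.wilcoxon_p for c in combos], alpha)
    for combo, rej in zip(combos, rejects):
        combo.significant = bool(rej)

    significant = [c for c in combos if c.significant]
    if not significant:
        raise NoSignificantComboError(min(c.wilcoxon_p for c in combos), alpha)
    chosen = pick_winner(significant)
    logger.info(
        "selected %s (I = %.3f, p = %.3g) out of %d combinations (%d significant)",
        chosen.features, chosen.informedness, chosen.wilcoxon_p, len(combos), len(significant),
    )
    return SelectionResult(list(table.columns), combos, chosen, alpha=alpha)
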