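"""Training, calibration and evaluation of the linear-SVM radiomic signature.

The model is a linear SVM on the four selected (min-max-normalized)
features.  Mirroring the two-parameter search of the original analysis, the
kernel scale ``gamma`` divides the inputs (``x / gamma``) and the
misclassification cost ``C`` is the usual soft-margin penalty; both are
tuned by Bayesian optimization inside repeated 3-fold cross-validation.
Candidate models whose validation AUC exceeds their training AUC are
discarded as overfitting-prone; the survivors are re-scored on the full
training set and ranked by (AUC, informedness).  The winner's decision
values are mapped to a radiomic score in (0, 1) with a binomial-logit
(Platt sigmoid) calibration; classification thresholds the score at 0.5.

The published four-feature signature is available as
:data:`PUBLISHED_INTERCEPT` / :data:`PUBLISHED_COEFFS` and can be evaluated
on any feature row with :func:`evaluate_published_signature`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import _bayesopt
from .augment import SplitSet
from .selection import NormalizationParams, informedness_from_counts

logger = logging.getLogger(__name__)

#: Coefficients of the published radiomic signature
#: g(x) = -0.04 + 1.67 cv-m + 0.96 mu-u + 0.22 s-s - 1.12 sigma-IQR
PUBLISHED_INTERCEPT: float = -0.04
PUBLISHED_COEFFS: dict[str, float] = {
    "cv-m": 1.67,
    "mu-u": 0.96,
    "s-s": 0.22,
    "sigma-IQR": -1.12,
}

_UNICODE_ALIASES = {
    "cv−m": "cv-m",
    "μ−u": "mu-u",
    "s−s": "s-s",
    "σ−IQR": "sigma-IQR",
}


@dataclass
class SVMConfig:
    """Hyperparameter-search configuration for the linear SVM."""

    c_range: tuple[float, float] = (1e-4, 1e3)
    gamma_range: tuple[float, float] = (1e-4, 1e3)
    cv_runs: int = 100
    cv_folds: int = 3
    bayes_opt_iters: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(*self.c_range, *self.gamma_range) <= 0:
            raise ValueError("C and gamma search ranges must be positive")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")

    def to_dict(self) -> dict:
        return {
            "c_range": list(self.c_range),
            "gamma_range": list(self.gamma_range),
            "cv_runs": self.cv_runs,
            "cv_folds": self.cv_folds,
            "bayes_opt_iters": self.bayes_opt_iters,
            "seed": self.seed,
        }


@dataclass
class SignatureModel:
    """A calibrated 4-feature linear signature: g(x) = w.x + b, score = sigmoid(A g + B)."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    calibration: tuple[float, float] = (1.0, 0.0)  # (A, B), A > 0
    normalization: NormalizationParams | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != len(self.weights):
            raise ValueError("one weight per feature name required")
        if self.calibration[0] <= 0:
            raise ValueError("calibration slope must be positive (score monotone in g)")

    def _row_to_array(self, row: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(row, Mapping):
            canon = {_UNICODE_ALIASES.get(k, k): v for k, v in row.items()}
            missing = [n for n in self.feature_names if n not in canon]
            if missing:
                raise KeyError(f"missing feature(s): {missing}")
            return np.array([canon[n] for n in self.feature_names], dtype=float)
        arr = np.asarray(row, dtype=float)
        if arr.shape[-1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features")
        return arr

    def decision_value(self, row) -> np.ndarray | float:
        x = self._row_to_array(row)
        return float(x @ self.weights + self.intercept) if x.ndim == 1 else x @ self.weights + self.intercept

    def score(self, row) -> np.ndarray | float:
        a, b = self.calibration
        g = self.decision_value(row)
        return 1.0 / (1.0 + np.exp(-(a * np.asarray(g) + b))) if np.ndim(g) else float(
            1.0 / (1.0 + np.exp(-(a * g + b)))
        )

    def predict(self, row) -> np.ndarray | int:
        s = self.score(row)
        return (np.asarray(s) >= 0.5).astype(int) if np.ndim(s) else int(s >= 0.5)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "calibration": list(self.calibration),
            "normalization": self.normalization.to_dict() if self.normalization else None,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        norm = NormalizationParams.from_dict(d["normalization"]) if d.get("normalization") else None
        return cls(
            tuple(d["feature_names"]),
            np.asarray(d["weights"], dtype=float),
            float(d["intercept"]),
            tuple(d["calibration"]),
            norm,
            d.get("provenance", {}),
        )


def radiomic_score(model: SignatureModel, feature_row) -> float:
    """Calibrated probability-like score in (0, 1) for one feature row."""
    return model.score(feature_row)


def evaluate_published_signature(feature_row: Mapping[str, float]) -> float:
    """Evaluate the published linear signature g(x) on a normalized row.

    Accepts canonical ASCII names (cv-m, mu-u, s-s, sigma-IQR) or their
    unicode aliases.
    """
    canon = {_UNICODE_ALIASES.get(k, k): v for k, v in feature_row.items()}
    missing = [n for n in PUBLISHED_COEFFS if n not in canon]
    if missing:
        raise KeyError(f"missing signature feature(s): {missing}")
    return PUBLISHED_INTERCEPT + sum(w * canon[n] for n, w in PUBLISHED_COEFFS.items())


# ---------------------------------------------------------------------------
# training


def _fold_aucs(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float, folds: StratifiedKFold
) -> tuple[float, float]:
    """Mean training and validation AUC of a (C, gamma) candidate over CV folds."""
    train_aucs, val_aucs = [], []
    for tr, va in folds.split(X, y):
        svm = SVC(kernel="linear", C=c, max_iter=200_000)
        with warnings.catch_warnings():
            # extreme (C, gamma) candidates may hit the iteration cap; they
            # are simply scored poorly and discarded by the search
            warnings.simplefilter("ignore")
            svm.fit(X[tr] / gamma, y[tr])
        d_tr = svm.decision_function(X[tr] / gamma)
        d_va = svm.decision_function(X[va] / gamma)
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        train_aucs.append(roc_auc_score(y[tr], d_tr))
        val_aucs.append(roc_auc_score(y[va], d_va))
    if not val_aucs:
        return 0.5, 0.5
    return float(np.mean(train_aucs)), float(np.mean(val_aucs))


def _platt_calibration(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Binomial-logit (Platt sigmoid) fit of P(y=1 | decision value)."""
    lr = LogisticRegression(C=1e6, max_iter=5000)
    lr.fit(decision.reshape(-1, 1), y)
    a, b = float(lr.coef_[0, 0]), float(lr.intercept_[0])
    if a <= 0:  # pathological fit: fall back to the unscaled logistic
        logger.warning("calibration slope non-positive; falling back to sigmoid(g)")
        return 1.0, 0.0
    return a, b


def train_signature(
    split: SplitSet,
    cfg: SVMConfig,
    *,
    feature_names: Sequence[str] | None = None,
    normalization: NormalizationParams | None = None,
) -> SignatureModel:
    """Train the calibrated linear-SVM signature on a training split.

    Runs ``cfg.cv_runs`` independent rounds of ``cfg.cv_folds``-fold CV; in
    each round Bayesian optimization proposes (C, gamma) candidates scored
    by mean validation AUC, candidates with validation AUC above training
    AUC are discarded as overfitting-prone, and the best survivor defines
    that round's model.  Survivors are re-scored on the full training set
    and ranked by (AUC, informedness); the winner is Platt-calibrated.
    """
    X, y = split.train_X, split.train_y
    if len(np.unique(y)) < 2:
        raise ValueError("training split must contain both classes")
    names = tuple(feature_names) if feature_names else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    rng = np.random.default_rng(cfg.seed)
    log_bounds = [
        (np.log10(cfg.c_range[0]), np.log10(cfg.c_range[1])),
        (np.log10(cfg.gamma_range[0]), np.log10(cfg.gamma_range[1])),
    ]

    run_models: list[tuple[float, float, SVC, float]] = []  # (val_auc, gamma, svm, c)
    n_discarded = 0
    for run in range(cfg.cv_runs):
        folds = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        evaluated: list[tuple[float, float, float, float]] = []  # c, gamma, train, val

        def objective(point: np.ndarray) -> float:
            c, gamma = 10.0 ** point[0], 10.0 ** point[1]
            tr_auc, va_auc = _fold_aucs(X, y, c, gamma, folds)
            evaluated.append((c, gamma, tr_auc, va_auc))
            return va_auc

        _bayesopt.maximize(
            objective, log_bounds, n_iter=cfg.bayes_opt_iters, rng=rng
        )
        survivors = [e for e in evaluated if e[3] <= e[2]]
        n_discarded += len(evaluated) - len(survivors)
        if not survivors:
            logger.warning("run %d: every candidate overfit-flagged; filter relaxed", run)
            survivors = evaluated
        c, gamma, _, va = max(survivors, key=lambda e: e[3])
        svm = SVC(kernel="linear", C=c, max_iter=200_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm.fit(X / gamma, y)
        run_models.append((va, gamma, svm, c))

    # re-score each run's model on the full training set, rank by (AUC, I)
    scored = []
    for va, gamma, svm, c in run_models:
        d = svm.decision_function(X / gamma)
        auc = roc_auc_score(y, d)
        pred = (d > 0).astype(int)
        inf = informedness_from_counts(
            int(((pred == 1) & (y == 1)).sum()),
            int(((pred == 0) & (y == 1)).sum()),
            int(((pred == 0) & (y == 0)).sum()),
            int(((pred == 1) & (y == 0)).sum()),
        )
        scored.append((auc, inf, gamma, svm, c, va))
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    best_auc, best_inf, gamma, svm, c, best_va = scored[0]

    weights = svm.coef_.ravel() / gamma  # fold the kernel scale into the weights
    intercept = float(svm.intercept_[0])
    decision = X @ weights + intercept
    calibration = _platt_calibration(decision, y)

    return SignatureModel(
        names,
        weights,
        intercept,
        calibration,
        normalization,
        provenance={
            "config": cfg.to_dict(),
            "C": c,
            "gamma": gamma,
            "split_rule": split.rule,
            "split_seed": split.seed,
            "cv": {
                "runs": cfg.cv_runs,
                "candidates_discarded_overfit": n_discarded,
                "selected_run_val_auc": best_va,
                "training_auc": best_auc,
                "training_informedness": best_inf,
            },
        },
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Confusion counts, SN/SP/I/PPV/NPV, ROC and AUC of one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    waterfall: tuple[np.ndarray, np.ndarray] | None = None  # sorted scores, labels

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def npv(self) -> float | None:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else None

    @property
    def informedness(self) -> float | None:
        sn, sp = self.sensitivity, self.specificity
        return None if sn is None or sp is None else sn + sp - 1.0

    def report(self) -> dict:
        """Rounded summary: integer percentages, I and AUC to 2 decimals."""

        def pct(v):
            return "n/a" if v is None else int(round(v * 100))

        out = {
            "n": self.n,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "SN": pct(self.sensitivity),
            "SP": pct(self.specificity),
            "PPV": pct(self.ppv),
            "NPV": pct(self.npv),
            "I": "n/a" if self.informedness is None else round(self.informedness, 2),
        }
        if self.auc is not None:
            out["AUC"] = round(self.auc, 2)
        if self.auc_ci is not None:
            out["AUC_CI95"] = [round(self.auc_ci[0], 2), round(self.auc_ci[1], 2)]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.report(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float] | None = None,
    *,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricsReport:
    """Build a full metrics report from labels and binary predictions.

    When ``scores`` are given the ROC curve, AUC and its 95% CI are added,
    along with the waterfall data (per-sample score sorted, with labels).
    """
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    if y.shape != pred.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    rep = MetricsReport(tp, fp, tn, fn)
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        fpr, tpr, thr, auc, ci = roc_with_ci(
            s, y, method=ci_method, n_boot=n_boot, seed=seed
        )
        rep.auc, rep.auc_ci, rep.roc = auc, ci, (fpr, tpr, thr)
        order = np.argsort(-s, kind="stable")
        rep.waterfall = (s[order], y[order])
    return rep


def _delong_ci(scores: np.ndarray, y: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI for the AUC (normal approximation on the AUC scale)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    *,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Empirical ROC with trapezoidal AUC and a 95% CI.

    Ties are handled by rank averaging, so the AUC equals the Mann-Whitney
    statistic U / (n1 n2).  The CI is a stratified bootstrap (percentile,
    default 2000 replicates) or DeLong's normal approximation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bi = np.concatenate(
                [
                    rng.choice(pos_idx, len(pos_idx), replace=True),
                    rng.choice(neg_idx, len(neg_idx), replace=True),
                ]
            )
            reps[i] = roc_auc_score(y[bi], s[bi])
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    elif method == "delong":
        ci = _delong_ci(s, y, auc)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return fpr, tpr, thr, auc, ci


# ---------------------------------------------------------------------------
# figures


def plot_roc(report: MetricsReport, path: str | Path, title: str = "ROC") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.roc is None:
        raise ValueError("report carries no ROC data")
    fpr, tpr, _ = report.roc
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, lw=2, label=f"AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_waterfall(report: MetricsReport, path: str | Path, title: str = "Waterfall") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.waterfall is None:
        raise ValueError("report carries no waterfall data")
    s, y = report.waterfall
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = np.where(y == 1, "#c0392b", "#2980b9")
    ax.bar(np.arange(len(s)), s - 0.5, bottom=0.5, color=colors, width=1.0)
    ax.axhline(0.5, color="k", lw=1)
    ax.set_xlabel("samples (sorted by score)")
    ax.set_ylabel("radiomic score")
    ax.set_title(f"{title} (red = GG≥3, blue = GG<3)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
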