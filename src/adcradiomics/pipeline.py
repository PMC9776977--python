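"""End-to-end orchestration: cohort -> features -> selection -> model -> reports.

Runs the two experiments — csPCa (GG >= 3) prediction and the GG-group
similarity analysis — from a single :class:`RunConfig`, writing a fixed set
of artifacts plus a manifest with SHA-256 hashes so that reruns with the
same config and seed are byte-reproducible.

Augmentation modes:

* ``split_first`` (default): partition the original lesions 75/25 first,
  then oversample the two pools independently (no synthetic sample ever
  straddles the split);
* ``augment_then_split``: oversample the whole cohort to 200 and split the
  augmented pool 150/50 — the ordering used by the analysis this package
  re-implements, at the cost of potential synthetic-sample leakage;
* ``none``: no oversampling (the "preliminary model" pathway); the report
  is flagged accordingly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import SplitSet, augment, split
from .features import FeatureTable, build_feature_table
from .ggstats import GGSimilarityReport, gg_similarity_report, plot_gg_boxplot
from .model import (
    MetricsReport,
    SignatureModel,
    SVMConfig,
    confusion_metrics,
    plot_roc,
    plot_waterfall,
    train_signature,
)
from .selection import SelectionResult, exhaustive_quadruple_search, lasso_screen, minmax_normalize
from .simulate import Cohort, CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

AUGMENT_MODES = ("split_first", "augment_then_split", "none")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    cohort_dir: str | None = None  # load a saved cohort instead of simulating
    cohort_spec: CohortSpec | None = None
    window: int = 9
    bins: int = 32
    min_support: float = 0.5
    selection_alpha: float = 1e-3
    lasso_folds: int = 10
    max_screened: int | None = None
    augment_mode: str = "split_first"
    augment_method: str = "interpolate"
    n_target: int = 200
    train_frac: float = 0.75
    split_rule: str = "random"
    normalization_mode: str = "full_cohort"  # or "train_only" (leakage-safe)
    svm: SVMConfig = field(default_factory=SVMConfig)
    ci_method: str = "bootstrap"
    seed: int = 0
    outdir: str = "adcradiomics_run"

    def __post_init__(self) -> None:
        if self.augment_mode not in AUGMENT_MODES:
            raise ValueError(f"augment_mode must be one of {AUGMENT_MODES}")
        if self.normalization_mode not in ("full_cohort", "train_only"):
            raise ValueError("normalization_mode must be 'full_cohort' or 'train_only'")
        if self.normalization_mode == "train_only" and self.augment_mode == "augment_then_split":
            raise ValueError(
                "train-only normalization requires an original-lesion split "
                "(augment_mode 'split_first' or 'none')"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort_spec" in d and isinstance(d["cohort_spec"], dict):
            import tempfile

            from .simulate import CohortSpec as _CS

            with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
                yaml.safe_dump(d["cohort_spec"], fh)
            d["cohort_spec"] = _CS.from_yaml(fh.name)
        if "svm" in d and isinstance(d["svm"], dict):
            d["svm"] = SVMConfig(**{k: tuple(v) if k.endswith("_range") else v for k, v in d["svm"].items()})
        return cls(**d)


@dataclass
class RunReport:
    """Artifacts and headline numbers of one pipeline run."""

    table: FeatureTable
    selection: SelectionResult
    model: SignatureModel
    split: SplitSet
    metrics_train: MetricsReport
    metrics_test: MetricsReport
    similarity: GGSimilarityReport
    artifacts: dict[str, str]
    config: RunConfig


def _seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ("cohort", "lasso", "split", "augment_train", "augment_test", "svm", "ci")
    return {n: int(rng.integers(2**31)) for n in names}


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - reported with stage context
            raise StageError(name, err) from err
        logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)
        return out

    return wrap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> RunReport:
    """Run the whole analysis and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)

    # --- cohort ---------------------------------------------------------
    if config.cohort_dir is not None:
        cohort = _stage("cohort")(Cohort.load, config.cohort_dir)
    else:
        spec = config.cohort_spec or CohortSpec(seed=seeds["cohort"])
        cohort = _stage("cohort")(generate_cohort, spec)

    # --- features -------------------------------------------------------
    table: FeatureTable = _stage("features")(
        build_feature_table,
        cohort.slices,
        window=config.window,
        bins=config.bins,
        min_support=config.min_support,
    )
    table.to_csv(outdir / "feature_table.csv")
    y = table.y
    gg = table.labels["gg"].to_numpy()

    # --- normalization + selection -------------------------------------
    def do_selection():
        if config.normalization_mode == "train_only":
            pre = split(
                np.zeros((len(y), 1)), y,
                train_frac=config.train_frac, rule="random", seed=seeds["split"],
            )
            norm_fit_rows = table.features.iloc[pre.train_idx]
            _, params = minmax_normalize(norm_fit_rows)
            normed = params.transform(table.features)
            orig_split_idx = (pre.train_idx, pre.test_idx)
        else:
            normed, params = minmax_normalize(table.features)
            orig_split_idx = None
        screened = lasso_screen(
            normed, y, folds=config.lasso_folds, seed=seeds["lasso"],
            max_features=config.max_screened,
        )
        if len(screened) < 4:
            raise RuntimeError(
                f"LASSO screen kept only {len(screened)} feature(s); cannot search quadruples"
            )
        sel = exhaustive_quadruple_search(
            normed[screened], y, alpha=config.selection_alpha
        )
        return normed, params, sel, orig_split_idx

    normed, norm_params, sel, orig_split_idx = _stage("selection")(do_selection)
    sel.to_json(outdir / "selection.json")
    X4 = normed[sel.chosen_features].to_numpy(dtype=float)

    # --- augmentation + split ------------------------------------------
    def do_split() -> SplitSet:
        if config.augment_mode == "augment_then_split":
            aug = augment(
                X4, y, n_target=config.n_target, seed=seeds["augment_train"],
                method=config.augment_method,
            )
            return split(
                aug, train_frac=config.train_frac, rule=config.split_rule,
                seed=seeds["split"],
            )
        if orig_split_idx is not None:
            tr_idx, te_idx = orig_split_idx
            base = SplitSet(
                X4[tr_idx], y[tr_idx], X4[te_idx], y[te_idx],
                "random", seeds["split"], tr_idx, te_idx,
            )
        else:
            base = split(
                X4, y, train_frac=config.train_frac, rule=config.split_rule,
                seed=seeds["split"],
            )
        if config.augment_mode == "none":
            return base
        n_tr = int(round(config.n_target * config.train_frac))
        n_te = config.n_target - n_tr
        aug_tr = augment(
            base.train_X, base.train_y, n_target=n_tr,
            seed=seeds["augment_train"], method=config.augment_method,
        )
        aug_te = augment(
            base.test_X, base.test_y, n_target=n_te,
            seed=seeds["augment_test"], method=config.augment_method,
        )
        return SplitSet(
            aug_tr.samples, aug_tr.labels, aug_te.samples, aug_te.labels,
            f"{base.rule}+augment", seeds["split"],
        )

    splitset = _stage("augment/split")(do_split)

    # --- model ----------------------------------------------------------
    cfg = SVMConfig(**{**config.svm.to_dict(), "seed": seeds["svm"]})
    cfg.c_range = tuple(cfg.c_range)
    cfg.gamma_range = tuple(cfg.gamma_range)
    model: SignatureModel = _stage("train")(
        train_signature, splitset, cfg,
        feature_names=sel.chosen_features, normalization=norm_params,
    )
    model.provenance["augment_mode"] = config.augment_mode
    if config.augment_mode == "none":
        model.provenance["note"] = (
            "preliminary model developed on the original population, "
            "without any feature sample augmentation"
        )
    model.to_json(outdir / "model.json")

    # --- evaluation -----------------------------------------------------
    def evaluate(X: np.ndarray, yy: np.ndarray) -> MetricsReport:
        scores = model.score(X)
        return confusion_metrics(
            yy, (np.asarray(scores) >= 0.5).astype(int), scores,
            ci_method=config.ci_method, seed=seeds["ci"],
        )

    metrics_train = _stage("metrics")(evaluate, splitset.train_X, splitset.train_y)
    metrics_test = _stage("metrics")(evaluate, splitset.test_X, splitset.test_y)
    metrics_train.to_json(outdir / "metrics_train.json")
    metrics_test.to_json(outdir / "metrics_test.json")

    # --- similarity on the original lesions -----------------------------
    decision = model.decision_value(X4)
    similarity = _stage("similarity")(gg_similarity_report, decision, gg)
    similarity.to_json(outdir / "similarity.json")

    # --- figures --------------------------------------------------------
    plot_roc(metrics_train, figdir / "roc_train.png", "ROC — training")
    plot_roc(metrics_test, figdir / "roc_test.png", "ROC — test")
    plot_waterfall(metrics_train, figdir / "waterfall_train.png", "Training")
    plot_waterfall(metrics_test, figdir / "waterfall_test.png", "Test")
    plot_gg_boxplot(decision, gg, figdir / "boxplot_gg.png")

    artifact_names = [
        "feature_table.csv", "selection.json", "model.json",
        "metrics_train.json", "metrics_test.json", "similarity.json",
    ]
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "augment_mode": config.augment_mode,
        "normalization_mode": config.normalization_mode,
        "chosen_features": sel.chosen_features,
        "artifacts": {n: _sha256(outdir / n) for n in artifact_names},
        "figures": sorted(p.name for p in figdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts = {n: str(outdir / n) for n in artifact_names}
    artifacts["manifest.json"] = str(outdir / "manifest.json")

    return RunReport(
        table, sel, model, splitset, metrics_train, metrics_test,
        similarity, artifacts, config,
    )
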