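"""Classification, validation harness and the experiment runner.

The classifier is a support vector machine with an RBF kernel; problems
with more than two classes are handled one-against-all: one binary machine
per class versus the rest, prediction by argmax of the decision values
(ties broken toward the lowest class index).

Two validation schemes are provided.  Resubstitution (all-train-all-test)
fits the normalization and the classifier on the entire matrix and scores
the same rows — a self-consistency ceiling.  Six-fold cross-validation uses
the segment index as the fold id, so each fold holds exactly one 30-s
segment from every (subject, stage) recording; normalization statistics are
re-estimated from the five training folds in every split.

The statsmodels-style surface is :class:`EmotionClassifier` (built from a
feature matrix) whose :meth:`~EmotionClassifier.fit` returns a
:class:`ClassificationResults` with accuracies, per-fold detail, selected
features and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import featurization as fz
from . import selection as sel

N_FOLDS = 6


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-kernel SVM settings; ``gamma='auto'`` means 1 / (n_features × pooled
    feature variance) — the data-driven kernel width."""

    C: float = 10.0
    gamma: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be > 0 or 'auto'")

    @property
    def sklearn_gamma(self):
        # sklearn's "scale" = 1 / (n_features * X.var()) — the 'auto' contract
        return "scale" if self.gamma == "auto" else self.gamma


class OneVsAllSVM:
    """One-against-all assembly of binary RBF-SVMs.

    For K classes, K binary machines are trained (class k vs rest); the
    prediction is the class with the largest decision value, ties resolved
    toward the lowest class index.  A two-class problem uses one binary
    machine directly.
    """

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.classes_: np.ndarray | None = None
        self._machines: list[SVC] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsAllSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set holds a single class")
        cfg = self.config
        self._machines = []
        if len(self.classes_) == 2:
            m = SVC(kernel="rbf", C=cfg.C, gamma=cfg.sklearn_gamma, random_state=cfg.seed)
            m.fit(X, (y == self.classes_[1]).astype(int))
            self._machines.append(m)
        else:
            for cls in self.classes_:
                m = SVC(kernel="rbf", C=cfg.C, gamma=cfg.sklearn_gamma, random_state=cfg.seed)
                m.fit(X, (y == cls).astype(int))
                self._machines.append(m)
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if len(self.classes_) == 2:
            d = self._machines[0].decision_function(X)
            return np.column_stack([-d, d])
        return np.column_stack([m.decision_function(X) for m in self._machines])

    def predict(self, X: np.ndarray) -> np.ndarray:
        dv = self.decision_values(X)
        # argmax returns the first (lowest-index) class on exact ties
        return self.classes_[np.argmax(dv, axis=1)]


def train_classifier(X: np.ndarray, y: np.ndarray, config: ClassifierConfig | None = None) -> OneVsAllSVM:
    """Fit the one-against-all RBF-SVM on normalized features."""
    return OneVsAllSVM(config).fit(X, y)


def make_folds(matrix: pd.DataFrame) -> pd.Series:
    """Deterministic segment-index folds.

    Fold k (1–6) collects segment k of every (subject, stage) recording, so
    every recording contributes exactly one segment per fold.  Recordings
    without all six segments are dropped with a warning.
    """
    counts = matrix.groupby(["subject_id", "stage"])["segment_idx"].nunique()
    bad = counts[counts != N_FOLDS]
    folds = matrix["segment_idx"].astype(int)
    if len(bad):
        warnings.warn(f"dropping {len(bad)} recordings without {N_FOLDS} segments")
        keep = ~matrix.set_index(["subject_id", "stage"]).index.isin(bad.index)
        folds = folds.where(pd.Series(keep, index=matrix.index), other=-1)
    return folds.rename("fold")


def resubstitution_accuracy(
    matrix: pd.DataFrame,
    feature_cols: list[str],
    config: ClassifierConfig | None = None,
    subset: tuple[int, ...] | None = None,
) -> float:
    """All-train-all-test accuracy: z-score and train on every row, then
    score those same rows."""
    cols = [feature_cols[i] for i in subset] if subset is not None else list(feature_cols)
    norm = fz.zscore_fit(matrix, cols)
    X = norm.apply(matrix)[cols].to_numpy()
    y = matrix["label"].to_numpy()
    model = train_classifier(X, y, config)
    return float(np.mean(model.predict(X) == y))


def kfold_cv_accuracy(
    matrix: pd.DataFrame,
    feature_cols: list[str],
    folds: pd.Series | None = None,
    config: ClassifierConfig | None = None,
    subset: tuple[int, ...] | None = None,
) -> tuple[float, list[float]]:
    """Segment-fold cross-validation.

    For each fold, normalization is fitted on the five training folds only,
    the classifier trained on them, and the held-out fold scored; returns
    the unweighted mean of the fold accuracies and the per-fold vector.
    """
    cols = [feature_cols[i] for i in subset] if subset is not None else list(feature_cols)
    folds = make_folds(matrix) if folds is None else folds
    accs: list[float] = []
    for k in sorted(folds[folds > 0].unique()):
        train = matrix[(folds != k) & (folds > 0)]
        test = matrix[folds == k]
        if set(np.unique(test["label"])) - set(np.unique(train["label"])):
            raise ValueError(f"fold {k}: class absent from training folds")
        norm = fz.zscore_fit(train, cols)
        model = train_classifier(norm.apply(train)[cols].to_numpy(), train["label"].to_numpy(), config)
        pred = model.predict(norm.apply(test)[cols].to_numpy())
        accs.append(float(np.mean(pred == test["label"].to_numpy())))
    return float(np.mean(accs)), accs


def make_fitness_evaluator(
    matrix: pd.DataFrame,
    feature_cols: list[str],
    config: ClassifierConfig | None = None,
    validation: str = "sixfold",
) -> sel.MemoizedEvaluator:
    """Wrapper-selection fitness: accuracy of the configured validation on a
    column subset.  Memoized, so repeated subsets are not re-evaluated.

    Normalization statistics are per-column and hence independent of the
    candidate subset, so the z-scored fold arrays are precomputed once and a
    subset evaluation only slices columns and refits the SVM — the same
    numbers as the row-level harness at a fraction of the cost.
    """
    cols = list(feature_cols)
    if validation == "resubstitution":
        norm = fz.zscore_fit(matrix, cols)
        X_all = norm.apply(matrix)[cols].to_numpy()
        y_all = matrix["label"].to_numpy()

        def score(subset: tuple[int, ...]) -> float:
            X = X_all[:, list(subset)]
            model = train_classifier(X, y_all, config)
            return float(np.mean(model.predict(X) == y_all))

    else:
        folds = make_folds(matrix)
        splits = []
        for k in sorted(folds[folds > 0].unique()):
            train = matrix[(folds != k) & (folds > 0)]
            test = matrix[folds == k]
            norm = fz.zscore_fit(train, cols)
            splits.append(
                (
                    norm.apply(train)[cols].to_numpy(),
                    train["label"].to_numpy(),
                    norm.apply(test)[cols].to_numpy(),
                    test["label"].to_numpy(),
                )
            )

        def score(subset: tuple[int, ...]) -> float:
            idx = list(subset)
            accs = []
            for X_tr, y_tr, X_te, y_te in splits:
                model = train_classifier(X_tr[:, idx], y_tr, config)
                accs.append(float(np.mean(model.predict(X_te[:, idx]) == y_te)))
            return float(np.mean(accs))

    return sel.MemoizedEvaluator(score)


class EmotionClassifier:
    """Emotion-state classification model over a segment feature matrix.

    Parameters
    ----------
    features : cohort feature table from
        :func:`ppgaffect.featurization.extract_cohort_features`, or an
        already-assembled task matrix (then pass ``assembled=True``).
    task : one of the task names in :data:`ppgaffect.featurization.TASKS`.
    feature_set : "waveform10", "differential10" or "combined20".
    config : SVM settings.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        task: str = "4C",
        feature_set: str = "waveform10",
        config: ClassifierConfig | None = None,
        assembled: bool = False,
    ):
        self.task = task
        self.feature_set = feature_set
        self.feature_cols = list(fz.FEATURE_SETS[feature_set])
        self.config = config or ClassifierConfig()
        self.matrix = features if assembled else fz.assemble_matrix(features, feature_set, task)

    @classmethod
    def from_cohort(cls, cohort, task="4C", feature_set="waveform10", config=None, **extract_kw):
        """Build directly from a synthetic cohort (delineates + featurizes)."""
        features = fz.extract_cohort_features(cohort, **extract_kw)
        return cls(features, task=task, feature_set=feature_set, config=config)

    def fit(
        self,
        validation: str = "sixfold",
        selection: str = "none",
        ga_config: sel.GAConfig | None = None,
    ) -> "ClassificationResults":
        """Train and validate, optionally with wrapper feature selection.

        ``selection``: "none", "full" (exhaustive, feature sets up to 20) or
        "ga" (genetic algorithm).  Selection fitness uses the same
        validation scheme as the reported accuracy.
        """
        if validation not in ("sixfold", "resubstitution"):
            raise ValueError(f"unknown validation {validation!r}")
        evaluator = make_fitness_evaluator(self.matrix, self.feature_cols, self.config, validation)
        n = len(self.feature_cols)
        log: list = []
        if selection == "none":
            subset = tuple(range(n))
        elif selection == "full":
            subset, _, log = sel.full_search(evaluator, n)
        elif selection == "ga":
            subset, _, log = sel.ga_select(evaluator, n, ga_config or sel.GAConfig())
        else:
            raise ValueError(f"unknown selection {selection!r}")

        per_fold: list[float] = []
        if validation == "resubstitution":
            accuracy = resubstitution_accuracy(self.matrix, self.feature_cols, self.config, subset)
        else:
            accuracy, per_fold = kfold_cv_accuracy(
                self.matrix, self.feature_cols, None, self.config, subset
            )
        return ClassificationResults(
            model=self,
            validation=validation,
            selection=selection,
            accuracy=accuracy,
            per_fold_accuracies=per_fold,
            selected_features=[self.feature_cols[i] for i in subset],
            n_evaluations=evaluator.n_evaluations,
            selection_log=log,
        )


@dataclass
class ClassificationResults:
    """Fitted-and-validated outcome of one (task, feature set, validation,
    selection) cell."""

    model: EmotionClassifier
    validation: str
    selection: str
    accuracy: float
    per_fold_accuracies: list[float]
    selected_features: list[str]
    n_evaluations: int
    selection_log: list = field(default_factory=list, repr=False)

    def summary(self) -> str:
        lines = [
            "Emotion-state classification results",
            "=" * 44,
            f"task:               {self.model.task}",
            f"feature set:        {self.model.feature_set} ({len(self.model.feature_cols)} features)",
            f"rows:               {len(self.model.matrix)}",
            f"classifier:         RBF SVM, one-against-all, C={self.model.config.C}, gamma={self.model.config.gamma}",
            f"validation:         {self.validation}",
            f"feature selection:  {self.selection} ({self.n_evaluations} subset evaluations)",
            f"accuracy:           {self.accuracy:.4f} ({self.accuracy:.2%})",
        ]
        if self.per_fold_accuracies:
            folds = "  ".join(f"{a:.3f}" for a in self.per_fold_accuracies)
            lines.append(f"per-fold accuracy:  {folds}")
        if self.selection != "none":
            lines.append(f"selected features:  {', '.join(self.selected_features)}")
        return "\n".join(lines)


BASELINE_TASKS = [f"baseline_vs_{s}" for s in fz.EMOTION_STAGES]
MULTI_TASKS = ["2C", "3C", "4C"]


@dataclass
class ExperimentConfig:
    """Grid for the experiment runner; defaults cover the full
    task × feature-set × validation × selection design."""

    baseline_feature_set: str = "waveform10"
    feature_sets: tuple[str, ...] = ("waveform10", "differential10", "combined20")
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ga: sel.GAConfig = field(default_factory=sel.GAConfig)
    with_selection: bool = True
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(
            {
                "baseline_feature_set": self.baseline_feature_set,
                "feature_sets": self.feature_sets,
                "C": self.classifier.C,
                "gamma": self.classifier.gamma,
                "ga": vars(self.ga),
                "with_selection": self.with_selection,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Accuracy tables of the experiment grid.

    ``table4``: baseline-vs-state accuracies per validation scheme.
    ``table5``: 2C/3C/4C accuracies per feature set, six-fold CV, with and
    without selection.  ``table6_incidence``: which of the 20 combined
    features the selector kept per task.  ``report`` holds every cell.
    """

    table4: pd.DataFrame
    table5: pd.DataFrame
    table6_incidence: pd.DataFrame
    report: pd.DataFrame
    config_hash: str

    def to_dir(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table4.to_csv(out / "table4.tsv", sep="\t", index=False)
        self.table5.to_csv(out / "table5.tsv", sep="\t", index=False)
        self.table6_incidence.to_csv(out / "table6_incidence.tsv", sep="\t", index=False)
        self.report.to_json(out / "report.json", orient="records", indent=2)


def run_experiment(features: pd.DataFrame, config: ExperimentConfig | None = None) -> ExperimentReport:
    """Execute the full task × feature-set × validation × selection grid.

    ``features`` is the cohort feature table.  Failures in one cell are
    logged and do not abort the others.
    """
    config = config or ExperimentConfig()
    cells: list[dict] = []

    def run_cell(task, feature_set, validation, selection, ga_config=None):
        try:
            model = EmotionClassifier(features, task, feature_set, config.classifier)
            res = model.fit(validation=validation, selection=selection, ga_config=ga_config)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            warnings.warn(f"cell ({task}, {feature_set}, {validation}, {selection}) failed: {exc}")
            return None
        cells.append(
            {
                "task": task,
                "feature_set": feature_set,
                "validation": validation,
                "selection": selection,
                "accuracy": res.accuracy,
                "selected_features": ",".join(res.selected_features),
                "seed": config.seed,
                "config_hash": config.hash(),
            }
        )
        return res

    # baseline-vs-state binary tasks, both validation schemes
    for task in BASELINE_TASKS:
        for validation in ("resubstitution", "sixfold"):
            run_cell(task, config.baseline_feature_set, validation, "none")

    # multi-state categorization: six-fold CV per feature set,
    # without and (optionally) with selection — full search on the 10-feature
    # sets, GA on the 20-feature combined set.
    incidence_rows: dict[str, dict[str, bool]] = {}
    for task in MULTI_TASKS:
        for feature_set in config.feature_sets:
            run_cell(task, feature_set, "resubstitution", "none")
            run_cell(task, feature_set, "sixfold", "none")
            if config.with_selection:
                method = "ga" if feature_set == "combined20" else "full"
                ga_cfg = replace(config.ga) if method == "ga" else None
                res = run_cell(task, feature_set, "sixfold", method, ga_cfg)
                if res is not None and feature_set == "combined20":
                    incidence_rows[task] = {
                        col: col in res.selected_features for col in fz.COMBINED_FEATURES
                    }

    report = pd.DataFrame(cells)
    t4 = report[report["task"].isin(BASELINE_TASKS)]
    table4 = t4.pivot_table(index="validation", columns="task", values="accuracy").reset_index()
    t5 = report[report["task"].isin(MULTI_TASKS) & (report["validation"] == "sixfold")]
    table5 = t5.pivot_table(
        index=["selection", "feature_set"], columns="task", values="accuracy"
    ).reset_index()
    if incidence_rows:
        table6 = pd.DataFrame(incidence_rows).rename_axis("feature").reset_index()
    else:
        table6 = pd.DataFrame({"feature": fz.COMBINED_FEATURES})
    return ExperimentReport(
        table4=table4, table5=table5, table6_incidence=table6, report=report, config_hash=config.hash()
    )
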