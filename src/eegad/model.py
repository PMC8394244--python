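"""Panel screening, fusion and validation of diagnostic models.

Every candidate panel is scored by a linear support-vector machine under
stratified cross-validation with per-fold standardisation; panels whose
pooled out-of-fold sensitivity and specificity both reach 80% survive.
Surviving panels are fused by concatenating their biomarkers into one
linear-discriminant model, and a final optimisation searches the small
cross-method panels (sizes 1..4) for the smallest compliant panel.

The :class:`AdDiagnosisModel` / :class:`AdDiagnosisResults` pair wraps
these steps in the fit/results idiom: build the model from a biomarker
table, call ``fit`` and inspect ``summary()``, then ``validate`` on an
unseen cohort.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import BiomarkerTable
from .io import GROUP_AD, GROUP_NOLD
from .panels import PanelSpec, build_stage2_panels
from .montage import FeatureId

logger = logging.getLogger(__name__)

SEN_MIN = 80.0
SPEC_MIN = 80.0
TRAIN_FRAC = 0.6
CV_FOLDS = 10


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with AD as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Classification metrics; percentages in [0, 100], MCC in [-1, 1].

    A metric whose defining ratio has a zero denominator is ``None``
    (absent), never coerced to 0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f_measure: float | None
    mcc: float | None
    ppv: float | None
    npv: float | None

    def rounded(self) -> dict[str, float | None]:
        """Report form: percentages and MCC to two decimals."""
        return {k: (None if v is None else round(v, 2))
                for k, v in vars(self).items()}

    def compliant(self, sen_min: float = SEN_MIN,
                  spec_min: float = SPEC_MIN) -> bool:
        return (self.sensitivity is not None and self.specificity is not None
                and self.sensitivity >= sen_min
                and self.specificity >= spec_min)

    @property
    def sen_spec_sum(self) -> float:
        return (self.sensitivity or 0.0) + (self.specificity or 0.0)


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Sensitivity, specificity, accuracy, F-measure, MCC, PPV and NPV.

    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` and
    ``F = 2*PPV*Sen / (PPV + Sen)``; percentages on the 0-100 scale.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sen = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    acc = (tp + tn) / cm.total
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    f = None
    if ppv is not None and sen is not None and (ppv + sen) > 0:
        f = 2 * ppv * sen / (ppv + sen)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    pct = lambda v: None if v is None else 100.0 * v
    return PerformanceMetrics(pct(sen), pct(spec), pct(acc), pct(f),
                              mcc, pct(ppv), pct(npv))


def confusion_from_labels(y_true: Sequence[str],
                          y_pred: Sequence[str]) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == GROUP_AD
    pos_p = y_pred == GROUP_AD
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def split_train_test(table: BiomarkerTable, train_frac: float = TRAIN_FRAC,
                     seed: int = 0) -> tuple[BiomarkerTable, BiomarkerTable]:
    """Stratified, seeded train/test split of a biomarker table."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for grp in (GROUP_AD, GROUP_NOLD):
        ids = list(table.groups.index[table.groups == grp])
        if len(ids) < 2:
            raise ValueError(f"group {grp} needs at least 2 subjects")
        rng.shuffle(ids)
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both parts non-empty
        train_ids += ids[:n_train]
        test_ids += ids[n_train:]
    def pick(ids):
        return BiomarkerTable(table.values.loc[ids].copy(),
                              table.groups.loc[ids].copy(), dict(table.meta))
    return pick(sorted(train_ids)), pick(sorted(test_ids))


def _panel_xy(panel_columns: list[str],
              table: BiomarkerTable) -> tuple[np.ndarray, np.ndarray]:
    X = table.values[panel_columns].to_numpy(dtype=float)
    y = table.groups.to_numpy()
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.info("dropping %d subjects with non-finite panel values",
                    int((~keep).sum()))
    return X[keep], y[keep]


def _svm_pipeline():
    # linear kernel, unit C: a conservative screen for small-n tabular data;
    # the scaler standardises inside each CV training fold
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def evaluate_panel_svm(panel: PanelSpec | list[str], table: BiomarkerTable,
                       folds: int = CV_FOLDS, seed: int = 0
                       ) -> PerformanceMetrics:
    """Cross-validated SVM screen of one panel.

    Stratified k-fold with per-fold standardisation; the out-of-fold
    predictions are pooled into a single confusion matrix.  Folds are
    reduced (with a warning) when a class has fewer members than folds.
    """
    cols = panel.columns if isinstance(panel, PanelSpec) else list(panel)
    X, y = _panel_xy(cols, table)
    class_min = min(np.sum(y == GROUP_AD), np.sum(y == GROUP_NOLD))
    if class_min < 2:
        raise ValueError("need at least 2 subjects per group after exclusions")
    n_folds = min(folds, int(class_min))
    if n_folds < folds:
        logger.warning("reducing folds from %d to %d (smallest class has %d)",
                       folds, n_folds, class_min)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = cross_val_predict(_svm_pipeline(), X, y, cv=cv)
    return metrics_from_confusion(confusion_from_labels(y, y_pred))


def filter_panels(scored: Iterable[tuple[PanelSpec, PerformanceMetrics]],
                  sen_min: float = SEN_MIN, spec_min: float = SPEC_MIN
                  ) -> list[tuple[PanelSpec, PerformanceMetrics]]:
    """Panels meeting both thresholds, ranked by fewest locations then
    descending sensitivity + specificity."""
    kept = [(p, m) for p, m in scored if m.compliant(sen_min, spec_min)]
    kept.sort(key=lambda pm: (pm[0].size, -pm[1].sen_spec_sum,
                              pm[0].panel_id))
    return kept


@dataclass
class DiagnosticModel:
    """A trained linear diagnostic model over a fixed biomarker list.

    Stores the standardisation statistics and the linear decision rule
    (weights, intercept, class order), so predictions are deterministic
    and the model round-trips through JSON exactly.
    """

    feature_columns: list[str]
    classes: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    kind: str  # "lda" or "svm"
    meta: dict = field(default_factory=dict)

    def decision_scores(self, values: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in values.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = values[self.feature_columns].to_numpy(dtype=float)
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.coef + self.intercept

    def predict(self, values: pd.DataFrame) -> pd.Series:
        scores = self.decision_scores(values)
        labels = np.where(scores > 0, self.classes[1], self.classes[0])
        return pd.Series(labels, index=values.index, name="prediction")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format_version": 1,
            "kind": self.kind,
            "feature_columns": self.feature_columns,
            "classes": self.classes,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DiagnosticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            feature_columns=d["feature_columns"],
            classes=d["classes"],
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            kind=d["kind"],
            meta=d.get("meta", {}),
        )


def _fit_linear(estimator, columns: list[str], table: BiomarkerTable,
                kind: str, meta: dict) -> DiagnosticModel:
    X, y = _panel_xy(columns, table)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    est = estimator.fit(Z, y)
    return DiagnosticModel(
        feature_columns=list(columns),
        classes=[str(c) for c in est.classes_],
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=est.coef_.ravel().copy(),
        intercept=float(np.ravel(est.intercept_)[0]),
        kind=kind,
        meta=meta,
    )


def fuse_lda(panels: Sequence[PanelSpec], train: BiomarkerTable,
             test: BiomarkerTable | None = None, seed: int = 0
             ) -> tuple[DiagnosticModel, PerformanceMetrics | None]:
    """Fuse surviving panels into one linear-discriminant model.

    All biomarkers of the surviving panels are concatenated (duplicates
    removed, order preserved) into one feature vector; the LDA is fitted
    on the training table and, when a test table is given, scored on it.
    Shrinkage regularisation is used when the feature count approaches
    the sample count (singular within-class covariance).
    """
    if not panels:
        raise ValueError("need at least one surviving panel to fuse")
    columns: list[str] = []
    for p in panels:
        for c in p.columns:
            if c not in columns:
                columns.append(c)
    n_train = len(train.values)
    if len(columns) >= n_train:
        logger.warning("LDA with %d features >= %d samples: applying "
                       "shrinkage regularisation", len(columns), n_train)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        lda = LinearDiscriminantAnalysis()
    model = _fit_linear(lda, columns, train, "lda",
                        {"n_panels": len(panels), "seed": seed})
    metrics = None
    if test is not None:
        metrics = validate(model, test)
    return model, metrics


def fit_panel_svm(panel: PanelSpec | list[str], table: BiomarkerTable,
                  meta: dict | None = None) -> DiagnosticModel:
    """Refit a linear SVM on a whole table (no cross-validation)."""
    cols = panel.columns if isinstance(panel, PanelSpec) else list(panel)
    return _fit_linear(SVC(kernel="linear", C=1.0), cols, table, "svm",
                       meta or {})


@dataclass
class OptimizeResult:
    """Outcome of the minimal-subset search."""

    panel: PanelSpec
    model: DiagnosticModel
    cv_metrics: PerformanceMetrics
    compliant: bool
    n_evaluated: int


def optimize_min_subset(biomarkers: Sequence[FeatureId],
                        dev: BiomarkerTable,
                        max_size: int = 4,
                        folds: int = CV_FOLDS,
                        sen_min: float = SEN_MIN,
                        spec_min: float = SPEC_MIN,
                        seed: int = 0,
                        max_panels: int | None = None) -> OptimizeResult:
    """Smallest cross-method panel meeting the screening thresholds.

    Panels of each size (1 upward) are evaluated by cross-validated SVM;
    as soon as a size yields compliant panels the best of them (maximal
    sensitivity + specificity, ties broken lexicographically) is
    returned, refitted on all development data.  If no panel of any size
    complies, the best-scoring panel is returned flagged non-compliant.
    ``max_panels`` caps the number of evaluations for scaled-down runs.
    """
    best: tuple[PanelSpec, PerformanceMetrics] | None = None
    n_eval = 0
    current_size = 1
    compliant_at_size: list[tuple[PanelSpec, PerformanceMetrics]] = []

    def decide(cands: list[tuple[PanelSpec, PerformanceMetrics]]):
        return min(cands, key=lambda pm: (-pm[1].sen_spec_sum,
                                          pm[0].panel_id))

    for panel in build_stage2_panels(list(biomarkers), max_size):
        if panel.size != current_size:
            if compliant_at_size:
                break
            current_size = panel.size
        if max_panels is not None and n_eval >= max_panels:
            logger.warning("panel-evaluation cap %d reached", max_panels)
            break
        m = evaluate_panel_svm(panel, dev, folds=folds, seed=seed)
        n_eval += 1
        if best is None or (m.sen_spec_sum, -panel.size) > (
                best[1].sen_spec_sum, -best[0].size):
            best = (panel, m)
        if m.compliant(sen_min, spec_min):
            compliant_at_size.append((panel, m))
    if compliant_at_size:
        panel, m = decide(compliant_at_size)
        compliant = True
    else:
        if best is None:
            raise ValueError("no panels were evaluated")
        panel, m = best
        compliant = False
        logger.warning("no panel of size <= %d met Sen/Spec >= %s/%s",
                       max_size, sen_min, spec_min)
    model = fit_panel_svm(panel, dev,
                          {"optimized": True, "seed": seed, "folds": folds,
                           "cv_metrics": m.rounded()})
    return OptimizeResult(panel, model, m, compliant, n_eval)


def validate(model: DiagnosticModel, table: BiomarkerTable
             ) -> PerformanceMetrics:
    """Score a trained model on an unseen cohort; never refits."""
    values = table.values
    missing = [c for c in model.feature_columns if c not in values.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    keep = np.isfinite(values[model.feature_columns].to_numpy(dtype=float)
                       ).all(axis=1)
    values = values.loc[keep]
    y_true = table.groups.loc[values.index].to_numpy()
    y_pred = model.predict(values).to_numpy()
    return metrics_from_confusion(confusion_from_labels(y_true, y_pred))


class AdDiagnosisModel:
    """AD-vs-control diagnostic model over a biomarker table.

    Parameters
    ----------
    table : BiomarkerTable
        Development cohort (subjects x biomarkers with group labels).
    panels : sequence of PanelSpec, optional
        Candidate panels to screen.  When omitted, ``fit`` screens the
        single-feature panels of every column in the table.
    sen_min, spec_min : float
        Screening thresholds in percent.

    Examples
    --------
    >>> model = AdDiagnosisModel(table, panels=panels)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    >>> res.validate(unseen_table)
    """

    def __init__(self, table: BiomarkerTable,
                 panels: Sequence[PanelSpec] | None = None,
                 sen_min: float = SEN_MIN, spec_min: float = SPEC_MIN,
                 train_frac: float = TRAIN_FRAC, folds: int = CV_FOLDS):
        self.table = table
        self.panels = list(panels) if panels is not None else [
            PanelSpec((FeatureId.from_column(c),))
            for c in table.values.columns
        ]
        self.sen_min = sen_min
        self.spec_min = spec_min
        self.train_frac = train_frac
        self.folds = folds

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, groups: pd.Series,
                       **kwargs) -> "AdDiagnosisModel":
        return cls(BiomarkerTable(values.copy(), pd.Series(groups)), **kwargs)

    def fit(self, seed: int = 0) -> "AdDiagnosisResults":
        """Screen the candidate panels and fuse the survivors."""
        train, test = split_train_test(self.table, self.train_frac, seed)
        scored = [(p, evaluate_panel_svm(p, train, self.folds, seed))
                  for p in self.panels]
        surviving = filter_panels(scored, self.sen_min, self.spec_min)
        fused = fused_metrics = None
        if surviving:
            fused, fused_metrics = fuse_lda([p for p, _ in surviving],
                                            train, test, seed)
        else:
            logger.warning("no panel met Sen/Spec >= %s/%s; no fused model",
                           self.sen_min, self.spec_min)
        return AdDiagnosisResults(self, train, test, scored, surviving,
                                  fused, fused_metrics, seed)


class AdDiagnosisResults:
    """Fitted screening results: per-panel metrics and the fused model."""

    def __init__(self, model: AdDiagnosisModel, train: BiomarkerTable,
                 test: BiomarkerTable,
                 scored: list[tuple[PanelSpec, PerformanceMetrics]],
                 surviving: list[tuple[PanelSpec, PerformanceMetrics]],
                 fused: DiagnosticModel | None,
                 fused_metrics: PerformanceMetrics | None, seed: int):
        self.model = model
        self.train = train
        self.test = test
        self.scored = scored
        self.surviving = surviving
        self.fused = fused
        self.fused_metrics = fused_metrics
        self.seed = seed

    @property
    def panel_metrics(self) -> pd.DataFrame:
        rows = []
        surviving_ids = {p.panel_id for p, _ in self.surviving}
        for p, m in self.scored:
            row = {"panel": p.panel_id, "size": p.size,
                   "survives": p.panel_id in surviving_ids}
            row.update({k: v for k, v in m.rounded().items()})
            rows.append(row)
        return pd.DataFrame(rows).sort_values(
            ["survives", "size"], ascending=[False, True]).reset_index(drop=True)

    def predict(self, values: pd.DataFrame) -> pd.Series:
        if self.fused is None:
            raise ValueError("no fused model (no panel survived screening)")
        return self.fused.predict(values)

    def validate(self, table: BiomarkerTable) -> PerformanceMetrics:
        if self.fused is None:
            raise ValueError("no fused model (no panel survived screening)")
        return validate(self.fused, table)

    def summary(self) -> str:
        n_ad = int((self.model.table.groups == GROUP_AD).sum())
        n_nold = int((self.model.table.groups == GROUP_NOLD).sum())
        lines = [
            "AD diagnostic panel screening",
            "=" * 45,
            f"subjects: {n_ad} AD / {n_nold} control",
            f"panels screened: {len(self.scored)}",
            f"panels surviving Sen/Spec >= "
            f"{self.model.sen_min:g}/{self.model.spec_min:g}%: "
            f"{len(self.surviving)}",
            f"train/test split: {self.model.train_frac:.0%} "
            f"(seed {self.seed}), CV folds: {self.model.folds}",
        ]
        if self.fused_metrics is not None:
            r = self.fused_metrics.rounded()
            lines += [
                "fused LDA model on held-out test set:",
                f"  Sen {r['sensitivity']}%  Spec {r['specificity']}%  "
                f"Acc {r['accuracy']}%  F {r['f_measure']}%  "
                f"MCC {r['mcc']}  PPV {r['ppv']}%  NPV {r['npv']}%",
            ]
        if self.surviving:
            lines.append("top surviving panels:")
            for p, m in self.surviving[:10]:
                r = m.rounded()
                lines.append(f"  {p.panel_id}: Sen {r['sensitivity']}% "
                             f"Spec {r['specificity']}%")
        return "\n".join(lines)

    def plot_panel_metrics(self, ax=None, top: int = 15):
        """Bar chart of sensitivity/specificity for the top panels."""
        import matplotlib.pyplot as plt

        df = self.panel_metrics.head(top)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1))
        y = np.arange(len(df))
        ax.barh(y - 0.2, df["sensitivity"], height=0.4, label="Sen %")
        ax.barh(y + 0.2, df["specificity"], height=0.4, label="Spec %")
        ax.set_yticks(y, df["panel"], fontsize=7)
        ax.axvline(self.model.sen_min, color="k", ls="--", lw=0.8)
        ax.invert_yaxis()
        ax.set_xlabel("percent")
        ax.legend()
        return ax
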