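"""Evaluation harness: balanced Monte-Carlo CV, linear SVMs, metrics, odds ratios.

Tasks are either *classification* of an ordinal grade (KLG 0-4, medial or
lateral JSN 0-3, optionally grouped, e.g. [0,1] vs 2 vs [3,4]) or
*prediction* of a binary clinical outcome (incident knee OA or total knee
replacement within a 1-5 year horizon).  For each of ``n_repeats``
(default 1000) Monte-Carlo repeats, every class is subsampled without
replacement to the minority-class size, the balanced sample is split 90/10
stratified by class, features are min-max normalized on the training
split, and a linear SVM (squared hinge, L2 penalty, C = 1) is fitted.
Classification tasks report balanced accuracy and weighted kappa;
prediction tasks report the AUC of the SVM decision margin.  Results are
aggregated as mean +- SD over repeats.

Feature importance for outcome prediction is assessed separately with a
multivariable logistic regression on standardized MEAS features, reported
as per-SD odds ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.svm import LinearSVC

from .meas_features import MEAS_COLUMNS

__all__ = ["TaskSpec", "SplitConfig", "EvalResult", "OddsRatioTable",
           "build_task_labels", "derive_incident_koa", "balanced_monte_carlo",
           "minmax_normalize", "fit_predict_linear_svm", "balanced_accuracy",
           "weighted_kappa", "roc_auc", "logistic_odds_ratios", "run_task",
           "resolve_feature_columns", "weighted_average_results",
           "TaskInfeasibleError"]

logger = logging.getLogger(__name__)

#: LDSE-bearing structures in combined-encoding block order.
LDSE_STRUCTURES = ("FB", "TB", "mM", "lM")


class TaskInfeasibleError(ValueError):
    """A task has an empty or degenerate class after filtering."""


# ---------------------------------------------------------------------------
# task specification & label construction
# ---------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """One cell of the task grid.

    ``kind`` is ``classification`` (label_source KLG | mJSN | lJSN with a
    class ``grouping`` such as ``[[0, 1], [2], [3, 4]]``) or ``prediction``
    (label_source incident_koa | tkr with a ``horizon_years`` in 1..5).
    ``feature_set`` names the columns: ``MEAS``, ``LDSE-FB`` .. ``LDSE-lM``,
    ``LDSE-COMB``, or any ``<LDSE-x> + MEAS`` combination.
    """

    kind: str
    label_source: str
    grouping: tuple[tuple[int, ...], ...] | None = None
    horizon_years: int | None = None
    feature_set: str = "MEAS"

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "prediction"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "classification":
            if self.grouping is None:
                raise ValueError("classification task needs a class grouping")
            self.grouping = tuple(tuple(g) for g in self.grouping)
            flat = [g for grp in self.grouping for g in grp]
            if len(set(flat)) != len(flat):
                raise ValueError("class groups must be disjoint")
        else:
            if self.horizon_years not in (1, 2, 3, 4, 5):
                raise ValueError("prediction task needs horizon_years in 1..5")

    @property
    def name(self) -> str:
        if self.kind == "classification":
            grp = "_vs_".join("".join(str(g) for g in grp) for grp in self.grouping)
            return f"{self.label_source}_{grp}"
        return f"{self.label_source}_{self.horizon_years}y"


@dataclass
class SplitConfig:
    """Balanced Monte-Carlo split settings (90/10 x 1000 by default)."""

    n_repeats: int = 1000
    test_fraction: float = 0.10
    seed: int = 0
    min_class_size: int = 10

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EvalResult:
    """Repeat-level metrics with mean +- SD summaries."""

    task: str
    feature_set: str
    n_included: int
    n_dropped_missing: int
    ba: np.ndarray | None = None       # per-repeat balanced accuracy
    kappa: np.ndarray | None = None    # per-repeat weighted kappa
    auc: np.ndarray | None = None      # per-repeat AUC (binary prediction)

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("ba", "kappa", "auc"):
            arr = getattr(self, name)
            if arr is not None:
                out[f"{name}_mean"] = float(np.mean(arr))
                out[f"{name}_sd"] = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return out


@dataclass
class OddsRatioTable:
    """Per-feature odds ratios with 95% Wald confidence intervals."""

    features: tuple[str, ...]
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    separation_flags: tuple[bool, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features, "OR": self.odds_ratio,
                             "CI_low": self.ci_low, "CI_high": self.ci_high})


def derive_incident_koa(records: pd.DataFrame, horizon_years: int) -> pd.Series:
    """Incident knee OA from longitudinal grade records.

    ``records`` needs columns ``knee_id``, ``years`` (time since index
    visit), ``klg``, ``mjsn``, ``ljsn``.  A knee is at risk if KLG < 2 at
    its index (earliest) visit; it is positive if any later visit within
    the horizon shows KLG >= 2 together with joint space narrowing
    (mJSN >= 1 or lJSN >= 1).  Returns per-knee 1/0, NaN for not-at-risk.
    """
    out = {}
    for knee, grp in records.groupby("knee_id"):
        grp = grp.sort_values("years")
        base = grp.iloc[0]
        if not np.isfinite(base["klg"]) or base["klg"] >= 2:
            out[knee] = np.nan
            continue
        later = grp[(grp["years"] > base["years"])
                    & (grp["years"] <= base["years"] + horizon_years)]
        hit = ((later["klg"] >= 2)
               & ((later["mjsn"] >= 1) | (later["ljsn"] >= 1))).any()
        out[knee] = 1.0 if hit else 0.0
    return pd.Series(out, name=f"incident_koa_{horizon_years}y")


def build_task_labels(records: pd.DataFrame, task: TaskSpec
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Class label per knee and inclusion mask for one task.

    Classification: grades are mapped to their group index; rows with a
    missing grade are excluded.  Prediction: the per-horizon outcome
    column (``tkr_{h}y`` / ``inc_koa_{h}y``) is used when present,
    otherwise incident KOA is derived from longitudinal grades;
    not-at-risk rows (NaN) are excluded.

    Returns ``(labels, include)`` aligned with ``records``; ``labels`` is
    -1 where excluded.
    """
    n = len(records)
    labels = np.full(n, -1, dtype=int)
    include = np.zeros(n, dtype=bool)
    if task.kind == "classification":
        col = {"KLG": "klg", "mJSN": "mjsn", "lJSN": "ljsn"}[task.label_source]
        grades = pd.to_numeric(records[col], errors="coerce").to_numpy(float)
        for gi, group in enumerate(task.grouping):
            m = np.isin(grades, list(group)) & np.isfinite(grades)
            labels[m] = gi
            include |= m
    else:
        h = task.horizon_years
        col = f"tkr_{h}y" if task.label_source == "tkr" else f"inc_koa_{h}y"
        if col in records.columns:
            y = pd.to_numeric(records[col], errors="coerce").to_numpy(float)
        elif task.label_source == "incident_koa":
            per_knee = derive_incident_koa(records, h)
            y = records["knee_id"].map(per_knee).to_numpy(float)
        else:
            raise KeyError(f"outcome column {col!r} missing from records")
        m = np.isfinite(y)
        labels[m] = y[m].astype(int)
        include = m
    present = np.unique(labels[include])
    n_classes = (len(task.grouping) if task.kind == "classification" else 2)
    if len(present) < n_classes:
        raise TaskInfeasibleError(
            f"task {task.name}: only classes {present.tolist()} remain after filtering")
    return labels, include


# ---------------------------------------------------------------------------
# balanced Monte-Carlo splits
# ---------------------------------------------------------------------------

def balanced_monte_carlo(labels: np.ndarray, cfg: SplitConfig
                         ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream of (train, test) index arrays, balanced and stratified.

    Per repeat (independent child seed spawned from ``cfg.seed``): every
    class is subsampled without replacement to the minority-class size,
    then split ``1 - test_fraction`` / ``test_fraction`` stratified by
    class.  Requires at least two classes and a minority class of
    ``min_class_size`` or more.
    """
    cfg.validate()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels[labels >= 0], return_counts=True)
    if len(classes) < 2:
        raise TaskInfeasibleError("need at least 2 classes to split")
    m = int(counts.min())
    if m < cfg.min_class_size:
        raise TaskInfeasibleError(
            f"minority class has {m} < {cfg.min_class_size} cases; split degenerate")
    n_test = max(1, round(cfg.test_fraction * m))
    pools = [np.flatnonzero(labels == c) for c in classes]
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        train_parts, test_parts = [], []
        for pool in pools:
            pick = rng.choice(pool, size=m, replace=False)
            test_parts.append(pick[:n_test])
            train_parts.append(pick[n_test:])
        yield np.concatenate(train_parts), np.concatenate(test_parts)


def minmax_normalize(train: np.ndarray, other: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize per feature on the training range.

    ``z = (x - train_min) / (train_max - train_min)``; the identical
    transform is applied to ``other`` (values outside [0, 1] allowed).
    Constant training features map to 0 everywhere (logged).
    """
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    const = rng == 0
    if const.any():
        logger.warning("%d constant feature(s) in training split; set to 0",
                       int(const.sum()))
    rng = np.where(const, 1.0, rng)
    ztr = (train - lo) / rng
    zot = (other - lo) / rng
    ztr[:, const] = 0.0
    zot[:, const] = 0.0
    return ztr, zot


def fit_predict_linear_svm(train_x: np.ndarray, train_y: np.ndarray,
                           test_x: np.ndarray, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Linear SVM (squared hinge, L2 penalty, C = 1), one-vs-rest multiclass.

    Returns hard labels and continuous decision margins for the test set
    (binary: one score per case).
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("single-class training set")
    clf = LinearSVC(C=1.0, loss="squared_hinge", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional liblinear convergence notes
        clf.fit(train_x, train_y)
    return clf.predict(test_x), clf.decision_function(test_x)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(true: Sequence[int], predicted: Sequence[int]) -> float:
    """Unweighted mean of per-class recall ((sens + spec) / 2 when binary)."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("length mismatch")
    classes = np.unique(true)
    if any((true == c).sum() == 0 for c in classes):  # defensive; cannot occur
        raise ValueError("class with zero true cases")
    return float(_skm.balanced_accuracy_score(true, predicted))


def weighted_kappa(true: Sequence[int], predicted: Sequence[int],
                   weights: str = "linear",
                   labels: Sequence[int] | None = None) -> float:
    """Chance-corrected ordinal agreement with distance-dependent weights.

    ``1 - sum(w O) / sum(w E)`` with disagreement weights
    ``w_ij = |i - j| / (k - 1)`` (linear, default) or the squared analogue
    (quadratic); the chance matrix E comes from the marginals.  ``labels``
    fixes the ordinal scale when some grades are absent from a sample.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"weights must be linear|quadratic, got {weights!r}")
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(np.unique(np.concatenate([true, predicted]))) < 2:
        raise ValueError("kappa undefined: single distinct label in both vectors")
    return float(_skm.cohen_kappa_score(true, predicted, weights=weights,
                                        labels=labels))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: one class absent")
    return float(_skm.roc_auc_score(labels, np.asarray(scores, float)))


# ---------------------------------------------------------------------------
# logistic regression odds ratios
# ---------------------------------------------------------------------------

def logistic_odds_ratios(features: pd.DataFrame, outcome: Sequence[int]
                         ) -> OddsRatioTable:
    """Per-SD odds ratios from one multivariable logistic regression.

    Features are standardized to unit SD before the maximum-likelihood
    fit, so odds ratios are comparable across features with mixed units.
    Per-feature quasi-separation is flagged and its CI reported unbounded.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    x = features.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("features contain missing values; filter upstream")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature(s); cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    design = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    params = fit.params[1:]
    bse = fit.bse[1:]
    sep = ~np.isfinite(bse) | (bse > 50) | ~np.isfinite(params)
    lo = np.where(sep, 0.0, np.exp(params - 1.959963984540054 * bse))
    hi = np.where(sep, np.inf, np.exp(params + 1.959963984540054 * bse))
    return OddsRatioTable(features=tuple(features.columns),
                          odds_ratio=np.exp(params), ci_low=lo, ci_high=hi,
                          separation_flags=tuple(bool(s) for s in sep))


# ---------------------------------------------------------------------------
# feature-set resolution & task orchestration
# ---------------------------------------------------------------------------

def resolve_feature_columns(feature_set: str, columns: Sequence[str]
                            ) -> list[str]:
    """Map a feature-set name to concrete feature-table columns.

    Recognized: ``MEAS``; ``LDSE-FB`` | ``LDSE-TB`` | ``LDSE-mM`` |
    ``LDSE-lM`` (all available ``ldse_<s>_###`` columns); ``LDSE-COMB``
    (first 75 per structure, 300 total); and any of those plus `` + MEAS``.
    """
    parts = [p.strip() for p in feature_set.split("+")]
    cols: list[str] = []
    for part in parts:
        if part == "MEAS":
            missing = [c for c in MEAS_COLUMNS if c not in columns]
            if missing:
                raise KeyError(f"MEAS columns missing from table: {missing}")
            cols.extend(MEAS_COLUMNS)
        elif part == "LDSE-COMB":
            for s in LDSE_STRUCTURES:
                block = sorted(c for c in columns if c.startswith(f"ldse_{s}_"))[:75]
                if not block:
                    raise KeyError(f"no LDSE columns for structure {s}")
                cols.extend(block)
        elif part.startswith("LDSE-"):
            s = part[5:]
            if s not in LDSE_STRUCTURES:
                raise KeyError(f"unknown LDSE structure {s!r}")
            block = sorted(c for c in columns if c.startswith(f"ldse_{s}_"))
            if not block:
                raise KeyError(f"no LDSE columns for structure {s}")
            cols.extend(block)
        else:
            raise KeyError(f"unknown feature set component {part!r}")
    return cols


def run_task(features: pd.DataFrame, records: pd.DataFrame,
             task: TaskSpec, cfg: SplitConfig) -> EvalResult:
    """Full balanced Monte-Carlo evaluation of one task / feature set.

    ``features`` and ``records`` must be row-aligned (same knees in the
    same order).  Rows with a missing label or any missing selected
    feature are discarded.  Classification yields per-repeat balanced
    accuracy and weighted kappa; binary prediction yields per-repeat AUC
    of the SVM decision margin.
    """
    if len(features) != len(records):
        raise ValueError("features and records must be row-aligned")
    cols = resolve_feature_columns(task.feature_set, features.columns)
    x = features[cols].to_numpy(dtype=float)
    labels, include = build_task_labels(records, task)
    complete = np.isfinite(x).all(axis=1)
    n_dropped = int((include & ~complete).sum())
    include = include & complete
    labels = np.where(include, labels, -1)
    present = np.unique(labels[labels >= 0])
    n_classes = len(task.grouping) if task.kind == "classification" else 2
    if len(present) < n_classes:
        raise TaskInfeasibleError(
            f"task {task.name}: class lost to missing features")

    bas, kappas, aucs = [], [], []
    seeds = np.random.SeedSequence((cfg.seed, 0xC1A55)).spawn(cfg.n_repeats)
    split_cfg = SplitConfig(cfg.n_repeats, cfg.test_fraction, cfg.seed,
                            cfg.min_class_size)
    for rep, (tr, te) in enumerate(balanced_monte_carlo(labels, split_cfg)):
        ztr, zte = minmax_normalize(x[tr], x[te])
        svm_seed = int(seeds[rep].generate_state(1)[0] % (2 ** 31))
        pred, score = fit_predict_linear_svm(ztr, labels[tr], zte, seed=svm_seed)
        if task.kind == "classification":
            bas.append(balanced_accuracy(labels[te], pred))
            kappas.append(weighted_kappa(labels[te], pred,
                                         labels=list(range(n_classes))))
        else:
            aucs.append(roc_auc(score, labels[te]))
    return EvalResult(
        task=task.name, feature_set=task.feature_set,
        n_included=int(include.sum()), n_dropped_missing=n_dropped,
        ba=np.asarray(bas) if bas else None,
        kappa=np.asarray(kappas) if kappas else None,
        auc=np.asarray(aucs) if aucs else None)


def weighted_average_results(results: Sequence[EvalResult], metric: str
                             ) -> tuple[float, float]:
    """Mean and SD of a metric across cohorts, weighted by cases included."""
    means, sds, ws = [], [], []
    for r in results:
        arr = getattr(r, metric)
        if arr is None:
            continue
        means.append(np.mean(arr))
        sds.append(np.std(arr, ddof=1) if len(arr) > 1 else 0.0)
        ws.append(r.n_included)
    if not ws:
        raise ValueError(f"no results carry metric {metric!r}")
    w = np.asarray(ws, float) / np.sum(ws)
    return float(np.dot(w, means)), float(np.dot(w, sds))
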