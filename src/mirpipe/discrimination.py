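"""Case-control discrimination models for the qualitative microRNA panel.

Two complementary analyses mirror the study design:

* per-microRNA logistic regression with case/control status as the response,
  run both unadjusted and adjusted for the clinical covariates (age, gender,
  smoking status, pack-years, quit-years, underlying-lung-disease group);
* random-forest classifiers on clinical features, microRNA calls, or both,
  evaluated by repeated stratified 2-fold cross-validation and by repeatedly
  splitting the cohort 50/50 and comparing the resulting ROC AUC samples of
  two models with a Welch two-sample t-test.

The cohort is a pandas DataFrame; see ``validate_cohort`` for the column
contract.  The Welch test on resampled AUCs treats overlapping splits as
independent (as the source analysis does); a paired-test alternative is
available via ``paired=True``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, ShuffleSplit
import statsmodels.api as sm

from .panels import DEFAULT_MIR_PANEL, HOUSEKEEPER_ALIASES, normalize_mir_id

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_COVARIATES",
    "FeatureSet",
    "LrResult",
    "CvMetrics",
    "ModelComparison",
    "validate_cohort",
    "fit_univariate_lr",
    "run_panel_lr",
    "lr_results_frame",
    "rf_cv_metrics",
    "resampled_roc_comparison",
    "subgroup_view",
]

CLINICAL_COVARIATES = ("age", "gender", "smoking_status", "pack_years", "quit_years", "uld_group")
SMOKING_LEVELS = ("never", "former", "current")  # never = reference
ULD_LEVELS = ("none_other", "risk", "granulomatous_airway")  # none_other = reference
GENDER_LEVELS = ("female", "male")  # female = reference

FeatureSet = Literal["clinical", "mirs", "combined"]

REQUIRED_COLUMNS = ("subject_id", "status") + CLINICAL_COVARIATES


def validate_cohort(df: pd.DataFrame, panel: Sequence[str] | None = None) -> list[str]:
    """Check the cohort column contract; return the mir columns found.

    Required columns: subject_id, status in {case, control}, age, gender in
    {male, female}, smoking_status in {never, former, current}, pack_years,
    quit_years, uld_group in {risk, granulomatous_airway, none_other}.
    Optional: stage (cases only, I-IV), histology (cases only).  MicroRNA
    columns hold 1 / 0 / missing.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    bad_status = set(df["status"].dropna().unique()) - {"case", "control"}
    if bad_status:
        raise ValueError(f"status must be case/control, found {sorted(bad_status)}")
    bad_smoke = set(df["smoking_status"].dropna().unique()) - set(SMOKING_LEVELS)
    if bad_smoke:
        raise ValueError(f"unknown smoking_status levels: {sorted(bad_smoke)}")
    bad_uld = set(df["uld_group"].dropna().unique()) - set(ULD_LEVELS)
    if bad_uld:
        raise ValueError(f"unknown uld_group levels: {sorted(bad_uld)}")
    if panel is not None:
        absent = [m for m in panel if m not in df.columns]
        if absent:
            raise ValueError(f"cohort lacks panel columns: {absent}")
        return list(panel)
    reserved = set(REQUIRED_COLUMNS) | {"stage", "histology"}
    return [c for c in df.columns if c not in reserved]


@dataclass(frozen=True)
class LrResult:
    """Per-microRNA logistic-regression outcome (both p columns)."""

    mir_id: str
    p_unadjusted: float | None
    p_adjusted: float | None
    coefficient: float | None  # adjusted log-odds when available
    n_used: int
    reliable: bool = True
    note: str = ""


def _clinical_design(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed-reference dummy coding of the clinical covariates.

    References: never-smoker, none_other underlying disease, female.
    """
    X = pd.DataFrame(index=df.index)
    X["age"] = df["age"].astype(float)
    X["gender_male"] = (df["gender"] == "male").astype(float)
    X["smoking_former"] = (df["smoking_status"] == "former").astype(float)
    X["smoking_current"] = (df["smoking_status"] == "current").astype(float)
    X["pack_years"] = df["pack_years"].astype(float)
    X["quit_years"] = df["quit_years"].astype(float)
    X["uld_risk"] = (df["uld_group"] == "risk").astype(float)
    X["uld_granulomatous"] = (df["uld_group"] == "granulomatous_airway").astype(float)
    return X


def fit_univariate_lr(cohort: pd.DataFrame, mir_id: str, adjusted: bool = True) -> LrResult:
    """Logistic regression of case/control status on one microRNA call.

    When ``adjusted``, clinical covariates enter the model; the reported
    p-value is the Wald p for the microRNA coefficient.  Subjects with a
    missing call for this microRNA are excluded (``n_used`` records the rest).
    Complete/quasi-separation is flagged (``reliable=False``) rather than
    silently reported.
    """
    if mir_id not in cohort.columns:
        raise ValueError(f"cohort has no column for {mir_id!r}")
    sub = cohort[cohort[mir_id].notna()]
    y = (sub["status"] == "case").astype(float)
    x_mir = sub[mir_id].astype(float)
    if x_mir.nunique() < 2:
        raise ValueError(f"{mir_id} has zero variance among usable subjects")
    if y.nunique() < 2:
        raise ValueError("both cases and controls are required")

    X = pd.DataFrame({"mir": x_mir.values}, index=sub.index)
    if adjusted:
        clin = _clinical_design(sub)
        # constant covariates (e.g. smoking dummies within a smoking-status
        # subgroup) are collinear with the intercept; drop them
        clin = clin.loc[:, clin.nunique() > 1]
        X = pd.concat([X, clin], axis=1)
    X = sm.add_constant(X, has_constant="add")

    reliable, note = True, ""
    p = coef = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.values, X.astype(float)).fit(disp=0, maxiter=200)
            coef = float(res.params["mir"])
            p = float(res.pvalues["mir"])
            se = float(res.bse["mir"])
            if not res.mle_retvals.get("converged", True) or not np.isfinite(se) or se > 50:
                reliable, note = False, "possible separation or non-convergence"
        except Exception as exc:  # statsmodels raises on perfect separation
            reliable, note = False, f"fit failed: {type(exc).__name__}"
            p, coef = None, None

    return LrResult(
        mir_id=mir_id,
        p_unadjusted=None if adjusted else p,
        p_adjusted=p if adjusted else None,
        coefficient=coef,
        n_used=int(len(sub)),
        reliable=reliable,
        note=note,
    )


def run_panel_lr(cohort: pd.DataFrame, panel: Sequence[str] | None = None) -> list[LrResult]:
    """Unadjusted and adjusted univariate logistic models for every panel
    microRNA, never aborting the panel for one degenerate marker.

    Housekeeper transcripts are excluded from the panel with a logged note.
    """
    panel = list(panel) if panel is not None else list(DEFAULT_MIR_PANEL)
    results: list[LrResult] = []
    for mir in panel:
        if normalize_mir_id(mir) in HOUSEKEEPER_ALIASES:
            logger.info("excluding housekeeper %s from the logistic panel", mir)
            continue
        try:
            unadj = fit_univariate_lr(cohort, mir, adjusted=False)
            adj = fit_univariate_lr(cohort, mir, adjusted=True)
        except ValueError as exc:
            results.append(
                LrResult(
                    mir_id=mir,
                    p_unadjusted=None,
                    p_adjusted=None,
                    coefficient=None,
                    n_used=0,
                    reliable=False,
                    note=str(exc),
                )
            )
            continue
        results.append(
            LrResult(
                mir_id=mir,
                p_unadjusted=unadj.p_unadjusted,
                p_adjusted=adj.p_adjusted,
                coefficient=adj.coefficient,
                n_used=adj.n_used,
                reliable=unadj.reliable and adj.reliable,
                note="; ".join(n for n in (unadj.note, adj.note) if n),
            )
        )
    return results


def lr_results_frame(results: Iterable[LrResult]) -> pd.DataFrame:
    """Tabulate LR results (mir, p, p.adj, coefficient, n, flag)."""
    return pd.DataFrame(
        [
            {
                "miRNA": r.mir_id,
                "p": r.p_unadjusted,
                "p.adj": r.p_adjusted,
                "coef": r.coefficient,
                "n": r.n_used,
                "reliable": r.reliable,
                "note": r.note,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Random-forest comparisons
# ---------------------------------------------------------------------------


def _assemble_features(
    cohort: pd.DataFrame,
    feature_set: FeatureSet,
    panel: Sequence[str],
    include_histology: bool = False,
) -> pd.DataFrame:
    """Numeric feature matrix for a feature set; mir cells may be NaN
    (imputed per training fold, never globally).

    ``include_histology`` adds case-only histology/stage dummies; these leak
    case status by construction and are off by default.
    """
    parts = []
    if feature_set in ("clinical", "combined"):
        clin = _clinical_design(cohort)
        if include_histology:
            for col in ("histology", "stage"):
                if col in cohort.columns:
                    dummies = pd.get_dummies(
                        cohort[col].fillna("none"), prefix=col, dtype=float
                    )
                    clin = pd.concat([clin, dummies], axis=1)
        parts.append(clin)
    if feature_set in ("mirs", "combined"):
        parts.append(cohort[list(panel)].astype(float))
    if not parts:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return pd.concat(parts, axis=1)


def _impute_train_test(
    X_train: pd.DataFrame, X_test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute missing cells using training-half statistics only."""
    med = X_train.median(numeric_only=True)
    med = med.fillna(0.0)
    return (
        X_train.fillna(med).to_numpy(dtype=float),
        X_test.fillna(med).to_numpy(dtype=float),
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def _metrics_from_confusion(c: dict[str, int]) -> dict[str, float]:
    tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


@dataclass
class CvMetrics:
    """Repeated stratified 2-fold CV summary for one random-forest model."""

    feature_set: str
    n_repeats: int
    seed: int
    metrics: dict[str, float]  # fold-averaged accuracy/sens/spec/ppv/npv
    per_fold: list[dict] = field(repr=False, default_factory=list)


DEFAULT_N_TREES = 500


def rf_cv_metrics(
    cohort: pd.DataFrame,
    feature_set: FeatureSet,
    n_repeats: int = 20,
    seed: int = 0,
    *,
    panel: Sequence[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    include_histology: bool = False,
) -> CvMetrics:
    """Random-forest classifier gauged by stratified 2-fold CV repeated
    ``n_repeats`` times; out-of-fold predictions use the forest's majority
    vote.  Metrics are averaged over all folds.
    """
    panel = list(panel) if panel is not None else list(DEFAULT_MIR_PANEL)
    y = (cohort["status"] == "case").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < 2:
        raise ValueError(
            "a class has fewer than 2 members; stratified 2-fold CV is impossible "
            "— reduce folds or enlarge the cohort"
        )
    X = _assemble_features(cohort, feature_set, panel, include_histology)
    rng = np.random.default_rng(seed)
    per_fold: list[dict] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=int(rng.integers(2**31)))
        for train_idx, test_idx in skf.split(X, y):
            Xtr, Xte = _impute_train_test(X.iloc[train_idx], X.iloc[test_idx])
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
            )
            clf.fit(Xtr, y[train_idx])
            pred = clf.predict(Xte)
            conf = _confusion(y[test_idx], pred)
            per_fold.append({"repeat": rep, **conf, **_metrics_from_confusion(conf)})
    keys = ("accuracy", "sensitivity", "specificity", "ppv", "npv")
    means = {k: float(np.nanmean([f[k] for f in per_fold])) for k in keys}
    return CvMetrics(
        feature_set=feature_set, n_repeats=n_repeats, seed=seed, metrics=means, per_fold=per_fold
    )


@dataclass
class ModelComparison:
    """Paired resampled-AUC comparison of two feature sets."""

    model_a_label: str
    model_b_label: str
    auc_a: list[float]
    auc_b: list[float]
    mean_auc_a: float
    mean_auc_b: float
    auc_difference_pct: float  # 100 * (mean_b - mean_a), percentage points
    welch_p: float
    seed: int
    n_splits: int
    n_redraws: int = 0
    cv_metrics_a: dict[str, float] | None = None
    cv_metrics_b: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def resampled_roc_comparison(
    cohort: pd.DataFrame,
    feature_set_a: FeatureSet = "clinical",
    feature_set_b: FeatureSet = "combined",
    n_splits: int = 100,
    seed: int = 0,
    *,
    panel: Sequence[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    stratified: bool = True,
    paired: bool = False,
    include_histology: bool = False,
) -> ModelComparison:
    """Compare two random-forest models by resampled ROC AUC.

    For each of ``n_splits`` 50/50 splits, both models are trained on the
    identical training half and score the identical testing half; the test
    half's case probability gives a ROC AUC per model per split.  The two AUC
    samples are compared with a Welch two-sample t-test (``paired=True``
    switches to a paired t-test on the per-split differences, which respects
    the shared splits).  The AUC difference is reported in percentage points
    (positive when model b is better).
    """
    panel = list(panel) if panel is not None else list(DEFAULT_MIR_PANEL)
    y = (cohort["status"] == "case").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xa = _assemble_features(cohort, feature_set_a, panel, include_histology)
    Xb = _assemble_features(cohort, feature_set_b, panel, include_histology)
    rng = np.random.default_rng(seed)

    auc_a: list[float] = []
    auc_b: list[float] = []
    n_redraws = 0
    if stratified:
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=0.5, random_state=int(rng.integers(2**31))
        )
        split_iter = splitter.split(Xa, y)
    else:
        splitter = ShuffleSplit(
            n_splits=n_splits, test_size=0.5, random_state=int(rng.integers(2**31))
        )
        split_iter = splitter.split(Xa)

    for train_idx, test_idx in split_iter:
        while len(np.unique(y[test_idx])) < 2:  # only reachable unstratified
            n_redraws += 1
            logger.info("degenerate test half redrawn (%d so far)", n_redraws)
            perm = rng.permutation(len(y))
            train_idx, test_idx = perm[: len(train_idx)], perm[len(train_idx):]
        for X, out in ((Xa, auc_a), (Xb, auc_b)):
            Xtr, Xte = _impute_train_test(X.iloc[train_idx], X.iloc[test_idx])
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
            )
            clf.fit(Xtr, y[train_idx])
            scores = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
            out.append(float(roc_auc_score(y[test_idx], scores)))

    a = np.asarray(auc_a)
    b = np.asarray(auc_b)
    if paired:
        welch_p = float(stats.ttest_rel(b, a).pvalue)
    else:
        welch_p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
    return ModelComparison(
        model_a_label=feature_set_a,
        model_b_label=feature_set_b,
        auc_a=list(map(float, a)),
        auc_b=list(map(float, b)),
        mean_auc_a=float(a.mean()),
        mean_auc_b=float(b.mean()),
        auc_difference_pct=float(100.0 * (b.mean() - a.mean())),
        welch_p=welch_p,
        seed=seed,
        n_splits=n_splits,
        n_redraws=n_redraws,
    )


def roc_coordinates(
    cohort: pd.DataFrame,
    feature_set: FeatureSet,
    seed: int = 0,
    *,
    panel: Sequence[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    include_histology: bool = False,
) -> pd.DataFrame:
    """ROC curve coordinates (fpr, tpr, threshold) for one representative
    stratified 50/50 split, for plotting."""
    from sklearn.metrics import roc_curve

    panel = list(panel) if panel is not None else list(DEFAULT_MIR_PANEL)
    y = (cohort["status"] == "case").astype(int).to_numpy()
    X = _assemble_features(cohort, feature_set, panel, include_histology)
    rng = np.random.default_rng(seed)
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.5, random_state=int(rng.integers(2**31)))
    train_idx, test_idx = next(splitter.split(X, y))
    Xtr, Xte = _impute_train_test(X.iloc[train_idx], X.iloc[test_idx])
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1)
    clf.fit(Xtr, y[train_idx])
    scores = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
    fpr, tpr, thresholds = roc_curve(y[test_idx], scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


_NAMED_SUBGROUPS = ("all", "former", "current", "never", "early", "late")


def subgroup_view(
    cohort: pd.DataFrame,
    subgroup: str | Callable[[pd.Series], bool],
) -> pd.DataFrame:
    """Subset the cohort for a named or custom subgroup analysis.

    Named subgroups: ``former``/``current``/``never`` filter both arms on
    smoking status; ``early`` keeps cases with stage I/II, ``late`` cases with
    stage III/IV — stage-based filters retain *all* controls, since controls
    carry no tumor stage.  A callable is applied row-wise as a predicate.
    """
    if callable(subgroup):
        mask = cohort.apply(subgroup, axis=1).astype(bool)
        label = getattr(subgroup, "__name__", "predicate")
    elif subgroup == "all":
        mask = pd.Series(True, index=cohort.index)
        label = "all"
    elif subgroup in ("former", "current", "never"):
        mask = cohort["smoking_status"] == subgroup
        label = subgroup
    elif subgroup in ("early", "late"):
        stages = ("I", "II") if subgroup == "early" else ("III", "IV")
        is_case = cohort["status"] == "case"
        if "stage" not in cohort.columns:
            raise ValueError("cohort has no stage column for a stage-based subgroup")
        mask = (~is_case) | cohort["stage"].isin(stages)
        label = subgroup
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}; named options: {_NAMED_SUBGROUPS}")
    out = cohort[mask]
    if out.empty:
        raise ValueError(f"subgroup {label!r} matched no subjects")
    return out.reset_index(drop=True)
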