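"""Brain-network-activity tables and the inference stack built on them.

The N-by-k BNA table (row i = diagonal of run i's latent covariance) feeds
three analyses: (1) pairwise nonparametric group tests between anesthetic
conditions with Benjamini-Yekutieli FDR control and a Shapiro-Wilk
normality diagnostic; (2) condition decoding under leave-one-subject-out
validation with either a bagged RBF-kernel SVM (C = 1, gamma by the
inverse feature-count-times-variance heuristic) or an all-threshold
ordinal logistic model with L2 penalty; (3) permutation feature importance
and a learning curve over acquisition duration.

Three label schemes are supported: ``All`` (awake and each anesthetic
condition separate), ``DeepModerate`` (awake / moderate / deep sedation,
an ordinal scale), and ``Anesthesia`` (awake vs any anesthetic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .mha import MHAModel, estimate_run_params
from .preprocess import denoise_timeseries, empirical_covariance, truncate_run

__all__ = [
    "BNATable",
    "GroupTestReport",
    "DecodingReport",
    "OrdinalLogisticAT",
    "bna_table",
    "relabel",
    "pairwise_group_tests",
    "classify_conditions",
    "permutation_importance",
    "learning_curve_duration",
]

SCHEMES = ("All", "DeepModerate", "Anesthesia")


@dataclass
class BNATable:
    """N-by-k table of per-run brain network activities with metadata."""

    values: np.ndarray
    run_ids: list[str]
    subjects: list[str]
    conditions: list[str]
    network_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if not (len(self.run_ids) == len(self.subjects) == len(self.conditions) == n):
            raise ValueError("metadata length must match the number of rows")
        if len(self.network_labels) != k:
            raise ValueError("network_labels length must match the number of columns")
        if np.any(np.isnan(self.values)):
            raise ValueError("BNA table has missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.network_labels)
        frame.insert(0, "run_id", self.run_ids)
        frame.insert(1, "subject", self.subjects)
        frame.insert(2, "condition", self.conditions)
        return frame


def bna_table(model: MHAModel, metadata: pd.DataFrame | list) -> BNATable:
    """Assemble the BNA table: row i is the diagonal of G for run i.

    ``metadata`` is a DataFrame with columns run_id/subject/condition (or a
    list of objects carrying those attributes); its order defines the row
    order and every run in it must exist in the model.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame([
            {"run_id": m.run_id, "subject": m.subject, "condition": m.condition}
            for m in metadata
        ])
    by_run = {rl.run_id: rl for rl in model.run_latents}
    rows = []
    for rid in metadata["run_id"]:
        if rid not in by_run:
            raise KeyError(f"run {rid!r} missing from the model")
        rows.append(by_run[rid].bna)
    values = np.array(rows)
    return BNATable(values=values,
                    run_ids=metadata["run_id"].tolist(),
                    subjects=metadata["subject"].tolist(),
                    conditions=metadata["condition"].tolist(),
                    network_labels=[f"BN{j + 1}" for j in range(values.shape[1])])


def relabel(conditions, scheme: str) -> tuple[np.ndarray, dict[str, int]]:
    """Map condition names to integer labels under one of the three schemes.

    ``Anesthesia``: awake = 0, any anesthetic = 1.  ``DeepModerate``: awake =
    0, moderate sedation = 1, deep sedation = 2 (ordinal).  ``All``: awake =
    0 and each anesthetic condition its own class.  Returns the labels and
    the mapping actually used.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    conditions = list(conditions)
    mapping: dict[str, int] = {}
    for cond in conditions:
        if cond in mapping:
            continue
        if cond == "awake":
            mapping[cond] = 0
        elif scheme == "Anesthesia":
            mapping[cond] = 1
        elif scheme == "DeepModerate":
            if cond.endswith("-moderate"):
                mapping[cond] = 1
            elif cond.endswith("-deep"):
                mapping[cond] = 2
            else:
                raise ValueError(f"unknown condition label {cond!r}")
        else:  # All: one class per distinct anesthetic condition
            mapping[cond] = 0  # placeholder, rewritten below
    if scheme == "All":
        others = sorted(c for c in mapping if c != "awake")
        mapping = {"awake": 0} if "awake" in mapping else {}
        for i, cond in enumerate(others, start=1):
            mapping[cond] = i
    labels = np.array([mapping[c] for c in conditions], dtype=int)
    return labels, mapping


@dataclass
class GroupTestReport:
    tests: pd.DataFrame          # network, cond_a, cond_b, p_raw, p_adj, annotation
    normality: dict[str, float]  # network -> Shapiro-Wilk p-value on pooled BNAs
    skipped_conditions: list[str] = field(default_factory=list)


def _annotate(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    return "ns"


def pairwise_group_tests(table: BNATable, paired: bool = False,
                         min_runs: int = 3) -> GroupTestReport:
    """Condition-pair location tests per network, BY-adjusted jointly.

    Shapiro-Wilk normality is reported per network as a diagnostic (it
    motivates the nonparametric choice) but never gates anything.  The
    default test is the unpaired two-sided rank-sum (Mann-Whitney); with
    ``paired=True`` groups are truncated to equal length and the Wilcoxon
    signed-rank test is used instead.  All network-by-pair raw p-values form
    one multiple-testing family for the Benjamini-Yekutieli correction, and
    annotations follow the significance map: ** for p <= 1e-2, *** for
    p <= 1e-3, **** for p <= 1e-4, else ns.
    """
    conds = pd.Series(table.conditions)
    counts = conds.value_counts()
    usable = sorted(counts[counts >= min_runs].index)
    skipped = sorted(counts[counts < min_runs].index)
    if skipped:
        warnings.warn(f"conditions with < {min_runs} runs skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("need at least two conditions with enough runs")

    normality = {}
    for j, net in enumerate(table.network_labels):
        normality[net] = float(stats.shapiro(table.values[:, j]).pvalue)

    rows = []
    for j, net in enumerate(table.network_labels):
        col = table.values[:, j]
        for a, b in combinations(usable, 2):
            xa = col[conds.to_numpy() == a]
            xb = col[conds.to_numpy() == b]
            if paired:
                m = min(len(xa), len(xb))
                res = stats.wilcoxon(xa[:m], xb[:m], alternative="two-sided")
            else:
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({"network": net, "cond_a": a, "cond_b": b,
                         "p_raw": float(res.pvalue)})
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(frame["p_raw"], method="fdr_by")[1]
    frame["annotation"] = frame["p_adj"].map(_annotate)
    return GroupTestReport(tests=frame, normality=normality,
                           skipped_conditions=skipped)


class OrdinalLogisticAT(BaseEstimator, ClassifierMixin):
    """All-threshold ordinal logistic regression with an L2 penalty.

    Classes are treated as ordered categories separated by K-1 monotone
    thresholds on a single linear predictor; every threshold contributes a
    logistic loss term for every sample (the "all thresholds" variant),
    which makes the fitted cut-points automatically ordered.  ``alpha``
    is the quadratic penalty strength on the weight vector.
    """

    def __init__(self, alpha: float = 1.0, max_iter: int = 1000):
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.sort(np.unique(y))
        n_classes = len(self.classes_)
        yi = np.searchsorted(self.classes_, y)
        n, d = X.shape
        n_thresh = max(n_classes - 1, 1)

        # indicator[i, j] = 1 if sample i lies at or below threshold j
        below = (yi[:, None] <= np.arange(n_thresh)[None, :]).astype(float)

        def loss_grad(params):
            w, theta = params[:d], params[d:]
            eta = theta[None, :] - (X @ w)[:, None]   # (n, n_thresh)
            # logistic loss: softplus(-eta) where below, softplus(eta) otherwise
            loss = np.logaddexp(0.0, np.where(below > 0, -eta, eta)).sum()
            loss += 0.5 * self.alpha * w @ w
            dl_deta = expit(eta) - below               # (n, n_thresh)
            grad_theta = dl_deta.sum(axis=0)
            grad_w = -(X.T @ dl_deta.sum(axis=1)) + self.alpha * w
            return loss, np.concatenate([grad_w, grad_theta])

        x0 = np.zeros(d + n_thresh)
        x0[d:] = np.linspace(-1.0, 1.0, n_thresh)
        res = minimize(loss_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        self.coef_ = res.x[:d]
        self.theta_ = res.x[d:]
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_

    def predict(self, X):
        score = self.decision_function(X)
        if len(self.classes_) == 1:
            return np.full(len(score), self.classes_[0])
        idx = (score[:, None] > self.theta_[None, :]).sum(axis=1)
        return self.classes_[idx]


@dataclass
class DecodingReport:
    scheme: str
    classifier: str
    heldout_subject: str
    train_bacc: float
    validation_bacc_mean: float
    validation_bacc_sd: float
    test_bacc: float
    label_mapping: dict[str, int]
    n_train: int
    n_test: int
    chance_level: float
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.train_bacc, self.validation_bacc_mean, self.test_bacc):
            if not 0.0 <= v <= 1.0:
                raise ValueError("balanced accuracies must lie in [0, 1]")


class _SingleClassSafe(BaseEstimator, ClassifierMixin):
    """Fallback to a constant predictor when a bootstrap draw has one class."""

    def __init__(self, base=None):
        self.base = base

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.est_ = None
        if len(self.classes_) > 1:
            self.est_ = clone(self.base).fit(X, y)
        return self

    def predict(self, X):
        if self.est_ is None:
            return np.full(np.asarray(X).shape[0], self.classes_[0])
        return self.est_.predict(X)


def _make_estimator(classifier: str, seed: int, n_estimators: int = 10):
    if classifier == "svm":
        base = SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif classifier == "ordinal":
        base = OrdinalLogisticAT(alpha=1.0)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return BaggingClassifier(estimator=_SingleClassSafe(base),
                             n_estimators=n_estimators, random_state=seed)


def classify_conditions(table: BNATable, scheme: str, heldout_subject: str,
                        seed: int = 0, classifier: str = "svm",
                        n_estimators: int = 10, cv_folds: int = 5) -> DecodingReport:
    """Leave-one-subject-out condition decoding from the BNA table.

    All runs of ``heldout_subject`` form the test set; the base learner
    (bagged RBF-SVM or bagged ordinal logistic) is fitted on the remaining
    subjects, with stratified ``cv_folds``-fold cross-validation on the
    training set providing the validation estimate.  Balanced accuracy is
    reported for train / validation / test.  If the test set contains
    classes absent from training the score covers the classes present in
    the test labels, with a warning.
    """
    subjects = np.asarray(table.subjects)
    if heldout_subject not in subjects:
        raise ValueError(f"subject {heldout_subject!r} not present in the table")
    y, mapping = relabel(table.conditions, scheme)
    test_mask = subjects == heldout_subject
    X_tr, y_tr = table.values[~test_mask], y[~test_mask]
    X_te, y_te = table.values[test_mask], y[test_mask]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training subjects span fewer than 2 classes")

    warn_list: list[str] = []
    missing = set(np.unique(y_te)) - set(np.unique(y_tr))
    if missing:
        warn_list.append(f"test classes absent from training: {sorted(missing)}")

    est = _make_estimator(classifier, seed, n_estimators)

    # validation: stratified k-fold on the training subjects
    counts = np.bincount(y_tr)
    n_splits = min(cv_folds, counts[counts > 0].min())
    if n_splits < 2:
        raise ValueError("too few runs per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_scores = []
    for tr_idx, va_idx in cv.split(X_tr, y_tr):
        fold_est = clone(est).fit(X_tr[tr_idx], y_tr[tr_idx])
        fold_scores.append(
            balanced_accuracy_score(y_tr[va_idx], fold_est.predict(X_tr[va_idx])))
    fold_scores = np.array(fold_scores)

    est.fit(X_tr, y_tr)
    train_bacc = balanced_accuracy_score(y_tr, est.predict(X_tr))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y_pred may miss test-only classes
        test_bacc = balanced_accuracy_score(y_te, est.predict(X_te))

    chance = 1.0 / len(np.unique(y_te))
    report = DecodingReport(
        scheme=scheme, classifier=classifier, heldout_subject=heldout_subject,
        train_bacc=float(train_bacc),
        validation_bacc_mean=float(fold_scores.mean()),
        validation_bacc_sd=float(fold_scores.std(ddof=1)) if len(fold_scores) > 1 else 0.0,
        test_bacc=float(test_bacc), label_mapping=mapping,
        n_train=int((~test_mask).sum()), n_test=int(test_mask.sum()),
        chance_level=float(chance), warnings=warn_list)
    report._estimator = est  # fitted pipeline, reused for importance analysis
    report._test_data = (X_te, y_te)
    return report


def permutation_importance(estimator, table: BNATable, y: np.ndarray,
                           n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean and sd of the balanced-accuracy drop when one network is shuffled.

    Negative values are possible (a shuffled uninformative feature can score
    above the intact data on small samples) and are reported as-is.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    result = _sk_permutation_importance(
        estimator, table.values, y, scoring="balanced_accuracy",
        n_repeats=n_repeats, random_state=seed)
    return pd.DataFrame({
        "network": table.network_labels,
        "importance_mean": result.importances_mean,
        "importance_sd": result.importances_std,
    })


def learning_curve_duration(runs, model: MHAModel, scheme: str,
                            durations, heldout_subject: str, seed: int = 0,
                            classifier: str = "svm", denoise: bool = True,
                            confounds_by_run: dict | None = None) -> pd.DataFrame:
    """Decoding accuracy as a function of acquisition duration (in TR).

    For each duration the raw series are truncated, re-preprocessed from
    scratch, covariances and per-run BNAs recomputed at the fixed fitted W,
    and the leave-one-subject-out decoder re-run.  Durations too short for
    the filters are recorded as missing points.
    """
    rows = []
    for dur in durations:
        covs, meta = [], []
        try:
            for run in runs:
                X = truncate_run(run.X, int(dur))
                if denoise:
                    conf = None
                    if confounds_by_run is not None:
                        conf = confounds_by_run.get(run.run_id)
                        if conf is not None:
                            conf = np.asarray(conf)[: int(dur)]
                    X = denoise_timeseries(X, run.tr_seconds, confounds=conf)
                covs.append(empirical_covariance(X))
                meta.append({"run_id": run.run_id, "subject": run.subject,
                             "condition": run.condition})
        except ValueError:  # duration below the minimum filterable length
            rows.append({"duration_tr": int(dur), "test_bacc": np.nan,
                         "validation_bacc": np.nan})
            continue
        latents = [estimate_run_params(model.loading, K, run_id=m["run_id"])
                   for K, m in zip(covs, meta)]
        sub_model = MHAModel(loading=model.loading, run_latents=latents,
                             objective_trace=[], seed=model.seed, converged=True,
                             run_ids=[m["run_id"] for m in meta])
        table = bna_table(sub_model, pd.DataFrame(meta))
        report = classify_conditions(table, scheme, heldout_subject,
                                     seed=seed, classifier=classifier)
        rows.append({"duration_tr": int(dur), "test_bacc": report.test_bacc,
                     "validation_bacc": report.validation_bacc_mean})
    return pd.DataFrame(rows)
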