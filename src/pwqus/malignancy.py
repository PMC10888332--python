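"""QUS-based malignancy scoring and the study's statistical battery.

The central object is a four-parameter logistic model of lesion
malignancy,

    log odds = b0 + b_AC * AC + b_SoS * SoS + b_ESD * ESD + b_ESC * ESC,

converted to a probability with the sigmoid.  The packaged default model
(:func:`default_model`) carries the published coefficients estimated on a
55-lesion clinical cohort (intercept -31.7558; AC +10.6396 per dB/cm/MHz;
SoS +0.0210 per m/s; ESD -0.0975 per um; ESC +0.0805 per scatterer/
wavelength^2), together with its inference table.  New cohorts can be
refitted with :func:`fit_logistic` (maximum likelihood via statsmodels,
Wald inference).

The supporting statistics match the study design: Mann-Whitney U for
group differences, ROC/AUC with a stratified percentile bootstrap CI, and
Clopper-Pearson exact binomial intervals for proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "LesionMeasurement",
    "LogisticModel",
    "ROCResult",
    "default_model",
    "table5_lesions",
    "table2_inference",
    "log_odds",
    "probability",
    "classify",
    "fit_logistic",
    "odds_ratio_table",
    "mann_whitney",
    "roc_auc",
    "clopper_pearson",
    "QUSMalignancyClassifier",
]

FEATURES = ("ac", "sos", "esd", "esc")


@dataclass
class LesionMeasurement:
    """One lesion's four QUS scalars plus the biopsy label."""

    ac: float  # dB/cm/MHz
    sos: float  # m/s
    esd: float  # um
    esc: float  # /wavelength^2
    label: str | None = None  # benign | malignant | None
    source_id: str | None = None

    def __post_init__(self) -> None:
        for name in FEATURES:
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.label is not None and self.label not in ("benign", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class LogisticModel:
    """Intercept + four coefficients, with optional Wald inference table."""

    intercept: float
    coef_ac: float
    coef_sos: float
    coef_esd: float
    coef_esc: float
    inference: pd.DataFrame | None = None
    separation_warning: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.coef_ac, self.coef_sos, self.coef_esd, self.coef_esc])

    def validate(self) -> None:
        if self.inference is None:
            return
        for name, coef in zip(FEATURES, self.coefficients):
            row = self.inference.loc[self.inference["parameter"] == name]
            if len(row) == 1:
                odds = float(row["odds_ratio"].iloc[0])
                if abs(np.exp(coef) - odds) / odds > 0.005:
                    raise ValueError(
                        f"inference table odds ratio for {name} inconsistent "
                        f"with coefficient {coef}"
                    )


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("pwqus.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def table5_lesions() -> pd.DataFrame:
    """The nine BI-RADS 3/4 lesions with per-lesion QUS measurements."""
    return _read_packaged("table5_lesions.csv")


def table2_inference() -> pd.DataFrame:
    """The published logistic-regression inference table."""
    return _read_packaged("table2_inference.csv")


def default_model() -> LogisticModel:
    """The packaged published logistic model with its inference table."""
    model = LogisticModel(
        intercept=-31.7558,
        coef_ac=10.6396,
        coef_sos=0.0210,
        coef_esd=-0.0975,
        coef_esc=0.0805,
        inference=table2_inference(),
    )
    model.validate()
    return model


def _as_features(m) -> np.ndarray:
    if isinstance(m, LesionMeasurement):
        return np.array([m.ac, m.sos, m.esd, m.esc], dtype=float)
    if isinstance(m, (pd.Series, dict)):
        return np.array([float(m[k]) for k in FEATURES])
    arr = np.asarray(m, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("measurement must provide (ac, sos, esd, esc)")
    return arr


def log_odds(measurement, model: LogisticModel | None = None):
    """Linear predictor of the malignancy model."""
    model = model or default_model()
    x = _as_features(measurement)
    if not np.all(np.isfinite(x)):
        raise ValueError("measurement contains missing or non-finite values")
    return float(model.intercept + x @ model.coefficients) if x.ndim == 1 else (
        model.intercept + x @ model.coefficients
    )


def probability(score):
    """Sigmoid conversion of a log-odds score to a probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(score, dtype=float)))


def classify(measurement, model: LogisticModel | None = None, threshold: float = 0.5):
    """Benign/malignant call at the given probability threshold."""
    p = probability(log_odds(measurement, model))
    return np.where(p >= threshold, "malignant", "benign"), p


def fit_logistic(cohort: pd.DataFrame) -> LogisticModel:
    """Maximum-likelihood logistic fit with Wald inference.

    ``cohort`` needs columns ``ac, sos, esd, esc, label``.  Perfect or
    quasi-perfect separation is flagged on the returned model rather than
    allowed to fail silently.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    if len(cohort) < 10:
        raise ValueError("need at least 10 lesions to fit")
    labels = set(cohort["label"])
    if labels != {"benign", "malignant"}:
        raise ValueError("cohort must contain both benign and malignant lesions")
    X = sm.add_constant(cohort[list(FEATURES)].astype(float))
    y = (cohort["label"] == "malignant").astype(int)

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as err:  # statsmodels raises on exact separation
            raise_separation = "Separation" in type(err).__name__ or "separation" in str(err)
            if not raise_separation:
                raise
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
            separation = True
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    if not separation and np.any(np.abs(res.params[1:]) > 1e3):
        separation = True

    params = np.asarray(res.params)
    bse = np.asarray(res.bse) if hasattr(res, "bse") else np.full(5, np.nan)
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # separated fits have huge Wald CIs
        inference = pd.DataFrame(
        {
            "parameter": FEATURES,
            "coef": params[1:],
            "se": bse[1:],
            "odds_ratio": np.exp(params[1:]),
            "std_err": np.exp(params[1:]) * bse[1:],  # delta-method OR scale
            "z": z[1:],
            "p": p[1:],
            "ci_low": np.exp(params[1:] - 1.96 * bse[1:]),
            "ci_high": np.exp(params[1:] + 1.96 * bse[1:]),
        }
    )
    return LogisticModel(
        intercept=float(params[0]),
        coef_ac=float(params[1]),
        coef_sos=float(params[2]),
        coef_esd=float(params[3]),
        coef_esc=float(params[4]),
        inference=inference,
        separation_warning=separation,
    )


def odds_ratio_table(model: LogisticModel, se: np.ndarray | None = None) -> pd.DataFrame:
    """Odds ratios (exp of coefficients) with Wald 95% CIs when SEs exist."""
    if se is None and model.inference is not None and "se" in model.inference:
        se = model.inference["se"].to_numpy()
    rows = []
    for i, name in enumerate(FEATURES):
        coef = model.coefficients[i]
        row = {"parameter": name, "coef": coef, "odds_ratio": float(np.exp(coef))}
        if se is not None and np.isfinite(se[i]):
            row["ci_low"] = float(np.exp(coef - 1.96 * se[i]))
            row["ci_high"] = float(np.exp(coef + 1.96 * se[i]))
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Returns ``(U_a, p)`` where ``U_a`` counts wins of ``group_a``.  When
    every value in both groups is identical the test is degenerate and
    ``p = 1`` is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return len(a) * len(b) / 2.0, 1.0
    method = "asymptotic" if (len(a) > 20 or len(b) > 20) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]
    n: int
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci[0] - 1e-12 <= self.auc <= self.ci[1] + 1e-12):
            raise ValueError("CI must contain the point estimate")


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ROCResult:
    """AUC with a stratified percentile-bootstrap confidence interval.

    ``labels`` may be 0/1 or benign/malignant strings; the AUC is computed
    by the trapezoidal rule (equivalently the rank statistic).
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "biuf":
        y = (y == "malignant").astype(int)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)

    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bi = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        boots[i] = roc_auc_score(y[bi], scores[bi])
    alpha = (1 - ci_level) / 2
    ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
    ci = (min(ci[0], auc), max(ci[1], auc))
    return ROCResult(auc=auc, ci=ci, n=len(y), fpr=fpr, tpr=tpr)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


class QUSMalignancyClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn wrapper around the QUS logistic malignancy model.

    With ``use_default_model=True`` the published coefficients are used as
    a fixed scorer and ``fit`` only records the class layout; otherwise
    ``fit`` runs the maximum-likelihood fit on the provided cohort.
    Feature order is (AC, SoS, ESD, ESC).
    """

    def __init__(self, use_default_model: bool = False, threshold: float = 0.5):
        self.use_default_model = use_default_model
        self.threshold = threshold

    def fit(self, X, y=None):
        self.classes_ = np.array(["benign", "malignant"])
        if self.use_default_model:
            self.model_ = default_model()
            return self
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("y required when fitting a new model")
        labels = np.asarray(y)
        if labels.dtype.kind not in "US":
            labels = np.where(labels.astype(int) == 1, "malignant", "benign")
        cohort = pd.DataFrame(X, columns=list(FEATURES))
        cohort["label"] = labels
        self.model_ = fit_logistic(cohort)
        return self

    def decision_function(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        return self.model_.intercept + X @ self.model_.coefficients

    def predict_proba(self, X):
        p = probability(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.threshold, "malignant", "benign")
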