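"""Logistic calibration of computed similarity against expert majority verdicts.

The model is a binary logistic regression

    logit p = ln(p / (1 - p)) = beta0 + beta1 * x,      x = 10 * similarity,

where p is the probability that a majority of the expert panel judges a
molecule pair "similar".  The predictor is the Tanimoto similarity expressed
in 0.1-units, so beta1 is the change in log-odds per 0.1 increment of
similarity (exp(beta1) the corresponding odds multiplier).  The calibration
threshold t_LR is the similarity at which the fitted model predicts
probability 0.5, i.e. t_LR = -beta0 / (10 * beta1).

Fitting is by maximum likelihood (IRLS, via statsmodels GLM).  Complete or
quasi-complete separation — a real possibility when the panel agrees almost
perfectly with the similarity ranking — is detected up front and handled by
a Jeffreys-prior (Firth) penalized fit, flagged on the returned model.

Goodness of fit is summarised by Nagelkerke's R² and the Hosmer–Lemeshow
deciles-of-risk chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .fingerprints import SimilarityProfile

__all__ = [
    "CalibrationModel",
    "CalibrationResult",
    "label_majority",
    "fit_logistic",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "predict_probability",
    "flag_outliers",
    "calibrate_profiles",
]


@dataclass
class CalibrationModel:
    """Fitted logistic calibration for one fingerprint scheme.

    ``beta1`` is on the 0.1-similarity scale (log-odds per 0.1 Tanimoto).
    """

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    cov: np.ndarray | None  # 2x2 covariance of (beta0, beta1)
    r2_nagelkerke: float
    hl_statistic: float
    hl_pvalue: float
    t_lr: float
    n_obs: int
    loglik: float
    loglik_null: float
    scheme: str | None = None
    separation: bool = False
    method: str = "mle"  # "mle", "firth", or "fixed" for externally given coefficients
    excluded_pairs: list[str] = field(default_factory=list)

    @classmethod
    def from_coefficients(
        cls, beta0: float, beta1: float, scheme: str | None = None
    ) -> "CalibrationModel":
        """Build a model from externally reported coefficients (no fit diagnostics)."""
        t_lr = -beta0 / (10.0 * beta1) if beta1 > 0 else float("nan")
        nan = float("nan")
        return cls(
            beta0=beta0, beta1=beta1, se_beta0=nan, se_beta1=nan, cov=None,
            r2_nagelkerke=nan, hl_statistic=nan, hl_pvalue=nan, t_lr=t_lr,
            n_obs=0, loglik=nan, loglik_null=nan, scheme=scheme, method="fixed",
        )

    def odds_multiplier(self) -> float:
        """Factor by which the odds of a 'similar' verdict grow per 0.1 similarity."""
        return float(np.exp(self.beta1))


@dataclass
class CalibrationResult:
    """Primary fit plus outlier bookkeeping from :func:`calibrate_profiles`."""

    model: CalibrationModel
    flagged_pairs: list[str]
    model_without_flagged: CalibrationModel | None = None


def label_majority(yes_fraction: float) -> bool:
    """Majority rule: similar iff strictly more than 50% of responses are Yes."""
    if not 0.0 <= yes_fraction <= 1.0:
        raise ValueError(f"yes_fraction must lie in [0, 1], got {yes_fraction}")
    return yes_fraction > 0.5


def _bernoulli_loglik(p: np.ndarray, y: np.ndarray, trials: np.ndarray | None) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    if trials is not None:
        ll = trials * ll
    return float(ll.sum())


def _separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete or quasi-complete separation for a single monotone predictor."""
    x0, x1 = x[y == 0], x[y == 1]
    return bool(x0.max() <= x1.min() or x1.max() <= x0.min())


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic regression (Firth 1993), via modified IRLS."""
    beta = np.zeros(X.shape[1])

    def penalized_ll(b):
        p = expit(X @ b)
        info = (X.T * (p * (1 - p))) @ X
        sign, logdet = np.linalg.slogdet(info)
        return _bernoulli_loglik(p, y, None) + 0.5 * logdet

    ll_old = penalized_ll(beta)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = p * (1 - p)
        info = (X.T * w) @ X
        info_inv = np.linalg.inv(info)
        h = w * np.einsum("ij,ij->i", X @ info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ score
        step = 1.0
        for _ in range(30):  # step-halving keeps the penalized likelihood climbing
            ll_new = penalized_ll(beta + step * delta)
            if ll_new >= ll_old - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        if np.abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    p = expit(X @ beta)
    info = (X.T * (p * (1 - p))) @ X
    cov = np.linalg.inv(info)
    return beta, cov


def fit_logistic(
    similarities,
    labels,
    *,
    trials=None,
    scheme: str | None = None,
    hl_groups: int = 10,
    on_separation: str = "firth",
) -> CalibrationModel:
    """Fit the logistic calibration of similarity against panel verdicts.

    Parameters
    ----------
    similarities
        Tanimoto values in [0, 1], one per molecule pair.
    labels
        Binary majority verdicts (0/1) — or, when ``trials`` is given, the
        per-pair fraction of Yes votes, fitted as a grouped binomial response
        with ``trials`` Bernoulli trials per pair.
    trials
        Panel size(s) for the grouped-binomial variant; scalar or per-pair.
    on_separation
        ``"firth"`` (default) fits with a Jeffreys prior and flags the model;
        ``"error"`` raises :class:`PerfectSeparationError` instead.
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.ndim != 1 or s.shape != y.shape:
        raise ValueError("similarities and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("similarities must be finite")
    grouped = trials is not None
    if grouped:
        trials_arr = np.broadcast_to(np.asarray(trials, dtype=float), y.shape).copy()
        if np.any(trials_arr < 1):
            raise ValueError("trials must be >= 1")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("grouped response must be fractions in [0, 1]")
        if np.allclose(y, y[0]):
            raise ValueError("response is constant; cannot fit a logistic model")
    else:
        trials_arr = None
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("both classes must be present to fit a logistic model")

    x = 10.0 * s
    X = np.column_stack([np.ones_like(x), x])
    separation = (not grouped) and _separated(x, y)
    if separation and on_separation == "error":
        raise PerfectSeparationError("labels are perfectly separated by similarity")

    beta = cov = None
    if not separation:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=trials_arr)
                res = glm.fit(maxiter=100, tol=1e-8)
            beta = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
            # IRLS can walk off to infinity under near-separation without raising
            if not np.all(np.isfinite(beta)) or np.max(np.abs(X @ beta)) > 36.0:
                separation = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
        if separation and on_separation == "error":
            raise PerfectSeparationError("divergent fit: labels (quasi-)separated by similarity")

    if separation:
        if grouped:
            raise ValueError("divergent grouped fit; response is degenerate")
        beta, cov = _firth_fit(X, y)

    p_hat = expit(X @ beta)
    ll = _bernoulli_loglik(p_hat, y, trials_arr)
    p_null = float(np.average(y, weights=trials_arr))
    ll0 = _bernoulli_loglik(np.full_like(y, p_null), y, trials_arr)
    n_eff = int(trials_arr.sum()) if grouped else int(y.size)
    r2 = nagelkerke_r2(ll0, max(ll, ll0), n_eff)
    if grouped:
        hl_stat, hl_p = float("nan"), float("nan")
    else:
        try:
            hl_stat, hl_p = hosmer_lemeshow(p_hat, y, n_groups=hl_groups)
        except ValueError:
            hl_stat, hl_p = float("nan"), float("nan")
    beta0, beta1 = float(beta[0]), float(beta[1])
    t_lr = -beta0 / (10.0 * beta1) if beta1 > 0 else float("nan")
    se = np.sqrt(np.diag(cov))
    return CalibrationModel(
        beta0=beta0,
        beta1=beta1,
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        cov=cov,
        r2_nagelkerke=r2,
        hl_statistic=hl_stat,
        hl_pvalue=hl_p,
        t_lr=t_lr,
        n_obs=int(y.size),
        loglik=ll,
        loglik_null=ll0,
        scheme=scheme,
        separation=separation,
        method="firth" if separation else "mle",
    )


def nagelkerke_r2(loglik_null: float, loglik_model: float, n_obs: int) -> float:
    """Nagelkerke's rescaled Cox–Snell R², in [0, 1]."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood cannot be below the null log-likelihood")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n_obs)
    denom = 1.0 - np.exp(2.0 * loglik_null / n_obs)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def hosmer_lemeshow(predicted_probs, labels, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer–Lemeshow deciles-of-risk goodness-of-fit test.

    Observations are sorted by predicted probability and cut into
    ``n_groups`` equal-size groups, with tied probabilities kept in one
    group.  The statistic sums (O−E)² / (E·(1−E/n_g)) over groups and is
    referred to a chi-square with ``groups − 2`` degrees of freedom.  Groups
    whose expected count is degenerate (E = 0 or E = n_g) are merged into
    their neighbour, with a warning.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = p.size
    if n_groups < 3:
        raise ValueError("need at least 3 groups")
    if n < n_groups:
        raise ValueError("need at least as many observations as groups")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    # group boundaries at multiples of n/g, pushed right past ties
    bounds = [0]
    for k in range(1, n_groups):
        j = round(k * n / n_groups)
        while 0 < j < n and ps[j] == ps[j - 1]:
            j += 1
        if j > bounds[-1]:
            bounds.append(j)
    bounds.append(n)
    groups = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if bounds[i] < bounds[i + 1]]
    obs = np.array([ys[a:b].sum() for a, b in groups])
    exp = np.array([ps[a:b].sum() for a, b in groups])
    size = np.array([b - a for a, b in groups], dtype=float)
    # merge groups with a degenerate expected count into the previous neighbour
    i = 0
    while i < len(obs):
        if exp[i] <= 1e-12 or size[i] - exp[i] <= 1e-12:
            j = i - 1 if i > 0 else i + 1
            if j < 0 or j >= len(obs):
                break
            warnings.warn("merging a Hosmer-Lemeshow group with degenerate expected count",
                          stacklevel=2)
            obs[j] += obs[i]
            exp[j] += exp[i]
            size[j] += size[i]
            obs = np.delete(obs, i)
            exp = np.delete(exp, i)
            size = np.delete(size, i)
            i = 0
        else:
            i += 1
    denom = exp * (1.0 - exp / size)
    valid = denom > 1e-12
    stat = float((((obs - exp) ** 2)[valid] / denom[valid]).sum())
    df = len(obs) - 2
    if df < 1:
        warnings.warn("too few distinct risk groups for a Hosmer-Lemeshow p-value", stacklevel=2)
        return stat, float("nan")
    return stat, float(chi2.sf(stat, df))


def predict_probability(model: CalibrationModel, similarity):
    """Predicted probability of a majority 'similar' verdict, with 95% CI.

    The confidence band comes from the covariance of (beta0, beta1) on the
    linear-predictor scale, transformed through the logistic function.
    Returns scalars for scalar input, arrays for array input.
    """
    s = np.asarray(similarity, dtype=float)
    x = 10.0 * s
    lp = model.beta0 + model.beta1 * x
    prob = expit(lp)
    if model.cov is not None:
        var = (
            model.cov[0, 0]
            + 2.0 * x * model.cov[0, 1]
            + x ** 2 * model.cov[1, 1]
        )
        half = 1.96 * np.sqrt(var)
        lo, hi = expit(lp - half), expit(lp + half)
    else:
        lo = hi = np.full_like(prob, np.nan)
    if prob.ndim == 0:
        return float(prob), float(lo), float(hi)
    return prob, lo, hi


def flag_outliers(model: CalibrationModel, similarities, labels) -> np.ndarray:
    """Indices of observations with |standardized Pearson residual| > 3.

    Flagging never removes anything by itself; refitting without flagged
    pairs is an explicit, reported choice (see :func:`calibrate_profiles`).
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=float)
    x = 10.0 * s
    X = np.column_stack([np.ones_like(x), x])
    p = expit(X @ np.array([model.beta0, model.beta1]))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    w = p * (1 - p)
    info = (X.T * w) @ X
    h = w * np.einsum("ij,ij->i", X @ np.linalg.inv(info), X)
    r = (y - p) / np.sqrt(w * np.clip(1.0 - h, 1e-12, None))
    return np.flatnonzero(np.abs(r) > 3.0)


def calibrate_profiles(
    profiles: list[SimilarityProfile],
    scheme: str,
    *,
    refit_without_flagged: bool = False,
    hl_groups: int = 10,
) -> CalibrationResult:
    """Run the full calibration for one scheme over labelled similarity profiles.

    Majority labels are derived from each profile's ``yes_fraction`` (unless
    already present), the logistic calibration is fitted, and outlying pairs
    are flagged.  With ``refit_without_flagged`` a second fit excluding the
    flagged pairs is reported alongside — never silently in place of — the
    full-data fit.
    """
    sims, labels, ids = [], [], []
    for prof in profiles:
        if scheme not in prof.similarities:
            raise ValueError(f"pair {prof.pair_id!r} has no similarity for scheme {scheme!r}")
        label = prof.majority_label
        if label is None:
            if prof.yes_fraction is None:
                raise ValueError(f"pair {prof.pair_id!r} has neither a label nor a yes_fraction")
            label = label_majority(prof.yes_fraction)
        sims.append(prof.similarities[scheme])
        labels.append(float(label))
        ids.append(prof.pair_id)
    sims_arr = np.array(sims)
    labels_arr = np.array(labels)
    model = fit_logistic(sims_arr, labels_arr, scheme=scheme, hl_groups=hl_groups)
    flagged_idx = flag_outliers(model, sims_arr, labels_arr)
    flagged = [ids[i] for i in flagged_idx]
    refit = None
    if refit_without_flagged and flagged:
        keep = np.setdiff1d(np.arange(len(ids)), flagged_idx)
        refit = fit_logistic(sims_arr[keep], labels_arr[keep], scheme=scheme, hl_groups=hl_groups)
        refit.excluded_pairs = flagged
    return CalibrationResult(model=model, flagged_pairs=flagged, model_without_flagged=refit)
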