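"""Logistic-exposure daily nest survival.

An interval between two nest checks with exposure ``t`` days survives
with probability ``theta^t``, where the daily survival rate (DSR)
``theta`` sits on the logit scale:

    logit(theta_i) = x_i' beta + u_plot,   u_plot ~ Normal(0, sigma^2).

The marginal likelihood integrates the plot random effect by
Gauss-Hermite quadrature.  Seasonal survival is DSR raised to the
nesting-period length (19 days for Brewer's sparrow, 15 for vesper
sparrow by default).  Descriptive summaries (apparent success, failure
causes) live here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .selection import aicc, akaike_table

__all__ = [
    "build_exposure_intervals", "interval_loglik", "seasonal_survival",
    "apparent_success", "failure_cause_breakdown",
    "LogisticExposureModel", "LogisticExposureResults",
]


# ---------------------------------------------------------------------------
# interval construction and elementary quantities

def build_exposure_intervals(visits: pd.DataFrame,
                             midpoint: bool = False) -> pd.DataFrame:
    """Decompose visit histories into interval-level survival trials.

    Consecutive visit pairs become one row each with exposure ``t`` =
    days between visits, outcome ``survived`` (0 if the nest was failed
    at the interval's end, else 1) and the stage at the interval start.
    With ``midpoint=True`` a failed interval is credited half its length
    of exposure (it must have failed at an unknown day inside it).

    Single-visit histories carry no exposure and are dropped with a
    warning; non-monotone visit dates raise a ``ValueError`` naming the
    nest.
    """
    required = {"nest_id", "visit_day", "stage", "status"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visits table missing columns {sorted(missing)}")

    rows = []
    dropped = 0
    for nest_id, grp in visits.groupby("nest_id", sort=False):
        # visits must already be in chronological order; sorting here
        # would silently repair corrupt records instead of flagging them
        days = grp["visit_day"].to_numpy()
        if len(days) < 2:
            dropped += 1
            continue
        if np.any(np.diff(days) <= 0):
            raise ValueError(
                f"nest {nest_id}: visit dates not strictly increasing")
        stages = grp["stage"].to_numpy()
        statuses = grp["status"].to_numpy()
        carry = {c: grp[c].iloc[0] for c in grp.columns
                 if c not in {"visit_day", "stage", "status", "cause"}}
        for a in range(len(days) - 1):
            t = float(days[a + 1] - days[a])
            failed = statuses[a + 1] == "failed"
            if failed and midpoint:
                t = max(t / 2.0, 0.5)
            rows.append({**carry, "t": t,
                         "stage": stages[a],
                         "survived": 0 if failed else 1})
            if statuses[a + 1] in ("failed", "fledged"):
                break
    if dropped:
        warnings.warn(f"{dropped} single-visit histories excluded "
                      "(no exposure)", stacklevel=2)
    return pd.DataFrame(rows)


def interval_loglik(y: int, t: float, theta: float) -> float:
    """Log-probability of one exposure interval.

    ln(theta^t) when the nest survived, ln(1 - theta^t) when it failed.
    Boundary theta is guarded with a large finite penalty.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    if t <= 0:
        raise ValueError("exposure t must be positive")
    log_surv = t * math.log(theta)
    if y == 1:
        return log_surv
    if log_surv == 0.0:         # theta == 1, failure impossible
        return -1e10
    return math.log(-math.expm1(log_surv))


def seasonal_survival(dsr: float, period_days: float) -> float:
    """Season-long nest survival: DSR compounded over the nesting period."""
    if not 0.0 <= dsr <= 1.0:
        raise ValueError("dsr must be in [0, 1]")
    if period_days < 1:
        raise ValueError("period must be >= 1 day")
    return dsr ** period_days


def _terminal_fates(histories: pd.DataFrame) -> pd.DataFrame:
    """Reduce a visits table (or fate table) to one row per nest."""
    if "fledged" in histories.columns and "visit_day" not in histories.columns:
        out = histories.copy()
        out["fate"] = np.where(out["fledged"], "fledged", "failed")
        return out[["nest_id", "fate"] +
                   (["cause"] if "cause" in out.columns else [])]
    last = (histories.sort_values("visit_day", kind="mergesort")
            .groupby("nest_id", sort=False).tail(1))
    out = last.rename(columns={"status": "fate"})
    cols = ["nest_id", "fate"] + (["cause"] if "cause" in out.columns else [])
    return out[cols]


def apparent_success(histories: pd.DataFrame,
                     include_censored: bool = False) -> dict:
    """Raw fledging fraction: nests that fledged / nests with known fate.

    Histories still active at the last visit are censored and excluded
    unless ``include_censored`` (then they count as failures in the
    denominator).  Returns ``{"fraction", "n_fledged", "n_total"}``.
    """
    fates = _terminal_fates(histories)
    terminal = fates[fates["fate"].isin(["fledged", "failed"])]
    n_censored = len(fates) - len(terminal)
    n_fledged = int((terminal["fate"] == "fledged").sum())
    n_total = len(terminal) + (n_censored if include_censored else 0)
    if n_total == 0:
        raise ValueError("no histories with terminal fate")
    return {"fraction": n_fledged / n_total,
            "n_fledged": n_fledged, "n_total": n_total}


def failure_cause_breakdown(histories: pd.DataFrame) -> pd.DataFrame:
    """Tabulate causes of failure over failed nests only.

    Returns one row per cause with ``count`` and ``fraction`` (of all
    failures; fractions sum to 1).  Unlabelled failures fall in an
    ``unknown`` bucket.
    """
    fates = _terminal_fates(histories)
    failed = fates[fates["fate"] == "failed"].copy()
    if failed.empty:
        return pd.DataFrame(columns=["cause", "count", "fraction"])
    if "cause" not in failed.columns:
        failed["cause"] = ""
    cause = failed["cause"].fillna("").replace("", "unknown")
    counts = cause.value_counts()
    out = counts.rename("count").reset_index().rename(
        columns={"index": "cause"})
    out["fraction"] = out["count"] / out["count"].sum()
    return out


# ---------------------------------------------------------------------------
# design matrix from a light-weight formula

def _design_matrix(data: pd.DataFrame, formula: str
                   ) -> tuple[np.ndarray, list[str]]:
    """Build [1 | terms] from a '+'-separated RHS formula.

    Object/category columns are dummy-coded dropping the first sorted
    level; numeric columns enter as-is.  ``"1"`` gives intercept-only.
    """
    rhs = formula.split("~")[-1].strip()
    cols, names = [np.ones(len(data))], ["intercept"]
    for term in [t.strip() for t in rhs.split("+") if t.strip()]:
        if term == "1":
            continue
        if term not in data.columns:
            raise KeyError(f"formula term {term!r} not in data")
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(term)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank-deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {names}")
    return X, names


# ---------------------------------------------------------------------------
# the model

class LogisticExposureModel:
    """Logistic-exposure DSR model over interval data.

    Parameters
    ----------
    intervals : output of :func:`build_exposure_intervals` (columns
        ``survived``, ``t``, plus covariates).
    formula : RHS formula for the fixed effects, e.g.
        ``"~ stage + year + shrub_cover"``.
    random_plot : include a Normal plot random intercept, integrated
        out by Gauss-Hermite quadrature.
    quadrature_nodes : Gauss-Hermite node count (default 20).
    """

    def __init__(self, intervals: pd.DataFrame, formula: str = "~ 1",
                 random_plot: bool = False, quadrature_nodes: int = 20):
        if intervals.empty:
            raise ValueError("no exposure intervals")
        self.data = intervals.reset_index(drop=True)
        self.formula = formula
        self.random_plot = bool(random_plot)
        self.y = self.data["survived"].to_numpy(float)
        self.t = self.data["t"].to_numpy(float)
        if np.any(self.t <= 0):
            raise ValueError("exposure t must be positive")
        self.X, self.param_names = _design_matrix(self.data, formula)
        if random_plot:
            if "plot_id" not in self.data.columns:
                raise ValueError("random_plot requires a plot_id column")
            codes, self._plots = pd.factorize(self.data["plot_id"])
            self._plot_idx = codes
            self.param_names = self.param_names + ["log_sigma_plot"]
            # probabilists' Gauss-Hermite: sum w_k f(z_k) integrates
            # f against exp(-z^2/2), so dividing by sqrt(2*pi) gives the
            # standard-normal expectation of f
            z, wq = np.polynomial.hermite_e.hermegauss(quadrature_nodes)
            self._gh_z = z
            self._gh_logw = np.log(wq) - 0.5 * math.log(2 * math.pi)
        if np.all(self.y == self.y[0]):
            warnings.warn("all intervals share one outcome; estimates "
                          "may sit at the boundary (separation)",
                          stacklevel=2)

    @classmethod
    def from_dataframe(cls, intervals, formula="~ 1", **kw):
        return cls(intervals, formula=formula, **kw)

    @classmethod
    def from_histories(cls, visits, formula="~ 1", midpoint=False, **kw):
        return cls(build_exposure_intervals(visits, midpoint=midpoint),
                   formula=formula, **kw)

    # -- likelihood ---------------------------------------------------------
    def _interval_logp(self, eta: np.ndarray) -> np.ndarray:
        """Elementwise log P(y_i | theta_i = expit(eta_i)) for array eta."""
        log_theta = -np.logaddexp(0.0, -eta)        # log expit(eta)
        log_surv = self.t.reshape(-1, *([1] * (eta.ndim - 1))) * log_theta \
            if eta.ndim > 1 else self.t * log_theta
        y = self.y.reshape(-1, *([1] * (eta.ndim - 1))) \
            if eta.ndim > 1 else self.y
        with np.errstate(divide="ignore"):
            log_fail = np.where(log_surv < 0,
                                np.log(-np.expm1(np.minimum(log_surv,
                                                            -1e-12))),
                                -1e10)
        return y * log_surv + (1 - y) * log_fail

    def loglike(self, params: np.ndarray) -> float:
        p = self.X.shape[1]
        beta = params[:p]
        eta0 = self.X @ beta
        if not self.random_plot:
            return float(np.sum(self._interval_logp(eta0)))
        sigma = math.exp(params[p])
        eta = eta0[:, None] + sigma * self._gh_z[None, :]
        logp = self._interval_logp(eta)                # (n, K)
        n_plots = len(self._plots)
        per_plot = np.zeros((n_plots, len(self._gh_z)))
        np.add.at(per_plot, self._plot_idx, logp)
        return float(np.sum(logsumexp(per_plot + self._gh_logw[None, :],
                                      axis=1)))

    def fit(self, start: np.ndarray | None = None, maxiter: int = 500
            ) -> "LogisticExposureResults":
        p = self.X.shape[1]
        if start is None:
            crude = np.clip(self.y.mean(), 0.01, 0.995)
            start = np.zeros(p + (1 if self.random_plot else 0))
            start[0] = math.log(crude / (1 - crude))
            if self.random_plot:
                start[p] = math.log(0.3)
        nll = lambda par: -self.loglike(par)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimize.minimize(
                nll, start, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
        H = _num_hessian(nll, opt.x)
        try:
            cov = np.linalg.inv(H)
            if not np.all(np.isfinite(cov)):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
        return LogisticExposureResults(
            model=self, params=opt.x, loglik=-float(opt.fun),
            cov_params=cov, converged=bool(opt.success))


def _num_hessian(f, x, eps=1e-4):
    m = len(x)
    H = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            ei, ej = np.zeros(m), np.zeros(m)
            ei[i], ej[j] = eps, eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps * eps)
    return H


@dataclass
class LogisticExposureResults:
    """Fitted logistic-exposure model: coefficients, SEs, AICc, DSR."""

    model: LogisticExposureModel
    params: np.ndarray
    loglik: float
    cov_params: np.ndarray | None
    converged: bool
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = self.model.formula

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def n(self) -> int:
        return len(self.model.y)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def beta(self) -> np.ndarray:
        return self.params[:self.model.X.shape[1]]

    @property
    def random_sd(self) -> float:
        if not self.model.random_plot:
            return 0.0
        return math.exp(self.params[self.model.X.shape[1]])

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(self.k, np.nan)
        d = np.diag(self.cov_params)
        return np.sqrt(np.where(d > 0, d, np.nan))

    def predict_dsr(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """DSR on the data scale at the fixed effects (random effect 0)."""
        if data is None:
            X = self.model.X
        else:
            X, _ = _design_matrix(data, self.model.formula)
        return expit(X @ self.beta)

    def dsr_at_mean(self) -> float:
        """DSR at the average design row (a convenient point summary)."""
        return float(expit(self.model.X.mean(axis=0) @ self.beta))

    def seasonal_survival(self, period_days: float,
                          dsr: float | None = None) -> float:
        return seasonal_survival(
            self.dsr_at_mean() if dsr is None else dsr, period_days)

    def summary(self) -> str:
        lines = [
            f"Logistic-exposure model: survived ~ {self.model.formula.split('~')[-1].strip()}",
            f"  n intervals = {self.n}, log-likelihood = {self.loglik:.4f}, "
            f"AICc = {self.aicc:.4f}",
            f"  {'term':<22}{'coef':>10}{'se':>10}{'z':>8}",
        ]
        bse = self.bse
        for i, nm in enumerate(self.model.param_names):
            val = self.params[i]
            se = bse[i]
            zval = val / se if se and np.isfinite(se) else np.nan
            lines.append(f"  {nm:<22}{val:>10.4f}{se:>10.4f}{zval:>8.2f}")
        if self.model.random_plot:
            lines.append(f"  plot random-effect SD = {self.random_sd:.4f}")
        lines.append(f"  DSR at mean covariates = {self.dsr_at_mean():.4f}")
        return "\n".join(lines)


def model_selection_table(results: list[LogisticExposureResults]
                          ) -> pd.DataFrame:
    """AICc ranking of fitted survival models (shared AICc machinery)."""
    return akaike_table(
        [r.name for r in results],
        [r.loglik for r in results],
        [r.k for r in results],
        [r.n for r in results])
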