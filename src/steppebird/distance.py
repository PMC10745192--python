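"""Line-transect distance sampling for nest density.

Maximum-likelihood detection functions (half-normal, hazard-rate and
uniform keys; cosine, simple-polynomial and Hermite-polynomial
adjustment series; covariates on the log detection scale), AICc model
selection, and stratified density estimation

    D_hat = n / (2 * w * L * P_a)

with encounter-rate variance across transects combined with the
delta-method variance of the average detection probability ``P_a``, and
log-normal confidence intervals.  Densities are reported per 25 ha
(the 500 x 500 m plot unit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import t as t_dist

from .selection import aicc, akaike_table

__all__ = [
    "key_function", "truncate", "DistanceSamplingModel",
    "DetectionFunctionResults", "DensityEstimate", "estimate_density",
]

PLOT_AREA_M2 = 500.0 * 500.0        # 25 ha in square metres

_QUAD_NODES = 64
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_QUAD_NODES)


class EmptyStratumError(ValueError):
    """All detections removed or a stratum has no usable data."""


class FitError(RuntimeError):
    """Detection-function optimizer failed to converge."""


# ---------------------------------------------------------------------------
# key and adjustment functions

def key_function(key: str, scale: float, shape: float = 2.0):
    """Return the detection key g(x) with g(0) = 1.

    Keys: ``half-normal`` g(x) = exp(-x^2 / (2 sigma^2));
    ``hazard-rate`` g(x) = 1 - exp(-(x/sigma)^-b); ``uniform`` g = 1.
    """
    if key == "half-normal":
        return lambda x: np.exp(-np.square(x) / (2.0 * scale ** 2))
    if key == "hazard-rate":
        def g(x):
            x = np.asarray(x, dtype=float)
            with np.errstate(divide="ignore", over="ignore"):
                ratio = np.where(x > 0, x / scale, np.inf)
                val = -np.expm1(-np.power(ratio, -shape))
            return np.where(x > 0, val, 1.0)
        return g
    if key == "uniform":
        return lambda x: np.ones_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown key function {key!r}")


def _adjustment_series(adjustment: str, orders: tuple[int, ...],
                       z: np.ndarray) -> np.ndarray:
    """Adjustment basis evaluated at scaled distance z = x / w.

    Returns an array of shape (len(orders), len(z)).
    """
    z = np.asarray(z, dtype=float)
    if adjustment == "cosine":
        return np.stack([np.cos(j * np.pi * z) for j in orders])
    if adjustment == "simple-polynomial":
        return np.stack([np.power(z, j) for j in orders])
    if adjustment == "hermite-polynomial":
        return np.stack([special.eval_hermitenorm(j, z) for j in orders])
    raise ValueError(f"unknown adjustment {adjustment!r}")


def truncate(detections: pd.DataFrame, w: float) -> pd.DataFrame:
    """Drop detections beyond the truncation distance ``w``."""
    if w <= 0:
        raise ValueError("truncation distance must be positive")
    kept = detections[detections["distance_m"] <= w].copy()
    if kept.empty:
        raise EmptyStratumError(
            f"all {len(detections)} detections beyond w={w} m")
    return kept


# ---------------------------------------------------------------------------
# fitted detection function

@dataclass
class DetectionFunctionResults:
    """A fitted detection function g(x) on [0, w] with g(0) = 1."""

    key: str
    adjustment: str | None
    orders: tuple[int, ...]
    covariates: tuple[str, ...]
    params: np.ndarray               # internal parameter vector
    loglik: float
    k: int
    n: int
    w: float
    converged: bool
    monotone_ok: bool
    cov_params: np.ndarray | None = None
    _covariate_data: np.ndarray | None = field(default=None, repr=False)

    # -- parameter unpacking ------------------------------------------------
    @property
    def name(self) -> str:
        parts = [self.key]
        if self.adjustment:
            parts.append(f"{self.adjustment}({','.join(map(str, self.orders))})")
        if self.covariates:
            parts.append("cov(" + "+".join(self.covariates) + ")")
        return "+".join(parts)

    def _n_key_params(self) -> int:
        return {"half-normal": 1, "hazard-rate": 2, "uniform": 0}[self.key]

    def _sigma(self, params=None, covrow=None) -> float:
        params = self.params if params is None else params
        if self.key == "uniform":
            return math.nan
        log_sigma = params[0]
        if self.covariates and covrow is not None:
            nk = self._n_key_params()
            beta = params[nk:nk + len(self.covariates)]
            log_sigma = log_sigma + float(np.dot(beta, covrow))
        return math.exp(log_sigma)

    @property
    def sigma(self) -> float:
        """Detection scale (m); at mean covariates for covariate models."""
        if self.covariates and self._covariate_data is not None:
            return self._sigma(covrow=self._covariate_data.mean(axis=0))
        return self._sigma()

    @property
    def shape(self) -> float:
        if self.key != "hazard-rate":
            return math.nan
        return 1.0 + math.exp(self.params[1])

    def _adj_coefs(self, params=None) -> np.ndarray:
        params = self.params if params is None else params
        nk = self._n_key_params() + len(self.covariates)
        return np.asarray(params[nk:nk + len(self.orders)])

    # -- evaluation ---------------------------------------------------------
    def g(self, x, params=None, covrow=None) -> np.ndarray:
        """Detection probability at perpendicular distance x (metres)."""
        params = self.params if params is None else params
        x = np.asarray(x, dtype=float)
        sigma = 1.0 if self.key == "uniform" else self._sigma(params, covrow)
        shape = (1.0 + math.exp(params[1])
                 if self.key == "hazard-rate" else 2.0)
        base = key_function(self.key, sigma, shape)(x)
        if not self.adjustment:
            return base
        a = self._adj_coefs(params)
        h = _adjustment_series(self.adjustment, self.orders, x / self.w)
        h0 = _adjustment_series(self.adjustment, self.orders,
                                np.zeros(1))[:, 0]
        num = base * (1.0 + a @ h)
        den = 1.0 + float(a @ h0)     # key(0) = 1 for all keys
        return num / den

    def _mu(self, params=None, covrow=None) -> float:
        """Effective strip half-width: integral of g over [0, w].

        Closed form (erf) for a plain half-normal key — exact at any w,
        including truncation distances far beyond the data; fixed-node
        Gauss-Legendre otherwise (w is data-driven there).
        """
        params = self.params if params is None else params
        if self.key == "half-normal" and not self.adjustment:
            sigma = self._sigma(params, covrow)
            return float(sigma * math.sqrt(math.pi / 2.0)
                         * math.erf(self.w / (sigma * math.sqrt(2.0))))
        xg = 0.5 * self.w * (_GL_X + 1.0)
        wg = 0.5 * self.w * _GL_W
        return float(np.sum(wg * self.g(xg, params=params, covrow=covrow)))

    def pdf(self, x) -> np.ndarray:
        """f(x) = g(x) / integral(g) on [0, w]."""
        return self.g(x) / self._mu()

    @property
    def average_p(self) -> float:
        """Average detection probability P_a within w.

        For covariate models this is the harmonic mean over detections,
        so that D_hat = n / (2 w L P_a) matches the Horvitz-Thompson sum
        of inverse detection probabilities.
        """
        if self.covariates and self._covariate_data is not None:
            ps = np.array([self._mu(covrow=row) / self.w
                           for row in self._covariate_data])
            return float(len(ps) / np.sum(1.0 / ps))
        return self._mu() / self.w

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def summary(self) -> str:
        lines = [
            f"Detection function: {self.name}",
            f"  n = {self.n}, w = {self.w:.2f} m, k = {self.k}",
            f"  log-likelihood = {self.loglik:.4f}, AICc = {self.aicc:.4f}",
            f"  P_a = {self.average_p:.4f}",
        ]
        if self.key != "uniform":
            lines.append(f"  sigma = {self.sigma:.4f} m")
        if self.key == "hazard-rate":
            lines.append(f"  shape b = {self.shape:.4f}")
        if not self.monotone_ok:
            lines.append("  WARNING: adjusted g(x) not monotone/in [0,1]")
        return "\n".join(lines)

    def plot(self, ax=None, bins=12):
        """Histogram of distances with the fitted pdf overlaid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(0, self.w, 200)
        ax.plot(xs, self.g(xs), label=self.name)
        ax.set_xlabel("perpendicular distance (m)")
        ax.set_ylabel("detection probability g(x)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# model

class DistanceSamplingModel:
    """Detection-function model for perpendicular nest distances.

    Parameters
    ----------
    detections : DataFrame with ``distance_m`` (plus covariate columns
        for covariate models); opportunistic rows must be excluded by
        the caller (they carry no usable distance).
    w : truncation distance in metres; defaults to the largest observed
        distance.
    """

    #: candidate suite tried by :meth:`fit_all`
    DEFAULT_CANDIDATES = (
        ("uniform", None, ()),
        ("uniform", "cosine", (2,)),
        ("uniform", "cosine", (2, 3)),
        ("half-normal", None, ()),
        ("half-normal", "cosine", (2,)),
        ("half-normal", "cosine", (2, 3)),
        ("half-normal", "simple-polynomial", (4,)),
        ("half-normal", "simple-polynomial", (4, 6)),
        ("half-normal", "hermite-polynomial", (4,)),
        ("half-normal", "hermite-polynomial", (4, 6)),
        ("hazard-rate", None, ()),
        ("hazard-rate", "cosine", (2,)),
        ("hazard-rate", "simple-polynomial", (4, 6)),
    )

    def __init__(self, detections: pd.DataFrame, w: float | None = None):
        if "opportunistic" in detections.columns:
            detections = detections[~detections["opportunistic"]]
        if len(detections) < 2:
            raise EmptyStratumError(
                "detection function requires >= 2 detections")
        dist = detections["distance_m"].to_numpy(dtype=float)
        if np.any(dist < 0) or not np.all(np.isfinite(dist)):
            raise ValueError("distances must be finite and >= 0")
        self.w = float(np.max(dist)) if w is None else float(w)
        keep = dist <= self.w
        if keep.sum() < 2:
            raise EmptyStratumError("fewer than 2 detections within w")
        self.detections = detections.loc[keep].reset_index(drop=True)
        self.x = dist[keep]
        self.n = len(self.x)

    @classmethod
    def from_dataframe(cls, detections: pd.DataFrame,
                       w: float | None = None) -> "DistanceSamplingModel":
        return cls(detections, w=w)

    # -- likelihood ---------------------------------------------------------
    def _make_result(self, key, adjustment, orders, covariates, params,
                     loglik, converged) -> DetectionFunctionResults:
        covdata = None
        if covariates:
            covdata = self.detections[list(covariates)].to_numpy(float)
        k = ({"half-normal": 1, "hazard-rate": 2, "uniform": 0}[key]
             + len(orders) + len(covariates))
        res = DetectionFunctionResults(
            key=key, adjustment=adjustment, orders=tuple(orders),
            covariates=tuple(covariates), params=np.asarray(params, float),
            loglik=loglik, k=k, n=self.n, w=self.w, converged=converged,
            monotone_ok=True, _covariate_data=covdata)
        # flag shape violations of the adjusted curve
        grid = np.linspace(0.0, self.w, 101)
        gv = res.g(grid)
        if np.any(gv < -1e-9) or np.any(gv > 1.0 + 1e-6):
            res.monotone_ok = False
        return res

    def _negloglik(self, res: DetectionFunctionResults,
                   params: np.ndarray) -> float:
        try:
            if res.covariates:
                ll = 0.0
                for xi, row in zip(self.x, res._covariate_data):
                    gi = float(res.g(np.array([xi]), params=params,
                                     covrow=row)[0])
                    mui = res._mu(params=params, covrow=row)
                    if gi <= 0 or mui <= 0:
                        return 1e10
                    ll += math.log(gi) - math.log(mui)
            else:
                gx = res.g(self.x, params=params)
                mu = res._mu(params=params)
                if np.any(gx <= 0) or mu <= 0:
                    return 1e10
                ll = float(np.sum(np.log(gx))) - self.n * math.log(mu)
            if not math.isfinite(ll):
                return 1e10
            return -ll
        except (FloatingPointError, OverflowError):
            return 1e10

    def fit(self, key: str = "half-normal", adjustment: str | None = None,
            orders: tuple[int, ...] = (), covariates: tuple[str, ...] = (),
            ) -> DetectionFunctionResults:
        """Fit one detection function by maximum conditional likelihood.

        Adjustment series and covariates cannot be combined in a single
        model (the conventional multiple-covariate restriction).
        """
        if adjustment and covariates:
            raise ValueError(
                "adjustment terms and covariates cannot be combined")
        if adjustment and not orders:
            raise ValueError("adjustment requested without orders")

        n_key = {"half-normal": 1, "hazard-rate": 2, "uniform": 0}[key]
        n_par = n_key + len(covariates) + len(orders)
        template = self._make_result(key, adjustment, orders, covariates,
                                     np.zeros(max(n_par, 1)), 0.0, False)

        if n_par == 0:
            # uniform, no adjustments: closed form, f = 1/w
            loglik = -self.n * math.log(self.w)
            return self._make_result(key, adjustment, orders, covariates,
                                     np.zeros(1), loglik, True)

        starts = self._starting_values(key, n_key, len(covariates),
                                       len(orders))
        best = None
        for x0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                opt = optimize.minimize(
                    lambda p: self._negloglik(template, p), x0,
                    method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
            if best is None or opt.fun < best.fun - 1e-12:
                best = opt
        if best is None or not math.isfinite(best.fun) or best.fun >= 1e9:
            raise FitError(
                f"detection function {key}/{adjustment} failed to "
                f"converge; starts tried: {[list(s) for s in starts]}")
        res = self._make_result(key, adjustment, orders, covariates,
                                best.x, -best.fun, bool(best.success))
        res.cov_params = self._param_cov(res)
        return res

    def _starting_values(self, key, n_key, n_cov, n_adj):
        sig0 = max(float(np.sqrt(np.mean(self.x ** 2))), 1e-3)
        starts = []
        for s in (sig0, 0.5 * sig0, self.w / 2.0):
            base = []
            if key in ("half-normal", "hazard-rate"):
                base.append(math.log(s))
            if key == "hazard-rate":
                base.append(math.log(1.5))   # b = 2.5
            base.extend([0.0] * n_cov)
            base.extend([0.0] * n_adj)
            starts.append(np.array(base))
        return starts

    def _param_cov(self, res: DetectionFunctionResults,
                   eps: float = 1e-4) -> np.ndarray | None:
        """Finite-difference Hessian of the negative log-likelihood."""
        p = res.params
        m = len(p)
        H = np.zeros((m, m))
        f0 = self._negloglik(res, p)
        for i in range(m):
            for j in range(i, m):
                pi, pj = np.zeros(m), np.zeros(m)
                pi[i], pj[j] = eps, eps
                fpp = self._negloglik(res, p + pi + pj)
                fpm = self._negloglik(res, p + pi - pj)
                fmp = self._negloglik(res, p - pi + pj)
                fmm = self._negloglik(res, p - pi - pj)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps ** 2)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)):
            return None
        return cov

    # -- model selection ----------------------------------------------------
    def fit_all(self, candidates=None, covariate_models=()
                ) -> tuple[pd.DataFrame, dict]:
        """Fit the candidate suite and rank by AICc.

        Returns ``(table, fits)`` where ``fits`` maps model name to its
        :class:`DetectionFunctionResults`.  Non-converged or
        shape-violating candidates are excluded from the ranking.
        """
        candidates = candidates or self.DEFAULT_CANDIDATES
        fits = {}
        for key, adj, orders in candidates:
            k_model = ({"half-normal": 1, "hazard-rate": 2,
                        "uniform": 0}[key] + len(orders))
            if self.n <= k_model + 1:
                continue        # AICc undefined at this sample size
            try:
                res = self.fit(key, adj, orders)
            except FitError:
                continue
            if res.monotone_ok:
                fits[res.name] = res
        for covs in covariate_models:
            try:
                res = self.fit("half-normal", covariates=tuple(covs))
            except (FitError, KeyError):
                continue
            if res.monotone_ok:
                fits[res.name] = res
        if not fits:
            raise FitError("no converged candidate detection function")
        names = list(fits)
        table = akaike_table(
            names,
            [fits[m].loglik for m in names],
            [fits[m].k for m in names],
            [fits[m].n for m in names])
        return table, fits

    def select(self, **kwargs) -> DetectionFunctionResults:
        table, fits = self.fit_all(**kwargs)
        return fits[table["model"].iloc[0]]


# ---------------------------------------------------------------------------
# density estimation

@dataclass
class DensityEstimate:
    """Stratum-level nest density in nests per 25 ha."""

    stratum: str
    n: int
    effort_m: float
    density: float                  # nests per 25 ha
    se: float
    ci_low: float
    ci_high: float
    p_a: float

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum, "n": self.n, "effort_m": self.effort_m,
            "density_per_25ha": self.density, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p_a": self.p_a,
        }


def _encounter_rate_cv2(counts: np.ndarray, lengths: np.ndarray
                        ) -> tuple[float, int]:
    """Squared CV of the encounter rate n/L across transects (R2-type)
    and its degrees of freedom (K - 1 replicate lines)."""
    K = len(counts)
    n, L = counts.sum(), lengths.sum()
    if n == 0:
        return 0.0, 1
    if K < 2:
        warnings.warn(
            "single-transect stratum: encounter-rate variance undefined; "
            "falling back to Poisson variance", stacklevel=2)
        return 1.0 / n, max(int(n) - 1, 1)
    er = n / L
    var_er = K / (L ** 2 * (K - 1)) * float(
        np.sum(lengths ** 2 * (counts / lengths - er) ** 2))
    return var_er / er ** 2, K - 1


def _pa_cv2(model_res: DetectionFunctionResults) -> float:
    """Delta-method squared CV of P_a from the parameter covariance."""
    if model_res.cov_params is None or model_res.k == 0:
        return 0.0
    p = model_res.params
    eps = 1e-5
    grad = np.zeros(len(p))
    for i in range(len(p)):
        dp = np.zeros(len(p))
        dp[i] = eps
        hi = DetectionFunctionResults(**{**model_res.__dict__,
                                         "params": p + dp})
        lo = DetectionFunctionResults(**{**model_res.__dict__,
                                         "params": p - dp})
        grad[i] = (hi._mu() - lo._mu()) / (2 * eps)
    var_mu = float(grad @ model_res.cov_params @ grad)
    mu = model_res._mu()
    if var_mu < 0 or mu <= 0:
        return 0.0
    return var_mu / mu ** 2


def estimate_density(
    model_res: DetectionFunctionResults,
    detections: pd.DataFrame,
    effort: pd.DataFrame,
    strata: list[str] | None = None,
    alpha: float = 0.05,
) -> list[DensityEstimate]:
    """Estimate nest density per stratum from a fitted detection function.

    ``effort`` needs columns ``transect_id``, ``length_m`` and
    optionally ``rounds`` (line length is multiplied by survey rounds),
    plus the stratum columns.  ``strata`` is a list of column names
    shared by both tables (e.g. ``["year", "enrollment"]``); ``None``
    pools everything into one stratum.

    D_hat = n / (2 w L P_a), scaled to nests per 25 ha; the variance
    combines encounter-rate variation across transects with the
    delta-method variance of P_a.  The CI is log-normal with a
    Satterthwaite-t critical value (replicate lines contribute K-1
    degrees of freedom, the detection function n-k).
    """
    if "opportunistic" in detections.columns:
        detections = detections[~detections["opportunistic"]]
    detections = truncate(detections, model_res.w)
    eff = effort.copy()
    if "rounds" in eff.columns:
        eff["length_total"] = eff["length_m"] * eff["rounds"]
    else:
        eff["length_total"] = eff["length_m"]

    if strata:
        groups = [(tuple(k) if isinstance(k, tuple) else (k,), g)
                  for k, g in eff.groupby(strata)]
    else:
        groups = [(("all",), eff)]

    p_a = model_res.average_p
    cv2_p = _pa_cv2(model_res)
    df_p = max(model_res.n - model_res.k, 1)
    # re-detections of one nest on later rounds are clustered, not
    # independent draws from f(x); inflate the detection-function
    # variance by the mean cluster size (design effect)
    if "nest_id" in detections.columns:
        n_unique = detections["nest_id"].nunique()
        if n_unique:
            cv2_p *= len(detections) / n_unique
    out = []
    for keyvals, eff_g in groups:
        label = "/".join(str(v) for v in keyvals)
        if strata:
            mask = np.ones(len(detections), dtype=bool)
            for col, val in zip(strata, keyvals):
                mask &= (detections[col] == val).to_numpy()
            det_g = detections[mask]
        else:
            det_g = detections
        n = len(det_g)
        if n < 2:
            warnings.warn(f"stratum {label}: fewer than 2 detections; "
                          "skipped", stacklevel=2)
            continue
        # per-transect counts aligned with per-transect effort
        unit_cols = [c for c in ("plot_id", "transect_id")
                     if c in eff_g.columns]
        eff_units = eff_g.groupby(unit_cols)["length_total"].sum()
        cnt = det_g.groupby(unit_cols).size() if unit_cols else None
        counts = np.array([cnt.get(idx, 0) if cnt is not None else n
                           for idx in eff_units.index], dtype=float)
        lengths = eff_units.to_numpy(dtype=float)
        L = float(lengths.sum())
        if L <= 0:
            raise ValueError(f"stratum {label}: no positive effort")

        d_per_m2 = n / (2.0 * model_res.w * L * p_a)
        density = d_per_m2 * PLOT_AREA_M2
        cv2_er, df_er = _encounter_rate_cv2(counts, lengths)
        cv2 = cv2_er + cv2_p
        se = density * math.sqrt(cv2)
        if cv2 > 0:
            # Satterthwaite df pooled over the two variance components
            denom = cv2_er ** 2 / df_er + cv2_p ** 2 / df_p
            df = cv2 ** 2 / denom if denom > 0 else df_p
            crit = t_dist.ppf(1 - alpha / 2, df)
            c = math.exp(crit * math.sqrt(math.log1p(cv2)))
            ci_low, ci_high = density / c, density * c
        else:
            ci_low = ci_high = density
        out.append(DensityEstimate(
            stratum=label, n=n, effort_m=L, density=density, se=se,
            ci_low=ci_low, ci_high=ci_high, p_a=p_a))
    if not out:
        raise EmptyStratumError("no stratum had >= 2 detections")
    return out


def density_table(estimates: list[DensityEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in estimates])
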