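"""Hierarchical multispecies dependent double-observer abundance model.

In a dependent double-observer (DDO) survey the primary observer calls
out every bird seen and the secondary observer records those plus any
the primary missed.  With latent plot abundance ``N ~ Poisson(lambda)``
and per-observer detection probabilities ``p1`` (primary) and ``p2``
(secondary), Poisson thinning marginalizes N exactly:

    x1 ~ Poisson(lambda * p1)
    x2 ~ Poisson(lambda * (1 - p1) * p2),   independent.

The hierarchical model places
``log lambda = alpha_species + beta_enroll * SGI + beta_year + eps_plot``
with ``eps_plot ~ Normal(0, sigma_plot^2)``, and
``logit p = observer + species + year`` effects.  Priors are vague
Normal(0, 1000) on every linear-predictor coefficient and Uniform(0,
100) on ``sigma_plot``.  Inference is adaptive random-walk Metropolis
within Gibbs on the marginal likelihood; proposal scales adapt toward
0.3 acceptance during burn-in only and are frozen afterwards.
Convergence is summarized with split-Rhat and effective sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "ddo_loglik", "moment_detection_estimate",
    "DependentDoubleObserverModel", "DDOResults", "diagnose",
]

_COEF_PRIOR_VAR = 1000.0
_SIGMA_UPPER = 100.0


def ddo_loglik(x1, x2, lam, p1, p2) -> float:
    """Joint log-probability of DDO tallies with latent N integrated out.

    Accepts scalars or aligned arrays; returns the summed log-likelihood
    of ``x1 ~ Poisson(lam*p1)`` and ``x2 ~ Poisson(lam*(1-p1)*p2)``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0) or \
            np.any(x1 != np.floor(x1)) or np.any(x2 != np.floor(x2)):
        raise ValueError("counts must be non-negative integers")
    lam = np.asarray(lam, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(lam < 0) or np.any((p1 <= 0) | (p1 > 1)) or \
            np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("require lam >= 0 and p1, p2 in (0, 1]")
    mu1 = lam * p1
    mu2 = lam * (1.0 - p1) * p2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll1 = np.where(x1 > 0, x1 * np.log(mu1), 0.0) - mu1 \
            - gammaln(x1 + 1.0)
        ll2 = np.where(x2 > 0, x2 * np.log(mu2), 0.0) - mu2 \
            - gammaln(x2 + 1.0)
    total = np.sum(ll1 + ll2)
    return float(total) if np.isfinite(total) else -np.inf


def moment_detection_estimate(counts: pd.DataFrame) -> float:
    """Method-of-moments detection probability under shared p.

    Pooled over all cells, E[x2]/E[x1] = 1 - p, so p_hat = 1 - sum(x2) /
    sum(x1).  Used as MCMC initialization and a sanity cross-check.
    """
    s1 = float(counts["x1"].sum())
    s2 = float(counts["x2"].sum())
    if s1 <= 0:
        raise ValueError("no primary detections; p not estimable")
    p = 1.0 - s2 / s1
    if p <= 0:
        warnings.warn("sum(x2) >= sum(x1); detection estimate floored at "
                      "0.05", stacklevel=2)
        return 0.05
    return p


# ---------------------------------------------------------------------------

class DependentDoubleObserverModel:
    """DDO abundance model over per-visit count records.

    Parameters
    ----------
    counts : DataFrame with columns plot_id, year, visit, species,
        observer_primary, observer_secondary, x1, x2.
    plots : optional DataFrame with plot_id, year, enrollment used to
        attach the SGI covariate; an ``enrollment`` column already on
        ``counts`` also works.

    Repeat visits are conditionally independent replicate observations
    of a shared plot-year ``lambda`` (closed season).
    """

    def __init__(self, counts: pd.DataFrame,
                 plots: pd.DataFrame | None = None):
        counts = counts.copy()
        if plots is not None and "enrollment" not in counts.columns:
            counts = counts.merge(
                plots[["plot_id", "year", "enrollment"]].drop_duplicates(),
                on=["plot_id", "year"], how="left")
        if "enrollment" not in counts.columns:
            counts["enrollment"] = "non-SGI"
        if counts[["x1", "x2"]].lt(0).any().any():
            raise ValueError("negative counts")
        self.counts = counts.reset_index(drop=True)

        c = self.counts
        self.species = sorted(c["species"].unique())
        self.years = sorted(c["year"].unique())
        self.observers = sorted(set(c["observer_primary"])
                                | set(c["observer_secondary"]))
        self.plot_ids = sorted(c["plot_id"].unique())

        self._sp = np.searchsorted(self.species, c["species"])
        self._yr = np.searchsorted(self.years, c["year"])
        self._pl = np.searchsorted(self.plot_ids, c["plot_id"])
        self._o1 = np.searchsorted(self.observers, c["observer_primary"])
        self._o2 = np.searchsorted(self.observers, c["observer_secondary"])
        self._sgi = (c["enrollment"] == "SGI").to_numpy(float)
        self._x1 = c["x1"].to_numpy(float)
        self._x2 = c["x2"].to_numpy(float)
        self._lgam = gammaln(self._x1 + 1.0) + gammaln(self._x2 + 1.0)

        self.n_species = len(self.species)
        self.n_years = len(self.years)
        self.n_obs = len(self.observers)
        self.n_plots = len(self.plot_ids)
        self._has_sgi = self._sgi.std() > 0

        # parameter layout: abundance then detection
        self.coef_names = [f"alpha[{s}]" for s in self.species]
        if self._has_sgi:
            self.coef_names.append("beta_sgi")
        self.coef_names += [f"beta_year[{y}]" for y in self.years[1:]]
        self.coef_names += [f"gamma_obs[{o}]" for o in self.observers]
        self.coef_names += [f"delta_sp[{s}]" for s in self.species[1:]]
        self.coef_names += [f"zeta_year[{y}]" for y in self.years[1:]]

    # -- state -> cell rates -------------------------------------------------
    def _rates(self, coefs: np.ndarray, eps: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = 0
        alpha = coefs[i:i + self.n_species]; i += self.n_species
        beta_sgi = coefs[i] if self._has_sgi else 0.0
        i += int(self._has_sgi)
        byear = np.concatenate([[0.0], coefs[i:i + self.n_years - 1]])
        i += self.n_years - 1
        gamma = coefs[i:i + self.n_obs]; i += self.n_obs
        dsp = np.concatenate([[0.0], coefs[i:i + self.n_species - 1]])
        i += self.n_species - 1
        zyear = np.concatenate([[0.0], coefs[i:i + self.n_years - 1]])

        log_lam = (alpha[self._sp] + beta_sgi * self._sgi
                   + byear[self._yr] + eps[self._pl])
        lam = np.exp(np.clip(log_lam, -30, 30))
        p1 = expit(gamma[self._o1] + dsp[self._sp] + zyear[self._yr])
        p2 = expit(gamma[self._o2] + dsp[self._sp] + zyear[self._yr])
        return lam, p1, p2

    def _cell_loglik(self, coefs, eps) -> np.ndarray:
        lam, p1, p2 = self._rates(coefs, eps)
        mu1 = lam * p1
        mu2 = lam * (1.0 - p1) * p2
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (np.where(self._x1 > 0, self._x1 * np.log(mu1), 0.0) - mu1
                  + np.where(self._x2 > 0, self._x2 * np.log(mu2), 0.0)
                  - mu2 - self._lgam)
        return np.where(np.isfinite(ll), ll, -1e12)

    def loglike(self, coefs, eps) -> float:
        return float(np.sum(self._cell_loglik(coefs, eps)))

    def _log_prior_coefs(self, coefs) -> float:
        return float(-0.5 * np.sum(coefs ** 2) / _COEF_PRIOR_VAR)

    # -- sampler -------------------------------------------------------------
    def fit(self, chains: int = 3, iterations: int = 10000,
            burn_in: int = 1000, seed: int = 0,
            prior_only: bool = False) -> "DDOResults":
        """Run the adaptive Metropolis-within-Gibbs sampler.

        Returns a :class:`DDOResults` holding post-burn-in draws of
        every coefficient, the plot effects, ``sigma_plot``, and the
        acceptance-rate log.  ``prior_only`` drops the data term so the
        sampler targets the prior — a correctness check (the
        ``sigma_plot`` marginal must come back Uniform(0, 100)).
        """
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        cell_loglik = ((lambda c, e: np.zeros(len(self._x1)))
                       if prior_only else self._cell_loglik)
        n_coef = len(self.coef_names)
        kept = iterations - burn_in
        draws_coef = np.empty((chains, kept, n_coef))
        draws_eps = np.empty((chains, kept, self.n_plots))
        draws_sigma = np.empty((chains, kept))
        accept_log = []

        p0 = moment_detection_estimate(self.counts) \
            if self.counts["x1"].sum() > 0 else 0.5
        if self.counts["x1"].sum() == 0:
            warnings.warn("all counts zero for at least one species: "
                          "posterior will be prior-dominated", stacklevel=2)

        for ch in range(chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed).spawn(chains)[ch])
            coefs = np.zeros(n_coef)
            # initialize abundance intercepts at the naive corrected rate
            pooled = self.counts.groupby("species")[["x1", "x2"]].sum()
            p_tot = 1.0 - (1.0 - p0) * (1.0 - p0)
            for s_i, s in enumerate(self.species):
                tot = pooled.loc[s, "x1"] + pooled.loc[s, "x2"]
                n_cells = (self._sp == s_i).sum()
                mean_count = tot / max(n_cells, 1)
                coefs[s_i] = math.log(max(mean_count / p_tot, 0.1))
            logit_p0 = math.log(p0 / (1 - p0)) if 0 < p0 < 1 else 0.0
            off = self.n_species + int(self._has_sgi) + self.n_years - 1
            coefs[off:off + self.n_obs] = logit_p0 + \
                rng.normal(0, 0.05, self.n_obs)
            eps = rng.normal(0.0, 0.1, self.n_plots)
            sigma = 0.5

            step_coef = np.full(n_coef, 0.1)
            step_eps = np.full(self.n_plots, 0.2)
            step_sigma = 0.2
            acc_coef = np.zeros(n_coef)
            acc_eps = np.zeros(self.n_plots)
            acc_sigma = 0.0
            window = 50

            cell_ll = cell_loglik(coefs, eps)
            total_ll = float(cell_ll.sum())

            for it in range(iterations):
                # --- global coefficients, one at a time
                for j in range(n_coef):
                    prop = coefs.copy()
                    prop[j] += step_coef[j] * rng.standard_normal()
                    prop_cell = cell_loglik(prop, eps)
                    prop_ll = float(prop_cell.sum())
                    logr = (prop_ll - total_ll
                            + self._log_prior_coefs(prop)
                            - self._log_prior_coefs(coefs))
                    if math.log(rng.random() + 1e-300) < logr:
                        coefs, cell_ll, total_ll = prop, prop_cell, prop_ll
                        acc_coef[j] += 1

                # --- plot effects, vectorized independent updates
                prop_eps_delta = step_eps * rng.standard_normal(self.n_plots)
                prop_eps = eps + prop_eps_delta
                prop_cell = cell_loglik(coefs, prop_eps)
                cur_by_plot = np.zeros(self.n_plots)
                prop_by_plot = np.zeros(self.n_plots)
                np.add.at(cur_by_plot, self._pl, cell_ll)
                np.add.at(prop_by_plot, self._pl, prop_cell)
                logr = (prop_by_plot - cur_by_plot
                        + (eps ** 2 - prop_eps ** 2) / (2 * sigma ** 2))
                take = np.log(rng.random(self.n_plots) + 1e-300) < logr
                eps = np.where(take, prop_eps, eps)
                acc_eps += take
                cell_ll = cell_loglik(coefs, eps)
                total_ll = float(cell_ll.sum())

                # --- sigma_plot (uniform prior on [0, 100])
                prop_sigma = sigma + step_sigma * rng.standard_normal()
                if 0.0 < prop_sigma < _SIGMA_UPPER:
                    cur = -self.n_plots * math.log(sigma) \
                        - np.sum(eps ** 2) / (2 * sigma ** 2)
                    new = -self.n_plots * math.log(prop_sigma) \
                        - np.sum(eps ** 2) / (2 * prop_sigma ** 2)
                    if math.log(rng.random() + 1e-300) < new - cur:
                        sigma = prop_sigma
                        acc_sigma += 1

                # --- adaptation during burn-in only
                if it < burn_in and (it + 1) % window == 0:
                    rate_c = acc_coef / window
                    step_coef *= np.exp(rate_c - 0.3)
                    rate_e = acc_eps / window
                    step_eps *= np.exp(rate_e - 0.3)
                    step_sigma *= math.exp(acc_sigma / window - 0.3)
                    acc_coef[:] = 0
                    acc_eps[:] = 0
                    acc_sigma = 0.0

                if it >= burn_in:
                    kidx = it - burn_in
                    draws_coef[ch, kidx] = coefs
                    draws_eps[ch, kidx] = eps
                    draws_sigma[ch, kidx] = sigma
            accept_log.append({
                "chain": ch,
                "coef_accept": float(np.mean(acc_coef)
                                     / max(iterations - burn_in, 1)),
                "eps_accept": float(np.mean(acc_eps)
                                    / max(iterations - burn_in, 1)),
                "sigma_accept": acc_sigma / max(iterations - burn_in, 1),
            })

        return DDOResults(model=self, draws_coef=draws_coef,
                          draws_eps=draws_eps, draws_sigma=draws_sigma,
                          accept_log=accept_log)


# ---------------------------------------------------------------------------

def diagnose(draws: dict[str, np.ndarray],
             rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Split-Rhat and effective sample size per monitored parameter.

    ``draws`` maps parameter name -> array of shape (chains, draws).
    Parameters with Rhat above the threshold are flagged; constant
    parameters get NaN diagnostics (reported, not hidden).  Rhat needs
    at least 2 chains; with one chain only ESS is reported.
    """
    import arviz as az
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            arr = arr[None, :]
        n_chains = arr.shape[0]
        if np.ptp(arr) == 0:
            rows.append({"parameter": name, "rhat": np.nan,
                         "ess": np.nan, "flagged": False,
                         "note": "constant"})
            continue
        ess = float(np.asarray(az.ess(arr)))
        rhat = float(np.asarray(az.rhat(arr))) if n_chains >= 2 else np.nan
        rows.append({"parameter": name, "rhat": rhat, "ess": ess,
                     "flagged": bool(rhat > rhat_threshold)
                     if np.isfinite(rhat) else False,
                     "note": ""})
    return pd.DataFrame(rows)


@dataclass
class DDOResults:
    """Posterior draws and summaries from the DDO abundance model."""

    model: DependentDoubleObserverModel
    draws_coef: np.ndarray          # (chains, draws, n_coef)
    draws_eps: np.ndarray           # (chains, draws, n_plots)
    draws_sigma: np.ndarray         # (chains, draws)
    accept_log: list

    # -- draw access ---------------------------------------------------------
    def coef_draws(self, name: str) -> np.ndarray:
        j = self.model.coef_names.index(name)
        return self.draws_coef[:, :, j]

    def as_dict(self, include_eps: bool = False) -> dict[str, np.ndarray]:
        out = {name: self.draws_coef[:, :, j]
               for j, name in enumerate(self.model.coef_names)}
        out["sigma_plot"] = self.draws_sigma
        if include_eps:
            for k, pid in enumerate(self.model.plot_ids):
                out[f"eps[{pid}]"] = self.draws_eps[:, :, k]
        return out

    def diagnostics(self, include_eps: bool = True) -> pd.DataFrame:
        return diagnose(self.as_dict(include_eps=include_eps))

    # -- derived quantities ---------------------------------------------------
    def lambda_draws(self, plot_id, year, species) -> np.ndarray:
        """Posterior draws of expected abundance for one plot-year-species."""
        m = self.model
        flat_coef = self.draws_coef.reshape(-1, self.draws_coef.shape[-1])
        flat_eps = self.draws_eps.reshape(-1, self.draws_eps.shape[-1])
        s = m.species.index(species)
        k = m.plot_ids.index(plot_id)
        y = m.years.index(year)
        i = 0
        alpha = flat_coef[:, i + s]; i += m.n_species
        beta_sgi = flat_coef[:, i] if m._has_sgi else 0.0
        i += int(m._has_sgi)
        byear = 0.0 if y == 0 else flat_coef[:, i + y - 1]
        sgi = 0.0
        sel = (m.counts["plot_id"] == plot_id) & (m.counts["year"] == year)
        if sel.any():
            sgi = float(m.counts.loc[sel, "enrollment"].iloc[0] == "SGI")
        log_lam = alpha + (beta_sgi * sgi if m._has_sgi else 0.0) \
            + byear + flat_eps[:, k]
        return np.exp(log_lam)

    def detection_draws(self, species) -> np.ndarray:
        """Posterior draws of mean detection probability for a species,
        averaged over observers and years present in the data."""
        m = self.model
        flat = self.draws_coef.reshape(-1, self.draws_coef.shape[-1])
        s = m.species.index(species)
        i = m.n_species + int(m._has_sgi) + m.n_years - 1
        gamma = flat[:, i:i + m.n_obs]; i += m.n_obs
        dsp = 0.0 if s == 0 else flat[:, i + s - 1]
        i += m.n_species - 1
        zyears = np.concatenate(
            [np.zeros((flat.shape[0], 1)),
             flat[:, i:i + m.n_years - 1]], axis=1)
        # average p over observer x year cells
        ps = [expit(gamma[:, o] + dsp + zyears[:, y])
              for o in range(m.n_obs) for y in range(m.n_years)]
        return np.mean(ps, axis=0)

    def pair_density(self, ci: float = 0.95) -> pd.DataFrame:
        """Adult pair density per plot-year-species (pairs per 25 ha).

        Two same-species adults equal one pair, so pair density is
        lambda / 2, summarized by posterior mean, median and credible
        interval.
        """
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        m = self.model
        combos = m.counts[["plot_id", "year", "species"]].drop_duplicates()
        rows = []
        for r in combos.itertuples(index=False):
            lam = self.lambda_draws(r.plot_id, r.year, r.species)
            pairs = lam / 2.0
            rows.append({
                "plot_id": r.plot_id, "year": r.year, "species": r.species,
                "pair_density": float(np.mean(pairs)),
                "pair_density_median": float(np.median(pairs)),
                "ci_low": float(np.quantile(pairs, lo)),
                "ci_high": float(np.quantile(pairs, hi)),
                "lambda_mean": float(np.mean(lam)),
                "lambda_ci_low": float(np.quantile(lam, lo)),
                "lambda_ci_high": float(np.quantile(lam, hi)),
            })
        return pd.DataFrame(rows)

    def detection_summary(self, ci: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        rows = []
        for s in self.model.species:
            d = self.detection_draws(s)
            rows.append({"species": s, "p_mean": float(np.mean(d)),
                         "ci_low": float(np.quantile(d, lo)),
                         "ci_high": float(np.quantile(d, hi))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Dependent double-observer abundance model",
                 f"  {self.draws_coef.shape[0]} chains x "
                 f"{self.draws_coef.shape[1]} kept draws, "
                 f"{len(self.model.coef_names)} coefficients, "
                 f"{self.model.n_plots} plot effects"]
        diag = self.diagnostics(include_eps=False)
        worst = diag["rhat"].max()
        lines.append(f"  max Rhat (coefficients) = {worst:.3f}")
        det = self.detection_summary()
        for r in det.itertuples(index=False):
            lines.append(f"  detection {r.species}: {r.p_mean:.3f} "
                         f"({r.ci_low:.3f}-{r.ci_high:.3f})")
        lines.append(f"  sigma_plot posterior mean = "
                     f"{float(np.mean(self.draws_sigma)):.3f}")
        return "\n".join(lines)
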