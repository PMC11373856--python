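"""Hierarchical Bayesian regression of per-unit measures on area structure.

The measure y of unit i in mouse j (a timescale in ms or a predictability
in [0, 1]) is modelled through its logarithm,

    log y_ij ~ Normal(mu_ij, eps)              (log-normal measure)
    log y_ij ~ SkewNormal(mu_ij, eps, alpha)   (skew-log-normal, timescales)

    mu_ij = theta_lognu * lognu_norm_i + theta_rf * rf_i + f_j(area_i)

with an area term that is specific to mouse j:

    cortical groups     f_j = log(theta_0,j + theta_hc,j * 1_hc(area_i))
    cortical hierarchy  f_j = log(theta_0,j + theta_hs,j * HS(area_i))

Per-mouse parameters theta_.,j are drawn from normal parent distributions
with hyper-mean mu_theta and hyper-sd sigma_theta.  Priors: standard normal
on the hyper-means and on theta_lognu, theta_rf, alpha; HalfCauchy(0, 1) on
the hyper-sds and HalfCauchy(0, 10) on eps.  Positivity of the log argument
is enforced by a log-barrier (posterior density zero outside), which keeps
the normal parent distributions of the per-mouse parameters intact.

Sampling uses an affine-invariant ensemble sampler (emcee); scale
parameters are sampled on the log scale with the Jacobian included.  Model
comparison uses PSIS-LOO expected log pointwise predictive density and
calibration is checked with LOO-PIT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import kstest, skewnorm

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: HalfCauchy scales: hyper-sds and the residual scale eps
BETA_SIGMA = 1.0
BETA_EPS = 10.0

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class ModelSpec:
    """Which area term and unit-level likelihood to use, plus sampler knobs.

    Convention: ``skew_lognormal`` for timescales (their log distribution is
    negatively skewed), ``lognormal`` for the predictability R_tot.
    """

    area_term: Literal["groups", "hierarchy"] = "hierarchy"
    likelihood: Literal["lognormal", "skew_lognormal"] = "lognormal"
    n_walkers: int = 50
    n_burn: int = 6000
    n_steps: int = 3000
    n_loo_draws: int = 1000
    seed: int = 0

    @staticmethod
    def for_measure(measure: str, area_term: str = "hierarchy", **kw) -> "ModelSpec":
        lik = "lognormal" if measure == "R_tot" else "skew_lognormal"
        return ModelSpec(area_term=area_term, likelihood=lik, **kw)


def build_design(units: pd.DataFrame) -> pd.DataFrame:
    """Cortical design table: covariates, mouse index, area predictors.

    ``units`` needs columns mouse_id, area, group, hierarchy_score,
    firing_rate_hz, rf_flag (thalamic units are dropped — the area models
    are cortical).  The hierarchy score is re-shifted so V1 sits at zero,
    log firing rate is centered and divided by two standard deviations (so
    its coefficient is comparable to the binary predictors), and 1_hc marks
    higher cortical areas.
    """
    required = {"mouse_id", "area", "group", "hierarchy_score", "firing_rate_hz", "rf_flag"}
    missing = required - set(units.columns)
    if missing:
        raise ValueError(f"units table missing columns: {sorted(missing)}")
    bad = set(units["group"]) - {"thalamus", "V1", "higher_cortical"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    d = units[units["group"] != "thalamus"].copy()
    if not len(d):
        raise ValueError("no cortical units in table")
    hs = d["hierarchy_score"].to_numpy(dtype=float)
    v1 = d["group"] == "V1"
    if v1.any():
        hs = hs - float(d.loc[v1, "hierarchy_score"].iloc[0])
    d["hs"] = hs
    d["hc"] = (d["group"] == "higher_cortical").astype(float)
    lognu = np.log(d["firing_rate_hz"].to_numpy(dtype=float))
    sd = lognu.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance in firing rates; lognu_norm set to 0")
        d["lognu_norm"] = 0.0
    else:
        d["lognu_norm"] = (lognu - lognu.mean()) / (2.0 * sd)
    mice = {m: j for j, m in enumerate(pd.unique(d["mouse_id"]))}
    d["mouse_index"] = d["mouse_id"].map(mice)
    d.attrs["mice"] = list(mice)
    return d


# -- log posterior ---------------------------------------------------------


class _Model:
    """Vectorized log posterior over walker ensembles."""

    def __init__(self, spec: ModelSpec, design: pd.DataFrame, log_y: np.ndarray):
        self.spec = spec
        self.skew = spec.likelihood == "skew_lognormal"
        self.J = int(design["mouse_index"].max()) + 1
        self.j_idx = design["mouse_index"].to_numpy(dtype=np.int64)
        self.x = design["hs" if spec.area_term == "hierarchy" else "hc"].to_numpy(dtype=float)
        self.lognu = design["lognu_norm"].to_numpy(dtype=float)
        self.rf = design["rf_flag"].to_numpy(dtype=float)
        self.ly = np.asarray(log_y, dtype=float)
        slope = "theta_hs" if spec.area_term == "hierarchy" else "theta_hc"
        self.names = (
            ["mu_theta0", f"mu_{slope}", "sigma_theta0", f"sigma_{slope}",
             "theta_lognu", "theta_rf", "epsilon"]
            + (["alpha"] if self.skew else [])
            + [f"theta0[{j}]" for j in range(self.J)]
            + [f"{slope}[{j}]" for j in range(self.J)]
        )
        #: indices of log-scale coordinates (hyper-sds, eps)
        self.log_scale = [2, 3, 6]
        self.i_alpha = 7 if self.skew else None
        self.i_theta0 = 7 + int(self.skew)
        self.ndim = len(self.names)
        if not self.skew:
            self._build_cell_stats()

    def _build_cell_stats(self):
        """Per-(mouse, area) sufficient statistics for the normal loglik.

        With log y_i ~ N(a_i + f_cell, eps), a_i = th_nu x1_i + th_rf x2_i,
        the residual sum of squares per cell is quadratic in (th_nu, th_rf)
        with coefficients that depend on the data only — the likelihood of
        8000 units collapses onto ~#mice x #areas cells.
        """
        key = self.j_idx.astype(np.float64) * 1e6 + self.x
        _, inv = np.unique(key, return_inverse=True)
        n_cells = inv.max() + 1

        def cell_sum(v):
            return np.bincount(inv, weights=v, minlength=n_cells)

        one = np.ones_like(self.ly)
        self.c_n = cell_sum(one)
        self.c_j = np.zeros(n_cells, dtype=np.int64)
        self.c_x = np.zeros(n_cells)
        self.c_j[inv] = self.j_idx  # constant within cell
        self.c_x[inv] = self.x
        self.c_Sl = cell_sum(self.ly)
        self.c_Sll = cell_sum(self.ly**2)
        self.c_S1 = cell_sum(self.lognu)
        self.c_S11 = cell_sum(self.lognu**2)
        self.c_S2 = cell_sum(self.rf)
        self.c_S22 = cell_sum(self.rf**2)
        self.c_Sl1 = cell_sum(self.ly * self.lognu)
        self.c_Sl2 = cell_sum(self.ly * self.rf)
        self.c_S12 = cell_sum(self.lognu * self.rf)

    # parameter vector layout (log-scale coords hold log sigma / log eps):
    # [mu_t0, mu_slope, log s_t0, log s_slope, th_lognu, th_rf, log eps,
    #  (alpha,) theta0_j x J (centered), z_slope_j x J (non-centered)]
    # The per-mouse slopes are weakly informed (5 area medians per mouse),
    # so they are sampled non-centered (slope_j = mu + sigma * z_j) to
    # avoid the funnel in sigma_slope; intercepts are data-dominated and
    # stay centered.

    def split(self, p: np.ndarray):
        p = np.atleast_2d(p)
        i0 = self.i_theta0
        mu_slope = p[:, 1]
        sigma_slope = np.exp(p[:, 3])
        z_slope = p[:, i0 + self.J : i0 + 2 * self.J]
        return {
            "mu_theta0": p[:, 0],
            "mu_slope": mu_slope,
            "sigma_theta0": np.exp(p[:, 2]),
            "sigma_slope": sigma_slope,
            "theta_lognu": p[:, 4],
            "theta_rf": p[:, 5],
            "epsilon": np.exp(p[:, 6]),
            "alpha": p[:, self.i_alpha] if self.skew else np.zeros(p.shape[0]),
            "theta0": p[:, i0 : i0 + self.J],
            "z_slope": z_slope,
            "slope": mu_slope[:, None] + sigma_slope[:, None] * z_slope,
        }

    def _mu(self, q) -> np.ndarray:
        """(W, n) log-mean and a validity mask per walker."""
        arg = q["theta0"][:, self.j_idx] + q["slope"][:, self.j_idx] * self.x[None, :]
        ok = np.all(arg > 0, axis=1)
        arg = np.where(arg > 0, arg, 1.0)
        mu = (
            q["theta_lognu"][:, None] * self.lognu[None, :]
            + q["theta_rf"][:, None] * self.rf[None, :]
            + np.log(arg)
        )
        return mu, ok

    def pointwise_loglik(self, p: np.ndarray) -> np.ndarray:
        """(W, n) log density of each observed log-measure."""
        q = self.split(p)
        mu, ok = self._mu(q)
        eps = q["epsilon"][:, None]
        z = (self.ly[None, :] - mu) / eps
        ll = -np.log(eps) - 0.5 * _LOG_2PI - 0.5 * z * z
        if self.skew:
            ll += np.log(2.0) + log_ndtr(q["alpha"][:, None] * z)
        ll[~ok] = -np.inf
        return ll

    def log_prob(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        q = self.split(p)
        lp = np.zeros(p.shape[0])
        # N(0,1) priors on hyper-means, covariate effects and alpha
        for key in ("mu_theta0", "mu_slope", "theta_lognu", "theta_rf"):
            lp -= 0.5 * q[key] ** 2
        if self.skew:
            lp -= 0.5 * q["alpha"] ** 2
        # HalfCauchy priors on scales, sampled as log(scale): the Jacobian
        # contributes +log(scale)
        for key, beta in (("sigma_theta0", BETA_SIGMA), ("sigma_slope", BETA_SIGMA),
                          ("epsilon", BETA_EPS)):
            s = q[key]
            lp += -np.log1p((s / beta) ** 2) + np.log(s)
        # normal parent distributions of the per-mouse parameters:
        # centered intercepts, non-centered slopes (z ~ N(0,1))
        z0 = (q["theta0"] - q["mu_theta0"][:, None]) / q["sigma_theta0"][:, None]
        lp += -0.5 * np.sum(z0 * z0, axis=1) - self.J * np.log(q["sigma_theta0"])
        lp += -0.5 * np.sum(q["z_slope"] ** 2, axis=1)
        if self.skew:
            ll = np.sum(self.pointwise_loglik(p), axis=1)
        else:
            ll = self._normal_loglik_cells(q)
        with np.errstate(invalid="ignore"):
            tot = lp + ll
        tot[~np.isfinite(tot)] = -np.inf
        return tot

    def _normal_loglik_cells(self, q) -> np.ndarray:
        """Total normal log-likelihood via per-cell sufficient statistics."""
        arg = q["theta0"][:, self.c_j] + q["slope"][:, self.c_j] * self.c_x[None, :]
        ok = np.all(arg > 0, axis=1)
        f = np.log(np.where(arg > 0, arg, 1.0))
        tn = q["theta_lognu"][:, None]
        tr = q["theta_rf"][:, None]
        S1c = self.c_Sl[None, :] - tn * self.c_S1[None, :] - tr * self.c_S2[None, :]
        S2c = (
            self.c_Sll[None, :]
            + tn**2 * self.c_S11[None, :]
            + tr**2 * self.c_S22[None, :]
            - 2 * tn * self.c_Sl1[None, :]
            - 2 * tr * self.c_Sl2[None, :]
            + 2 * tn * tr * self.c_S12[None, :]
        )
        rss = np.sum(S2c - 2 * f * S1c + self.c_n[None, :] * f * f, axis=1)
        n = self.ly.shape[0]
        eps = q["epsilon"]
        ll = -n * np.log(eps) - 0.5 * n * _LOG_2PI - rss / (2 * eps**2)
        ll[~ok] = -np.inf
        return ll

    def initial_guess(self, design: pd.DataFrame) -> np.ndarray:
        """Moment-based start: per-mouse OLS of exp(area-mean log y) on x."""
        d = design.copy()
        d["_ly"] = self.ly
        d["_x"] = self.x
        theta0 = np.full(self.J, np.nan)
        slope = np.zeros(self.J)
        resid_var = []
        for j, grp in d.groupby("mouse_index"):
            by_area = grp.groupby("_x")["_ly"].mean()
            med = np.exp(by_area.to_numpy())
            xs = by_area.index.to_numpy(dtype=float)
            if len(xs) > 1:
                b, a = np.polyfit(xs, med, 1)
            else:
                b, a = 0.0, med[0]
            theta0[j] = max(a, 0.05)
            slope[j] = b
            resid_var.append(grp["_ly"].var(ddof=0))
        # keep every mouse's smallest area argument positive
        for j in range(self.J):
            lo = theta0[j] + slope[j] * self.x.min()
            hi = theta0[j] + slope[j] * self.x.max()
            if min(lo, hi) <= 0:
                slope[j] *= 0.5 * theta0[j] / (abs(slope[j]) * max(abs(self.x).max(), 1e-9))
        eps = float(np.sqrt(np.nanmean(resid_var)))
        sig_slope = max(slope.std(), 0.02)
        z_slope = (slope - slope.mean()) / sig_slope
        p = np.concatenate(
            [
                [theta0.mean(), slope.mean(),
                 np.log(max(theta0.std(), 0.02)), np.log(sig_slope),
                 0.0, 0.0, np.log(max(eps, 0.05))],
                [0.0] if self.skew else [],
                theta0,
                z_slope,
            ]
        )
        return p


@dataclass
class PosteriorSummary:
    """Posterior draws plus sampler diagnostics for one fitted model."""

    spec: ModelSpec
    names: list
    draws: dict  # name -> (chain, draw) array, full sampled chain
    idata: az.InferenceData  # thinned, with log_likelihood (and mu/scale draws)
    diagnostics: dict
    model: "_Model" = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)
    log_y: np.ndarray = field(repr=False, default=None)

    @property
    def valid(self) -> bool:
        return bool(self.diagnostics.get("valid", False))

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.draws[name]))

    def hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo, hi = az.hdi(self.draws[name].reshape(-1), hdi_prob=prob)
        return float(lo), float(hi)


def _natural_scale(chain: np.ndarray, model: "_Model") -> np.ndarray:
    """Sampling coords -> reported values: exp scales, z -> actual slopes."""
    nat = chain.copy()
    for i in (2, 3, 6):
        nat[..., i] = np.exp(nat[..., i])
    i0 = model.i_theta0
    sl = slice(i0 + model.J, i0 + 2 * model.J)
    nat[..., sl] = nat[..., 1:2] + nat[..., 3:4] * chain[..., sl]
    return nat


def _sample_once(model: "_Model", spec: ModelSpec, p0, nw, seed):
    """One ensemble run; returns ((walkers, steps, ndim) chain, mean acc)."""
    rng = np.random.RandomState(seed)
    starts = p0[None, :] + 1e-2 * rng.randn(nw, model.ndim)
    lp = model.log_prob(starts)
    for i in np.flatnonzero(~np.isfinite(lp)):
        for _ in range(100):
            starts[i] = p0 + 1e-3 * rng.randn(model.ndim)
            if np.isfinite(model.log_prob(starts[i : i + 1])[0]):
                break
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nw, model.ndim, model.log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(starts, spec.n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, spec.n_steps, progress=False)
    chain = np.swapaxes(sampler.get_chain(), 0, 1)
    return chain, float(sampler.acceptance_fraction.mean())


def fit_model(
    spec: ModelSpec,
    design: pd.DataFrame,
    measures: Sequence[float],
) -> PosteriorSummary:
    """Sample the posterior of the hierarchical area model.

    ``measures`` are the positive per-unit values aligned with ``design``.
    Pointwise log-likelihoods of the thinned draws are retained for LOO.
    The fit is flagged invalid when max R-hat over reported parameters
    exceeds 1.01.
    """
    y = np.asarray(measures, dtype=float)
    if np.any(~(y > 0)):
        raise ValueError("measures must be positive")
    if len(y) != len(design):
        raise ValueError("measures and design are misaligned")
    model = _Model(spec, design, np.log(y))
    if spec.area_term == "groups" and design["hc"].nunique() < 2:
        raise ValueError("groups model needs both V1 and higher cortical units")
    if spec.area_term == "hierarchy" and design["hs"].nunique() < 2:
        raise ValueError("hierarchy model needs at least two distinct areas")

    p0 = model.initial_guess(design)
    nw = max(spec.n_walkers, 2 * model.ndim + 2)
    nw += nw % 2

    # a run that fails to mix (R-hat far above the limit) is retried once
    # from a re-seeded walker cloud; the best-mixing run is kept
    best = None
    for attempt in range(2):
        chain, acc = _sample_once(
            model, spec, p0, nw, (spec.seed + attempt * 7919) % (2**32 - 1)
        )
        nat = _natural_scale(chain, model)
        draws = {name: nat[:, :, i] for i, name in enumerate(model.names)}
        post = az.from_dict(posterior=draws)
        rhat = az.rhat(post)
        rhat_max = float(max(rhat[v].values.max() for v in rhat.data_vars))
        if best is None or rhat_max < best[0]:
            ess = az.ess(post)
            ess_min = float(min(ess[v].values.min() for v in ess.data_vars))
            best = (rhat_max, chain, draws, ess_min, acc)
        if rhat_max <= 1.2:
            break
    rhat_max, chain, draws, ess_min, acc = best
    diagnostics = {
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "divergences": 0,
        "valid": rhat_max <= RHAT_LIMIT,
        "acceptance_fraction": acc,
    }
    if not diagnostics["valid"]:
        logger.warning("fit flagged invalid: max R-hat %.4f", rhat_max)

    # thin to ~n_loo_draws total for pointwise log-likelihood storage
    total = nw * spec.n_steps
    thin = max(1, int(np.ceil(total / spec.n_loo_draws)))
    flat = chain.reshape(-1, model.ndim)[::thin]
    ll = model.pointwise_loglik(flat)  # (draws, n)
    n_chains = 4
    per = ll.shape[0] // n_chains
    ll = ll[: n_chains * per].reshape(n_chains, per, -1)
    flat_used = flat[: n_chains * per]
    nat_flat = _natural_scale(flat_used[None], model)[0]
    post_thin = {
        name: nat_flat[:, i].reshape(n_chains, per) for i, name in enumerate(model.names)
    }
    idata = az.from_dict(
        posterior=post_thin,
        log_likelihood={"log_y": ll},
        observed_data={"log_y": model.ly},
    )
    return PosteriorSummary(
        spec=spec,
        names=model.names,
        draws=draws,
        idata=idata,
        diagnostics=diagnostics,
        model=model,
        design=design,
        log_y=model.ly,
    )


def summarize_posterior(fit: PosteriorSummary, params: Sequence[str] | None = None) -> pd.DataFrame:
    """Median and 95% highest-density interval per parameter."""
    params = list(params) if params is not None else list(fit.names)
    rows = []
    for name in params:
        d = fit.draws[name]
        hdi = az.hdi(az.from_dict(posterior={name: d}), hdi_prob=0.95)[name].values.ravel()
        rows.append(
            {"param": name, "median": float(np.median(d)),
             "hdi_2.5": float(hdi[0]), "hdi_97.5": float(hdi[1])}
        )
    return pd.DataFrame(rows, columns=["param", "median", "hdi_2.5", "hdi_97.5"])


def _pareto_k_frac(loo_res) -> float:
    k = np.asarray(loo_res.pareto_k)
    return float(np.mean(k > 0.7))


def compare_elpd(fit_groups: PosteriorSummary, fit_hierarchy: PosteriorSummary) -> dict:
    """PSIS-LOO ELPD difference (hierarchy minus groups) with its SE.

    Both fits must be on identical data.  The comparison is flagged
    unreliable when more than 5% of Pareto-k diagnostics exceed 0.7.
    """
    if len(fit_groups.log_y) != len(fit_hierarchy.log_y) or not np.allclose(
        fit_groups.log_y, fit_hierarchy.log_y
    ):
        raise ValueError("fits are not on identical data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo_g = az.loo(fit_groups.idata, pointwise=True)
        loo_h = az.loo(fit_hierarchy.idata, pointwise=True)
    diff_i = np.asarray(loo_h.loo_i) - np.asarray(loo_g.loo_i)
    n = len(diff_i)
    se = float(np.sqrt(n * np.var(diff_i, ddof=1)))
    k_frac = max(_pareto_k_frac(loo_g), _pareto_k_frac(loo_h))
    return {
        "elpd_groups": float(loo_g.elpd_loo),
        "elpd_hierarchy": float(loo_h.elpd_loo),
        "elpd_diff": float(loo_h.elpd_loo - loo_g.elpd_loo),
        "se_diff": se,
        "preferred": "hierarchy" if loo_h.elpd_loo >= loo_g.elpd_loo else "groups",
        "pareto_k_frac_bad": k_frac,
        "reliable": k_frac <= 0.05,
    }


def loo_pit(fit: PosteriorSummary, seed: int = 0, n_envelope: int = 100) -> dict:
    """LOO-PIT calibration check against a uniform envelope.

    Computes Pr(y_model <= y_i | y^(-i)) per datum with PSIS-LOO weights,
    the Kolmogorov-Smirnov distance of the PITs to Uniform(0,1), and the KS
    distances of ``n_envelope`` simulated uniform samples of the same size.
    ``inside`` reports whether the observed distance lies within that
    envelope.  With a single datum no test is performed.
    """
    rng = np.random.default_rng(seed)
    idata = fit.idata
    ll = idata.log_likelihood["log_y"].values  # (chain, draw, n)
    c, d, n = ll.shape
    # posterior predictive draws of log y for each datum; the stored
    # posterior is on the natural scale, so assemble q directly
    model = fit.model
    post = idata.posterior
    flat = {name: post[name].values.reshape(-1) for name in fit.names}
    q = {
        "theta_lognu": flat["theta_lognu"],
        "theta_rf": flat["theta_rf"],
        "epsilon": flat["epsilon"],
        "alpha": flat["alpha"] if model.skew else np.zeros_like(flat["epsilon"]),
        "theta0": np.stack(
            [flat[f"theta0[{j}]"] for j in range(model.J)], axis=1
        ),
        "slope": np.stack(
            [flat[n] for n in fit.names[model.i_theta0 + model.J :]], axis=1
        ),
    }
    mu, _ = model._mu(q)
    eps = q["epsilon"][:, None]
    if model.skew:
        y_rep = skewnorm.rvs(
            q["alpha"][:, None], loc=mu, scale=eps, size=mu.shape, random_state=rng
        )
    else:
        y_rep = rng.normal(mu, eps)
    idata_pp = az.from_dict(
        posterior={k: np.asarray(v) for k, v in idata.posterior.items()},
        posterior_predictive={"log_y": y_rep.reshape(c, d, n)},
        log_likelihood={"log_y": ll},
        observed_data={"log_y": fit.log_y},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pit = np.asarray(az.loo_pit(idata_pp, y="log_y"))
    if n < 2:
        return {"pit": pit, "ks": np.nan, "envelope": None, "inside": None}
    ks = float(kstest(pit, "uniform").statistic)
    env = np.array(
        [kstest(rng.random(n), "uniform").statistic for _ in range(n_envelope)]
    )
    return {
        "pit": pit,
        "ks": ks,
        "envelope": env,
        "inside": bool(ks <= env.max()),
    }
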