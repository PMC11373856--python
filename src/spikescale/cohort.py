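"""Synthetic multi-mouse cohorts with known area effects.

Generates per-unit measures from the same generative structure the
hierarchical area model assumes: per-mouse parameter sets drawn from normal
parent distributions, a log-normal (or skew-log-normal) unit-level
likelihood, and a log-mean that combines normalized log firing rate, a
receptive-field predictor and an area term that is either linear in the
anatomical hierarchy score or a higher-cortical offset.  Used for
simulation-based parameter recovery of the Bayesian module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import skewnorm

#: Anatomical hierarchy scores of mouse visual cortical areas, shifted so
#: V1 = 0 (values follow the standard anatomical ordering of the mouse
#: visual pathway: V1 < LM < RL < AL < PM < AM).
CORTICAL_HS = {
    "V1": 0.0,
    "LM": 0.264,
    "RL": 0.298,
    "AL": 0.509,
    "PM": 0.684,
    "AM": 0.798,
}

#: default 5-area cohort used for parameter-recovery studies
DEFAULT_AREAS = {k: CORTICAL_HS[k] for k in ("V1", "LM", "AL", "PM", "AM")}


@dataclass(frozen=True)
class CohortConfig:
    """Ground truth for a synthetic cohort.

    Hyper-parameters are the means/sds of the normal parent distributions
    the per-mouse parameters are drawn from.  ``area_term`` selects whether
    the slope multiplies the hierarchy score or a higher-cortical indicator.
    The intercept default (0.5) keeps theta_0 + slope * HS positive across
    slopes of either sign up to |slope| ~ 0.5 for the default areas.
    """

    n_mice: int = 8
    areas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AREAS))
    units_per_area: int = 200
    area_term: Literal["hierarchy", "groups"] = "hierarchy"
    mu_theta0: float = 0.5
    sigma_theta0: float = 0.05
    mu_slope: float = 0.3
    sigma_slope: float = 0.05
    theta_lognu: float = 0.1
    theta_rf: float = 0.1
    epsilon: float = 0.5
    alpha: float = 0.0
    # nuisance covariate distributions
    rate_log_mean: float = float(np.log(3.5))  # median unit rate 3.5 Hz
    rate_log_sd: float = 1.0
    rf_prob: float = 0.7

    def __post_init__(self):
        if self.n_mice < 1 or self.units_per_area < 1:
            raise ValueError("cohort must contain mice and units")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def generate_bayes_cohort(cfg: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort table ready for the hierarchical area model.

    Columns: unit_id, mouse_id, area, group, hierarchy_score,
    firing_rate_hz, rf_flag, measure.  The log measure of unit i in mouse j
    is Normal(mu_ij, epsilon) (or SkewNormal(mu_ij, epsilon, alpha)) with

        mu_ij = theta_lognu * lognu_norm_i + theta_rf * rf_i
                + log(theta_0,j + slope_j * x(area_i)),

    x = hierarchy score (``hierarchy``) or higher-cortical indicator
    (``groups``).  Raises if any mouse's area term argument is non-positive.
    """
    rng = np.random.default_rng(seed)
    theta0 = rng.normal(cfg.mu_theta0, cfg.sigma_theta0, cfg.n_mice)
    slope = rng.normal(cfg.mu_slope, cfg.sigma_slope, cfg.n_mice)

    areas = list(cfg.areas.items())
    rows = []
    for j in range(cfg.n_mice):
        for area, hs in areas:
            x = hs if cfg.area_term == "hierarchy" else float(area != "V1")
            arg = theta0[j] + slope[j] * x
            if arg <= 0:
                raise ValueError(
                    f"mouse {j}, area {area}: theta_0 + slope*x = {arg:.3g} <= 0"
                )
            n = cfg.units_per_area
            lognu = rng.normal(cfg.rate_log_mean, cfg.rate_log_sd, n)
            rf = (rng.random(n) < cfg.rf_prob).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "mouse_id": f"m{j}",
                        "mouse_index": j,
                        "area": area,
                        "group": "V1" if area == "V1" else "higher_cortical",
                        "hierarchy_score": hs,
                        "firing_rate_hz": np.exp(lognu),
                        "rf_flag": rf,
                        "_f_area": np.log(arg),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "unit_id", [f"u{i}" for i in range(len(table))])

    lognu = np.log(table["firing_rate_hz"].to_numpy())
    sd = lognu.std(ddof=0)
    lognu_norm = (lognu - lognu.mean()) / (2 * sd) if sd > 0 else np.zeros_like(lognu)
    mu = (
        cfg.theta_lognu * lognu_norm
        + cfg.theta_rf * table["rf_flag"].to_numpy()
        + table["_f_area"].to_numpy()
    )
    if cfg.alpha == 0.0:
        log_y = rng.normal(mu, cfg.epsilon)
    else:
        log_y = skewnorm.rvs(
            cfg.alpha, loc=mu, scale=cfg.epsilon, size=len(mu), random_state=rng
        )
    table["measure"] = np.exp(log_y)
    return table.drop(columns=["_f_area"])
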