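"""Habitat models: space use vs prey density, with per-shark random effects.

Two analyses link predator space use to the acoustic prey field:

* horizontal: pooled 2D UD value per 500-m analysis cell regressed on
  NASC per cell, with NASC entering in dB (``10 log10(NASC + 1)``) --
  an ordinary least-squares fit because the response pools all sharks;
* vertical: per-shark time-at-depth (TAD, seconds per 1-m bin) against
  mean in-buffer prey density per bin, as a Gaussian linear mixed model
  with a random intercept per shark to avoid pseudo-replication, fitted
  by maximum likelihood (not REML) so AIC comparison against the null
  ``TAD ~ 1 + (1|shark)`` is valid. TAD is a nonnegative duration, so
  the default response scale is ``log(TAD + 1 s)``; the raw scale is
  retained as an option.

Model support is summarised by Akaike weights
``w_m = exp(-Delta_m/2) / sum_k exp(-Delta_k/2)``, ``Delta = AIC - min AIC``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "GLMMFit",
    "ModelComparison",
    "fit_ud_nasc",
    "fit_tad_density",
    "compare_waic",
    "simulate_tad_density",
]


@dataclass
class GLMMFit:
    """Summary of one (mixed) linear model fit."""

    label: str
    slope: float
    slope_se: float
    slope_ci: tuple  # 95%
    intercept: float
    re_var: float  # random-intercept variance (0 for fixed-effects fits)
    resid_var: float
    variance_share: float  # re_var / (re_var + resid_var)
    r2: float  # marginal (fixed-effects) r^2
    aic: float
    llf: float
    n_obs: int
    n_groups: int
    response: str = "identity"

    def __post_init__(self):
        if not np.isfinite(self.aic):
            raise ValueError("AIC must be finite")


@dataclass
class ModelComparison:
    labels: list
    aic: np.ndarray
    weights: np.ndarray  # Akaike weights, sum to 1

    @property
    def preferred(self) -> str:
        return self.labels[int(np.argmax(self.weights))]


def fit_ud_nasc(ud_values, nasc, eps: float = 1.0) -> GLMMFit:
    """Regress pooled UD cell values on NASC (dB) per analysis cell.

    ``ud_values`` and ``nasc`` are aligned per-cell arrays; cells with
    a missing value on either side are dropped. NASC enters as
    ``10 log10(NASC + eps)``.
    """
    ud = np.asarray(ud_values, dtype=float)
    na = np.asarray(nasc, dtype=float)
    ok = np.isfinite(ud) & np.isfinite(na)
    ud, na = ud[ok], na[ok]
    if ud.size < 10:
        raise ValueError("need >= 10 cells with both UD and NASC")
    x = 10.0 * np.log10(na + eps)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: zero-variance predictor")
    res = sm.OLS(ud, sm.add_constant(x)).fit()
    ci = res.conf_int()
    return GLMMFit(
        label="ud ~ nasc_db",
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept=float(res.params[0]),
        re_var=0.0,
        resid_var=float(res.mse_resid),
        variance_share=0.0,
        r2=float(res.rsquared),
        aic=float(res.aic),
        llf=float(res.llf),
        n_obs=int(res.nobs),
        n_groups=1,
    )


def _mixedlm_fit(y, x, groups, label, response):
    exog = sm.add_constant(x)
    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    re_var = float(np.asarray(res.cov_re)[0, 0])
    resid = float(res.scale)
    llf = float(res.llf)
    fe_params = np.asarray(res.fe_params)
    bse_fe = np.asarray(res.bse_fe)
    if not np.isfinite(llf):
        # boundary case (group variance profiled to exactly 0): the model
        # collapses to OLS; evaluate the likelihood there
        ols = sm.OLS(y, exog).fit()
        llf = float(ols.llf)
        re_var = 0.0
        resid = float(ols.mse_resid)
        fe_params = np.asarray(ols.params)
        bse_fe = np.asarray(ols.bse)
    k = exog.shape[1] + 1 + 1  # fixed effects + RE variance + residual variance
    aic = 2.0 * k - 2.0 * llf
    slope = float(fe_params[1]) if exog.shape[1] > 1 else np.nan
    se = float(bse_fe[1]) if exog.shape[1] > 1 else np.nan
    zq = 1.959963984540054
    fitted_fe = exog @ fe_params
    var_fe = float(np.var(fitted_fe))
    r2_marg = var_fe / (var_fe + re_var + resid) if (var_fe + re_var + resid) > 0 else 0.0
    return GLMMFit(
        label=label,
        slope=slope,
        slope_se=se,
        slope_ci=(slope - zq * se, slope + zq * se) if np.isfinite(se) else (np.nan, np.nan),
        intercept=float(fe_params[0]),
        re_var=re_var,
        resid_var=resid,
        variance_share=re_var / (re_var + resid) if (re_var + resid) > 0 else 0.0,
        r2=r2_marg,
        aic=aic,
        llf=llf,
        n_obs=int(y.size),
        n_groups=int(pd.unique(groups).size),
        response=response,
    )


def fit_tad_density(
    data: pd.DataFrame,
    depth_range=None,
    response: str = "log1p",
    null: bool = False,
) -> GLMMFit:
    """Mixed model of shark TAD on in-buffer prey density per depth bin.

    ``data`` columns: ``shark_id``, ``depth_bin`` (lower edge, m),
    ``tad_s`` (seconds in bin), ``density`` (mean ind m^-3 in bin).
    ``depth_range=(lo, hi)`` restricts to bins with ``lo <= depth_bin <
    hi`` (the study contrasts the full column against 5-50 m).
    ``response='log1p'`` models log(TAD + 1 s); ``'raw'`` models TAD
    directly. ``null=True`` fits the intercept-plus-random-effect null
    on the same rows. A single-shark input falls back to a
    fixed-effects fit with a warning.
    """
    df = data.copy()
    if depth_range is not None:
        lo, hi = depth_range
        df = df[(df["depth_bin"] >= lo) & (df["depth_bin"] < hi)]
    df = df.dropna(subset=["tad_s", "density"])
    if len(df) < 20:
        raise ValueError("need >= 20 (shark, depth-bin) rows")
    if response == "log1p":
        y = np.log1p(df["tad_s"].to_numpy(dtype=float))
    elif response == "raw":
        y = df["tad_s"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")
    dens = df["density"].to_numpy(dtype=float)
    if not null and np.ptp(dens) == 0:
        raise ValueError("degenerate design: all densities equal")
    groups = df["shark_id"].to_numpy()
    label = "tad ~ 1" if null else "tad ~ density"
    label += " + (1|shark)"
    x = np.empty((len(df), 0)) if null else dens[:, None]

    n_sharks = pd.unique(groups).size
    if n_sharks < 2:
        warnings.warn("single shark: falling back to a fixed-effects fit")
        exog = sm.add_constant(x) if x.size else np.ones((y.size, 1))
        res = sm.OLS(y, exog).fit()
        ci = res.conf_int()
        has_slope = exog.shape[1] > 1
        return GLMMFit(
            label=label + " [fixed-effects fallback]",
            slope=float(res.params[1]) if has_slope else np.nan,
            slope_se=float(res.bse[1]) if has_slope else np.nan,
            slope_ci=tuple(ci[1]) if has_slope else (np.nan, np.nan),
            intercept=float(res.params[0]),
            re_var=0.0,
            resid_var=float(res.mse_resid),
            variance_share=0.0,
            r2=float(res.rsquared) if has_slope else 0.0,
            aic=float(res.aic),
            llf=float(res.llf),
            n_obs=int(res.nobs),
            n_groups=1,
            response=response,
        )
    return _mixedlm_fit(y, x, groups, label, response)


def compare_waic(fits) -> ModelComparison:
    """Akaike weights across models fitted to the same observations."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 fitted models")
    n = {f.n_obs for f in fits}
    if len(n) != 1:
        raise ValueError("models were fitted on differing row counts")
    aic = np.array([f.aic for f in fits], dtype=float)
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelComparison([f.label for f in fits], aic, w)


def simulate_tad_density(
    n_sharks: int = 10,
    n_bins: int = 50,
    beta0: float = 2.0,
    beta1: float = 0.5,
    sd_group: float = 1.0,
    sd_resid: float = 1.0,
    rng=None,
) -> pd.DataFrame:
    """Simulate the TAD-vs-density mixed-model generating process.

    ``y_ij = beta0 + b_i + beta1 * density_ij + e_ij`` with
    ``b_i ~ N(0, sd_group^2)`` per shark and standard-normal-scaled
    density covariates; the response is returned on the model scale in
    ``tad_s`` (use ``response='raw'`` when refitting).
    """
    rng = np.random.default_rng(rng)
    rows = []
    for i in range(n_sharks):
        b = rng.normal(0.0, sd_group)
        dens = rng.lognormal(0.0, 1.0, size=n_bins)
        dens = (dens - dens.mean()) / dens.std()
        y = beta0 + b + beta1 * dens + rng.normal(0.0, sd_resid, size=n_bins)
        for j in range(n_bins):
            rows.append((f"WS{i:02d}", float(j + 5), y[j], dens[j]))
    return pd.DataFrame(rows, columns=["shark_id", "depth_bin", "tad_s", "density"])
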