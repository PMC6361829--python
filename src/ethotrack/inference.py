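"""Two-choice preference models fitted across arenas, plants and trials.

For a behavior statistic with underlying zone means mu_A and mu_B and
observed per-arena values (y_A, y_B), the preference is expressed as

    pi_A = mu_A / (mu_A + mu_B),      logit(pi_A) = log(mu_A / mu_B),

so the estimate on the logit scale back-transforms directly to the ratio of
means between the two genotypes.  Two models are offered:

* **logit quasi-binomial GLMM** (default): the conditional distribution of
  y_A given m = y_A + y_B is treated as quasi-binomial with free dispersion
  phi — the values act as "trials" even when they are continuous amounts
  (durations in seconds), with phi absorbing the scale.  The model carries an
  intercept (the logit of pi_A) and crossed random effects for the plant
  providing the A leaf, the plant providing the B leaf, and the trial.  It is
  fitted by iterative re-weighted REML (IRREML): at each step the working
  response z = eta + (p - pi) / (pi (1 - pi)) with weights w = m pi (1 - pi)
  is fitted as a weighted linear mixed model by REML, and eta is updated from
  the fixed estimate plus predicted random effects, until eta stabilizes.
  Unlike the log-ratio model, it handles zero observations (p = 0 or 1) as
  long as not all arenas are at the same boundary.

* **log-ratio LMM**: a linear mixed model of log(y_A / y_B) with normal
  errors and the same random effects; arenas with a zero on either side must
  be excluded (their count is reported).

Tests and confidence intervals use t statistics with Satterthwaite degrees
of freedom computed on the final weighted mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ethotrack.mixedlm import fit_weighted_lmm, satterthwaite_df

__all__ = [
    "ChoiceObservation",
    "ChoiceModelResult",
    "SeparationError",
    "ConvergenceError",
    "fit_logit_glmm",
    "fit_logratio_lmm",
    "analyze_all_statistics",
]

LN2 = np.log(2.0)


class SeparationError(ValueError):
    """All observations at p = 0 or p = 1: the logit estimate diverges."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass(frozen=True)
class ChoiceObservation:
    """Paired per-arena values of one statistic for the two leaf zones."""

    arena_id: str
    trial_id: str
    plant_a: str
    plant_b: str
    y_a: float
    y_b: float

    @property
    def m(self) -> float:
        return self.y_a + self.y_b


@dataclass
class ChoiceModelResult:
    """Estimate of logit(pi_A) with its back-transformed mean ratio."""

    estimate: float               # logit(pi_A) = log(mu_A / mu_B)
    se: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    phi: float
    variance_components: dict[str, float] = field(default_factory=dict)
    n_used: int = 0
    n_excluded: int = 0
    n_iter: int = 0
    converged: bool = True
    model: str = "logit"

    @property
    def ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def ratio_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def pi_a(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.estimate)))

    @property
    def log2_ratio(self) -> float:
        return float(self.estimate / LN2)

    @property
    def log10_p(self) -> float:
        return float(np.log10(max(self.p_value, 1e-300)))


def _as_obs(obs) -> list[ChoiceObservation]:
    out = []
    for o in obs:
        if isinstance(o, ChoiceObservation):
            out.append(o)
        else:  # mapping / namedtuple-style row
            out.append(ChoiceObservation(
                arena_id=str(o["arena_id"]), trial_id=str(o["trial_id"]),
                plant_a=str(o["plant_a"]), plant_b=str(o["plant_b"]),
                y_a=float(o["y_a"]), y_b=float(o["y_b"])))
    return out


def _indicator(labels) -> np.ndarray:
    levels = sorted(set(labels))
    idx = {l: j for j, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, l in enumerate(labels):
        Z[i, idx[l]] = 1.0
    return Z


def _random_effect_designs(obs, include_trial_effect, include_plant_effects):
    Z_list, names = [], []
    if include_plant_effects:
        Z_list.append(_indicator([o.plant_a for o in obs]))
        names.append("plant_a")
        Z_list.append(_indicator([o.plant_b for o in obs]))
        names.append("plant_b")
    if include_trial_effect:
        trials = [o.trial_id for o in obs]
        if len(set(trials)) > 1:
            Z_list.append(_indicator(trials))
            names.append("trial")
    return Z_list, names


def _t_inference(est, se, df):
    if se <= 0 or not np.isfinite(se):
        return 1.0 if est == 0 else 0.0, est, est
    tval = est / se
    p = 2.0 * sps.t.sf(abs(tval), df)
    half = sps.t.ppf(0.975, df) * se
    return float(p), est - half, est + half


def fit_logit_glmm(obs, include_trial_effect: bool = True,
                   include_plant_effects: bool = True,
                   max_iter: int = 100, tol: float = 1e-6,
                   phi_floor: float = 1e-8) -> ChoiceModelResult:
    """Fit logit(pi_A) by IRREML with plant and trial random effects.

    With ``include_plant_effects=False`` and ``include_trial_effect=False``
    (or variance components estimated at zero) the fit coincides with an
    ordinary quasi-binomial GLM of y_A on m with Pearson-based dispersion.
    """
    obs = _as_obs(obs)
    data = [o for o in obs if o.m > 0 and o.y_a >= 0 and o.y_b >= 0]
    n_excluded = len(obs) - len(data)
    if len(data) < 2:
        raise ValueError("need at least 2 observations with m > 0")
    m = np.array([o.m for o in data])
    p_obs = np.array([o.y_a / o.m for o in data])
    if np.all(p_obs == 0.0) or np.all(p_obs == 1.0):
        raise SeparationError(
            "all arenas at the same boundary (p = 0 or 1); "
            "logit(pi_A) is not estimable")

    Z_list, names = _random_effect_designs(
        data, include_trial_effect, include_plant_effects)
    n = len(data)
    X = np.ones((n, 1))

    # the linear predictor is bounded: under quasi-separation (an arena with
    # p = 0 or 1 and its own random-effect level) eta would otherwise drift
    # to +/- infinity by ~1 per iteration and never converge
    ETA_MAX = 12.0
    pooled = float(np.clip(m @ p_obs / m.sum(), 1e-6, 1 - 1e-6))
    eta = np.full(n, np.log(pooled / (1 - pooled)))
    trace = []
    fit = None
    for it in range(1, max_iter + 1):
        pi = 1.0 / (1.0 + np.exp(-eta))
        pi = np.clip(pi, 1e-10, 1 - 1e-10)
        var = pi * (1.0 - pi)
        z = eta + (p_obs - pi) / var
        w = m * var
        fit = fit_weighted_lmm(z, X, Z_list, weights=w, re_names=names,
                               gamma0=None if fit is None else fit.gamma)
        eta_new = np.clip(fit.fitted_eta, -ETA_MAX, ETA_MAX)
        delta = float(np.max(np.abs(eta_new - eta)))
        trace.append(delta)
        eta = eta_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"IRREML did not converge in {max_iter} iterations "
            f"(last |d eta| = {trace[-1]:.3g})", trace)

    phi = max(fit.phi, phi_floor)
    est = float(fit.beta[0])
    se = float(np.sqrt(fit.cov_beta[0, 0]))
    pi = 1.0 / (1.0 + np.exp(-eta))
    z = eta + (p_obs - pi) / (pi * (1 - pi))
    w = m * pi * (1 - pi)
    df = satterthwaite_df(fit, z, X, Z_list, weights=w)
    pval, lo, hi = _t_inference(est, se, df)
    return ChoiceModelResult(
        estimate=est, se=se, df=df, p_value=pval, ci_low=lo, ci_high=hi,
        phi=phi,
        variance_components=dict(zip(fit.re_names, fit.sigma2)),
        n_used=n, n_excluded=n_excluded, n_iter=it,
        converged=fit.converged, model="logit")


def fit_logratio_lmm(obs, include_trial_effect: bool = True,
                     include_plant_effects: bool = True) -> ChoiceModelResult:
    """Fit log(y_A / y_B) as a normal-errors linear mixed model.

    Zero observations on either side cannot enter the log ratio; they are
    excluded and counted in ``n_excluded`` (with a warning).
    """
    obs = _as_obs(obs)
    data = [o for o in obs if o.y_a > 0 and o.y_b > 0]
    n_excluded = len(obs) - len(data)
    if n_excluded:
        warnings.warn(f"log-ratio model: {n_excluded} observation(s) with a "
                      "zero value excluded")
    if len(data) < 2:
        raise ValueError("need at least 2 observations with y_A, y_B > 0")
    y = np.log([o.y_a / o.y_b for o in data])
    n = len(data)
    X = np.ones((n, 1))
    Z_list, names = _random_effect_designs(
        data, include_trial_effect, include_plant_effects)
    fit = fit_weighted_lmm(y, X, Z_list, re_names=names)
    est = float(fit.beta[0])
    se = float(np.sqrt(fit.cov_beta[0, 0]))
    if se <= 1e-12:
        warnings.warn("degenerate residual variance (identical ratios); "
                      "SE is 0")
    df = satterthwaite_df(fit, y, X, Z_list)
    pval, lo, hi = _t_inference(est, se, df)
    return ChoiceModelResult(
        estimate=est, se=se, df=df, p_value=pval, ci_low=lo, ci_high=hi,
        phi=fit.phi,
        variance_components=dict(zip(fit.re_names, fit.sigma2)),
        n_used=n, n_excluded=n_excluded, n_iter=1,
        converged=fit.converged, model="logratio")


def analyze_all_statistics(pairs: pd.DataFrame, model: str = "logit",
                           include_trial_effect: bool = True,
                           include_plant_effects: bool = True,
                           bh_adjust: bool = False) -> pd.DataFrame:
    """Fit the chosen model for every (statistic, bin) in a pairs table.

    ``pairs`` is the output of :func:`ethotrack.stats.choice_ratio_table`.
    Returns one row per statistic and bin with the estimate on the logit
    scale, the back-transformed ratio of means with its 95% CI, log10(p) and
    log2(ratio) columns, variance components and convergence diagnostics.
    Statistics whose observations are all unusable are skipped with a reason
    in the ``error`` column.
    """
    if model not in ("logit", "logratio"):
        raise ValueError("model must be 'logit' or 'logratio'")
    rows = []
    for (statistic, b), grp in pairs.groupby(["statistic", "bin"], sort=True):
        usable = grp.dropna(subset=["y_a", "y_b"])
        base = {"statistic": statistic, "bin": b, "n": len(usable),
                "error": ""}
        if len(usable) < 2 or (usable.y_a + usable.y_b <= 0).all():
            rows.append({**base, "error": "no usable observations"})
            continue
        obs = [ChoiceObservation(str(r.arena_id), str(r.trial_id),
                                 str(r.plant_a), str(r.plant_b),
                                 float(r.y_a), float(r.y_b))
               for r in usable.itertuples()]
        try:
            if model == "logit":
                res = fit_logit_glmm(
                    obs, include_trial_effect=include_trial_effect,
                    include_plant_effects=include_plant_effects)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = fit_logratio_lmm(
                        obs, include_trial_effect=include_trial_effect,
                        include_plant_effects=include_plant_effects)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append({**base, "error": str(exc)})
            continue
        vc = res.variance_components
        rows.append({
            **base, "n": res.n_used,
            "estimate_logit": res.estimate, "se": res.se, "df": res.df,
            "p": res.p_value, "log10_p": res.log10_p,
            "ratio": res.ratio,
            "ratio_lo95": res.ratio_ci[0], "ratio_hi95": res.ratio_ci[1],
            "log2_ratio": res.log2_ratio, "pi_a": res.pi_a,
            "var_plant_a": vc.get("plant_a", np.nan),
            "var_plant_b": vc.get("plant_b", np.nan),
            "var_trial": vc.get("trial", np.nan),
            "phi": res.phi, "n_excluded": res.n_excluded,
            "converged": res.converged,
        })
    out = pd.DataFrame(rows)
    if bh_adjust and "p" in out.columns:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.sum() == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps)
    ranked = ps[order] * ok.sum() / (np.arange(ok.sum()) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    q[ok] = out
    return q
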