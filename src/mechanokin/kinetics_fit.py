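"""Statistical estimation for force-dependent kinetics.

Covers the fits used to characterize the talin-vinculin system:

* weighted log-linear Bell-Evans fits of rate-vs-force data;
* the biphasic binding-rate fit r_B(F) = k_B(F) P_U(F) with the talin
  folding branch held fixed;
* dwell-time analysis in logarithmic time: with x = ln t an exponential
  distribution p(t) = exp(-t/t0)/t0 transforms to
  g(x) = exp(x - x0 - exp(x - x0)), x0 = ln t0, whose mode sits at x0 with
  g(x0) = 1/e, so each kinetic timescale shows up as a peak ("square-root
  histogram": counts are conventionally displayed on a sqrt axis);
* maximum-likelihood exponential-mixture fitting (1 vs 2 components chosen
  by BIC) on the raw dwells;
* the maturation-timescale fit of mean unbinding time vs. complex lifetime,
  T(t) = t_w + (t_m - t_w)(1 - exp(-t/tau)); and
* the simulated binding probability over a finite observation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import presets
from .core_model import (
    BellEvansParams,
    ForceSense,
    TalinFoldingParams,
    ThermalContext,
    unfolding_probability,
)
from .simulator import (
    BOUND_STATES,
    ForceProtocol,
    KineticScheme,
    simulate_scheme,
)

__all__ = [
    "BellEvansFit",
    "LogDwellHistogram",
    "MixtureFit",
    "MaturationFit",
    "fit_bell_evans",
    "fit_biphasic_binding",
    "sqrt_histogram",
    "fit_dwell_mixture",
    "fit_maturation",
    "fit_maturation_from_dwells",
    "binding_probability",
]


# --------------------------------------------------------------------------
# Bell-Evans fits
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BellEvansFit:
    params: BellEvansParams
    k0_se: float
    x_dagger_se: float
    kT_pN_nm: float
    residual_ss: float


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("points must be (force, rate[, se]) rows")
    f = arr[:, 0]
    r = arr[:, 1]
    se = arr[:, 2] if arr.shape[1] == 3 else np.full_like(r, np.nan)
    return f, r, se


def fit_bell_evans(
    points,
    sense: ForceSense = ForceSense.force_accelerated,
    therm: ThermalContext | None = None,
) -> BellEvansFit:
    """Weighted least squares of ln(rate) on force.

    ``points`` is an iterable of (force_pN, rate_per_s[, rate_se]) rows.  The
    slope times kT gives +/- x_dagger and the intercept ln k0; standard
    errors come from the weighted-least-squares covariance (delta method for
    the rate SEs: se_ln = se/rate).  With fewer than 3 distinct forces the
    fit is refused.
    """
    therm = therm or presets.DEFAULT_THERM
    sense = ForceSense(sense)
    f, r, se = _as_points(points)
    if np.unique(f).size < 3:
        raise ValueError("need rates at >= 3 distinct forces")
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    y = np.log(r)
    w = np.where(np.isfinite(se) & (se > 0), (r / se) ** 2, 1.0)

    X = np.column_stack([np.ones_like(f), f])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    rss = float(resid @ (w * resid))
    dof = max(len(f) - 2, 1)
    cov = np.linalg.inv(xtwx) * (rss / dof if len(f) > 2 else 1.0)

    intercept, slope = beta
    x_dagger = sense.sign * slope * therm.kT
    if x_dagger < 0:
        raise ValueError(
            "fitted slope has the wrong sign for the requested force sense"
        )
    params = BellEvansParams(math.exp(intercept), x_dagger, sense)
    return BellEvansFit(
        params=params,
        k0_se=math.exp(intercept) * math.sqrt(cov[0, 0]),
        x_dagger_se=therm.kT * math.sqrt(cov[1, 1]),
        kT_pN_nm=therm.kT,
        residual_ss=rss,
    )


def fit_biphasic_binding(
    points,
    talin: TalinFoldingParams,
    therm: ThermalContext | None = None,
) -> BellEvansFit:
    """Nonlinear fit of the biphasic binding rate with talin held fixed.

    Fits k0 and x_dagger of the force-suppressed binding branch in
    r_B(F) = k0 exp(-F x/kT) * P_U(F), with P_U computed from the supplied
    talin folding/unfolding laws.  Parameters are fitted on a log scale to
    enforce positivity.
    """
    therm = therm or presets.DEFAULT_THERM
    f, r, se = _as_points(points)
    if len(f) < 3:
        raise ValueError("need >= 3 points")
    p_u = np.array([unfolding_probability(talin, fi, therm) for fi in f])

    def model(force, ln_k0, x_dagger):
        return np.exp(ln_k0 - force * x_dagger / therm.kT) * p_u

    kwargs = {}
    if np.any(np.isfinite(se) & (se > 0)):
        kwargs["sigma"] = np.where(np.isfinite(se) & (se > 0), se, np.nanmedian(se))
        kwargs["absolute_sigma"] = False
    p0 = [math.log(max(r.max(), 1e-12) / max(p_u.max(), 1e-12)), 1.0]
    try:
        popt, pcov = curve_fit(model, f, r, p0=p0, maxfev=20000, **kwargs)
    except RuntimeError as err:
        raise RuntimeError(f"biphasic binding fit did not converge: {err}") from err
    ln_k0, x_dagger = popt
    resid = r - model(f, *popt)
    params = BellEvansParams(
        math.exp(ln_k0), max(x_dagger, 0.0), ForceSense.force_suppressed
    )
    return BellEvansFit(
        params=params,
        k0_se=math.exp(ln_k0) * math.sqrt(max(pcov[0, 0], 0.0)),
        x_dagger_se=math.sqrt(max(pcov[1, 1], 0.0)),
        kT_pN_nm=therm.kT,
        residual_ss=float(resid @ resid),
    )


# --------------------------------------------------------------------------
# Log-binned dwell histogram and exponential mixtures
# --------------------------------------------------------------------------


@dataclass
class LogDwellHistogram:
    """Histogram of x = ln(t/s) with uniform bins; counts kept for sqrt display."""

    bin_centers: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    bin_width: float
    n: int
    sqrt_display: bool = True


def _uncensored_dwells(dwells) -> np.ndarray:
    if isinstance(dwells, pd.DataFrame):
        mask = ~dwells["censored"].to_numpy(dtype=bool) if "censored" in dwells else np.ones(len(dwells), bool)
        t = dwells.loc[mask, "dwell_s"].to_numpy(dtype=float)
    else:
        t = np.asarray(dwells, dtype=float)
    if np.any(t <= 0):
        raise ValueError("dwell times must be positive")
    return t


def sqrt_histogram(dwells, bins_per_decade: int = 8) -> LogDwellHistogram:
    """Log-binned dwell-time histogram: uniform bins in x = ln t.

    The returned density is normalized over the binned support; the raw
    counts are retained because the conventional display plots sqrt(counts),
    which equalizes the visual noise across bins.
    """
    t = _uncensored_dwells(dwells)
    if t.size < 10:
        raise ValueError("need >= 10 uncensored dwells")
    x = np.log(t)
    width = math.log(10.0) / bins_per_decade
    # anchor the first edge at the data minimum so that rescaling all dwells
    # by c shifts every bin center by exactly ln c
    lo = float(x.min())
    nbins = max(int(math.ceil((x.max() - lo) / width)), 1)
    edges = lo + width * np.arange(nbins + 1)
    edges[-1] += 1e-12 * max(abs(edges[-1]), 1.0)  # include the max dwell
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LogDwellHistogram(centers, density, counts, width, int(t.size))


@dataclass
class MixtureFit:
    """Exponential-mixture MLE; peak positions in log-time are ln(timescale)."""

    k: int
    amplitudes: np.ndarray  # sum to 1, aligned with timescales
    timescales_s: np.ndarray  # ascending
    loglik: float
    bic: float
    bic_by_k: dict = field(default_factory=dict)
    collapsed: bool = False  # 2-component solution was degenerate

    @property
    def peak_positions(self) -> np.ndarray:
        return np.log(self.timescales_s)


def _em_exponential_mixture(t, k, rng, n_restarts=8, max_iter=2000, tol=1e-10):
    """EM for a k-component exponential mixture; returns (w, tau, loglik)."""
    n = t.size
    if k == 1:
        tau = float(t.mean())
        ll = float(np.sum(-np.log(tau) - t / tau))
        return np.array([1.0]), np.array([tau]), ll

    best = None
    qs = np.quantile(t, np.linspace(0.15, 0.85, k))
    for restart in range(n_restarts):
        if restart == 0:
            tau = qs.copy()
        else:
            tau = qs * rng.uniform(0.3, 3.0, size=k)
        tau = np.maximum(tau, 1e-12)
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        for _ in range(max_iter):
            log_comp = np.log(w)[None, :] - np.log(tau)[None, :] - t[:, None] / tau[None, :]
            m = log_comp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
            resp = np.exp(log_comp - lse[:, None])
            ll = float(lse.sum())
            if ll - ll_old < tol * max(abs(ll), 1.0):
                break
            ll_old = ll
            nk = resp.sum(axis=0)
            w = nk / n
            tau = (resp * t[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
            tau = np.maximum(tau, 1e-12)
        if best is None or ll > best[2]:
            best = (w, tau, ll)
    w, tau, ll = best
    order = np.argsort(tau)
    return w[order], tau[order], ll


def fit_dwell_mixture(
    dwells,
    k_max: int = 2,
    seed: int = 0,
    degeneracy_rtol: float = 0.05,
) -> MixtureFit:
    """MLE fit of 1- and 2-component exponential mixtures; BIC selects k.

    Fitting operates on the raw dwell times, never on binned data, so the
    result is independent of any histogram binning.  A 2-component optimum
    whose timescales agree within ``degeneracy_rtol`` is collapsed to a
    single component.
    """
    t = _uncensored_dwells(dwells)
    if t.size < 30:
        raise ValueError("need >= 30 uncensored dwells")
    rng = np.random.default_rng(seed)
    n = t.size

    fits = {}
    bics = {}
    for k in range(1, k_max + 1):
        w, tau, ll = _em_exponential_mixture(t, k, rng)
        n_params = 2 * k - 1
        bics[k] = n_params * math.log(n) - 2.0 * ll
        fits[k] = (w, tau, ll)
    k_best = min(bics, key=bics.get)
    w, tau, ll = fits[k_best]

    collapsed = False
    if k_best == 2 and abs(tau[1] / tau[0] - 1.0) < degeneracy_rtol:
        k_best, collapsed = 1, True
        w, tau, ll = fits[1]
    return MixtureFit(
        k=k_best,
        amplitudes=np.asarray(w),
        timescales_s=np.asarray(tau),
        loglik=ll,
        bic=bics[k_best],
        bic_by_k=bics,
        collapsed=collapsed,
    )


# --------------------------------------------------------------------------
# Maturation fit
# --------------------------------------------------------------------------


@dataclass
class MaturationFit:
    t_weak_s: float
    t_mature_s: float
    tau_maturation_s: float
    tau_se_s: float
    covariance: np.ndarray
    model: str = "exponential"


def fit_maturation(curve, model: str = "exponential") -> MaturationFit:
    """Fit mean unbinding time vs. complex lifetime.

    The default is the first-order relaxation implied by an irreversible
    weak -> mature step, T(t) = t_w + (t_m - t_w)(1 - exp(-t/tau)).  A
    phenomenological logistic in ln t is available as ``model="logistic"``
    for data that are merely "sigmoidal" on a log-lifetime axis.

    ``curve`` rows are (lifetime_s, mean_unbinding_time_s[, se]).
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (lifetime, mean unbinding time[, se]) points")
    t = arr[:, 0]
    T = arr[:, 1]
    se = arr[:, 2] if arr.shape[1] > 2 else None

    if model == "exponential":

        def f(t, t_w, t_m, tau):
            return t_w + (t_m - t_w) * (1.0 - np.exp(-t / tau))

    elif model == "logistic":

        def f(t, t_w, t_m, tau):
            return t_w + (t_m - t_w) / (1.0 + (tau / t))

    else:
        raise ValueError(f"unknown maturation model {model!r}")

    p0 = [max(T.min(), 1e-6), T.max(), float(np.median(t))]
    kwargs = {}
    if se is not None and np.all(np.isfinite(se)) and np.all(se > 0):
        kwargs = {"sigma": se, "absolute_sigma": False}
    try:
        popt, pcov = curve_fit(
            f, t, T, p0=p0, maxfev=20000,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]), **kwargs
        )
    except RuntimeError as err:
        raise RuntimeError(f"maturation fit did not converge: {err}") from err
    t_w, t_m, tau = popt
    if t_m <= t_w:
        raise RuntimeError(
            f"maturation fit degenerate: t_mature ({t_m:.3g}) <= t_weak ({t_w:.3g})"
        )
    return MaturationFit(
        t_weak_s=float(t_w),
        t_mature_s=float(t_m),
        tau_maturation_s=float(tau),
        tau_se_s=float(math.sqrt(max(pcov[2, 2], 0.0))),
        covariance=pcov,
        model=model,
    )


def fit_maturation_from_dwells(
    dwells: pd.DataFrame,
    model: str = "exponential",
    irls_iterations: int = 2,
) -> MaturationFit:
    """Maturation fit straight from a hold-and-probe dwell table.

    Groups the table by ``lifetime_s``, takes the mean unbinding time per
    lifetime, and fits the relaxation model with iteratively reweighted
    least squares: after an unweighted first pass, each mean is weighted by
    the model-implied variance of a single draw (two-mode exponential
    mixture at the fitted maturation fraction) over its replicate count.
    Model-based weights avoid the instability of empirical standard errors
    at modest replicate counts.
    """
    g = (
        dwells.groupby("lifetime_s")["dwell_s"]
        .agg(["mean", "count"])
        .reset_index()
    )
    fit = fit_maturation(g[["lifetime_s", "mean"]].to_numpy(), model=model)
    for _ in range(irls_iterations):
        p = 1.0 - np.exp(-g["lifetime_s"].to_numpy() / fit.tau_maturation_s)
        t_w, t_m = fit.t_weak_s, fit.t_mature_s
        mean = t_w * (1 - p) + t_m * p
        var = p * 2 * t_m**2 + (1 - p) * 2 * t_w**2 - mean**2
        se = np.sqrt(var / g["count"].to_numpy())
        fit = fit_maturation(
            np.column_stack([g["lifetime_s"], g["mean"], se]), model=model
        )
    return fit


# --------------------------------------------------------------------------
# Binding probability over a finite window
# --------------------------------------------------------------------------


def binding_probability(
    scheme: KineticScheme,
    force_pN: float,
    window_s: float,
    n_reps: int,
    seed: int,
    therm: ThermalContext | None = None,
    definition: str = "end",
    bound_states=BOUND_STATES,
    initial_state: str | None = None,
) -> tuple[float, float]:
    """Simulated probability of being bound, with binomial SE.

    ``definition="end"`` (default) scores replicates bound at the end of the
    window; ``definition="ever"`` scores replicates that visit a bound state
    at any point within the window.
    """
    if window_s <= 0 or n_reps <= 0:
        raise ValueError("window and n_reps must be positive")
    if definition not in ("end", "ever"):
        raise ValueError("definition must be 'end' or 'ever'")
    rng = np.random.default_rng(seed)
    protocol = ForceProtocol.constant(force_pN, window_s)
    bound_states = set(bound_states)
    hits = 0
    for _ in range(n_reps):
        traj = simulate_scheme(scheme, protocol, rng, initial_state=initial_state, therm=therm)
        if definition == "end":
            hits += traj.states[-1] in bound_states
        else:
            hits += any(s in bound_states for s in traj.states)
    p = hits / n_reps
    return p, math.sqrt(p * (1.0 - p) / n_reps)
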