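"""TCSPC decay histograms: reconvolution model and exponential-mixture fitting.

A time-correlated single-photon-counting (TCSPC) histogram records photon
arrival times after pulsed excitation.  The measured curve is the true
multi-exponential fluorescence decay

    I(t) = I0 + Σᵢ aᵢ exp(−t/τᵢ)

convolved with the instrument response function (IRF) and, at high
repetition rates (here 80 MHz, a 12.5 ns window), wrapped modulo the
repetition period: the tail of each excitation cycle folds into the start
of the next ("wrap-around").

The forward model here is exact for a piecewise-constant IRF: within each
bin the convolution of a constant IRF density with an exponential has a
closed form, chained by a first-order recursion, and the periodic wrap is
summed analytically as a geometric series.  Bin contents are the exact time
integrals of the modeled intensity over each bin, which is what a counting
detector accumulates.

Fitting maximizes the Poisson likelihood (via least squares on deviance
residuals) or minimizes Neyman-weighted least squares, with the lifetime
pair multi-started from log-spaced values to avoid local minima, and an IRF
time-shift nuisance parameter.  Model order (1 vs 2 components) is chosen
by requiring both a reduced-χ² improvement and a residual-runs rejection of
the single-exponential fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "DecayTrace",
    "DecayModel",
    "DecayFit",
    "ModelOrderDecision",
    "gaussian_irf",
    "reconvolve",
    "multi_exp_reconvolve",
    "fit_decay",
    "select_model_order",
    "read_decay_csv",
    "write_decay_csv",
]

IRF_FWHM_DEFAULT_NS = 0.19          # instrument temporal resolution ~190 ps
REP_PERIOD_DEFAULT_NS = 12.5        # 80 MHz excitation
N_BINS_DEFAULT = 4096               # ~3 ps/bin over the 12.5 ns window
MULTISTART_SEED_DEFAULT = 20190719


class DecayError(ValueError):
    """Invalid decay trace, model, or fitting input."""


# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class DecayTrace:
    """A binned photon-count histogram with its IRF and acquisition metadata.

    ``time_ns`` are uniform bin start times beginning at 0; ``counts`` are
    non-negative integers; ``irf`` is a non-negative same-grid curve whose
    integral is positive (normalized internally wherever it is used).
    """

    time_ns: np.ndarray
    counts: np.ndarray
    irf: np.ndarray
    rep_period_ns: float = REP_PERIOD_DEFAULT_NS
    excitation_nm: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ns, dtype=float)
        c = np.asarray(self.counts)
        irf = np.asarray(self.irf, dtype=float)
        object.__setattr__(self, "time_ns", t)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "irf", irf)
        if t.ndim != 1 or t.size < 4:
            raise DecayError("time grid must be 1-D with at least 4 bins")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12) or t[0] != 0:
            raise DecayError("time grid must be uniform and start at 0")
        if c.shape != t.shape or irf.shape != t.shape:
            raise DecayError("counts and irf must match the time grid")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise DecayError("counts must be non-negative integers")
        if np.any(irf < 0) or irf.sum() <= 0:
            raise DecayError("irf must be non-negative with positive integral")
        if t[-1] > self.rep_period_ns + 1e-9:
            raise DecayError("time grid exceeds the repetition period")

    @property
    def dt_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DecayModel:
    """Exponential-mixture decay: baseline I0 plus 1 or 2 components.

    Amplitudes are pre-exponential fractions normalized to Σaᵢ = 1 (the
    overall counts scale is carried separately, see :class:`DecayFit`);
    for two components the fast lifetime is listed first.
    """

    baseline: float
    components: tuple[tuple[float, float], ...]   # (amplitude, lifetime_ns)

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(tau)) for a, tau in self.components)
        if not 1 <= len(comps) <= 2:
            raise DecayError("1 or 2 decay components supported")
        if any(tau <= 0 for _, tau in comps) or any(a < 0 for a, _ in comps):
            raise DecayError("lifetimes must be > 0 and amplitudes >= 0")
        total = sum(a for a, _ in comps)
        if total > 0:
            comps = tuple((a / total, tau) for a, tau in comps)
        comps = tuple(sorted(comps, key=lambda c: c[1]))
        object.__setattr__(self, "components", comps)
        if self.baseline < 0:
            raise DecayError("baseline must be >= 0")

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(a for a, _ in self.components)

    @property
    def lifetimes_ns(self) -> tuple[float, ...]:
        return tuple(tau for _, tau in self.components)


@dataclass(frozen=True)
class DecayFit:
    """Result of an exponential-mixture fit to a TCSPC histogram."""

    model: DecayModel
    scale: float                    # total modeled signal counts above baseline
    irf_shift_ns: float
    reduced_chi2: float
    stderr: dict[str, Optional[float]]
    n_iterations: int
    converged: bool
    degenerate: bool
    objective: str
    method: str
    window: tuple[int, int]         # [start, stop) bin indices used in the fit
    cost: float

    def to_report(self) -> dict:
        return {
            "baseline": self.model.baseline,
            "components": [{"amplitude": a, "lifetime_ns": tau}
                           for a, tau in self.model.components],
            "scale": self.scale,
            "irf_shift_ns": self.irf_shift_ns,
            "reduced_chi2": self.reduced_chi2,
            "stderr": self.stderr,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "objective": self.objective,
            "method": self.method,
            "window": list(self.window),
        }


@dataclass(frozen=True)
class ModelOrderDecision:
    """Outcome of the 1-vs-2 component selection rule."""

    order: int
    fit1: DecayFit
    fit2: DecayFit
    delta_reduced_chi2: float
    runs_pvalue: float
    reason: str

    def to_report(self) -> dict:
        return {
            "order": self.order,
            "delta_reduced_chi2": self.delta_reduced_chi2,
            "runs_pvalue": self.runs_pvalue,
            "reason": self.reason,
            "fit1": self.fit1.to_report(),
            "fit2": self.fit2.to_report(),
        }


# ---------------------------------------------------------------------------
# Forward model


def gaussian_irf(time_ns: np.ndarray, fwhm_ns: float = IRF_FWHM_DEFAULT_NS,
                 center_ns: float = 0.8) -> np.ndarray:
    """Bin-integrated Gaussian IRF masses on a uniform bin-start grid."""
    t = np.asarray(time_ns, dtype=float)
    dt = t[1] - t[0]
    sigma = fwhm_ns / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    edges = np.append(t, t[-1] + dt)
    cdf = ndtr((edges - center_ns) / sigma)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise DecayError("IRF has no mass inside the time window")
    return mass / total


def _shift_irf(irf: np.ndarray, shift_ns: float, dt: float) -> np.ndarray:
    """Circularly shift IRF masses by a fractional number of bins."""
    if shift_ns == 0.0:
        return irf
    s = shift_ns / dt
    k = int(np.floor(s))
    f = s - k
    return (1.0 - f) * np.roll(irf, k) + f * np.roll(irf, k + 1)


def _exp_component_bins(tau: float, irf_mass: np.ndarray, dt: float,
                        rep_period: float) -> np.ndarray:
    """Exact per-bin integrals of a unit-amplitude wrapped exponential decay
    convolved with a piecewise-constant IRF of unit total mass.

    The linear part y(t) = ∫₀ᵗ c(s)e^{−(t−s)/τ} ds obeys
    y(t_{j+1}) = y(t_j)·e^{−Δt/τ} + c_j τ(1 − e^{−Δt/τ}) within bin j
    (c_j the IRF density); the contribution of all previous excitation
    cycles adds w·e^{−t/τ} with w the analytically summed geometric tail.
    Bin contents integrate the resulting intensity exactly.  The integrals
    sum to τ when the grid spans the full repetition period.
    """
    n = irf_mass.size
    c = irf_mass / dt
    decay = math.exp(-dt / tau)
    one_minus = -math.expm1(-dt / tau)
    b = c * tau * one_minus
    # y at bin edges t_1..t_n via the first-order recursion
    y_tail = lfilter([1.0], [1.0, -decay], b)
    y_edges = np.concatenate(([0.0], y_tail))            # y(t_0..t_n)
    t_grid = np.arange(n) * dt
    window = n * dt
    denom = -math.expm1(-rep_period / tau)
    w = y_edges[-1] * math.exp(-(rep_period - window) / tau) / denom
    level = y_edges[:-1] + w * np.exp(-t_grid / tau)     # intensity at bin starts
    # exact integral over each bin of (level − cτ)e^{−(t−t_j)/τ} + cτ
    return c * tau * dt + (level - c * tau) * tau * one_minus


def multi_exp_reconvolve(amplitudes: Sequence[float], lifetimes_ns: Sequence[float],
                         irf: np.ndarray, time_ns: np.ndarray,
                         rep_period_ns: float,
                         irf_shift_ns: float = 0.0) -> np.ndarray:
    """Per-bin expected signal for an arbitrary exponential mixture.

    Amplitudes may be negative (acceptor rise terms in cascade kinetics).
    The result integrates to Σᵢ aᵢτᵢ over a full repetition window for a
    unit-mass IRF and is *not* normalized.
    """
    t = np.asarray(time_ns, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if irf.shape != t.shape:
        raise DecayError("IRF must be on the same time grid as the model")
    dt = float(t[1] - t[0])
    mass = irf / irf.sum()
    mass = _shift_irf(mass, irf_shift_ns, dt)
    out = np.zeros_like(t)
    for a, tau in zip(amplitudes, lifetimes_ns):
        out += a * _exp_component_bins(float(tau), mass, dt, rep_period_ns)
    return out


def reconvolve(model: DecayModel, irf: np.ndarray, time_ns: np.ndarray,
               rep_period_ns: float = REP_PERIOD_DEFAULT_NS,
               scale: float = 1.0, irf_shift_ns: float = 0.0) -> np.ndarray:
    """Expected counts per bin: baseline + scale·(normalized wrapped signal).

    The signal shape is normalized so it sums to 1 over the window, making
    ``scale`` the total signal counts above baseline.
    """
    sig = multi_exp_reconvolve(model.amplitudes, model.lifetimes_ns, irf,
                               time_ns, rep_period_ns, irf_shift_ns)
    norm = sum(a * tau for a, tau in model.components)
    if norm <= 0:
        return np.full_like(np.asarray(time_ns, float), model.baseline)
    return model.baseline + scale * sig / norm


def _tail_model(model_params: dict, time_ns: np.ndarray, t0: float) -> np.ndarray:
    """Plain exponential mixture (no IRF), for tail fitting past the pulse."""
    out = np.zeros_like(time_ns)
    for a, tau in model_params["components"]:
        out += a * np.exp(-(time_ns - t0) / tau)
    norm = sum(a * tau for a, tau in model_params["components"])
    return model_params["baseline"] + model_params["scale"] * out / max(norm, 1e-300)


# ---------------------------------------------------------------------------
# Fitting


def _fit_window(counts: np.ndarray, threshold: float = 0.01) -> tuple[int, int]:
    """Fit window: from the first bin reaching ``threshold`` of the smoothed
    peak to the end of the trace."""
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    peak = smooth.max()
    if peak <= 0:
        return 0, counts.size
    start = int(np.argmax(smooth >= threshold * peak))
    return start, counts.size


def _estimate_baseline(counts: np.ndarray, start: int) -> float:
    """Baseline guess from pre-pulse bins (with a guard before the rise)."""
    guard = max(start - 10, 0)
    if guard >= 20:
        return float(np.median(counts[:guard]))
    return float(np.percentile(counts, 5))


def _tau_starts(n_components: int, n_starts: int,
                window_ns: float) -> list[tuple[float, ...]]:
    """Deterministic log-spaced lifetime starting points."""
    if n_components == 1:
        taus = np.geomspace(0.05, window_ns / 2.5, n_starts)
        return [(float(t),) for t in taus]
    fast = np.geomspace(0.05, 0.8, n_starts)
    slow = np.geomspace(0.5, 8.0, n_starts)
    return [(float(f), float(s)) for f, s in zip(fast, slow)]


def _residual(params: lmfit.Parameters, trace: DecayTrace, n_components: int,
              objective: str, method: str, window: tuple[int, int],
              tail_t0: float) -> np.ndarray:
    comps = [(params[f"a{i}"].value, params[f"tau{i}"].value)
             for i in range(n_components)]
    p = {"baseline": params["baseline"].value, "scale": params["scale"].value,
         "components": comps}
    if method == "reconvolution":
        sig = multi_exp_reconvolve([a for a, _ in comps], [t for _, t in comps],
                                   trace.irf, trace.time_ns, trace.rep_period_ns,
                                   irf_shift_ns=params["shift"].value)
        norm = max(sum(a * t for a, t in comps), 1e-300)
        model = p["baseline"] + p["scale"] * sig / norm
    else:
        model = _tail_model(p, trace.time_ns, tail_t0)
    lo, hi = window
    m = np.clip(model[lo:hi], 1e-12, None)
    c = trace.counts[lo:hi].astype(float)
    if objective == "poisson_mle":
        # deviance 2[m − c + c·ln(c/m)] written as 2c[x − ln(1+x)], x=(m−c)/c,
        # which stays accurate when c ≈ m at high counts
        x = (m - c) / np.maximum(c, 1.0)
        dev = np.where(c > 0, 2.0 * c * (x - np.log1p(x)), 2.0 * m)
        return np.sign(c - m) * np.sqrt(np.clip(dev, 0.0, None))
    return (c - m) / np.sqrt(np.maximum(c, 1.0))


def _pearson_reduced_chi2(trace: DecayTrace, params: lmfit.Parameters,
                          n_components: int, method: str,
                          window: tuple[int, int], tail_t0: float,
                          n_free: int) -> tuple[float, np.ndarray]:
    comps = [(params[f"a{i}"].value, params[f"tau{i}"].value)
             for i in range(n_components)]
    if method == "reconvolution":
        sig = multi_exp_reconvolve([a for a, _ in comps], [t for _, t in comps],
                                   trace.irf, trace.time_ns, trace.rep_period_ns,
                                   irf_shift_ns=params["shift"].value)
        norm = max(sum(a * t for a, t in comps), 1e-300)
        model = params["baseline"].value + params["scale"].value * sig / norm
    else:
        model = _tail_model({"baseline": params["baseline"].value,
                             "scale": params["scale"].value,
                             "components": comps}, trace.time_ns, tail_t0)
    lo, hi = window
    resid = trace.counts[lo:hi] - model[lo:hi]
    chi2 = float(np.sum(resid ** 2 / np.maximum(model[lo:hi], 1.0)))
    dof = max((hi - lo) - n_free, 1)
    return chi2 / dof, resid


def fit_decay(trace: DecayTrace, n_components: Literal[1, 2] = 1,
              objective: Literal["poisson_mle", "weighted_ls"] = "poisson_mle",
              method: Literal["reconvolution", "tail"] = "reconvolution",
              vary_shift: bool = True, max_shift_ns: float = 0.05,
              n_starts: int = 5,
              seed: int = MULTISTART_SEED_DEFAULT) -> DecayFit:
    """Fit a 1- or 2-exponential decay model to a TCSPC histogram.

    Reconvolution (default) fits the full wrapped IRF-convolved model with
    an IRF time-shift nuisance parameter bounded to ±``max_shift_ns``; tail
    fitting restricts to times past the pulse and ignores the IRF.  Five
    deterministic log-spaced lifetime starts guard against local minima;
    the best objective value wins.  Non-convergence and degenerate (no or
    single-component) signals are flagged, not raised.
    """
    if trace.total_counts <= 0:
        raise DecayError("trace has no counts")
    if n_components not in (1, 2):
        raise DecayError("n_components must be 1 or 2")

    window = _fit_window(trace.counts)
    if method == "tail":
        peak_idx = int(np.argmax(trace.counts))
        start = min(peak_idx + int(round(0.2 / trace.dt_ns)), trace.counts.size - 8)
        window = (start, trace.counts.size)
    tail_t0 = trace.time_ns[window[0]]

    baseline0 = _estimate_baseline(trace.counts, window[0])
    scale0 = max(trace.total_counts - baseline0 * trace.counts.size, 1.0)
    window_ns = float(trace.time_ns[-1] + trace.dt_ns)

    best = None
    for taus in _tau_starts(n_components, n_starts, window_ns):
        params = lmfit.Parameters()
        for i, tau in enumerate(taus):
            params.add(f"tau{i}", value=tau, min=5e-3, max=4 * window_ns)
        if n_components == 1:
            params.add("a0", value=1.0, vary=False)
        else:
            params.add("frac", value=0.5, min=0.0, max=1.0)
            params.add("a0", expr="frac")
            params.add("a1", expr="1 - frac")
        params.add("scale", value=scale0, min=0.0)
        params.add("baseline", value=max(baseline0, 0.0), min=0.0)
        params.add("shift", value=0.0, min=-max_shift_ns, max=max_shift_ns,
                   vary=vary_shift and method == "reconvolution")
        try:
            res = lmfit.minimize(_residual, params, method="least_squares",
                                 args=(trace, n_components, objective, method,
                                       window, tail_t0),
                                 ftol=1e-10, xtol=1e-10)
        except Exception:
            continue
        cost = float(np.sum(res.residual ** 2))
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise DecayError("all fit starts failed")
    cost, res = best

    n_free = res.nvarys
    red_chi2, _ = _pearson_reduced_chi2(trace, res.params, n_components, method,
                                        window, tail_t0, n_free)
    comps = [(res.params[f"a{i}"].value, res.params[f"tau{i}"].value)
             for i in range(n_components)]
    total_amp = sum(a for a, _ in comps)
    model = DecayModel(baseline=res.params["baseline"].value,
                       components=tuple(comps) if total_amp > 0
                       else tuple((1.0 / n_components, t) for _, t in comps))
    stderr = {name: (res.params[name].stderr
                     if res.params[name].stderr is not None else None)
              for name in res.params if res.params[name].vary}
    finite_err = all(v is not None and np.isfinite(v) for v in stderr.values())
    scale = float(res.params["scale"].value)
    # a decay signal should carry the bulk of the counts; a fit that parks
    # nearly everything in the flat baseline has found no decay at all
    degenerate = scale <= 0.1 * trace.total_counts or total_amp <= 0
    if n_components == 2 and not degenerate:
        # spurious second component: pre-exponential weight or intensity
        # fraction ~0, or lifetime pinned at the lower bound
        intensities = [a * tau for a, tau in model.components]
        degenerate = (min(a for a, _ in model.components) < 1e-4
                      or min(intensities) / sum(intensities) < 1e-3
                      or min(model.lifetimes_ns) <= 1.5 * 5e-3)
    converged = bool(res.success) and finite_err and not degenerate
    return DecayFit(model=model, scale=scale,
                    irf_shift_ns=float(res.params["shift"].value),
                    reduced_chi2=red_chi2, stderr=stderr,
                    n_iterations=int(res.nfev), converged=converged,
                    degenerate=degenerate, objective=objective, method=method,
                    window=window, cost=cost)


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Wald–Wolfowitz runs test on residual signs; one-sided p-value for
    too few runs (systematic misfit)."""
    signs = residuals > 0
    n1 = int(signs.sum())
    n2 = signs.size - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu + 0.5) / math.sqrt(var)
    return float(norm.cdf(z))


def select_model_order(trace: DecayTrace,
                       objective: Literal["poisson_mle", "weighted_ls"] = "poisson_mle",
                       delta_chi2_threshold: float = 0.05,
                       runs_alpha: float = 0.05,
                       amplitude_floor: float = 0.02,
                       **fit_kwargs) -> ModelOrderDecision:
    """Choose between 1 and 2 decay components.

    Two components are accepted only if the single-exponential fit is
    rejected by BOTH criteria: its reduced χ² exceeds the 2-component one
    by more than ``delta_chi2_threshold``, and a Wald–Wolfowitz runs test
    on its residual signs rejects randomness at ``runs_alpha``.  A
    2-component fit whose smaller amplitude falls below
    ``amplitude_floor`` is treated as degenerate; ties break toward fewer
    components.
    """
    fit1 = fit_decay(trace, 1, objective=objective, **fit_kwargs)
    fit2 = fit_decay(trace, 2, objective=objective, **fit_kwargs)
    _, resid1 = _pearson_reduced_chi2(
        trace, _params_from_fit(fit1), 1, fit1.method, fit1.window,
        trace.time_ns[fit1.window[0]], 0)
    runs_p = _runs_test_pvalue(resid1)
    delta = fit1.reduced_chi2 - fit2.reduced_chi2
    min_amp = min(fit2.model.amplitudes)
    if min_amp < amplitude_floor or fit2.degenerate:
        order, reason = 1, "second component degenerate (amplitude below floor)"
    elif delta > delta_chi2_threshold and runs_p < runs_alpha:
        order, reason = 2, ("single-exponential rejected by reduced-chi2 "
                            "improvement and residual runs test")
    else:
        order, reason = 1, "single-exponential not rejected by both criteria"
    return ModelOrderDecision(order=order, fit1=fit1, fit2=fit2,
                              delta_reduced_chi2=delta, runs_pvalue=runs_p,
                              reason=reason)


def _params_from_fit(fit: DecayFit) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for i, (a, tau) in enumerate(fit.model.components):
        params.add(f"tau{i}", value=tau)
        params.add(f"a{i}", value=a)
    params.add("scale", value=fit.scale)
    params.add("baseline", value=fit.model.baseline)
    params.add("shift", value=fit.irf_shift_ns)
    return params


# ---------------------------------------------------------------------------
# File I/O: CSV histograms (`time_ns,counts`), same-format IRF companion,
# JSON metadata sidecar.


def read_decay_csv(path, irf_path=None, meta_path=None, sep: str = ",") -> DecayTrace:
    df = pd.read_csv(path, comment="#", sep=sep)
    if not {"time_ns", "counts"}.issubset(df.columns):
        raise DecayError(f"{path}: expected columns time_ns,counts")
    t = df["time_ns"].to_numpy(float)
    counts = df["counts"].to_numpy()
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    if irf_path is not None:
        irf_df = pd.read_csv(irf_path, comment="#", sep=sep)
        irf = irf_df["counts"].to_numpy(float)
    else:
        irf = np.zeros_like(t)
        irf[0] = 1.0                      # delta IRF when none is supplied
    return DecayTrace(time_ns=t, counts=counts, irf=irf,
                      rep_period_ns=float(meta.get("rep_period_ns",
                                                   REP_PERIOD_DEFAULT_NS)),
                      excitation_nm=meta.get("excitation_nm"),
                      label=meta.get("label", ""))


def write_decay_csv(trace: DecayTrace, path, irf_path=None, meta_path=None,
                    sep: str = ",") -> None:
    pd.DataFrame({"time_ns": trace.time_ns, "counts": trace.counts}).to_csv(
        path, sep=sep, index=False)
    if irf_path is not None:
        pd.DataFrame({"time_ns": trace.time_ns, "counts": trace.irf}).to_csv(
            irf_path, sep=sep, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump({"rep_period_ns": trace.rep_period_ns,
                       "excitation_nm": trace.excitation_nm,
                       "label": trace.label}, fh, indent=2)
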