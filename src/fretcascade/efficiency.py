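"""Energy-transfer-efficiency statistics for the two-step FRET sensor.

Three related read-outs quantify the K⁺-induced cascade:

* lifetime efficiency  φ = 1 − τ_DA/τ_D  from donor lifetimes measured with
  and without the acceptor;
* time-resolved efficiency  E(t) = [I_D(t) − I_DA(t)]/I_D(t)  from donor
  intensity traces (negative values are physical — they signal population
  *gain* by upstream compensation — and are never clipped);
* cumulative gain efficiency  η(t) = [∫I_with − ∫I_w/o]/∫I_w/o  comparing
  the acceptor's emission with and without K⁺; the pointwise variant uses
  instantaneous intensities instead of integrals.  η can exceed 1 when the
  cascade more than doubles the acceptor population.

Internal values are fractions; percent formatting belongs to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LifetimePair",
    "EfficiencyCurve",
    "lifetime_efficiency",
    "time_resolved_efficiency",
    "cumulative_gain_efficiency",
    "gain_efficiency_curve",
    "enhancement_ratio",
]


class EfficiencyError(ValueError):
    """Invalid efficiency input."""


@dataclass(frozen=True)
class LifetimePair:
    """Donor lifetimes without (τ_D) and with (τ_DA) the acceptor, in ns."""

    tau_donor_ns: float
    tau_donor_acceptor_ns: float

    def __post_init__(self) -> None:
        if self.tau_donor_ns <= 0 or self.tau_donor_acceptor_ns <= 0:
            raise EfficiencyError("lifetimes must be > 0")


@dataclass(frozen=True)
class EfficiencyCurve:
    """Time-indexed transfer efficiency under a stated convention."""

    time_ns: np.ndarray
    values: np.ndarray
    convention: Literal["pointwise", "cumulative_gain", "pointwise_gain"]
    reference_label: str = ""
    comparison_label: str = ""
    excluded_bins: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.convention == "pointwise" and np.any(self.values > 1 + 1e-12):
            raise EfficiencyError("pointwise efficiency cannot exceed 1")
        if self.convention.endswith("gain") and np.any(self.values < -1 - 1e-12):
            raise EfficiencyError("gain efficiency cannot fall below -1")

    def at(self, t_ns: float) -> float:
        return float(np.interp(t_ns, self.time_ns, self.values))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ns": self.time_ns,
                      "efficiency": self.values}).to_csv(path, index=False)


def lifetime_efficiency(pair: LifetimePair) -> float:
    """φ = 1 − τ_DA/τ_D.  Negative when the donor lifetime lengthens."""
    return 1.0 - pair.tau_donor_acceptor_ns / pair.tau_donor_ns


def time_resolved_efficiency(time_ns: np.ndarray, I_donor: np.ndarray,
                             I_donor_acceptor: np.ndarray,
                             reference_label: str = "I_D",
                             comparison_label: str = "I_DA") -> EfficiencyCurve:
    """E(t) = [I_D(t) − I_DA(t)]/I_D(t) on the bins where I_D > 0.

    Bins with non-positive donor intensity are excluded and recorded in
    ``excluded_bins``.  Negative values (population gain by compensation)
    are reported as-is.
    """
    t = np.asarray(time_ns, dtype=float)
    Id = np.asarray(I_donor, dtype=float)
    Ida = np.asarray(I_donor_acceptor, dtype=float)
    if t.shape != Id.shape or t.shape != Ida.shape:
        raise EfficiencyError("curves must share one time grid")
    valid = Id > 0
    if not valid.any():
        raise EfficiencyError("donor intensity non-positive everywhere")
    values = (Id[valid] - Ida[valid]) / Id[valid]
    return EfficiencyCurve(time_ns=t[valid], values=values,
                           convention="pointwise",
                           reference_label=reference_label,
                           comparison_label=comparison_label,
                           excluded_bins=np.nonzero(~valid)[0])


def cumulative_gain_efficiency(time_ns: np.ndarray, I_without: np.ndarray,
                               I_with: np.ndarray, t_eval_ns: float,
                               mode: Literal["cumulative", "pointwise"] = "pointwise",
                               ) -> float:
    """Gain efficiency η at ``t_eval_ns`` as a fraction.

    ``pointwise`` (default) uses the instantaneous intensities at t_eval —
    the convention matching the sensor's worked read-out; ``cumulative``
    integrates both curves from 0 to t_eval (trapezoid) before taking the
    ratio.  Both are invariant under a common rescaling of the two curves.
    """
    t = np.asarray(time_ns, dtype=float)
    Iw = np.asarray(I_without, dtype=float)
    Ik = np.asarray(I_with, dtype=float)
    if t.shape != Iw.shape or t.shape != Ik.shape:
        raise EfficiencyError("curves must share one time grid")
    if mode == "pointwise":
        denom = float(np.interp(t_eval_ns, t, Iw))
        num = float(np.interp(t_eval_ns, t, Ik))
    elif mode == "cumulative":
        mask = t <= t_eval_ns
        if mask.sum() < 2:
            raise EfficiencyError("t_eval below the second grid point")
        denom = float(np.trapezoid(Iw[mask], t[mask]))
        num = float(np.trapezoid(Ik[mask], t[mask]))
    else:
        raise EfficiencyError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise EfficiencyError("reference intensity integral/value is not positive")
    return num / denom - 1.0


def gain_efficiency_curve(time_ns: np.ndarray, I_without: np.ndarray,
                          I_with: np.ndarray,
                          mode: Literal["cumulative", "pointwise"] = "pointwise",
                          reference_label: str = "I_w/o_K+",
                          comparison_label: str = "I_with_K+") -> EfficiencyCurve:
    """η(t) evaluated on every grid point where the reference is positive."""
    t = np.asarray(time_ns, dtype=float)
    Iw = np.asarray(I_without, dtype=float)
    Ik = np.asarray(I_with, dtype=float)
    if mode == "pointwise":
        valid = Iw > 0
        vals = Ik[valid] / Iw[valid] - 1.0
        tt = t[valid]
    else:
        cw = np.concatenate(([0.0], np.cumsum(
            0.5 * (Iw[1:] + Iw[:-1]) * np.diff(t))))
        ck = np.concatenate(([0.0], np.cumsum(
            0.5 * (Ik[1:] + Ik[:-1]) * np.diff(t))))
        valid = cw > 0
        vals = ck[valid] / cw[valid] - 1.0
        tt = t[valid]
    conv = "pointwise_gain" if mode == "pointwise" else "cumulative_gain"
    return EfficiencyCurve(time_ns=tt, values=vals, convention=conv,
                           reference_label=reference_label,
                           comparison_label=comparison_label)


def enhancement_ratio(time_ns: np.ndarray, I_a: np.ndarray, I_b: np.ndarray,
                      t_ns: float) -> float:
    """Intensity ratio I_a(t)/I_b(t), e.g. two-dye vs TAMRA-only traces."""
    t = np.asarray(time_ns, dtype=float)
    denom = float(np.interp(t_ns, t, np.asarray(I_b, dtype=float)))
    if denom <= 0:
        raise EfficiencyError("denominator intensity is not positive at t")
    return float(np.interp(t_ns, t, np.asarray(I_a, dtype=float))) / denom
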