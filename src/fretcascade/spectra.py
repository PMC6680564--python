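"""Fluorophore spectra, spectral overlap, and Förster-theory rate conversions.

The donor–acceptor resonance coupling in FRET is quantified by the spectral
overlap integral

    J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ        [M⁻¹·cm⁻¹·nm⁴]

where ``f_D`` is the *area-normalized* donor emission spectrum and ``ε_A``
the acceptor molar extinction coefficient.  The Förster distance — the
donor–acceptor separation at which the transfer efficiency is 50% — follows
from J through the standard closed form

    R0 = 0.2108 · [κ² · n⁻⁴ · Q_D · J]^(1/6)   [Å]

with κ² the dipole orientation factor (2/3 under dynamic isotropic
averaging), n the medium refractive index and Q_D the donor quantum yield.
Distances convert to rates via the R⁻⁶ Förster law, while the competing
photo-induced charge transfer (PCT) channel decays exponentially with
distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FORSTER_PREFACTOR_ANGSTROM",
    "Spectrum",
    "FluorophoreSpec",
    "OverlapResult",
    "normalize_emission",
    "overlap_integral",
    "forster_distance",
    "fret_rate",
    "pct_rate",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Prefactor of the Förster-distance formula for R0 in Å and J in
#: M⁻¹·cm⁻¹·nm⁴.  The SI-equivalent statement is
#: R0⁶ = (9000 ln10 / (128 π⁵ N_A)) κ² n⁻⁴ Q_D J with J in M⁻¹·cm⁻¹·nm⁴
#: and R0 in nm after taking the sixth root and dividing by 10.
FORSTER_PREFACTOR_ANGSTROM = 0.2108


class SpectrumError(ValueError):
    """Invalid spectrum content or incompatible spectra."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-gridded absorption or emission curve.

    Parameters
    ----------
    wavelengths_nm : array
        Strictly increasing wavelength grid, all values > 0, in nm.
    values : array
        Non-negative curve values.  Molar extinction (M⁻¹·cm⁻¹) for
        ``kind="absorption"``; arbitrary or normalized units for emission.
    kind : {"absorption", "emission"}
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: Literal["absorption", "emission"]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two grid points")
        if np.any(np.diff(wl) <= 0) or np.any(wl <= 0):
            raise SpectrumError("wavelength grid must be strictly increasing and > 0")
        if np.any(vals < 0):
            raise SpectrumError("spectrum values must be non-negative")
        if self.kind not in ("absorption", "emission"):
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")

    @property
    def peak_nm(self) -> float:
        """Wavelength of the maximum value."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def area(self) -> float:
        """Trapezoid integral over the grid."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def interpolate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the spectrum's support."""
        return np.interp(wavelengths_nm, self.wavelengths_nm, self.values,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class FluorophoreSpec:
    """A fluorophore's spectra plus scalar photophysical parameters."""

    name: str
    absorption: Spectrum
    emission: Spectrum
    quantum_yield: float
    extinction_max: float
    abs_peak_nm: float
    emission_peaks_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise SpectrumError("quantum_yield must lie in [0, 1]")
        step = float(np.max(np.diff(self.absorption.wavelengths_nm)))
        if abs(self.absorption.peak_nm - self.abs_peak_nm) > step:
            raise SpectrumError(
                f"{self.name}: abs_peak_nm {self.abs_peak_nm} is not the argmax "
                f"of the absorption spectrum ({self.absorption.peak_nm})"
            )


@dataclass(frozen=True)
class OverlapResult:
    """Spectral overlap integral and (optionally) the derived Förster distance."""

    J: float                      # M⁻¹·cm⁻¹·nm⁴
    kappa2: Optional[float] = None
    refractive_index: Optional[float] = None
    donor_qy: Optional[float] = None
    R0_angstrom: Optional[float] = None

    def __post_init__(self) -> None:
        if self.J < 0:
            raise SpectrumError("overlap integral J must be >= 0")
        if self.R0_angstrom is not None and self.R0_angstrom < 0:
            raise SpectrumError("R0 must be >= 0")

    def to_json(self) -> str:
        payload = {
            "J": {"value": self.J, "unit": "M^-1 cm^-1 nm^4"},
            "kappa2": {"value": self.kappa2, "unit": "dimensionless"},
            "refractive_index": {"value": self.refractive_index,
                                 "unit": "dimensionless"},
            "donor_qy": {"value": self.donor_qy, "unit": "fraction"},
            "R0": {"value": self.R0_angstrom, "unit": "angstrom"},
        }
        return json.dumps(payload, indent=2)


def normalize_emission(spectrum: Spectrum, mode: Literal["area", "peak"] = "area") -> Spectrum:
    """Rescale an emission spectrum so its area (default) or peak equals 1.

    Area normalization is the convention the overlap integral requires
    (``f_D`` a spectral density); peak normalization is the usual display
    convention.  Both preserve the spectral shape.
    """
    if spectrum.kind != "emission":
        raise SpectrumError("normalize_emission requires an emission spectrum")
    if not np.any(spectrum.values > 0):
        raise SpectrumError("cannot normalize an all-zero spectrum")
    if mode == "area":
        scale = spectrum.area()
    elif mode == "peak":
        scale = float(np.max(spectrum.values))
    else:
        raise SpectrumError(f"unknown normalization mode {mode!r}")
    return replace(spectrum, values=spectrum.values / scale)


def _union_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Union of both grids restricted to the overlapping wavelength range."""
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    if lo >= hi:
        return np.empty(0)
    grid = np.union1d(a.wavelengths_nm, b.wavelengths_nm)
    return grid[(grid >= lo) & (grid <= hi)]


def overlap_integral(donor_emission: Spectrum,
                     acceptor_absorption: Spectrum) -> OverlapResult:
    """Spectral overlap J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ in M⁻¹·cm⁻¹·nm⁴.

    The donor emission is area-normalized internally; both spectra are
    resampled by linear interpolation onto the union grid restricted to
    their common wavelength range.  Disjoint spectra give J = 0 with a
    warning.
    """
    if donor_emission.kind != "emission":
        raise SpectrumError("donor spectrum must be an emission spectrum")
    if acceptor_absorption.kind != "absorption":
        raise SpectrumError("acceptor spectrum must be an absorption spectrum")
    fd = normalize_emission(donor_emission, mode="area")
    grid = _union_grid(fd, acceptor_absorption)
    if grid.size < 2:
        warnings.warn("donor emission and acceptor absorption do not overlap; J = 0",
                      stacklevel=2)
        return OverlapResult(J=0.0)
    integrand = fd.interpolate(grid) * acceptor_absorption.interpolate(grid) * grid ** 4
    return OverlapResult(J=float(np.trapezoid(integrand, grid)))


def forster_distance(J: float, kappa2: float = 2.0 / 3.0,
                     refractive_index: float = 1.33,
                     donor_qy: float = 1.0) -> float:
    """Förster distance R0 in Å from J in M⁻¹·cm⁻¹·nm⁴."""
    if min(J, kappa2, donor_qy) < 0 or refractive_index <= 0:
        raise SpectrumError("J, kappa2, donor_qy must be >= 0 and n > 0")
    return FORSTER_PREFACTOR_ANGSTROM * (
        kappa2 * refractive_index ** -4 * donor_qy * J
    ) ** (1.0 / 6.0)


def forster_from_spectra(donor: FluorophoreSpec, acceptor: FluorophoreSpec,
                         kappa2: float = 2.0 / 3.0,
                         refractive_index: float = 1.33) -> OverlapResult:
    """Overlap integral and Förster distance for a donor/acceptor pair."""
    res = overlap_integral(donor.emission, acceptor.absorption)
    r0 = forster_distance(res.J, kappa2=kappa2, refractive_index=refractive_index,
                          donor_qy=donor.quantum_yield)
    return OverlapResult(J=res.J, kappa2=kappa2, refractive_index=refractive_index,
                         donor_qy=donor.quantum_yield, R0_angstrom=r0)


def fret_rate(distance_angstrom: float, R0_angstrom: float,
              donor_intrinsic_lifetime_ns: float) -> float:
    """Förster transfer rate k = (1/τ_D)(R0/R)⁶ in ns⁻¹.

    At R = R0 the rate equals the donor's intrinsic decay rate, so the
    transfer efficiency is 50% by construction.
    """
    if distance_angstrom <= 0:
        raise SpectrumError("distance must be > 0 (rate diverges at contact)")
    if R0_angstrom < 0 or donor_intrinsic_lifetime_ns <= 0:
        raise SpectrumError("R0 must be >= 0 and the donor lifetime > 0")
    return (1.0 / donor_intrinsic_lifetime_ns) * (R0_angstrom / distance_angstrom) ** 6


def pct_rate(distance_angstrom: float, k0_per_ns: float, beta_per_angstrom: float) -> float:
    """Photo-induced charge-transfer rate k = k0·exp(−β·R) in ns⁻¹."""
    if min(distance_angstrom, k0_per_ns, beta_per_angstrom) < 0:
        raise SpectrumError("pct_rate arguments must be >= 0")
    return k0_per_ns * float(np.exp(-beta_per_angstrom * distance_angstrom))


# ---------------------------------------------------------------------------
# File I/O: two-column CSV/TSV, header `wavelength_nm,value`, '#' comments.

def read_spectrum_csv(path, kind: Literal["absorption", "emission"],
                      sep: str = ",") -> Spectrum:
    df = pd.read_csv(path, comment="#", sep=sep)
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise SpectrumError(f"{path}: expected columns wavelength_nm,value")
    return Spectrum(df["wavelength_nm"].to_numpy(float),
                    df["value"].to_numpy(float), kind)


def write_spectrum_csv(spectrum: Spectrum, path, sep: str = ",") -> None:
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelengths_nm,
                       "value": spectrum.values})
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        df.to_csv(fh, sep=sep, index=False)
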