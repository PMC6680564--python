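"""Synthetic inputs for the K⁺-sensor pipeline: spectra, scenarios, TCSPC data.

No measured spectra or photon histograms ship with the sensor study, so
this module generates statistically faithful stand-ins:

* vibronic mirror-image absorption/emission spectra built from Gaussian
  progressions pinned to the published peak wavelengths and molar
  extinction maxima of the three fluorophores (CP, 6-FAM, TAMRA);
* kinetic scenarios (free fluorophores, CP/aptamer complex without K⁺,
  complex with K⁺) that convert inter-fluorophore distances into FRET and
  PCT rates — K⁺-driven G-quadruplex folding shortens the 6-FAM–TAMRA
  distance and switches on the two-step cascade;
* Poisson photon-count histograms from the wrapped IRF-reconvolution
  forward model (Gaussian IRF, FWHM 190 ps, 12.5 ns repetition window).

Everything is deterministic given a seed; ``write_fixture_set`` emits the
full CSV/JSON fixture suite plus a manifest of generating parameters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np

from .spectra import (FluorophoreSpec, Spectrum, forster_from_spectra,
                      fret_rate, normalize_emission, pct_rate,
                      write_spectrum_csv)
from .decay_fitting import (DecayModel, DecayTrace, gaussian_irf,
                            multi_exp_reconvolve, write_decay_csv,
                            IRF_FWHM_DEFAULT_NS, N_BINS_DEFAULT,
                            REP_PERIOD_DEFAULT_NS)
from .kinetics import DeltaPulse, KineticNetwork, StateRates

__all__ = [
    "ScenarioSpec",
    "make_vibronic_spectrum",
    "fluorophore",
    "build_scenario",
    "network_state_mixture",
    "simulate_tcspc",
    "tamra_gain_demo",
    "write_fixture_set",
    "TABLE1_MODELS",
]


class SyntheticError(ValueError):
    """Invalid synthetic-data request."""


# ---------------------------------------------------------------------------
# Vibronic spectra

WAVELENGTH_GRID_NM = np.arange(300.0, 800.0 + 0.25, 0.5)

#: Gaussian vibronic parameters for the three fluorophores.  Peak
#: wavelengths and extinction maxima are the published values; widths and
#: progression amplitudes are free choices calibrated once so the
#: CP-donor overlap-integral ratio J(CP/6-FAM)/J(CP/TAMRA) reproduces the
#: published 3.09 ratio (see docs/methods.md).
FLUOROPHORE_PRESETS: dict[str, dict] = {
    "CP": {
        "abs_peaks_nm": (397.8,),
        "abs_amps": (1.0,),
        "abs_width_nm": 18.0,
        "em_peaks_nm": (426.6, 451.0, 483.0, 520.0),
        "em_amps": (1.0, 0.70, 0.45, 0.10),
        "em_width_nm": (9.0, 9.0, 16.0, 22.0),
        "extinction_max": 0.52e4,
        "quantum_yield": 0.58,
        "tau_int_ns": {"free_no_K": 0.38, "free_with_K": 0.43},
    },
    "FAM": {
        "abs_peaks_nm": (490.4, 450.0),
        "abs_amps": (1.0, 0.35),
        "abs_width_nm": 15.0,
        "em_peaks_nm": (514.4, 545.0),
        "em_amps": (1.0, 0.35),
        "em_width_nm": 15.0,
        "extinction_max": 1.25e4,
        "quantum_yield": 0.90,      # not published; typical fluorescein value
        "tau_int_ns": 3.72,
    },
    "TAMRA": {
        "abs_peaks_nm": (567.6, 522.0),
        "abs_amps": (1.0, 0.45),
        "abs_width_nm": 15.0,
        "em_peaks_nm": (590.2, 630.0),
        "em_amps": (1.0, 0.40),
        "em_width_nm": 15.0,
        "extinction_max": 1.96e4,
        "quantum_yield": 0.55,      # not published; typical rhodamine value
        "tau_int_ns": 1.01,
    },
}


def make_vibronic_spectrum(kind: Literal["absorption", "emission"],
                           peaks_nm: Sequence[float],
                           widths_nm: Union[float, Sequence[float]],
                           amplitudes: Optional[Sequence[float]] = None,
                           epsilon_max: Optional[float] = None,
                           mirror_of: Optional[Spectrum] = None,
                           zero_zero_nm: Optional[float] = None,
                           grid_nm: np.ndarray = WAVELENGTH_GRID_NM) -> Spectrum:
    """A sum of Gaussians at the stated vibronic peaks.

    ``mirror_of`` reflects an existing spectrum about ``zero_zero_nm`` (the
    0-0 transition wavelength), emulating the mirror-image symmetry of
    absorption and emission band shapes; applied twice this is an
    involution up to grid interpolation.  Absorption spectra are rescaled
    so their maximum equals ``epsilon_max``.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if mirror_of is not None:
        if zero_zero_nm is None:
            raise SyntheticError("mirroring requires the 0-0 wavelength")
        reflected = np.interp(2.0 * zero_zero_nm - grid,
                              mirror_of.wavelengths_nm, mirror_of.values,
                              left=0.0, right=0.0)
        values = reflected
    else:
        peaks = np.asarray(peaks_nm, dtype=float)
        if np.any((peaks < 300.0) | (peaks > 800.0)):
            raise SyntheticError("vibronic peaks must lie in [300, 800] nm")
        widths = np.broadcast_to(np.asarray(widths_nm, dtype=float), peaks.shape)
        if np.any(widths <= 0):
            raise SyntheticError("widths must be > 0")
        amps = (np.ones_like(peaks) if amplitudes is None
                else np.asarray(amplitudes, dtype=float))
        values = np.zeros_like(grid)
        for mu, sig, a in zip(peaks, widths, amps):
            values += a * np.exp(-0.5 * ((grid - mu) / sig) ** 2)
    if epsilon_max is not None:
        peak = values.max()
        if peak <= 0:
            raise SyntheticError("cannot scale an all-zero spectrum")
        values = values * (epsilon_max / peak)
    return Spectrum(wavelengths_nm=grid, values=values, kind=kind)


def fluorophore(name: str) -> FluorophoreSpec:
    """Build the preset FluorophoreSpec for CP, FAM, or TAMRA."""
    try:
        p = FLUOROPHORE_PRESETS[name]
    except KeyError:
        raise SyntheticError(f"unknown fluorophore {name!r}") from None
    absorption = make_vibronic_spectrum("absorption", p["abs_peaks_nm"],
                                        p["abs_width_nm"], p["abs_amps"],
                                        epsilon_max=p["extinction_max"])
    emission = make_vibronic_spectrum("emission", p["em_peaks_nm"],
                                      p["em_width_nm"], p["em_amps"])
    return FluorophoreSpec(
        name=name, absorption=absorption,
        emission=normalize_emission(emission, mode="peak"),
        quantum_yield=p["quantum_yield"],
        extinction_max=p["extinction_max"],
        abs_peak_nm=p["abs_peaks_nm"][0],
        emission_peaks_nm=tuple(p["em_peaks_nm"]))


def _intrinsic_tau(name: str, tag: str) -> float:
    tau = FLUOROPHORE_PRESETS[name]["tau_int_ns"]
    if isinstance(tau, dict):
        return tau["free_with_K" if tag == "complex_with_K" else "free_no_K"]
    return float(tau)


# ---------------------------------------------------------------------------
# Scenarios

#: Inter-fluorophore distances (Å) and loss-channel parameters per assay
#: state.  Calibrated once against the published fitted lifetimes: the
#: with-K⁺ distances make the CP total decay rate ≈ 1/0.19 ns⁻¹ and the
#: 6-FAM rate ≈ 1/0.25 ns⁻¹; without K⁺ the unfolded aptamer keeps the
#: dyes further apart (CP rate ≈ 1/0.35 ns⁻¹, 6-FAM ≈ 1/0.36 ns⁻¹).
SCENARIO_PRESETS: dict[str, dict] = {
    "free": {
        "R_cp_fam": None, "R_cp_tamra": None, "R_fam_tamra": None,
        "pct_k0_per_ns": 0.0, "pct_beta_per_angstrom": 0.3,
        "fam_quench_per_ns": 0.0,
    },
    "complex_no_K": {
        "R_cp_fam": 60.2, "R_cp_tamra": 57.3, "R_fam_tamra": 32.3,
        "pct_k0_per_ns": 2000.0, "pct_beta_per_angstrom": 0.3,
        "fam_quench_per_ns": 0.05,
    },
    "complex_with_K": {
        "R_cp_fam": 37.3, "R_cp_tamra": 37.1, "R_fam_tamra": 30.7,
        "pct_k0_per_ns": 2000.0, "pct_beta_per_angstrom": 0.3,
        "fam_quench_per_ns": 0.40,
    },
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Assay scenario: distances, loss channels, counting budget, seed.

    ``complex_with_K`` must keep the 6-FAM–TAMRA distance shorter than
    ``complex_no_K`` (G-quadruplex folding); the free scenario has no
    transfer at all.
    """

    tag: Literal["free", "complex_no_K", "complex_with_K"]
    R_cp_fam: Optional[float] = None
    R_cp_tamra: Optional[float] = None
    R_fam_tamra: Optional[float] = None
    pct_k0_per_ns: float = 0.0
    pct_beta_per_angstrom: float = 0.3
    fam_quench_per_ns: float = 0.0
    total_counts: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tag not in SCENARIO_PRESETS:
            raise SyntheticError(f"unknown scenario tag {self.tag!r}")
        for R in (self.R_cp_fam, self.R_cp_tamra, self.R_fam_tamra):
            if R is not None and R <= 0:
                raise SyntheticError("distances must be > 0")
        if self.tag == "complex_with_K" and self.R_fam_tamra is not None:
            no_k = SCENARIO_PRESETS["complex_no_K"]["R_fam_tamra"]
            if self.R_fam_tamra >= no_k:
                raise SyntheticError(
                    "with-K+ FAM-TAMRA distance must be shorter than without K+")

    @classmethod
    def preset(cls, tag: str, total_counts: int = 1_000_000,
               seed: int = 0) -> "ScenarioSpec":
        return cls(tag=tag, total_counts=total_counts, seed=seed,
                   **SCENARIO_PRESETS[tag])


# Cache for the overlap/Förster results of the three preset pairs.
_R0_CACHE: dict[str, float] = {}


def preset_forster_distances() -> dict[str, float]:
    """R0 (Å) of the three preset donor/acceptor pairs (κ²=2/3, n=1.33)."""
    if not _R0_CACHE:
        cp, fam, tamra = fluorophore("CP"), fluorophore("FAM"), fluorophore("TAMRA")
        _R0_CACHE["CP/FAM"] = forster_from_spectra(cp, fam).R0_angstrom
        _R0_CACHE["CP/TAMRA"] = forster_from_spectra(cp, tamra).R0_angstrom
        _R0_CACHE["FAM/TAMRA"] = forster_from_spectra(fam, tamra).R0_angstrom
    return dict(_R0_CACHE)


def build_scenario(spec: ScenarioSpec) -> KineticNetwork:
    """Convert a scenario's distances into a CP→FAM→TAMRA kinetic network.

    FRET rates follow the R⁻⁶ law with the preset-spectra Förster
    distances; the PCT loss channel on the CP decays exponentially with
    the CP–dye contact distance.  The free scenario has no transfer, so
    each state decays with its intrinsic lifetime.
    """
    r0 = preset_forster_distances()
    tau_cp = _intrinsic_tau("CP", spec.tag)
    tau_fam = _intrinsic_tau("FAM", spec.tag)
    tau_tamra = _intrinsic_tau("TAMRA", spec.tag)

    transfers: dict[tuple[str, str], float] = {}
    cp_extra = 0.0
    if spec.tag != "free":
        if None in (spec.R_cp_fam, spec.R_cp_tamra, spec.R_fam_tamra):
            raise SyntheticError("complex scenarios need all three distances")
        transfers[("CP", "FAM")] = fret_rate(spec.R_cp_fam, r0["CP/FAM"], tau_cp)
        transfers[("CP", "TAMRA")] = fret_rate(spec.R_cp_tamra, r0["CP/TAMRA"],
                                               tau_cp)
        transfers[("FAM", "TAMRA")] = fret_rate(spec.R_fam_tamra,
                                                r0["FAM/TAMRA"], tau_fam)
        cp_extra = pct_rate(min(spec.R_cp_fam, spec.R_cp_tamra),
                            spec.pct_k0_per_ns, spec.pct_beta_per_angstrom)

    rates = {
        "CP": StateRates.from_lifetime(tau_cp,
                                       FLUOROPHORE_PRESETS["CP"]["quantum_yield"],
                                       k_extra=cp_extra),
        "FAM": StateRates.from_lifetime(tau_fam,
                                        FLUOROPHORE_PRESETS["FAM"]["quantum_yield"],
                                        k_extra=spec.fam_quench_per_ns),
        "TAMRA": StateRates.from_lifetime(tau_tamra,
                                          FLUOROPHORE_PRESETS["TAMRA"]["quantum_yield"]),
    }
    return KineticNetwork(states=("CP", "FAM", "TAMRA"), rates=rates,
                          transfers=transfers)


def network_state_mixture(network: KineticNetwork, state: str,
                          pulse: DeltaPulse) -> tuple[np.ndarray, np.ndarray]:
    """Exact exponential-mixture representation of one state's impulse decay.

    The cascade's rate matrix is triangular, so populations are finite
    sums of exponentials; amplitudes may be negative (rise terms of a
    downstream acceptor).  Returns (amplitudes, lifetimes_ns).
    """
    A = network.rate_matrix()
    lam, V = np.linalg.eig(A)
    gaps = np.abs(np.subtract.outer(lam, lam))
    gaps[np.eye(lam.size, dtype=bool)] = np.inf
    if gaps.min() < 1e-9:
        raise SyntheticError("degenerate decay rates; perturb the scenario")
    n0 = np.zeros(network.n_states)
    for s, amp in pulse.amplitudes.items():
        n0[network.states.index(s)] = amp
    coeff = np.linalg.solve(V, n0)
    i = network.states.index(state)
    amps = np.real(V[i] * coeff)
    taus = np.real(-1.0 / lam)
    keep = np.abs(amps) > 1e-12 * np.abs(amps).max()
    return amps[keep], taus[keep]


# ---------------------------------------------------------------------------
# TCSPC simulation

IRF_CENTER_DEFAULT_NS = 0.8


def simulate_tcspc(source: Union[DecayModel, KineticNetwork], *,
                   state: Optional[str] = None,
                   pulse: Optional[DeltaPulse] = None,
                   total_counts: int = 1_000_000,
                   irf_fwhm_ns: float = IRF_FWHM_DEFAULT_NS,
                   irf_center_ns: float = IRF_CENTER_DEFAULT_NS,
                   rep_period_ns: float = REP_PERIOD_DEFAULT_NS,
                   n_bins: int = N_BINS_DEFAULT,
                   background_fraction: float = 1e-4,
                   seed: int = 0,
                   excitation_nm: Optional[float] = None,
                   label: str = "") -> DecayTrace:
    """Simulate a Poisson TCSPC histogram from a decay model or a network.

    The expected curve is the wrapped IRF-reconvolved signal scaled to the
    requested counting budget, plus a flat dark-count background of
    ``background_fraction`` of the signal peak per bin; each bin is then an
    independent Poisson draw.  A fixed seed yields a bit-identical trace.
    """
    if total_counts < 1:
        raise SyntheticError("total_counts must be >= 1")
    time_ns = np.arange(n_bins) * (rep_period_ns / n_bins)
    irf = gaussian_irf(time_ns, irf_fwhm_ns, irf_center_ns)

    if isinstance(source, DecayModel):
        amps = np.asarray(source.amplitudes)
        taus = np.asarray(source.lifetimes_ns)
    elif isinstance(source, KineticNetwork):
        if state is None:
            raise SyntheticError("network simulation needs a state to observe")
        pulse = pulse or DeltaPulse({source.states[0]: 1.0})
        amps, taus = network_state_mixture(source, state, pulse)
    else:
        raise SyntheticError("source must be a DecayModel or KineticNetwork")

    signal = multi_exp_reconvolve(amps, taus, irf, time_ns, rep_period_ns)
    signal = np.clip(signal, 0.0, None)
    if signal.sum() <= 0:
        raise SyntheticError("source produces no signal in the window")
    signal = signal / signal.sum()
    background = background_fraction * signal.max() * np.ones(n_bins)
    expected = signal + background
    expected *= total_counts / expected.sum()

    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    return DecayTrace(time_ns=time_ns, counts=counts, irf=irf,
                      rep_period_ns=rep_period_ns, excitation_nm=excitation_nm,
                      label=label)


# ---------------------------------------------------------------------------
# Published Table-1 decay models (pre-exponential fractions, lifetimes in ns)

TABLE1_MODELS: dict[str, dict] = {
    "cp_free_no_K":   {"components": ((1.0, 0.38),), "excitation_nm": 380,
                       "label": "Free CP, w/o K+"},
    "cp_free_with_K": {"components": ((1.0, 0.43),), "excitation_nm": 380,
                       "label": "Free CP, with K+"},
    "cp_no_K":        {"components": ((0.94, 0.35), (0.06, 1.76)),
                       "excitation_nm": 380, "label": "CP, w/o K+"},
    "cp_with_K":      {"components": ((0.73, 0.19), (0.27, 1.46)),
                       "excitation_nm": 380, "label": "CP, with K+"},
    "fam_380_no_K":   {"components": ((1.0, 0.49),), "excitation_nm": 380,
                       "label": "6-FAM, 380 nm, w/o K+"},
    "fam_380_with_K": {"components": ((1.0, 0.33),), "excitation_nm": 380,
                       "label": "6-FAM, 380 nm, with K+"},
    "fam_free":       {"components": ((1.0, 3.72),), "excitation_nm": 490,
                       "label": "Free 6-FAM, 490 nm"},
    "fam_490_no_K":   {"components": ((0.51, 0.36), (0.49, 2.09)),
                       "excitation_nm": 490, "label": "6-FAM, 490 nm, w/o K+"},
    "fam_490_with_K": {"components": ((0.61, 0.25), (0.39, 2.18)),
                       "excitation_nm": 490, "label": "6-FAM, 490 nm, with K+"},
    "tamra_only":     {"components": ((1.0, 1.01),), "excitation_nm": 380,
                       "label": "CP/TAMRA (no 6-FAM)"},
    "tamra_no_K":     {"components": ((1.0, 0.87),), "excitation_nm": 380,
                       "label": "TAMRA, w/o K+"},
    "tamra_with_K":   {"components": ((1.0, 0.90),), "excitation_nm": 380,
                       "label": "TAMRA, with K+"},
}


def table1_model(name: str) -> DecayModel:
    """DecayModel for one published fitted-parameter set."""
    try:
        entry = TABLE1_MODELS[name]
    except KeyError:
        raise SyntheticError(f"unknown Table-1 preset {name!r}") from None
    return DecayModel(baseline=0.0, components=entry["components"])


# ---------------------------------------------------------------------------
# TAMRA gain-efficiency demonstration curves

TAMRA_GAIN_CALIBRATION = {
    "I_without_at_2ns": 100.0,    # arbitrary units, published read-out
    "I_with_at_2ns": 330.0,
    "initial_enhancement": 4.0,   # 4-fold intensity at the excitation moment
    "tau_without_ns": 0.87,
    "tau_with_ns": 0.90,
    "tau_transient_ns": 0.40,     # fast two-step feeding transient
}


def tamra_gain_demo(time_ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated TAMRA intensity curves without / with K⁺.

    The without-K⁺ curve is the single-exponential TAMRA decay; the
    with-K⁺ curve adds a fast transient emulating the two-step feeding of
    the acceptor.  Scales are *calibrated* (not predicted) so the
    pointwise intensities at 2 ns are 100 and 330 and the initial
    enhancement is 4-fold — reproducing the published sensor read-out of a
    230% plateau efficiency and ~300% initial efficiency.
    """
    cal = TAMRA_GAIN_CALIBRATION
    t = np.asarray(time_ns, dtype=float)
    A = cal["I_without_at_2ns"] * math.exp(2.0 / cal["tau_without_ns"])
    s = math.exp(-2.0 / cal["tau_with_ns"])
    f = math.exp(-2.0 / cal["tau_transient_ns"])
    target0 = cal["initial_enhancement"] * A
    b = (target0 * s - cal["I_with_at_2ns"]) / (cal["I_with_at_2ns"] - target0 * f)
    B = cal["I_with_at_2ns"] / (s + b * f)
    I_without = A * np.exp(-t / cal["tau_without_ns"])
    I_with = B * (np.exp(-t / cal["tau_with_ns"])
                  + b * np.exp(-t / cal["tau_transient_ns"]))
    return I_without, I_with


# ---------------------------------------------------------------------------
# Fixture suite


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(output_dir, seed: int = 0,
                      total_counts: int = 1_000_000) -> dict:
    """Write the full fixture suite and return (and save) its manifest.

    Emits the three absorption/emission spectrum pairs, one decay trace per
    published fitted-parameter set (plus the shared IRF), and a JSON
    manifest recording seeds, generating parameters, and file hashes.
    Regenerating with the manifest's seeds reproduces byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "total_counts": total_counts,
                      "spectra": [], "decays": [],
                      "fluorophore_presets": {
                          k: {kk: vv for kk, vv in v.items()}
                          for k, v in FLUOROPHORE_PRESETS.items()},
                      "scenario_presets": SCENARIO_PRESETS}

    for name in ("CP", "FAM", "TAMRA"):
        spec = fluorophore(name)
        for kind, spectrum in (("absorption", spec.absorption),
                               ("emission", spec.emission)):
            path = out / f"{name.lower()}_{kind}.csv"
            write_spectrum_csv(spectrum, path)
            manifest["spectra"].append({"file": path.name, "fluorophore": name,
                                        "kind": kind, "sha256": _sha256(path)})

    rng = np.random.default_rng(seed)
    irf_written = False
    for i, (name, entry) in enumerate(sorted(TABLE1_MODELS.items())):
        child_seed = int(rng.integers(2 ** 31))
        trace = simulate_tcspc(table1_model(name), total_counts=total_counts,
                               seed=child_seed,
                               excitation_nm=entry["excitation_nm"],
                               label=entry["label"])
        path = out / f"decay_{name}.csv"
        meta = out / f"decay_{name}.meta.json"
        irf_path = out / "irf.csv" if not irf_written else None
        write_decay_csv(trace, path, irf_path=irf_path, meta_path=meta)
        record = {"file": path.name, "meta": meta.name, "preset": name,
                  "seed": child_seed,
                  "components": entry["components"],
                  "sha256": _sha256(path)}
        if irf_path is not None:
            record["irf"] = irf_path.name
            irf_written = True
        manifest["decays"].append(record)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
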