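"""Energy-gap statistics, linear-response estimators and the Marcus rate.

The central object is the vertical energy gap ΔE = E_ox − E_red evaluated
along trajectories sampled on each redox surface. Under the linear
response approximation (Gaussian gap fluctuations with state-independent
variance) the reorganization energy follows from the two trajectory means,

    λ = ½(⟨ΔE⟩_red − ⟨ΔE⟩_ox),

with the companion driving-force estimator ΔG = ½(⟨ΔE⟩_red + ⟨ΔE⟩_ox) and
the variance diagnostic λ_var = σ²/(2 k_B T). Agreement between the
mean-based and variance-based λ is the standard self-consistency check of
the approximation. The nonadiabatic Marcus rate is

    k_ET = (|V|²/ħ) √(π / (λ k_B T)) · exp[−(λ + ΔG)² / (4 λ k_B T)],

with the diabatic coupling V; all energies in kcal/mol (per-mole ħ), so
the rate comes out in s⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .constants import DEFAULT_TEMPERATURE_K, HBAR_KCAL_S_MOL, KB_KCAL_MOL_K
from .errors import (
    DomainError,
    EmptyWindowError,
    StateLabelError,
    UndefinedCorrelationError,
)
from .structure_io import GapSeries

__all__ = [
    "GapStatistics",
    "MarcusInputs",
    "StrainResult",
    "gap_statistics",
    "reorganization_energy",
    "driving_force",
    "variance_lambda",
    "marcus_rate",
    "strain_energy",
    "gap_geometry_correlation",
]


@dataclass(frozen=True)
class GapStatistics:
    """Mean/SD of ΔE over the post-equilibration window of one trajectory.

    ``sd_delta_e`` uses the sample (n−1) convention: it estimates the
    width of the underlying gap distribution from a finite trajectory.
    """

    mean_delta_e: float  # kcal/mol
    sd_delta_e: float  # kcal/mol
    n_frames: int
    discarded_before: float  # ps
    state: str

    def __post_init__(self) -> None:
        if self.state not in ("oxidized", "reduced"):
            raise StateLabelError(f"bad state label {self.state!r}")
        if self.n_frames < 1:
            raise DomainError("gap statistics need at least one frame")
        if self.sd_delta_e < 0:
            raise DomainError("standard deviation cannot be negative")


@dataclass(frozen=True)
class MarcusInputs:
    """Inputs to the nonadiabatic Marcus rate, kcal/mol and K."""

    coupling_v: float
    lambda_: float
    delta_g: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise DomainError("reorganization energy must be positive")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")
        if self.coupling_v < 0:
            raise DomainError("|V| cannot be negative")


@dataclass(frozen=True)
class StrainResult:
    """Strain = energy at the in-protein geometry minus at the optimum."""

    e_in_protein_geometry: float
    e_optimized: float
    strain: float


def gap_statistics(series: GapSeries, discard_before: float = 0.0) -> GapStatistics:
    """Mean and sample SD of ΔE over frames with time ≥ ``discard_before``.

    The discard window drops the initial equilibration transient; with the
    default 0 the whole series is kept.
    """
    mask = series.times >= discard_before
    n = int(mask.sum())
    if n == 0:
        raise EmptyWindowError(
            f"no frames at or after {discard_before} ps "
            f"(series ends at {series.times[-1]} ps)"
        )
    kept = series.delta_e[mask]
    sd = float(np.std(kept, ddof=1)) if n > 1 else 0.0
    return GapStatistics(
        mean_delta_e=float(kept.mean()),
        sd_delta_e=sd,
        n_frames=n,
        discarded_before=float(discard_before),
        state=series.state,
    )


def _check_pair(stats_red: GapStatistics, stats_ox: GapStatistics) -> None:
    if stats_red.state != "reduced" or stats_ox.state != "oxidized":
        raise StateLabelError(
            f"expected (reduced, oxidized) statistics, got "
            f"({stats_red.state!r}, {stats_ox.state!r})"
        )


def reorganization_energy(stats_red: GapStatistics,
                          stats_ox: GapStatistics) -> float:
    """Linear-response λ = ½(⟨ΔE⟩_red − ⟨ΔE⟩_ox), kcal/mol."""
    _check_pair(stats_red, stats_ox)
    return 0.5 * (stats_red.mean_delta_e - stats_ox.mean_delta_e)


def driving_force(stats_red: GapStatistics, stats_ox: GapStatistics) -> float:
    """Linear-response ΔG = ½(⟨ΔE⟩_red + ⟨ΔE⟩_ox), kcal/mol.

    Sign convention: ΔG is the free-energy change of the ox→red vertical
    pair of states; with λ it satisfies λ + ΔG = ⟨ΔE⟩_red and
    λ − ΔG = −⟨ΔE⟩_ox exactly.
    """
    _check_pair(stats_red, stats_ox)
    return 0.5 * (stats_red.mean_delta_e + stats_ox.mean_delta_e)


def variance_lambda(stats: GapStatistics,
                    temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Variance-based reorganization energy λ_var = σ²/(2 k_B T).

    Coincides with the mean-based λ exactly when linear response holds;
    the gap between the two diagnoses its breakdown.
    """
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return stats.sd_delta_e ** 2 / (2.0 * KB_KCAL_MOL_K * temperature)


def marcus_rate(inputs: MarcusInputs) -> float:
    """Nonadiabatic electron-transfer rate k_ET in s⁻¹."""
    kbt = KB_KCAL_MOL_K * inputs.temperature
    prefactor = (inputs.coupling_v ** 2 / HBAR_KCAL_S_MOL) * np.sqrt(
        np.pi / (inputs.lambda_ * kbt)
    )
    exponent = -((inputs.lambda_ + inputs.delta_g) ** 2) / (4.0 * inputs.lambda_ * kbt)
    return float(prefactor * np.exp(exponent))


def strain_energy(e_in_protein_geometry: float, e_optimized: float) -> StrainResult:
    """Strain energy of a site held at its in-protein geometry.

    Both energies must be evaluated on the same potential-energy surface
    with the same reference. A negative strain is physically suspect (the
    "optimized" input is not a minimum) and raises a warning, not an
    error.
    """
    if not (np.isfinite(e_in_protein_geometry) and np.isfinite(e_optimized)):
        raise DomainError("strain energies must be finite")
    strain = e_in_protein_geometry - e_optimized
    if strain < 0:
        warnings.warn(
            f"negative strain {strain:.3f} kcal/mol: the reference energy is "
            "not a minimum on this surface", stacklevel=2,
        )
    return StrainResult(float(e_in_protein_geometry), float(e_optimized),
                        float(strain))


def gap_geometry_correlation(rmsd_values, gap_values) -> float:
    """Pearson r between a structural RMSD series and the gap series."""
    r_arr = np.asarray(rmsd_values, dtype=float)
    g_arr = np.asarray(gap_values, dtype=float)
    if r_arr.shape != g_arr.shape or r_arr.ndim != 1:
        raise DomainError("rmsd and gap series must be equal-length 1-D arrays")
    if len(r_arr) < 3:
        raise DomainError("correlation needs at least 3 points")
    if np.ptp(r_arr) == 0 or np.ptp(g_arr) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    return float(sp_stats.pearsonr(r_arr, g_arr).statistic)
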