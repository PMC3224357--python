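"""Filtered bremsstrahlung tube spectrum with aluminum half-value-layer tuning.

The unfiltered spectrum follows the Kramers form N(E) dE proportional to
(E_max - E)/E; an aluminum filter thickness is then solved numerically so the
air-kerma-weighted first half-value layer matches a target (7.4 mm Al for the
modelled 120 kV CT beam).  Characteristic tungsten lines are omitted; the
anode angle is carried as beam metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import materials as mat
from .errors import SpectrumInfeasibleError


@dataclass(frozen=True)
class XRaySpectrum:
    """Discrete photon-fluence spectrum, weights normalized to sum 1."""

    kvp: float
    energy_bins_keV: np.ndarray
    fluence_weights: np.ndarray
    hvl_al_mm: float
    anode_angle_deg: float
    filter_mm_al: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.fluence_weights, dtype=float)
        if np.any(w < 0):
            raise SpectrumInfeasibleError("negative fluence weights")
        total = w.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "fluence_weights", w / total)
        if self.energy_bins_keV.max() > self.kvp + 1e-9:
            raise SpectrumInfeasibleError("energy bin above the tube potential")

    @property
    def mean_energy_keV(self) -> float:
        return float(np.sum(self.energy_bins_keV * self.fluence_weights))

    def air_kerma_per_fluence(self) -> float:
        """Air kerma per unit fluence, keV cm2 / g."""
        air = mat.load_table("air")
        return float(np.sum(
            self.fluence_weights * self.energy_bins_keV
            * air.mu_en_rho(self.energy_bins_keV)
        ))

    @classmethod
    def monoenergetic(cls, energy_keV: float, anode_angle_deg: float = 7.0) -> "XRaySpectrum":
        """Single-line spectrum; its Al HVL is ln2 / mu_Al(E) by construction."""
        mu_al = mat.linear_mu("aluminum", energy_keV)
        return cls(
            kvp=energy_keV,
            energy_bins_keV=np.array([energy_keV], dtype=float),
            fluence_weights=np.array([1.0]),
            hvl_al_mm=10.0 * math.log(2.0) / float(mu_al),
            anode_angle_deg=anode_angle_deg,
        )


def _kerma_weights(energies: np.ndarray, fluence: np.ndarray) -> np.ndarray:
    air = mat.load_table("air")
    return fluence * energies * air.mu_en_rho(energies)


def hvl_al_mm(energies: np.ndarray, fluence: np.ndarray) -> float:
    """First aluminum half-value layer (mm) of a fluence spectrum, by air kerma."""
    mu_al = mat.linear_mu("aluminum", energies)  # 1/cm
    kw = _kerma_weights(energies, fluence)
    k0 = kw.sum()

    def transmitted(x_cm):
        return float(np.sum(kw * np.exp(-mu_al * x_cm))) / k0 - 0.5

    return 10.0 * brentq(transmitted, 0.0, 100.0, xtol=1e-10)


def build_spectrum(kvp: float, target_hvl_al_mm: float = 7.4,
                   anode_angle_deg: float = 7.0,
                   max_filter_mm: float = 60.0) -> XRaySpectrum:
    """Kramers spectrum at ``kvp`` filtered to the requested Al half-value layer.

    Raises :class:`SpectrumInfeasibleError` when the target HVL is below the
    unfiltered beam's HVL or unreachable within ``max_filter_mm`` of aluminum.
    """
    if not (40.0 <= kvp <= 150.0):
        raise SpectrumInfeasibleError(f"tube potential {kvp} kV outside supported 40-150 kV")
    if target_hvl_al_mm <= 0:
        raise SpectrumInfeasibleError("target HVL must be positive")

    energies = np.arange(5.0, kvp + 0.5, 1.0)
    energies = energies[energies <= kvp]
    kramers = (kvp - energies) / energies
    kramers = np.clip(kramers, 0.0, None)
    mu_al = mat.linear_mu("aluminum", energies)  # 1/cm

    def hvl_for_filter(t_mm: float) -> float:
        fluence = kramers * np.exp(-mu_al * t_mm / 10.0)
        return hvl_al_mm(energies, fluence)

    hvl_lo = hvl_for_filter(0.0)
    hvl_hi = hvl_for_filter(max_filter_mm)
    if not (hvl_lo <= target_hvl_al_mm <= hvl_hi):
        raise SpectrumInfeasibleError(
            f"target HVL {target_hvl_al_mm} mm Al unreachable at {kvp} kV "
            f"(achievable range {hvl_lo:.2f}-{hvl_hi:.2f} mm)"
        )

    t_mm = brentq(lambda t: hvl_for_filter(t) - target_hvl_al_mm, 0.0, max_filter_mm,
                  xtol=1e-8)
    fluence = kramers * np.exp(-mu_al * t_mm / 10.0)
    fluence = fluence / fluence.sum()
    achieved = hvl_al_mm(energies, fluence)
    if abs(achieved - target_hvl_al_mm) > 0.01 * target_hvl_al_mm:
        raise SpectrumInfeasibleError(
            f"HVL solver missed target: {achieved:.3f} vs {target_hvl_al_mm} mm"
        )
    return XRaySpectrum(
        kvp=kvp, energy_bins_keV=energies, fluence_weights=fluence,
        hvl_al_mm=achieved, anode_angle_deg=anode_angle_deg, filter_mm_al=t_mm,
    )
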