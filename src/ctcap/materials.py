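"""Photon interaction data for the transport engine.

Mass attenuation and mass energy-absorption coefficients are packaged as CSV
tables on the standard compilation energy grid (5-150 keV) and interpolated
log-log.  Soft tissue and lung are treated as water-equivalent media at
densities 1.04 and 0.26 g/cm3 respectively; at CT energies their coefficients
differ from water by a couple of percent, which is well inside the engine's
statistical resolution.

The incoherent (Compton) part of the linear attenuation coefficient is built
analytically from the total Klein-Nishina cross section per electron and the
medium's electron density; whatever remains of the total coefficient is
treated as locally absorbing (photoelectric, plus the small coherent part --
see docs/methods.md for the approximation ledger).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: classical electron radius, cm
R_E_CM = 2.8179403262e-13
#: Avogadro's number
N_AVOGADRO = 6.02214076e23
#: electron rest energy, keV
MEC2_KEV = 510.99895
#: 1 keV/g expressed in mGy
KEV_PER_G_TO_MGY = 1.602176634e-10

#: ratio of atomic number to mass number (electrons per amu) by table medium
Z_OVER_A = {
    "water": 0.55509,
    "air": 0.49919,
    "aluminum": 0.48181,
    "bone_cortical": 0.51478,
}

#: default mass densities, g/cm3
DENSITY_G_CM3 = {
    "water": 1.00,
    "air": 1.205e-3,
    "aluminum": 2.699,
    "bone_cortical": 1.92,
    "soft_tissue": 1.04,
    "lung": 0.26,
}

#: medium name -> packaged attenuation table
TABLE_FOR = {
    "water": "water",
    "air": "air",
    "aluminum": "aluminum",
    "bone_cortical": "bone_cortical",
    "soft_tissue": "water",
    "lung": "water",
}


@dataclass(frozen=True)
class AttenuationTable:
    """Log-log interpolated mass coefficients for one medium."""

    name: str
    energy_keV: np.ndarray
    mu_over_rho: np.ndarray      # cm2/g, total (with coherent)
    mu_en_over_rho: np.ndarray   # cm2/g, mass energy absorption

    def mu_rho(self, energy_keV) -> np.ndarray:
        return _loglog_interp(energy_keV, self.energy_keV, self.mu_over_rho)

    def mu_en_rho(self, energy_keV) -> np.ndarray:
        return _loglog_interp(energy_keV, self.energy_keV, self.mu_en_over_rho)


def _loglog_interp(x, xp, fp):
    x = np.asarray(x, dtype=float)
    out = np.exp(np.interp(np.log(x), np.log(xp), np.log(fp)))
    return out if out.shape else float(out)


@functools.lru_cache(maxsize=None)
def load_table(table: str) -> AttenuationTable:
    """Load a packaged attenuation table ('water', 'air', 'aluminum', 'bone_cortical')."""
    ref = resources.files("ctcap.data.attenuation").joinpath(f"{table}.csv")
    raw = np.genfromtxt(str(ref), delimiter=",", names=True)
    return AttenuationTable(
        name=table,
        energy_keV=np.asarray(raw["energy_keV"], dtype=float),
        mu_over_rho=np.asarray(raw["mu_over_rho_cm2_g"], dtype=float),
        mu_en_over_rho=np.asarray(raw["mu_en_over_rho_cm2_g"], dtype=float),
    )


def klein_nishina_total(energy_keV) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm2.

    Closed form for a free electron at rest; binding corrections are ignored
    (a percent-level effect at CT energies).
    """
    k = np.asarray(energy_keV, dtype=float) / MEC2_KEV
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    out = 2.0 * np.pi * R_E_CM**2 * (t1 + t2 - t3)
    return out if out.shape else float(out)


def linear_mu(medium: str, energy_keV) -> np.ndarray:
    """Total linear attenuation coefficient, 1/cm, for a named medium."""
    table = load_table(TABLE_FOR[medium])
    return DENSITY_G_CM3[medium] * table.mu_rho(energy_keV)


def linear_mu_incoherent(medium: str, energy_keV) -> np.ndarray:
    """Incoherent (Klein-Nishina) linear attenuation coefficient, 1/cm."""
    rho = DENSITY_G_CM3[medium]
    n_e = rho * N_AVOGADRO * Z_OVER_A[TABLE_FOR[medium]]
    mu_inc = n_e * klein_nishina_total(energy_keV)
    # guard: never exceed the tabulated total
    return np.minimum(mu_inc, linear_mu(medium, energy_keV))


@dataclass(frozen=True)
class MaterialGrid:
    """Materials discretized on a uniform energy grid for the transport kernel."""

    names: tuple
    e0_keV: float
    de_keV: float
    energies_keV: np.ndarray
    mu_tot: np.ndarray   # (n_materials, n_energies) 1/cm
    mu_inc: np.ndarray   # (n_materials, n_energies) 1/cm
    mu_maj: np.ndarray   # (n_energies,) majorant over materials

    def index(self, name: str) -> int:
        return self.names.index(name)


def build_material_grid(materials, e0_keV: float = 1.0, e_max_keV: float = 160.0,
                        de_keV: float = 0.5) -> MaterialGrid:
    """Tabulate linear coefficients for ``materials`` on a uniform energy grid.

    ``materials`` maps a material label to (density g/cm3, table name).
    """
    energies = np.arange(e0_keV, e_max_keV + de_keV / 2, de_keV)
    names = tuple(materials)
    mu_tot = np.empty((len(names), energies.size))
    mu_inc = np.empty_like(mu_tot)
    for i, name in enumerate(names):
        rho, tab = materials[name]
        table = load_table(tab)
        mu_tot[i] = rho * table.mu_rho(energies)
        n_e = rho * N_AVOGADRO * Z_OVER_A[tab]
        mu_inc[i] = np.minimum(n_e * klein_nishina_total(energies), mu_tot[i])
    return MaterialGrid(
        names=names, e0_keV=e0_keV, de_keV=de_keV, energies_keV=energies,
        mu_tot=mu_tot, mu_inc=mu_inc, mu_maj=mu_tot.max(axis=0),
    )
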