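"""Organ-dose Monte Carlo for a CAP scan: four projections per axial slice.

A helical chest-abdomen-pelvis acquisition is modelled as contiguous axial
slices, each exposed from four directions (AP, PA, RLAT, LLAT) by a parallel
beam collimated to the slice; the summed axial dose is converted to helical
dose by dividing by the pitch.  Absolute normalization is the free-in-air
entrance air kerma per projection and slice.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import materials as mat
from ._kernel import transport_batches
from .errors import BatchingError, ConfigurationError, InvalidPitchError
from .phantoms import PhantomGeometry, REST_OF_BODY
from .spectrum import XRaySpectrum, build_spectrum

PROJECTIONS = ("AP", "PA", "RLAT", "LLAT")

#: packaged default entrance air kerma, mGy per projection per slice.  This is
#: the engine's free normalization, calibrated once so the reference phantom's
#: CAP effective dose lands on the anthropomorphic-measurement scale
#: (~13 mSv); see docs/methods.md.
DEFAULT_ENTRANCE_AIR_KERMA_MGY = 13.33


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition settings for one CAP scan."""

    kvp: float = 120.0
    pitch: float = 1.375
    slice_thickness_cm: float = 1.0
    scan_start_cm: float = 0.0
    scan_end_cm: float = 70.0
    entrance_air_kerma_mGy: float = DEFAULT_ENTRANCE_AIR_KERMA_MGY
    n_photons_per_slice: int = 10_000
    projections: tuple = PROJECTIONS
    n_batches: int = 10
    cutoff_keV: float = 5.0
    target_hvl_al_mm: float = 7.4
    anode_angle_deg: float = 7.0

    def __post_init__(self):
        if self.pitch <= 0:
            raise InvalidPitchError(f"pitch must be > 0, got {self.pitch}")
        if self.scan_end_cm <= self.scan_start_cm:
            raise ConfigurationError("scan_end must exceed scan_start")
        if self.n_photons_per_slice < 1:
            raise ConfigurationError("n_photons_per_slice must be >= 1")
        if not self.projections:
            raise ConfigurationError("at least one projection required")
        for p in self.projections:
            if p not in PROJECTIONS:
                raise ConfigurationError(f"unknown projection {p!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class OrganDoseTable:
    """Per-organ mean absorbed dose (mGy) with one-sigma statistical uncertainty."""

    rows: dict  # organ -> (dose_mGy, sigma_mGy)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for organ, (dose, sigma) in self.rows.items():
            if dose < 0 or sigma < 0:
                raise ConfigurationError(f"negative dose/uncertainty for {organ!r}")

    @property
    def organs(self) -> tuple:
        return tuple(self.rows)

    def dose(self, organ: str) -> float:
        return self.rows[organ][0]

    def sigma(self, organ: str) -> float:
        return self.rows[organ][1]

    def scaled(self, factor: float, note: str | None = None) -> "OrganDoseTable":
        prov = dict(self.provenance)
        if note:
            prov["rescales"] = list(prov.get("rescales", [])) + [note]
        return OrganDoseTable(
            rows={o: (d * factor, s * factor) for o, (d, s) in self.rows.items()},
            provenance=prov,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": list(self.rows),
                "dose_mGy": [d for d, _ in self.rows.values()],
                "sigma_mGy": [s for _, s in self.rows.values()],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "rows": {o: {"dose_mGy": d, "sigma_mGy": s} for o, (d, s) in self.rows.items()},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "OrganDoseTable":
        df = pd.read_csv(path)
        return cls(rows={r.organ: (float(r.dose_mGy), float(r.sigma_mGy))
                         for r in df.itertuples()})


# ---------------------------------------------------------------------------
# geometry compilation

def _compile_geometry(phantom: PhantomGeometry):
    organ_names = list(phantom.organ_names)
    name_to_id = {n: i for i, n in enumerate(organ_names)}

    mat_labels = sorted(phantom.materials)
    grid = mat.build_material_grid(
        {label: phantom.materials[label] for label in mat_labels}
    )

    bodies = np.array(
        [[b.cx, b.cy, b.a, b.b, b.zmin, b.zmax] for b in phantom.bodies], dtype=float
    )
    body_mat = np.array([grid.index(b.material) for b in phantom.bodies], dtype=np.int64)
    org_c = np.array([p.center for p in phantom.organs], dtype=float)
    org_ax = np.array([p.half_axes for p in phantom.organs], dtype=float)
    org_mat = np.array([grid.index(p.material) for p in phantom.organs], dtype=np.int64)
    org_id = np.array([name_to_id[p.name] for p in phantom.organs], dtype=np.int64)
    bb_lo, bb_hi = phantom.bounding_box()

    masses = np.array([phantom.organ_mass_g(n) for n in organ_names]
                      + [phantom.rest_of_body_mass_g])
    return {
        "organ_names": organ_names, "grid": grid, "bodies": bodies,
        "body_mat": body_mat, "org_c": org_c, "org_ax": org_ax,
        "org_mat": org_mat, "org_id": org_id, "bb_lo": bb_lo, "bb_hi": bb_hi,
        "masses_g": masses,
    }


def _beam_geometry(phantom: PhantomGeometry, projection: str):
    """Source axis, direction sign, start plane and transverse extent."""
    bb_lo, bb_hi = phantom.bounding_box()
    if projection == "AP":        # enters anterior (+y), travels -y
        return 1, -1.0, bb_hi[1], bb_lo[0], bb_hi[0]
    if projection == "PA":
        return 1, +1.0, bb_lo[1], bb_lo[0], bb_hi[0]
    if projection == "RLAT":      # enters the patient-right (-x) side
        return 0, +1.0, bb_lo[0], bb_lo[1], bb_hi[1]
    if projection == "LLAT":
        return 0, -1.0, bb_hi[0], bb_lo[1], bb_hi[1]
    raise ConfigurationError(f"unknown projection {projection!r}")


def derive_seed(seed: int, slice_index: int, projection_index: int) -> int:
    """Deterministic per-(slice, projection) substream seed."""
    ss = np.random.SeedSequence((int(seed), int(slice_index), int(projection_index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# public operations

def transport_photons(phantom: PhantomGeometry, spectrum: XRaySpectrum,
                      projection: str, slice_z: float, slice_thickness: float,
                      entrance_air_kerma: float, n_photons: int, seed: int,
                      n_batches: int = 10, cutoff_keV: float = 5.0,
                      primary_only: bool = False,
                      _compiled=None) -> OrganDoseTable:
    """Transport one slice/projection exposure; returns per-organ doses in mGy.

    ``entrance_air_kerma`` (mGy) is the free-in-air kerma the sampled fluence
    delivers at the entrance plane; doses are normalized to it exactly.
    """
    if n_photons < n_batches or n_photons < 1:
        raise BatchingError(
            f"n_photons={n_photons} incompatible with {n_batches} batches")
    zmin, zmax = phantom.z_extent
    if slice_z + slice_thickness <= zmin or slice_z >= zmax:
        raise ConfigurationError(
            f"slice at z={slice_z} outside phantom axial extent [{zmin}, {zmax}]")

    comp = _compiled if _compiled is not None else _compile_geometry(phantom)
    grid = comp["grid"]
    axis, sign, start, t_lo, t_hi = _beam_geometry(phantom, projection)

    e_vals = np.asarray(spectrum.energy_bins_keV, dtype=float)
    e_cdf = np.cumsum(np.asarray(spectrum.fluence_weights, dtype=float))
    e_cdf /= e_cdf[-1]

    per_batch = n_photons // n_batches
    n_actual = per_batch * n_batches
    seeds = np.random.SeedSequence(int(seed)).generate_state(n_batches, dtype=np.uint64)

    edep, emitted = transport_batches(
        per_batch, seeds,
        axis, sign, start, t_lo, t_hi, float(slice_z), float(slice_z + slice_thickness),
        e_cdf, e_vals,
        comp["bodies"], comp["body_mat"], comp["org_c"], comp["org_ax"],
        comp["org_mat"], comp["org_id"], len(comp["organ_names"]),
        comp["bb_lo"], comp["bb_hi"],
        grid.e0_keV, grid.de_keV, grid.mu_tot, grid.mu_inc, grid.mu_maj,
        float(cutoff_keV), primary_only,
    )

    # fluence (photons/cm2) delivering the stated entrance air kerma
    kerma_per_fluence = spectrum.air_kerma_per_fluence() * mat.KEV_PER_G_TO_MGY
    fluence = entrance_air_kerma / kerma_per_fluence
    area = (t_hi - t_lo) * slice_thickness
    real_photons = fluence * area

    masses = comp["masses_g"]
    # per-batch estimate of the full-exposure dose
    dose_b = edep * (real_photons / per_batch) * mat.KEV_PER_G_TO_MGY / masses
    dose = dose_b.mean(axis=0)
    sigma = dose_b.std(axis=0, ddof=1) / math.sqrt(n_batches)

    names = comp["organ_names"] + [REST_OF_BODY]
    rows = {n: (float(dose[i]), float(sigma[i])) for i, n in enumerate(names)}
    prov = {
        "seed": int(seed), "projection": projection, "slice_z_cm": float(slice_z),
        "n_photons": int(n_actual), "n_batches": int(n_batches),
        "entrance_air_kerma_mGy": float(entrance_air_kerma),
        "energy_emitted_keV": float(emitted.sum()),
        "energy_deposited_keV": float(edep.sum()),
        "primary_only": bool(primary_only),
    }
    return OrganDoseTable(rows=rows, provenance=prov)


def simulate_axial_scan(phantom: PhantomGeometry, protocol: ScanProtocol,
                        seed: int) -> OrganDoseTable:
    """Simulate the full axial scan: contiguous slices x four projections.

    The per-slice photon budget is split equally over the projections, each run
    with the same entrance air kerma; organ doses sum over slices and
    projections, uncertainties combine in quadrature.  Per-slice seeds derive
    deterministically from (seed, slice index, projection index).
    """
    zmin, zmax = phantom.z_extent
    if protocol.scan_end_cm <= zmin or protocol.scan_start_cm >= zmax:
        raise ConfigurationError("scan range does not overlap the phantom")

    spectrum = build_spectrum(protocol.kvp, protocol.target_hvl_al_mm,
                              protocol.anode_angle_deg)
    comp = _compile_geometry(phantom)

    n_slices = int(math.ceil(
        (protocol.scan_end_cm - protocol.scan_start_cm) / protocol.slice_thickness_cm
        - 1e-9))
    n_proj = len(protocol.projections)
    n_per_proj = max(protocol.n_photons_per_slice // n_proj, protocol.n_batches)

    names = comp["organ_names"] + [REST_OF_BODY]
    total = np.zeros(len(names))
    var = np.zeros(len(names))
    emitted = 0.0
    deposited = 0.0
    for i_slice in range(n_slices):
        z0 = protocol.scan_start_cm + i_slice * protocol.slice_thickness_cm
        for i_proj, proj in enumerate(protocol.projections):
            table = transport_photons(
                phantom, spectrum, proj, z0, protocol.slice_thickness_cm,
                protocol.entrance_air_kerma_mGy, n_per_proj,
                seed=derive_seed(seed, i_slice, i_proj),
                n_batches=protocol.n_batches, cutoff_keV=protocol.cutoff_keV,
                _compiled=comp,
            )
            for j, n in enumerate(names):
                d, s = table.rows[n]
                total[j] += d
                var[j] += s * s
            emitted += table.provenance["energy_emitted_keV"]
            deposited += table.provenance["energy_deposited_keV"]

    rows = {n: (float(total[j]), float(math.sqrt(var[j]))) for j, n in enumerate(names)}
    prov = {
        "seed": int(seed), "protocol": protocol.fingerprint(),
        "n_slices": n_slices, "photons_per_slice_per_projection": n_per_proj,
        "mode": "axial", "energy_emitted_keV": emitted,
        "energy_deposited_keV": deposited,
        "height_cm": phantom.spec.height_cm, "weight_kg": phantom.spec.weight_kg,
    }
    return OrganDoseTable(rows=rows, provenance=prov)


def axial_to_helical(doses: OrganDoseTable, pitch: float) -> OrganDoseTable:
    """Convert axial-scan doses to helical by dividing dose and sigma by pitch."""
    if pitch <= 0:
        raise InvalidPitchError(f"pitch must be > 0, got {pitch}")
    out = doses.scaled(1.0 / pitch)
    prov = dict(out.provenance)
    prov["mode"] = "helical"
    prov["pitch"] = float(pitch)
    return replace(out, provenance=prov)


def apply_calibration(doses: OrganDoseTable, factor: float) -> OrganDoseTable:
    """Uniform multiplicative cross-calibration (e.g. against reference CT software)."""
    if factor <= 0:
        raise ConfigurationError(f"calibration factor must be > 0, got {factor}")
    out = doses.scaled(factor)
    prov = dict(out.provenance)
    prov["calibration_factors"] = list(prov.get("calibration_factors", [])) + [float(factor)]
    return replace(out, provenance=prov)
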