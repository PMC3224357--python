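"""Monte Carlo transport engine: analytic oracles, symmetries, normalization."""

import math

import numpy as np
import pytest

from ctcap import (BodySpec, OrganDoseTable, ScanProtocol, XRaySpectrum,
                   apply_calibration, axial_to_helical, scale_reference_phantom,
                   simulate_axial_scan, transport_photons)
from ctcap.errors import BatchingError, ConfigurationError, InvalidPitchError
from ctcap.materials import linear_mu
from ctcap.phantoms import BodyRegion, OrganPart, PhantomGeometry
from ctcap.transport import derive_seed

WATER = {"water": (1.0, "water"), "soft_tissue": (1.04, "water"),
         "lung": (0.26, "water"), "bone": (1.92, "bone_cortical")}


def _slab_phantom(depths, disk_half_thickness=0.25):
    """Water block entered from +y (AP); thin scoring disks at given depths."""
    body = BodyRegion(name="trunk", cx=0, cy=0, a=40.0, b=15.0, zmin=0.0,
                      zmax=20.0, material="water")
    organs = tuple(
        OrganPart(name=f"disk_{i}", center=(0.0, 15.0 - d, 10.0),
                  half_axes=(30.0, disk_half_thickness, 8.0), material="water")
        for i, d in enumerate(depths)
    )
    return PhantomGeometry(
        spec=BodySpec(height_cm=170, weight_kg=70), bodies=(body,), organs=organs,
        materials=WATER, reference_height_cm=170, reference_weight_kg=70,
    )


def _symmetric_phantom():
    """Elliptical body with one midline organ equidistant from front and back."""
    body = BodyRegion(name="trunk", cx=0, cy=0, a=15.0, b=10.0, zmin=0.0,
                      zmax=20.0, material="soft_tissue")
    organ = OrganPart(name="core", center=(0.0, 0.0, 10.0),
                      half_axes=(3.0, 3.0, 3.0), material="soft_tissue")
    return PhantomGeometry(
        spec=BodySpec(height_cm=170, weight_kg=70), bodies=(body,), organs=(organ,),
        materials=WATER, reference_height_cm=170, reference_weight_kg=70,
    )


class TestSlabOracle:
    def test_primary_only_transmission_matches_beer_lambert(self):
        """Dose vs depth in primary-only mode follows exp(-mu d) at three energies."""
        depths = (3.0, 6.0, 10.0)
        phantom = _slab_phantom(depths)
        for energy in (40.0, 60.0, 100.0):
            mu = float(linear_mu("water", energy))
            spectrum = XRaySpectrum.monoenergetic(energy)
            table = transport_photons(
                phantom, spectrum, "AP", slice_z=9.0, slice_thickness=2.0,
                entrance_air_kerma=10.0, n_photons=400_000, seed=11,
                primary_only=True)
            doses = [table.dose(f"disk_{i}") for i in range(len(depths))]
            sigmas = [table.sigma(f"disk_{i}") for i in range(len(depths))]
            for i, j in ((0, 1), (0, 2), (1, 2)):
                ratio = doses[i] / doses[j]
                expected = math.exp(-mu * (depths[i] - depths[j]))
                sd = ratio * math.hypot(sigmas[i] / doses[i], sigmas[j] / doses[j])
                assert abs(ratio - expected) < 3 * sd + 1e-12, (energy, i, j)


class TestTransportProperties:
    def test_ap_pa_symmetry_for_midline_organ(self, ct_spectrum):
        phantom = _symmetric_phantom()
        kwargs = dict(slice_z=8.5, slice_thickness=3.0, entrance_air_kerma=10.0,
                      n_photons=120_000)
        ap = transport_photons(phantom, ct_spectrum, "AP", seed=3, **kwargs)
        pa = transport_photons(phantom, ct_spectrum, "PA", seed=4, **kwargs)
        sd = math.hypot(ap.sigma("core"), pa.sigma("core"))
        assert abs(ap.dose("core") - pa.dose("core")) < 3 * sd

    def test_kerma_linearity_with_same_seed(self, ct_spectrum):
        phantom = _symmetric_phantom()
        kwargs = dict(slice_z=9.0, slice_thickness=2.0, n_photons=20_000, seed=5)
        one = transport_photons(phantom, ct_spectrum, "AP", entrance_air_kerma=10.0, **kwargs)
        two = transport_photons(phantom, ct_spectrum, "AP", entrance_air_kerma=20.0, **kwargs)
        for organ in one.rows:
            assert two.dose(organ) == pytest.approx(2.0 * one.dose(organ), rel=1e-12)

    def test_seeded_determinism(self, ct_spectrum):
        phantom = _symmetric_phantom()
        kwargs = dict(slice_z=9.0, slice_thickness=2.0, entrance_air_kerma=10.0,
                      n_photons=20_000, seed=9)
        a = transport_photons(phantom, ct_spectrum, "AP", **kwargs)
        b = transport_photons(phantom, ct_spectrum, "AP", **kwargs)
        assert a.rows == b.rows

    def test_energy_conservation(self, ct_spectrum):
        phantom = _symmetric_phantom()
        for seed in (1, 2, 3):
            t = transport_photons(phantom, ct_spectrum, "RLAT", slice_z=9.0,
                                  slice_thickness=2.0, entrance_air_kerma=10.0,
                                  n_photons=30_000, seed=seed)
            assert (t.provenance["energy_deposited_keV"]
                    <= t.provenance["energy_emitted_keV"] + 1e-6)

    def test_uncertainty_shrinks_with_photon_count(self, ct_spectrum):
        """One-sigma uncertainty scales roughly as 1/sqrt(n) over a 4x ladder."""
        phantom = _symmetric_phantom()
        kwargs = dict(slice_z=9.0, slice_thickness=2.0, entrance_air_kerma=10.0,
                      n_batches=20)
        lo = transport_photons(phantom, ct_spectrum, "AP", n_photons=40_000,
                               seed=21, **kwargs)
        hi = transport_photons(phantom, ct_spectrum, "AP", n_photons=160_000,
                               seed=22, **kwargs)
        ratio = lo.sigma("core") / hi.sigma("core")
        assert 1.3 < ratio < 3.1

    def test_photon_batching_errors(self, ct_spectrum):
        phantom = _symmetric_phantom()
        with pytest.raises(BatchingError):
            transport_photons(phantom, ct_spectrum, "AP", slice_z=9.0,
                              slice_thickness=2.0, entrance_air_kerma=10.0,
                              n_photons=0, seed=1)
        with pytest.raises(BatchingError):
            transport_photons(phantom, ct_spectrum, "AP", slice_z=9.0,
                              slice_thickness=2.0, entrance_air_kerma=10.0,
                              n_photons=5, seed=1, n_batches=10)

    def test_slice_outside_phantom_rejected(self, ct_spectrum):
        phantom = _symmetric_phantom()
        with pytest.raises(ConfigurationError):
            transport_photons(phantom, ct_spectrum, "AP", slice_z=50.0,
                              slice_thickness=1.0, entrance_air_kerma=10.0,
                              n_photons=1000, seed=1)


class TestAxialScan:
    def test_single_slice_single_projection_reduces_to_transport(self, ct_spectrum,
                                                                  reference_phantom):
        protocol = ScanProtocol(scan_start_cm=40.0, scan_end_cm=41.0,
                                projections=("AP",), n_photons_per_slice=8_000,
                                entrance_air_kerma_mGy=10.0)
        scan = simulate_axial_scan(reference_phantom, protocol, seed=77)
        direct = transport_photons(
            reference_phantom, ct_spectrum, "AP", slice_z=40.0, slice_thickness=1.0,
            entrance_air_kerma=10.0, n_photons=8_000, seed=derive_seed(77, 0, 0))
        for organ, (dose, sigma) in direct.rows.items():
            assert scan.dose(organ) == pytest.approx(dose, rel=1e-12)
            assert scan.sigma(organ) == pytest.approx(sigma, rel=1e-12)

    def test_out_of_view_brain_gets_scatter_only(self, reference_phantom):
        """A CAP (trunk) scan leaves the brain with under 5% of the lung dose."""
        trunk = reference_phantom.trunk
        protocol = ScanProtocol(scan_start_cm=trunk.zmin, scan_end_cm=trunk.zmax,
                                n_photons_per_slice=10_000)
        scan = simulate_axial_scan(reference_phantom, protocol, seed=13)
        assert scan.dose("brain") < 0.05 * scan.dose("lung")

    def test_dose_decreases_with_weight_at_fixed_height(self):
        """Central-organ dose falls as the phantom gets heavier (same exposure)."""
        doses = []
        for weight in (55.0, 110.0):
            phantom = scale_reference_phantom(BodySpec(175.0, weight))
            trunk = phantom.trunk
            protocol = ScanProtocol(scan_start_cm=trunk.zmin, scan_end_cm=trunk.zmax,
                                    n_photons_per_slice=8_000)
            scan = simulate_axial_scan(phantom, protocol, seed=29)
            doses.append(scan.dose("colon"))
        assert doses[1] < doses[0]


class TestRescaling:
    def _table(self):
        return OrganDoseTable(rows={"liver": (11.0, 0.55), "lung": (2.0, 0.1)})

    def test_axial_to_helical_divides_by_pitch(self):
        out = axial_to_helical(self._table(), 1.375)
        assert out.dose("liver") == pytest.approx(8.0)
        assert out.sigma("liver") == pytest.approx(0.4)

    def test_pitch_one_is_identity_and_zero_rejected(self):
        assert axial_to_helical(self._table(), 1.0).rows == self._table().rows
        with pytest.raises(InvalidPitchError):
            axial_to_helical(self._table(), 0.0)

    def test_calibration_round_trip(self):
        t = self._table()
        assert apply_calibration(t, 1.15).dose("liver") == pytest.approx(12.65)
        back = apply_calibration(apply_calibration(t, 2.0), 0.5)
        assert back.dose("liver") == pytest.approx(t.dose("liver"), rel=1e-12)
        with pytest.raises(ConfigurationError):
            apply_calibration(t, 0.0)
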