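"""Scalable mathematical hermaphrodite phantoms and the design population.

The reference anatomy is a MIRD-style stylized body: trunk, head and legs as
elliptical cylinders filled with soft tissue, organs as ellipsoids (lungs at
low density).  Any (height, weight) is reached by scaling the reference:
longitudinal dimensions by ``height / reference height`` and every transverse
dimension by ``sqrt((weight/ref_weight) / (height/ref_height))``, so total
body volume -- and hence mass at fixed density -- scales exactly as
``weight / ref_weight`` while trunk cross-sectional area scales as
weight per unit height.

The design population is a deterministic grid: evenly spaced heights crossed
with evenly spaced BMI levels, each (height, BMI) converted to a
(height, weight) pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .body import BodySpec
from .errors import ConfigurationError

#: the 12 dosimetered organ entries (one per measured row) -- multi-part
#: organs (lung, uterus/testes) repeat a name in the geometry part list.
TABLE_ORGANS = (
    "adrenals_gall_bladder", "brain", "colon", "esophagus", "eye", "kidney",
    "liver", "lung", "pancreas", "thymus", "thyroid", "uterus_testes",
)
REST_OF_BODY = "rest_of_body"

#: organs seated in the head region, exempt from the trunk-containment check
HEAD_ORGANS = frozenset({"brain", "eye"})


@dataclass(frozen=True)
class BodyRegion:
    """Elliptical cylinder: ((x-cx)/a)^2 + ((y-cy)/b)^2 <= 1, zmin <= z <= zmax."""

    name: str
    cx: float
    cy: float
    a: float
    b: float
    zmin: float
    zmax: float
    material: str = "soft_tissue"

    @property
    def volume_cm3(self) -> float:
        return math.pi * self.a * self.b * (self.zmax - self.zmin)


@dataclass(frozen=True)
class OrganPart:
    """One ellipsoidal part of an organ."""

    name: str
    center: tuple  # (cx, cy, cz) cm
    half_axes: tuple  # (ax, ay, az) cm
    material: str

    @property
    def volume_cm3(self) -> float:
        ax, ay, az = self.half_axes
        return 4.0 / 3.0 * math.pi * ax * ay * az


@dataclass(frozen=True)
class PhantomGeometry:
    """Scaled stylized phantom: body regions, organ parts, material map."""

    spec: BodySpec
    bodies: tuple            # of BodyRegion
    organs: tuple            # of OrganPart, scoring-priority order
    materials: dict          # label -> (density g/cm3, attenuation table name)
    reference_height_cm: float
    reference_weight_kg: float
    provenance: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    @property
    def organ_names(self) -> tuple:
        seen = []
        for part in self.organs:
            if part.name not in seen:
                seen.append(part.name)
        return tuple(seen)

    def organ_mass_g(self, name: str) -> float:
        mass = sum(
            self.materials[p.material][0] * p.volume_cm3
            for p in self.organs if p.name == name
        )
        if mass <= 0:
            raise ConfigurationError(f"organ {name!r} has no mass")
        return mass

    @property
    def rest_of_body_mass_g(self) -> float:
        # body tissue mass minus the tissue displaced by organ volumes
        body_mass = sum(self.materials[b.material][0] * b.volume_cm3 for b in self.bodies)
        displaced = sum(
            self.materials[self._body_material_at(p)][0] * p.volume_cm3 for p in self.organs
        )
        return body_mass - displaced

    def _body_material_at(self, part: OrganPart) -> str:
        cx, cy, cz = part.center
        for b in self.bodies:
            if ((cx - b.cx) / b.a) ** 2 + ((cy - b.cy) / b.b) ** 2 <= 1.0 and b.zmin <= cz <= b.zmax:
                return b.material
        return "soft_tissue"

    @property
    def total_mass_kg(self) -> float:
        body_mass = sum(self.materials[b.material][0] * b.volume_cm3 for b in self.bodies)
        # organs replace body tissue: add (rho_organ - rho_body) * V
        delta = sum(
            (self.materials[p.material][0] - self.materials[self._body_material_at(p)][0])
            * p.volume_cm3
            for p in self.organs
        )
        return (body_mass + delta) / 1000.0

    @property
    def trunk(self) -> BodyRegion:
        for b in self.bodies:
            if b.name == "trunk":
                return b
        raise ConfigurationError("phantom has no trunk region")

    @property
    def z_extent(self) -> tuple:
        return (min(b.zmin for b in self.bodies), max(b.zmax for b in self.bodies))

    def bounding_box(self, margin: float = 0.5) -> tuple:
        lo = np.array([
            min(b.cx - b.a for b in self.bodies) - margin,
            min(b.cy - b.b for b in self.bodies) - margin,
            min(b.zmin for b in self.bodies) - margin,
        ])
        hi = np.array([
            max(b.cx + b.a for b in self.bodies) + margin,
            max(b.cy + b.b for b in self.bodies) + margin,
            max(b.zmax for b in self.bodies) + margin,
        ])
        return lo, hi


class ExtrapolationWarning(UserWarning):
    """Body spec outside the plausibility envelope of the scaling model."""


def load_reference_geometry() -> dict:
    """Parse the packaged reference phantom description."""
    ref = resources.files("ctcap.data").joinpath("reference_phantom.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def scale_reference_phantom(spec: BodySpec, reference: dict | None = None,
                            bmi_envelope: tuple = (15.0, 45.0)) -> PhantomGeometry:
    """Scale the packaged reference anatomy to ``spec``.

    Outside the BMI plausibility envelope an :class:`ExtrapolationWarning` is
    issued (not fatal) and recorded in the geometry's provenance.
    """
    raw = reference if reference is not None else load_reference_geometry()
    h_ref = float(raw["reference"]["height_cm"])
    w_ref = float(raw["reference"]["weight_kg"])

    sz = spec.height_cm / h_ref
    st = math.sqrt((spec.weight_kg / w_ref) / sz)

    provenance = {"scale_longitudinal": sz, "scale_transverse": st}
    if not (bmi_envelope[0] <= spec.bmi <= bmi_envelope[1]):
        msg = (f"BMI {spec.bmi:.1f} outside plausibility envelope "
               f"[{bmi_envelope[0]}, {bmi_envelope[1]}]; geometry extrapolated")
        warnings.warn(msg, ExtrapolationWarning, stacklevel=2)
        provenance["extrapolation"] = msg

    bodies = tuple(
        BodyRegion(
            name=b["name"], cx=st * b["cx"], cy=st * b["cy"],
            a=st * b["a"], b=st * b["b"],
            zmin=sz * b["zmin"], zmax=sz * b["zmax"],
            material=b.get("material", "soft_tissue"),
        )
        for b in raw["bodies"]
    )
    organs = tuple(
        OrganPart(
            name=o["name"],
            center=(st * o["cx"], st * o["cy"], sz * o["cz"]),
            half_axes=(st * o["ax"], st * o["ay"], sz * o["az"]),
            material=o["material"],
        )
        for o in raw["organs"]
    )
    materials = {
        name: (float(m["density_g_cm3"]), m["table"])
        for name, m in raw["materials"].items()
    }
    return PhantomGeometry(
        spec=spec, bodies=bodies, organs=organs, materials=materials,
        reference_height_cm=h_ref, reference_weight_kg=w_ref,
        provenance=provenance,
    )


@dataclass(frozen=True)
class PopulationGrid:
    """Deterministic height x BMI design grid converted to (height, weight) pairs."""

    members: tuple  # of BodySpec
    bmi_min: float
    bmi_max: float
    height_min: float
    height_max: float

    @property
    def weight_min(self) -> float:
        return min(m.weight_kg for m in self.members)

    @property
    def weight_max(self) -> float:
        return max(m.weight_kg for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "height_cm": [m.height_cm for m in self.members],
                "weight_kg": [m.weight_kg for m in self.members],
                "bmi": [m.bmi for m in self.members],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationGrid":
        df = pd.read_csv(path)
        members = tuple(
            BodySpec(height_cm=row.height_cm, weight_kg=row.weight_kg)
            for row in df.itertuples()
        )
        return cls(
            members=members,
            bmi_min=min(m.bmi for m in members), bmi_max=max(m.bmi for m in members),
            height_min=min(m.height_cm for m in members),
            height_max=max(m.height_cm for m in members),
        )


#: default design ranges: BMI 18 (underweight) to 36 (obese); heights spanning
#: 5 ft 1 in to 6 ft 7 in.
DEFAULT_BMI_RANGE = (18.0, 36.0)
DEFAULT_HEIGHT_RANGE_CM = (154.94, 200.66)
#: the corresponding weight span, 95-317 lb in kg
DEFAULT_WEIGHT_SPAN_KG = (43.0913, 143.7888)


def build_population(bmi_min: float = DEFAULT_BMI_RANGE[0],
                     bmi_max: float = DEFAULT_BMI_RANGE[1],
                     height_min: float = DEFAULT_HEIGHT_RANGE_CM[0],
                     height_max: float = DEFAULT_HEIGHT_RANGE_CM[1],
                     n_per_axis: int = 10,
                     max_weight_kg: float = 250.0) -> PopulationGrid:
    """Build the deterministic n x n height/BMI design population.

    The default 10 x 10 configuration yields the 100-phantom design spanning
    BMI 18-36 and heights 154.94-200.66 cm.
    """
    if not (bmi_min < bmi_max):
        raise ConfigurationError("bmi_min must be < bmi_max")
    if not (height_min < height_max):
        raise ConfigurationError("height_min must be < height_max")
    if n_per_axis < 2:
        raise ConfigurationError("n_per_axis must be >= 2")

    heights = np.linspace(height_min, height_max, n_per_axis)
    bmis = np.linspace(bmi_min, bmi_max, n_per_axis)
    members = []
    for h in heights:
        for b in bmis:
            spec = BodySpec.from_bmi(height_cm=float(h), bmi=float(b))
            if spec.weight_kg <= 0 or spec.weight_kg > max_weight_kg:
                raise ConfigurationError(
                    f"grid produces non-physical weight {spec.weight_kg:.1f} kg "
                    f"at height {h:.1f} cm, BMI {b:.1f}"
                )
            members.append(spec)
    return PopulationGrid(
        members=tuple(members), bmi_min=bmi_min, bmi_max=bmi_max,
        height_min=height_min, height_max=height_max,
    )
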