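"""Machine-side dose chain and effective-dose assembly.

The machine-side chain is the standard CTDI arithmetic:

    CTDI_w   = (2/3) CTDI_periphery + (1/3) CTDI_center          [mGy]
    CTDI_vol = CTDI_w / pitch                                    [mGy]
    DLP      = CTDI_vol x scan length                            [mGy cm]
    E        = DLP x CC                                          [mSv]

with CC the body-region conversion coefficient (0.015 mSv/(mGy cm) for a
chest-abdomen-pelvis scan).

The phantom-side assembly weights organ absorbed doses by ICRP-103 tissue
weighting factors; the default scheme is the measured-organ subset with a
four-organ remainder (pancreas, uterus, kidney, adrenals/gall bladder) at
w = 0.12 applied to the arithmetic mean of the remainder doses.  Those
factors sum to 0.53, not 1.0 -- the scheme covers only the dosimetered
organs and is kept as-is to stay on the anthropomorphic measurement scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import (IncompleteTableError, InvalidMeasurementError,
                     InvalidPitchError, UndefinedComparisonError)
from .transport import OrganDoseTable

# ---------------------------------------------------------------------------
# organ-name canonicalization

_ALIASES = {
    "uterus": "uterus_testes",
    "testes": "uterus_testes",
    "uterus/testes": "uterus_testes",
    "adrenals/gall bladder": "adrenals_gall_bladder",
    "adrenals/gall_bladder": "adrenals_gall_bladder",
    "gall bladder": "adrenals_gall_bladder",
    "eyes": "eye",
    "lungs": "lung",
}


def canonical_organ(name: str) -> str:
    """Map an organ label to its canonical snake_case form."""
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    key = key.replace("/", "_").replace("-", "_").replace(" ", "_")
    return _ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# machine-side chain

@dataclass(frozen=True)
class CTDIMeasurements:
    """Pencil-chamber CTDI readings in the acrylic cylinder, mGy."""

    ctdi_p: float  # periphery
    ctdi_c: float  # center

    def __post_init__(self):
        if self.ctdi_p < 0 or self.ctdi_c < 0:
            raise InvalidMeasurementError("CTDI measurements must be >= 0")


def ctdi_w(m: CTDIMeasurements) -> float:
    """Weighted CTDI: two thirds periphery plus one third center."""
    return (2.0 / 3.0) * m.ctdi_p + (1.0 / 3.0) * m.ctdi_c


def ctdi_vol(ctdi_w_mGy: float, pitch: float) -> float:
    """Volume CTDI: weighted CTDI divided by helical pitch."""
    if pitch <= 0:
        raise InvalidPitchError(f"pitch must be > 0, got {pitch}")
    return ctdi_w_mGy / pitch


def dlp(ctdi_vol_mGy: float, scan_length_cm: float) -> float:
    """Dose-length product, mGy cm."""
    if scan_length_cm < 0:
        raise InvalidMeasurementError("scan length must be >= 0")
    return ctdi_vol_mGy * scan_length_cm


@dataclass(frozen=True)
class DoseReport:
    """Machine-side quantities for one scan."""

    ctdi_w: float
    ctdi_vol: float
    pitch: float
    scan_length: float
    dlp: float

    @classmethod
    def from_measurements(cls, m: CTDIMeasurements, pitch: float,
                          scan_length_cm: float) -> "DoseReport":
        w = ctdi_w(m)
        v = ctdi_vol(w, pitch)
        return cls(ctdi_w=w, ctdi_vol=v, pitch=pitch,
                   scan_length=scan_length_cm, dlp=dlp(v, scan_length_cm))


# ---------------------------------------------------------------------------
# tissue weighting

@dataclass(frozen=True)
class TissueWeightingScheme:
    """ICRP-103-style weights over named organs plus a pooled remainder."""

    weights: dict                 # organ (canonical) -> w_T; key 'remainder' pools
    remainder_members: tuple      # canonical organ names
    cc: float = 0.015             # mSv per mGy cm

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise InvalidMeasurementError("tissue weighting factors must be >= 0")
        if "remainder" in self.weights:
            if not self.remainder_members:
                raise InvalidMeasurementError("remainder members must be non-empty")
            individual = set(self.weights) - {"remainder"}
            if individual & set(self.remainder_members):
                raise InvalidMeasurementError(
                    "remainder members overlap individually weighted organs")

    @property
    def individually_weighted(self) -> tuple:
        return tuple(o for o in self.weights if o != "remainder")


def load_weighting_scheme(path=None) -> TissueWeightingScheme:
    """Load a weighting scheme; default is the packaged measured-organ subset."""
    if path is None:
        ref = resources.files("ctcap.data").joinpath("tissue_weighting_published.yaml")
        with ref.open("r") as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return TissueWeightingScheme(
        weights={canonical_organ(k): float(v) for k, v in raw["weights"].items()},
        remainder_members=tuple(canonical_organ(o) for o in raw["remainder_members"]),
        cc=float(raw.get("cc_mSv_per_mGy_cm", 0.015)),
    )


DEFAULT_SCHEME = load_weighting_scheme()


@dataclass(frozen=True)
class EffectiveDoseResult:
    """Tissue-weighted effective dose with per-organ contributions, mSv."""

    effective_dose: float
    contributions: dict  # organ (or 'remainder') -> mSv
    uncertainty: float = 0.0


def effective_dose_dlp_cc(dlp_mGy_cm: float,
                          scheme: TissueWeightingScheme = DEFAULT_SCHEME) -> float:
    """Machine-side effective dose: DLP times the conversion coefficient."""
    if dlp_mGy_cm < 0:
        raise InvalidMeasurementError("DLP must be >= 0")
    return dlp_mGy_cm * scheme.cc


def effective_dose_from_organ_doses(
        doses: OrganDoseTable,
        scheme: TissueWeightingScheme = DEFAULT_SCHEME) -> EffectiveDoseResult:
    """Assemble effective dose from per-organ absorbed doses.

    Individually weighted organs contribute w_T x dose; the remainder
    contributes w_remainder x (arithmetic mean of the remainder members'
    doses).  For photons the equivalent dose equals the absorbed dose, so the
    result is in mSv.  Uncertainties propagate in quadrature.
    """
    table = {canonical_organ(o): v for o, v in doses.rows.items()}

    contributions = {}
    var = 0.0
    for organ in scheme.individually_weighted:
        if organ not in table:
            raise IncompleteTableError(organ)
        w = scheme.weights[organ]
        d, s = table[organ]
        contributions[organ] = w * d
        var += (w * s) ** 2

    if "remainder" in scheme.weights:
        w_rem = scheme.weights["remainder"]
        member_doses = []
        svar = 0.0
        for organ in scheme.remainder_members:
            if organ not in table:
                raise IncompleteTableError(organ)
            d, s = table[organ]
            member_doses.append(d)
            svar += s * s
        n = len(member_doses)
        contributions["remainder"] = w_rem * sum(member_doses) / n
        var += (w_rem / n) ** 2 * svar

    return EffectiveDoseResult(
        effective_dose=sum(contributions.values()),
        contributions=contributions,
        uncertainty=math.sqrt(var),
    )


# ---------------------------------------------------------------------------
# reporting conventions

def percent_difference(a: float, b: float) -> float:
    """Percent difference of two doses relative to their mean: 100 |a-b| / ((a+b)/2)."""
    mean = (a + b) / 2.0
    if mean <= 0:
        raise UndefinedComparisonError("percent difference undefined for mean <= 0")
    return 100.0 * abs(a - b) / mean


def percent_difference_printed(a: float, b: float) -> int:
    """Percent difference rounded to the nearest integer (reporting convention)."""
    return int(round(percent_difference(a, b)))


def energy_response_correction(reading_mGy: float, factor: float = 1.15) -> float:
    """Dosimeter energy-response correction: reading times a calibration factor.

    The packaged default 1.15 corrects 80 kVp-calibrated OSL dosimeter
    readings for use at 120 kVp.
    """
    if factor <= 0:
        raise InvalidMeasurementError(f"correction factor must be > 0, got {factor}")
    return reading_mGy * factor


# ---------------------------------------------------------------------------
# packaged anthropomorphic-measurement tables

def load_anthropomorphic_doses() -> dict:
    """Packaged organ-absorbed-dose tables for the two anthropomorphic phantoms.

    Returns a dict keyed by (sex, source) with sex in {'female', 'male'} and
    source in {'measured', 'calculated'}; the calculated tables omit the eyes
    (no simulated value exists for them).
    """
    import pandas as pd

    ref = resources.files("ctcap.data").joinpath("anthropomorphic_organ_doses.csv")
    df = pd.read_csv(str(ref))
    out = {}
    for sex in ("female", "male"):
        for source in ("measured", "calculated"):
            rows = {}
            for r in df.itertuples():
                d = getattr(r, f"{sex}_{source}_mGy")
                s = getattr(r, f"{sex}_{source}_sigma_mGy")
                if pd.isna(d):
                    continue
                rows[r.organ] = (float(d), float(s))
            out[(sex, source)] = OrganDoseTable(
                rows=rows, provenance={"source": f"anthropomorphic {sex} {source}"})
    return out
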