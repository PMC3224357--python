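"""Synthetic stand-ins for the unavailable validation cohort and dose tables.

The real 28-patient validation cohort is known only through its printed
summaries: median height 170.25 cm, median weight 72 kg, median BMI
26 kg/m2, median DLP 956.19 mGy cm, a positive BMI-DLP association, three
BMI values above 36 and one at 35.  The generator draws truncated-normal
heights and BMIs, injects the high-BMI patients by exact count, derives
weight from BMI and height, and draws DLP lognormally around its median with
a log-scale BMI slope.  Cohorts are resampled (deterministically, bounded
retries) until all four realized medians fall within a relative tolerance of
their targets.

Note the printed medians are not jointly consistent (26 x 1.7025^2 = 75.4,
not 72), so accepted cohorts necessarily sit where sampling fluctuations
reconcile them; the 3% default tolerance makes that region reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .body import BodySpec
from .errors import ConfigurationError, GenerationError
from .phantoms import PopulationGrid
from .regression import FittedModel, RegressionDataset
from .transport import OrganDoseTable


@dataclass(frozen=True)
class CohortSpec:
    """Targets and free parameters of the synthetic validation cohort."""

    n: int = 28
    height_median_cm: float = 170.25
    height_sd_cm: float = 8.0
    height_range_cm: tuple = (150.0, 205.0)
    weight_median_kg: float = 72.0
    bmi_median: float = 26.0
    bmi_sd: float = 3.5
    bmi_nonoutlier_range: tuple = (19.5, 34.4)
    dlp_median: float = 956.19
    dlp_sigma_log: float = 0.22
    bmi_dlp_slope: float = 0.015       # per BMI unit, log-DLP scale
    n_bmi_outliers_above_36: int = 3
    outlier_bmi_range: tuple = (36.5, 40.5)
    n_bmi_at_35: int = 1
    median_tol: float = 0.03
    max_retries: int = 2000
    seed: int = 20111017

    def __post_init__(self):
        if self.n < self.n_bmi_outliers_above_36 + self.n_bmi_at_35:
            raise ConfigurationError("cohort smaller than its injected outlier count")
        for name in ("height_median_cm", "weight_median_kg", "bmi_median", "dlp_median"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class SyntheticPatient:
    id: str
    body: BodySpec
    dlp: float  # mGy cm

    def __post_init__(self):
        if self.dlp <= 0:
            raise ConfigurationError("DLP must be positive")


def _truncated_normal(rng, loc, scale, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(loc, scale, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list:
    """Draw the synthetic validation cohort; deterministic for a given spec.

    Raises :class:`GenerationError` if no draw satisfies the median
    constraints within the retry budget.
    """
    n_out = spec.n_bmi_outliers_above_36
    n_at35 = spec.n_bmi_at_35
    n_typical = spec.n - n_out - n_at35
    tol = spec.median_tol

    for attempt in range(spec.max_retries):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, attempt)))

        heights = _truncated_normal(
            rng, spec.height_median_cm, spec.height_sd_cm,
            spec.height_range_cm[0], spec.height_range_cm[1], spec.n)
        bmis = np.empty(spec.n)
        bmis[:n_typical] = _truncated_normal(
            rng, spec.bmi_median, spec.bmi_sd,
            spec.bmi_nonoutlier_range[0], spec.bmi_nonoutlier_range[1], n_typical)
        bmis[n_typical:n_typical + n_out] = rng.uniform(
            spec.outlier_bmi_range[0], spec.outlier_bmi_range[1], size=n_out)
        bmis[n_typical + n_out:] = 35.0

        weights = bmis * (heights / 100.0) ** 2
        log_dlp = (np.log(spec.dlp_median)
                   + spec.bmi_dlp_slope * (bmis - spec.bmi_median)
                   + spec.dlp_sigma_log * rng.standard_normal(spec.n))
        dlps = np.exp(log_dlp)

        ok = (
            abs(np.median(heights) / spec.height_median_cm - 1.0) <= tol
            and abs(np.median(weights) / spec.weight_median_kg - 1.0) <= tol
            and abs(np.median(bmis) / spec.bmi_median - 1.0) <= tol
            and abs(np.median(dlps) / spec.dlp_median - 1.0) <= tol
        )
        if not ok:
            continue

        order = rng.permutation(spec.n)  # decouple outlier position from id
        return [
            SyntheticPatient(
                id=f"P{i + 1:03d}",
                body=BodySpec(height_cm=float(heights[j]), weight_kg=float(weights[j])),
                dlp=float(dlps[j]),
            )
            for i, j in enumerate(order)
        ]

    raise GenerationError(
        f"no cohort satisfied the median constraints in {spec.max_retries} draws")


def cohort_frame(patients):
    """Cohort as a DataFrame with the pipeline's frozen column schema."""
    import pandas as pd

    return pd.DataFrame({
        "id": [p.id for p in patients],
        "height_cm": [p.body.height_cm for p in patients],
        "weight_kg": [p.body.weight_kg for p in patients],
        "bmi": [p.body.bmi for p in patients],
        "dlp_mGy_cm": [p.dlp for p in patients],
    })


def generate_organ_dose_fixture(reference: OrganDoseTable, noise_sd_rel: float,
                                seed: int) -> OrganDoseTable:
    """Multiplicative lognormal perturbation of a reference organ-dose table.

    The lognormal is parameterized to unit mean, so replicate averages are
    unbiased estimates of the reference; ``noise_sd_rel = 0`` returns the
    input unchanged.
    """
    if noise_sd_rel < 0:
        raise ConfigurationError("noise_sd_rel must be >= 0")
    if noise_sd_rel == 0:
        return reference
    rng = np.random.default_rng(seed)
    sigma_log = np.sqrt(np.log1p(noise_sd_rel ** 2))
    rows = {}
    for organ, (dose, sig) in reference.rows.items():
        factor = float(np.exp(sigma_log * rng.standard_normal() - sigma_log ** 2 / 2))
        rows[organ] = (dose * factor, sig)
    prov = dict(reference.provenance)
    prov["noise_sd_rel"] = noise_sd_rel
    prov["seed"] = seed
    return OrganDoseTable(rows=rows, provenance=prov)


def generate_regression_dataset(truth: FittedModel, grid: PopulationGrid,
                                noise_sd: float, seed: int) -> RegressionDataset:
    """Evaluate a truth model on a population grid with additive normal noise."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if len(grid) == 0:
        raise ConfigurationError("population grid is empty")
    rng = np.random.default_rng(seed)
    rows = tuple(
        (member, truth.predict_raw(member) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
        for member in grid.members
    )
    return RegressionDataset(rows=rows)
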