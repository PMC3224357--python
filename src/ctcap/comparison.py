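"""Agreement analysis between two per-patient effective-dose series.

Differences are oriented as method A minus method B with the label order
fixed by the caller (for the pipeline: predictive model minus DLP x CC).
Limits of agreement use the n-1 sample standard deviation and +/- 1.96 SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import percent_difference, percent_difference_printed
from .errors import InsufficientDataError, InvalidMeasurementError


@dataclass(frozen=True)
class PairedDoseEstimates:
    """Per-patient effective doses from two methods, mSv."""

    ids: tuple
    dose_a: np.ndarray
    dose_b: np.ndarray
    labels: tuple = ("method_a", "method_b")

    def __post_init__(self):
        a = np.asarray(self.dose_a, dtype=float)
        b = np.asarray(self.dose_b, dtype=float)
        if not (len(self.ids) == a.size == b.size):
            raise InvalidMeasurementError("ids and dose series must align")
        if a.size < 1:
            raise InsufficientDataError("at least one patient required")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidMeasurementError("doses must be finite")
        if np.any(a < 0) or np.any(b < 0):
            raise InvalidMeasurementError("doses must be >= 0")
        object.__setattr__(self, "dose_a", a)
        object.__setattr__(self, "dose_b", b)

    @property
    def n(self) -> int:
        return len(self.ids)

    def swapped(self) -> "PairedDoseEstimates":
        return PairedDoseEstimates(
            ids=self.ids, dose_a=self.dose_b.copy(), dose_b=self.dose_a.copy(),
            labels=(self.labels[1], self.labels[0]),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   labels=("method_a", "method_b")) -> "PairedDoseEstimates":
        return cls(ids=tuple(df.iloc[:, 0]),
                   dose_a=df.iloc[:, 1].to_numpy(dtype=float),
                   dose_b=df.iloc[:, 2].to_numpy(dtype=float),
                   labels=tuple(labels))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias (mean of a-b), SD of differences, and 1.96-SD limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    per_patient: tuple  # of (mean, difference)
    labels: tuple = ("method_a", "method_b")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_mSv": [m for m, _ in self.per_patient],
             "difference_mSv": [d for _, d in self.per_patient]}
        )


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    degrees_freedom: int
    p_value: float
    degenerate: bool = False


def bland_altman(pairs: PairedDoseEstimates) -> BlandAltmanResult:
    """Average-versus-difference agreement summary for two dose series."""
    if pairs.n < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 patients")
    diff = pairs.dose_a - pairs.dose_b
    mean = (pairs.dose_a + pairs.dose_b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        per_patient=tuple(zip(mean.tolist(), diff.tolist())),
        labels=pairs.labels,
    )


def paired_t_test(pairs: PairedDoseEstimates) -> PairedTestResult:
    """Two-sided paired Student t-test on the per-patient differences."""
    if pairs.n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 patients")
    diff = pairs.dose_a - pairs.dose_b
    df = pairs.n - 1
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedTestResult(t_statistic=0.0, degrees_freedom=df, p_value=1.0)
        t = math.inf if diff.mean() > 0 else -math.inf
        return PairedTestResult(t_statistic=t, degrees_freedom=df, p_value=0.0,
                                degenerate=True)
    t = float(diff.mean() / (sd / math.sqrt(pairs.n)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(t_statistic=t, degrees_freedom=df, p_value=p)


def cohort_summary(pairs: PairedDoseEstimates) -> dict:
    """Per-method location/spread summary plus the between-method percent difference."""
    out = {"n": pairs.n, "labels": list(pairs.labels)}
    for label, series in zip(pairs.labels, (pairs.dose_a, pairs.dose_b)):
        q1, med, q3 = (np.percentile(series, q) for q in (25, 50, 75))
        out[label] = {
            "mean_mSv": float(series.mean()),
            "sd_mSv": float(series.std(ddof=1)) if pairs.n > 1 else 0.0,
            "sd_defined": pairs.n > 1,
            "median_mSv": float(med),
            "q1_mSv": float(q1),
            "q3_mSv": float(q3),
        }
    mean_a = out[pairs.labels[0]]["mean_mSv"]
    mean_b = out[pairs.labels[1]]["mean_mSv"]
    out["percent_difference_of_means"] = percent_difference(mean_a, mean_b)
    out["percent_difference_of_means_printed"] = percent_difference_printed(mean_a, mean_b)
    return out


# ---------------------------------------------------------------------------
# plotting (plain-data CSV always; image on request)

def write_bland_altman_outputs(result: BlandAltmanResult, csv_path,
                               png_path=None) -> None:
    """Persist the scatter data as CSV and optionally render the plot."""
    result.to_frame().to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = result.to_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(df["mean_mSv"], df["difference_mSv"], s=18)
        ax.axhline(result.bias, linestyle="--", label=f"bias {result.bias:.2f} mSv")
        ax.axhline(result.loa_low, color="k")
        ax.axhline(result.loa_high, color="k")
        ax.axhline(0.0, color="grey", linewidth=0.8)
        ax.set_xlabel("mean of methods (mSv)")
        ax.set_ylabel(f"{result.labels[0]} - {result.labels[1]} (mSv)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def write_comparison_json(pairs: PairedDoseEstimates, path) -> dict:
    """Compute and persist the full comparison statistics bundle."""
    ba = bland_altman(pairs)
    tt = paired_t_test(pairs)
    payload = {
        "bland_altman": {
            "bias_mSv": ba.bias, "sd_diff_mSv": ba.sd_diff,
            "loa_low_mSv": ba.loa_low, "loa_high_mSv": ba.loa_high,
        },
        "paired_t_test": {
            "t": tt.t_statistic, "df": tt.degrees_freedom, "p": tt.p_value,
        },
        "summary": cohort_summary(pairs),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
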