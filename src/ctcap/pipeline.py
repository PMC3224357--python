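"""End-to-end drivers for the three-step study structure.

``run_model_development`` builds the phantom design population, simulates a
CAP scan on every member, assembles effective doses, and fits/selects the
height-weight regression.  ``run_validation`` generates the synthetic
validation cohort, evaluates the predictive-model and DLP x CC pathways per
patient, and runs the agreement analysis.  Every CSV/JSON artifact is
recorded in a :class:`RunManifest` with content hashes, so reruns are
verifiable byte-for-byte (plots excluded).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body import BodySpec
from .comparison import (PairedDoseEstimates, write_bland_altman_outputs,
                         write_comparison_json, bland_altman)
from .dosimetry import (DEFAULT_SCHEME, TissueWeightingScheme,
                        effective_dose_dlp_cc, effective_dose_from_organ_doses)
from .errors import CtcapError, PipelineStageError
from .phantoms import build_population, scale_reference_phantom
from .regression import (FittedModel, RegressionDataset, predict_effective_dose,
                         select_by_bic)
from .synthetic import CohortSpec, cohort_frame, generate_cohort
from .transport import ScanProtocol, axial_to_helical, simulate_axial_scan


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full pipeline."""

    outdir: str = "ctcap_run"
    # population
    bmi_min: float = 18.0
    bmi_max: float = 36.0
    height_min_cm: float = 154.94
    height_max_cm: float = 200.66
    n_per_axis: int = 10
    # scan
    protocol: ScanProtocol = field(default_factory=ScanProtocol)
    scheme: TissueWeightingScheme = DEFAULT_SCHEME
    # validation cohort
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # seeds
    sim_seed: int = 1
    # reporting
    bmi_flag_margin: float = 1.0
    make_plots: bool = False


@dataclass
class RunManifest:
    """Ordered record of pipeline stages and the artifacts they emitted."""

    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict) -> None:
        self.stages.append({
            "stage": stage,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                        for name, p in outputs.items()},
        })

    def artifact_paths(self) -> list:
        return [o["path"] for s in self.stages for o in s["outputs"].values()]

    def verify(self) -> bool:
        """Recompute every artifact hash; True iff all match."""
        return all(
            o["sha256"] == _sha256(o["path"])
            for s in self.stages for o in s["outputs"].values()
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seeds": self.seeds, "stages": self.stages}, fh, indent=2)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _member_seed(sim_seed: int, index: int) -> int:
    ss = np.random.SeedSequence((int(sim_seed), int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CtcapError as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def model_to_json(model: FittedModel, path) -> None:
    payload = {
        "intercept_mSv": model.intercept,
        "coefficients": model.coefficients,
        "included_terms": list(model.included_terms),
        "r_squared": model.r_squared,
        "bic": model.bic,
        "p_values": model.p_values,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def model_from_json(path) -> FittedModel:
    with open(path) as fh:
        raw = json.load(fh)
    return FittedModel(
        intercept=raw["intercept_mSv"], coefficients=raw["coefficients"],
        included_terms=tuple(raw["included_terms"]), r_squared=raw["r_squared"],
        bic=raw["bic"], p_values=raw.get("p_values", {}),
    )


def run_model_development(config: PipelineConfig):
    """Population -> per-phantom CAP simulation -> effective doses -> BIC fit.

    Returns ``(FittedModel, RunManifest)``; intermediates are persisted under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seeds={"sim_seed": config.sim_seed})

    population = _stage("population")(build_population)(
        bmi_min=config.bmi_min, bmi_max=config.bmi_max,
        height_min=config.height_min_cm, height_max=config.height_max_cm,
        n_per_axis=config.n_per_axis,
    )
    pop_path = outdir / "population.csv"
    population.to_csv(pop_path)
    manifest.record("population", {"population": pop_path})

    @_stage("simulation")
    def _simulate():
        records = []
        for i, member in enumerate(population.members):
            phantom = scale_reference_phantom(member)
            trunk = phantom.trunk
            proto = dataclasses.replace(
                config.protocol, scan_start_cm=trunk.zmin, scan_end_cm=trunk.zmax)
            axial = simulate_axial_scan(phantom, proto, seed=_member_seed(config.sim_seed, i))
            helical = axial_to_helical(axial, proto.pitch)
            result = effective_dose_from_organ_doses(helical, config.scheme)
            records.append({
                "height_cm": member.height_cm, "weight_kg": member.weight_kg,
                "bmi": member.bmi, "effective_dose_mSv": result.effective_dose,
                "effective_dose_sigma_mSv": result.uncertainty,
            })
        return pd.DataFrame(records)

    doses = _simulate()
    doses_path = outdir / "effective_doses.csv"
    doses.to_csv(doses_path, index=False)
    manifest.record("simulation", {"effective_doses": doses_path})

    @_stage("model_fit")
    def _fit():
        data = RegressionDataset.from_frame(doses)
        return select_by_bic(data)

    model = _fit()
    model_path = outdir / "model.json"
    model_to_json(model, model_path)
    manifest.record("model_fit", {"model": model_path})
    manifest.to_json(outdir / "manifest.json")
    return model, manifest


def run_validation(config: PipelineConfig, model: FittedModel):
    """Synthetic cohort -> predictive-model and DLP x CC doses -> agreement stats.

    Returns ``(results dict, RunManifest)``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seeds={"cohort_seed": config.cohort.seed})

    patients = _stage("cohort")(generate_cohort)(config.cohort)
    df = cohort_frame(patients)

    @_stage("dose_estimation")
    def _doses():
        preds, flags = [], []
        lo = config.bmi_min + config.bmi_flag_margin
        hi = config.bmi_max - config.bmi_flag_margin
        for p in patients:
            pred = predict_effective_dose(
                model, p.body, bmi_range=(config.bmi_min, config.bmi_max))
            preds.append(pred.value_mSv)
            flags.append(p.body.bmi <= lo or p.body.bmi >= hi)
        dlpcc = [effective_dose_dlp_cc(p.dlp, config.scheme) for p in patients]
        return preds, dlpcc, flags

    preds, dlpcc, flags = _doses()
    df["predictive_model_mSv"] = preds
    df["dlp_cc_mSv"] = dlpcc
    df["bmi_at_or_beyond_training_range"] = flags
    cohort_path = outdir / "validation_cohort.csv"
    df.to_csv(cohort_path, index=False)
    manifest.record("cohort", {"validation_cohort": cohort_path})

    pairs = PairedDoseEstimates(
        ids=tuple(df["id"]), dose_a=df["predictive_model_mSv"].to_numpy(),
        dose_b=df["dlp_cc_mSv"].to_numpy(),
        labels=("predictive_model", "dlp_cc"),
    )
    stats_path = outdir / "comparison.json"
    results = _stage("comparison")(write_comparison_json)(pairs, stats_path)
    ba_csv = outdir / "bland_altman.csv"
    write_bland_altman_outputs(
        bland_altman(pairs), ba_csv,
        png_path=(outdir / "bland_altman.png") if config.make_plots else None)
    manifest.record("comparison", {"comparison": stats_path, "bland_altman": ba_csv})

    results["n_flagged_bmi"] = int(sum(flags))
    manifest.to_json(outdir / "manifest.json")
    return results, manifest
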