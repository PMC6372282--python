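"""Configuration, NIfTI/table IO, and the staged pipeline driver.

One YAML config file carries every stage's parameters (defaults equal the
protocol values used throughout the package); CLI flags override config
entries.  Every stage writes a provenance sidecar (config hash, seed,
package version) next to its outputs, and identical config + seed yields
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import bioheat, connectivity, preprocess, synthetic
from .acoustics import (SonicationProtocol, TransducerGeometry, hu_to_medium,
                        pulse_intensities, rayleigh_field,
                        rescale_by_calibration)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "sonoprint_out"
    seed: int = 0
    # phantom / acoustics
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    phantom_spacing: float = 0.5          # mm
    skull_hu: float = 1800.0
    skull_thickness: float = 2.0          # mm
    drive_voltage: float = 130.0          # V
    cap_quadrature: tuple[int, int] = (60, 120)  # theta x phi source points
    # thermal
    pulsed_heating: bool = False
    # BOLD
    n_subjects: int = 3
    n_runs: int = 3
    n_volumes: int = 800
    tr: float = 2.0
    bold_grid: tuple[int, int, int] = (14, 14, 10)
    bold_spacing: float = 2.0             # mm
    local_gain: float = 1.3
    distal_loss: float = 0.6
    global_confound_sd: float = 0.0
    meningeal_regression: bool = True
    # inference
    permutation_mode: str = "exhaustive"
    n_mc: int = 9999

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "bold_grid", "cap_quadrature"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sidecar(path: Path, config: PipelineConfig, stage: str) -> None:
    meta = {"stage": stage, "config_sha": config.digest(), "seed": config.seed,
            "version": __version__}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# NIfTI / table IO
# ---------------------------------------------------------------------------

def write_nifti(path: str | Path, data: np.ndarray,
                spacing: float | tuple[float, float, float]) -> None:
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    affine = np.diag([*sp, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), zooms


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    np.savetxt(str(path), motion, fmt="%.8f")


def read_motion(path: str | Path) -> np.ndarray:
    M = np.loadtxt(str(path))
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    return M


def export_bold(dataset: synthetic.BoldDataset, out_dir: str | Path,
                condition: str) -> pd.DataFrame:
    """Write one 4D NIfTI + motion table per run, the label volume, and a
    manifest (subject, run, condition, paths)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for info in dataset.runs:
        key = (info.subject, info.run)
        bold_path = out / f"sub-{info.subject}_run-{info.run}_{condition}_bold.nii.gz"
        mot_path = out / f"sub-{info.subject}_run-{info.run}_{condition}_motion.txt"
        write_nifti(bold_path, dataset.timeseries[key].astype(np.float32),
                    dataset.spacing)
        write_motion(mot_path, dataset.motion_params[key])
        rows.append({"subject": info.subject, "run": info.run,
                     "condition": condition, "bold": str(bold_path),
                     "motion": str(mot_path)})
    write_nifti(out / f"labels_{condition}.nii.gz",
                dataset.compartments.astype(np.int16), dataset.spacing)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / f"manifest_{condition}.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

STAGE_ORDER = ["simulate", "acoustic", "thermal", "preprocess", "fingerprint",
               "permtest"]


def run_acoustic(config: PipelineConfig, out: Path) -> dict:
    phantom = synthetic.make_head_phantom(config.grid_shape, config.phantom_spacing,
                                          config.skull_hu, config.skull_thickness,
                                          seed=config.seed)
    protocol = SonicationProtocol(drive_voltage=config.drive_voltage)
    medium = hu_to_medium(phantom, f=protocol.f0)
    shape = phantom.hu_volume.shape
    spacing = phantom.spacing
    # transducer above the water cone, aimed down the +z axis at the focus
    focus = np.asarray(phantom.focus_point, dtype=float) * spacing
    apex = focus.copy()
    apex[2] = focus[2] + 63.0
    geom = TransducerGeometry(position=tuple(apex), axis=(0.0, 0.0, -1.0))
    n_theta, n_phi = config.cap_quadrature
    free = rayleigh_field(geom, shape, spacing, protocol.f0, medium=None,
                          focus_index=phantom.focus_point,
                          n_theta=n_theta, n_phi=n_phi)
    skull_field = rayleigh_field(geom, shape, spacing, protocol.f0, medium=medium,
                                 focus_index=phantom.focus_point,
                                 n_theta=n_theta, n_phi=n_phi)
    scaled = rescale_by_calibration(skull_field, protocol,
                                    free_water_max=float(free.peak_pressure.max()))
    i_sppa, i_spta = pulse_intensities(scaled.focus_value,
                                       duty_cycle=protocol.duty_cycle)
    write_nifti(out / "pressure.nii.gz", scaled.peak_pressure.astype(np.float32),
                spacing)
    _sidecar(out / "pressure.nii.gz", config, "acoustic")
    report = {"focal_pressure_mpa": scaled.focus_value / 1e6,
              "i_sppa_w_cm2": i_sppa, "i_spta_w_cm2": i_spta,
              "duty_cycle": protocol.duty_cycle}
    (out / "acoustic_report.json").write_text(json.dumps(report, indent=1))
    return {"phantom": phantom, "medium": medium, "field": scaled,
            "protocol": protocol, "report": report}


def run_thermal(config: PipelineConfig, out: Path, acoustic: dict) -> dict:
    phantom = acoustic["phantom"]
    protocol = acoustic["protocol"]
    materials = bioheat.ThermalMaterials.from_medium(acoustic["medium"],
                                                     phantom.compartment_labels,
                                                     f=protocol.f0)
    q = bioheat.heat_source(acoustic["field"], materials, protocol,
                            time_averaged=not config.pulsed_heating)
    state0 = bioheat.initial_temperature(phantom.compartment_labels)
    timeline = bioheat.ThermalTimeline()
    frames, _ = bioheat.solve_pennes(
        state0, materials, bioheat.PerfusionParams(), q, timeline,
        spacing_mm=phantom.spacing,
        brain_mask=phantom.compartment_labels == synthetic.BRAIN,
        protocol=protocol, pulsed=config.pulsed_heating)
    report = bioheat.summarize_thermal(frames, phantom.compartment_labels,
                                       phantom.focus_point)
    pd.DataFrame({"time_s": report["times"],
                  "focal_T_degC": report["focal_timecourse"]}).to_csv(
        out / "focal_timecourse.csv", index=False)
    scalar = {k: v for k, v in report.items()
              if k not in ("times", "focal_timecourse")}
    (out / "thermal_report.json").write_text(json.dumps(scalar, indent=1))
    _sidecar(out / "thermal_report.json", config, "thermal")
    return {"report": report}


def _bold_datasets(config: PipelineConfig):
    effect = synthetic.EffectSpec(local_gain=config.local_gain,
                                  distal_loss=config.distal_loss,
                                  global_confound_sd=config.global_confound_sd)
    return synthetic.make_bold_dataset(
        n_subjects=config.n_subjects, n_runs=config.n_runs,
        n_volumes=config.n_volumes, tr=config.tr, grid_shape=config.bold_grid,
        spacing=config.bold_spacing, effect=effect, seed=config.seed)


def run_fmri(config: PipelineConfig, out: Path, do_preprocess: bool = True) -> dict:
    """simulate -> preprocess -> per-run fingerprints -> permutation test."""
    control, stim = _bold_datasets(config)
    centres, _ = synthetic.default_roi_layout(config.bold_grid)
    seed_name = "SMA"
    grid = config.bold_grid
    spacing = config.bold_spacing
    rois = {name: connectivity.Roi(name=name,
                                   left=control.roi_voxels[name]["left"],
                                   right=control.roi_voxels[name]["right"])
            for name in centres}
    targets = [rois[n] for n in centres if n != seed_name]

    fps, labels = [], []
    for ds, cond in ((control, "control"), (stim, "stim")):
        for info in ds.runs:
            X = ds.timeseries[(info.subject, info.run)]
            if do_preprocess:
                X = preprocess.clean_run(X, ds.motion_params[(info.subject, info.run)],
                                         ds.compartments, ds.tr, spacing,
                                         include_meningeal=config.meningeal_regression)
            vals, names = connectivity.fingerprint(X, rois[seed_name], targets, grid)
            fps.append(vals)
            labels.append(cond)
    F = np.asarray(fps)
    res = connectivity.permutation_test(F, labels, mode=config.permutation_mode,
                                        n_mc=config.n_mc, seed=config.seed)
    fp_table = pd.DataFrame(F, columns=names)
    fp_table.insert(0, "condition", labels)
    fp_table.to_csv(out / "fingerprints.csv", index=False)
    perm = {"seed_roi": seed_name, "observed_cosine": res.observed_cosine,
            "n_permutations": res.n_permutations, "p_value": res.p_value,
            "exhaustive": res.exhaustive}
    (out / "permutation_report.json").write_text(json.dumps(perm, indent=1))
    _sidecar(out / "permutation_report.json", config, "permtest")
    return {"fingerprints": F, "labels": labels, "result": res, "targets": names}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns a manifest of
    stage outputs.  Missing upstream stages raise a dependency error."""
    stages = stages or STAGE_ORDER
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {}
    acoustic = None
    if "acoustic" in stages:
        acoustic = run_acoustic(config, out)
        manifest["acoustic"] = acoustic["report"]
    if "thermal" in stages:
        if acoustic is None:
            raise RuntimeError("thermal stage requires the acoustic stage")
        manifest["thermal"] = run_thermal(config, out, acoustic)["report"]
    fmri_stages = {"simulate", "preprocess", "fingerprint", "permtest"} & set(stages)
    if fmri_stages:
        if "permtest" in fmri_stages or "fingerprint" in fmri_stages:
            fmri = run_fmri(config, out,
                            do_preprocess="preprocess" in stages)
            manifest["permtest"] = {"p_value": fmri["result"].p_value,
                                    "observed_cosine": fmri["result"].observed_cosine}
        elif "simulate" in fmri_stages:
            control, stim = _bold_datasets(config)
            export_bold(control, out / "bold", "control")
            export_bold(stim, out / "bold", "stim")
            manifest["simulate"] = {"runs": len(control.runs) + len(stim.runs)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
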