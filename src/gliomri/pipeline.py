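"""End-to-end orchestration: simulate -> quantify -> summarize -> report.

The pipeline ties the phantom generator to the three quantification
stages (MTR, diffusion MD/FA, DSC perfusion) and the group statistics,
producing the study-style report tables: absolute values per group
(mean +/- SEM, per tumour core/periphery plus whole-tumour perfusion)
and the percent-change table with male-vs-female Welch tests.

Everything is seeded and a provenance JSON (package and library
versions, seeds, config hash) is written next to the outputs, so a rerun
with the same config reproduces them bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dsc import DSCAcquisition, normalize_to_reference, perfusion_maps
from .dti import DiffusionScheme, default_scheme, fit_tensor, md_fa_maps
from .groupstats import build_report, roi_summary
from .mt import MTPair, compute_mtr
from .phantom import (GROUPS, PhantomGeometry, PhantomTruth, default_effects,
                      simulate_cohort, simulate_dsc, simulate_dwi,
                      simulate_mt_pair)
from .volumes import ImageVolume, ROIMask, write_volume

__all__ = [
    "PipelineConfig",
    "quantify_subject",
    "quantify_cohort",
    "run_pipeline",
    "write_cohort_files",
    "analyze_manifest",
]

log = logging.getLogger("gliomri")

_INVALID_WARN_FRACTION = 0.01


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serializable)."""

    outdir: str = "scratch/run"
    seed: int = 42
    n_per_group: int = 8
    snr: float | None = None            # None = noiseless
    subject_sd: str | float = "sem"     # "sem", or 0 for a deterministic cohort
    delta_mode: str = "group-mean"
    dsc_fit: str = "rois"               # "rois" or "brain"
    scheme_file: str | None = None
    geometry: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scheme_file is not None and not Path(self.scheme_file).exists():
            raise FileNotFoundError(
                f"scheme file not found: {self.scheme_file}")
        if self.delta_mode not in ("group-mean", "per-subject"):
            raise ValueError(f"bad delta_mode {self.delta_mode!r}")
        if self.dsc_fit not in ("rois", "brain"):
            raise ValueError(f"bad dsc_fit {self.dsc_fit!r}")

    def build_geometry(self) -> PhantomGeometry:
        return PhantomGeometry(**self.geometry)

    def build_scheme(self) -> DiffusionScheme:
        if self.scheme_file is not None:
            return DiffusionScheme.from_file(self.scheme_file)
        return default_scheme()

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _warn_invalid(label: str, summary) -> None:
    total = summary.n_voxels + summary.n_invalid
    if total and summary.n_invalid / total > _INVALID_WARN_FRACTION:
        log.warning("%s: %d/%d ROI voxels flagged invalid", label,
                    summary.n_invalid, total)


def quantify_subject(mt_pair: MTPair, dwi: ImageVolume, dsc_series: ImageVolume,
                     masks: dict[str, ROIMask], scheme: DiffusionScheme,
                     acq: DSCAcquisition, dsc_fit: str = "rois"
                     ) -> list[tuple[str, str, float]]:
    """Quantify one subject's acquisitions into ROI values.

    Returns rows (region, parameter, value): MTR/MD/FA per core and
    periphery, and reference-normalized CBV/CBF/MTT over the whole
    tumour (the perfusion maps are not split into core/periphery).
    ``dsc_fit`` chooses whether the bolus model is fitted over the whole
    brain or only over the analysed regions (tumour + reference).
    """
    brain = masks["brain"]
    rows: list[tuple[str, str, float]] = []

    mtr = compute_mtr(mt_pair, mask=brain)
    tensors = fit_tensor(dwi, scheme, mask=brain)
    md_map, fa_map = md_fa_maps(tensors)
    for region in ("core", "periphery"):
        for name, pmap in (("MTR", mtr), ("MD", md_map), ("FA", fa_map)):
            s = roi_summary(pmap, masks[region])
            _warn_invalid(f"{name}/{region}", s)
            rows.append((region, name, s.mean))

    if dsc_fit == "rois":
        fit_region = ROIMask(masks["tumour"].data | masks["reference"].data,
                             brain.voxel_size, "tumour+reference")
    else:
        fit_region = brain
    perf = perfusion_maps(dsc_series, acq, mask=fit_region).normalize(
        masks["reference"])
    for name, pmap in (("CBV", perf.rel_cbv), ("CBF", perf.rel_cbf),
                       ("MTT", perf.rel_mtt)):
        s = roi_summary(pmap, masks["tumour"])
        _warn_invalid(f"{name}/tumour", s)
        rows.append(("tumour", name, s.mean))
    return rows


def quantify_cohort(effects: pd.DataFrame | None = None,
                    n_per_group: int = 8, seed: int = 42,
                    snr: float | None = None,
                    subject_sd: str | float = "sem",
                    geometry: PhantomGeometry | None = None,
                    scheme: DiffusionScheme | None = None,
                    acq: DSCAcquisition | None = None,
                    dsc_fit: str = "rois"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and push every subject through the full pipeline.

    Subjects are rendered and quantified one at a time (images are
    discarded after measurement, only ROI values are kept). Returns the
    tidy measured cohort table and the ground-truth draw table.
    """
    effects = default_effects() if effects is None else effects
    geometry = geometry or PhantomGeometry()
    scheme = scheme or default_scheme()
    acq = acq or DSCAcquisition()
    if isinstance(subject_sd, (int, float)):
        sd_table = effects.assign(sd=float(subject_sd))
    else:
        sd_table = subject_sd
    truth_table, subjects = simulate_cohort(
        effects, n_per_group=n_per_group, seed=seed, subject_sd=sd_table,
        render=False, geometry=geometry)

    rng = np.random.default_rng(seed + 1)
    rows = []
    for subj in subjects:
        sub_seed = int(rng.integers(0, 2**31 - 3))
        truth = subj.truth
        mt_pair = simulate_mt_pair(truth, snr=snr, seed=sub_seed)
        dwi = simulate_dwi(truth, scheme=scheme, snr=snr, seed=sub_seed + 1)
        dsc_series = simulate_dsc(truth, acq=acq, seed=sub_seed + 2)
        sex, condition = subj.group.split("/")
        for region, parameter, value in quantify_subject(
                mt_pair, dwi, dsc_series, truth.masks, scheme, acq, dsc_fit):
            rows.append((subj.subject_id, sex, condition, subj.group,
                         region, parameter, value))
        log.info("quantified %s (%s)", subj.subject_id, subj.group)
    measured = pd.DataFrame(rows, columns=["subject", "sex", "condition",
                                           "group", "region", "parameter",
                                           "value"])
    return measured, truth_table


def run_pipeline(config: PipelineConfig) -> Path:
    """Full run: simulate -> map -> summarize -> report into ``outdir``.

    Writes cohort.csv (per-subject measurements), truth.csv (the draws),
    summary.csv and deltas.csv (the two report tables) plus
    provenance.json; returns the output directory. Reruns with the same
    config are identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        stage = "simulate+quantify"
        measured, truth_table = quantify_cohort(
            n_per_group=config.n_per_group, seed=config.seed, snr=config.snr,
            subject_sd=config.subject_sd, geometry=config.build_geometry(),
            scheme=config.build_scheme(), dsc_fit=config.dsc_fit)
        stage = "report"
        summary, deltas = build_report(measured, mode=config.delta_mode)
        stage = "write"
        measured.to_csv(outdir / "cohort.csv", index=False)
        truth_table.to_csv(outdir / "truth.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        deltas.to_csv(outdir / "deltas.csv", index=False)
        provenance = {
            "gliomri_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


# ---------------------------------------------------------------------------
# file-based interface (NIfTI cohort export and manifest-driven analysis)


def write_cohort_files(outdir: str | Path, n_per_group: int = 2,
                       seed: int = 42, snr: float | None = None,
                       subject_sd: str | float = "sem",
                       geometry: PhantomGeometry | None = None) -> Path:
    """Render a cohort to disk: NIfTI volumes per subject and modality, the
    diffusion scheme file, ROI masks and a manifest CSV."""
    effects = default_effects()
    geometry = geometry or PhantomGeometry()
    scheme = default_scheme()
    acq = DSCAcquisition()
    if isinstance(subject_sd, (int, float)):
        sd_table = effects.assign(sd=float(subject_sd))
    else:
        sd_table = subject_sd
    outdir = Path(outdir)
    (outdir / "rois").mkdir(parents=True, exist_ok=True)
    scheme.to_file(outdir / "scheme.txt")

    truth_table, subjects = simulate_cohort(
        effects, n_per_group=n_per_group, seed=seed, subject_sd=sd_table,
        render=False, geometry=geometry)
    masks = geometry.masks()
    for name, m in masks.items():
        write_volume(ImageVolume(m.data.astype(float), m.voxel_size),
                     outdir / "rois" / f"{name}.nii.gz")

    rng = np.random.default_rng(seed + 1)
    manifest_rows = []
    for subj in subjects:
        sub_seed = int(rng.integers(0, 2**31 - 3))
        sdir = outdir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        pair = simulate_mt_pair(subj.truth, snr=snr, seed=sub_seed)
        dwi = simulate_dwi(subj.truth, scheme=scheme, snr=snr, seed=sub_seed + 1)
        dsc_series = simulate_dsc(subj.truth, acq=acq, seed=sub_seed + 2)
        paths = {
            "s0": write_volume(pair.s0, sdir / "mt_s0.nii.gz"),
            "smt": write_volume(pair.smt, sdir / "mt_smt.nii.gz"),
            "dwi": write_volume(dwi, sdir / "dwi.nii.gz"),
            "dsc": write_volume(dsc_series, sdir / "dsc.nii.gz"),
        }
        sex, condition = subj.group.split("/")
        manifest_rows.append({"subject": subj.subject_id, "sex": sex,
                              "condition": condition, "group": subj.group,
                              **{k: str(p.relative_to(outdir))
                                 for k, p in paths.items()}})
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    truth_table.to_csv(outdir / "truth.csv", index=False)
    return outdir


def analyze_manifest(manifest_path: str | Path, rois_dir: str | Path,
                     scheme_path: str | Path, outdir: str | Path,
                     delta_mode: str = "group-mean",
                     dsc_fit: str = "rois") -> Path:
    """Quantify a cohort described by a manifest CSV and write the report.

    The manifest lists subject, sex, condition, group and per-modality
    NIfTI paths (relative to the manifest's directory); ``rois_dir`` must
    contain brain/core/periphery/tumour/reference masks.
    """
    from .volumes import read_mask, read_volume

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    rois_dir = Path(rois_dir)
    masks = {}
    for name in ("brain", "core", "periphery", "tumour", "reference"):
        candidates = list(rois_dir.glob(f"{name}.nii*"))
        if not candidates:
            raise FileNotFoundError(f"ROI mask {name!r} not found in {rois_dir}")
        masks[name] = read_mask(candidates[0], label=name)
    scheme = DiffusionScheme.from_file(scheme_path)
    acq = DSCAcquisition()

    rows = []
    for rec in manifest.itertuples(index=False):
        pair = MTPair(s0=read_volume(base / rec.s0, expect_4d=False),
                      smt=read_volume(base / rec.smt, expect_4d=False))
        dwi = read_volume(base / rec.dwi, expect_4d=True)
        dsc_series = read_volume(base / rec.dsc, expect_4d=True)
        for region, parameter, value in quantify_subject(
                pair, dwi, dsc_series, masks, scheme, acq, dsc_fit):
            rows.append((rec.subject, rec.sex, rec.condition, rec.group,
                         region, parameter, value))
    measured = pd.DataFrame(rows, columns=["subject", "sex", "condition",
                                           "group", "region", "parameter",
                                           "value"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measured.to_csv(outdir / "cohort.csv", index=False)
    summary, deltas = build_report(measured, mode=delta_mode)
    summary.to_csv(outdir / "summary.csv", index=False)
    deltas.to_csv(outdir / "deltas.csv", index=False)
    return outdir
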