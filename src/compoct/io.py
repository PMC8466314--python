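"""Readers and writers for slices, masks and results, plus the pipeline.

CT slices are read from DICOM (stored values converted to HU with the
rescale slope/intercept) or NIfTI; phantoms and label maps are written
as paired NIfTI images.  The end-to-end pipeline chains
phantom simulation -> ensemble training -> segmentation -> body
composition -> cohort simulation -> survival analysis, and writes a
manifest recording seeds, inputs and content hashes.

Pixel coordinates are 0-based (row, col) everywhere; masks share the
image grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from compoct import bodycomp, cohortsim, ensemble, groundtruth, phantom, survstats
from compoct.rois import ROI_NAMES

logger = logging.getLogger("compoct")

__all__ = [
    "read_ct_slice",
    "write_slice_nifti",
    "write_label_map",
    "read_label_map",
    "masks_to_rle_json",
    "rle_json_to_masks",
    "PipelineConfig",
    "run_pipeline",
]


def read_ct_slice(path: str | pathlib.Path, format: str | None = None
                  ) -> phantom.HUSlice:
    """Load one axial slice as HU values with pixel spacing.

    ``format`` is ``'dicom'`` or ``'nifti'``; inferred from the suffix
    when omitted.  DICOM stored values are converted with
    HU = slope * stored + intercept; a missing rescale tag means the
    values are assumed to be HU already (logged).  Multi-frame files
    are rejected — this package works on a single, manually selected
    L3 slice.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        format = "nifti" if (".nii" in suffixes) else "dicom"
    format = format.lower()
    if format == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError(
                f"{path} is multi-frame; select a single L3 slice first")
        stored = ds.pixel_array.astype(np.float64)
        if stored.ndim != 2:
            raise ValueError(f"{path} does not contain a single 2-D frame")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = getattr(ds, "RescaleIntercept", None)
        if intercept is None:
            logger.info("%s has no RescaleIntercept; assuming values are HU",
                        path)
            hu = stored * slope
        else:
            hu = stored * slope + float(intercept)
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        thickness = float(getattr(ds, "SliceThickness", 1.0))
        return phantom.HUSlice(
            values=hu,
            pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
            slice_thickness_mm=thickness,
            metadata={"source": str(path), "format": "dicom"},
        )
    if format == "nifti":
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj).astype(np.float64)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(
                f"{path} holds a {data.ndim}-D volume; select one slice")
        zooms = img.header.get_zooms()
        thickness = float(zooms[2]) if len(zooms) > 2 else 1.0
        meta = {"source": str(path), "format": "nifti"}
        extra = img.header.extensions
        for ext in extra:
            try:
                meta.update(json.loads(ext.get_content().decode()))
            except Exception:
                pass
        return phantom.HUSlice(
            values=data,
            pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
            slice_thickness_mm=thickness,
            metadata=meta,
        )
    raise ValueError(f"unknown format {format!r}")


def _nifti_image(data: np.ndarray, spacing: tuple[float, float],
                 thickness: float, metadata: dict | None = None):
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], thickness, 1.0])
    img = nib.Nifti1Image(data[:, :, None], affine)
    img.header.set_zooms((spacing[0], spacing[1], thickness))
    if metadata:
        payload = json.dumps(metadata, default=str).encode()
        img.header.extensions.append(nib.nifti1.Nifti1Extension("comment",
                                                                payload))
    return img


def write_slice_nifti(slc: phantom.HUSlice, path: str | pathlib.Path) -> None:
    """Write a slice as NIfTI (float32 HU, spacing in the affine/zooms)."""
    import nibabel as nib

    img = _nifti_image(slc.values.astype(np.float32), slc.pixel_spacing_mm,
                       slc.slice_thickness_mm, slc.metadata)
    nib.save(img, str(path))


def write_label_map(labels: phantom.TissueLabelMap, path: str | pathlib.Path,
                    spacing: tuple[float, float] = (1.0, 1.0),
                    thickness: float = 1.0) -> None:
    import nibabel as nib

    img = _nifti_image(labels.labels.astype(np.int16), spacing, thickness)
    nib.save(img, str(path))


def read_label_map(path: str | pathlib.Path) -> phantom.TissueLabelMap:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj)).astype(np.int16)
    return phantom.TissueLabelMap(labels=data)


def masks_to_rle_json(masks: groundtruth.ROIMaskSet) -> str:
    """Serialize a mask set as run-length-encoded JSON (row-major runs)."""
    payload = {"shape": list(masks.shape), "provenance": masks.provenance,
               "rois": {}}
    for roi in ROI_NAMES:
        flat = masks[roi].ravel()
        change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [flat.size]])
        runs = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if flat[a]:
                runs.append([int(a), int(b - a)])
        payload["rois"][roi] = runs
    return json.dumps(payload)


def rle_json_to_masks(text: str) -> groundtruth.ROIMaskSet:
    payload = json.loads(text)
    shape = tuple(payload["shape"])
    masks = {}
    for roi, runs in payload["rois"].items():
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        for start, length in runs:
            flat[start:start + length] = True
        masks[roi] = flat.reshape(shape)
    return groundtruth.ROIMaskSet(masks=masks,
                                  provenance=payload.get("provenance",
                                                         "ground_truth"))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; ``seed`` feeds every stochastic stage."""

    workdir: str = "compoct_run"
    n_phantoms: int = 20
    test_fraction: float = 0.25
    unet: ensemble.UNetConfig = field(default_factory=ensemble.UNetConfig)
    cutoffs: bodycomp.Cutoffs = field(default_factory=bodycomp.Cutoffs)
    cohort: cohortsim.CohortSpec = field(default_factory=cohortsim.CohortSpec)
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "train", "segment", "measure",
                               "simulate-cohort", "analyze")
    log_level: str = "INFO"


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and write a manifest.

    Any stage failure raises with the stage name in the message; the
    manifest lists every output file with a content hash so a run can be
    audited and reproduced.
    """
    logging.basicConfig(level=config.log_level)
    wd = pathlib.Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}

    def record(stage: str, t0: float, files: Sequence[pathlib.Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["outputs"][str(f.relative_to(wd))] = _sha256(f)

    for stage in config.stages:
        t0 = time.time()
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                size = config.unet.input_size
                base = phantom.PhantomSpec(
                    image_size=size,
                    pixel_spacing_mm=128 * 3.0 / size)  # keep the field of view
                data = phantom.generate_dataset(config.n_phantoms, base,
                                                seed=config.seed)
                files = []
                pdir = wd / "phantoms"
                pdir.mkdir(exist_ok=True)
                for i, (slc, labels) in enumerate(data):
                    fp = pdir / f"phantom_{i:03d}.nii.gz"
                    lp = pdir / f"phantom_{i:03d}_labels.nii.gz"
                    write_slice_nifti(slc, fp)
                    write_label_map(labels, lp, slc.pixel_spacing_mm,
                                    slc.slice_thickness_mm)
                    files += [fp, lp]
                state["data"] = data
                record(stage, t0, files)
            elif stage == "train":
                data = state["data"]
                n_test = max(1, int(round(config.test_fraction * len(data))))
                train = data[:-n_test]
                state["test"] = data[-n_test:]
                pairs = [(s, groundtruth.make_ground_truth(s, lab))
                         for s, lab in train]
                ens = ensemble.train_ensemble(pairs, config.unet)
                mdir = wd / "models"
                ens.save(mdir)
                state["ensemble"] = ens
                record(stage, t0, sorted(mdir.glob("*")))
            elif stage == "segment":
                mdir = wd / "models"
                if "ensemble" not in state:
                    if not mdir.exists():
                        raise FileNotFoundError(
                            f"model directory {mdir} not found")
                    state["ensemble"] = ensemble.SegmentationEnsemble.load(mdir)
                sdir = wd / "segmentations"
                sdir.mkdir(exist_ok=True)
                files = []
                state["predicted"] = []
                for i, (slc, _lab) in enumerate(state.get("test", [])):
                    pred = ensemble.predict_masks(state["ensemble"], slc)
                    fp = sdir / f"test_{i:03d}_masks.json"
                    fp.write_text(masks_to_rle_json(pred))
                    state["predicted"].append((slc, pred))
                    files.append(fp)
                record(stage, t0, files)
            elif stage == "measure":
                import pandas as pd

                rows = []
                for i, (slc, pred) in enumerate(state.get("predicted", [])):
                    md = slc.metadata
                    h = float(md.get("height_m", 1.75))
                    meta = bodycomp.PatientMeta(
                        sex=md.get("sex", "male"), height_m=h,
                        weight_kg=24.0 * h * h, age_years=50.0)
                    bc = bodycomp.compute_indices(slc, pred, meta)
                    bc = bodycomp.classify(bc, meta, config.cutoffs)
                    rows.append({"patient_id": f"T{i:03d}", "sex": meta.sex,
                                 "height_m": h, "bmi": meta.bmi,
                                 **dataclasses.asdict(bc)})
                fp = wd / "bodycomp.csv"
                pd.DataFrame(rows).to_csv(fp, index=False)
                record(stage, t0, [fp])
            elif stage == "simulate-cohort":
                spec = dataclasses.replace(config.cohort, seed=config.seed)
                table = cohortsim.cohort_to_table(
                    cohortsim.simulate_cohort(spec))
                fp = wd / "cohort.csv"
                table.to_csv(fp, index=False)
                state["cohort"] = table
                record(stage, t0, [fp])
            elif stage == "analyze":
                table = state["cohort"]
                out = {}
                for endpoint in ("os", "pfs"):
                    uni = {}
                    for cov in ("hypodense", "obese", "sarcopenic"):
                        fit = survstats.cox_fit(table, [cov], endpoint)
                        e = fit.effects[cov]
                        uni[cov] = {"hr": e.hr, "ci95": list(e.ci95), "p": e.p}
                    multi = survstats.cox_fit(
                        table, ["hypodense", "obese", "aaipi", "age_years"],
                        endpoint)
                    out[endpoint] = {
                        "univariate": uni,
                        "multivariate": {
                            c: {"hr": e.hr, "ci95": list(e.ci95), "p": e.p}
                            for c, e in multi.effects.items()},
                        "logrank_p_hypodense": survstats.km_logrank(
                            table, "hypodense", endpoint).logrank_p,
                    }
                cif = survstats.cumulative_incidence(table, "hypodense")
                out["nrm_36m"] = {
                    str(lev): cif.cif_at(lev, "nrm", 36.0)
                    for lev in (0, 1)}
                out["gray_p"] = cif.gray_p
                fp = wd / "analysis.json"
                fp.write_text(json.dumps(out, indent=2))
                record(stage, t0, [fp])
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    mf = wd / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2))
    return manifest
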