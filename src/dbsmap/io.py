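"""Readers and writers: NIfTI volumes, TCK/TRK tractograms, CSV tables,
cohort config bundles.

Streamlines are always handed to and received from the rest of the package
in world (RAS mm) coordinates; TRK voxel-space storage quirks are
normalized on read by nibabel's RAS+mm tractogram convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    SCALES,
    ClinicalRecord,
    CohortDataset,
    ElectrodeRecord,
    GroundTruth,
    ImageVolume,
    LabelAtlas,
    LeadGeometry,
    Tractogram,
    ValidationError,
)

_COORD_COLS = [f"c{i}{ax}" for i in range(4) for ax in "xyz"]


# ---------------------------------------------------------------------------
# images

def read_image(path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError([f"expected 3-D volume, got {data.ndim}-D in {path.name}"])
    return ImageVolume(data, np.asarray(img.affine, dtype=float))


def write_image(vol: ImageVolume, path) -> Path:
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))
    return path


def read_atlas(image_path, legend_path) -> LabelAtlas:
    vol = read_image(image_path)
    with open(legend_path) as fh:
        legend = {int(k): str(v) for k, v in json.load(fh).items()}
    vol.data = np.rint(vol.data).astype(np.int32)
    return LabelAtlas(vol, legend)


def write_atlas(atlas: LabelAtlas, image_path, legend_path) -> None:
    write_image(atlas.volume, image_path)
    with open(legend_path, "w") as fh:
        json.dump({int(k): v for k, v in atlas.legend.items()}, fh, indent=1)


# ---------------------------------------------------------------------------
# tractograms

def read_tractogram(path) -> Tractogram:
    path = Path(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValidationError([f"unknown tractogram extension {path.suffix!r} (expected .tck/.trk)"])
    if not path.exists():
        raise FileNotFoundError(path)
    tfile = nib.streamlines.load(str(path))  # nibabel yields RAS+ mm streamlines
    return Tractogram([np.asarray(s, dtype=float) for s in tfile.streamlines])


def write_tractogram(tractogram: Tractogram, path) -> Path:
    path = Path(path)
    sl = [s.astype(np.float32) for s in tractogram.streamlines]
    t = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".tck":
        nib.streamlines.save(t, str(path))
    elif path.suffix.lower() == ".trk":
        # TRK needs a reference grid; use an identity 1 mm header.
        hdr = nib.streamlines.trk.TrkFile.create_empty_header()
        nib.streamlines.save(t, str(path), header=hdr)
    else:
        raise ValidationError([f"unknown tractogram extension {path.suffix!r}"])
    return path


# ---------------------------------------------------------------------------
# tables

def electrodes_to_frame(electrodes) -> pd.DataFrame:
    rows = []
    for e in electrodes:
        row = {"patient_id": e.patient_id, "hemisphere": e.hemisphere}
        row.update({c: e.contact_coords[i, j] for (i, j), c in zip(
            [(i, j) for i in range(4) for j in range(3)], _COORD_COLS)})
        row.update(
            active_contact=int(e.active_contact),
            amplitude_v=e.amplitude_v,
            frequency_hz=e.frequency_hz,
            pulse_width_us=e.pulse_width_us,
            mode=e.mode,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_electrodes(df: pd.DataFrame) -> list:
    problems, out = [], []
    for idx, row in df.iterrows():
        coords = np.array([[row[f"c{i}{ax}"] for ax in "xyz"] for i in range(4)])
        try:
            out.append(ElectrodeRecord(
                patient_id=str(row["patient_id"]),
                hemisphere=str(row["hemisphere"]),
                contact_coords=coords,
                active_contact=int(row["active_contact"]),
                amplitude_v=float(row["amplitude_v"]),
                frequency_hz=float(row["frequency_hz"]),
                pulse_width_us=float(row["pulse_width_us"]),
                mode=str(row.get("mode", "monopolar")),
            ))
        except ValidationError as err:
            problems.append(f"electrode row {idx}: {err}")
    if problems:
        raise ValidationError(problems)
    return out


def clinical_to_frame(clinical) -> pd.DataFrame:
    rows = []
    for c in clinical:
        row = {"patient_id": c.patient_id}
        for scale, (pre, post) in c.scores.items():
            row[f"pre_{scale}"] = pre
            row[f"post_{scale}"] = post
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_clinical(df: pd.DataFrame) -> list:
    scales = sorted({c[4:] for c in df.columns if c.startswith("pre_")})
    out = []
    for _, row in df.iterrows():
        scores = {s: (float(row[f"pre_{s}"]), float(row[f"post_{s}"])) for s in scales
                  if pd.notna(row.get(f"pre_{s}")) and pd.notna(row.get(f"post_{s}"))}
        out.append(ClinicalRecord(str(row["patient_id"]), scores))
    return out


# ---------------------------------------------------------------------------
# cohort bundles

def write_cohort(cohort: CohortDataset, out_dir) -> Path:
    """Write a cohort as a directory of standard files plus cohort.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out_dir / "atlas.nii.gz", out_dir / "atlas_legend.json")
    electrodes_to_frame(cohort.electrodes).to_csv(out_dir / "electrodes.csv", index=False)
    clinical_to_frame(cohort.clinical).to_csv(out_dir / "clinical.csv", index=False)
    write_tractogram(cohort.tractogram, out_dir / "tractogram.tck")
    cfg = {
        "atlas": "atlas.nii.gz",
        "atlas_legend": "atlas_legend.json",
        "electrodes": "electrodes.csv",
        "clinical": "clinical.csv",
        "tractogram": "tractogram.tck",
        "lead": {
            "n_contacts": cohort.lead.n_contacts,
            "contact_spacing_mm": cohort.lead.contact_spacing_mm,
            "contact_radius_mm": cohort.lead.contact_radius_mm,
            "contact_length_mm": cohort.lead.contact_length_mm,
        },
    }
    if cohort.ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(cohort.ground_truth.to_dict(), fh, indent=1)
        cfg["ground_truth"] = "ground_truth.json"
    with open(out_dir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return out_dir / "cohort.yaml"


def read_cohort(config_path) -> CohortDataset:
    """Load a cohort from a YAML/JSON config; validates all cross-file
    invariants and reports every violation at once."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    atlas = read_atlas(base / cfg["atlas"], base / cfg["atlas_legend"])
    electrodes = frame_to_electrodes(pd.read_csv(base / cfg["electrodes"]))
    clinical = frame_to_clinical(pd.read_csv(base / cfg["clinical"]))
    tract = read_tractogram(base / cfg["tractogram"])
    gt = None
    if cfg.get("ground_truth"):
        with open(base / cfg["ground_truth"]) as fh:
            gt = GroundTruth.from_dict(json.load(fh))
    lead = LeadGeometry(**cfg["lead"]) if "lead" in cfg else LeadGeometry()
    return CohortDataset(atlas, electrodes, clinical, tract, ground_truth=gt, lead=lead)
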