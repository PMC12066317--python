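"""Volume of tissue activated (VTA) estimation and atlas overlap.

The stimulation field is a quasi-static homogeneous point-source model
centered at the active contact of a monopolar lead:

    |E|(r) = U * r_c / r**2      for r >= r_c,

with U the stimulation amplitude in volts, r_c the contact radius in mm,
and |E| clamped to its surface value U / r_c inside r < r_c.  Thresholding
at E_th (default 0.2 V/mm) yields a ball of radius

    r* = sqrt(U * r_c / E_th)

around the active contact.  The field model is deliberately isolated in
:func:`field_magnitude` so a finite-element or axon-model estimate can be
slotted in without touching anything downstream: every later stage consumes
only the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortDataset, ElectrodeRecord, ImageVolume, LabelAtlas, LeadGeometry

#: activation threshold on the field magnitude, V/mm
DEFAULT_E_THRESHOLD = 0.2


@dataclass
class VTAMask:
    """Binary activation mask on the analysis grid."""

    mask: ImageVolume            # boolean data
    patient_id: str
    hemisphere: str
    threshold_v_per_mm: float

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.data.sum()) * self.mask.voxel_volume_mm3

    @property
    def flat_indices(self) -> np.ndarray:
        """Flat voxel indices of active voxels (C order)."""
        return np.flatnonzero(self.mask.data.ravel())


def field_magnitude(
    electrode: ElectrodeRecord,
    points: np.ndarray,
    lead: LeadGeometry | None = None,
) -> np.ndarray:
    """Field magnitude |E| (V/mm) of the point-source model at world-mm points."""
    if electrode.mode != "monopolar":
        raise ValueError(f"only monopolar stimulation is supported, got {electrode.mode!r}")
    lead = lead or LeadGeometry()
    r_c = lead.contact_radius_mm
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts - electrode.active_coordinate, axis=1)
    u = electrode.amplitude_v
    if u == 0:
        return np.zeros(r.shape)
    return u * r_c / np.maximum(r, r_c) ** 2


def activation_radius_mm(
    amplitude_v: float,
    lead: LeadGeometry | None = None,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> float:
    """Radius of the thresholded point-source VTA, sqrt(U * r_c / E_th)."""
    lead = lead or LeadGeometry()
    return float(np.sqrt(amplitude_v * lead.contact_radius_mm / e_threshold))


def estimate_vta(
    electrode: ElectrodeRecord,
    grid: ImageVolume,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    lead: LeadGeometry | None = None,
) -> VTAMask:
    """Binary VTA: voxels whose center field magnitude is >= ``e_threshold``.

    Only a bounding box around the active contact is evaluated; outside it
    the field is strictly below threshold.
    """
    lead = lead or LeadGeometry()
    mask = np.zeros(grid.shape, dtype=bool)
    if electrode.amplitude_v > 0:
        center_vox = grid.world_to_voxel(electrode.active_coordinate)[0]
        if np.any(center_vox < -0.5) or np.any(center_vox > np.array(grid.shape) - 0.5):
            raise ValueError(
                f"active contact {electrode.active_coordinate} outside grid bounds"
            )
        r_star = activation_radius_mm(electrode.amplitude_v, lead, e_threshold)
        margin = r_star / grid.voxel_size_mm + 1
        lo = np.maximum(np.floor(center_vox - margin).astype(int), 0)
        hi = np.minimum(np.ceil(center_vox + margin).astype(int) + 1, grid.shape)
        ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        pts = grid.voxel_to_world(ijk)
        vals = field_magnitude(electrode, pts, lead)
        sub = (vals >= e_threshold).reshape(ii.shape)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return VTAMask(
        mask=grid.like(mask),
        patient_id=electrode.patient_id,
        hemisphere=electrode.hemisphere,
        threshold_v_per_mm=e_threshold,
    )


def compute_cohort_vtas(
    cohort: CohortDataset, e_threshold: float = DEFAULT_E_THRESHOLD
) -> dict:
    """One VTAMask per (patient_id, hemisphere), on the atlas grid."""
    grid = cohort.atlas.volume
    return {
        (e.patient_id, e.hemisphere): estimate_vta(e, grid, e_threshold, cohort.lead)
        for e in cohort.electrodes
    }


def patient_vta_indices(cohort: CohortDataset, vtas: dict) -> list:
    """Per patient (aligned with ``cohort.patients``): flat voxel indices of
    the union of both hemispheres' VTAs."""
    out = []
    for pid in cohort.patients:
        parts = [v.flat_indices for (p, _), v in vtas.items() if p == pid]
        out.append(np.unique(np.concatenate(parts)) if parts else np.array([], dtype=np.intp))
    return out


def overlap_with_atlas(vta: VTAMask, atlas: LabelAtlas) -> pd.DataFrame:
    """Intersection volume (mm^3) and fraction-of-region for every atlas
    region, including the aggregate STN_left / STN_right nuclei."""
    if not vta.mask.same_grid(atlas.volume):
        raise ValueError("VTA and atlas are on different grids")
    vox = atlas.volume.voxel_volume_mm3
    m = vta.mask.data
    regions = [name for _, name in sorted(atlas.legend.items())]
    regions += ["STN_left", "STN_right"]
    rows = []
    for region in regions:
        rmask = atlas.mask(region)
        n_region = int(rmask.sum())
        n_int = int((rmask & m).sum())
        rows.append({
            "patient_id": vta.patient_id,
            "hemisphere": vta.hemisphere,
            "region": region,
            "overlap_mm3": n_int * vox,
            "overlap_fraction_of_region": n_int / n_region if n_region else 0.0,
        })
    return pd.DataFrame(rows)


def cohort_overlap_table(cohort: CohortDataset, vtas: dict | None = None,
                         e_threshold: float = DEFAULT_E_THRESHOLD) -> pd.DataFrame:
    vtas = vtas if vtas is not None else compute_cohort_vtas(cohort, e_threshold)
    return pd.concat(
        [overlap_with_atlas(v, cohort.atlas) for v in vtas.values()],
        ignore_index=True,
    )


def active_contact_coordinates(cohort: CohortDataset) -> pd.DataFrame:
    """World-mm coordinates of the active contact per (patient, hemisphere)."""
    rows = []
    for e in cohort.electrodes:
        x, y, z = e.active_coordinate
        rows.append({"patient_id": e.patient_id, "hemisphere": e.hemisphere,
                     "x": x, "y": y, "z": z})
    return pd.DataFrame(rows).sort_values(["patient_id", "hemisphere"]).reset_index(drop=True)
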