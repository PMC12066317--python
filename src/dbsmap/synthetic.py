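"""Synthetic cohort generator with planted ground truth.

Builds an MNI-like toy world on a regular RAS-mm grid: two mirrored
ellipsoidal subthalamic nuclei (STN) split into sensorimotor (dorsal),
associative (middle) and limbic (ventral) thirds, plus two cortical target
boxes ("PFC-like" anterior/superior, "SMC-like" posterior/superior).
Electrodes are vertical four-contact leads entering through the STN long
axis with the most distal contact at the inferior STN border (plus a
configurable dorsoventral offset).  Streamline bundles run from the
ventral/limbic STN to the PFC-like box and from the dorsal/sensorimotor STN
to the SMC-like box.

Outcome changes follow a linear-additive model with Gaussian noise:

    change_i = w_v * |VTA_i ∩ sweet sphere| / |sweet sphere|
             + sum_b w_b * connected_frac(i, b) + eps_i

so every analysis stage has a recoverable, known answer.  Scenarios:

- ``ventral_effect``: voxel effect only (w_v > 0, tract weights 0) — a
  sweet sphere planted in the ventrocentral left STN.
- ``tract_only``: tract effects only (PFC bundle positive, SMC negative).
- ``null``: all effect weights zero; changes are pure noise.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ClinicalRecord,
    CohortDataset,
    ElectrodeRecord,
    GroundTruth,
    ImageVolume,
    LabelAtlas,
    LeadGeometry,
    Tractogram,
)
from .fibers import streamline_vta_connectivity
from .vta import compute_cohort_vtas, estimate_vta, patient_vta_indices

# ---------------------------------------------------------------------------
# toy-world geometry (world mm, RAS; ventral = smaller Z)

STN_CENTERS = {"left": np.array([-10.0, 0.0, 0.0]), "right": np.array([10.0, 0.0, 0.0])}
#: ellipsoid semi-axes (x, y, z): ~3.5 mm wide, 8 mm long, long axis vertical
STN_SEMI_AXES = np.array([1.75, 1.75, 4.0])
PFC_BOX = {"x": (-14.0, 14.0), "y": (6.0, 14.0), "z": (8.0, 14.0)}
SMC_BOX = {"x": (-14.0, 14.0), "y": (-14.0, -6.0), "z": (8.0, 14.0)}

LABELS = {
    1: "STN_left_sensorimotor", 2: "STN_left_associative", 3: "STN_left_limbic",
    4: "STN_right_sensorimotor", 5: "STN_right_associative", 6: "STN_right_limbic",
    7: "PFC_box", 8: "SMC_box",
}

#: planted sweet sphere: ventrocentral left STN
SWEET_CENTER = np.array([-10.0, 0.0, -2.0])
SWEET_RADIUS_MM = 2.5

#: scenario -> (voxel weight, bundle weights, default noise SD), in scale points
SCENARIOS = {
    "ventral_effect": (6.0, {"PFC": 0.0, "SMC": 0.0}, 1.0),
    "tract_only": (0.0, {"PFC": 4.0, "SMC": -4.0}, 0.5),
    "null": (0.0, {"PFC": 0.0, "SMC": 0.0}, 1.0),
}

_ATLAS_CACHE: dict = {}


def make_toy_atlas(grid_shape=(64, 64, 64), voxel_size_mm: float = 0.5) -> LabelAtlas:
    """Tripartite ellipsoidal STNs plus two cortical target boxes.

    The grid is centered on the world origin with voxel centers at
    ``(index - n/2) * voxel_size``.  Sublabels are thirds of the STN long
    (vertical) axis: sensorimotor dorsal, associative middle, limbic ventral.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    key = (grid_shape, float(voxel_size_mm))
    if key in _ATLAS_CACHE:
        cached = _ATLAS_CACHE[key]
        vol = ImageVolume(cached.volume.data.copy(), cached.volume.affine.copy())
        return LabelAtlas(vol, dict(cached.legend))

    if min(grid_shape) < 40 or voxel_size_mm > 1.0:
        raise ValueError("grid must be at least 40^3 voxels at <= 1 mm")
    sub_thickness = 2 * STN_SEMI_AXES[2] / 3.0
    if sub_thickness / voxel_size_mm < 3:
        raise ValueError(
            f"voxel size {voxel_size_mm} mm too coarse to resolve STN sublabels "
            f"({sub_thickness:.2f} mm each; need >= 3 voxels)"
        )

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -np.array(grid_shape) / 2.0 * voxel_size_mm
    vol = ImageVolume(np.zeros(grid_shape, dtype=np.int32), affine)
    xyz = vol.world_coordinates()
    data = vol.data

    for hemi, base in (("left", 1), ("right", 4)):
        c = STN_CENTERS[hemi]
        rel = (xyz - c) / STN_SEMI_AXES
        inside = (rel**2).sum(axis=-1) <= 1.0
        dz = xyz[..., 2] - c[2]
        third = STN_SEMI_AXES[2] / 3.0 * 2  # 8/3 mm
        sensorimotor = inside & (dz > STN_SEMI_AXES[2] - third)
        limbic = inside & (dz < -(STN_SEMI_AXES[2] - third))
        associative = inside & ~sensorimotor & ~limbic
        data[sensorimotor] = base
        data[associative] = base + 1
        data[limbic] = base + 2

    for box, label in ((PFC_BOX, 7), (SMC_BOX, 8)):
        m = np.ones(grid_shape, dtype=bool)
        for ax, (lo, hi) in zip(range(3), (box["x"], box["y"], box["z"])):
            m &= (xyz[..., ax] >= lo) & (xyz[..., ax] <= hi)
        data[m & (data == 0)] = label

    atlas = LabelAtlas(vol, dict(LABELS))
    _ATLAS_CACHE[key] = atlas
    # return a copy so callers cannot mutate the cache
    return LabelAtlas(
        ImageVolume(atlas.volume.data.copy(), atlas.volume.affine.copy()),
        dict(atlas.legend),
    )


def make_electrode(
    atlas: LabelAtlas,
    hemisphere: str,
    dorsoventral_offset_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    jitter_mm: float = 0.5,
    patient_id: str = "P000",
    active_contact: int = 0,
    amplitude_v: float = 2.5,
    frequency_hz: float = 130.0,
    pulse_width_us: float = 60.0,
    lead: LeadGeometry | None = None,
) -> ElectrodeRecord:
    """Vertical 4-contact lead through the STN long axis.

    With offset 0 (and no jitter) contact 0 sits at the ventral STN border;
    a positive offset translates the whole lead dorsally (+Z) by that many
    mm.  ``rng`` adds uniform in-plane jitter up to ``jitter_mm``.
    """
    lead = lead or LeadGeometry()
    stn = atlas.mask(f"STN_{hemisphere}")
    if not stn.any():
        raise ValueError(f"atlas has no STN_{hemisphere} voxels")
    coords = atlas.volume.voxel_to_world(np.argwhere(stn))
    cx, cy = coords[:, 0].mean(), coords[:, 1].mean()
    jx = jy = 0.0
    if rng is not None and jitter_mm > 0:
        jx, jy = rng.uniform(-jitter_mm, jitter_mm, size=2)
    lx, ly = cx + jx, cy + jy

    vox = float(atlas.volume.voxel_size_mm.max())
    near = (np.abs(coords[:, 0] - lx) <= vox) & (np.abs(coords[:, 1] - ly) <= vox)
    if not near.any():
        raise ValueError(
            f"electrode trajectory at ({lx:.2f}, {ly:.2f}) misses the {hemisphere} STN entirely"
        )
    z0 = float(coords[near, 2].min()) + dorsoventral_offset_mm
    zs = z0 + np.arange(lead.n_contacts) * lead.contact_spacing_mm
    contacts = np.column_stack([np.full(lead.n_contacts, lx), np.full(lead.n_contacts, ly), zs])
    return ElectrodeRecord(
        patient_id=patient_id,
        hemisphere=hemisphere,
        contact_coords=contacts,
        active_contact=active_contact,
        amplitude_v=amplitude_v,
        frequency_hz=frequency_hz,
        pulse_width_us=pulse_width_us,
    )


def _bezier(p0, p1, p2, n_points):
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def make_tractogram(
    atlas: LabelAtlas,
    n_fibers_per_bundle: int = 200,
    rng: np.random.Generator | None = None,
    n_points: int = 24,
) -> tuple:
    """Two smooth synthetic bundles; returns (tractogram, bundle_ids).

    Bundle "PFC": from limbic (ventral) STN voxel centers, curving
    anteriorly then up into the PFC-like box.  Bundle "SMC": from
    sensorimotor (dorsal) STN voxels, curving posteriorly into the SMC-like
    box.  ``bundle_ids`` maps bundle name -> list of fiber indices.
    """
    if n_fibers_per_bundle < 10:
        raise ValueError("need at least 10 fibers per bundle")
    rng = rng or np.random.default_rng(0)
    vol = atlas.volume

    def seeds(sub):
        masks = [atlas.mask(f"STN_{h}_{sub}") for h in ("left", "right")]
        ijk = np.concatenate([np.argwhere(m) for m in masks])
        return vol.voxel_to_world(ijk)

    streamlines, bundles = [], {"PFC": [], "SMC": []}
    for name, sub, box, y_ctrl in (
        ("PFC", "limbic", PFC_BOX, 6.0),
        ("SMC", "sensorimotor", SMC_BOX, -6.0),
    ):
        pts = seeds(sub)
        idx = rng.integers(0, len(pts), size=n_fibers_per_bundle)
        for i in idx:
            start = pts[i]
            end = np.array([
                np.clip(start[0] + rng.normal(0, 2.0), box["x"][0] + 0.5, box["x"][1] - 0.5),
                rng.uniform(box["y"][0] + 1.0, box["y"][1] - 1.0),
                rng.uniform(box["z"][0] + 1.0, box["z"][1] - 1.0),
            ])
            ctrl = np.array([start[0], y_ctrl, start[2]])
            bundles[name].append(len(streamlines))
            streamlines.append(_bezier(start, ctrl, end, n_points))
    return Tractogram(streamlines), bundles


def sweet_sphere_indices(grid: ImageVolume, center=SWEET_CENTER, radius=SWEET_RADIUS_MM) -> np.ndarray:
    """Flat voxel indices of the planted sweet sphere on ``grid``."""
    xyz = grid.world_coordinates()
    inside = ((xyz - np.asarray(center)) ** 2).sum(axis=-1) <= radius**2
    return np.flatnonzero(inside.ravel())


def simulate_outcomes(
    skeleton: CohortDataset,
    ground_truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list:
    """Clinical records for every patient of a cohort skeleton (a cohort
    with electrodes/atlas/tractogram but no clinical records yet).

    HAMA and HAMD carry the planted change (independent noise draws);
    UPDRS-III, PDQ-39 and LEDD get generic plausible improvements so the
    cohort summary machinery has realistic input.
    """
    rng = rng or np.random.default_rng(ground_truth.rng_seed)
    grid = skeleton.atlas.volume
    vtas = compute_cohort_vtas(skeleton)
    pids = sorted({e.patient_id for e in skeleton.electrodes})
    unions = []
    for pid in pids:
        parts = [v.flat_indices for (p, _), v in vtas.items() if p == pid]
        unions.append(np.unique(np.concatenate(parts)))

    sphere = sweet_sphere_indices(grid, ground_truth.sweet_center, ground_truth.sweet_radius_mm)
    overlap_frac = np.array([
        np.intersect1d(u, sphere, assume_unique=True).size / sphere.size for u in unions
    ])

    tract_part = np.zeros(len(pids))
    if ground_truth.bundles and skeleton.tractogram.count:
        conn = streamline_vta_connectivity(skeleton.tractogram, unions, grid)
        for name, w in ground_truth.tract_effect_weights.items():
            ids = np.asarray(ground_truth.bundles.get(name, []), dtype=int)
            if ids.size:
                tract_part += w * conn.matrix[ids].mean(axis=0)

    signal = ground_truth.voxel_effect_weight * overlap_frac + tract_part
    sd = ground_truth.noise_sd

    records = []
    for i, pid in enumerate(pids):
        hama_pre = rng.uniform(5.0, 15.0)
        hama_change = signal[i] + rng.normal(0.0, sd) if sd > 0 else signal[i]
        hamd_pre = rng.uniform(6.0, 14.0)
        hamd_change = signal[i] + rng.normal(0.0, sd) if sd > 0 else signal[i]
        updrs_pre = rng.uniform(32.0, 55.0)
        updrs_rate = np.clip(rng.normal(0.42, 0.08), 0.05, 0.9)
        pdq_pre = float(np.clip(rng.normal(50.0, 19.0), 15.0, 95.0))
        pdq_rate = np.clip(rng.normal(0.45, 0.12), 0.05, 0.9)
        ledd_pre = rng.uniform(520.0, 975.0)
        ledd_post = rng.uniform(195.0, 305.0)
        records.append(ClinicalRecord(pid, {
            "UPDRS_III": (updrs_pre, updrs_pre * (1 - updrs_rate)),
            "PDQ39": (pdq_pre, pdq_pre * (1 - pdq_rate)),
            "HAMA": (hama_pre, max(hama_pre - hama_change, 0.0)),
            "HAMD": (hamd_pre, max(hamd_pre - hamd_change, 0.0)),
            "LEDD": (ledd_pre, ledd_post),
        }))
    return records


def generate_cohort(
    n_patients: int = 56,
    scenario: str = "ventral_effect",
    seed: int = 0,
    noise_sd: float | None = None,
    n_fibers_per_bundle: int = 200,
    grid_shape=(64, 64, 64),
    voxel_size_mm: float = 0.5,
) -> CohortDataset:
    """Complete synthetic cohort with ground truth.

    Per-patient dorsoventral targeting offsets are one Uniform[0, 10] mm
    draw per patient shared across hemispheres plus a small per-side
    deviation, so active-contact depth varies over the ventral-to-dorsal
    extent of the STN and beyond, in both hemispheres jointly.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    if n_patients < 8:
        raise ValueError("need at least 8 patients for the analysis stages")
    w_v, w_b, default_sd = SCENARIOS[scenario]
    sd = default_sd if noise_sd is None else float(noise_sd)

    rng = np.random.default_rng(seed)
    atlas = make_toy_atlas(grid_shape, voxel_size_mm)

    electrodes = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        depth = rng.uniform(0.0, 10.0)
        for hemi in ("left", "right"):
            offset = float(np.clip(depth + rng.normal(0.0, 0.75), 0.0, 11.0))
            electrodes.append(make_electrode(
                atlas, hemi,
                dorsoventral_offset_mm=offset,
                rng=rng,
                patient_id=pid,
                amplitude_v=float(np.clip(rng.normal(2.5, 0.31), 1.0, 4.0)),
                frequency_hz=float(np.clip(rng.normal(128.62, 18.74), 60.0, 185.0)),
                pulse_width_us=float(np.clip(rng.normal(64.29, 6.64), 30.0, 120.0)),
            ))

    tractogram, bundles = make_tractogram(atlas, n_fibers_per_bundle, rng)
    gt = GroundTruth(
        sweet_center=SWEET_CENTER,
        sweet_radius_mm=SWEET_RADIUS_MM,
        voxel_effect_weight=w_v,
        tract_effect_weights=w_b,
        noise_sd=sd,
        rng_seed=seed,
        scenario=scenario,
        bundles=bundles,
    )
    skeleton = CohortDataset(atlas, electrodes, [], tractogram, ground_truth=gt)
    clinical = simulate_outcomes(skeleton, gt, rng)
    return CohortDataset(atlas, electrodes, clinical, tractogram, ground_truth=gt)
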