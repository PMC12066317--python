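"""Core data model for DBS outcome mapping.

All spatial quantities live in a single world frame: RAS-oriented
millimetres (an MNI-like space), so +X = right, +Y = anterior, +Z =
superior; "more ventral" always means smaller Z.  Images carry a 4x4
voxel-index -> world-mm affine; voxel indices are 0-based and masks are
defined on voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Clinical scales tracked by default.  Change = pre - post, so a positive
#: change is an improvement on every scale (all are "lower is better").
SCALES = ("UPDRS_III", "PDQ39", "HAMA", "HAMD", "LEDD")

HEMISPHERES = ("left", "right")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass
class LeadGeometry:
    """Four-contact DBS lead geometry (config parameter; mm).

    The lead model the cohort used is not parameterised anywhere public,
    so spacing/length are configurable with conventional quadripolar
    defaults.
    """

    n_contacts: int = 4
    contact_spacing_mm: float = 2.0   # center-to-center
    contact_radius_mm: float = 0.635
    contact_length_mm: float = 1.5


@dataclass
class ImageVolume:
    """A 3-D scalar/label grid with a voxel->world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "MNI-like"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        problems = []
        if self.data.ndim != 3:
            problems.append(
                f"expected 3-D volume, got {self.data.ndim}-D shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            problems.append(f"affine must be 4x4, got {self.affine.shape}")
        elif abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            problems.append("affine is not invertible")
        if problems:
            raise ValidationError(problems)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (N,3) to world mm (N,3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (N,3) to fractional voxel indices (N,3)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (*shape, 3)."""
        ii, jj, kk = np.meshgrid(
            *[np.arange(n, dtype=float) for n in self.shape], indexing="ij"
        )
        ijk = np.stack([ii, jj, kk], axis=-1)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on the same grid."""
        return ImageVolume(np.asarray(data), self.affine.copy(), self.space_tag)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class LabelAtlas:
    """Integer label volume plus a label -> region-name legend.

    Region naming convention: ``STN_<hemi>_<subregion>`` for the three STN
    subregions (sensorimotor / associative / limbic) per hemisphere.  The
    aggregate nuclei ``STN_left`` / ``STN_right`` are derived as the union
    of their subregions.
    """

    volume: ImageVolume
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.legend = dict(self.legend)
        problems = []
        present = set(np.unique(self.volume.data).astype(int).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            problems.append(f"labels {sorted(unknown)} present in volume but not in legend")
        for hemi in HEMISPHERES:
            for sub in ("sensorimotor", "associative", "limbic"):
                name = f"STN_{hemi}_{sub}"
                if name not in self.legend.values():
                    problems.append(f"legend missing required region {name}")
        if problems:
            raise ValidationError(problems)

    @property
    def name_to_label(self) -> dict:
        return {v: k for k, v in self.legend.items()}

    def stn_labels(self, hemisphere: str) -> list:
        """Label ids of the three STN subregions of one hemisphere."""
        n2l = self.name_to_label
        return [n2l[f"STN_{hemisphere}_{s}"] for s in ("sensorimotor", "associative", "limbic")]

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask for a named region (subregion or whole STN)."""
        if region in ("STN_left", "STN_right"):
            hemi = region.split("_")[1]
            return np.isin(self.volume.data, self.stn_labels(hemi))
        return self.volume.data == self.name_to_label[region]


@dataclass
class ElectrodeRecord:
    """One implanted lead: 4 ordered contact coordinates plus the active
    monopolar stimulation setting.  Contact 0 is the most distal (ventral)."""

    patient_id: str
    hemisphere: str
    contact_coords: np.ndarray  # (4, 3) world mm, contact 0 first
    active_contact: int
    amplitude_v: float
    frequency_hz: float
    pulse_width_us: float
    mode: str = "monopolar"

    def __post_init__(self) -> None:
        self.contact_coords = np.asarray(self.contact_coords, dtype=float)
        problems = self._problems()
        if problems:
            raise ValidationError(problems)

    def _problems(self, lead: LeadGeometry | None = None) -> list:
        lead = lead or LeadGeometry()
        p = []
        if self.hemisphere not in HEMISPHERES:
            p.append(f"unknown hemisphere {self.hemisphere!r}")
        if self.contact_coords.shape != (lead.n_contacts, 3):
            p.append(f"expected {lead.n_contacts} contact coordinates, got shape {self.contact_coords.shape}")
            return p
        if not np.all(np.isfinite(self.contact_coords)):
            p.append("non-finite contact coordinate")
            return p
        if not 0 <= int(self.active_contact) < lead.n_contacts:
            p.append(f"active_contact {self.active_contact} out of range")
        if self.amplitude_v < 0:
            p.append(f"amplitude {self.amplitude_v} V is negative")
        if self.mode != "monopolar":
            p.append(f"unsupported stimulation mode {self.mode!r} (only monopolar)")
        # collinearity + spacing against the configured lead geometry
        d = np.diff(self.contact_coords, axis=0)
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - lead.contact_spacing_mm) > 0.2):
            p.append(f"contact spacing {norms.round(3).tolist()} deviates from lead geometry ({lead.contact_spacing_mm} mm)")
        if norms.min() > 0:
            units = d / norms[:, None]
            if np.any(np.abs(units - units[0]) > 0.02):
                p.append("contacts are not collinear within tolerance")
        return p

    @property
    def active_coordinate(self) -> np.ndarray:
        return self.contact_coords[int(self.active_contact)]


@dataclass
class ClinicalRecord:
    """Pre/post scale scores for one patient.

    ``scores`` maps scale name -> (pre, post).  Change = pre - post
    (positive = improvement on all tracked scales).
    """

    patient_id: str
    scores: Mapping[str, tuple]

    def __post_init__(self) -> None:
        self.scores = {k: (float(v[0]), float(v[1])) for k, v in dict(self.scores).items()}

    def pre(self, scale: str) -> float:
        return self.scores[scale][0]

    def post(self, scale: str) -> float:
        return self.scores[scale][1]

    def change(self, scale: str) -> float:
        pre, post = self.scores[scale]
        return pre - post

    def improvement_rate(self, scale: str) -> float:
        """[(pre - post) / pre] x 100, in percent; NaN when pre == 0."""
        pre, post = self.scores[scale]
        if pre == 0:
            return float("nan")
        return (pre - post) / pre * 100.0


@dataclass
class Tractogram:
    """Streamlines as ordered polylines of world-mm points (>= 2 each)."""

    streamlines: list

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        problems = []
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                problems.append(f"streamline {i}: expected (n>=2, 3) points, got shape {s.shape}")
            elif not np.all(np.isfinite(s)):
                problems.append(f"streamline {i}: non-finite point")
        if problems:
            raise ValidationError(problems)

    @property
    def count(self) -> int:
        return len(self.streamlines)


@dataclass
class GroundTruth:
    """Planted generative parameters of a synthetic cohort (for recovery tests)."""

    sweet_center: np.ndarray          # world mm
    sweet_radius_mm: float
    voxel_effect_weight: float
    tract_effect_weights: Mapping[str, float]   # bundle name -> signed weight
    noise_sd: float
    rng_seed: int
    scenario: str
    bundles: Mapping[str, list] = field(default_factory=dict)  # bundle -> fiber ids

    def __post_init__(self) -> None:
        self.sweet_center = np.asarray(self.sweet_center, dtype=float)
        problems = []
        if not self.sweet_radius_mm > 0:
            problems.append("sweet_radius_mm must be > 0")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ValidationError(problems)

    def to_dict(self) -> dict:
        return {
            "sweet_center": self.sweet_center.tolist(),
            "sweet_radius_mm": self.sweet_radius_mm,
            "voxel_effect_weight": self.voxel_effect_weight,
            "tract_effect_weights": dict(self.tract_effect_weights),
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "scenario": self.scenario,
            "bundles": {k: list(map(int, v)) for k, v in self.bundles.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            sweet_center=np.asarray(d["sweet_center"], dtype=float),
            sweet_radius_mm=float(d["sweet_radius_mm"]),
            voxel_effect_weight=float(d["voxel_effect_weight"]),
            tract_effect_weights={k: float(v) for k, v in d["tract_effect_weights"].items()},
            noise_sd=float(d["noise_sd"]),
            rng_seed=int(d["rng_seed"]),
            scenario=str(d["scenario"]),
            bundles={k: list(map(int, v)) for k, v in d.get("bundles", {}).items()},
        )


@dataclass
class CohortDataset:
    """Everything one analysis run consumes: atlas + electrodes + clinical
    scores + (shared, normative-style) tractogram, with optional ground truth
    for synthetic cohorts."""

    atlas: LabelAtlas
    electrodes: list
    clinical: list
    tractogram: Tractogram
    ground_truth: GroundTruth | None = None
    lead: LeadGeometry = field(default_factory=LeadGeometry)

    def __post_init__(self) -> None:
        problems = []
        e_ids = {e.patient_id for e in self.electrodes}
        c_ids = {c.patient_id for c in self.clinical}
        # an empty clinical list marks a cohort "skeleton" awaiting simulated
        # outcomes; cross-table checks apply once any clinical data exists
        if self.clinical:
            for pid in sorted(e_ids - c_ids):
                problems.append(f"patient {pid} has electrodes but no clinical record")
            for pid in sorted(c_ids - e_ids):
                problems.append(f"patient {pid} has clinical record but no electrodes")
        seen = {}
        for e in self.electrodes:
            key = (e.patient_id, e.hemisphere)
            seen[key] = seen.get(key, 0) + 1
        for (pid, hemi), n in sorted(seen.items()):
            if n > 1:
                problems.append(f"duplicate electrode record for ({pid}, {hemi})")
        for pid in sorted(e_ids & c_ids):
            hemis = {e.hemisphere for e in self.electrodes if e.patient_id == pid}
            missing = set(HEMISPHERES) - hemis
            if missing:
                problems.append(f"patient {pid} missing {sorted(missing)} electrode")
        dup_c = [pid for pid in c_ids if sum(c.patient_id == pid for c in self.clinical) > 1]
        for pid in sorted(dup_c):
            problems.append(f"duplicate clinical record for patient {pid}")
        if problems:
            raise ValidationError(problems)

    @property
    def patients(self) -> list:
        return sorted({c.patient_id for c in self.clinical})

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def electrode(self, patient_id: str, hemisphere: str) -> ElectrodeRecord:
        for e in self.electrodes:
            if e.patient_id == patient_id and e.hemisphere == hemisphere:
                return e
        raise KeyError((patient_id, hemisphere))

    def clinical_record(self, patient_id: str) -> ClinicalRecord:
        for c in self.clinical:
            if c.patient_id == patient_id:
                return c
        raise KeyError(patient_id)

    def changes(self, scale: str) -> np.ndarray:
        """Per-patient change scores aligned with ``self.patients``."""
        return np.array([self.clinical_record(p).change(scale) for p in self.patients])

    def improvement_rates(self, scale: str) -> np.ndarray:
        return np.array(
            [self.clinical_record(p).improvement_rate(scale) for p in self.patients]
        )
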