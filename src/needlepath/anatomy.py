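"""Labeled-volume IO, anatomical role binding, and run configuration.

Conventions used throughout the package:

* voxel indices are 0-based with axis order (x, y, z);
* the world coordinate of voxel (i, j, k) is ``origin + (i, j, k) * spacing``
  (voxel-center convention), all geometry in millimetres;
* label 0 is background/air; anatomical labels are positive integers.

Oblique acquisitions are rejected: the image direction matrix must be the
identity, i.e. the CT axes coincide with the world axes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError, EmptyStructureError, FormatError

logger = logging.getLogger(__name__)

#: All role names a scene may bind.
ROLE_NAMES = frozenset(
    {
        "skin",
        "lung_target_lobe",
        "lung_other",
        "tumor",
        "bone",
        "heart",
        "vessels",
        "bronchi",
        "mediastinum",
    }
)

#: Roles that must be present in every scene.
MANDATORY_ROLES = ("tumor", "skin", "lung_target_lobe")

#: Structures a trajectory must never cross (hard constraint H1).
DEFAULT_RISK_ROLES = (
    "bone",
    "bronchi",
    "vessels",
    "heart",
    "mediastinum",
    "lung_other",
)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


@dataclass
class LabeledVolume:
    """Integer label map on a regular anisotropic grid.

    Attributes
    ----------
    labels
        Integer array of shape ``(W, H, D)``, axis order (x, y, z).
    spacing
        Voxel size in mm per axis, all components > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label volume must be integer, got {self.labels.dtype}")
        if self.labels.ndim != 3 or min(self.labels.shape) < 3:
            raise FormatError(f"volume must be 3D with every side >= 3, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise FormatError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.origin.shape != (3,):
            raise FormatError(f"origin must be 3 reals, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers ``ijk`` (…, 3)."""
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points ``xyz`` (…, 3)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """True where a world point falls inside the voxel lattice extent."""
        v = self.world_to_index(xyz)
        hi = np.asarray(self.shape) - 0.5
        return np.all((v >= -0.5) & (v <= hi), axis=-1)


def write_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a label volume to NIfTI / NRRD / MetaImage, chosen by suffix."""
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.labels.T))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> LabeledVolume:
    """Read a label volume (NIfTI / NRRD / MetaImage)."""
    path = Path(path)
    if not str(path).lower().endswith(_SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name}")
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError("oblique direction matrices are not supported (identity orientation required)")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"non-integer voxel type {arr.dtype}; labeled segmentation expected")
    return LabeledVolume(
        labels=np.ascontiguousarray(arr.T),
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


@dataclass
class AnatomyScene:
    """A labeled thorax volume with anatomical roles bound to label values.

    ``roles`` maps role names (subset of :data:`ROLE_NAMES`) to tuples of label
    values. ``risk_roles`` is the subset of bound roles whose structures a
    trajectory must never cross.
    """

    volume: LabeledVolume
    roles: dict[str, tuple[int, ...]]
    risk_roles: tuple[str, ...] = ()
    _mask_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.roles = {k: tuple(int(v) for v in vals) for k, vals in self.roles.items()}
        unknown = set(self.roles) - ROLE_NAMES
        if unknown:
            raise ConfigurationError(f"unknown role name(s): {sorted(unknown)}")
        for role in MANDATORY_ROLES:
            if not self.roles.get(role):
                raise ConfigurationError(f"mandatory role {role!r} is missing or empty")
        present = set(np.unique(self.volume.labels).tolist())
        for role, vals in self.roles.items():
            absent = [v for v in vals if v not in present]
            if absent:
                raise ConfigurationError(f"role {role!r} references label(s) {absent} absent from the volume")
        if not self.risk_roles:
            self.risk_roles = tuple(r for r in DEFAULT_RISK_ROLES if r in self.roles)
        bad = [r for r in self.risk_roles if r not in self.roles]
        if bad:
            raise ConfigurationError(f"risk role(s) {bad} not bound in the scene")

    # -- convenience accessors -------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.volume.labels

    @property
    def spacing(self) -> np.ndarray:
        return self.volume.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.volume.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    def label_set(self, *roles: str) -> frozenset[int]:
        out: set[int] = set()
        for role in roles:
            out.update(self.roles.get(role, ()))
        return frozenset(out)

    def role_mask(self, *roles: str) -> np.ndarray:
        """Boolean voxel mask of the union of the given roles (cached)."""
        key = tuple(sorted(roles))
        if key not in self._mask_cache:
            self._mask_cache[key] = np.isin(self.labels, sorted(self.label_set(*roles)))
        return self._mask_cache[key]

    def risk_mask(self) -> np.ndarray:
        return self.role_mask(*self.risk_roles)

    def body_mask(self) -> np.ndarray:
        """Everything enclosed by the skin (any non-background label)."""
        if "body" not in self._mask_cache:
            self._mask_cache["body"] = self.labels > 0
        return self._mask_cache["body"]

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update(self.spacing.tobytes())
        h.update(self.origin.tobytes())
        h.update(json.dumps(sorted(self.roles.items())).encode())
        return h.hexdigest()


def read_roles(path: str | Path) -> dict[str, tuple[int, ...]]:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("roles file must be a JSON object mapping role -> label list")
    return {str(k): tuple(int(v) for v in vals) for k, vals in raw.items()}


def write_roles(roles: Mapping[str, Sequence[int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in roles.items()}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_scene(volume_path: str | Path, roles_path: str | Path) -> AnatomyScene:
    """Load a volume and its role binding into an :class:`AnatomyScene`."""
    return AnatomyScene(volume=read_volume(volume_path), roles=read_roles(roles_path))


def tumor_centroid(scene: AnatomyScene) -> np.ndarray:
    """Unweighted mean world coordinate (mm) of all tumor voxels.

    This point is the target C every candidate trajectory aims at.
    """
    mask = scene.role_mask("tumor")
    if not mask.any():
        raise EmptyStructureError("tumor mask is empty")
    ijk = np.argwhere(mask)
    return scene.volume.index_to_world(ijk).mean(axis=0)


class PlanConfig(BaseModel):
    """Run configuration for the planner.

    Attributes
    ----------
    needle_length_mm
        Shaft length of the ablation applicator; the percutaneous path length
        must be strictly shorter (H2).
    angle_threshold_deg
        Minimum pleural entry angle; paths at or below it are discarded (H3).
    depth_margin_mm
        Required intrapulmonary depth beyond the ablation zone (H4).
    ablation_margin_mm
        Safety margin added around the tumor to form the expected ablation
        zone (clinically 5-10 mm).
    weights
        (λ1, λ2, λ3) for the soft constraints S1-S3; renormalized to sum 1.
    ray_step_mm
        Sampling step along candidate segments; defaults to half the smallest
        voxel spacing when left unset.
    """

    needle_length_mm: float = Field(default=150.0, gt=0)
    angle_threshold_deg: float = 20.0
    depth_margin_mm: float = Field(default=5.0, gt=0)
    ablation_margin_mm: float = Field(default=5.0, gt=0)
    weights: tuple[float, float, float] = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    top_k: int = Field(default=5, ge=1)
    ray_step_mm: float | None = Field(default=None, gt=0)
    s1_full_ray: bool = False
    s3_printed_form: bool = False
    aggregate: str = "sum"
    seed: int = 0

    @field_validator("weights")
    @classmethod
    def _normalize_weights(cls, w: tuple[float, float, float]) -> tuple[float, float, float]:
        arr = np.asarray(w, dtype=float)
        if arr.shape != (3,) or np.any(arr < 0):
            raise ValueError("weights must be 3 non-negative reals")
        total = float(arr.sum())
        if total <= 0:
            raise ValueError("weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            logger.warning("weights %s do not sum to 1; renormalizing", w)
            arr = arr / total
        return tuple(float(x) for x in arr)  # type: ignore[return-value]

    @field_validator("aggregate")
    @classmethod
    def _check_aggregate(cls, v: str) -> str:
        if v not in ("sum", "product"):
            raise ValueError("aggregate must be 'sum' or 'product'")
        return v

    @model_validator(mode="after")
    def _check_sum(self) -> "PlanConfig":
        assert abs(sum(self.weights) - 1.0) <= 1e-9
        return self

    def resolved_ray_step(self, spacing: np.ndarray) -> float:
        step = self.ray_step_mm if self.ray_step_mm is not None else float(np.min(spacing)) / 2.0
        if step > float(np.min(spacing)) + 1e-12:
            raise ConfigurationError(
                f"ray_step_mm={step} exceeds the smallest voxel spacing {float(np.min(spacing))}"
            )
        return step

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanConfig":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(**data)
        except Exception as exc:  # pydantic ValidationError or TypeError
            raise ConfigurationError(str(exc)) from exc
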