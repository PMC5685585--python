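"""Patch grids and per-subject inter-patch connectivity.

A registered brain volume is partitioned into rectangular ``l1 x l2 x l3``
voxel patches, tiled separately over the two hemispheres starting at the
midsagittal plane (so medial tissue is covered first and a mirror-symmetric
mask yields mirror-symmetric patches). Each retained patch is one network
node; the connectivity between two nodes is the Pearson correlation between
their raveled voxel-intensity vectors — pure image similarity, with no
axonal or tractographic meaning.

Coordinates are 0-based voxel indices; boxes are half-open; volumes are
assumed 1 mm isotropic, so voxel counts and mm^3 coincide.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from patchconn.errors import SizingError, ValidationError

logger = logging.getLogger(__name__)

#: Default patch edge lengths (lateral, anterior-posterior, inferior-superior),
#: giving the standard 3000-voxel patch.
DEFAULT_PATCH_DIMS = (10, 15, 20)

#: Default minimum in-mask voxel fraction for a patch to become a node.
DEFAULT_RETENTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class Patch:
    """One axis-aligned box: ``origin`` voxel, ``extents`` edge lengths."""

    origin: tuple[int, int, int]
    extents: tuple[int, int, int]
    hemisphere: str  # "left" | "right"
    mask_fraction: float = 1.0

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(o, o + e) for o, e in zip(self.origin, self.extents)
        )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.extents))


@dataclass
class PatchGrid:
    """A fixed whole-brain partition into patches (the network nodes).

    Node order is deterministic: hemisphere ("left" before "right"), then
    patch origin in lexicographic order.
    """

    patches: list[Patch]
    volume_shape: tuple[int, int, int]
    patch_dims: tuple[int, int, int]
    midplane: int
    retention_threshold: float
    lateral_axis: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.patches)

    @property
    def hemispheres(self) -> list[str]:
        return [p.hemisphere for p in self.patches]

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "volume_shape": list(self.volume_shape),
            "patch_dims": list(self.patch_dims),
            "midplane": self.midplane,
            "retention_threshold": self.retention_threshold,
            "lateral_axis": self.lateral_axis,
            "patches": [
                {
                    "origin": list(p.origin),
                    "extents": list(p.extents),
                    "hemisphere": p.hemisphere,
                    "mask_fraction": p.mask_fraction,
                }
                for p in self.patches
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatchGrid":
        return cls(
            patches=[
                Patch(
                    origin=tuple(p["origin"]),
                    extents=tuple(p["extents"]),
                    hemisphere=p["hemisphere"],
                    mask_fraction=float(p["mask_fraction"]),
                )
                for p in d["patches"]
            ],
            volume_shape=tuple(d["volume_shape"]),
            patch_dims=tuple(d["patch_dims"]),
            midplane=int(d["midplane"]),
            retention_threshold=float(d["retention_threshold"]),
            lateral_axis=int(d.get("lateral_axis", 0)),
        )


def _axis_starts(size: int, edge: int) -> list[int]:
    return list(range(0, size - edge + 1, edge))


def _lateral_starts(size: int, mid: int, edge: int) -> tuple[list[int], list[int]]:
    """Tile the lateral axis outward from the midplane.

    Left hemisphere boxes end at or before ``mid``; right hemisphere boxes
    start at or after ``mid``. Both sides are anchored at the midplane, so
    a mirror-symmetric mask gets mirrored tilings.
    """
    right = list(range(mid, size - edge + 1, edge))
    left = list(range(mid - edge, -1, -edge))
    left.reverse()
    return left, right


def build_patch_grid(
    mask: np.ndarray,
    patch_dims: tuple[int, int, int] = DEFAULT_PATCH_DIMS,
    retention_threshold: float = DEFAULT_RETENTION_THRESHOLD,
    lateral_axis: int = 0,
) -> PatchGrid:
    """Tile the mask with patches, split at the midsagittal plane.

    The midplane is the sagittal index ``floor(X/2)`` of the lateral axis.
    A candidate box is retained as a node iff it contains at least one
    in-mask voxel and its in-mask fraction is >= ``retention_threshold``.

    Parameters
    ----------
    mask : bool array, 3-D
        Brain mask in template space.
    patch_dims : (l1, l2, l3)
        Patch edge lengths, assigned to (lateral, AP, IS) axes by default.
    retention_threshold : float in [0, 1]
        Minimum in-mask voxel fraction of a retained patch.
    lateral_axis : int
        Which array axis is left-right.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValidationError(f"mask must be 3-D, got ndim={mask.ndim}")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("mask is empty (no in-mask voxels)")
    if not 0.0 <= retention_threshold <= 1.0:
        raise ValidationError(
            f"retention_threshold must be in [0, 1], got {retention_threshold}"
        )
    patch_dims = tuple(int(d) for d in patch_dims)
    if len(patch_dims) != 3 or any(d < 1 for d in patch_dims):
        raise SizingError(f"patch_dims must be 3 positive ints, got {patch_dims}")

    shape = mask.shape
    axes = [lateral_axis] + [a for a in range(3) if a != lateral_axis]
    # patch_dims[0] is the lateral edge regardless of which axis is lateral
    edge = {axes[i]: patch_dims[i] for i in range(3)}

    size_lat = shape[lateral_axis]
    mid = size_lat // 2
    left_lat, right_lat = _lateral_starts(size_lat, mid, edge[lateral_axis])
    if not left_lat or not right_lat:
        raise SizingError(
            f"patch edge {edge[lateral_axis]} does not fit in a hemisphere of "
            f"width {mid} / {size_lat - mid}"
        )
    other = [a for a in range(3) if a != lateral_axis]
    starts_other = {a: _axis_starts(shape[a], edge[a]) for a in other}
    for a in other:
        if not starts_other[a]:
            raise SizingError(
                f"patch edge {edge[a]} exceeds volume extent {shape[a]} on axis {a}"
            )

    patches: list[Patch] = []
    for hemi, lat_starts in (("left", left_lat), ("right", right_lat)):
        for s_lat in lat_starts:
            for s1 in starts_other[other[0]]:
                for s2 in starts_other[other[1]]:
                    origin = [0, 0, 0]
                    origin[lateral_axis] = s_lat
                    origin[other[0]] = s1
                    origin[other[1]] = s2
                    extents = [0, 0, 0]
                    for a in range(3):
                        extents[a] = edge[a]
                    box = tuple(
                        slice(o, o + e) for o, e in zip(origin, extents)
                    )
                    frac = float(mask[box].mean())
                    if frac > 0.0 and frac >= retention_threshold:
                        patches.append(
                            Patch(
                                origin=tuple(origin),
                                extents=tuple(extents),
                                hemisphere=hemi,
                                mask_fraction=frac,
                            )
                        )
    if not patches:
        raise SizingError("no patch met the retention threshold")
    patches.sort(key=lambda p: (p.hemisphere, p.origin))
    return PatchGrid(
        patches=patches,
        volume_shape=shape,
        patch_dims=patch_dims,
        midplane=mid,
        retention_threshold=retention_threshold,
        lateral_axis=lateral_axis,
    )


def extract_patch_vector(volume: np.ndarray, patch: Patch) -> np.ndarray:
    """Serialize a patch's voxels into a vector of length l1*l2*l3.

    Raster order is fixed (C order, axis 0 slowest) and identical for every
    subject and patch, so correlations compare corresponding voxels.
    """
    volume = np.asarray(volume)
    for o, e, s in zip(patch.origin, patch.extents, volume.shape):
        if o < 0 or o + e > s:
            raise IndexError(
                f"patch origin={patch.origin} extents={patch.extents} is out "
                f"of bounds for volume shape {volume.shape}"
            )
    return volume[patch.slices].ravel(order="C").astype(float)


@dataclass
class ConnectivityMatrix:
    """One subject's N x N inter-patch Pearson network.

    ``flagged_nodes`` lists nodes whose patch vector had zero variance; their
    off-diagonal entries are 0 by policy (the node is kept so the matrix
    dimension stays uniform across subjects).
    """

    values: np.ndarray
    subject_id: str = ""
    grid_hash: str = ""
    flagged_nodes: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=atol):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValidationError("matrix diagonal is not 1")
        if np.abs(v).max() > 1.0 + atol:
            raise ValidationError("matrix entries exceed [-1, 1]")


def compute_connectivity(
    volume: np.ndarray, grid: PatchGrid, subject_id: str = ""
) -> ConnectivityMatrix:
    """Pearson correlation between every pair of patch vectors.

    The matrix is symmetric with unit diagonal by construction. Zero-variance
    patches (Pearson undefined) get 0 in all their off-diagonal entries and
    are flagged; a warning is logged.
    """
    volume = np.asarray(volume, dtype=float)
    if tuple(volume.shape) != tuple(grid.volume_shape):
        raise ValidationError(
            f"volume shape {volume.shape} does not match grid shape "
            f"{grid.volume_shape}"
        )
    vectors = np.stack(
        [extract_patch_vector(volume, p) for p in grid.patches]
    )  # (N, L)
    L = vectors.shape[1]
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_var = norms == 0.0
    if zero_var.any():
        flagged = tuple(int(i) for i in np.flatnonzero(zero_var))
        logger.warning(
            "subject %s: zero-variance patch vector(s) at node(s) %s; "
            "their connectivity entries are set to 0",
            subject_id or "<unnamed>", flagged,
        )
    else:
        flagged = ()
    safe = np.where(zero_var, 1.0, norms)
    unit = centered / safe[:, None]
    unit[zero_var] = 0.0
    C = unit @ unit.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(
        values=C,
        subject_id=subject_id,
        grid_hash=grid.content_hash(),
        flagged_nodes=flagged,
    )


def mean_strength(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Mean absolute value over all N^2 entries (diagonal included).

    The unit diagonal adds the same constant N/N^2 to every subject, so
    group comparisons of strength are unaffected by its inclusion.
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    return float(np.abs(np.asarray(values)).mean())
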