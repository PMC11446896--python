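"""Click-seeded CT bone segmentation and marching-cubes surface extraction.

The clinical workflow segments the zygoma from a CT by placing seed clicks
on bone; each click adds the connected bone region around it.  Here that is
a threshold + 26-connected region-growing operation: the mask is the union,
over all seeds, of the 26-connected component of ``{intensity >= threshold}``
containing each seed.  Adding seeds can therefore only grow the mask, and
lowering the threshold (with fixed seeds) yields a superset.

Surfaces are extracted with marching cubes at the 0.5 iso-level of the
binary mask, in index space, then scaled into world millimetres; anisotropic
voxel spacing is fully supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from zygoplan.geometry import GeometryError, make_mesh

#: conventional cortical-bone cutoff in Hounsfield units
DEFAULT_BONE_THRESHOLD_HU = 300.0


class SegmentationError(ValueError):
    """Invalid seed, threshold or mask."""


@dataclass
class ScalarVolume:
    """A CT-like scalar volume: intensities (HU) on a regular voxel grid.

    Voxel index ``(i, j, k)`` maps to world millimetres as
    ``origin + spacing * (i, j, k)`` (0-based indices, right-handed frame).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise SegmentationError(
                f"volume must be 3D with >= 2 voxels per axis, got {self.data.shape}"
            )
        if (self.spacing <= 0).any():
            raise SegmentationError(f"spacing must be positive, got {self.spacing}")

    def index_to_world(self, ijk) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(ijk, dtype=float)

    # -- file I/O ------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> Path:
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, affine), str(path))
        return Path(path)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScalarVolume":
        """Read NIfTI (.nii/.nii.gz) via nibabel or NRRD via SimpleITK."""
        path = Path(path)
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            affine = img.affine
            spacing = np.linalg.norm(affine[:3, :3], axis=0)
            return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])
        if name.endswith(".nrrd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
            return cls(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))
        raise SegmentationError(f"unsupported volume format: {path.name}")


@dataclass
class BinaryMask:
    """Segmentation result: a boolean volume plus the seeds/threshold used."""

    data: np.ndarray
    volume: ScalarVolume
    seeds: list[tuple[int, int, int]] = field(default_factory=list)
    threshold: float = DEFAULT_BONE_THRESHOLD_HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.volume.data.shape:
            raise SegmentationError("mask shape differs from source volume")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def to_nifti(self, path: str | Path) -> Path:
        import nibabel as nib

        affine = np.diag([*self.volume.spacing, 1.0])
        affine[:3, 3] = self.volume.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))
        return Path(path)


# 26-connectivity: permissive click-to-grow behaviour
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def seeded_segment(
    volume: ScalarVolume,
    seeds: list[tuple[int, int, int]],
    threshold: float = DEFAULT_BONE_THRESHOLD_HU,
) -> BinaryMask:
    """Region-grow bone from seed voxels above an HU threshold.

    The result is the union over seeds of the 26-connected component of
    ``{intensity >= threshold}`` containing each seed, so re-running with a
    mask's own provenance reproduces it exactly and extra seeds never shrink
    the mask.
    """
    if not seeds:
        raise SegmentationError("at least one seed voxel is required")
    shape = volume.data.shape
    idx = []
    for s in seeds:
        ijk = tuple(int(v) for v in s)
        if len(ijk) != 3 or any(v < 0 or v >= n for v, n in zip(ijk, shape)):
            raise SegmentationError(f"seed {s} outside volume of shape {shape}")
        hu = float(volume.data[ijk])
        if hu < threshold:
            raise SegmentationError(
                f"seed {ijk} has intensity {hu:.1f} HU, below threshold {threshold:.1f} HU"
            )
        idx.append(ijk)

    above = volume.data >= threshold
    labels, _ = ndimage.label(above, structure=_STRUCTURE)
    wanted = np.unique([labels[ijk] for ijk in idx])
    mask = np.isin(labels, wanted)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask")
    return BinaryMask(mask, volume, seeds=[tuple(s) for s in idx], threshold=float(threshold))


def extract_surface(mask: BinaryMask, closing_radius_voxels: int = 0) -> trimesh.Trimesh:
    """Marching-cubes isosurface (level 0.5) of a mask, in world millimetres.

    The mask is zero-padded so surfaces at the array border close; an
    optional binary closing smooths single-voxel pits first.  The output is
    a consistently outward-oriented surface; for a solid mask it is closed.
    """
    data = mask.data
    if not data.any():
        raise SegmentationError("cannot extract a surface from an empty mask")
    if closing_radius_voxels > 0:
        r = int(closing_radius_voxels)
        ball = ndimage.generate_binary_structure(3, 1)
        data = ndimage.binary_closing(data, ball, iterations=r)
    padded = np.pad(data, 1).astype(np.uint8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # index space -> world: un-pad, then scale anisotropically
    world = mask.volume.origin + (verts - 1.0) * mask.volume.spacing
    mesh = make_mesh(world, faces)
    if mesh.volume < 0:
        mesh.invert()
    return mesh
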