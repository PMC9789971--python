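"""Grey-matter parcellations: a label volume plus per-region metadata.

A parcellation is the node definition of the connectome: an integer label
volume in which 0 is background/white matter and every positive label is one
grey-matter region of interest (ROI) carrying a name and a hemisphere tag
(``left``, ``right`` or ``midline``). Voxel indices map to world (scanner) mm
coordinates through an invertible 4x4 affine, as in NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataContractError

HEMISPHERES = ("left", "right", "midline")


@dataclass
class Parcellation:
    """Label volume with region names and hemisphere tags.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Region label per voxel; 0 is background / white matter.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm transform (invertible).
    names : dict
        Maps every nonzero label to a region name.
    hemisphere : dict
        Maps every nonzero label to ``left`` / ``right`` / ``midline``.
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str]
    hemisphere: dict[int, str]
    _inv_affine: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataContractError("label volume must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DataContractError("affine must be 4x4")
        try:
            self._inv_affine = np.linalg.inv(self.affine)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise DataContractError("affine is not invertible") from exc
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise DataContractError(f"labels without names: {sorted(missing)}")
        for lab, hemi in self.hemisphere.items():
            if hemi not in HEMISPHERES:
                raise DataContractError(f"bad hemisphere tag {hemi!r} for label {lab}")
        missing = present - set(self.hemisphere)
        if missing:
            raise DataContractError(f"labels without hemisphere: {sorted(missing)}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths of a voxel in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def roi_labels(self) -> list[int]:
        """Sorted nonzero labels present in the metadata."""
        return sorted(self.names)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return nib.affines.apply_affine(self.affine, ijk)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates for world mm points."""
        xyz = np.atleast_2d(xyz)
        return nib.affines.apply_affine(self._inv_affine, xyz)

    # -- I/O --------------------------------------------------------------
    def save(self, nifti_path: str | Path, metadata_path: str | Path) -> None:
        """Write the label volume as NIfTI (uint16) and metadata as CSV."""
        img = nib.Nifti1Image(self.labels.astype(np.uint16), self.affine)
        nib.save(img, str(nifti_path))
        rows = [
            {"label": lab, "name": self.names[lab], "hemisphere": self.hemisphere[lab]}
            for lab in self.roi_labels
        ]
        pd.DataFrame(rows).to_csv(metadata_path, index=False)

    @classmethod
    def load(cls, nifti_path: str | Path, metadata_path: str | Path) -> "Parcellation":
        img = nib.load(str(nifti_path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        meta = pd.read_csv(metadata_path)
        names = {int(r.label): str(r.name) for r in meta.itertuples(index=False)}
        hemis = {int(r.label): str(r.hemisphere) for r in meta.itertuples(index=False)}
        return cls(labels=labels, affine=np.asarray(img.affine), names=names, hemisphere=hemis)
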