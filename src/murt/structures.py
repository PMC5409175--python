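"""Named integer-label structure sets sharing a grid with a reference volume."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .image import FormatError, ImageVolume, Modality, read_volume, write_volume


@dataclass
class StructureSet:
    """Integer 3D label grid plus a label -> name map.

    Label 0 is background.  Every nonzero label present in the grid must
    be named.  Organ masks are expected to be subsets of the ``body`` (or
    ``gel``) envelope where one exists.
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise FormatError("labels must be a 3D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = np.rint(lab).astype(np.int16)
        self.labels = lab
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise FormatError(f"unnamed labels present: {sorted(unnamed)}")

    # -- access --------------------------------------------------------
    @property
    def shape(self):
        return self.labels.shape

    def label_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return k
        raise KeyError(f"no structure named {name!r}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def has(self, name: str) -> bool:
        return name in self.names.values()

    def centroid_world(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.mask(name))
        if idx.size == 0:
            raise ValueError(f"structure {name!r} is empty")
        c = idx.mean(axis=0)
        return c @ self.affine[:3, :3].T + self.affine[:3, 3]

    def volume_mm3(self, name: str) -> float:
        vpv = abs(np.linalg.det(self.affine[:3, :3]))
        return float(self.mask(name).sum()) * vpv

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.labels, self.affine.copy(), Modality.LABEL)

    @staticmethod
    def from_masks(masks: dict, affine: np.ndarray, meta: dict | None = None) -> "StructureSet":
        """Build from ``{name: boolean mask}``; later masks win on overlap."""
        names = {}
        labels = None
        for i, (name, m) in enumerate(masks.items(), start=1):
            m = np.asarray(m, dtype=bool)
            if labels is None:
                labels = np.zeros(m.shape, dtype=np.int16)
            labels[m] = i
            names[i] = name
        return StructureSet(labels, affine, names, meta or {})

    # -- I/O -----------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Write labels as NIfTI plus a ``.json`` sidecar name map."""
        path = os.fspath(path)
        write_volume(ImageVolume(self.labels.astype(np.int16), self.affine,
                                 Modality.LABEL), path)
        side = _sidecar_path(path)
        with open(side, "w") as fh:
            json.dump({"names": {str(k): v for k, v in self.names.items()},
                       "meta": self.meta}, fh, indent=2)

    @staticmethod
    def load(path: str | os.PathLike) -> "StructureSet":
        path = os.fspath(path)
        vol = read_volume(path, modality=Modality.LABEL)
        with open(_sidecar_path(path)) as fh:
            side = json.load(fh)
        names = {int(k): v for k, v in side["names"].items()}
        return StructureSet(np.rint(vol.voxels).astype(np.int16), vol.affine,
                            names, side.get("meta", {}))


def _sidecar_path(path: str) -> str:
    for ext in (".nii.gz", ".nii", ".mha", ".mhd"):
        if path.endswith(ext):
            return path[: -len(ext)] + ".json"
    return path + ".json"
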