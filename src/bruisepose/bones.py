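"""Bone-surface containers: a triangulated bone plus landmarks and patches.

A `BoneMesh` bundles a triangulated surface (any STL/PLY readable by
trimesh, units mm), its anatomical landmark set, and an optional
per-vertex compartment labelling (medial / lateral / none).  A
`BruisePatch` is a labelled subset of one bone's surface vertices
representing a single edema footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyPatch
from .knee_frames import (
    AnatomicalFrame,
    build_anatomical_frame,
    mirror_landmarks,
    read_landmarks,
    write_landmarks,
)

__all__ = ["BoneMesh", "BruisePatch", "read_patches", "write_patches"]

COMPARTMENTS = ("medial", "lateral")


@dataclass
class BoneMesh:
    """One bone: surface mesh, landmarks, compartment labels, side."""

    mesh: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]
    name: str  # "femur" | "tibia"
    compartment: np.ndarray | None = None  # per-vertex: "medial"/"lateral"/"none"
    side: str = "right"
    articular_faces: np.ndarray | None = None  # face indices of the joint surface

    def __post_init__(self) -> None:
        if self.name not in ("femur", "tibia"):
            raise ValueError(f"name must be 'femur' or 'tibia', got {self.name!r}")
        if self.compartment is not None:
            self.compartment = np.asarray(self.compartment)
            if len(self.compartment) != len(self.mesh.vertices):
                raise ValueError("compartment labels must match vertex count")
        if self.articular_faces is not None:
            self.articular_faces = np.asarray(self.articular_faces, dtype=np.int64)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices, dtype=float)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces, dtype=np.int64)

    def anatomical_frame(self) -> AnatomicalFrame:
        return build_anatomical_frame(self.landmarks, self.name, side=self.side)

    def compartment_vertices(self, compartment: str) -> np.ndarray:
        if self.compartment is None:
            raise ValueError(f"{self.name} carries no compartment labels")
        return np.flatnonzero(self.compartment == compartment)

    def articular_surface(self) -> tuple[np.ndarray, np.ndarray]:
        """(vertices, faces) of the articulating surface (whole mesh if unset)."""
        if self.articular_faces is None:
            return self.vertices, self.faces
        return self.vertices, self.faces[self.articular_faces]

    def mirrored(self) -> "BoneMesh":
        """Reflected copy across the sagittal plane (left <-> right)."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        f = self.faces[:, ::-1].copy()  # keep outward normals after reflection
        return BoneMesh(
            mesh=trimesh.Trimesh(vertices=v, faces=f, process=False),
            landmarks=mirror_landmarks(self.landmarks),
            name=self.name,
            compartment=None if self.compartment is None else self.compartment.copy(),
            side="left" if self.side == "right" else "right",
            articular_faces=None if self.articular_faces is None else self.articular_faces.copy(),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mesh.export(directory / f"{self.name}.ply", encoding="ascii")
        write_landmarks(self.landmarks, directory / f"{self.name}_landmarks.json")
        meta = {"side": self.side}
        if self.compartment is not None:
            meta["compartment_rle"] = _rle_encode(self.compartment)
        if self.articular_faces is not None:
            mask = np.zeros(len(self.faces), dtype="<U7")
            mask[:] = "no"
            mask[self.articular_faces] = "yes"
            meta["articular_rle"] = _rle_encode(mask)
        with open(directory / f"{self.name}_meta.json", "w") as fh:
            json.dump(meta, fh)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path, name: str) -> "BoneMesh":
        directory = Path(directory)
        mesh_path = directory / f"{name}.ply"
        if not mesh_path.exists():
            mesh_path = directory / f"{name}.stl"
        mesh = trimesh.load_mesh(mesh_path, process=False)
        landmarks = read_landmarks(directory / f"{name}_landmarks.json")
        compartment = None
        articular = None
        side = "right"
        meta_path = directory / f"{name}_meta.json"
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
            side = meta.get("side", "right")
            if "compartment_rle" in meta:
                compartment = _rle_decode(meta["compartment_rle"], len(mesh.vertices))
            if "articular_rle" in meta:
                mask = _rle_decode(meta["articular_rle"], len(mesh.faces))
                articular = np.flatnonzero(mask == "yes")
        return cls(
            mesh=mesh,
            landmarks=landmarks,
            name=name,
            compartment=compartment,
            side=side,
            articular_faces=articular,
        )


@dataclass(frozen=True)
class BruisePatch:
    """Compartment-tagged vertex subset of one bone's surface."""

    bone: str  # "femur" | "tibia"
    compartment: str  # "medial" | "lateral"
    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.vertex_indices, dtype=np.int64))
        if idx.size == 0:
            raise EmptyPatch(f"{self.bone} {self.compartment} patch is empty")
        if self.bone not in ("femur", "tibia") or self.compartment not in COMPARTMENTS:
            raise ValueError(f"bad patch tags ({self.bone!r}, {self.compartment!r})")
        object.__setattr__(self, "vertex_indices", idx)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def points(self, bone: BoneMesh) -> np.ndarray:
        return bone.vertices[self.vertex_indices]

    def submesh(self, bone: BoneMesh) -> tuple[np.ndarray, np.ndarray]:
        """(vertices, faces) of the faces touching the patch.

        A face belongs to the patch surface when any of its vertices is a
        patch vertex; requiring all three would shred a footprint only one
        or two vertex rows wide into isolated triangles.
        """
        mask = np.zeros(len(bone.vertices), dtype=bool)
        mask[self.vertex_indices] = True
        keep = mask[bone.faces].any(axis=1)
        return bone.vertices, bone.faces[keep]


def write_patches(patches: list[BruisePatch], path: str | Path) -> None:
    items = [
        {
            "bone": p.bone,
            "compartment": p.compartment,
            "vertex_indices": [int(i) for i in p.vertex_indices],
        }
        for p in patches
    ]
    with open(path, "w") as fh:
        json.dump(items, fh)
        fh.write("\n")


def read_patches(path: str | Path) -> list[BruisePatch]:
    with open(path) as fh:
        items = json.load(fh)
    return [
        BruisePatch(
            bone=i["bone"],
            compartment=i["compartment"],
            vertex_indices=np.asarray(i["vertex_indices"], dtype=np.int64),
        )
        for i in items
    ]


def _rle_encode(labels: np.ndarray) -> list[list]:
    labels = np.asarray(labels)
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([int(start), int(i), str(labels[start])])
            start = i
    return runs


def _rle_decode(runs: list[list], n: int) -> np.ndarray:
    out = np.full(n, "none", dtype="<U7")
    for start, end, label in runs:
        out[start:end] = label
    return out
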