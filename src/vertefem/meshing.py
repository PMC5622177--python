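"""Voxel hexahedral meshing and grayscale-derived material assignment.

Every labelled voxel of a continuum mask becomes one 8-node brick element of
uniform size equal to the voxel spacing; nodes shared between neighbouring
voxels are de-duplicated so the mesh is conforming.  Bone elements receive
an elastic modulus from the linear grayscale law ``E_ele = alpha * GS_ele``
(GPa, with GS the element's average 8-bit grayscale); cement elements get a
fixed modulus.  Units are mm / GPa / kN throughout, so stress times area is
directly kN and stiffness kN/mm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from vertefem.image_ops import ImageVolume, LabelMask

# standard trilinear brick corner ordering (C3D8): bottom face CCW, then top
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)


@dataclass
class HexMesh:
    """Conforming voxel-aligned hexahedral mesh.

    nodes : (n, 3) float, mm; elements : (m, 8) int node indices in
    trilinear-brick corner order; element_source : (m, 3) voxel index each
    element came from; node_sets / element_sets : named index arrays
    (``bottom_face``/``top_face`` nodes, ``bone``/``cement`` elements).
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_source: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_box(self) -> np.ndarray:
        """Edge lengths (hx, hy, hz) of the (uniform) brick elements."""
        e0 = self.nodes[self.elements[0]]
        h = e0.max(axis=0) - e0.min(axis=0)
        if np.any(h <= 0):
            raise ValueError("degenerate element geometry")
        return h


@dataclass
class MaterialField:
    """Per-element isotropic elasticity derived from image grayscale."""

    E_ele: np.ndarray  # GPa, per element
    nu: float = 0.3
    alpha: float | None = None  # GPa per grayscale unit (bone law)
    GS_ele: np.ndarray | None = None  # average grayscale per element
    E_cement: float = 2.45  # GPa

    def __post_init__(self):
        self.E_ele = np.asarray(self.E_ele, dtype=float)
        if np.any(self.E_ele <= 0):
            raise ValueError("all element moduli must be positive (check E_floor)")
        # nu = 0 is allowed for the uncoupled uniaxial oracle configurations
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


def build_voxel_mesh(mask: LabelMask) -> HexMesh:
    """One brick element per labelled voxel, with de-duplicated nodes.

    ``bottom_face`` / ``top_face`` node sets are the nodes at the minimal /
    maximal axial coordinate of the cement elements (the potted loading
    surfaces); if the mask holds no cement the sets fall back to the axial
    extremes of the whole mesh.
    """
    vox = np.argwhere(mask.labels > 0)
    if len(vox) == 0:
        raise ValueError("mask has no labelled voxels")
    spacing = np.asarray(mask.spacing)
    shape = np.asarray(mask.shape)
    grid = shape + 1  # corner grid dimensions

    corners = vox[:, None, :] + _CORNERS[None, :, :]  # (m, 8, 3)
    flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), tuple(grid)
    )
    uniq, elements = np.unique(flat, return_inverse=True)
    elements = elements.reshape(len(vox), 8).astype(np.int64)
    ci, cj, ck = np.unravel_index(uniq, tuple(grid))
    nodes = np.stack([ci, cj, ck], axis=1).astype(float) * spacing[None, :]

    labels = mask.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    element_sets = {
        "bone": np.flatnonzero(labels == 1),
        "cement": np.flatnonzero(labels == 2),
    }

    ref = element_sets["cement"] if len(element_sets["cement"]) else np.arange(len(vox))
    ref_nodes = np.unique(elements[ref].ravel())
    zs = nodes[ref_nodes, 2]
    tol = spacing[2] * 1e-6
    node_sets = {
        "bottom_face": ref_nodes[zs <= zs.min() + tol],
        "top_face": ref_nodes[zs >= zs.max() - tol],
    }
    return HexMesh(
        nodes=nodes,
        elements=elements,
        element_source=vox,
        node_sets=node_sets,
        element_sets=element_sets,
        spacing=tuple(float(s) for s in spacing),
    )


def assign_materials(
    mesh: HexMesh,
    gray: ImageVolume,
    alpha: float,
    E_cement: float = 2.45,
    nu: float = 0.3,
    E_floor: float = 0.001,
) -> MaterialField:
    """Element moduli from the linear grayscale law E = alpha * GS (GPa).

    ``gray`` must be the (down-sampled) gray8 volume the mask was derived
    from, so each element maps to exactly one voxel and ``GS_ele`` is that
    voxel's value.  Bone elements get ``max(alpha * GS, E_floor)``; cement
    elements get the fixed cement modulus (2.45 GPa for PMMA by default).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if gray.data.shape[0] < mesh.element_source[:, 0].max() + 1:
        raise ValueError("gray volume does not cover the mesh source voxels")
    src = mesh.element_source
    GS = gray.data[src[:, 0], src[:, 1], src[:, 2]].astype(float)
    E = np.maximum(alpha * GS, E_floor)
    cem = mesh.element_sets.get("cement", np.array([], dtype=int))
    E[cem] = E_cement
    return MaterialField(E_ele=E, nu=nu, alpha=alpha, GS_ele=GS, E_cement=E_cement)


# ---------------------------------------------------------------------------
# Abaqus .inp subset writer / reader (for interoperability with commercial
# solvers; 1-based ids on file, 0-based in memory)
# ---------------------------------------------------------------------------


def _modulus_groups(E: np.ndarray, n_bins: int = 255):
    """Group elements by modulus: exact distinct values when few, otherwise
    binned to ``n_bins`` levels (mirroring 8-bit grayscale resolution)."""
    uniq = np.unique(E)
    if len(uniq) <= n_bins:
        groups = [(float(v), np.flatnonzero(E == v)) for v in uniq]
    else:
        edges = np.linspace(uniq.min(), uniq.max(), n_bins + 1)
        idx = np.clip(np.digitize(E, edges) - 1, 0, n_bins - 1)
        groups = []
        for b in np.unique(idx):
            members = np.flatnonzero(idx == b)
            groups.append((float(E[members].mean()), members))
    return groups


def write_abaqus_inp(path, mesh: HexMesh, materials: MaterialField, n_bins: int = 255) -> None:
    """Write the mesh as an Abaqus input deck (subset).

    Emits *NODE, *ELEMENT TYPE=C3D8, one *ELSET / *SOLID SECTION /
    *MATERIAL per modulus group, *NSET for the bottom/top faces and a
    *BOUNDARY clamping the bottom face.
    """
    lines = ["*HEADING", "vertefem voxel mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.6g}, {y:.6g}, {z:.6g}")
    lines.append("*ELEMENT, TYPE=C3D8")
    for i, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{i}, " + ", ".join(str(c + 1) for c in conn))
    for name, nset in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        for chunk in np.array_split(nset + 1, max(1, len(nset) // 12)):
            lines.append(", ".join(str(int(n)) for n in chunk))
    groups = _modulus_groups(materials.E_ele, n_bins=n_bins)
    for g, (E, members) in enumerate(groups, start=1):
        lines.append(f"*ELSET, ELSET=MAT{g}")
        for chunk in np.array_split(members + 1, max(1, len(members) // 12)):
            lines.append(", ".join(str(int(m)) for m in chunk))
    for g, (E, members) in enumerate(groups, start=1):
        lines.append(f"*SOLID SECTION, ELSET=MAT{g}, MATERIAL=MAT{g}")
        lines.append(f"*MATERIAL, NAME=MAT{g}")
        lines.append("*ELASTIC")
        lines.append(f"{E:.9g}, {materials.nu:.6g}")
    if "bottom_face" in mesh.node_sets:
        lines.append("*BOUNDARY")
        lines.append("bottom_face, 1, 3, 0.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_abaqus_inp(path) -> tuple[HexMesh, MaterialField]:
    """Read back the .inp subset written by :func:`write_abaqus_inp`."""
    nodes, elements = [], []
    nsets: dict[str, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    materials: dict[str, tuple[float, float]] = {}
    section_mat: dict[str, str] = {}
    mode, current, mat_name = None, None, None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.split(",")[0].upper()
                opts = dict(
                    (kv.split("=")[0].strip().upper(), kv.split("=")[1].strip())
                    for kv in line.split(",")[1:]
                    if "=" in kv
                )
                if key == "*NODE":
                    mode = "node"
                elif key == "*ELEMENT":
                    mode = "element"
                elif key == "*NSET":
                    mode, current = "nset", opts["NSET"]
                    nsets.setdefault(current, [])
                elif key == "*ELSET":
                    mode, current = "elset", opts["ELSET"]
                    elsets.setdefault(current, [])
                elif key == "*SOLID SECTION":
                    section_mat[opts["ELSET"]] = opts["MATERIAL"]
                    mode = None
                elif key == "*MATERIAL":
                    mat_name, mode = opts["NAME"], None
                elif key == "*ELASTIC":
                    mode = "elastic"
                else:
                    mode = None
                continue
            vals = [v for v in re.split(r"[,\s]+", line) if v]
            if mode == "node":
                nodes.append([float(v) for v in vals[1:4]])
            elif mode == "element":
                elements.append([int(v) - 1 for v in vals[1:9]])
            elif mode == "nset":
                nsets[current].extend(int(v) - 1 for v in vals)
            elif mode == "elset":
                elsets[current].extend(int(v) - 1 for v in vals)
            elif mode == "elastic":
                materials[mat_name] = (float(vals[0]), float(vals[1]))
                mode = None
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=np.int64)
    E = np.zeros(len(elements))
    nu = 0.3
    for elset, mat in section_mat.items():
        Eg, nu = materials[mat]
        E[np.asarray(elsets[elset], dtype=int)] = Eg
    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        element_source=np.zeros((len(elements), 3), dtype=np.int64),
        node_sets={k: np.asarray(v, dtype=np.int64) for k, v in nsets.items()},
        element_sets={},
    )
    h = mesh.element_box()
    mesh.spacing = (float(h[0]), float(h[1]), float(h[2]))
    return mesh, MaterialField(E_ele=E, nu=nu)


def write_vtk(path, mesh: HexMesh, materials: MaterialField | None = None, displacements: np.ndarray | None = None) -> None:
    """Write the mesh (plus optional modulus / displacement fields) as a
    legacy-ASCII VTK unstructured grid for visualization."""
    lines = [
        "# vtk DataFile Version 3.0",
        "vertefem voxel mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
    ]
    lines += [f"{x:.6g} {y:.6g} {z:.6g}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    lines += ["8 " + " ".join(str(c) for c in conn) for conn in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["12"] * mesh.n_elements  # VTK_HEXAHEDRON
    if materials is not None:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        lines.append("SCALARS modulus_GPa float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{e:.6g}" for e in materials.E_ele]
    if displacements is not None:
        u = np.asarray(displacements, dtype=float).reshape(mesh.n_nodes, 3)
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement_mm float")
        lines += [f"{a:.6g} {b:.6g} {c:.6g}" for a, b, c in u]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
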