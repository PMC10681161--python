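"""Parametric synthetic face phantoms for LeFort I simulation studies.

Patient-specific CBCT+MRI models are not publicly available, so the study
geometry is emulated by a layered block phantom that reproduces every
mechanical ingredient of the clinical model:

* a posterior bone slab split into a fixed skull base, a mobile LeFort I
  (LF1) segment and a fixed mandible, separated by one-cell soft-tissue
  gap layers standing in for the osteotomy cuts;
* a soft-tissue envelope in front of the bone with a free anterior skin
  surface;
* seven embedded muscle volumes with distinct attachments — the midline
  orbicularis oris lies *in series* between the LF1 anterior face and the
  upper-lip skin patch, masseter and buccinator tether lateral tissue to
  the fixed mandible, and zygomaticus major descends from fixed
  upper-lateral bone toward the mouth-corner region;
* four skin landmarks: nose (N), upper lip (UL), left/right cheek (LC, RC).

Coordinates are right-handed with X = subject left(+)/right(-), Y =
posterior -> anterior (surgical advancement is +Y), Z = inferior ->
superior (impaction is +Z). All lengths in mm.

The block is meshed on a structured grid; each hexahedral cell is split
into five tetrahedra with checkerboard parity, which keeps the mesh
conforming and — with an even number of cells across the width — exactly
mirror-symmetric about the midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
import yaml

from .regions import BONE_REGIONS, LANDMARK_NAMES, MUSCLE_REGIONS, Region


class PhantomError(ValueError):
    """Invalid phantom configuration or degenerate generated geometry."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box (mm), used for muscle volumes and attachments."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmin: float
    zmax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax and self.zmin < self.zmax):
            raise PhantomError(f"degenerate box {self}")

    @property
    def dims(self) -> tuple[float, float, float]:
        return (self.xmax - self.xmin, self.ymax - self.ymin, self.zmax - self.zmin)

    @property
    def volume(self) -> float:
        dx, dy, dz = self.dims
        return dx * dy * dz

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, 3) array of points."""
        return (
            (pts[:, 0] >= self.xmin)
            & (pts[:, 0] < self.xmax)
            & (pts[:, 1] >= self.ymin)
            & (pts[:, 1] < self.ymax)
            & (pts[:, 2] >= self.zmin)
            & (pts[:, 2] < self.zmax)
        )

    def mirrored_x(self) -> "Box":
        return Box(-self.xmax, -self.xmin, self.ymin, self.ymax, self.zmin, self.zmax)


def _default_muscle_boxes() -> dict[str, Box]:
    # every coordinate is a multiple of the 6 mm default element size, so
    # the realized (meshed) regions coincide exactly with these boxes;
    # no dimension is below 18 mm, leaving headroom for the +/-10%
    # anatomical variation above the 2h resolution bound
    masseter = Box(24.0, 42.0, 18.0, 42.0, 6.0, 24.0)
    buccinator = Box(6.0, 24.0, 18.0, 42.0, 6.0, 24.0)
    zygomaticus = Box(18.0, 36.0, 18.0, 36.0, 48.0, 66.0)
    return {
        "ORBICULARIS_ORIS": Box(-12.0, 12.0, 18.0, 54.0, 24.0, 42.0),
        "MASSETER_L": masseter,
        "MASSETER_R": masseter.mirrored_x(),
        "BUCCINATOR_L": buccinator,
        "BUCCINATOR_R": buccinator.mirrored_x(),
        "ZYGOMATICUS_L": zygomaticus,
        "ZYGOMATICUS_R": zygomaticus.mirrored_x(),
    }


def _default_landmark_targets() -> dict[str, tuple[float, float, float]]:
    return {
        "N": (0.0, 60.0, 48.0),
        "UL": (0.0, 60.0, 34.0),
        "LC": (28.0, 60.0, 30.0),
        "RC": (-28.0, 60.0, 30.0),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, resolution and population settings of the synthetic face.

    The default geometry is an 84 x 60 x 90 mm block: an 18 mm posterior
    bone slab (skull base above z=48, LF1 segment 24<=z<42 freed by 6 mm
    osteotomy gaps and a 6 mm retro-maxillary soft layer, mandible below
    z=18) and a 42 mm soft-tissue shell with the free skin at y=depth.
    All boundaries are multiples of the 6 mm default element size, so the
    meshed regions match the configured boxes exactly at h = 6, 3, ...
    """

    width: float = 84.0
    depth: float = 60.0
    height: float = 90.0
    element_size: float = 6.0
    bone_depth: float = 18.0
    retro_gap: float = 6.0  # soft layer behind the LF1 segment
    mandible_z_max: float = 18.0
    lf1_z: tuple[float, float] = (24.0, 42.0)
    skull_z_min: float = 48.0
    muscle_boxes: dict[str, Box] = field(default_factory=_default_muscle_boxes)
    landmark_targets: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_landmark_targets
    )
    anatomical_variation: float = 0.10
    anatomical_variation_seed: int = 0
    n_subjects: int = 8

    @property
    def shell_thickness(self) -> float:
        return self.depth - self.bone_depth

    def validate(self) -> None:
        for name in ("width", "depth", "height", "element_size"):
            if not getattr(self, name) > 0:
                raise PhantomError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.bone_depth < self.depth:
            raise PhantomError("bone_depth must lie strictly inside the block depth")
        if not 0 < self.mandible_z_max < self.lf1_z[0] < self.lf1_z[1] < self.skull_z_min < self.height:
            raise PhantomError("bone bands must be ordered: mandible < LF1 < skull base")
        min_dim = self.shell_thickness
        for box in self.muscle_boxes.values():
            min_dim = min(min_dim, *box.dims)
        if self.element_size > min_dim / 2:
            raise PhantomError(
                f"element_size {self.element_size} too coarse: must be <= "
                f"min(shell thickness, smallest muscle dimension)/2 = {min_dim / 2}"
            )
        if self.n_subjects < 1:
            raise PhantomError("n_subjects must be >= 1")
        for name in self.muscle_boxes:
            Region[name]  # raises KeyError on unknown labels
        missing = set(LANDMARK_NAMES) - set(self.landmark_targets)
        if missing:
            raise PhantomError(f"missing landmark targets: {sorted(missing)}")

    def to_yaml(self, path) -> None:
        data = {
            "width": self.width,
            "depth": self.depth,
            "height": self.height,
            "element_size": self.element_size,
            "bone_depth": self.bone_depth,
            "retro_gap": self.retro_gap,
            "mandible_z_max": self.mandible_z_max,
            "lf1_z": list(self.lf1_z),
            "skull_z_min": self.skull_z_min,
            "muscle_boxes": {
                name: [b.xmin, b.xmax, b.ymin, b.ymax, b.zmin, b.zmax]
                for name, b in self.muscle_boxes.items()
            },
            "landmark_targets": {k: list(v) for k, v in self.landmark_targets.items()},
            "anatomical_variation": self.anatomical_variation,
            "anatomical_variation_seed": self.anatomical_variation_seed,
            "n_subjects": self.n_subjects,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "muscle_boxes" in data:
            data["muscle_boxes"] = {k: Box(*v) for k, v in data["muscle_boxes"].items()}
        if "landmark_targets" in data:
            data["landmark_targets"] = {
                k: tuple(float(x) for x in v) for k, v in data["landmark_targets"].items()
            }
        if "lf1_z" in data:
            data["lf1_z"] = tuple(float(x) for x in data["lf1_z"])
        return cls(**data)


@dataclass
class LabeledMesh:
    """Conforming tetrahedral mesh with per-element anatomical labels."""

    nodes: np.ndarray  # (n_nodes, 3) float64, mm
    tets: np.ndarray  # (n_tets, 4) int
    element_region: np.ndarray  # (n_tets,) int (Region values)
    skin_faces: np.ndarray  # (n_faces, 3) int, triangles on the free skin
    node_sets: dict[str, np.ndarray]  # TOP_HEAD / BACK_HEAD / NECK
    landmark_targets: dict[str, tuple[float, float, float]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def skin_nodes(self) -> np.ndarray:
        return np.unique(self.skin_faces)

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def region_nodes(self, region: Region) -> np.ndarray:
        """Sorted unique node indices touched by elements of ``region``."""
        return np.unique(self.tets[self.element_region == int(region)])

    def region_volume(self, region: Region) -> float:
        return float(self.element_volumes()[self.element_region == int(region)].sum())

    def regions_present(self) -> set[Region]:
        return {Region(r) for r in np.unique(self.element_region)}


@dataclass(frozen=True)
class LandmarkSet:
    """The four named skin landmarks: node index + coordinate each."""

    landmarks: dict[str, tuple[int, np.ndarray]]

    def node(self, name: str) -> int:
        return self.landmarks[name][0]

    def coordinate(self, name: str) -> np.ndarray:
        return self.landmarks[name][1]

    def names(self) -> tuple[str, ...]:
        return tuple(self.landmarks)

    def to_json(self, path) -> None:
        data = {
            name: {"node": int(idx), "xyz": [float(c) for c in xyz]}
            for name, (idx, xyz) in self.landmarks.items()
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            {name: (int(v["node"]), np.asarray(v["xyz"], dtype=float)) for name, v in data.items()}
        )


# Five-tet decomposition of a hexahedral cell. Each corner entry is a cube
# vertex (di,dj,dk); a corner tet joins it to its three edge neighbours and
# the central tet joins the four corners. The two parities are mirror
# images of each other, so a checkerboard assignment yields a conforming
# mesh that is midsagittally symmetric when the x cell count is even.
_PARITY_CORNERS = (
    ((0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
    ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
)


def _grid_shape(config: PhantomConfig) -> tuple[int, int, int]:
    # ceil keeps every cell no larger than element_size in each direction
    nx = max(1, int(np.ceil(config.width / config.element_size - 1e-9)))
    if nx % 2 == 1:
        # x-mirroring maps a cell's 5-tet split onto the opposite parity's
        # split, so the checkerboard is mirror-symmetric iff reflection
        # flips cell parity: the x cell count must be even (this also puts
        # a node column exactly on the midsagittal plane)
        nx += 1
    ny = max(1, int(np.ceil(config.depth / config.element_size - 1e-9)))
    nz = max(1, int(np.ceil(config.height / config.element_size - 1e-9)))
    return nx, ny, nz


def _classify(config: PhantomConfig, centroids: np.ndarray) -> np.ndarray:
    """Label grid cells by center membership, priority bone > muscle > soft."""
    labels = np.full(len(centroids), int(Region.SOFT_TISSUE), dtype=np.int32)
    x, y, z = centroids.T
    bone = y < config.bone_depth
    labels[bone & (z < config.mandible_z_max)] = int(Region.MANDIBLE)
    lf1 = bone & (z >= config.lf1_z[0]) & (z < config.lf1_z[1]) & (y >= config.retro_gap)
    labels[lf1] = int(Region.LF1)
    labels[bone & (z >= config.skull_z_min)] = int(Region.SKULL_BASE)
    # Remaining bone-slab cells (osteotomy gaps, retro-maxillary layer) stay soft.
    unassigned = ~bone
    for name, box in config.muscle_boxes.items():
        hit = unassigned & box.contains(centroids)
        labels[hit] = int(Region[name])
        unassigned &= ~hit
    return labels


def tetrahedral_block(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tetrahedralize the structured grid spanned by the given axis ticks.

    Returns (nodes, tets, tet_cell): node coordinates, positively
    oriented tet connectivity and the flat cell index of every tet.
    """
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    parity = (I + J + K) % 2

    tet_blocks = []
    tet_cells = []  # flat cell index of every emitted tet
    cell_flat = np.arange(nx * ny * nz)
    for p in (0, 1):
        sel = parity == p
        ci, cj, ck = I[sel], J[sel], K[sel]
        corners = _PARITY_CORNERS[p]
        cids = [node_id(ci + d[0], cj + d[1], ck + d[2]) for d in corners]
        # four corner tets: corner + its three axis neighbours
        for d in corners:
            c = node_id(ci + d[0], cj + d[1], ck + d[2])
            n1 = node_id(ci + (1 - d[0]), cj + d[1], ck + d[2])
            n2 = node_id(ci + d[0], cj + (1 - d[1]), ck + d[2])
            n3 = node_id(ci + d[0], cj + d[1], ck + (1 - d[2]))
            tet_blocks.append(np.column_stack([c, n1, n2, n3]))
            tet_cells.append(cell_flat[sel])
        tet_blocks.append(np.column_stack(cids))  # central tet
        tet_cells.append(cell_flat[sel])
    tets = np.vstack(tet_blocks).astype(np.int64)
    tet_cell = np.concatenate(tet_cells)

    # enforce positive orientation
    p = nodes[tets]
    vols = np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return nodes, tets, tet_cell


def build_phantom(config: PhantomConfig) -> LabeledMesh:
    """Generate the labeled tetrahedral phantom for one subject.

    Deterministic for a given config. Raises :class:`PhantomError` when a
    configured region captures no elements (mesh too coarse or box outside
    the block).
    """
    config.validate()
    nx, ny, nz = _grid_shape(config)
    xs = np.linspace(-config.width / 2, config.width / 2, nx + 1)
    ys = np.linspace(0.0, config.depth, ny + 1)
    zs = np.linspace(0.0, config.height, nz + 1)
    nodes, tets, tet_cell = tetrahedral_block(xs, ys, zs)

    # classify whole cells by their centers so labeled regions have clean,
    # grid-aligned boundaries (band limits snap to cell granularity)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    cz = 0.5 * (zs[:-1] + zs[1:])
    CI, CJ, CK = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cell_centers = np.column_stack([cx[CI.ravel()], cy[CJ.ravel()], cz[CK.ravel()]])
    cell_labels = _classify(config, cell_centers)
    labels = cell_labels[tet_cell]

    expected = {Region.SKULL_BASE, Region.LF1, Region.MANDIBLE, Region.SOFT_TISSUE}
    expected |= {Region[name] for name in config.muscle_boxes}
    present = {Region(r) for r in np.unique(labels)}
    for region in sorted(expected - present, key=int):
        raise PhantomError(f"empty region {region.name}")

    # boundary faces -> skin triangles on the anterior plane y = depth
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    uniq, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = faces[first[counts == 1]]
    on_skin = np.all(np.isclose(nodes[boundary][:, :, 1], config.depth, atol=1e-9), axis=1)
    skin = boundary[on_skin]
    # orient outward (+y)
    v = nodes[skin]
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    back = normals[:, 1] < 0
    skin[back] = skin[back][:, [0, 2, 1]]

    node_sets = {
        "TOP_HEAD": np.flatnonzero(np.isclose(nodes[:, 2], config.height, atol=1e-9)),
        "BACK_HEAD": np.flatnonzero(np.isclose(nodes[:, 1], 0.0, atol=1e-9)),
        "NECK": np.flatnonzero(np.isclose(nodes[:, 2], 0.0, atol=1e-9)),
    }

    return LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=labels,
        skin_faces=skin,
        node_sets=node_sets,
        landmark_targets=dict(config.landmark_targets),
    )


def place_landmarks(mesh: LabeledMesh) -> LandmarkSet:
    """Snap each configured landmark target to the nearest skin node.

    Ties in Euclidean distance are broken by the lowest node index.
    """
    skin = mesh.skin_nodes
    if skin.size == 0:
        raise PhantomError("mesh has an empty skin surface")
    coords = mesh.nodes[skin]
    out: dict[str, tuple[int, np.ndarray]] = {}
    for name, target in mesh.landmark_targets.items():
        d2 = np.sum((coords - np.asarray(target, dtype=float)) ** 2, axis=1)
        best = d2 <= d2.min() + 1e-12
        node = int(skin[best].min())  # lowest-index tie break
        out[name] = (node, mesh.nodes[node].copy())
    return LandmarkSet(out)


def _perturb_config(config: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """One subject's anatomy: +/-variation scaling of muscle boxes and shell."""
    v = config.anatomical_variation
    thickness = config.shell_thickness * (1.0 + v * rng.uniform(-1, 1))
    bone_depth = config.depth - thickness
    boxes: dict[str, Box] = {}
    for name, box in config.muscle_boxes.items():
        fx, fy, fz = 1.0 + v * rng.uniform(-1, 1, size=3)
        cx = 0.5 * (box.xmin + box.xmax)
        cz = 0.5 * (box.zmin + box.zmax)
        hx = 0.5 * (box.xmax - box.xmin) * fx
        hz = 0.5 * (box.zmax - box.zmin) * fz
        ylen = (box.ymax - box.ymin) * fy
        # keep the bone-face attachment: boxes grow forward from the slab
        boxes[name] = Box(cx - hx, cx + hx, bone_depth, bone_depth + ylen, cz - hz, cz + hz)
    return replace(config, bone_depth=bone_depth, muscle_boxes=boxes)


def generate_population(config: PhantomConfig) -> list[tuple[LabeledMesh, LandmarkSet]]:
    """Generate the study cohort: seeded anatomical variants of the phantom.

    Muscle box dimensions and the soft-tissue shell thickness receive
    independent uniform perturbations of up to ``anatomical_variation``
    (default +/-10%); attachments to the bone face are preserved. Fully
    reproducible from ``anatomical_variation_seed``. A perturbation that
    yields an invalid config is retried on the next substream (at most 100
    attempts per subject).
    """
    config.validate()
    ss = np.random.SeedSequence(config.anatomical_variation_seed)
    subjects: list[tuple[LabeledMesh, LandmarkSet]] = []
    for _ in range(config.n_subjects):
        if config.anatomical_variation == 0:
            sub_cfg = config
        else:
            for attempt in range(100):
                rng = np.random.default_rng(ss.spawn(1)[0])
                sub_cfg = _perturb_config(config, rng)
                try:
                    sub_cfg.validate()
                    break
                except PhantomError:
                    continue
            else:
                raise PhantomError("no valid anatomy found in 100 attempts")
        mesh = build_phantom(sub_cfg)
        subjects.append((mesh, place_landmarks(mesh)))
    return subjects


def skin_surface(mesh: LabeledMesh):
    """Extract the free skin as a standalone surface.

    Returns the :class:`~orthofem.compare.SurfaceMesh` (vertices
    reindexed) and the volume-mesh node index of each surface vertex, so
    nodal fields can be restricted to the skin via ``u[skin_nodes]``.
    """
    from .compare import SurfaceMesh

    skin_nodes = mesh.skin_nodes
    if skin_nodes.size == 0:
        raise PhantomError("mesh has an empty skin surface")
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[skin_nodes] = np.arange(len(skin_nodes))
    return (
        SurfaceMesh(vertices=mesh.nodes[skin_nodes].copy(), faces=remap[mesh.skin_faces]),
        skin_nodes,
    )


def make_synthetic_postop_surface(
    skin,
    displacements: np.ndarray,
    noise_sd: float = 0.0,
    rigid_offset=None,
    seed: int = 0,
):
    """Fabricate a stand-in for the postoperative skin surface scan.

    Takes the FEM-predicted skin (a :class:`~orthofem.compare.SurfaceMesh`),
    applies the per-vertex displacement field, adds isotropic Gaussian
    vertex noise of standard deviation ``noise_sd`` mm, then applies a
    rigid misalignment. Synthetic by construction — it exercises the
    validation stage (ICP + cropping + signed distance) end to end.
    """
    from .compare import RigidTransform, SurfaceMesh

    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != skin.vertices.shape:
        raise PhantomError("displacement field must be defined on all skin vertices")
    if noise_sd < 0:
        raise PhantomError(f"noise_sd must be >= 0, got {noise_sd}")
    verts = skin.vertices + displacements
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(0.0, noise_sd, size=verts.shape)
    if rigid_offset is None:
        rigid_offset = RigidTransform.identity()
    verts = rigid_offset.apply(verts)
    return SurfaceMesh(vertices=verts, faces=skin.faces.copy())
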