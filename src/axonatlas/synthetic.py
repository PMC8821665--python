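"""Synthetic atlases, barrel maps, reconstructions and transforms.

Everything the pipeline consumes can be generated here with analytically
known ground truth, so every stage is testable without any imaging data:

* a layered cortical parcellation with a nested ontology (cortical areas
  subdivided into layers, a white-matter block, a dorsal-striatum block),
* a barrel-column map of labeled cylinders with named columns and
  unlabeled septal gaps,
* branched neuron reconstructions written in anisotropic imaging-voxel
  coordinates (0.8 x 0.8 x 5 um by default) whose per-region axon and
  dendrite cable is known exactly from clipping each straight cable
  segment against the region boxes,
* transform chains (identity / translation / rigid / affine / smooth
  displacement fields) with known inverses.

The default cohort emulates the study conditions this package targets:
ten layer-2/3 barrel-cortex neurons with total axonal cable drawn from
N(67.9, 13.0) mm and dendritic cable from N(7.2, 0.8) mm, somata in named
barrel columns (or septa), dense local axon in the home column plus
long-range branches into neighbouring cortical areas, the white matter
and the dorsal striatum.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import (
    UNASSIGNED_ACRONYM,
    UNASSIGNED_ID,
    BarrelColumnMap,
    ParcellationVolume,
    StructureEntry,
    StructureOntology,
)
from .reconstruction import (
    AXON,
    BASAL_DENDRITE,
    SOMA,
    NeuronReconstruction,
    ReconNode,
)
from .transforms import AffineTransform, DisplacementField, TransformChain

__all__ = [
    "RegionBlock",
    "BarrelGridSpec",
    "AtlasSpec",
    "CableSegment",
    "NeuronSpec",
    "GroundTruth",
    "default_atlas_spec",
    "make_atlas",
    "make_neuron",
    "make_transform",
    "make_cohort",
    "default_cohort_specs",
]

DEFAULT_IMAGING_VOXEL = (0.8, 0.8, 5.0)
DEFAULT_ATLAS_VOXEL = 25.0

# axis conventions shared with projections: 0 = AP, 1 = DV (depth, 0 at the
# pial surface), 2 = ML
CORTEX_DEPTH_UM = 1000.0
LAYERS = (("1", 0.0, 100.0), ("2/3", 100.0, 300.0), ("4", 300.0, 450.0),
          ("5", 450.0, 700.0), ("6", 700.0, 1000.0))


# --------------------------------------------------------------------------
# atlas specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionBlock:
    """An axis-aligned box region; with ``layered`` the box is subdivided
    along the depth (DV) axis into layer children that tile it exactly."""

    acronym: str
    name: str
    parent: str
    lo: tuple[float, float, float]      # um, inclusive
    hi: tuple[float, float, float]      # um, exclusive
    layered: bool = False


@dataclass(frozen=True)
class BarrelGridSpec:
    """Rows x arcs of vertical cylindrical columns inside the barrel field."""

    rows: str = "ABCDE"                 # row letters along ML
    n_arcs: int = 3                     # arc numbers along AP
    radius_um: float = 140.0
    row_pitch_um: float = 350.0
    arc_pitch_um: float = 500.0
    first_center: tuple[float, float] = (2500.0, 2250.0)   # (AP, ML) um
    depth_range: tuple[float, float] = (0.0, CORTEX_DEPTH_UM)

    def centers(self) -> dict[str, tuple[float, float]]:
        """Column name -> (AP, ML) center."""
        out = {}
        for r, letter in enumerate(self.rows):
            for a in range(self.n_arcs):
                out[f"{letter}{a + 1}"] = (
                    self.first_center[0] + a * self.arc_pitch_um,
                    self.first_center[1] + r * self.row_pitch_um,
                )
        return out


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry + ontology of a synthetic parcellation."""

    shape: tuple[int, int, int]
    voxel_size: float = DEFAULT_ATLAS_VOXEL
    ontology_parents: tuple[tuple[str, str, str], ...] = (
        ("Isocortex", "isocortex", "root"),
        ("fiber tracts", "fiber tracts", "root"),
        ("STRd", "striatum dorsal region", "root"),
    )
    regions: tuple[RegionBlock, ...] = ()
    barrels: BarrelGridSpec | None = None

    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size for s in self.shape)  # type: ignore


def default_atlas_spec() -> AtlasSpec:
    """A 6 x 2 x 6 mm block: a 1 mm cortical sheet tiled by nine layered
    areas, a white-matter slab beneath, and a striatal block below that.

    The barrel field sits in the central area (SSp-bfd) with a 5-row x
    3-arc column grid.  All region boxes are aligned to the 25 um grid so
    voxelized and analytic region membership coincide.
    """
    regions: list[RegionBlock] = []

    def cortex(acr, name, ap, ml):
        regions.append(RegionBlock(
            acr, name, "Isocortex",
            (ap[0], 0.0, ml[0]), (ap[1], CORTEX_DEPTH_UM, ml[1]),
            layered=True))

    #                 AP range          ML range
    cortex("MOp",     "primary motor area",            (0, 2000), (0, 2000))
    cortex("MOs",     "secondary motor area",          (0, 2000), (2000, 4000))
    cortex("VISrl",   "rostrolateral visual area",     (0, 2000), (4000, 6000))
    cortex("SSp-un",  "primary somatosensory, unassigned", (2000, 4000), (0, 2000))
    cortex("SSp-bfd", "primary somatosensory, barrel field", (2000, 4000), (2000, 4000))
    cortex("SSs",     "supplemental somatosensory area", (2000, 4000), (4000, 6000))
    cortex("SSp-ul",  "primary somatosensory, upper limb", (4000, 6000), (0, 2000))
    cortex("SSp-tr",  "primary somatosensory, trunk",  (4000, 6000), (2000, 4000))
    cortex("VISa",    "anterior visual area",          (4000, 6000), (4000, 6000))

    regions.append(RegionBlock("cc", "corpus callosum", "fiber tracts",
                               (0, 1000, 0), (6000, 1200, 3000)))
    regions.append(RegionBlock("scwm", "supra-callosal white matter",
                               "fiber tracts",
                               (0, 1000, 3000), (6000, 1200, 6000)))
    regions.append(RegionBlock("CP", "caudoputamen", "STRd",
                               (1500, 1200, 1500), (4500, 2000, 4500)))

    return AtlasSpec(shape=(240, 80, 240), regions=tuple(regions),
                     barrels=BarrelGridSpec())


# --------------------------------------------------------------------------
# atlas construction
# --------------------------------------------------------------------------

def _leaf_blocks(spec: AtlasSpec) -> list[tuple[str, str, str, tuple, tuple]]:
    """Expand layered regions into leaf (acronym, name, parent, lo, hi)."""
    leaves = []
    for r in spec.regions:
        if not r.layered:
            leaves.append((r.acronym, r.name, r.parent, r.lo, r.hi))
            continue
        for lname, d0, d1 in LAYERS:
            lo = (r.lo[0], d0, r.lo[2])
            hi = (r.hi[0], d1, r.hi[2])
            leaves.append((f"{r.acronym}{lname}",
                           f"{r.name} layer {lname}", r.acronym, lo, hi))
    return leaves


def make_atlas(spec: AtlasSpec) -> tuple[ParcellationVolume, StructureOntology,
                                         BarrelColumnMap | None]:
    """Voxelize an :class:`AtlasSpec`.

    Returns the parcellation volume, the nested ontology
    (root -> compartment -> region -> layer) and the barrel-column map
    (``None`` when the spec has no barrel grid).  Region boxes must align
    to the voxel grid and sibling leaves must not overlap.
    """
    v = spec.voxel_size
    entries = [StructureEntry(1, "root", "root", None)]
    ids = {"root": 1}

    def add(acr: str, name: str, parent: str) -> int:
        if acr in ids:
            raise ValueError(f"duplicate acronym {acr!r}")
        sid = len(entries) + 1
        entries.append(StructureEntry(sid, acr, name, ids[parent]))
        ids[acr] = sid
        return sid

    for acr, name, parent in spec.ontology_parents:
        add(acr, name, parent)
    for r in spec.regions:
        add(r.acronym, r.name, r.parent)
    leaves = _leaf_blocks(spec)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for acr, name, parent, lo, hi in leaves:
        sid = ids[acr] if acr in ids else add(acr, name, parent)
        sl = []
        for a in range(3):
            i0, i1 = lo[a] / v, hi[a] / v
            if abs(i0 - round(i0)) > 1e-9 or abs(i1 - round(i1)) > 1e-9:
                raise ValueError(
                    f"region {acr}: box not aligned to the {v} um grid")
            i0, i1 = int(round(i0)), int(round(i1))
            if i0 < 0 or i1 > spec.shape[a]:
                raise ValueError(f"region {acr}: box outside the grid")
            sl.append(slice(i0, i1))
        block = labels[tuple(sl)]
        if np.any(block != 0):
            raise ValueError(f"region {acr}: overlaps a sibling block")
        block[...] = sid
    vol = ParcellationVolume(labels, (v, v, v))
    ontology = StructureOntology(entries)

    barrel_map = None
    if spec.barrels is not None:
        bl = np.zeros(spec.shape, dtype=np.int32)
        names: dict[int, str] = {}
        b = spec.barrels
        # voxel centers in the cortical depth range
        ap = (np.arange(spec.shape[0]) + 0.5) * v
        dv = (np.arange(spec.shape[1]) + 0.5) * v
        ml = (np.arange(spec.shape[2]) + 0.5) * v
        dmask = (dv >= b.depth_range[0]) & (dv < b.depth_range[1])
        for label, (cname, (cap, cml)) in enumerate(sorted(b.centers().items()),
                                                    start=1):
            r2 = (ap[:, None] - cap) ** 2 + (ml[None, :] - cml) ** 2
            disk = r2 <= b.radius_um ** 2                 # (AP, ML)
            sel = np.zeros(spec.shape, dtype=bool)
            sel[:, dmask, :] = disk[:, None, :]
            if np.any(bl[sel] != 0):
                raise ValueError(f"barrel column {cname} overlaps another")
            bl[sel] = label
            names[label] = cname
        barrel_map = BarrelColumnMap(ParcellationVolume(bl, (v, v, v)), names)
    return vol, ontology, barrel_map


# --------------------------------------------------------------------------
# neurons with analytic ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CableSegment:
    """One straight cable piece: ``attach`` is 'soma' or the index of the
    segment whose endpoint this one grows from (its start must coincide
    with that endpoint)."""

    start: tuple[float, float, float]   # um
    end: tuple[float, float, float]     # um
    type_code: int
    attach: int | str = "soma"

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)


@dataclass
class NeuronSpec:
    """Blueprint of one synthetic neuron in atlas/micron space."""

    name: str
    soma: tuple[float, float, float]
    segments: list[CableSegment]
    imaging_voxel: tuple[float, float, float] = DEFAULT_IMAGING_VOXEL
    node_spacing_um: float = 5.0
    jitter_um: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Analytic per-leaf-structure cable of one neuron.

    ``lengths``: (structure id, neurite class) -> um, with id 0 for cable
    outside every region box.  ``intervals``: per structure id, the number
    of contiguous cable intervals inside it (used for discretization error
    bounds: midpoint resampling can miscount each interval by at most one
    point, and each interval boundary interior to a path by one more).
    ``jitter_bound_um``: per-segment arclength inflation bound when jitter
    is enabled (0 otherwise).
    """

    lengths: dict[tuple[int, str], float] = field(default_factory=dict)
    intervals: dict[int, int] = field(default_factory=dict)
    crossings: dict[int, int] = field(default_factory=dict)
    jitter_bound_um: float = 0.0

    def add(self, sid: int, ntype: str, length: float,
            n_crossings: int = 0) -> None:
        if length <= 0:
            return
        key = (sid, ntype)
        self.lengths[key] = self.lengths.get(key, 0.0) + length
        self.intervals[sid] = self.intervals.get(sid, 0) + 1
        self.crossings[sid] = self.crossings.get(sid, 0) + n_crossings

    def total(self, ntype: str) -> float:
        return sum(v for (sid, t), v in self.lengths.items() if t == ntype)

    def per_acronym(self, ontology: StructureOntology,
                    ntype: str = "axon") -> dict[str, float]:
        out: dict[str, float] = {}
        for (sid, t), v in self.lengths.items():
            if t != ntype:
                continue
            acr = UNASSIGNED_ACRONYM if sid == UNASSIGNED_ID else ontology.acronym(sid)
            out[acr] = out.get(acr, 0.0) + v
        return out

    def aggregated(self, ontology: StructureOntology, targets: Sequence[str],
                   ntype: str = "axon") -> dict[str, float]:
        """Truth lengths summed onto target acronyms (descendants pooled)."""
        tids = {t: ontology.by_acronym(t).id for t in targets}
        out = {t: 0.0 for t in targets}
        for (sid, nt), v in self.lengths.items():
            if nt != ntype or sid == UNASSIGNED_ID:
                continue
            for t, tid in tids.items():
                if ontology.is_descendant(sid, tid):
                    out[t] += v
                    break
        return out

    def to_frame(self, ontology: StructureOntology) -> pd.DataFrame:
        rows = []
        for (sid, t), v in sorted(self.lengths.items()):
            acr = UNASSIGNED_ACRONYM if sid == UNASSIGNED_ID else ontology.acronym(sid)
            rows.append({"structure_id": sid, "acronym": acr,
                         "neurite_type": t, "length_um": v})
        return pd.DataFrame(rows)


def _clip_segment(a: np.ndarray, b: np.ndarray,
                  boxes: list[tuple[int, np.ndarray, np.ndarray]]
                  ) -> list[tuple[int, float, float]]:
    """Clip segment a->b against disjoint boxes.

    Returns (structure id, t0, t1) parameter intervals covering [0, 1];
    uncovered stretches are returned with id 0.  Boxes are half-open but
    for lengths the boundary convention is immaterial.
    """
    d = b - a
    hits: list[tuple[float, float, int]] = []
    for sid, lo, hi in boxes:
        t0, t1 = 0.0, 1.0
        ok = True
        for ax in range(3):
            if d[ax] == 0:
                if not (lo[ax] <= a[ax] < hi[ax]):
                    ok = False
                    break
                continue
            u0 = (lo[ax] - a[ax]) / d[ax]
            u1 = (hi[ax] - a[ax]) / d[ax]
            if u0 > u1:
                u0, u1 = u1, u0
            t0, t1 = max(t0, u0), min(t1, u1)
            if t0 >= t1:
                ok = False
                break
        if ok and t1 > t0:
            hits.append((t0, t1, sid))
    hits.sort()
    out: list[tuple[int, float, float]] = []
    cursor = 0.0
    for t0, t1, sid in hits:
        if t0 > cursor + 1e-12:
            out.append((UNASSIGNED_ID, cursor, t0))
        out.append((sid, max(t0, cursor), t1))
        cursor = max(cursor, t1)
    if cursor < 1.0 - 1e-12:
        out.append((UNASSIGNED_ID, cursor, 1.0))
    return out


def make_neuron(spec: NeuronSpec, atlas_spec: AtlasSpec
                ) -> tuple[NeuronReconstruction, GroundTruth]:
    """Materialize a :class:`NeuronSpec` as an ESWC-style reconstruction in
    imaging-voxel coordinates plus its analytic ground truth.

    Nodes are laid along each straight segment at <= ``node_spacing_um``;
    the ground truth clips each segment against the leaf region boxes, so
    it is exact (jitter, when enabled, carries an inflation bound instead).
    Coordinates are divided componentwise by ``imaging_voxel`` to mimic raw
    tracing output.  Generation is deterministic for a given spec.
    """
    extent = atlas_spec.extent_um()
    leaves = _leaf_blocks(atlas_spec)
    # ids assigned exactly as in make_atlas
    _, ontology, _ = _ontology_only(atlas_spec)
    boxes = [(ontology.by_acronym(acr).id, np.asarray(lo, float),
              np.asarray(hi, float)) for acr, _, _, lo, hi in leaves]

    truth = GroundTruth()
    nodes: list[ReconNode] = []
    soma = np.asarray(spec.soma, float)
    nodes.append(ReconNode(1, *soma, radius=6.0, type_code=SOMA, parent_id=-1))
    seg_tail_node: dict[int, int] = {}

    for i, seg in enumerate(spec.segments):
        a, b = np.asarray(seg.start, float), np.asarray(seg.end, float)
        for p in (a, b):
            if np.any(p < 0) or np.any(p >= np.asarray(extent)):
                raise ValueError(
                    f"{spec.name}: segment {i} leaves the atlas grid at {p}")
        if seg.attach == "soma":
            parent = 1
            expect = soma
        else:
            parent = seg_tail_node[int(seg.attach)]
            expect = np.array(
                [nodes[parent - 1].x, nodes[parent - 1].y, nodes[parent - 1].z])
        if not np.allclose(a, expect, atol=1e-6):
            raise ValueError(
                f"{spec.name}: segment {i} start {a} does not coincide with "
                f"its attachment point {expect}")
        L = seg.length
        if L < 1e-9:
            seg_tail_node[i] = parent
            continue
        n_sub = max(1, int(math.ceil(L / spec.node_spacing_um)))
        wavelength = 20 * spec.node_spacing_um
        frames = _orthonormal_frame(b - a) if spec.jitter_um > 0 else None
        for j in range(1, n_sub + 1):
            p = a + (j / n_sub) * (b - a)
            if frames is not None and j < n_sub:
                s = (j / n_sub) * L
                u, _ = frames
                p = p + spec.jitter_um * math.sin(2 * math.pi * s / wavelength) * u
            nid = len(nodes) + 1
            nodes.append(ReconNode(nid, *p, radius=0.5,
                                   type_code=seg.type_code, parent_id=parent))
            parent = nid
        seg_tail_node[i] = parent
        ntype = ("axon" if seg.type_code == AXON else
                 "dendrite" if seg.type_code in (3, 4) else "other")
        for sid, t0, t1 in _clip_segment(a, b, boxes):
            n_cross = int(t0 > 1e-12) + int(t1 < 1 - 1e-12)
            truth.add(sid, ntype, (t1 - t0) * L, n_cross)
        if spec.jitter_um > 0:
            # sinusoid of amplitude A, wavelength W inflates arclength by
            # at most (1/2) (2 pi A / W)^2 per unit length
            slope = 2 * math.pi * spec.jitter_um / wavelength
            truth.jitter_bound_um += 0.5 * slope * slope * L

    vx = np.asarray(spec.imaging_voxel, float)
    voxel_nodes = [replace(n, x=n.x / vx[0], y=n.y / vx[1], z=n.z / vx[2])
                   for n in nodes]
    recon = NeuronReconstruction(name=spec.name, nodes=voxel_nodes,
                                 space="voxel",
                                 voxel_size=tuple(spec.imaging_voxel))
    return recon, truth


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _ontology_only(spec: AtlasSpec):
    """Build just the ontology (shared id assignment with make_atlas)."""
    entries = [StructureEntry(1, "root", "root", None)]
    ids = {"root": 1}

    def add(acr, name, parent):
        sid = len(entries) + 1
        entries.append(StructureEntry(sid, acr, name, ids[parent]))
        ids[acr] = sid

    for acr, name, parent in spec.ontology_parents:
        add(acr, name, parent)
    for r in spec.regions:
        add(r.acronym, r.name, r.parent)
    for acr, name, parent, lo, hi in _leaf_blocks(spec):
        if acr not in ids:
            add(acr, name, parent)
    return None, StructureOntology(entries), None


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------

def make_transform(kind: str, params: dict | None = None,
                   seed: int = 0) -> TransformChain:
    """Build a transform chain of a given kind.

    kinds: ``identity``; ``translation`` (params: offset);
    ``rigid`` (angle_deg, axis, center, offset); ``affine`` (matrix, or a
    random well-conditioned one from the seed); ``smooth_field``
    (shape, voxel_size, origin, max_displacement_um) — low-frequency
    sinusoidal offsets with the given amplitude cap.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "identity":
        return TransformChain.identity()
    if kind == "translation":
        return TransformChain(
            [AffineTransform.translation(params.get("offset", (100.0, 0.0, 0.0)))])
    if kind == "rigid":
        angle = math.radians(params.get("angle_deg", 10.0))
        axis = int(params.get("axis", 1))
        center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), float)
        offset = np.asarray(params.get("offset", (0.0, 0.0, 0.0)), float)
        c, s = math.cos(angle), math.sin(angle)
        other = [a for a in range(3) if a != axis]
        r = np.eye(3)
        r[other[0], other[0]] = c
        r[other[0], other[1]] = -s
        r[other[1], other[0]] = s
        r[other[1], other[1]] = c
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = offset + center - r @ center
        return TransformChain([AffineTransform(m)])
    if kind == "affine":
        if "matrix" in params:
            return TransformChain([AffineTransform(np.asarray(params["matrix"]))])
        r = np.eye(3) + rng.uniform(-0.05, 0.05, (3, 3))
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = rng.uniform(-200, 200, 3)
        if abs(np.linalg.det(r)) < 1e-3:
            raise ValueError("singular affine request")
        return TransformChain([AffineTransform(m)])
    if kind == "smooth_field":
        shape = tuple(params.get("shape", (12, 12, 12)))
        vsize = params.get("voxel_size", (500.0, 500.0, 500.0))
        origin = params.get("origin", (0.0, 0.0, 0.0))
        amp = float(params.get("max_displacement_um", 20.0))
        extent = np.asarray(shape) * np.asarray(vsize)
        centers = [
            (np.arange(n) + 0.5) * v + o
            for n, v, o in zip(shape, vsize, origin)
        ]
        gx, gy, gz = np.meshgrid(*centers, indexing="ij")
        offsets = np.zeros(shape + (3,))
        for c in range(3):
            phase = rng.uniform(0, 2 * math.pi, 3)
            offsets[..., c] = (amp / 3.0) * (
                np.sin(2 * math.pi * gx / extent[0] + phase[0])
                + np.sin(2 * math.pi * gy / extent[1] + phase[1])
                + np.sin(2 * math.pi * gz / extent[2] + phase[2]))
        return TransformChain([DisplacementField(offsets, tuple(vsize),
                                                 tuple(origin))])
    raise ValueError(f"unknown transform kind {kind!r}")


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

COHORT_TARGET_AREAS = ("SSs", "MOp", "MOs", "SSp-ul", "SSp-tr", "SSp-un",
                       "VISa", "VISrl")

AXON_TOTAL_MEAN_MM = 67.9
AXON_TOTAL_SD_MM = 13.0
DENDRITE_TOTAL_MEAN_MM = 7.2
DENDRITE_TOTAL_SD_MM = 0.8


def _random_point_in(lo, hi, rng, margin=25.0):
    lo = np.asarray(lo, float) + margin
    hi = np.asarray(hi, float) - margin
    return rng.uniform(lo, hi)


def _wander(rng, start: np.ndarray, lo, hi, total_um: float,
            type_code: int, attach0, segments: list[CableSegment],
            mean_seg_um: float = 250.0) -> float:
    """Append a random walk of straight segments confined to a box until
    ``total_um`` cable is laid (the last segment is trimmed to land on the
    target exactly).  Returns the cable actually added."""
    lo = np.asarray(lo, float) + 25.0
    hi = np.asarray(hi, float) - 25.0
    pos = start.copy()
    laid = 0.0
    attach = attach0
    while laid < total_um - 1e-9:
        want = min(rng.uniform(0.5, 1.5) * mean_seg_um, total_um - laid)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            end = pos + want * d
            if np.all(end > lo) and np.all(end < hi):
                break
        else:
            end = np.clip(pos + want * d, lo, hi)
            want = float(np.linalg.norm(end - pos))
            if want < 1e-9:
                end = (lo + hi) / 2
                want = float(np.linalg.norm(end - pos))
        segments.append(CableSegment(tuple(pos), tuple(end), type_code, attach))
        attach = len(segments) - 1
        pos = end
        laid += want
    return laid


def _route(points: Sequence[np.ndarray], type_code: int, attach0,
           segments: list[CableSegment]) -> int:
    """Append straight segments through the way-points; returns the index
    of the last appended segment."""
    attach = attach0
    for a, b in zip(points[:-1], points[1:]):
        segments.append(CableSegment(tuple(a), tuple(b), type_code, attach))
        attach = len(segments) - 1
    return attach


def default_cohort_specs(n: int = 10, seed: int = 7,
                         atlas_spec: AtlasSpec | None = None
                         ) -> list[NeuronSpec]:
    """Blueprints for a cohort of layer-2/3 barrel-cortex neurons.

    Each neuron: soma in a barrel column (one in three sits in a septum
    between two columns), ~7 mm of local dendrite, dense local axon in the
    home area, long-range axonal branches into 2-4 neighbouring cortical
    areas, and — for a subset — a branch through the white-matter slab and
    one descending into the dorsal striatum.  Total axon per neuron is
    drawn from N(67.9, 13.0) mm, dendrite from N(7.2, 0.8) mm.
    """
    atlas_spec = atlas_spec or default_atlas_spec()
    rng = np.random.default_rng(seed)
    bfd = next(r for r in atlas_spec.regions if r.acronym == "SSp-bfd")
    region_boxes = {r.acronym: (np.asarray(r.lo, float), np.asarray(r.hi, float))
                    for r in atlas_spec.regions}
    centers = atlas_spec.barrels.centers() if atlas_spec.barrels else {}
    col_names = sorted(centers)
    specs: list[NeuronSpec] = []
    for i in range(n):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        name = f"SYN{i:03d}"
        # soma: layer 2/3 depth, in a column or (every third neuron) a septum
        if centers and i % 3 != 2:
            cap, cml = centers[col_names[int(sub.integers(len(col_names)))]]
            soma = np.array([cap + sub.uniform(-50, 50), 200.0,
                             cml + sub.uniform(-50, 50)])
        elif centers:
            pairs = [(c1, c2) for c1, c2 in zip(col_names, col_names[1:])
                     if c1[0] == c2[0]]           # arc-adjacent, same row
            c1, c2 = pairs[int(sub.integers(len(pairs)))]
            (a_ap, a_ml), (b_ap, b_ml) = centers[c1], centers[c2]
            soma = np.array([(a_ap + b_ap) / 2, 200.0, (a_ml + b_ml) / 2])
        else:
            soma = _random_point_in(bfd.lo, bfd.hi, sub)
            soma[1] = 200.0

        axon_total = max(30.0, sub.normal(AXON_TOTAL_MEAN_MM,
                                          AXON_TOTAL_SD_MM)) * 1000.0
        dend_total = max(3.0, sub.normal(DENDRITE_TOTAL_MEAN_MM,
                                         DENDRITE_TOTAL_SD_MM)) * 1000.0
        segments: list[CableSegment] = []

        # dendrites: local arbor around the soma, upper layers of home area
        dend_box = (np.maximum(soma - (400, 180, 400), bfd.lo),
                    np.minimum(soma + (400, 500, 400), bfd.hi))
        _wander(sub, soma, dend_box[0], dend_box[1], dend_total,
                BASAL_DENDRITE, "soma", segments, mean_seg_um=120.0)

        # choose long-range targets and budget the axon
        k_targets = int(sub.integers(2, 5))
        targets = list(sub.choice(COHORT_TARGET_AREAS, size=k_targets,
                                  replace=False))
        goes_wm = i % 2 == 0          # half the cohort sends a callosal branch
        goes_cp = i % 3 == 0          # a third descends to the striatum
        budget = axon_total
        local_frac = sub.uniform(0.5, 0.65)
        local_axon = budget * local_frac
        remote = budget - local_axon
        wm_axon = remote * 0.15 if goes_wm else 0.0
        cp_axon = remote * 0.2 if goes_cp else 0.0
        per_target = (remote - wm_axon - cp_axon) / k_targets

        # dense local axon through the home-column layers
        local_box = (np.maximum(soma - (700, 200, 700), bfd.lo),
                     np.minimum(soma + (700, 750, 700), bfd.hi))
        _wander(sub, soma, local_box[0], local_box[1], local_axon,
                AXON, "soma", segments)

        # long-range intracortical branches (stay in the gray matter)
        for t in targets:
            lo, hi = region_boxes[t]
            entry = _random_point_in(lo, hi, sub)
            entry[1] = sub.uniform(120, 280)   # travel in layer 2/3
            mid = soma + 0.5 * (entry - soma)
            mid[1] = sub.uniform(120, 280)
            last = _route([soma, mid, entry], AXON, "soma", segments)
            arbor = max(0.0, per_target - segments[last].length
                        - segments[last - 1].length)
            _wander(sub, np.asarray(segments[last].end), lo, hi, arbor,
                    AXON, last, segments)

        # white-matter branch: descend through L5/6 into the callosal slab
        if goes_wm:
            below = np.array([soma[0], 1100.0, soma[2]])
            last = _route([soma, below], AXON, "soma", segments)
            wm_lo = (max(soma[0] - 2000, 50.0), 1000.0, 50.0)
            wm_hi = (min(soma[0] + 2000, 5950.0), 1200.0, 5950.0)
            spent = segments[last].length
            _wander(sub, below, wm_lo, wm_hi, max(0.0, wm_axon - spent),
                    AXON, last, segments, mean_seg_um=400.0)

        # striatal branch: through the white matter into the CP block
        if goes_cp:
            cp_lo, cp_hi = region_boxes["CP"]
            target = _random_point_in(cp_lo, cp_hi, sub)
            way = np.array([soma[0], 1100.0, soma[2]])
            last = _route([soma, way, target], AXON, "soma", segments)
            spent = segments[last].length + segments[last - 1].length
            _wander(sub, target, cp_lo, cp_hi, max(0.0, cp_axon - spent),
                    AXON, last, segments, mean_seg_um=300.0)

        specs.append(NeuronSpec(name=name, soma=tuple(soma),
                                segments=segments,
                                seed=int(sub.integers(0, 2**31 - 1))))
    return specs


def make_cohort(n: int = 10, seed: int = 7,
                atlas_spec: AtlasSpec | None = None
                ) -> list[tuple[NeuronReconstruction, GroundTruth]]:
    """Generate ``n`` neurons with analytic truth on the default atlas."""
    atlas_spec = atlas_spec or default_atlas_spec()
    specs = default_cohort_specs(n, seed, atlas_spec)
    return [make_neuron(s, atlas_spec) for s in specs]
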