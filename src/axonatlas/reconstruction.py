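"""Reading, validating and writing ESWC neuron reconstructions.

A reconstruction is a forest of annotated nodes.  Each node row carries a
node id, x/y/z coordinate, radius, an integer neurite type code and the id
of its parent node (-1 for a root).  Coordinates start out in imaging-voxel
units (anisotropic two-photon stacks, typically 0.8 x 0.8 x 5 um) and are
converted once to physical micrometres with :func:`to_physical`.

Type codes follow the SWC convention: 1 = soma, 2 = axon, 3 = basal
dendrite, 4 = apical dendrite.  Other codes are preserved verbatim but are
excluded from axon/dendrite length totals downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

__all__ = [
    "ReconNode",
    "NeuronReconstruction",
    "ValidationReport",
    "EswcParseError",
    "StructureError",
    "SpaceError",
    "parse_eswc",
    "write_eswc",
    "to_physical",
    "validate",
]

SOMA, AXON, BASAL_DENDRITE, APICAL_DENDRITE = 1, 2, 3, 4
DENDRITE_CODES = frozenset({BASAL_DENDRITE, APICAL_DENDRITE})


class EswcParseError(ValueError):
    """A malformed ESWC data row (non-numeric field or too few columns)."""


class StructureError(ValueError):
    """Dangling parent references, duplicate ids or cycles."""


class SpaceError(RuntimeError):
    """Operation applied to a reconstruction in the wrong coordinate space."""


@dataclass(frozen=True)
class ReconNode:
    """One annotated point of a traced neurite."""

    id: int
    x: float
    y: float
    z: float
    radius: float
    type_code: int
    parent_id: int
    extra: tuple[str, ...] = ()

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def as_tuple(self) -> tuple:
        return (self.id, self.x, self.y, self.z, self.radius,
                self.type_code, self.parent_id, self.extra)


@dataclass
class NeuronReconstruction:
    """A forest of :class:`ReconNode` with its coordinate-space bookkeeping.

    ``space`` is ``"voxel"`` while coordinates are in imaging-voxel units and
    ``"micron"`` after :func:`to_physical`; ``voxel_size`` records the
    imaging resolution in um per voxel along X, Y, Z either way.
    """

    name: str
    nodes: list[ReconNode]
    space: str = "voxel"
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 5.0)

    def __post_init__(self) -> None:
        if self.space not in ("voxel", "micron"):
            raise ValueError(f"unknown space {self.space!r}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive um values")
        _check_structure(self.nodes)

    # -- convenience accessors -------------------------------------------
    def node_by_id(self) -> dict[int, ReconNode]:
        return {n.id: n for n in self.nodes}

    def roots(self) -> list[ReconNode]:
        return [n for n in self.nodes if n.parent_id == -1]

    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in the current space."""
        if not self.nodes:
            return np.empty((0, 3))
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def edges(self) -> list[tuple[ReconNode, ReconNode]]:
        """(parent, child) pairs; children order follows file order."""
        by_id = self.node_by_id()
        return [(by_id[n.parent_id], n) for n in self.nodes if n.parent_id != -1]

    def total_edge_length(self) -> float:
        return float(sum(math.dist(p.xyz, c.xyz) for p, c in self.edges()))

    def coordinate_ranges(self) -> dict[str, tuple[float, float]]:
        """Min/max per axis, reported so a user can decide whether a file is
        already in um (deposited exports are not guaranteed either way)."""
        if not self.nodes:
            return {ax: (math.nan, math.nan) for ax in "xyz"}
        c = self.coords()
        return {ax: (float(c[:, i].min()), float(c[:, i].max()))
                for i, ax in enumerate("xyz")}


def _check_structure(nodes: Sequence[ReconNode]) -> None:
    ids = [n.id for n in nodes]
    id_set = set(ids)
    if len(id_set) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise StructureError(f"duplicate node id {dup}")
    parent = {}
    for n in nodes:
        if n.parent_id != -1 and n.parent_id not in id_set:
            raise StructureError(
                f"node {n.id} references missing parent id {n.parent_id}")
        parent[n.id] = n.parent_id
    # cycle check by path compression walk
    state: dict[int, int] = {}  # 0 visiting, 1 done
    for start in ids:
        path = []
        cur = start
        while cur != -1 and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise StructureError(f"cycle involving node id {cur}")
            state[cur] = 0
            path.append(cur)
            cur = parent[cur]
        for p in path:
            state[p] = 1


@dataclass
class ValidationReport:
    """Summary of structural findings for a parsed reconstruction."""

    n_nodes: int
    n_roots: int
    nodes_per_type: dict[int, int]
    zero_length_edges: list[tuple[int, int]]
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def parse_eswc(
    stream: TextIO | str | Path,
    name: str = "",
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 5.0),
    space: str = "voxel",
) -> NeuronReconstruction:
    """Parse an (E)SWC text stream into a :class:`NeuronReconstruction`.

    Rows are whitespace-delimited; lines starting with ``#`` are comments.
    At least seven columns in the SWC standard order ``id type x y z radius
    parent`` (the order Vaa3D exports) are required; extra ESWC columns are
    preserved verbatim for round-tripping.

    Raises :class:`EswcParseError` naming the offending line for malformed
    rows and :class:`StructureError` for dangling parents, cycles or
    duplicate ids.
    """
    close = False
    if isinstance(stream, (str, Path)):
        path = Path(stream)
        if not name:
            name = path.stem
        fh: TextIO = open(path, "rt")
        close = True
    else:
        fh = stream
    try:
        nodes: list[ReconNode] = []
        header_meta: dict[str, str] = {}
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header_meta[key.strip().lower()] = val.strip()
                continue
            fields = line.split()
            if len(fields) < 7:
                raise EswcParseError(
                    f"line {lineno}: expected >=7 columns, got {len(fields)}")
            try:
                nid = int(fields[0])
                type_code = int(fields[1])
                x, y, z = (float(fields[2]), float(fields[3]), float(fields[4]))
                radius = float(fields[5])
                parent_id = int(fields[6])
            except ValueError as exc:
                raise EswcParseError(f"line {lineno}: non-numeric field ({exc})")
            if nid <= 0:
                raise EswcParseError(f"line {lineno}: node id must be positive")
            if radius < 0:
                raise EswcParseError(f"line {lineno}: negative radius")
            nodes.append(ReconNode(nid, x, y, z, radius, type_code,
                                   parent_id, tuple(fields[7:])))
        if "name" in header_meta and not name:
            name = header_meta["name"]
        if "space" in header_meta:
            space = header_meta["space"]
        if "voxel_size" in header_meta:
            voxel_size = tuple(float(v) for v in header_meta["voxel_size"].split())  # type: ignore[assignment]
        return NeuronReconstruction(name=name or "neuron", nodes=nodes,
                                    space=space, voxel_size=voxel_size)
    finally:
        if close:
            fh.close()


def write_eswc(recon: NeuronReconstruction, stream: TextIO | str | Path) -> None:
    """Write a reconstruction in ESWC layout; the comment header records the
    name, coordinate space and imaging voxel size so a round-trip is exact."""
    close = False
    if isinstance(stream, (str, Path)):
        fh: TextIO = open(stream, "wt")
        close = True
    else:
        fh = stream
    try:
        fh.write(f"# name: {recon.name}\n")
        fh.write(f"# space: {recon.space}\n")
        fh.write("# voxel_size: "
                 + " ".join(repr(float(v)) for v in recon.voxel_size) + "\n")
        fh.write("# columns: id type x y z radius parent [extra...]\n")
        for n in recon.nodes:
            row = [str(n.id), str(n.type_code), repr(float(n.x)),
                   repr(float(n.y)), repr(float(n.z)), repr(float(n.radius)),
                   str(n.parent_id), *n.extra]
            fh.write(" ".join(row) + "\n")
    finally:
        if close:
            fh.close()


def to_physical(recon: NeuronReconstruction) -> NeuronReconstruction:
    """Scale voxel-unit coordinates componentwise by the imaging voxel size.

    Coordinates are treated as continuous positions in a 0-based voxel
    frame; no half-voxel offset is applied (see the methods note).  Calling
    this on a micron-space reconstruction raises :class:`SpaceError` rather
    than silently rescaling twice.
    """
    if recon.space != "voxel":
        raise SpaceError("reconstruction is already in micron space")
    sx, sy, sz = recon.voxel_size
    nodes = [replace(n, x=n.x * sx, y=n.y * sy, z=n.z * sz)
             for n in recon.nodes]
    return NeuronReconstruction(name=recon.name, nodes=nodes,
                                space="micron", voxel_size=recon.voxel_size)


def validate(recon: NeuronReconstruction) -> ValidationReport:
    """Structural report: root count, per-type counts, zero-length edges."""
    per_type: dict[int, int] = {}
    for n in recon.nodes:
        per_type[n.type_code] = per_type.get(n.type_code, 0) + 1
    zero_edges = [(p.id, c.id) for p, c in recon.edges()
                  if math.dist(p.xyz, c.xyz) == 0.0]
    findings = [f"zero-length edge {p}->{c}" for p, c in zero_edges]
    return ValidationReport(
        n_nodes=len(recon.nodes),
        n_roots=len(recon.roots()),
        nodes_per_type=per_type,
        zero_length_edges=zero_edges,
        findings=findings,
    )
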