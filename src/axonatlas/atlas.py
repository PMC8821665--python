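"""Parcellation volumes, structure ontologies and barrel-column maps.

The parcellation is a 3D integer label grid (25 um isotropic in the Allen
CCFv3); label 0 means outside the brain / unassigned.  Point lookups use a
half-open voxel convention: a point p in um belongs to voxel
floor((p - origin) / voxel_size), so the boundary plane at k * voxel_size
goes to the higher voxel.  The structure ontology is the id/acronym/parent
hierarchy used to aggregate layer-resolved labels up to named regions and
to classify labels into the gray-matter / fiber-tract / striatum
compartments used for display and compartment splits.

The barrel-column map is a second label volume in the same frame, whose
labels name whisker columns by row letter and arc number (C2, D1, ...).
Unlabeled voxels between columns are septa: a soma falling there is
reported as septal between its flanking columns rather than force-assigned.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ParcellationVolume",
    "StructureOntology",
    "BarrelColumnMap",
    "ColumnReport",
    "CompartmentRoots",
    "load_annotation",
    "save_annotation",
    "load_ontology",
    "load_barrel_map",
    "region_at",
    "classify_compartment",
    "barrel_column_at",
    "aggregate_lengths",
]

UNASSIGNED_ID = 0
UNASSIGNED_ACRONYM = "unassigned"


# --------------------------------------------------------------------------
# label volumes
# --------------------------------------------------------------------------

@dataclass
class ParcellationVolume:
    """3D integer structure labels on a regular grid.

    ``labels`` is indexed [i, j, k] along the declared ``axis_order`` (grid
    axis -> anatomical axis, default "xyz" meaning grid axes are already the
    anatomical x/y/z of the point queries).  ``origin`` is the um position
    of the corner of voxel (0, 0, 0).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("parcellation labels must be an integer dtype")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3  # type: ignore
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ValueError("axis_order must be a permutation of 'xyz'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def distinct_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def _grid_permutation(self) -> list[int]:
        # for grid axis g, which anatomical axis (0=x,1=y,2=z) it carries
        return ["xyz".index(c) for c in self.axis_order]

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """floor((p - origin)/voxel_size) per anatomical axis, then permuted
        to grid order; no bounds clipping."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        idx_anat = np.floor(rel).astype(np.int64)
        perm = self._grid_permutation()
        return idx_anat[:, perm]

    def lookup(self, points: np.ndarray) -> np.ndarray:
        """Vectorized half-open voxel lookup; out-of-grid points get 0."""
        idx = self.voxel_indices(points)
        shape = np.asarray(self.labels.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def voxel_centers(self) -> np.ndarray:
        """(n, 3) um centers of all voxels, in anatomical axis order."""
        grids = np.meshgrid(*[np.arange(s) for s in self.labels.shape],
                            indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        perm = self._grid_permutation()
        inv = np.argsort(perm)
        idx_anat = idx[:, inv]
        return (idx_anat + 0.5) * np.asarray(self.voxel_size) + np.asarray(self.origin)


def region_at(point: Sequence[float] | np.ndarray, vol: ParcellationVolume) -> int:
    """Structure id at a um point (0 outside the grid or the brain)."""
    return int(vol.lookup(np.atleast_2d(point))[0])


# --------------------------------------------------------------------------
# structure ontology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureEntry:
    id: int
    acronym: str
    name: str
    parent_id: int | None


class OntologyError(ValueError):
    pass


class StructureOntology:
    """The id/acronym/parent hierarchy of brain structures.

    Indexed for O(depth) ancestor queries; a single root, acyclic, acronyms
    unique.  Mirrors the Allen structure graph (id, acronym, name,
    parent_structure_id).
    """

    def __init__(self, entries: Iterable[StructureEntry]):
        self._by_id: dict[int, StructureEntry] = {}
        for e in entries:
            if e.id in self._by_id:
                raise OntologyError(f"duplicate structure id {e.id}")
            self._by_id[e.id] = e
        self._by_acronym: dict[str, StructureEntry] = {}
        roots = []
        for e in self._by_id.values():
            if e.acronym in self._by_acronym:
                raise OntologyError(f"duplicate acronym {e.acronym!r}")
            self._by_acronym[e.acronym] = e
            if e.parent_id is None:
                roots.append(e)
            elif e.parent_id not in self._by_id:
                raise OntologyError(
                    f"structure {e.id} ({e.acronym}) has unknown parent "
                    f"{e.parent_id}")
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {i: [] for i in self._by_id}
        for e in self._by_id.values():
            if e.parent_id is not None:
                self._children[e.parent_id].append(e.id)
        # acyclicity: every id must reach the root
        for e in self._by_id.values():
            seen = set()
            cur: int | None = e.id
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle at structure {cur}")
                seen.add(cur)
                cur = self._by_id[cur].parent_id

    # -- queries ---------------------------------------------------------
    def __contains__(self, sid: int) -> bool:
        return sid in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def ids(self) -> list[int]:
        return list(self._by_id)

    def get(self, sid: int) -> StructureEntry:
        try:
            return self._by_id[sid]
        except KeyError:
            raise OntologyError(f"unknown structure id {sid}") from None

    def by_acronym(self, acronym: str) -> StructureEntry:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise OntologyError(f"unknown acronym {acronym!r}") from None

    def acronym(self, sid: int) -> str:
        return self.get(sid).acronym

    def parent(self, sid: int) -> int | None:
        return self.get(sid).parent_id

    def children(self, sid: int) -> list[int]:
        return list(self._children[self.get(sid).id])

    def ancestors(self, sid: int) -> list[int]:
        """Parent chain from immediate parent up to the root."""
        out = []
        cur = self.get(sid).parent_id
        while cur is not None:
            out.append(cur)
            cur = self._by_id[cur].parent_id
        return out

    def is_descendant(self, sid: int, ancestor_id: int) -> bool:
        """True if ``sid`` equals or lies below ``ancestor_id``."""
        cur: int | None = self.get(sid).id
        while cur is not None:
            if cur == ancestor_id:
                return True
            cur = self._by_id[cur].parent_id
        return False

    def subtree(self, sid: int) -> set[int]:
        out, stack = set(), [self.get(sid).id]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self._children[cur])
        return out

    def leaves(self) -> list[int]:
        return [i for i in self._by_id if not self._children[i]]


def load_ontology(path: str | Path) -> StructureOntology:
    """Load an ontology from Allen structure-graph JSON or a flat CSV.

    JSON: either a bare list of records or the Allen web-service envelope
    ``{"msg": [...]}``; records need id, acronym, name,
    parent_structure_id (null for the root).  CSV needs columns id,
    acronym, name, parent_structure_id ('' for the root).
    """
    path = Path(path)
    entries: list[StructureEntry] = []
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        records = doc["msg"] if isinstance(doc, dict) else doc
        for r in records:
            entries.append(StructureEntry(
                id=int(r["id"]), acronym=str(r["acronym"]),
                name=str(r.get("name", r["acronym"])),
                parent_id=(None if r.get("parent_structure_id") is None
                           else int(r["parent_structure_id"]))))
    else:
        with open(path, newline="") as fh:
            for r in csv.DictReader(fh):
                pid = r.get("parent_structure_id", "")
                entries.append(StructureEntry(
                    id=int(r["id"]), acronym=r["acronym"],
                    name=r.get("name", r["acronym"]),
                    parent_id=None if pid in ("", None) else int(pid)))
    return StructureOntology(entries)


def save_ontology_json(ontology: StructureOntology, path: str | Path) -> None:
    records = [
        {"id": e.id, "acronym": e.acronym, "name": e.name,
         "parent_structure_id": e.parent_id}
        for e in (ontology.get(i) for i in ontology.ids())
    ]
    with open(path, "w") as fh:
        json.dump({"msg": records}, fh, indent=1)


# --------------------------------------------------------------------------
# NRRD label-volume I/O (via SimpleITK)
# --------------------------------------------------------------------------

def _read_nrrd(path: str | Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)          # (z, y, x)
    arr = np.transpose(arr, (2, 1, 0))         # -> (x, y, z)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    return arr, spacing, origin


def _write_nrrd(arr: np.ndarray, spacing, origin, path: str | Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def load_annotation(path: str | Path, axis_order: str = "xyz") -> ParcellationVolume:
    """Load a parcellation NRRD; non-integer voxel types are rejected."""
    arr, spacing, origin = _read_nrrd(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"annotation volume must be integer-typed, got {arr.dtype}")
    return ParcellationVolume(arr, spacing, origin, axis_order)


def save_annotation(vol: ParcellationVolume, path: str | Path) -> None:
    _write_nrrd(vol.labels, vol.voxel_size, vol.origin, path)


def load_barrel_map(path: str | Path, name_table: str | Path | Mapping[int, str],
                    axis_order: str = "xyz") -> "BarrelColumnMap":
    """Load a barrel-column label NRRD plus its label -> column-name table.

    ``name_table`` is either a mapping {label: "C2", ...} or a CSV with
    columns label, row, arc (name = row letter + arc number).
    """
    vol = load_annotation(path, axis_order)
    if isinstance(name_table, Mapping):
        names = dict(name_table)
    else:
        names = {}
        with open(name_table, newline="") as fh:
            for r in csv.DictReader(fh):
                names[int(r["label"])] = f"{r['row']}{r['arc']}"
    return BarrelColumnMap(vol, names)


def save_barrel_map(barrel_map: "BarrelColumnMap", nrrd_path: str | Path,
                    table_path: str | Path) -> None:
    save_annotation(barrel_map.volume, nrrd_path)
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "row", "arc"])
        for label in sorted(barrel_map.names):
            name = barrel_map.names[label]
            w.writerow([label, name[0], name[1:]])


# --------------------------------------------------------------------------
# compartment classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentRoots:
    """Acronyms of the subtree roots deciding each display compartment.

    Configured by acronym (not hard-coded ids) so alternative atlas
    versions load cleanly.
    """

    gray_matter: str = "Isocortex"
    fiber_tract: str = "fiber tracts"
    striatum: str = "STRd"


def classify_compartment(
    sid: int,
    ontology: StructureOntology,
    roots: CompartmentRoots = CompartmentRoots(),
) -> str:
    """Map a structure id to one of gray_matter / fiber_tract / striatum /
    other / outside by subtree membership; 0 is the out-of-atlas sentinel."""
    if sid == UNASSIGNED_ID:
        return "outside"
    entry = ontology.get(sid)  # raises for unknown ids
    for name in ("gray_matter", "fiber_tract", "striatum"):
        acr = getattr(roots, name)
        try:
            root = ontology.by_acronym(acr)
        except OntologyError:
            continue
        if ontology.is_descendant(entry.id, root.id):
            return name
    return "other"


COMPARTMENTS = ("gray_matter", "fiber_tract", "striatum", "other", "outside")


# --------------------------------------------------------------------------
# barrel columns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnReport:
    """Soma localization: inside a column, in a septum between (up to) two
    columns, or outside the barrel field."""

    kind: str                     # "column" | "septum" | "outside"
    columns: tuple[str, ...]      # 1 name, 2 names, or empty

    def __str__(self) -> str:
        if self.kind == "column":
            return self.columns[0]
        if self.kind == "septum":
            return "septum between " + " and ".join(self.columns)
        return "outside barrel field"


class BarrelColumnMap:
    """Labeled barrel-column volume sharing the parcellation's frame."""

    def __init__(self, volume: ParcellationVolume, names: Mapping[int, str]):
        self.volume = volume
        self.names = {int(k): str(v) for k, v in names.items()}
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("column names must be unique")
        present = set(np.unique(volume.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without column names: {sorted(missing)}")
        self._tree: cKDTree | None = None
        self._tree_labels: np.ndarray | None = None

    def _kdtree(self) -> tuple[cKDTree, np.ndarray]:
        if self._tree is None:
            mask = self.volume.labels != 0
            centers = self.volume.voxel_centers()[mask.ravel()]
            self._tree = cKDTree(centers)
            self._tree_labels = self.volume.labels[mask]
        return self._tree, self._tree_labels  # type: ignore[return-value]

    def column_name(self, label: int) -> str:
        return self.names[int(label)]


def barrel_column_at(
    point: Sequence[float] | np.ndarray,
    barrel_map: BarrelColumnMap,
    septum_radius: float = 150.0,
) -> ColumnReport:
    """Locate a um point in the barrel-column map.

    A labeled containing voxel gives a direct column hit.  Otherwise the up
    to two nearest distinct columns with labeled voxels within
    ``septum_radius`` um are reported as a septal position; with none in
    range the point is outside the barrel field.
    """
    label = region_at(point, barrel_map.volume)
    if label != 0:
        return ColumnReport("column", (barrel_map.column_name(label),))
    tree, labels = barrel_map._kdtree()
    dists, idx = tree.query(np.asarray(point, float), k=min(64, len(labels)))
    dists, idx = np.atleast_1d(dists), np.atleast_1d(idx)
    near: list[tuple[float, str]] = []
    seen: set[str] = set()
    for d, i in zip(dists, idx):
        if not np.isfinite(d) or d > septum_radius:
            break
        name = barrel_map.column_name(labels[i])
        if name not in seen:
            seen.add(name)
            near.append((float(d), name))
        if len(near) == 2:
            break
    if not near:
        return ColumnReport("outside", ())
    return ColumnReport("septum", tuple(name for _, name in near))


# --------------------------------------------------------------------------
# hierarchy aggregation
# --------------------------------------------------------------------------

def aggregate_lengths(table, ontology: StructureOntology, targets: Iterable[int | str]):
    """Aggregate a per-structure length table onto target structures.

    Each target's length is the sum over table rows whose structure is the
    target or one of its descendants.  Targets may be ids or acronyms;
    overlapping targets (one a descendant of another) are an error because
    they would double-count.  Rows not under any target (including the
    unassigned sentinel) are kept in a residual bucket so totals conserve.

    Returns a new table of the same type (see quantify.RegionLengthTable).
    """
    from .quantify import RegionLengthTable  # local import avoids a cycle

    target_ids = []
    for t in targets:
        target_ids.append(ontology.by_acronym(t).id if isinstance(t, str)
                          else ontology.get(int(t)).id)
    if len(set(target_ids)) != len(target_ids):
        raise ValueError("duplicate aggregation targets")
    for a in target_ids:
        for b in target_ids:
            if a != b and ontology.is_descendant(a, b):
                raise ValueError(
                    f"overlapping targets: {ontology.acronym(a)} is a "
                    f"descendant of {ontology.acronym(b)}")

    df = table.df
    rows: dict[tuple[int, str], dict] = {}

    def _add(sid: int, acr: str, ntype: str, length: float, npts: int) -> None:
        key = (sid, ntype)
        r = rows.setdefault(key, {"structure_id": sid, "acronym": acr,
                                  "neurite_type": ntype, "length_um": 0.0,
                                  "n_points": 0})
        r["length_um"] += length
        r["n_points"] += npts

    for rec in df.itertuples(index=False):
        sid = int(rec.structure_id)
        assigned = False
        if sid != UNASSIGNED_ID:
            ontology.get(sid)  # every table id must resolve
            for t in target_ids:
                if ontology.is_descendant(sid, t):
                    _add(t, ontology.acronym(t), rec.neurite_type,
                         rec.length_um, rec.n_points)
                    assigned = True
                    break
        if not assigned:
            _add(UNASSIGNED_ID if sid == UNASSIGNED_ID else -1,
                 UNASSIGNED_ACRONYM if sid == UNASSIGNED_ID else "other",
                 rec.neurite_type, rec.length_um, rec.n_points)

    return RegionLengthTable.from_records(list(rows.values()), dict(table.metadata))
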