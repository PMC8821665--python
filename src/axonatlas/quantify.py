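"""Per-region neurite-length tables, compartment splits and cohort stats.

Every resampled point is assigned to the brain structure whose voxel
contains it; counts per (structure, neurite type) times the resampling
step give lengths in um.  The identity

    sum of all table lengths (incl. "unassigned") == point count * step

holds exactly for every run — it is the definition of the measure, not an
approximation — and is asserted in the test suite.

Soma-type points are excluded from the axon/dendrite totals and basal and
apical dendrite codes are pooled as "dendrite", since the readouts of
interest are per-neuron axon and dendrite cable.  Points falling outside
the atlas are kept in a named "unassigned" row, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    UNASSIGNED_ACRONYM,
    UNASSIGNED_ID,
    BarrelColumnMap,
    ColumnReport,
    CompartmentRoots,
    ParcellationVolume,
    StructureOntology,
    barrel_column_at,
    classify_compartment,
)
from .reconstruction import (
    AXON,
    DENDRITE_CODES,
    SOMA,
    NeuronReconstruction,
    to_physical,
)
from .resampling import ResampledCloud

__all__ = [
    "RegionLengthTable",
    "CohortSummary",
    "quantify_lengths",
    "total_length",
    "compartment_split",
    "locate_soma",
    "cohort_summary",
    "round_mm",
]

_COLUMNS = ["structure_id", "acronym", "neurite_type", "length_um", "n_points"]


def neurite_class(type_code: int) -> str:
    """Pool SWC type codes into axon / dendrite / soma / other."""
    if type_code == AXON:
        return "axon"
    if type_code in DENDRITE_CODES:
        return "dendrite"
    if type_code == SOMA:
        return "soma"
    return "other"


@dataclass
class RegionLengthTable:
    """Rows of (structure id, acronym, neurite type, length um, points).

    ``length_um == n_points * step`` exactly per row; metadata records the
    neuron name, resampling step and atlas version.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.df.columns) != _COLUMNS:
            self.df = self.df.reindex(columns=_COLUMNS)
        dup = self.df.duplicated(subset=["structure_id", "neurite_type"])
        if dup.any():
            raise ValueError("duplicate (structure, neurite_type) rows")

    @classmethod
    def from_records(cls, records: list[dict], metadata: dict) -> "RegionLengthTable":
        df = pd.DataFrame.from_records(records, columns=_COLUMNS)
        df = df.sort_values(["neurite_type", "structure_id"], ignore_index=True)
        return cls(df, metadata)

    @property
    def step(self) -> float:
        return float(self.metadata.get("step", 1.0))

    def rows_for(self, neurite_type: str) -> pd.DataFrame:
        return self.df[self.df.neurite_type == neurite_type]

    def length_of(self, structure: int | str, neurite_type: str = "axon") -> float:
        if isinstance(structure, str):
            sel = (self.df.acronym == structure)
        else:
            sel = (self.df.structure_id == structure)
        sel &= self.df.neurite_type == neurite_type
        return float(self.df.loc[sel, "length_um"].sum())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}: {v}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionLengthTable":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
                body_start = i + 1
            else:
                break
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        if "step" in meta:
            meta["step"] = float(meta["step"])
        return cls(df, meta)


def quantify_lengths(
    cloud: ResampledCloud,
    vol: ParcellationVolume,
    ontology: StructureOntology,
    *,
    include_soma: bool = False,
    metadata: Mapping | None = None,
) -> RegionLengthTable:
    """Count resampled points per brain structure and neurite class.

    Each point is assigned to the structure of its containing voxel
    (half-open floor convention); out-of-atlas points go to the
    "unassigned" row.  Lengths are counts times the resampling step, so the
    table total equals (tabulated point count) * step exactly.

    ``include_soma=False`` (default) drops soma-type and unknown-type
    points before tabulation; their counts are recorded in the metadata.
    """
    classes = np.array([neurite_class(t) for t in cloud.type_codes])
    keep = ((classes == "axon") | (classes == "dendrite")
            | (include_soma & (classes == "soma")))
    n_excluded = int((~keep).sum())
    labels = vol.lookup(cloud.points[keep]) if keep.any() else np.empty(0, int)
    kept_classes = classes[keep]

    records: list[dict] = []
    for ntype in ("axon", "dendrite", "soma"):
        mask = kept_classes == ntype
        if not mask.any():
            continue
        ids, counts = np.unique(np.asarray(labels)[mask], return_counts=True)
        for sid, cnt in zip(ids.tolist(), counts.tolist()):
            if sid == UNASSIGNED_ID:
                acr = UNASSIGNED_ACRONYM
            else:
                acr = ontology.acronym(int(sid))
            records.append({"structure_id": int(sid), "acronym": acr,
                            "neurite_type": ntype,
                            "length_um": cnt * cloud.step, "n_points": cnt})
    meta = dict(metadata or {})
    meta.setdefault("step", cloud.step)
    meta["n_points_tabulated"] = int(keep.sum())
    meta["n_points_excluded"] = n_excluded
    return RegionLengthTable.from_records(records, meta)


def total_length(table: RegionLengthTable, neurite_type: str = "axon") -> float:
    """Total cable of one neurite class in um, unassigned included."""
    return float(table.rows_for(neurite_type).length_um.sum())


def compartment_split(
    table: RegionLengthTable,
    ontology: StructureOntology,
    roots: CompartmentRoots = CompartmentRoots(),
    neurite_type: str = "axon",
) -> dict[str, float]:
    """Partition a neurite class's total over display compartments.

    Returns um per {gray_matter, fiber_tract, striatum, other, outside};
    the values sum exactly to :func:`total_length`.
    """
    out = {c: 0.0 for c in ("gray_matter", "fiber_tract", "striatum",
                            "other", "outside")}
    for rec in table.rows_for(neurite_type).itertuples(index=False):
        comp = classify_compartment(int(rec.structure_id), ontology, roots)
        out[comp] += float(rec.length_um)
    return out


def locate_soma(
    recon: NeuronReconstruction,
    barrel_map: BarrelColumnMap,
    septum_radius: float = 150.0,
    chain=None,
) -> ColumnReport:
    """Barrel-column report for the soma centroid.

    Uses the centroid of all soma-type nodes, falling back to the (single)
    root node when no soma type is present.  ``chain`` optionally maps the
    soma position into the barrel map's frame first.
    """
    rec = recon if recon.space == "micron" else to_physical(recon)
    soma_nodes = [n for n in rec.nodes if n.type_code == SOMA]
    if not soma_nodes:
        roots = rec.roots()
        if len(roots) != 1:
            raise ValueError(
                "no soma-type node and no unique root to designate")
        soma_nodes = roots
    centroid = np.mean([[n.x, n.y, n.z] for n in soma_nodes], axis=0)
    if chain is not None:
        centroid = chain.apply(centroid)[0]
    return barrel_column_at(centroid, barrel_map, septum_radius)


@dataclass
class CohortSummary:
    """Per-structure mean/SD/n of per-neuron lengths across a cohort.

    Regions absent from a neuron count as 0 for that neuron, so n equals
    the cohort size for every row.  SD is the sample SD (n-1 denominator);
    rows sort by descending mean with acronym tie-break.
    """

    df: pd.DataFrame            # structure_id, acronym, mean_um, sd_um, n
    neurite_type: str
    neuron_names: tuple[str, ...]


def cohort_summary(
    tables: Sequence[RegionLengthTable],
    neurite_type: str = "axon",
) -> CohortSummary:
    """Cohort mean/SD per structure with zero-imputation for absent regions."""
    if not tables:
        raise ValueError("need at least one table")
    versions = {t.metadata.get("atlas_version") for t in tables}
    if len(versions) > 1:
        raise ValueError(f"mixed atlas versions: {sorted(map(str, versions))}")
    names = tuple(str(t.metadata.get("neuron", f"neuron{i}"))
                  for i, t in enumerate(tables))
    per_neuron = []
    acronyms: dict[int, str] = {}
    for t in tables:
        rows = t.rows_for(neurite_type)
        series = rows.set_index("structure_id").length_um
        acronyms.update(zip(rows.structure_id, rows.acronym))
        per_neuron.append(series)
    wide = pd.DataFrame(per_neuron).fillna(0.0)   # neurons x structures
    n = len(tables)
    mean = wide.mean(axis=0)
    sd = wide.std(axis=0, ddof=1) if n > 1 else mean * 0.0
    df = pd.DataFrame({
        "structure_id": mean.index.astype(int),
        "acronym": [acronyms[i] for i in mean.index],
        "mean_um": mean.to_numpy(),
        "sd_um": sd.to_numpy(),
        "n": n,
    })
    df = df.sort_values(["mean_um", "acronym"], ascending=[False, True],
                        ignore_index=True)
    return CohortSummary(df, neurite_type, names)


def round_mm(length_um: float) -> float:
    """Report a length in mm at 0.1 mm precision (round half to even)."""
    return float(np.round(length_um / 1000.0, 1))
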