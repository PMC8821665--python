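"""End-to-end quantification of one reconstruction against an atlas.

Steps: voxel -> um conversion, path decomposition, 1 um arclength
resampling, optional registration transform, point-to-structure lookup,
and the per-region length table plus soma localization.

Two equivalent registration routes are supported when a transform chain is
given (the chain maps atlas space into sample space, as produced by
registering the atlas template to the imaged brain):

* ``route="points"`` (default, cheaper): map the resampled points into
  atlas space with the inverse chain and query the unwarped parcellation.
* ``route="volume"``: warp the parcellation into sample space once
  (nearest-neighbour labels) and query the points directly.

The two agree up to nearest-neighbour ties at voxel boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .atlas import BarrelColumnMap, ParcellationVolume, StructureOntology
from .quantify import RegionLengthTable, locate_soma, quantify_lengths
from .reconstruction import NeuronReconstruction, to_physical
from .resampling import ResampledCloud, resample_reconstruction
from .transforms import TransformChain, apply_to_labels

__all__ = ["PipelineResult", "quantify_neuron"]

log = logging.getLogger("axonatlas")


@dataclass
class PipelineResult:
    table: RegionLengthTable
    cloud: ResampledCloud              # in the frame the lookup used
    soma: object | None = None         # ColumnReport when a barrel map given


def quantify_neuron(
    recon: NeuronReconstruction,
    vol: ParcellationVolume,
    ontology: StructureOntology,
    *,
    chain: TransformChain | None = None,
    route: str = "points",
    step: float = 1.0,
    barrel_map: BarrelColumnMap | None = None,
    include_soma: bool = False,
    septum_radius: float = 150.0,
    metadata: Mapping | None = None,
) -> PipelineResult:
    """Run the full single-neuron quantification.

    ``recon`` may be in voxel or micron space (voxel space is converted
    with its recorded imaging voxel size).  ``chain`` maps atlas space to
    sample space; without one, sample and atlas frames are assumed
    identical.
    """
    rec = to_physical(recon) if recon.space == "voxel" else recon
    cloud = resample_reconstruction(rec, step)
    log.info("%s: %d paths, %d resampled points at %g um",
             recon.name, cloud.n_paths, len(cloud), step)

    soma_chain = None
    if chain is None:
        lookup_cloud = cloud
        lookup_vol = vol
    elif route == "points":
        sample_to_atlas = (chain.inverse()
                           if chain.direction == "atlas_to_sample" else chain)
        lookup_cloud = cloud.transformed(sample_to_atlas.apply(cloud.points))
        lookup_vol = vol
        soma_chain = sample_to_atlas
    elif route == "volume":
        atlas_to_sample = (chain if chain.direction == "atlas_to_sample"
                           else chain.inverse())
        lookup_vol = apply_to_labels(atlas_to_sample, vol)
        lookup_cloud = cloud
        if barrel_map is not None:
            barrel_map = BarrelColumnMap(
                apply_to_labels(atlas_to_sample, barrel_map.volume),
                barrel_map.names)
    else:
        raise ValueError(f"unknown route {route!r}")

    meta = dict(metadata or {})
    meta.setdefault("neuron", recon.name)
    table = quantify_lengths(lookup_cloud, lookup_vol, ontology,
                             include_soma=include_soma, metadata=meta)
    unassigned = table.df[table.df.structure_id == 0].length_um.sum()
    total = table.df.length_um.sum()
    if total:
        log.info("%s: %.1f um tabulated, %.2f%% unassigned",
                 recon.name, total, 100 * unassigned / total)

    soma = None
    if barrel_map is not None:
        # the barrel map shares the atlas frame, so apply the same mapping
        soma = locate_soma(rec, barrel_map, septum_radius, chain=soma_chain)
        log.info("%s: soma %s", recon.name, soma)
    return PipelineResult(table=table, cloud=lookup_cloud, soma=soma)
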