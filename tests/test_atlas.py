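"""Parcellation lookup, ontology queries, compartments, barrel columns."""

import json

import numpy as np
import pytest

from axonatlas.atlas import (
    BarrelColumnMap,
    CompartmentRoots,
    OntologyError,
    ParcellationVolume,
    StructureEntry,
    StructureOntology,
    aggregate_lengths,
    barrel_column_at,
    classify_compartment,
    load_annotation,
    load_barrel_map,
    load_ontology,
    region_at,
    save_annotation,
    save_ontology_json,
)
from axonatlas.quantify import RegionLengthTable


def _toy_ontology():
    return StructureOntology([
        StructureEntry(1, "root", "root", None),
        StructureEntry(2, "Isocortex", "isocortex", 1),
        StructureEntry(3, "fiber tracts", "fiber tracts", 1),
        StructureEntry(4, "STRd", "dorsal striatum", 1),
        StructureEntry(5, "SSp-bfd", "barrel field", 2),
        StructureEntry(6, "SSp-bfd1", "bfd L1", 5),
        StructureEntry(7, "SSp-bfd2/3", "bfd L2/3", 5),
        StructureEntry(8, "SSp-bfd4", "bfd L4", 5),
        StructureEntry(9, "cc", "corpus callosum", 3),
        StructureEntry(10, "CP", "caudoputamen", 4),
    ])


# -- volumes ---------------------------------------------------------------

def test_toy_volume_distinct_labels():
    vol = ParcellationVolume(np.array([[[0, 5], [5, 5]], [[0, 0], [5, 0]]]))
    assert set(vol.distinct_labels().tolist()) == {0, 5}


def test_non_integer_volume_rejected():
    with pytest.raises(TypeError):
        ParcellationVolume(np.zeros((2, 2, 2), dtype=float))


def test_region_at_floor_and_boundary():
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0, 0, 0] = 7
    labels[1, 0, 0] = 9
    vol = ParcellationVolume(labels, (25.0, 25.0, 25.0))
    assert region_at((12, 12, 12), vol) == 7
    # boundary plane goes to the higher voxel (half-open convention)
    assert region_at((25, 0, 0), vol) == 9
    assert region_at((-1, 0, 0), vol) == 0
    assert region_at((1000, 0, 0), vol) == 0


def test_region_at_matches_brute_force(rng):
    labels = rng.integers(0, 6, (9, 7, 5)).astype(np.int32)
    vol = ParcellationVolume(labels, (25.0, 25.0, 25.0), origin=(-30.0, 10.0, 0.0))
    pts = rng.uniform(-100, 300, (1000, 3))
    got = vol.lookup(pts)
    for p, g in zip(pts, got):
        idx = [int(np.floor((p[a] - vol.origin[a]) / 25.0)) for a in range(3)]
        expect = 0
        if all(0 <= idx[a] < labels.shape[a] for a in range(3)):
            expect = labels[idx[0], idx[1], idx[2]]
        assert g == expect


def test_annotation_nrrd_round_trip(tmp_path, rng):
    labels = rng.integers(0, 100, (6, 5, 4)).astype(np.int32)
    vol = ParcellationVolume(labels, (25.0, 25.0, 25.0))
    save_annotation(vol, tmp_path / "ann.nrrd")
    back = load_annotation(tmp_path / "ann.nrrd")
    assert np.array_equal(back.labels, labels)
    assert back.voxel_size == (25.0, 25.0, 25.0)


# -- ontology --------------------------------------------------------------

def test_ontology_ancestors_terminate_at_root():
    onto = _toy_ontology()
    assert onto.ancestors(2) == [1]
    for leaf in onto.leaves():
        assert onto.ancestors(leaf)[-1] == 1


def test_ontology_structural_errors():
    with pytest.raises(OntologyError):
        StructureOntology([StructureEntry(1, "root", "root", None),
                           StructureEntry(2, "a", "a", 99)])
    with pytest.raises(OntologyError):  # two roots
        StructureOntology([StructureEntry(1, "r1", "r", None),
                           StructureEntry(2, "r2", "r", None)])
    with pytest.raises(OntologyError):  # duplicate acronym
        StructureOntology([StructureEntry(1, "root", "root", None),
                           StructureEntry(2, "a", "a", 1),
                           StructureEntry(3, "a", "a", 1)])


def test_ontology_json_round_trip(tmp_path):
    onto = _toy_ontology()
    save_ontology_json(onto, tmp_path / "onto.json")
    back = load_ontology(tmp_path / "onto.json")
    assert len(back) == len(onto)
    assert back.by_acronym("SSp-bfd2/3").parent_id == onto.by_acronym("SSp-bfd").id


def test_random_ontology_ancestor_paths(rng):
    entries = [StructureEntry(1, "n1", "n1", None)]
    for i in range(2, 31):
        entries.append(StructureEntry(i, f"n{i}", f"n{i}",
                                      int(rng.integers(1, i))))
    onto = StructureOntology(entries)
    for leaf in onto.leaves():
        path = [leaf] + onto.ancestors(leaf)
        assert path[-1] == 1
        assert len(set(path)) == len(path)


# -- compartments ----------------------------------------------------------

def test_classify_compartment_subtrees():
    onto = _toy_ontology()
    assert classify_compartment(onto.by_acronym("cc").id, onto) == "fiber_tract"
    assert classify_compartment(onto.by_acronym("CP").id, onto) == "striatum"
    assert classify_compartment(onto.by_acronym("SSp-bfd4").id, onto) == "gray_matter"
    assert classify_compartment(0, onto) == "outside"
    assert classify_compartment(1, onto) == "other"   # root above all subtrees
    with pytest.raises(OntologyError):
        classify_compartment(999, onto)


def test_classify_compartment_constant_below_subtree_root():
    onto = _toy_ontology()
    bfd = onto.by_acronym("SSp-bfd").id
    for sid in onto.subtree(bfd):
        assert classify_compartment(sid, onto) == "gray_matter"


# -- aggregation -----------------------------------------------------------

def _table(rows):
    recs = [{"structure_id": sid, "acronym": acr, "neurite_type": nt,
             "length_um": float(L), "n_points": int(L)}
            for sid, acr, nt, L in rows]
    return RegionLengthTable.from_records(recs, {"step": 1.0})


def test_aggregate_layers_to_parent():
    onto = _toy_ontology()
    t = _table([(6, "SSp-bfd1", "axon", 10), (7, "SSp-bfd2/3", "axon", 20),
                (8, "SSp-bfd4", "axon", 5)])
    agg = aggregate_lengths(t, onto, ["SSp-bfd"])
    assert agg.length_of("SSp-bfd", "axon") == 35


def test_aggregate_to_root_reproduces_grand_total():
    onto = _toy_ontology()
    t = _table([(6, "SSp-bfd1", "axon", 10), (9, "cc", "axon", 4),
                (10, "CP", "axon", 6)])
    agg = aggregate_lengths(t, onto, ["root"])
    assert agg.length_of("root", "axon") == 20


def test_aggregate_overlapping_targets_rejected():
    onto = _toy_ontology()
    t = _table([(6, "SSp-bfd1", "axon", 10)])
    with pytest.raises(ValueError):
        aggregate_lengths(t, onto, ["SSp-bfd", "Isocortex"])


def test_aggregate_keeps_unassigned_and_conserves():
    onto = _toy_ontology()
    t = _table([(6, "SSp-bfd1", "axon", 10), (0, "unassigned", "axon", 3),
                (10, "CP", "axon", 6)])
    agg = aggregate_lengths(t, onto, ["SSp-bfd"])
    assert agg.df.length_um.sum() == t.df.length_um.sum()
    assert agg.length_of(0, "axon") == 3


def test_aggregate_matches_brute_force_descendant_scan(rng):
    entries = [StructureEntry(1, "n1", "n1", None)]
    for i in range(2, 80):
        entries.append(StructureEntry(i, f"n{i}", f"n{i}",
                                      int(rng.integers(1, i))))
    onto = StructureOntology(entries)
    present = rng.choice(np.arange(1, 80), size=30, replace=False)
    t = _table([(int(s), f"n{s}", "axon", float(rng.integers(1, 50)))
                for s in present])
    targets = [int(c) for c in onto.children(1)]
    agg = aggregate_lengths(t, onto, targets)
    for tgt in targets:
        desc = onto.subtree(tgt)
        brute = sum(r.length_um for r in t.df.itertuples()
                    if r.structure_id in desc)
        assert agg.length_of(tgt, "axon") == pytest.approx(brute)


# -- barrel columns --------------------------------------------------------

def test_barrel_column_lookup(atlas, atlas_spec):
    _, _, bmap = atlas
    centers = atlas_spec.barrels.centers()
    cap, cml = centers["D3"]
    rep = barrel_column_at((cap, 500.0, cml), bmap)
    assert rep.kind == "column" and rep.columns == ("D3",)
    # septum between two arc-adjacent columns
    (a_ap, a_ml), (b_ap, b_ml) = centers["C1"], centers["C2"]
    rep = barrel_column_at(((a_ap + b_ap) / 2, 500.0, (a_ml + b_ml) / 2), bmap)
    assert rep.kind == "septum"
    assert set(rep.columns) == {"C1", "C2"}
    # far away
    rep = barrel_column_at((5900.0, 1900.0, 5900.0), bmap)
    assert rep.kind == "outside"


def test_barrel_map_csv_round_trip(tmp_path, atlas):
    from axonatlas.atlas import save_barrel_map
    _, _, bmap = atlas
    save_barrel_map(bmap, tmp_path / "b.nrrd", tmp_path / "names.csv")
    back = load_barrel_map(tmp_path / "b.nrrd", tmp_path / "names.csv")
    assert back.names == bmap.names
    assert np.array_equal(back.volume.labels, bmap.volume.labels)
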