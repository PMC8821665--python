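"""Region length tables, totals, compartment splits, soma, cohort stats."""

import numpy as np
import pandas as pd
import pytest

from axonatlas.atlas import ParcellationVolume, StructureEntry, StructureOntology
from axonatlas.pipeline import quantify_neuron
from axonatlas.quantify import (
    RegionLengthTable,
    cohort_summary,
    compartment_split,
    locate_soma,
    quantify_lengths,
    round_mm,
    total_length,
)
from axonatlas.reconstruction import NeuronReconstruction, ReconNode
from axonatlas.resampling import ResampledCloud


def _two_region_setup():
    onto = StructureOntology([
        StructureEntry(1, "root", "root", None),
        StructureEntry(2, "A", "region A", 1),
        StructureEntry(3, "B", "region B", 1),
    ])
    labels = np.zeros((40, 4, 4), dtype=np.int32)
    labels[:20] = 2
    labels[20:] = 3                       # plane boundary at x = 500 um
    vol = ParcellationVolume(labels, (25.0, 25.0, 25.0))
    return onto, vol


def _cloud(points, types, step=1.0):
    points = np.asarray(points, float)
    return ResampledCloud(points, np.asarray(types, int),
                          np.zeros(len(points), int), step, n_paths=1)


def test_counting_rule_single_structure():
    onto, vol = _two_region_setup()
    pts = np.tile([100.0, 50.0, 50.0], (35, 1))
    table = quantify_lengths(_cloud(pts, [2] * 35), vol, onto)
    assert len(table.df) == 1
    assert table.df.iloc[0].length_um == 35.0
    assert table.df.iloc[0].acronym == "A"


def test_counting_identity_is_exact(rng):
    onto, vol = _two_region_setup()
    pts = rng.uniform(-100, 1100, (5000, 3))   # some points off the grid
    types = rng.choice([2, 3], 5000)
    cloud = _cloud(pts, types, step=1.0)
    table = quantify_lengths(cloud, vol, onto)
    assert table.df.length_um.sum() == len(cloud) * cloud.step
    assert table.df.n_points.sum() == len(cloud)


def test_plane_crossing_split():
    onto, vol = _two_region_setup()
    # straight 1000 um segment along x crossing the A|B plane at midpoint
    from axonatlas.resampling import PolylinePath, resample_path
    p = PolylinePath(np.array([[0, 50, 50], [1000, 50, 50]], float), 2, (1, 2))
    pts = resample_path(p, 1.0)
    table = quantify_lengths(_cloud(pts, [2] * len(pts)), vol, onto)
    a = table.length_of("A", "axon")
    b = table.length_of("B", "axon")
    assert a + b == 1000.0
    assert abs(a - 500.0) <= 1.0 and abs(b - 500.0) <= 1.0


def test_soma_and_unknown_types_excluded_by_default():
    onto, vol = _two_region_setup()
    pts = np.tile([100.0, 50.0, 50.0], (10, 1))
    types = [1, 1, 2, 2, 2, 3, 4, 7, 7, 7]    # 2 soma, 3 axon, 2 dendrite, 3 unknown
    table = quantify_lengths(_cloud(pts, types), vol, onto)
    assert total_length(table, "axon") == 3.0
    assert total_length(table, "dendrite") == 2.0
    assert table.metadata["n_points_excluded"] == 5
    with_soma = quantify_lengths(_cloud(pts, types), vol, onto, include_soma=True)
    assert total_length(with_soma, "soma") == 2.0


def test_unassigned_points_kept_in_named_row():
    onto, vol = _two_region_setup()
    pts = np.array([[100, 50, 50], [-500, 0, 0]], float)
    table = quantify_lengths(_cloud(pts, [2, 2]), vol, onto)
    assert table.length_of(0, "axon") == 1.0
    assert "unassigned" in set(table.df.acronym)


def test_table_permutation_invariance(rng):
    onto, vol = _two_region_setup()
    pts = rng.uniform(0, 1000, (800, 3))
    types = rng.choice([2, 3], 800)
    cloud = _cloud(pts, types)
    perm = rng.permutation(800)
    shuffled = _cloud(pts[perm], types[perm])
    t1 = quantify_lengths(cloud, vol, onto)
    t2 = quantify_lengths(shuffled, vol, onto)
    pd.testing.assert_frame_equal(t1.df, t2.df)


def test_total_length_empty_table():
    t = RegionLengthTable.from_records([], {"step": 1.0})
    assert total_length(t, "axon") == 0.0


def test_compartment_split_conserves(atlas, small_cohort):
    vol, onto, _ = atlas
    recon, truth = small_cohort[0]
    res = quantify_neuron(recon, vol, onto)
    split = compartment_split(res.table, onto)
    assert sum(split.values()) == pytest.approx(total_length(res.table, "axon"))
    assert split["gray_matter"] > 0


def test_compartment_split_against_truth(atlas, small_cohort):
    vol, onto, _ = atlas
    for recon, truth in small_cohort:
        res = quantify_neuron(recon, vol, onto)
        split = compartment_split(res.table, onto)
        truth_fiber = truth.aggregated(onto, ["fiber tracts"])["fiber tracts"]
        truth_str = truth.aggregated(onto, ["STRd"])["STRd"]
        assert split["fiber_tract"] == pytest.approx(truth_fiber, abs=200.0)
        assert split["striatum"] == pytest.approx(truth_str, abs=200.0)


def test_locate_soma_in_column_septum_outside(atlas, atlas_spec):
    vol, onto, bmap = atlas
    centers = atlas_spec.barrels.centers()

    def neuron_at(pos):
        return NeuronReconstruction(
            "s", [ReconNode(1, *pos, 6.0, 1, -1)], "micron")

    cap, cml = centers["C2"]
    assert str(locate_soma(neuron_at((cap, 200, cml)), bmap)) == "C2"
    (a_ap, a_ml), (b_ap, b_ml) = centers["D2"], centers["D3"]
    rep = locate_soma(neuron_at(((a_ap + b_ap) / 2, 200, (a_ml + b_ml) / 2)), bmap)
    assert rep.kind == "septum" and set(rep.columns) == {"D2", "D3"}
    far = locate_soma(neuron_at((5900, 1900, 5900)), bmap)
    assert far.kind == "outside"


def test_locate_soma_requires_soma_or_unique_root():
    rec = NeuronReconstruction(
        "two-roots",
        [ReconNode(1, 0, 0, 0, 1, 2, -1), ReconNode(2, 5, 0, 0, 1, 2, -1)],
        "micron")
    with pytest.raises(ValueError):
        locate_soma(rec, barrel_map=None)


# -- cohort statistics -----------------------------------------------------

def _table_for(name, rows):
    recs = [{"structure_id": sid, "acronym": acr, "neurite_type": "axon",
             "length_um": float(L), "n_points": int(L)}
            for sid, acr, L in rows]
    return RegionLengthTable.from_records(recs, {"step": 1.0, "neuron": name})


def test_cohort_single_neuron():
    s = cohort_summary([_table_for("a", [(2, "A", 10)])])
    assert s.df.iloc[0].mean_um == 10
    assert s.df.iloc[0].sd_um == 0
    assert s.df.iloc[0].n == 1


def test_cohort_zero_imputation_for_absent_regions():
    s = cohort_summary([_table_for("a", [(2, "A", 10)]),
                        _table_for("b", [(3, "B", 4)])])
    row = s.df[s.df.acronym == "A"].iloc[0]
    assert row.mean_um == 5.0
    assert row.n == 2
    assert row.sd_um == pytest.approx(np.std([10, 0], ddof=1))


def test_cohort_sorted_descending_with_acronym_tiebreak():
    s = cohort_summary([_table_for("a", [(2, "B", 7), (3, "A", 7), (4, "C", 9)])])
    assert list(s.df.acronym) == ["C", "A", "B"]


def test_cohort_removing_region_shifts_mean_exactly():
    tables = [_table_for("a", [(2, "A", 12)]), _table_for("b", [(2, "A", 6)]),
              _table_for("c", [(2, "A", 3)])]
    m_with = cohort_summary(tables).df.iloc[0].mean_um
    tables2 = tables[:2] + [_table_for("c", [(3, "B", 1)])]
    s2 = cohort_summary(tables2)
    m_without = s2.df[s2.df.acronym == "A"].iloc[0].mean_um
    assert m_with - m_without == pytest.approx(3 / 3)


def test_cohort_mixed_atlas_versions_rejected():
    t1 = _table_for("a", [(2, "A", 1)])
    t2 = _table_for("b", [(2, "A", 1)])
    t1.metadata["atlas_version"] = "v3"
    t2.metadata["atlas_version"] = "v2"
    with pytest.raises(ValueError):
        cohort_summary([t1, t2])


def test_round_mm_half_to_even():
    assert round_mm(70_650.0) == 70.6
    assert round_mm(70_750.0) == 70.8
    assert round_mm(70_700.0) == 70.7


def test_table_csv_round_trip(tmp_path):
    t = _table_for("a", [(2, "A", 10), (3, "B", 4)])
    t.to_csv(tmp_path / "t.csv")
    back = RegionLengthTable.from_csv(tmp_path / "t.csv")
    assert back.metadata["neuron"] == "a"
    pd.testing.assert_frame_equal(back.df, t.df, check_dtype=False)
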