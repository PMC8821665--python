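# axonatlas

Whole-brain, per-brain-region quantification of single-neuron axonal and
dendritic cable for reconstructions registered to the Allen Mouse Brain
Common Coordinate Framework (CCFv3).

## The problem

Tracing one GFP-labeled cortical neuron through a whole-brain two-photon
tomography volume yields an (E)SWC file: thousands of rows of
`id type x y z radius parent`, in anisotropic imaging-voxel coordinates
(typically 0.8 × 0.8 × 5 µm). The anatomical questions — *how many
millimetres of axon does this layer 2/3 barrel-cortex neuron place in SSs,
in MOp, in the corpus callosum, in the caudoputamen? which barrel column
holds the soma?* — require converting that tree into physical units,
registering it to a reference parcellation, and counting cable per brain
structure. axonatlas implements that pipeline for anatomists working with
single-cell reconstructions, together with a synthetic-data generator that
provides atlases and neurons with analytically known per-region cable so
every stage is testable without gigabytes of imaging data.

## The measure

For a reconstruction with node coordinates **p**ᵢ (voxel units) and imaging
voxel (vₓ, v_y, v_z):

1. **Physical conversion** — **x**ᵢ = **p**ᵢ ⊙ (vₓ, v_y, v_z) µm.
2. **Path decomposition** — the tree splits into unbranched polyline paths;
   paths break at roots, branch points, and neurite-type changes.
3. **Arclength resampling** — each path of length L is replaced by
   round(L/s) points at arclengths (k + ½)·s, with s = 1 µm (midpoint rule;
   unbiased, per-path error ≤ s/2).
4. **Structure assignment** — a point at **x** belongs to the parcellation
   voxel ⌊(**x** − o)/v⌋ (half-open convention, 25 µm CCF voxels); label 0
   is "unassigned".
5. **Length table** — length per (structure, neurite type) = point count × s,
   so Σ lengths = N·s holds exactly by construction.

Registration transforms (affine + dense displacement field, computed
externally, e.g. by Elastix) are consumed, not estimated: either the
resampled points are mapped atlas-ward through the inverse chain (default),
or the parcellation and barrel-column mask are warped sample-ward with
nearest-neighbour labels — the two routes agree up to nearest-neighbour
ties. On top of the tables sit hierarchy aggregation (layers → region →
compartment), gray-matter / white-matter / striatum splits, barrel-column
soma localization (with septal reporting between columns), cohort
mean ± SD statistics with zero-imputation for absent regions, and the
standard figure views (serial coronal slabs, horizontal projection, the
30°-rotated tangential barrel-field view, descending per-region bar
charts).

## Worked example

Generate a synthetic brain and one neuron, then quantify it:

```python
import axonatlas as ax
from axonatlas.synthetic import default_atlas_spec, make_atlas, make_cohort

spec = default_atlas_spec()                       # 6×2×6 mm, 25 µm voxels
vol, onto, bmap = make_atlas(spec)                # parcellation, ontology, barrels
recon, truth = make_cohort(n=1, seed=7, atlas_spec=spec)[0]

res = ax.quantify_neuron(recon, vol, onto, barrel_map=bmap)
print("axon total  : %.1f mm" % (ax.total_length(res.table, "axon") / 1000))
print("dendrite    : %.1f mm" % (ax.total_length(res.table, "dendrite") / 1000))
print("soma        :", res.soma)

agg = ax.aggregate_lengths(res.table, onto,
                           ["SSp-bfd", "SSs", "MOp", "MOs", "SSp-un", "SSp-ul",
                            "SSp-tr", "VISa", "VISrl", "fiber tracts", "STRd"])
for r in (agg.rows_for("axon")
             .sort_values("length_um", ascending=False).head(5).itertuples()):
    print(f"  {r.acronym:<14} {r.length_um/1000:6.2f} mm axon")
```

prints

```
axon total  : 75.5 mm
dendrite    : 6.9 mm
soma        : C1
  SSp-bfd         45.77 mm axon
  SSp-tr          10.80 mm axon
  SSp-ul           8.46 mm axon
  STRd             5.78 mm axon
  fiber tracts     4.65 mm axon
```

— a 75.5 mm axonal arbor, its soma in barrel column C1, most cable in the
home barrel field with long-range branches into trunk and upper-limb
somatosensory cortex, the dorsal striatum and the white matter. The neuron's
per-region cable is known analytically (`truth`), and the recovered values
agree within the midpoint-resampling bound.

The same operations are available from the shell:

```bash
axonatlas simulate --preset cohort10 --seed 7 --out fixtures/
axonatlas quantify --eswc fixtures/SYN000.eswc \
    --annotation fixtures/annotation.nrrd --ontology fixtures/ontology.json \
    --barrels fixtures/barrels.nrrd --barrel-names fixtures/barrel_names.csv \
    --voxel 0.8,0.8,5 --step 1 --out out/
axonatlas cohort --tables out/ --out summary.csv
axonatlas render --eswc fixtures/SYN000.eswc --view tangential --rotation 30 \
    --sections 5 --span 1500 --out views/
```

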