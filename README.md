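# mitomorph

Morphometry of mitochondrial networks in fluorescence and volume
electron microscopy, built for studies like mitochondrial phenotyping of
cumulus cells: how fragmented or fused is the network, how long are the
organelles, and how do those distributions shift under a perturbation
such as rotenone.

The package implements two measurement chains plus a statistical
comparison, with synthetic generators that carry exact ground truth:

* **2D confocal-style.** A calibrated grayscale image (TMRM-like
  staining) is binarized, skeletonized, and each connected network
  component decomposed into *ends* (degree-1 skeleton nodes),
  *junctions* (merged degree-≥3 nodes) and *tubules* (maximal
  junction-free paths). Components with more than 7 elements are
  *clustered*, with a junction *branched*, otherwise *isolated*. Because
  a projection hides which tubules form one organelle, lengths are
  estimated probabilistically: at each junction of degree *d* the
  incident stubs are pairwise matched in all 1, 1, 2, 4, 10, 26, …
  (involution numbers) ways; each matching combination is one reading of
  the cluster, and all readings are averaged into a whole-cell length
  distribution *P(ℓ)*. Network fusion is summarized by the connectivity
  *C = J / (J + E)* over pooled junction and end counts.
* **3D FIB-SEM-style.** Anisotropic label volumes (e.g. 5 nm × 5 nm ×
  10 nm voxels) are component-labeled (26-connectivity); fused clusters
  are split into individual mitochondria by watershed on the negated
  anisotropy-aware distance transform seeded at its h-maxima; every
  object gets an exact voxel volume, minimum/maximum Feret diameters
  from its physical convex hull, and an element-based phenotype.
* **Condition comparison.** Length distributions are compared by the 1D
  Earth-mover distance, EMD = Σ |CDF₁ − CDF₂| · Δℓ (µm), with
  significance from a cell-level permutation test.

See `docs/methods.md` for the full model description and the design
decisions.

## Worked example

Simulate a TMRM-like scene, analyze it, and read the network summary:

```sh
mitomorph simulate2d --n-objects 12 --seed 3 --out scene.tif
mitomorph analyze2d scene.tif --out results/
```

Typical output (numbers vary with the seed):

```json
{
 "cell_id": "cell",
 "threshold_used": 0.2813,
 "n_components": 12,
 "cell_phenotype": "intermediate",
 "median_length_um": 1.875,
 "mean_elements_per_cluster": 4.75,
 "connectivity": 0.2121,
 "area_fractions": {"isolated": 0.71, "branched": 0.29, "clustered": 0.0},
 "fraction_length_gt_2um": 0.5,
 "isolated_gt2um_area_fraction": 0.95
}
```

Reading it: the scene contains 12 network components averaging 4.75
elements each; 21 % of the pooled end/junction count are junctions
(mildly interconnected); half of the probabilistic length mass lies
above 2 µm, and the cell's median organelle length of 1.9 µm classifies
it as having intermediate mitochondria. Per-component element counts and
the binned length distribution are written as CSV next to the JSON
summary.

The same in Python:

```python
import mitomorph as mm

mask, truth = mm.generate_tubule_2d(4.0, radius_um=0.15)
graph = mm.skeletonize(mask, spacing_um=0.1)[0]
summary = mm.decompose_elements(graph)
print(summary.n_ends, summary.n_junctions, summary.n_tubules)  # 2 0 1
print(mm.classify_component(summary))                          # isolated
```

For 3D volumes: `mitomorph simulate3d --specs specs.json --voxel-size
0.005,0.005,0.010 --fuse --out vol.tif` followed by `mitomorph analyze3d
vol.tif --voxel-size 0.005,0.005,0.010 --out results/` produces a
per-object CSV (volume, Feret min/max, elements, phenotype) and a
population report (phenotype abundance and volume coverage). `mitomorph
compare --a ctrl/ --b treated/` runs the EMD permutation test on two
directories of per-cell distribution CSVs.

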