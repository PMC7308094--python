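# conemosaic

Spatial analysis of cone photoreceptor mosaics in flat-mounted retinas,
built around the question of how *true S-cones* (cones expressing only the
short-wavelength opsin, S⁺M⁻) are distributed across the mouse retina and
how they wire to S-cone bipolar cells (SCBCs, type 9).

Mouse cones express S- and M-opsin in opposing dorso-ventral gradients, so
most cones are "mixed" (M⁺S⁺); the minority classes are true S (S⁺M⁻) and
M-only (M⁺S⁻).  The package provides the full analysis chain used to
characterize these populations:

* **detection** — cone outer-segment counting in single-opsin fluorescence
  channels: background subtraction, fractional thresholding (15.7% of the
  channel maximum by default), despeckling, marker-controlled watershed
  splitting of touching cones, size/shape filtering, sub-pixel centroids;
* **cone_typing** — mutual-nearest-neighbour matching of S- and M-channel
  detections into MIXED / TRUE_S / M_ONLY cones, and regional composition
  over standard 135 × 135 μm sampling squares;
* **topography** — isodensity maps (83.3 μm bins, 10-step color scales up
  to 17,300 cones/mm²) and per-quadrant (DT/DN/VT/VN) composition profiles
  versus distance from the optic-nerve head;
* **mosaic_stats** — the clustering analysis for 1 mm circular samples on
  the DT–VN axis: nearest-neighbour and Voronoi-domain regularity indices
  (NNRI = mean/SD of nearest-neighbour distances, VDRI = mean/SD of
  Voronoi cell areas), the S-cone neighbour ratio (SCNR: per cone, the
  proportion of true S-cones among all cones within a density-scaled
  search radius r = 3·√(A/(√2·π·N))), "shuffled" (label-permutation) and
  "distributed" (mutual-repulsion) null ensembles, Z-score normalization
  and one-tailed t-tests;
* **connectivity** — convergence/divergence of true-S-pedicle ↔ SCBC
  contacts from branch-level contact tables (blind endings dropped,
  same-branch duplicates collapsed), density ratios, and cluster-to-SCBC
  convergence summaries;
* **synthetic_retina** — a generator of hard-core cone mosaics at mouse
  densities with strain-specific opsin gradients, optional clonal
  clustering of true S-cones, SCBC mosaics, distance-limited wiring, and
  two-channel image rendering with ground truth, so every stage can be
  validated against known truth.

## Worked example

```python
import conemosaic as cm

spec = cm.MosaicSpec(retina_radius_um=2000, density_profile=12_000, seed=42)
points = cm.generate_positions(spec)
mosaic = cm.assign_types(points, cm.pigmented(), seed=43,
                         region=cm.Disk(0, 0, 2000))

print(cm.regional_composition(mosaic)[["pct_MIXED", "pct_TRUE_S", "pct_M_ONLY"]].round(1))
for which in ("DT", "VN"):
    s = cm.extract_sample(mosaic, which)
    ens = cm.null_ensemble(s, "shuffled", n_sims=200, seed=44)
    z = ens.z_scores
    print(f"{which}: N={s.n_total} trueS={s.n_true_s} "
          f"z(NNRI)={z['nnri']:+.2f} z(SCNR)={z['scnr_true_s']:+.2f}")
```

prints

```
         pct_MIXED  pct_TRUE_S  pct_M_ONLY
region
dorsal         1.2         1.6        97.2
medial        49.6         4.3        46.1
ventral       67.7        32.3         0.0
DT: N=9470 trueS=116 z(NNRI)=-0.11 z(SCNR)=+0.05
VN: N=9357 trueS=1872 z(NNRI)=-6.43 z(SCNR)=+6.27
```

The regional table reproduces the expected composition of a pigmented-
strain retina: a dorsal region almost entirely M-only with ~1–2% true S,
and a ventral region where true S-cones are ~30% of the local population.
The Z-scores compare each 1 mm sample against 200 label-shuffled versions
of itself: the sparse dorsotemporal (DT) true-S mosaic is statistically
indistinguishable from random labelling (|z| ≪ 2.5), while the dense
ventronasal (VN) population shows an elevated S-cone neighbour ratio and
depressed regularity — the signature of spatial aggregation, here produced
by the steep ventral gradient of the true-S fraction across the sample.

A command-line interface mirrors the library
(`conemosaic simulate|detect|classify|composition|topography|mosaic-stats|connectivity|run`);
`conemosaic run --config cfg.json` executes the whole pipeline and writes
CSV tables plus a JSON report.

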