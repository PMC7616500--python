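# stitchkit

A toolkit for assembling multi-capture-area Visium experiments and the
companion statistics around them:

- **`stitchkit.stitcher`** — map spot coordinates of several capture areas
  into one reconstructed frame via 6-coefficient planar affine transforms
  (SVG/TrakEM2 `matrix(a,b,c,d,e,f)` convention), composite the section
  images under a centre-priority overlap rule, and merge count matrices by
  outer join on genes while keeping every spot.
- **`stitchkit.visium_io`** — readers/writers for Space Ranger spatial
  outputs (tissue positions CSV, scalefactors JSON, MTX triplet, TIFF
  image), affine-matrix files (canonical JSON plus a TrakEM2 XML subset),
  and the stitched h5ad-dialect container with a TIFF image sidecar.
- **`stitchkit.doublet_consolidation`** — replace per-cell doublet scores by
  their fine-cluster median, test cluster medians right-tailed against a
  median/MAD normal null (MAD from above-median values, scale 1.4826),
  Benjamini–Hochberg adjust, and flag doublet clusters.
- **`stitchkit.colocalization`** — pixel-level co-occurrence probability for
  binary RNA-ISH expression masks (dual-positive pixels over
  reference-positive pixels; same-pixel only, asymmetric).
- **`stitchkit.atlas_stats`** — scRNA-seq QC filters with strict boundary
  semantics, post-conception age from crown-rump length, odds-ratio
  selection of axis-biased genes (30-fold / 3-fold cutoffs), and
  NMF-microenvironment membership (fraction > 0.2 rule).
- **`stitchkit.fixtures`** — seeded generators of synthetic capture areas,
  overlapping section sets with known ground-truth transforms, doublet-score
  tables and mask pairs, so everything is testable without data downloads.

## CLI

```bash
stitchkit simulate --kind sections --seed 3 --out fixtures/
stitchkit stitch --sections fixtures/S0,fixtures/S1,fixtures/S2 \
    --affines fixtures/affines.json --centre S1 --out stitched.h5ad
stitchkit doublets --scores scores.csv --q 0.05 --floor 0.1 --out flagged.csv
stitchkit coloc --target target_mask.tif --reference reference_mask.tif
stitchkit qc --counts matrix_dir/ --out qc.json
stitchkit age --crl 15.1
stitchkit bias-genes --summaries summaries.csv --axis pd
stitchkit microenv --abundance abundance.csv --n-envs 4 --seed 0
```

Coordinates are full-resolution image pixels, row/col order, 0-based
(Space Ranger convention); affine transforms act on `(x, y) = (pxl_col,
pxl_row)`. Affine files must declare the image resolution the matrices act
on (`"resolution": "fullres"`).

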