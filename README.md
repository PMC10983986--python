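# lsgi — local spatial gradient inference for spatial transcriptomics

Tissue niches impose gradated gene expression on the cells inside them:
oxygen, signaling cues and cell-type composition all change smoothly over
tens to hundreds of micrometers, and with them the activity of whole
transcriptional programs.  `lsgi` detects these **spatial transcriptomic
gradients** on a slide — where they exist, which direction they point, and
which interpretable NMF program each belongs to — without any prior
pathological annotation.  It is aimed at people analysing 10x Visium or
similar spot-level data who want more than static spatial domains: a
vector field of local phenotype change.

## The method

1. **Programs.** The spots-by-genes count matrix is depth-normalized
   (`log(1 + count/depth · 10⁴)`) and factorized with non-negative matrix
   factorization into k programs (rank chosen by Wold-style
   cross-validation over k = 6…10): spot loadings `W` (per-spot program
   activity) and gene loadings `H` (per-gene attribution).  Any external
   phenotype quantification can be plugged in instead of the built-in NMF.
2. **Windows.** Spots are clustered into `P = round(N/S)` balanced spatial
   groups (default S = 5); each group's centroid is a *grid point* and its
   window is the Q = 25 spots nearest to it.  Every spot lies in
   Q/S = 5 windows on average, so windows tile the slide with overlap.
3. **Local fits.** In every window, each program's loadings are regressed
   on the coordinates, `F ~ X + Y` (OLS).  The coefficients
   `(β_X, β_Y)` point toward increasing program activity; `R²` measures
   how much of the local variation space explains.  A fit with `R² ≥ 0.6`
   is a gradient; a program is retained only if it passes in at least 5 %
   of grid points.
4. **Downstream.** Gradient-to-gradient proximity
   `D(A,B) = mean over A-grids of the distance to the nearest B-grid`
   (asymmetric by construction); per-window tumor ratios and per-program
   mean tumor ratios grouped into three tumor-ratio clusters
   (normal-leaning / boundary / tumor-leaning); cross-sample
   **meta-programs** clustered by top-50-gene overlap with a growing
   50-gene signature; study / tumor-type specificity by delta-Shannon
   entropy (real composition entropy minus its label-shuffled mean); and
   hypergeometric gene-set annotation with BH-adjusted p-values and a
   cross-program specificity score.

## Worked example

`lsgi` ships a synthetic-slide generator with planted ground truth: a hex
lattice of ~2000 spots, three planted gradient disks (in-window R² ≈ 0.8)
among five programs, and a tumor disk over the first gradient region.

```python
from lsgi import RunConfig, run_single_sample
from lsgi.synthetic import make_default_slide

ds, truth, W_true, _ = make_default_slide(seed=1)
result = run_single_sample(ds, RunConfig(seed=1), outdir="results/demo",
                           loadings=W_true)
print("retained:", result.gradient_map.retained)
print(result.tumor.program_mean.round(3))
print(result.proximity.distance.round(2))
```

prints

```
retained: ['NMF_1', 'NMF_2', 'NMF_3']
program
NMF_1    0.935
NMF_2    0.002
NMF_3    0.000
Name: mean_tumor_ratio, dtype: float64
       NMF_1  NMF_2  NMF_3
NMF_1   0.00   9.97  13.33
NMF_2  11.09   0.00  12.19
NMF_3  13.35  12.95   0.00
```

Exactly the three planted gradient programs are retained (the two pure-noise
programs are filtered out); 119 of the 2000 window-program fits pass the
R² gate.  The program planted inside the tumor disk has a mean window tumor
ratio of 0.94 (tumor-ratio cluster 3, tumor-leaning) while the others sit in
normal tissue; the proximity matrix gives the mean distance (in lattice
pitch units) from each gradient's grid points to the nearest grid point of
every other program.  Passing fits, directions and R² land in
`results/demo/gradient_table.tsv` and `arrow_field.tsv`.

The same analysis runs from the shell:

```
lsgi simulate --n-spots 2000 --seed 1 --out slide/
lsgi run --matrix slide/matrix.mtx --genes slide/genes.tsv \
         --barcodes slide/barcodes.tsv --positions slide/positions.tsv \
         --tumor-labels slide/tumor_labels.tsv --k 5 --seed 1 --out results/
lsgi meta catalogA.tsv catalogB.tsv --out meta/
lsgi annotate --catalog catalogA.tsv --gmt hallmark.gmt --out anno/
```

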