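# lgcw — local gray-scale clustering watershed segmentation

`lgcw` segments 2-D grayscale images — designed around short-axis cardiac
MR slices — that suffer from smooth intensity inhomogeneity ("shading" from
coil sensitivity and blood-flow artifacts), noise, adherent structures, and
unclear or broken tissue boundaries. It is a library first (with a thin
`lgcw` command-line wrapper) for image-analysis researchers who need a
classical, fully inspectable alternative to learned segmenters, together
with the standard agreement metrics and the efficacy statistics used in
two-arm clinical comparisons.

## The model

Stage 1 is a **local intensity-clustering level set with joint bias-field
estimation**. The image `P` is modeled around each pixel `n` as
`P(m) ≈ e(n)·t_i` for pixels `m` of cluster `i`, with `e` a smooth positive
bias field and `t_1, t_2` global cluster intensities, weighted by a
truncated Gaussian window `K`:

    E(φ, e, t) = ΣₙΣₘ K(n−m) [ (P(m) − e(n)t₁)² M₁(m) + (P(m) − e(n)t₂)² M₂(m) ]

with memberships `M₁ = 1 − H_ε(φ)` (interior), `M₂ = H_ε(φ)` read off a
smoothed Heaviside of the level-set function `φ`. The energy is minimized
by alternating closed-form updates of `(t₁, t₂)` and `e` with
backtracking gradient descent on `φ` (plus standard contour-length and
distance-regularization terms), so the total energy is non-increasing by
construction.

Stage 2 **binarizes** the converged interior, computes the exact
**Euclidean distance transform**, suppresses shallow minima of the negated
distance map (**h-minima**, depth 2 px), and floods the relief with a
**marker-controlled watershed** (strict priority queue, FIFO ties,
4-connectivity). Watershed lines split structures that intensity alone
cannot separate and give every region a closed contour.

Agreement between automatic and manual segmentations is scored with the
symmetric mean absolute contour distance (MAD), the symmetric Hausdorff
distance (max-MAD), and the Dice overlap `2|Z∩D|/(|Z|+|D|)`. Clinical
efficacy is summarized by the total effective rate
`100·(markedly effective + effective)/total` with chi-square / Welch-t /
rank-sum group comparisons.

A seeded synthetic phantom (bright blood pool in a darker myocardial ring,
multiplicative bias field, Gaussian noise, optional boundary gaps and
adherent discs) provides ground truth for all of this.

## Worked example

```sh
python examples/segment_phantom.py
```

```
iterations:   25
regions:      1
dice:         0.9933
mad_px:       1.58
max_mad_px:   12.00
```

The pipeline recovers the heart (blood pool + myocardial ring) from a slice
corrupted by a 30%-amplitude bias field and 5% noise with Dice 0.993 and a
mean contour error of 1.6 px; the max-MAD is dominated by a single
noise-induced pinhole at the endocardial interface (a Hausdorff-type metric
counts its full depth). `examples/split_adherent_structures.py` shows the
watershed separating an adherent bright disc from the ring (two labels
where clustering alone gives one component),
`examples/bias_field_recovery.py` recovers the applied shading field with
correlation 0.987, and `examples/efficacy_statistics.py` reproduces a
two-arm efficacy comparison (76.47% vs 92.65%, χ² p = 0.009).

The same functionality is available from the shell:

```sh
lgcw phantom --seed 7 --out-image img.png --out-truth truth.png
lgcw segment --input img.png --out labels.png --report report.json
lgcw evaluate --auto labels.png --manual truth.png --out metrics.csv
lgcw stats effic --counts counts.csv
```

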