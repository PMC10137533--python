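# dermcad

A classical (handcrafted-feature) computer-aided diagnosis pipeline for
classifying close-up photographs of pigmented skin lesions as **melanoma**
(positive class, label +1) or **benign nevus** (label −1).  It is aimed at
researchers who want a fully inspectable, deterministic baseline for lesion
classification: every stage — artifact removal, segmentation, texture and
gradient descriptors, boosting — is implemented from its defining formulas
and covered by brute-force oracle tests, with a seeded synthetic lesion
generator so the whole chain runs and is testable without any image
download.

## The method

Given an RGB lesion photograph, the pipeline runs four stages:

1. **Preprocessing.** Grayscale conversion (BT.601 luminance), bilinear
   resize to 150×150, a 5×5 median filter against salt–pepper noise, and
   hair removal: the bottom-hat transform `closing(I, SE) − I` with a
   disk-shaped structuring element lights up thin dark strokes; pixels above
   a threshold are inpainted with the local median of their non-hair
   neighbors.
2. **Segmentation.** Otsu's threshold (maximizing between-class variance
   σ²_B(t) = ω₀ω₁(μ₀−μ₁)²) is applied to the R, G, B planes individually;
   the darker side of each cut is lesion.  The three masks are fused by
   per-pixel majority vote, then cleaned by morphological opening, a binary
   median cascade (7×7 → 5×5 → 3×3), an iterated open–close filter, and a
   size filter that drops components under 5% of the image area.  The lesion
   boundary is traced as the closed 8-connected contour of the largest
   component.
3. **Descriptors.**
   - *LBP*: per-pixel code `Σ_p s(g_p − g_c) 2^p` with `s(x) = 1 for x ≥ 0`,
     over the 8 neighbors of the 3×3 ring → a 256-bin histogram.
   - *N-LBP*: the same code over the 24 neighbors of the 5×5 ring → a sparse
     histogram over 2²⁴ = 16,777,216 codes.
   - *HOG*: central-difference gradients `Gx = I(x+1,y) − I(x−1,y)`,
     `Gy = I(x,y+1) − I(x,y−1)`, magnitude `√(Gx²+Gy²)` and unsigned
     orientation `atan2(Gy, Gx) mod 180°`, binned (9 bins, soft assignment,
     magnitude-weighted) into 8×8-pixel cells and L2-normalized over 2×2-cell
     blocks at stride 1.
   - *CS-HOG*: HOG with 2×2-pixel cells.
4. **Classification and evaluation.** Three models share one ±1 predict
   contract: **Gentle AdaBoost** (weighted-least-squares threshold stumps,
   responses = weighted label means, weight update `w_i ← w_i e^{−y_i f_m(x_i)}`
   renormalized each round, prediction `sign Σ_m f_m(x)`), **kNN** (Euclidean
   majority vote with deterministic tie rules), and an **RBF SVM**
   (`sign(Σ α_i y_i e^{−γ‖x_i−x‖²} + b)`, solved by scikit-learn behind the
   package's contract).  Evaluation uses seeded random over-sampling of the
   minority class, stratified 10-fold cross-validation (over-sampling inside
   the training folds only, so replicas never leak into their own test fold),
   and reports AC, SE, SP, PPV, NPV in percent from the pooled confusion
   matrix.

## Worked example

Generate a 20-image synthetic dataset (10 melanomas, 10 nevi) and
cross-validate the strongest descriptor/classifier pair:

```console
$ dermcad generate --n-melanoma 10 --n-nevus 10 --seed 1 --out-dir demo
wrote 20 samples; manifest: demo/manifest.csv
$ dermcad evaluate --manifest demo/manifest.csv --descriptor nlbp \
    --classifier gab --k 5 --seed 1
pooled  AC=100.0%  SE=100.0%  SP=100.0%  PPV=100.0%  NPV=100.0%
```

The five numbers are pooled over the 5 test folds: accuracy, sensitivity
(fraction of melanomas caught), specificity (fraction of nevi cleared), and
the positive/negative predictive values.  On the synthetic generator's two
texture classes (heterogeneous, ragged-border melanomas vs homogeneous,
smooth nevi) the 24-neighbor texture codes separate the classes completely;
real dermoscopy is far harder — see `docs/methods.md` for what the synthetic
benchmark does and does not demonstrate.

Other entry points: `dermcad preprocess`, `segment`, `extract`, `train`,
`predict`, and `dermcad run` for the full chain with all intermediate
artifacts written under a run directory.

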