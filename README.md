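# ddhkit

Semi-automatic measurement and rule-based diagnosis of **developmental
dysplasia of the hip (DDH)** on anteroposterior pelvic radiographs of
children, for pediatric orthopedists and researchers who want an
expert-like, auditable reading of the film from eight clicked key points.

DDH spans a spectrum from a shallow (dysplastic) acetabulum to complete
dislocation. On the AP pelvic film the diagnosis rests on a small set of
geometric constructs. Given per-side annotations of the **lateral
acetabular edge**, the **top of the triradiate cartilage**, and the
**inner and outer points of the proximal femoral metaphysis**, ddhkit:

1. **Rectifies the clicks onto the bony rim.** A square window (default
   30 px) around each click is Gaussian-filtered, binarized with a
   local-mean adaptive threshold (bone is radiodense, hence bright), and
   the rim is the gradient-validated boundary of the foreground. The click
   snaps to the rim pixel *(a, b)* minimizing the Euclidean distance
   *Ed = √((x−a)² + (y−b)²)*, with a guard distance against capture by
   distant structures.
2. **Draws the reference geometry.** Hilgenreiner's line (H-line) through
   the bilateral triradiate tops; per side, Perkin's line perpendicular to
   it through the lateral acetabular edge; the 45° diagonal line from
   their junction; and the **H-point**, the metaphysis midpoint, usable
   before the femoral head ossifies.
3. **Measures the hip parameters.** The **acetabular index**
   AI = ∠(H-line, roof line from triradiate top to acetabular edge) and
   Wiberg's **lateral center-edge angle**
   LCEA = ∠(vertical through the head center, line from center to the
   edge); both are computed in a frame aligned with the H-line, so they
   are invariant to film rotation and scale. Lacking an ossified head,
   the H-point serves as the (flagged) head-center proxy.
4. **Grades displacement (IHDI 1–4)** from the H-point's position against
   Perkin's line, the diagonal, and the H-line, and
5. **Applies the clinical decision rule.** A hip is dysplastic when its AI
   exceeds the normative mean by more than two standard deviations
   (x̄ + 2s) for the child's nationality, sex, and age stratum;
   non-dysplastic hips split into *normal* vs *other dislocation* by the
   IHDI grade. The shipped criteria table is a **synthetic transcription
   template** — substitute published normative values before any clinical
   use.

A parametric **phantom generator** renders stylized AP-pelvis images with
exact landmark ground truth (known AI, H-point offset, IHDI grade, seeded
noise), so the whole pipeline is testable end to end without clinical
data, and an **evaluation module** provides the usual agreement
statistics: confusion-count rates and two-point ROC AUC, DeLong's paired
AUC test, Bland–Altman limits of agreement, ICC(2,1), and Cohen's linearly
weighted kappa.

## Worked example

Generate a one-study phantom batch and diagnose it:

```sh
ddhkit --seed 5 phantom --batch 1 --out-dir demo
ddhkit diagnose \
    --annotations demo/study_0000.annotations.json \
    --criteria src/ddhkit/data/criteria_synthetic.tsv \
    --image demo/study_0000.png \
    --out demo/report.json
```

prints

```
left   AI  39.26 deg  threshold 31.00 deg  -> ddh (IHDI 4)
right  AI  32.91 deg  threshold 31.00 deg  -> ddh (IHDI 4)
```

Both hips' acetabular indices (39.26° and 32.91°) exceed the 31.00°
threshold (synthetic stratum mean 23° + 2·4°), so both are dysplastic, and
the H-points lie superior to Hilgenreiner's line, the most severe (IHDI 4)
displacement — matching the batch manifest's generated class (`ddh4`).
`demo/report.json` records every intermediate (refined landmarks, AI,
LCEA with head-center provenance, grade, threshold, warnings, input
checksums), so the diagnosis can be re-derived from the report alone.

The same steps are available as library calls (`make_phantom`,
`refine_annotations`, `build_reference_geometry`, `measure_ai`,
`classify_ihdi`, `diagnose_study`, …); see the module docstrings.

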