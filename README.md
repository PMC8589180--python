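# izmap

Quantification of the spatial overlap between deep-capillary-plexus (DCP)
telangiectasia and graded photoreceptor disruption on en-face OCT/OCTA in
macular telangiectasia type 2 (MacTel), including the longitudinal,
chance-normalized predictive value of interdigitation-zone (IZ) loss for
future ellipsoid-zone (EZ) loss.

## Who this is for

Ophthalmic imaging researchers who trace photoreceptor-disruption regions
and vascular lesions on en-face slabs and need a reproducible, tested
pipeline for the quantitative part of that protocol: binarizing vessels,
circumscribing telangiectatic zones, removing superficial-vessel
projection artifacts, decomposing nested traced regions into exclusive
classes and mm² areas, registering longitudinal visits, and running the
cohort statistics. A synthetic-scene generator stands in for patient
scans, so the whole pipeline is testable without any clinical data.

## The model in brief

One eye is a 3 mm × 3 mm en-face field (304 × 304 px). Photoreceptor
disruption is traced as nested combined regions

    A = IZ attenuation + IZ loss + EZ loss,  B = IZ loss + EZ loss,  C = EZ loss,
    C ⊆ B ⊆ A,

and decomposed by subtraction into exclusive classes; areas are pixel
counts × (3/304)² mm². Telangiectasia is circumscribed inside a marked
zone by Phansalkar local thresholding,

    T(x) = μ(x) · (1 + p·e^(−q·μ(x)) + k·(σ(x)/r − 1)),

followed by hole filling; large superficial vessels found by Kapur
max-entropy thresholding are subtracted as projection artifacts. Overlap
of telangiectasia with each class is reported as a percent of the
telangiectasia area.

Longitudinally, the follow-up SCP angiogram is registered to baseline
(affine + B-spline, mean-squared-error metric), the transform is applied
to the photoreceptor masks, new EZ loss = followup \ baseline, and the
predictive values of baseline IZ loss are chance-normalized within the
analysis domain Ω (scan minus baseline EZ loss):

    PPV = |new ∩ IZ| / |IZ ∩ Ω|      rPPV = PPV / prevalence
    NPV = |Ω \ (IZ ∪ new)| / |Ω \ IZ|  rNPV = NPV / (1 − prevalence)

rPPV = rNPV = 1 means no better than chance. Cohort statistics: Spearman
rank correlation with the ordinal severity stage, ICC(2,1) for grader
agreement, and a Gaussian GEE with exchangeable working correlation
(two eyes per patient) with Bonferroni pairwise contrasts.

See `docs/methods.md` for the full account.

## Worked example

```sh
python examples/05_longitudinal_predictive_value.py
```

prints, for one synthetic baseline/follow-up pair:

```
registration mean endpoint error vs known warp: 0.10 px
new EZ loss 0.091 mm^2, recovery 0.019 mm^2
PPV  17.4%   rPPV  16.1  (>1: better than chance)
NPV 99.93%  rNPV 1.010 (~1: chance level)
```

The registration recovers the (known) smooth inter-visit deformation to a
tenth of a pixel; the eye grew 0.091 mm² of new EZ loss, almost all of it
inside the baseline IZ-loss class, so baseline IZ loss predicts new loss
sixteen times better than chance (rPPV) while absence of IZ loss is only
chance-level informative (rNPV ≈ 1). The other examples cover scene
generation, the threshold operators, telangiectasia segmentation, region
decomposition and the cross-sectional cohort statistics; each prints the
numbers it computes and a line on what they mean.

A thin CLI mirrors the pipeline stages for shell use on user-supplied
TIFF/PNG images and JSON polygon ROIs:

```sh
izmap simulate --stage-group advanced --seed 1 --out scene/
izmap segment-telangiectasia --dcp scene/dcp.tif --scp scene/scp.tif \
    --roi roi.json --out tel.tif
izmap longitudinal --baseline-dir visit0/ --followup-dir visit1/ --out pv.csv
```

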