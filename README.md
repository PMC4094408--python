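# mucofract

Quantification of intestinal mucosal trophism from stained histology
sections: four-class colour segmentation of IHC/TUNEL fields,
proliferation (PCNA) and apoptotic indices, one-pixel mucosal-outline
extraction, and box-counting fractal dimension of the mucosal
interface, with the accompanying statistical comparison workflow.

## Who it is for

Fish intestines lack crypts and carry longitudinal mucosal folds
instead of villi, so the classical villus-height/crypt-depth
morphometry of mammalian gut does not apply. This package implements a
quantification strategy suited to that anatomy, for researchers
assessing gut trophic state under dietary or toxicological treatments:

* **Cell kinetics** — on DAB/haematoxylin-stained sections, every pixel
  is classified to the nearest of four operator-anchored reference
  colours (positive nuclei, negative nuclei, cytoplasm, background),
  with the lamina propria excluded via a mask. The indices are

  ```
  PCNA index      = 100 · %area_pos / (%area_pos + %area_neg)
  apoptotic index = 100 · n_apo / (n_neg + n_apo)
  n_neg           = field_area · (%area_neg / 100) / mean_nucleus_area
  ```

  Apoptotic (TUNEL) events are counted from operator annotation points,
  because TUNEL is prone to nonspecific cytoplasmic signal.

* **Mucosal architecture** — the complexity of the fold pattern is
  summarised by the box-counting fractal dimension D of the one-pixel
  tissue/lumen interface: D is the OLS slope of ln N(s) versus
  ln(1/s), where N(s) counts occupied boxes of edge s over the ladder
  2, 3, 4, 6, 8, 12, 16, 32, 64, 128, 256, 512, 1024, 2048 px. A
  smooth curve gives D = 1; increasingly convoluted folding pushes D
  towards 2.

* **Statistics** — each response variable passes a Shapiro–Wilk gate:
  normal variables go to one-way ANOVA with protected Fisher-LSD
  pairwise letters, non-normal ones to Kruskal–Wallis with Dunn
  pairwise letters; relationships between the indices and D are
  quantified by simple regression (standardized beta, two-sided p).

A synthetic generator (`mucofract.synthgen`) renders stained fields
with exact per-pixel ground truth and one-pixel outlines of tunable
complexity (including Koch references with known dimension), so the
whole pipeline is testable without any slide archive.

## Worked example

```python
import numpy as np
from mucofract import (
    ClassPalette, OutlineSpec, generate_ihc_field, generate_outline,
    segment_field, pcna_index, negative_nuclei_count, apoptotic_index,
    count_apoptotic, box_count, estimate_fd,
)

field = generate_ihc_field(n_positive=60, n_negative=140, n_apoptotic=12,
                           canvas=(512, 512), seed=42)
cmap = segment_field(field.image, ClassPalette.default_ihc(),
                     exclusion_mask=field.exclusion_mask)
print({k: round(v, 2) for k, v in cmap.area_percent.items()})

pi = pcna_index(cmap.area_percent["positive_nucleus"],
                cmap.area_percent["negative_nucleus"])
n_neg = negative_nuclei_count(field.truth.field_area,
                              cmap.area_percent["negative_nucleus"],
                              field.truth.mean_nucleus_area)
apo = count_apoptotic(field.image, field.apoptotic_points)
print(f"PCNA index = {pi:.2f}%  (truth {field.truth.true_pcna_index:.2f}%)")
print(f"negative nuclei = {n_neg:.1f}  (rendered 140)")
print(f"apoptotic index = {apoptotic_index(apo.count, n_neg):.3f}%")

outline = generate_outline(OutlineSpec("fold_curve", roughness=1.5,
                                       canvas=(1024, 1024), rng_seed=42))
est = estimate_fd(box_count(outline))
print(f"FD = {est.fd:.4f}  (r^2 = {est.r_squared:.4f})")
```

prints

```
{'positive_nucleus': 2.36, 'negative_nucleus': 5.18, 'cytoplasm': 50.17, 'background': 42.28}
PCNA index = 31.33%  (truth 30.00%)
negative nuclei = 140.0  (rendered 140)
apoptotic index = 7.895%
FD = 1.2398  (r^2 = 0.9986)
```

The segmented area percentages recover the generator's ground truth
through σ = 8 colour noise: the PCNA index lands within ~1.3 points of
the true proliferative fraction, and the stereological conversion of
the negative area percentage returns the rendered nucleus count. The
rough fold outline estimates D ≈ 1.24, between the smooth-curve value
1 and the plane-filling bound 2.

The same pipeline is available from the shell:

```sh
mucofract simulate --out sim --n-fields 36 --seed 1
mucofract study --manifest sim/manifest.csv --out results
```

which writes per-field indices, per-outline FD, the diet/segment
comparison tables with compact-letter displays, and the two
FD-versus-index regressions.

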