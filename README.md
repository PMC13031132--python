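# zonemap

Spatial single-cell proteomics along tissue gradients: strategic selection
of cells on a porto–central trajectory from segmented tissue images, and
continuous protein-gradient ("zonation") inference with a random-intercept
linear mixed model.

## Who this is for

Laser-microdissection / ultrasensitive-MS workflows (Deep Visual Proteomics
style) measure the proteome of single cell shapes cut out of intact tissue.
In organs with graded architecture — the liver lobule being the canonical
case, with hepatocyte function varying continuously from the central vein to
the portal vein — two analysis problems arise:

1. **Which cells to cut.** A trajectory between a central and a portal vein
   should be covered evenly with a fixed budget of shapes (44 per
   trajectory here), so the whole gradient is sampled without wasting
   instrument time.
2. **How to quantify a gradient.** Binning cells along the axis discards
   spatial resolution; a per-protein regression on the continuous position
   keeps it.

`zonemap` implements both, plus the supporting machinery: image-based vein
detection, QC filters, a binned comparator, healthy-vs-disease gradient
contrasts, cell-type contamination scoring, LMD-compatible contour export,
and variable-width DIA isolation-window design. Synthetic generators with
full ground truth make every stage testable without any external data.

## The model

Each cell carries a spatial ratio

&nbsp;&nbsp;&nbsp;&nbsp;*S* = *d*<sub>central</sub> / (*d*<sub>central</sub> + *d*<sub>portal</sub>) ∈ [0, 1],

its normalized position along the axis (0 = central vein, 1 = portal vein).
Per protein, expression *y<sub>ij</sub>* of cell *j* from patient *i* follows

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>ij</sub>* = *β*₀ + *β*₁ *S<sub>ij</sub>* + *u<sub>i</sub>* + *ε<sub>ij</sub>*,&nbsp;&nbsp;
*u<sub>i</sub>* ~ N(0, σ<sub>u</sub>²),&nbsp; *ε<sub>ij</sub>* ~ N(0, σ²),

fitted by REML. *β*₁ — the **zonation coefficient** — is the expression
change per unit *S*: negative means central-vein enrichment, positive
portal. *H*₀: *β*₁ = 0 is tested by a Wald *z* = *β*₁/SE(*β*₁) against the
standard normal, with Benjamini–Hochberg *Q* values across proteins.
A protein is **strongly zonated** when |*β*₁| > 1 and *Q* < 0.05.
Between two conditions, Δ*β*₁ = *β*₁(A) − *β*₁(B) with
SE = √(SE<sub>A</sub>² + SE<sub>B</sub>²) is Wald-tested the same way;
**zonation loss** is |Δ*β*₁| > 1 and *Q* < 0.05.

Cell selection solves max–min dispersion (remote-edge diversity
maximization) by farthest-first traversal: initialize with the two most
distant centroids, then repeatedly add the cell maximizing its minimum
distance to the selection — a 2-approximation to the exhaustive optimum.

## Worked example

`examples/` holds one short script per capability. From
`examples/02_zonation_gradients.py` (14 simulated patients × 44 cells,
200 proteins, half of them zonated, MNAR dropout):

```text
cohort: 200 proteins x 616 cells, 22% entries missing (MNAR dropout)
proteins passing 70% completeness: 200
significantly zonated (Q < 0.05): 102 (51%)
strongly zonated (|beta1| > 1 and Q < 0.05): 80 (37 central, 43 portal)

most significantly zonated proteins:
            beta1  se_beta1  sigma_u2       z    q direction
protein_id
PROT0045    1.833     0.048     0.207  38.442  0.0    portal
PROT0083   -1.770     0.044     0.266 -40.621  0.0   central
...
continuous vs 20-bin ANOVA: Spearman rho = 0.86, 100 proteins significant in both, 103 in either
```

The generator planted gradients in 100 of 200 proteins; the model calls 102
significant — the designed fraction plus type-I-level noise. `beta1` is the
fitted slope per unit *S*, `sigma_u2` the patient-intercept variance, and
the comparison line reproduces the key methodological point: the continuous
fit tracks the binned ANOVA but is more sensitive on moderate gradients.

The same library surface is exposed as a thin CLI for shell use
(`zonemap select | qc | zonation | bins | compare-methods | contrast |
dia-windows | simulate-tissue | simulate-proteome`), e.g.

```bash
zonemap simulate-tissue --out-dir scene --seed 0
zonemap select --boundary scene/boundary.tiff \
    --pericentral scene/pericentral.tiff --periportal scene/periportal.tiff \
    --contours scene/contours.csv --k 44 \
    --out-table cells.tsv --out-xml cells.xml
```

## Layout

```
src/zonemap/
  synthetic.py   tissue + proteome generators with ground truth
  tissue.py      vein detection, trajectory ROI, farthest-first selection, S
  lmdxml.py      LMD-dialect contour XML export / reader
  qc.py          intensity-matrix container, QC filters, contamination, PCA
  gradient.py    mixed-model fits, Wald/BH inference, condition contrasts
  binned.py      20-bin comparator: profiles, Z-scores, ANOVA, pathways
  dia.py         variable-width DIA isolation-window design
  pipeline.py    end-to-end orchestration (select / zonation / contrast)
  config.py      PipelineConfig with the published defaults
  cli.py         thin click CLI
docs/methods.md  model, conventions, design choices, limitations
examples/        narrative scripts, one per capability
```
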