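# hipposcaffold

Quantitative pipeline for studying scaffold-protein regulation of the Hippo
pathway (KSR1 → MST1/LATS1 → YAP), built entirely on synthetic data with
known ground truth.  The package re-creates, as tested and reusable code,
the five measurement procedures such a study rests on:

1. **Single-cell fluorescence morphometrics** — segment nuclei (median
   filter → Otsu → distance-transform watershed), cell bodies
   (marker-controlled watershed on the actin + protein composite) and actin
   stress fibers (intensity threshold gated by a multiscale tubularity
   filter) from 3-channel images, then measure per cell: nuclear area
   A_n, cell area A_c, axis-ratio eccentricity e = minor/major ∈ (0, 1],
   solidity s, N/C area ratio, nuclear displacement d (Euclidean distance
   between nuclear and cell centroids), percent stress-fiber area, and
   nuclear vs cytoplasmic protein intensity.
2. **ΔΔCT relative expression** — ΔCT = CT(target) − CT(reference),
   ΔΔCT referenced to a calibrator condition, fold change FC = 2^(−ΔΔCT),
   summarized over biological samples.
3. **RPPA differential ranking** — per-protein two-sample t-test and
   mean log2 fold change; differential set = |log2FC| ≥ 1 and p < 0.05;
   ranking by |log2FC|.
4. **Signed-PPI route scoring** — enumerate simple directed routes from a
   source protein (KSR1) to a target (YAP1) in a SIGNOR-style signed
   network and score each against a ranked protein list with three disjoint
   criteria: c1 = route nodes in the list, c2 = listed proteins one
   undirected edge from the route, c3 = listed proteins reachable through
   exactly one mediator; hub = most frequent interior node of top routes.
5. **Mass-photometry complex detection** — convert landing-event contrasts
   to masses (mass = a·contrast + b), fit Gaussian mixtures to raw masses
   by EM with BIC model selection, and call a complex when the mixed sample
   shows a sufficiently abundant peak above every individual-sample peak.

Every input is produced by a seeded generator (`hipposcaffold.synthetic`)
that records exact ground truth — instance masks and noise-free per-cell
metrics, designed fold changes, planted differential proteins, a planted
route with planted ranked-list overlap, and designed mass mixtures — so
each analysis can be validated as a blind parameter-recovery experiment.

## Worked example

```python
from hipposcaffold import synthetic, imaging
from hipposcaffold.fixture_data import load_profile

profiles = [load_profile("wt"), load_profile("ksr1_null")]
cs = synthetic.generate_condition_set(profiles, n_images=11, seed=201)

records = {}
for cond, items in cs.images.items():
    recs = []
    for image, truth in items:
        nuclei = imaging.segment_nuclei(image)
        cells = imaging.segment_cells(image, nuclei)
        recs.extend(imaging.measure_cells(image, nuclei, cells))
    records[cond] = recs

eff = imaging.estimate_effect(records["wt"], records["ksr1_null"],
                              "mean_nuc_intensity")
print(f"n = {eff.n_ref}/{eff.n_alt} cells, "
      f"change = {eff.percent_change:.1f}%, p = {eff.p_value:.2e}")
```

Output:

```
n = 110/110 cells, change = -38.0%, p = 1.35e-37
```

The wild-type and KSR1-null effect profiles encode a 38% lower nuclear
protein level in the null cells; the segmentation + measurement pipeline
recovers that reduction blind from the rendered images, and the
Mann–Whitney p-value shows the per-cell distributions are clearly
separated at ~100 cells per condition.

The qPCR side works the same way:

```python
from hipposcaffold import assays
from hipposcaffold.fixture_data import load_ct_design

design = load_ct_design("mef_ko_cyr61")       # designed fold change 0.20
table = synthetic.generate_ct_table(design, seed=7)
rel = assays.ddct(table, "CYR61", "GAPDH", calibrator="WT")
print(round(rel.fold("KSR1_KO"), 3))          # -> 0.229 (80% reduction)
```

A command-line interface mirrors the library (`hipposcaffold simulate`,
`quantify-images`, `qpcr`, `rppa`, `routes`, `massphoto`, `run`); the `run`
subcommand executes the whole suite from a YAML config with one seed and
byte-reproducible outputs.

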