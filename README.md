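# nsmuscle

Fully automated analysis of skeletal-muscle cross-section
immunofluorescence images: fiber counting, cross-sectional area (CSA),
MyHC fiber typing, and myonucleus / satellite-cell detection, built on a
neutrosophic-set segmentation model and verified end-to-end on synthetic
phantom sections with exact ground truth.

It is aimed at muscle physiologists quantifying whole sections stained
for laminin (fiber boundaries), MyHC I / IIa / IIb (blue / green / red),
DAPI (nuclei) and Pax7 (satellite cells), where manual outlining of
thousands of fibers is impractical — especially in regenerating muscle,
whose round, size-heterogeneous fibers defeat many threshold-only tools.

## The model

Each pixel of the normalized image C(i,j,k) receives neutrosophic
memberships — True T, Indeterminacy I, and False F = 1 − T. A raw
eligibility score τ is built per target structure from the RGB channel
triplet (k, max(3−k,1), θ(k+max(3−k,1))):

| structure | τ per pixel |
|---|---|
| laminin boundary | C₁ + C₂ + C₃ |
| stained class k  | C_k + (1 − C_o1) + (1 − C_o2) |
| unstained (IIx)  | Σ (1 − C_k) |
| nuclei (1 channel) | C |

T is the min-max scaled τ; I is the min-max scaled deviation of the
relevant plane from its local w×w mean (w = 15 px by default), so pixels
close to their neighbourhood are confidently assigned. The fused
membership **M = T × (1 − I)** is binarized with a strict automatic
threshold, followed by 8-connected component labeling, removal of
components below 20% of the mean component area, and filling of enclosed
background holes. Fibers of all types come from binarizing the boundary
T-plane and inverting it (each laminin-delimited cell becomes one
component); each fiber is then assigned the stained class covering the
majority of its pixels, or IIx when no class reaches 50% coverage. A
nucleus is a myonucleus of a fiber iff its centroid and more than 50% of
its area lie inside that fiber.

Full model details, threshold policy and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from nsmuscle import PhantomSpec, generate, segment_whole_section
from nsmuscle.quantify import assign_types, section_report

spec = PhantomSpec(image_size=(1024, 1024), n_fibers=100,
                   type_proportions=(0.1, 0.3, 0.2, 0.4),
                   noise_sigma=0.05, seed=7)
img, truth = generate(spec)                 # synthetic section + ground truth
results = segment_whole_section(img)        # boundary + 4 MyHC classes
records = assign_types(results["all"], results)
report = section_report(records)
print(f"fibers found: {report.overall['count']}  "
      f"mean CSA: {report.overall['mean_csa']:.0f} px^2")
print(report.per_type)
```

```
fibers found: 100  mean CSA: 9930 px^2
     count      mean_csa  proportion
I        7   9350.142857        0.07
IIa     24  10027.208333        0.24
IIx     30   9850.566667        0.30
IIb     39  10036.102564        0.39
```

All 100 fibers of the noisy phantom are recovered; the per-type counts
and proportions equal the generator's ground truth exactly (7/24/30/39
is the realized multinomial draw for proportions 0.1/0.3/0.2/0.4), and
the mean CSA matches the truth label map. Areas are in px² here because
the phantom is uncalibrated; set `um_per_px` to report µm².

The same pipelines are available from the shell:

```
nsmuscle phantom --seed 1 --size 1024 --n-fibers 100 --out ph/
nsmuscle typing ph/phantom.tif --out analysis/
nsmuscle nuclei ph/phantom.tif --dapi-channel 3 --pax7-channel 4 --out nuc/
```

Each run writes a per-fiber CSV, a summary JSON, 16-bit label TIFFs, an
RGB overlay PNG and a timestamp-free manifest that makes runs
byte-for-byte reproducible.

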