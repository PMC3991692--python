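# lcmicro

**3D lamina cribrosa microarchitecture analysis for OCT volumes** —
beam/pore segmentation, maximal-inscribed-sphere morphometry, synthetic
phantoms with known ground truth, and repeat-scan imprecision statistics.

The lamina cribrosa (LC) is the porous connective-tissue mesh in the optic
nerve head through which all retinal ganglion cell axons pass; its beams
(collagen) and pores (axon channels) remodel in glaucoma.  Swept-source
OCT can image the LC in vivo as a ~3.5 × 3.5 × 3.64 mm cube scan
(8.75 µm lateral / 4.0625 µm axial voxels), but the structure is too
complex to segment by hand at study scale.  `lcmicro` provides the
automated pipeline — and, because no LC scan data are publicly deposited,
a calibrated synthetic-phantom module so that every stage is testable
against known truth — for researchers who need reproducible,
physically-scaled LC microarchitecture measurements and a defensible
estimate of their scan–rescan repeatability.

## What it computes

For one segmented scan, the seven standard microarchitecture parameters:

| parameter | definition |
|---|---|
| pore diameter (µm), SD | voxel-weighted mean/SD of the pore local thickness map |
| beam thickness (µm), SD | same for the beam phase |
| beam-to-pore ratio | beam thickness mean / pore diameter mean |
| pore area (µm²) | mean area of 8-connected pore components on C-mode slices |
| pore aspect ratio | mean major/minor axis of the moment-equivalent ellipse |

*Local thickness* at a point is the diameter of the largest sphere that
contains the point and fits entirely within the phase — computed on the
physical (anisotropic) grid via exact Euclidean distance transform,
distance-ridge reduction and sphere painting, and tested for **exact**
agreement with a brute-force evaluation of the definition.

For a cohort of repeat-scanned eyes, the nested measurement error model

    value = µ + occasion + subject + eye(subject) + error,   bias ≡ 1

yields the **imprecision SD** (the replicate-error SD; for two replicates
per eye the REML solution is SD(paired differences)/√2) and the
**relative imprecision** (imprecision / mean, percent), overall or per
diagnostic group, with a bootstrap variance-ratio comparison between
groups.

## Worked example

```python
from lcmicro import PhantomSpec, SegConfig, VoxelGrid, analyze_volume, generate_phantom

spec = PhantomSpec(grid=VoxelGrid(shape=(96, 96, 72)), lc_depth=200.0, seed=7)
phantom = generate_phantom(spec)                  # speckle 0.3, 10% vessel shadows
params, seg = analyze_volume(phantom.volume, SegConfig())
```

prints (via `python examples/02_segment_and_measure.py`):

```
analyzable voxels   : 388,273
pore diameter       :    24.5 +- 8.9 um
beam thickness      :    46.7 +- 14.3 um
beam/pore ratio     :    1.90
pore area           :    1264 um^2
pore aspect ratio   :    2.21
pores top/bottom    : 607 / 938
```

The phantom was generated with true pore diameter 24 µm and beam
thickness 49 µm: the full pipeline recovers both within a few percent
through speckle, vessel shadows, and conservative masking.  The
imprecision example (`examples/04_imprecision_statistics.py`) fits the
measurement error model to a simulated two-group cohort:

```
healthy   mean  24.1 um | imprecision SD 0.90 um | relative 3.7% (22 eyes, 16 subjects)
glaucoma  mean  23.8 um | imprecision SD 0.28 um | relative 1.2% (22 eyes, 16 subjects)
healthy/glaucoma imprecision variance ratio 10.3 (95% bootstrap CI 5.0-21.8)
```

— the groups were simulated with residual SDs 0.9 and 0.3 µm, and the
model recovers both; the CI excluding 1 flags the difference.  The other
`examples/` scripts cover phantom generation, repeat-scan simulation and
the full cohort experiment; each prints what it computes and what the
numbers mean.

A thin CLI mirrors the library:

```bash
lcmicro simulate --out eye0 --seed 7
lcmicro segment --in eye0 --out eye0_seg
lcmicro experiment --out report --seed 0 --eyes 12
```

## Configuration surface

Everything is driven by one JSON-serializable `PipelineConfig`:
`PhantomSpec` (grid, true pore/beam targets, slab depth, speckle,
shadows, seed), `SegConfig` (denoise radius, local window, minimum
component, mask conservatism), `RepeatScanSpec` (rotation, shift,
contrast, speckle seed), and the experiment design (eyes, master seed,
between-eye jitter).  `docs/methods.md` documents the models, defaults,
units and the reasoning behind every numerical choice, along with what
the phantom does and does not emulate.
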