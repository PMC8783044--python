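# acquant

Quantification toolkit for anchor-cell (AC) positioning, invasion and
dynamics in fluorescence time-lapse recordings of *Caenorhabditis elegans*
vulval morphogenesis.

During vulval development the uterine AC breaches the basement membranes
(BM) separating uterus and vulva, aligns itself with the invaginating
primary (vulF) cells and organizes the junctions that connect the two
organs. Studies of this process score a recurring set of quantities from
two reporter channels (an AC/actin reporter and a junction/BM reporter):

- **Alignment ratio** `R_A = x / y`, where `x` is the anteroposterior (AP)
  distance from the AC mid-point (midpoint of the two HMR-1 punctae
  delineating the AC edges) to the *nearer* outer vulA junction, and `y`
  the AP distance between the two vulA junctions. `R_A = 0.5` means the AC
  sits exactly on the vulval midline.
- **Mid-vulF distance** `Δ = |mid_AC − vulF_mid|` in µm along the AP axis.
- **Dorsoventral polarity index** `I_DV`: ratio of ventral-half to
  dorsal-half reporter intensity in a summed z-projection of the AC.
- **BM breach**: collapse of the BM reporter ridge over a run of AP
  columns; the gap extent is read off the ridge-intensity profile.
- **Protrusion volume**: `voxel count × dz·dy·dx` of the binarized AC
  signal (constant threshold 0.05 of the stack maximum after
  Richardson–Lucy deconvolution) ventral of the BM surface, tracked over
  the first 90 min after breaching.
- **Correlation index** `C_I`: mean Pearson correlation (phi coefficient)
  of consecutive binarized 144×90 px AC frames from a 30-s-interval
  series; lower `C_I` = more dynamic shape changes.
- **Cohort statistics**: vulval induction index VI (mean induced VPCs per
  animal; wild type = 3.0), proportions with Wilson 95% CIs, Welch *t*,
  Mann–Whitney *U* (exact for small tie-free samples), *F*-test for
  variance, and actin-ring class fractions.

No raw image data from such studies are publicly deposited, so the
package bundles a ground-truthed synthetic microscopy generator
(`acquant.scenes`): an ellipsoidal AC with a ventral protrusion crossing
a BM gap, junction punctae, Gaussian PSF blur, Poisson photon noise,
Gaussian read noise and 16-bit quantization, with every fixture carrying
a JSON sidecar of true volumes, landmarks and applied stage shifts.
Every estimator is validated against that ground truth.

## Worked example

```python
import numpy as np
from acquant import scenes, alignment, dynamics, invasion
from acquant.imgproc import PSFModel, VoxelGrid, binarize, richardson_lucy

spec = scenes.SceneSpec(deform_amplitude=0.1, n_frames=6, seed=7)
ts = scenes.simulate_timeseries(spec)          # (6, 2, 24, 96, 160) uint16

bm = ts.channel(1)                             # junction/BM channel, frame 0
res = alignment.compute_alignment(alignment.detect_landmarks(bm))
print(f"R_A = {res.r_a:.3f}   Delta = {res.delta_um:.3f} um")

surf = invasion.annotate_gaps(invasion.extract_bm_surface(bm))
print(invasion.detect_breach(surf))

dec = richardson_lucy(ts.channel(0), PSFModel(*spec.psf_sigma_um), n_iter=400)
mask = VoxelGrid(binarize(dec.values, "fixed-normalized", 0.05).astype(np.uint8),
                 spec.voxel_size)
print(f"protrusion volume = {invasion.protrusion_volume(mask, surf):.2f} um^3")

series = dynamics.correlation_series(ts.frames[:, 0].astype(float),
                                     spec.voxel_size,
                                     psf=PSFModel(*spec.psf_sigma_um))
print(f"C_I = {series.c_i:.3f} over {len(series.pair_indices)} frame pairs")
```

Output:

```
R_A = 0.500   Delta = 0.018 um
breached = True, gap extent = 2.70 um
protrusion volume = 11.65 um^3   (ground truth 10.35)
C_I = 0.982 over 5 frame pairs
```

The detected landmarks recover the true alignment (`R_A` 0.500, `Δ` off
by 0.018 µm at 0.1 µm lateral voxels); the 3 µm rendered gap is called
breached with a 2.7 µm extent (PSF blur erodes the apparent edges); the
measured protrusion volume sits 13% above the voxelized truth (the
constant 0.05 threshold probes the far tail of the residual edge
profile); and the moderately deforming AC gives `C_I` just below the
static ceiling of 1.0.

A `click` CLI mirrors the library:
`acquant simulate|deconvolve|register|align|protrusion|dynamics|ring|morpho|stats`
(run any subcommand with `--help`).

## Layout

| module | contents |
| --- | --- |
| `acquant.scenes` | synthetic scene/time-series generator, fixture I/O |
| `acquant.imgproc` | Richardson–Lucy, registration, projections, crop, binarize |
| `acquant.alignment` | landmark metrics `R_A`, `Δ`, `I_DV`, landmark detection |
| `acquant.invasion` | BM surface, breach detection, protrusion volumetry |
| `acquant.dynamics` | frame correlation and `C_I` pipeline |
| `acquant.morphometry` | vulA distance, lumen-expansion delay, ring scoring |
| `acquant.stats` | VI, proportion CIs, Welch t, Mann–Whitney U, F-test |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
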