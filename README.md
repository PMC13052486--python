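# lsci — laser speckle contrast imaging analysis and simulation

`lsci` implements the desk-scale analysis chain of a laser speckle contrast
imaging (LSCI) system for assessing tissue perfusion — the kind of
measurement used intraoperatively to tell a perfused organ (e.g. a
parathyroid gland, or cortex) from one whose blood supply is compromised —
together with a physics-based dynamic-speckle simulator so that every stage
can be validated quantitatively without clinical recordings.

When coherent light (785 nm in the reference configuration) illuminates a
scattering tissue, interference produces a random speckle pattern.  Moving
scatterers (red blood cells) decorrelate the pattern; motion faster than the
camera exposure T blurs the speckle and lowers the local **spatial speckle
contrast**

    K = sigma_s / <I>

computed as the standard deviation over the mean of pixel intensities inside
a 5×5 window scanned across each frame.  K near 0 indicates fast flow; high
K indicates slow or absent flow.  K is used as a *qualitative* flow
indicator: the pipeline compares regions and conditions, it does not
calibrate absolute flow speed.

The package provides:

* **`lsci.simulate`** — dynamic-speckle video with a known per-pixel
  correlation time τc (field autocorrelation g1(τ) = exp(−τ/τc), exposure-
  time integration, coherence factor β), a virtual single-channel flow
  phantom, and injectable global hand-motion blur.  For this model the
  exposure-averaged contrast has the closed form
  `K² = β(e^(−2x) − 1 + 2x)/(2x²)`, `x = T/τc`, which the test suite uses as
  its oracle.
* **`lsci.contrast`** — the sliding-window contrast map, ROI reductions and
  per-frame trace statistics (first 30 frames by convention).
* **`lsci.motionfilter`** — rejection of frames whose whole-frame mean K
  falls below a blur threshold (default 0.025).
* **`lsci.analysis`** — two-sample two-sided Student's t-test between ROI
  traces and a perfused/compromised classification.
* **`lsci.optics`** — diffraction speckle size `ρ = 2.44·λ·(1+M)·f/#` and
  the speckle-to-pixel Nyquist sampling check.
* **`lsci.io` / `lsci.render` / `lsci.pipeline` / `lsci.cli`** — TIFF/PNG/
  CSV/JSON interchange, blue-to-red false-color maps (0–0.4 by default), and
  the `lsci` command-line interface.

## Worked example: flow vs no-flow phantom

Simulate a tissue phantom with a 40-pixel fluid channel (τc = 0.1 ms,
T = 5 ms) and its no-flow counterpart, extract the channel-ROI contrast
trace over 30 frames, and test the difference:

```sh
lsci simulate phantom --grid 128 --channel-width 40 --tau-c 0.1 \
    --exposure 5 --frames 30 --seed 7 --out flow.tif
lsci simulate phantom --grid 128 --channel-width 40 --no-flow \
    --frames 30 --seed 8 --out noflow.tif
python -c "
from lsci.simulate import make_flow_phantom, phantom_rois
from lsci import io as lio
spec = make_flow_phantom((128,128), 40, 0.1, seed=7, n_frames=30)
ch, _ = phantom_rois(spec)
lio.write_roi_mask(ch, 'channel.png')"
lsci contrast --in flow.tif   --roi channel.png --group-label flow    --out flow.csv
lsci contrast --in noflow.tif --roi channel.png --group-label no_flow --out noflow.csv
lsci compare --a flow.csv --b noflow.csv --out cmp.json
```

which prints

```
flow: K=0.1344±0.0019  no_flow: K=0.9307±0.0000  t=-2356.218 p=3.71e-146 -> classified
```

The flowing channel's mean contrast (0.134) sits far below the static
channel's (0.931); the two 30-frame traces do not overlap, the two-sided
t-test is overwhelmingly significant, and the flow group is classified
perfused-like.  The no-flow trace has zero variance because frozen
scatterers yield a frozen speckle pattern.

The optics helper reproduces the speckle-size arithmetic for a miniature
f/2.7 camera at 785 nm and unit magnification:

```sh
$ lsci optics speckle-size --wavelength 785 --magnification 1 --f-number 2.7 --pixel-pitch 3
{
  "adequately_sampled": true,
  "pixel_pitch_um": 3.0,
  "speckle_diameter_um": 10.3432,
  "speckle_per_pixel_ratio": 3.4477
}
```

Rendering (`lsci render --in flow.tif --render-range 0:0.4 --out k.png`)
writes the standard false-color map: blue = 0 (fast flow) to red = 0.4
(no flow).

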