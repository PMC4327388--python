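# spotcoloc

Object-based colocalisation analysis for punctate fluorescence microscopy:
subpixel spot detection, nearest-neighbour matching under a physical
distance threshold, and a scrambled-coordinate null model that converts raw
overlap percentages into chance-corrected **net percentages**.

## The problem

Endosomes, vesicles and similar structures appear in fluorescence
micrographs as diffraction-limited punctae. To ask whether two markers
(say, an ESCRT-0 subunit and EEA1) label the *same* structures, pixel
intensity correlation (Pearson/Manders) is a blunt instrument: it mixes
signal from overlapping and non-overlapping structures and is sensitive to
background. The object-based alternative implemented here works on the
*structures* themselves:

1. **Detect** the centre of every punctum in each channel with subpixel
   precision, by fitting a second-order polynomial with Gaussian weighting
   to the local intensity profile (localisation error of a few nm at high
   SNR, well below the ~20 nm regime this class of tracker is known for).
2. **Match**: for each particle in channel 1, find the nearest particle in
   channel 2. If their distance *d* satisfies *d* < τ (strictly), with
   τ ≈ 200 nm — 2 px (215 nm) at 107.5 nm/px, or 3 px (193.5 nm) at
   64.5 nm/px — the particle is scored as colocalised. The raw percentage
   for the directed pair 1→2 is

       P_raw(1→2) = 100 · #{i : min_j ‖x_i − y_j‖ < τ} / n_1

   The two directions are independent quantities and are always reported
   separately.
3. **Correct for chance**: dense random point patterns overlap by accident
   (for CSR targets of density ρ the chance level is
   100·(1 − e^(−ρπτ²))). The null is estimated empirically by adding
   independent uniform random offsets to the target coordinates (wrapped
   inside the analysis bounds), recomputing the percentage over many
   scrambles, and reporting

       P_net = P_raw − mean(P_scrambled)

Analysis can be restricted to ROI polygons (cell outlines, peripheral
regions), and three or more channels can be scored per particle
(triple-positive conjunction flags).

Because real micrographs rarely come with ground truth, the package ships a
simulator that renders multi-channel fields of Gaussian-PSF spots on a
Poisson-noise background with a *known* colocalised fraction, so every
stage — detection accuracy, matching, the scramble null, end-to-end
fraction recovery — is tested quantitatively.

## Worked example

```python
import numpy as np
from spotcoloc import AcquisitionConfig, net_colocalisation
from spotcoloc.simulate import PsfModel, generate_scene, render_channel
from spotcoloc.detect import DetectionParams, detect_particles

cfg = AcquisitionConfig(pixel_size_nm=107.5, threshold_px=2, channels=("hrs", "eea1"))

# a 512x512 two-channel field, 100 spots/channel, 40% truly colocalised
truth = generate_scene(
    100, (512, 512), channels=("hrs", "eea1"),
    coloc_fraction=0.4, jitter_nm=0.0, seed=42,
)
psf = PsfModel(sigma_nm=100, background=100)
maps = [
    detect_particles(render_channel(truth, ch, psf, seed=k), DetectionParams())
    for k, ch in enumerate(cfg.channels)
]
result = net_colocalisation(maps, cfg, n_repeats=100, seed=0)
print(result.to_frame().to_string(index=False))
```

prints

```
     pair  n_source  n_target  raw_percent  scrambled_mean  scrambled_sd  net_percent
eea1->hrs        99        98    39.393939        0.818182      0.869692    38.575758
hrs->eea1        98        99    39.795918        0.693878      0.856563    39.102041
```

Reading the table: ~99 of the 100 simulated spots per channel were detected
(a thin border strip is excluded); 39.8% of `hrs` particles have an `eea1`
particle within 215 nm; random scrambles of the `eea1` map put the chance
level at 0.69 ± 0.86%; the net percentage, 39.1%, recovers the simulated
40% colocalised fraction. The same pipeline is available from the shell:

```bash
spotcoloc simulate --config scene.yaml --out-dir scene/ --seed 5
spotcoloc pipeline --images scene/hrs.tif --images scene/eea1.tif \
    --config acquisition.yaml --seed 3 --out-dir run/
spotcoloc coloc --maps a.csv b.csv --threshold-px 2 --pixel-size-nm 107.5 \
    --repeats 100 --seed 1 --out report.json
```

Every run writes a manifest (seeds, parameters, input digests); reports
contain no timestamps, so fixed-seed runs are byte-identical.

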