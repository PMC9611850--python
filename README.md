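# agrifuse

A raster-analysis toolkit for precision viticulture that fuses
centimetric UAV multispectral imagery, decametric satellite imagery and
point soil-moisture sensors into vigour maps, moisture surfaces and
actionable field routes.

## The problem

NDVI, the standard vigour proxy

    NDVI = (NIR − Red) / (NIR + Red),

is routinely mapped from decametric satellites (e.g. Sentinel-2 at
10 m GSD). In a vineyard, however, every 10 m pixel mixes ~50% vine
canopy with ~50% inter-row soil or grass (rows 2 m apart, ~1 m canopy
width), so whole-pixel NDVI under-reports canopy vigour and confounds
it with inter-row state. A UAV flying at 5 cm GSD resolves individual
rows; the toolkit aligns both resolutions and decomposes the signal.

For each satellite cell s(i, j), the set G(i, j) of UAV pixels whose
centres fall inside the cell's half-open geographic footprint is found,
the UAV raster is partitioned into canopy pixels P_vin and inter-row
pixels P_int, and three aggregated maps are computed on the satellite
grid:

* **NDVI_uav(i, j)** — mean per-pixel UAV NDVI over the whole cell,
* **NDVI_vin(i, j)** — mean over canopy pixels only,
* **NDVI_int(i, j)** — mean over inter-row pixels only,

to compare with **NDVI_sat(i, j)** computed from the satellite bands.
NDVI_vin is the quantity that tracks true canopy vigour; NDVI_sat
cannot, because the sensor averages *reflectances* before the ratio.

Around that core the toolkit provides: ordinary kriging of
covariate-derived soil-moisture estimates with exhaustive calibration
against in-situ capacitance probes (0–0.57 VWC range); threshold-based
attention-point alerting (irrigation / fertilisation); and a
permutation-encoded genetic algorithm that orders the visits into a
tractor route. A built-in synthetic vineyard-scene simulator renders
ground truth at both resolutions so the entire chain is testable
without field data.

## Worked example

```python
import numpy as np
from agrifuse import (SimConfig, simulate_scene, render_uav, render_satellite,
                      ndvi, ndvi_sat, segment_canopy, match_footprints,
                      aggregate_ndvi)
from agrifuse.simulate import vigour_for_canopy_ndvi

# 50 m x 50 m vineyard, rows 2 m apart, 1 m canopy, canopy NDVI 0.8, soil 0.15
scene = simulate_scene(SimConfig(field_width_m=50, field_height_m=50,
                                 vigour_base=vigour_for_canopy_ndvi(0.8),
                                 vigour_gradient=(0.0, 0.0), noise_sd=0.0, seed=0))
uav = render_uav(scene, 0.05)          # 5 cm GSD, 1000 x 1000 px
sat = render_satellite(scene, 10.0)    # 10 m GSD, 5 x 5 cells

part = segment_canopy(ndvi(uav))       # Otsu NDVI threshold + cleanup
corr = match_footprints(sat.grid, uav.grid)
vin = aggregate_ndvi(uav, corr, mask=part, which="vin")
print("members per cell:", corr.counts[0, 0])
print("NDVI_vin mean:   %.3f" % vin.values.mean())
print("NDVI_sat mean:   %.3f" % ndvi_sat(sat).values.mean())
```

prints

```
members per cell: 40000
NDVI_vin mean:   0.800
NDVI_sat mean:   0.542
```

Each 10 m cell holds exactly 200 × 200 = 40,000 UAV pixel centres.
The canopy-only aggregation recovers the true canopy NDVI of 0.80,
while the satellite pixel — a 50/50 reflectance mixture of canopy and
soil — reads 0.54: a 0.26 bias that would misclassify a healthy
vineyard as mediocre.

The same operations are available from the shell:

```sh
agrifuse simulate -o scene --seed 1
agrifuse ndvi scene/uav.tif -o scene/ndvi.tif
agrifuse segment scene/ndvi.tif -o scene/mask.tif
agrifuse fuse --sat scene/satellite.tif --uav scene/uav.tif \
              --mask scene/mask.tif --which vin -o scene/ndvi_vin.tif
agrifuse run --seed 1 -o run          # full pipeline + manifest
```

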