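# phenopipe

Calibrated colour-threshold image analysis for high-throughput plant
phenotyping.

Automated greenhouse platforms photograph hundreds of potted plants from
a top-view and a side-view camera at regular intervals, producing far
more images than anyone can measure by hand. `phenopipe` turns such
image series into phenotypic parameters — plant height, width,
x/y-extent, maximum diameter and projected shoot area, all in
millimetres — for growth and stress-tolerance screening, e.g. comparing
barley cultivars under well-watered and drought conditions. It is aimed
at plant scientists running (or emulating, with a camera and tripod) a
fixed-camera imaging setup.

## Method in brief

Each pixel is classified by **multidimensional histogram thresholding
(MHT)** in the combined RGB + HSV colour space: an object class *c* is a
box

&nbsp;&nbsp;&nbsp;&nbsp;*c* = { **p** : ℓ<sub>ch</sub> ≤ p<sub>ch</sub> ≤ u<sub>ch</sub> for ch ∈ {R, G, B, H, S, V} },

with hue handled circularly, and each non-plant class (carrier, cages,
sticks, soil, conveyor belt) is additionally confined to a fixed image
**region** — so furniture with plant-like colours cannot leak into the
plant mask, while the plant itself may appear anywhere. The extracted
plant mask is cleaned by a **morphological opening** (erosion then
dilation, square structuring element), and the measurements follow:
extents as inclusive bounding-box sizes, the diameter as the maximum
Feret diameter max<sub>i,j</sub> ‖p<sub>i</sub> − p<sub>j</sub>‖ over
plant-pixel centres, and the projected shoot area as
*N*<sub>plant</sub> · (mm/px)². Group curves report mean ± SE (s/√n) of
projected shoot area per time point. Thresholds are calibrated from
labelled sample pixels (per-channel trimmed extrema) and stored in a
per-view YAML file. See `docs/methods.md` for the full account.

## Worked example

No public image set accompanies the original experiments, so the package
ships a scene generator with exact ground truth. Generate a synthetic
growth experiment (2 cultivars × 2 conditions × 4 plants × 5 days,
side view), analyse it, and summarise the group curves:

```sh
phenopipe synth timeseries --out data --seed 7 --plants 4
# 80 image(s) + manifest -> data

phenopipe analyse --input data --config-side data/config_side.yaml --out analysis
# 80 image(s) analysed -> analysis/results.csv
```

`analysis/results.csv` holds one row per image (lengths in mm, areas in
mm²; top-view columns stay empty for side views):

```
plant_id,view,timepoint,x_extent_mm,y_extent_mm,diameter_mm,width_mm,height_mm,projected_shoot_area_mm2,pixel_count,empty_flag,source_path,config_id,software_version
Barke-drought-p00,side,29,,,,37.00,27.00,999.0,999,false,data/Barke-drought-p00_side_d29.png,side-543625a496,0.1.0
Barke-drought-p00,side,35,,,,46.00,34.00,1564.0,1564,false,data/Barke-drought-p00_side_d35.png,side-543625a496,0.1.0
```

so this plant's silhouette was 37 mm wide and 27 mm tall at day 29,
covering 999 mm² of projected shoot area, and had grown to 1564 mm² six
days later. Summarise per cultivar × condition (the generator's manifest
provides the plant → group mapping):

```sh
phenopipe summarize --table analysis/results.csv --groups groups.csv \
    --out summary.csv --plot growth.png
# 20 group/timepoint cell(s) -> summary.csv
```

```
group,timepoint,n,mean_area_mm2,se_area_mm2
Barke/drought,29,4,1458.25,177.57598139012683
Barke/drought,35,4,1620.25,96.42991842092715
Barke/drought,41,4,1740.0,118.19263936472525
```

— the mean projected shoot area of the drought-stressed "Barke" group
rose from ≈1458 mm² (SE 178, n = 4) at day 29 to ≈1740 mm² by day 41,
and `growth.png` plots all four group curves with ±SE error bars.

Other entry points: `phenopipe calibrate` derives six-channel threshold
profiles from a labelled-pixel file (`r,g,b,label` lines);
`phenopipe synth scene` writes a single top- or side-view scene with its
ground-truth label map; `--annotate`/`--stacks` make `analyse` write
outlined result images and per-image processing stacks (multi-page
TIFF). Everything is also available as a library
(`import phenopipe`).

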