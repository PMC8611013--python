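# pcct — spectral photon-counting CT simulation and analysis

`pcct` is a desk-scale simulator and analysis toolkit for a prototype
**photon-counting-detector (PCD) CT** system.  It is aimed at medical-
physics and detector researchers who want a fully reproducible, pure-
Python model of the complete spectral CT chain:

* polychromatic **fan-beam acquisition** (140 kVp Kramers spectrum,
  Beer–Lambert attenuation through material phantoms) sorted into three
  photon-energy bins (30–50, 50–65, 65–140 keV) with Poisson counting
  noise, per-pixel counter saturation (14/13/12-bit), and 5×6 standard
  or 1×1 high-resolution (HR) detector binning;
* **equiangular fan-beam FBP** reconstruction to HU-calibrated per-bin
  and total-energy images (625×625 over a 250 mm FoV at full scale);
* **K-edge threshold calibration**: recovery of the DAC→keV threshold
  map from count sweeps behind gadolinium (K-edge 50.2 keV) and
  tungsten (69.5 keV) filters;
* per-pixel **neural-network material decomposition** — an 8-hidden-
  layer ReLU perceptron mapping each pixel's three bin values to
  iodine / calcium / white-matter / gray-matter scores, trained on
  25×25-pixel ROIs of known composition (9 ROIs × 625 px × 3 bins =
  16,875 scalar training units, learning rate 5·10⁻⁵, 4500 epochs);
* **image-quality statistics**: ROI mean ± SD,
  CNR = (ROI_tissue − ROI_muscle)/SD_noise, the iodine-map CNR gain,
  PCD-vs-EID HU comparison, and bar-pattern modulation for
  standard-vs-HR resolution scoring.

There is no external data: digital phantoms (calibration inserts,
brain, rim-enhanced liver tumor, 0.5 mm bar pattern) generate every
input.  The model, assumptions, and problem sizes are documented in
[docs/methods.md](docs/methods.md).

## Worked example: liver-tumor iodine map

The flagship experiment simulates a rim-enhanced liver tumor (6 mm rim
at 5 mg/mL iodine, aorta at 10 mg/mL), reconstructs total-energy and
per-bin images over three noise seeds, trains the decomposition network
on the insert phantom, and compares tumor CNR on the iodine map against
the total-energy image:

```bash
pcct demo liver --seed 1 --out out
```

prints

```
tissue  cnr_total_mean  cnr_total_sd  cnr_iodine_mean  cnr_iodine_sd  gain_mean  gain_sd
 tumor        4.007474      0.467244         9.638625       1.708234   2.443367 0.503759
 liver        0.438255      0.075114        -0.624545       0.434049  -1.294794 0.898485
 aorta       17.383440      1.524156        21.072867       3.747059   1.229157 0.277284
tumor iodine-map CNR gain (mean over 3 seeds): 2.44
```

Reading the numbers: the enhancing tumor rim is detected at CNR ≈ 4.0
in the total-energy image but at CNR ≈ 9.6 on the decomposed iodine
map — a gain of ≈ 2.4×, because the network suppresses the non-iodine
background while keeping the contrast-agent signal.  The aorta is
already high-contrast at total energy, so its gain is modest; the
liver-parenchyma ROI has near-zero total-energy contrast, so its ratio
is numerically unstable (the per-seed SD shows this).  The command also
writes `cnr_report.csv`, a preview image, and the fully resolved
configuration for exact re-running.

Other one-command experiments:

```bash
pcct demo brain --seed 1 --out out           # 4-material decomposition maps
pcct demo resolution --seed 1 --out out      # 0.5 mm bars, standard vs HR
pcct demo hu-comparison --seed 1 --out out   # PCD vs EID HU per ROI
```

Lower-level verbs (`pcct simulate | reconstruct | train | decompose |
metrics`) expose the individual pipeline stages on YAML configurations;
sinograms are stored as HDF5, images as NIfTI/TIFF with PNG previews,
and models as HDF5.

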