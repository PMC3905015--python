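# pixelccs

Predict a protein's collision cross section (CCS, Å²) from its PDB
coordinates by measuring the rotationally-averaged area of its projected
silhouette, and calibrate travelling-wave ion-mobility (TWIMS) drift times
against published standards so predictions can be compared with experiment.

## Who this is for

Structural and native mass-spectrometry groups who want a fast,
transparent projection-approximation size estimate for a protein — for
example to decide whether a tagged protein should pass a size-selective
barrier, or to sanity-check an ion-mobility measurement — without running a
scattering-based calculator.

## The method

**Prediction.** The structure is reduced to spheres: one per atom, radius
= van der Waals radius + probe radius (default 1.4 Å), so the sphere set's
silhouette is that of the solvent-accessible surface. The cloud is rotated
through a two-angle orientation grid with step θ about the laboratory x-
and y-axes — (180/θ)² orientations, with 180/θ required to be an integer
(the nearest admissible step is substituted otherwise). At each
orientation every sphere projects orthographically to a disk; the disk
union is rasterized at a fixed pixel size and the area is counted with a
sampling stride *k* (the "pixel skip": measure 1 pixel in every *k* along
each axis, then multiply the count by *k²*). The CCS estimate is

&nbsp;&nbsp;&nbsp;&nbsp;Ω ≈ mean over orientations of (counted pixels × k² × pixel_size²)

This is a pure projection approximation: it ignores buffer-gas scattering,
and is known to sit between scattering-free (PA) and hard-sphere-scattering
(EHSS) reference values for most proteins. Defaults are θ = 30° (36
orientations), stride k = 20, pixel size 0.2 Å.

**Calibration.** TWIMS drift times t_D map nonlinearly to CCS. Published
calibrant cross sections Ω are reduced for charge z and buffer-gas reduced
mass μ = mM/(m+M):

&nbsp;&nbsp;&nbsp;&nbsp;Ω′ = Ω / (z·√(1/μ))

then fitted against drift times with an allometric power law Ω′ = A·t_D^B
(ordinary least squares on logs). An analyte's CCS follows from its drift
time by Ω = A·t_D^B·z·√(1/μ).

## Worked example

Generate a synthetic 12-atom helical test structure (known face-on area)
and predict its CCS:

```sh
$ pixelccs fixtures make helix --count 12 --out helix.pdb --truth truth.json
wrote helix.pdb (12 atoms)
$ pixelccs predict helix.pdb --theta 30 --pixelskip 1 --pixel-size 0.1
200.9
```

The printed number is the CCS in Å²: the mean silhouette area over the 36
viewing orientations of the θ = 30° grid. The per-orientation areas range
from 180.1 Å² (the face-on view — matching the generator's independent
ground truth of 180.7 Å² for that orientation) to 226.8 Å²; the rotational
average 200.9 Å² is what an ion-mobility measurement of this rigid shape
would approximate. `--out summary.json` records the full parameter set and
structure provenance alongside the value.

Calibrate drift times against standards and size an analyte (illustrative
numbers; the calibrant table is user data, with published cross sections
from conventional ion-mobility databases):

```sh
$ pixelccs calibrate standards.csv --gas N2 --out fit.json
A = 462.048, B = 0.681869 (3 calibrants) -> fit.json
$ pixelccs apply-calibration analytes.csv --fit fit.json
    name  mass_da  charge  drift_ms      ccs_A2
mRFP_10+  25786.0      10       6.1 2997.309876
```

Other commands: `sweep-pixelskip` and `sweep-theta` trace how the estimate
converges as the sampling stride and orientation count vary; `compare`
builds a predicted-vs-measured table (percentage of measured, truncated to
one decimal) with optional PA/EHSS reference bracketing.

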