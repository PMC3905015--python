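# Methods

## Model

The package estimates a protein's collision cross section in the
projection approximation: the CCS is the average, over many viewing
directions, of the area of the molecule's 2-D silhouette. The molecule is
represented as a union of spheres — one per atom, centered on the
coordinates in the PDB file, with radius vdW(element) + r_probe. With the
default probe of 1.4 Å the silhouette of the inflated spheres equals the
silhouette of the 1.4 Å solvent-accessible surface, which is the surface
the method is defined on. Assumptions that follow from this model:

- the structure is rigid (a single conformer, or an average over NMR
  models when requested);
- buffer-gas scattering, long-range potentials, and concavity shadowing
  are ignored — the estimate is a geometric projected area, which for most
  proteins lies between scattering-free (PA) and exact-hard-sphere (EHSS)
  reference calculations and slightly below TWIMS-measured values;
- electrostatics are ignored; the area operation accepts any sphere cloud,
  so a charge-inflated cloud can be supplied, but the package does not
  compute one.

## Orientation grid

Viewing directions are generated by two nested rotations about the fixed
laboratory x- then y-axes, each stepping by θ through [0°, 180°), giving
(180/θ)² orientations. 180/θ must be an integer; otherwise the admissible
step nearest the request is used, ties resolved toward the smaller step
(more orientations). Endpoints: θ = 180° gives 1 orientation and θ = 1°
gives 32,400. The CCS is the unweighted arithmetic mean over the grid.
This grid oversamples some directions relative to a uniform distribution
on the sphere of viewing axes; no solid-angle weighting is applied because
the plain mean is the method's defining average. For compact shapes the
36-orientation default agrees with the 1,296-orientation θ = 5° average to
well under 1% (the acceptance script prints the measured deviation,
typically ≈0.3% on the helix fixture).

## Rasterized area with a sampling stride

Each orientation's silhouette area is measured on a pixel grid:

1. rotate the (centroid-centered) sphere centers and drop the viewing
   axis, leaving disks in the viewing plane;
2. lay a raster of `pixel_size` Å/pixel over the disks' bounding box plus
   `padding` (default 2 Å) on every side, anchored at the box's lower-left
   corner;
3. visit every `stride`-th pixel along x and y starting at pixel (0, 0); a
   pixel counts when its center lies inside at least one disk;
4. area = count × stride² × pixel_size².

Numerical choices:

- **Pixel rule.** Center-in-disk counting. Boundary-pixel errors then
  largely cancel (the rule is unbiased as the grid refines), so the
  measured area converges to the true union area with error well below the
  conservative bound perimeter × stride × pixel_size used in tests.
- **Resolution.** `pixel_size` defaults to 0.2 Å/pixel. The effective
  sampling spacing is stride × pixel_size; accuracy is governed by that
  product relative to the silhouette size, which is why the default stride
  of 20 (spacing 4 Å) is adequate for protein-sized silhouettes (≈2,000 Å²)
  but coarse for few-atom fixtures — tests on small fixtures therefore use
  finer rasters. A convergence test (stride-k area → stride-1 area as
  pixel_size → 0) replaces any assumption about a particular viewer zoom.
- **Stride phase.** Sampling starts at pixel (0, 0) of the padded box. The
  phase is part of the estimator's definition; results are deterministic
  for fixed inputs and bit-identical under rigid translation of the cloud
  (the raster anchors on the bounding box, which translates with it).
- **Resource guard.** Rasters beyond `max_pixels` (default 4×10⁸) raise an
  error advising a larger pixel size rather than exhausting memory.
- **Degenerate inputs.** Empty clouds and non-positive radii are rejected
  at construction; a single sphere yields the exact disk area to raster
  precision at every orientation.

Defaults θ = 30° and stride = 20 are the method's operating point: the
stride can grow to ≈40 before the area estimate degrades appreciably
(measured max deviation from stride 3 is ≈0.3–0.4% on a 200-sphere cloud at
0.05 Å/pixel), and θ = 30° is indistinguishable from θ = 5° at the 1% level
on asymmetric fixtures.

## Structure ingestion

PDB files are read with gemmi. Per model (default: the first; an option
averages the CCS over all NMR models), altloc conflicts resolve to the
highest-occupancy conformer with ties broken by altloc letter, so parsing
is independent of record order. Elements come from columns 77–78, with a
name-based inference fallback. The default selection drops waters
(HOH/WAT), keeps non-water HETATM groups (chromophores and cofactors are
part of the envelope) and keeps hydrogens when present. Radii are a
Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å,
fallback 1.50 Å for unlisted elements, logged); the table is overridable
via JSON/CSV because crystallographic renderers differ in their radii and
the choice shifts the absolute area.

## Drift-time calibration

Reduced cross sections Ω′ = Ω/(z·√(1/μ)), μ = mM/(m+M), use nitrogen
(28.0134 Da) as the default buffer gas; the gas mass is a parameter. The
allometric fit Ω′ = A·t_D^B is unweighted ordinary least squares on
(ln t_D, ln Ω′) — exact on noiseless power-law data, invariant to calibrant
ordering, and under a drift-time unit change t_D → c·t_D the exponent B is
unchanged while A rescales by c^(−B). An optional linear flight-time
correction (coefficient × √(m/z) subtracted from t_D) is accepted and
defaults to zero. At least two calibrants with distinct drift times are
required. Calibrant tables are user-supplied data, not constants: which
published charge states and cross sections to use is an experimental
choice.

## Synthetic fixtures and oracles

The fixture generator emits minimal valid PDB files (residue UNK, chain A,
unit occupancy) for five shapes: a single atom, a two-atom dimer, a
collinear rod, a seeded uniform random cloud, and a helix. These emulate
the geometric regimes the estimator must handle — isolated disks, partial
overlap (exact lens-formula truth), strong elongation (orientation
dependence), and dense many-sphere unions. They deliberately do **not**
emulate real proteins: no realistic packing density, secondary structure,
element mix, or concave envelopes. Passing tests therefore demonstrate
that the area estimator and its bookkeeping are correct and convergent,
not that predictions match ion-mobility measurements for real structures;
that comparison requires user-supplied PDB entries and is exercised by a
dedicated test when such files are provided.

Two independent oracles back the rasterizer:

- **Analytic/polygonal union** — exact closed forms for one and two disks
  (lens formula); for more disks, shapely polygonal buffers at 256
  segments per quarter-circle (polygonalization error < 10⁻⁵ relative,
  negligible against the bounds tested).
- **Monte-Carlo** — uniform points over the padded bounding box, area =
  hit fraction × box area, binomial standard error, fixed seeds. Where the
  suite compares the rasterizer with the Monte-Carlo oracle across 100
  clouds at 3 standard errors per cloud, the family-level assertion allows
  the chance exceedances the binomial null predicts (at most two, with a
  hard 5-SE cap and a zero-mean bias check), since a per-cloud 3-SE bound
  over 100 independent draws fails with ≈24% probability for a perfect
  estimator.

## Reporting

Predicted-to-measured percentages are truncated (not rounded) to one
decimal, matching the convention of the reference values the reporter
reproduces. "Between PA and EHSS" uses the closed interval; proteins
lacking either reference are excluded from the fraction's denominator and
flagged n/a. Reporter output is deterministic (byte-identical CSV for
identical input).

## Problem sizes used in the distributed tests

Test and acceptance runs use few-atom analytic fixtures, 50-sphere clouds
(100 of them, 10⁶ Monte-Carlo points each), one 200-sphere cloud for the
stride sweep at 0.05 Å/pixel, a 12-atom helix for the θ comparison
(θ = 5° → 1,296 orientations), and 1,000 replicates of a 10-calibrant
noisy calibration. The full suite runs in well under a minute on one CPU;
the acceptance script in about half a minute.

## Known limitations

- Projection areas systematically underestimate measured TWIMS cross
  sections for real proteins (no gas scattering); the observed scale of
  that bias for fluorescent proteins is ≈5–6%.
- The orientation grid is not uniform on the sphere; for strongly
  anisotropic shapes at large θ the mean can differ from a
  uniform-orientation average by more than the compact-shape figures above.
- mmCIF input, assembly expansion and hydrogen addition are out of scope;
  coordinates are used exactly as given.
- Electrostatic-surface projection is an extension point only: the area
  operation accepts any sphere cloud, but no charged-surface construction
  is provided.
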