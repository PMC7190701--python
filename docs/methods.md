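# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic fixtures do and do not emulate, and the
design decisions taken where more than one convention exists in the field.

## Geometry conventions

The membrane normal is fixed to the box z-axis throughout; no bilayer-plane
fitting is attempted. This is the convention of planar-bilayer simulation
analysis and is exact for the fixtures generated here; for strongly undulating
membranes it biases tilt angles by the local surface slope.

Boxes are orthorhombic only. A CRYST1 record with non-90° angles is a hard
error: silently treating a triclinic cell as rectangular corrupts every
minimum-image distance downstream.

All centres of mass are mass-weighted (standard atomic weights). Helix axis
vectors use backbone atoms (N, CA, C, O) of the terminal four-residue windows;
a Cα-only mode exists but is off by default. For an ideal α-helix the
four-residue window CoMs sit slightly off-axis (3.6 residues/turn means the
window does not cover a full turn), so the first4→last4 vector approximates the
helix axis to about a degree — the same estimator applied consistently across
frames, so differences and time series are unaffected.

α and β are reported unfolded in [0°, 180°]: the two ends of a helix vector are
distinguishable, and poses with β > 90° are physically meaningful. The heme
tilt is folded into [0°, 90°] because a plane has no orientation sign. The heme
plane is fitted by principal axes of the centred four-nitrogen set (smallest
singular direction = normal), which is invariant under relabelling the
nitrogens, unlike three-point cross-product constructions.

The representative frame minimises the sum of squared mean-normalised
deviations among frames where *every* monitored parameter is within 1 % of its
windowed mean (joint application; if no frame qualifies the global minimiser is
returned and flagged). Means and standard deviations use the sample (n−1)
convention. Convergence is declared at the first non-overlapping window after
which all consecutive window-mean differences of the monitored angles stay
below the tolerance.

## Area per lipid

Each lipid is seeded by the in-plane projection of its head-group reference
atom (phosphorus by default) — the one atom the dialect guarantees per lipid.
Protein atoms whose z lies within ±10 Å (configurable) of the leaflet's mean
head-atom z are injected as additional seeds; this carves the protein footprint
out of the lipid areas and reproduces the depressed boundary-lipid APL seen in
protein–membrane simulations. Periodicity is handled by replicating all seeds
into the eight neighbouring images, which keeps every central polygon bounded
and makes the tessellation exactly conservative (Σ areas = lx·ly, relative
error at machine precision). Coincident seeds are perturbed by 10⁻⁶ Å with a
warning. The Monte-Carlo estimator assigns uniform random points to the nearest
seed under the minimum image; it converges to the exact areas with binomial
sampling error and serves as an independent consistency check, never as the
primary method. Fewer than 10⁴ samples is rejected as statistically unusable.

Boundary lipids are those with *any* atom within 5 Å (minimum image) of any
protein atom, classified per snapshot; the heme cofactor counts as protein by
default (configurable), since it is buried in the protein and the distance
criterion is about the protein surface. Statistics over a window pool all
per-lipid areas over the analysed snapshots (configurable stride).

## Order parameters

S_CD = ⟨(3 cos²θ − 1)/2⟩ with θ the C–H bond angle to ẑ, averaged over each
carbon's hydrogens, the selected lipids (default: non-boundary only, so the
protein's local perturbation does not contaminate the bulk profile) and frames.
Values are reported signed and as |S_CD|; |S_CD| = 0.5 is the ceiling for C–H
vectors perpendicular to a normal-aligned chain, and values above 0.5 indicate
geometry outside that regime.

## Electron density and thickness

Each atom contributes its atomic number of electrons to the 0.1 Å z-slab
containing it, with z measured from the per-frame lipid centre of mass; slab
counts averaged over the window are divided by (time-averaged cross-sectional
area × slab thickness). Partial charges are deliberately ignored — integer
atomic numbers are the standard convention for simulation density profiles and
keep the electron-count conservation exact (verified to 0.1 %, limited only by
binning). The z-range is padded by a few slabs so extreme atoms never land in
an edge bin, where peak detection is blind.

Bilayer thickness is the distance between the two dominant head-group density
maxima, each refined by a three-point parabolic fit; fewer than two peaks
separated by at least 10 Å raises an "interdigitated or degenerate profile"
error rather than returning a number. The head-group component defaults to the
head reference atoms (phosphorus); a phosphate-segment mode is a matter of
supplying a different component selection.

The local thickness map bins head atoms into an nx×ny grid (periodic), takes
mean upper minus mean lower head z per cell, fills empty cells from the nearest
populated cell up to a radius (default 3 cells) and leaves the rest NaN. Cells
whose column contains protein atoms between the leaflet planes are flagged
occluded, never silently interpolated.

## Dynamics

Superposition is the SVD Procrustes solution with the determinant correction
guaranteeing a proper rotation; collinear selections are rejected. RMSD series
fit and measure on the same selection, against a caller-supplied reference
(typically the energy-minimised start; no internal minimisation). RMSF is
measured about the window-mean structure after two alignment passes (align to
first frame, re-align to the running mean) — the standard scheme that removes
the arbitrary-reference bias; B = 8π²·RMSF²/3 converts to crystallographic
temperature factors. Because the alignment absorbs six rigid-body degrees of
freedom, the recovered RMSF of an N-atom isotropic Gaussian cloud is biased low
by roughly a factor √(1 − 2/N), comfortably inside the 2 % recovery tolerance
used in the tests.

## Synthetic fixtures

The generators emulate the study conditions of a CYP 2C9-like system in a
fluid phosphatidylcholine bilayer, which are the package defaults: pose
α = 74.8°, β = 119.9°, γ = 11.9°, heme tilt = 43.2°, insertion depth = 45.5 Å;
APL 66.1 Å², head-plane separation 37.1 Å; default chain tilt 39.2°, chosen so
the per-carbon order parameter equals the fluid-phase plateau |S_CD| = 0.200.
The acceptance script uses 17×17 lipids per leaflet (578 lipids, near the
~594-lipid production systems); tests use 4×4–8×8 leaflets for speed — the
constructions are exact at any size, so scale only affects statistics, not
correctness.

Key guarantees, and their limits:

- Leaflets are exact mirror images in z (jitter included; lipids carved under
  the protein are removed pairwise), pinning the bilayer CoM at z = 0 to
  machine precision — this is what makes the recorded insertion depth exactly
  recoverable. Real bilayers are only statistically symmetric.
- Each helix fragment is rotated so that its *actual* first4→last4 CoM vector
  points at exactly the requested angle, so the five pose parameters are exact
  by construction, not approximately encoded.
- Each chain carbon carries two hydrogens at right angles about the chain
  axis; the two-H average of cos²θ is then exactly sin²t/2 for chain tilt t,
  giving the closed form S_CD = (3 sin²t − 2)/4 independent of the random
  chain azimuths. The "isotropic" mode instead draws an independent random
  orthonormal C–H pair per carbon, for testing the S_CD → 0 limit.
- Toy lipids are geometric models: correct atom names, elements and head/chain
  topology, but no torsional statistics, no chain-length distribution and no
  head-group internal structure. Passing recovery tests therefore validates
  the estimators' geometry and statistics, not force-field realism; electron
  densities of toy systems have the right peak positions but not the absolute
  e/Å³ values of real phosphatidylcholine.
- Trajectory noise is iid Gaussian per coordinate: exactly the assumption of
  the RMSF = √3·σ recovery test, but unlike real dynamics it decorrelates C–H
  directions, so order parameters computed from noisy synthetic trajectories
  are attenuated below the construction target (the noise-free value is an
  upper bound).

All generators are deterministic for a fixed seed, and every fixture's
construction values are recorded in a `SyntheticGroundTruth` next to it, so
recovery tests never re-derive truth from the geometry.

## Pipeline

The pipeline validates every file and selection against the topology before any
stage runs. Numeric output formats are fixed (3 decimals for angles/Å, 4 for
S_CD, 5 for densities, 1 for B-factors), so identical inputs + config + seed
give byte-identical CSVs. A stage failure removes partial outputs and reports
the stage name. The run log records all parameters, the package version and
SHA-256 checksums of the inputs.

## Known limitations

Single lipid species per system (mixed compositions would need per-species
dialects); no curvature-aware normals; no binary trajectory formats (multi-model
PDB only, with per-MODEL CRYST1 supported for fluctuating boxes); boundary
classification and tessellation assume the minimum-image cutoff is below half
the shortest box edge and error out otherwise.
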