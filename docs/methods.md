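# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic generator does and does not emulate, and
the known limitations.

## Coordinate models and selections

Models are read through gemmi from PDB or mmCIF into a flat ordered atom
list. Author numbering is kept verbatim, because domain boundaries and
landmark residues are always cited in author numbering. Only model 1 of a
multi-model file is read (deposited cryo-EM models are single-model).
Hydrogens and alternate locations survive I/O, but every geometry, density
and SASA operation first reduces to heavy atoms with one conformer per
site (blank alt-loc preferred, then highest occupancy, then alphabetical
alt-loc); deposited cryo-EM models are effectively heavy-atom,
single-conformer objects, and SASA conventions are heavy-atom based.

Selections are conjunctions over chains, inclusive residue ranges, atom
names, elements and polymer class; an unset axis matches everything. This
is deliberately minimal — enough to express "16S rRNA phosphates of the
body domain" — and is the unit in which domain definitions are stored.

16S head/body boundaries ship as versioned YAML data
(`data/domains_16s.yaml`), not code constants: head = 3′ major domain,
residues 930–1390 in E. coli numbering, body = the rest of 16S. The
*Sulfolobus* scheme ports these with piecewise offsets anchored on
conserved landmarks (Sac G1307 ↔ E. coli G1338, offset −31; Sac G496 ↔
E. coli G530, offset −34). Boundaries of this kind are never uniquely
defined; measured inter-conformation angles shift by a few tenths of a
degree under reasonable boundary changes, which is why the data file is
the editable surface.

## Density simulation

Each heavy atom contributes an isotropic Gaussian
A·exp(−d²/2σ²) with σ = sigma_factor × resolution. The default
sigma_factor is 1/(π√2) ≈ 0.2251, the convention under which the kernel's
Fourier transform falls to 1/e of its maximum at spatial frequency
1/resolution — the same convention used by the common visualization tools'
"simulate map from atoms" command, so simulated maps are directly
comparable with that workflow. The alternative half-max convention
(≈ 0.187 × resolution) is available by setting `sigma_factor`. Amplitude is
the atomic number by default (a form-factor-free low-resolution
approximation adequate for correlation work); unit amplitude is available
for point-response tests. Kernels are truncated at 4.5σ (< 4·10⁻⁵ of
peak); the truncation is the reason integral invariance under rigid motion
is asserted at 1% rather than exactly.

Default simulation resolution is 3.5 Å — the regime in which map–model
correlation sweeps are typically run.

## Pixel-size calibration

The sweep treats pixel size as what it is physically: a metadata scale
factor of the camera frame. For each candidate s, the experimental map's
geometry is rescaled by s/nominal about the grid's geometric center (the
fixed point minimises apparent drift of a centered particle; the data array
is never touched), the simulated model map is trilinearly resampled onto
that geometry, and the correlation is computed over the mask where the
simulated map is positive. Both `about_zero` (Σab/√(Σa²Σb²), the common
default of map-fitting tools) and `about_mean` (Pearson) are provided,
because published sweeps do not always state which was used; the default
is `about_zero` with mask threshold 0.

Sweep endpoints are inclusive: 1.047–1.087 step 0.01 yields exactly the
five candidates {1.047, 1.057, 1.067, 1.077, 1.087}. The argmax optimum is
always a candidate; with `refine`, a parabola through the top three points
gives a sub-step vertex, clamped to the sweep range and falling back to
the argmax at the sweep edge or on a concave-up triple. Out-of-footprint
resampling yields 0 rather than an error (edge voxels are excluded by the
mask); a model that overlaps the map nowhere at any scale raises a
degenerate-input error, and `overlap_fraction` lets a mis-docked input
fail loudly before a sweep. Automated docking is out of scope: the model
must already sit in the map frame.

## Rigid-body motion

Superposition is the Kabsch SVD with the proper-rotation correction (sign
flip of the smallest singular direction). Pairing matches atoms by
(chain, residue number, insertion code, atom name); when insertion codes
disagree, a pair is still formed if exactly one candidate exists on each
side, otherwise the atoms are dropped. Alignment selections without
explicit atom names are restricted to one atom per residue (P for rRNA,
CA for protein), which makes pairing robust to side-chain differences
between independently built models. Collinear or coincident point sets are
rejected (the rotation about the line is undetermined).

Domain rotation is a two-stage fit: global superposition of conformation B
onto A on the reference selection, then a Kabsch fit of the mobile
selection of the superposed pair. The mobile rotation is reported as
axis–angle (angle in [0°, 180°]); the decomposition into swivel and tilt
is the quaternion twist–swing factorisation R = R_swing·R_twist about a
declared swivel axis. This convention is declared, not canonical: published
"tilt" values are sometimes angles between fitted domain axes instead.
Recomposition R_swing·R_twist = R is exact to machine precision and is the
invariant the tests assert (swivel² + tilt² has no metric meaning). The
recommended canonical swivel axis for a structure series is the rotation
axis of the full end-to-end head motion, computed once and then frozen, so
intermediate states decompose consistently. Angles are reported to 0.1°;
comparisons against whole-degree literature values should use ±1°.

Displacements are Euclidean distances per paired atom of the measured
selection after reference superposition, summarised as mean, max or
per-residue means; minimum distances are exact KD-tree nearest-neighbour
queries between heavy-atom selections.

## Solvent accessibility and burial

Shrake–Rupley with a deterministic golden-section-spiral point set
(default 960 points per atom) instead of random sphere sampling: results
are bit-reproducible across runs and platforms, which matters because the
burial statistic is a count of threshold crossings. A surface point on the
probe-expanded sphere (r_vdw + 1.4 Å) is accessible iff it lies outside
every neighbour's expanded sphere; the KD-tree neighbour radius
r_i + r_max + 2·probe provably captures every atom that could occlude any
point of sphere i, so pruning is exactly equivalent to the all-pairs scan
(and is tested to be bit-identical to it). The vdW table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å, plus common ions) ships as data; an element
without a radius raises a configuration error naming it.

The burial statistic counts C and S atoms of hydrophobic residues
(ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP) whose SASA, computed with the
full model as occluder (rRNA and heteroatoms included, waters stripped),
falls below 0.1 Å². Burial thresholds are a free choice the literature
rarely states; a relative mode (< 5% of the isolated-atom area) is
provided, and a residue-level count (residues whose counted atoms are all
buried) is reported alongside the atom count. The percent excess between
two models is 100·(n_a − n_b)/n_b; note that quoting the *larger* model as
baseline instead gives 100·(n_a − n_b)/n_a, a systematically smaller
number — published percentages should be checked against both conventions
before comparison.

## Synthetic generator

Fixtures are ideal helices: an alpha-helical CA trace (rise 1.5 Å, twist
100°/residue, radius 2.3 Å) and an A-form-like RNA P trace (rise 2.81 Å,
twist 32.7°/residue, radius 8.8 Å), with real residue names so selection
and burial logic run unmodified. The two-domain pair stacks two P-trace
"domains" (body residues 1..n, head n+1..2n in one chain) and applies to
the head, about its centroid, R = R_tilt·R_swivel about declared orthogonal
axes — the same order the twist–swing decomposition inverts, so generated
(swivel, tilt) values are recovered exactly in the noise-free case. The
default motion is an 18° swivel, the magnitude of a full chimeric→POST
head rotation; default maps use true pixel 1.057 Å labelled as 1.087 Å —
inside the standard sweep window — at 3.5 Å resolution.

The mislabelled map is generated by simulating at the true pixel size and
rescaling the header geometry about the map center, which reproduces the
magnification-error scenario exactly: self-consistent data in pixel units,
wrong Å-per-pixel in the header. Optional Gaussian voxel noise
(σ as a fraction of peak) and coordinate noise are drawn from a
`default_rng` seeded by the spec, so identical specs are byte-identical.

What the toys do *not* emulate: real molecular packing (helices are
geometric, not stereochemical), CTF effects, solvent background, map
anisotropy, or partial occupancy. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise models,
not performance on real micrograph-derived maps; on deposited data the
dominant error sources are docking quality and domain-boundary choice.

Default fixture sizes used by the tests and the acceptance script: 25–60
residues per domain for map work (grids of ~10⁵ voxels), 200 residues per
domain for noisy-rotation recovery — comparable to the ~460-nt head domain
of a real small-subunit rRNA, and enough lever arm for a 0.3 Å coordinate
noise to leave rotation estimates within a few tenths of a degree. The
P-trace is a worst-case geometry for rotations about its own axis (all
atoms sit on one cylinder), so these tolerances are conservative.

## Numerical conventions and degenerate inputs

- Maps are (z, y, x) in memory regardless of file axis order; voxel size
  and origin are (x, y, z) triples. MRC reading honours mapc/mapr/maps,
  cella/mx-my-mz, nstart and ORIGIN (nonzero ORIGIN wins over nstart).
  Writing emits MRC2014 mode 2.
- Trilinear resampling outside the source support returns 0.
- Correlation requires identical geometry (resample first); an empty mask
  or zero variance raises a degenerate-input error rather than returning a
  number.
- Rotation angles come from `scipy.spatial.transform.Rotation`; the
  180°-rotation corner case of the twist–swing split (undefined twist)
  returns an identity twist.
- PDB coordinates round-trip at 3 decimals; mmCIF at full precision.

## Limitations

- No rigid-body docking, flexible fitting, FSC, sharpening, or
  magnification-anisotropy (per-axis) estimation.
- The calibration reports a single isotropic scale.
- SASA is O(atoms × points × neighbours) single-threaded Python/NumPy;
  full 70S assemblies (~150k atoms) take minutes, not seconds.
- Burial counts depend on the radius table, probe, threshold and residue
  set; cross-study comparisons are only meaningful with the parameter set
  pinned (the provenance sidecar records it).
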