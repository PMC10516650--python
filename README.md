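# ribometrics

Quantitative structural analysis for cryo-EM studies of the ribosome (and
other large assemblies): given deposited atomic models and density maps,
the package

- **simulates density maps from atomic coordinates** — every heavy atom
  contributes an isotropic Gaussian with σ = 0.225 × resolution, amplitude
  ∝ atomic number;
- **calibrates the pixel (voxel) size of a map** by sweeping candidate
  values and cross-correlating the experimental map against a
  model-simulated map, the standard remedy for miscalibrated microscope
  magnification;
- **quantifies rigid-body domain motion** between two conformations:
  Kabsch superposition on a reference selection (e.g. 16S rRNA phosphates
  of the 30S body), axis–angle of the mobile domain (e.g. the 30S head),
  and a twist–swing split of that rotation into *swivel* (about the neck
  axis) and *tilt* (residual, toward the solvent side), plus per-residue
  displacements and minimum inter-selection distances;
- **computes the buried-hydrophobic-atom statistic** — Shrake–Rupley
  solvent-accessible surface area per atom with a deterministic spherical
  point set, counting hydrophobic-residue C/S atoms of the r-proteins whose
  SASA falls below a burial threshold in the context of the full assembly —
  the quantity used to compare thermophilic and mesophilic subunits.

It is aimed at structural biologists who have models/maps in hand (PDB,
mmCIF, MRC/CCP4) and want the measurements behind figures — "the head
swivelled 18°", "the pixel size is actually 1.067 Å, not 1.087 Å" — as
reproducible, scriptable computations.

## The core computations

**Pixel-size calibration.** For candidate pixel size *s* in a sweep
(default 1.047–1.087 Å in 0.01 steps), the experimental map's geometry is
rescaled by *s*/nominal about the map center (the data are never
interpolated), the model-simulated map is resampled onto that geometry, and
the masked cross-correlation CC = Σab / √(Σa²·Σb²) is evaluated. The curve
peaks at the true pixel size; optional parabolic refinement through the top
three points gives a sub-step optimum.

**Domain rotation.** With paired coordinate sets X, Y (one atom per residue:
P for rRNA, CA for protein), the Kabsch SVD gives the least-squares proper
rotation R and translation t minimising ‖RY + t − X‖². After superposing on
the reference domain, the mobile-domain fit yields R_head; writing its
quaternion q and a swivel axis **u**, the twist–swing factorisation
R_head = R_swing·R_twist (R_twist about **u**, R_swing about an axis ⊥ **u**)
defines swivel = angle(R_twist), tilt = angle(R_swing).

**Burial.** SASA_i = (accessible fraction of quasi-uniform points on the
probe-expanded sphere) × 4π(r_vdw,i + r_probe)², probe 1.4 Å; an atom is
buried when SASA < 0.1 Å². The excess of buried hydrophobic atoms of model
a over model b is 100·(n_a − n_b)/n_b.

## Worked example

Generate a seeded toy particle (a two-domain rRNA-like P-trace whose "head"
is rotated 18° in conformation B, plus a density map simulated at a true
pixel size of 1.057 Å but labelled 1.087 Å in the header), then recover both
numbers:

```sh
$ ribometrics -q synth --out-dir demo
$ ribometrics -q calibrate --map demo/map_mislabelled.mrc \
      --model demo/model_a.pdb --refine
candidate_voxel correlation
1.0470  0.7354
1.0570  0.9732
1.0670  0.7404
1.0770  0.4435
1.0870  0.3198
optimum_voxel   1.0571
optimum_mode    parabolic
nominal_voxel   1.0870
```

The correlation peaks at 1.057 Å — the pixel size the map was actually
generated at — and parabolic refinement lands within 0.002 steps of it;
the header's nominal 1.087 Å would have been ~3% off.

```sh
$ printf 'residue_ranges: [[1, 60]]\n'   > body.yaml
$ printf 'residue_ranges: [[61, 120]]\n' > head.yaml
$ ribometrics -q motion --ref-model demo/model_a.pdb \
      --mobile-model demo/model_b.pdb \
      --reference-sel body.yaml --mobile-sel head.yaml --swivel-axis 0,0,1
angle_deg       18.0
axis    0.0000,0.0000,-1.0000
swivel_deg      18.0
tilt_deg        0.0
mobile_rmsd_A   0.001
mobile_n_pairs  60
reference_rmsd_A        0.000
reference_n_pairs       60
```

The constructed 18° head swivel is recovered exactly (the axis sign is
negative because the report maps conformation B back onto A). The same
`motion`, `displace`, `mindist` and `burial` subcommands run unchanged on
deposited mmCIF models; `calibrate --nominal` overrides a map header whose
pixel size was already corrected. The library API (`ribometrics.*`) exposes
every step individually.

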