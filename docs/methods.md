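# Methods notes

This note records the model, the numerical choices and the open design
decisions behind `optmorph`, and what the synthetic tests do and do not
demonstrate about real data.

## Coordinate and unit conventions

Right-handed axes, µm everywhere after load. A volume grid is indexed
`grid[i, j, k]` with the voxel *centre* at `origin + (i·sx, j·sy, k·sz)`,
0-based. TIFF stacks carry no reliable spacing metadata, so a spacing
override is mandatory for TIFF; NRRD/MHD spacing is read from the header.
Dark-stain polarity (signal = low grey, as for NBT/BCIP precipitate under
transmitted light) is the internal convention; bright-stain volumes are
inverted on load, which makes all downstream rules polarity-symmetric.

## Expression-domain segmentation

The "last grey value showing the domain" is operationalized as the highest
scanned threshold whose largest 26-connected component of {grey ≤ T} is
*detectable*: at least `v_min` voxels (default 50 — smaller components are
indistinguishable from staining speckle) and at most `f_max` of the tissue
mask (default 0.5 — beyond that the "domain" is really the whole tissue).
The scan uses `n_levels` evenly spaced levels over the masked grey range
(default 256, a histogram-resolution analogue of interactive threshold
sliders). The segmentation rule fixes the thresholds at 1/3
(high expression) and 2/3 (moderate) of G_last; with a graded stain this
makes the high core strictly nested inside the moderate domain.

Domain volume is reported from the voxel count (default); the
marching-cubes mesh volume is available as an independent estimator and
agrees within a few percent for blobs larger than ~10 voxel radius.
`isosurface` applies a 1-voxel Gaussian pre-smoothing by default: marching
cubes on near-binary grids otherwise inflates surface area by ~8%
(staircase bias), while the smoothed surface reproduces an analytic
sphere's area within 0.5% and its volume within ~1.5%. Set
`smooth_sigma=0` for the raw surface.

Whether the scan should run per organ or per embryo is not fixed by the
method; `optmorph` scans per organ volume, matching the per-limb workflow.

## Thin-plate splines and semilandmark sliding

The 3D TPS uses kernel U(r) = r (the standard 3D morphometrics
convention). With this kernel the quadratic form w'Kw is conditionally
*negative* on the affine-orthogonal subspace, so the bending energy is its
negation, clipped at zero against roundoff; it vanishes exactly for affine
maps and is invariant under rigid motions of the target. (It is *not*
invariant under general affine transforms of the target — a shear changes
the non-affine cost — so only rigid invariance is asserted in tests.)

Sliding follows the bending-energy formulation: with B the bending-energy
matrix of the consensus (the negated top-left block of the inverse TPS
system matrix), the energy of consensus → specimen is tr(X'BX), and each
semilandmark moves along its tangent — curve points along the
predecessor→successor central difference (one-sided at open curve ends),
surface points in the tangent plane of the local normal (nearest mesh face
normal when a mesh is given, otherwise the smallest principal axis of the
neighbour cloud) — by the exact minimizer of that quadratic. A tiny ridge
(1e-12 · tr G) stabilizes near-singular tangent systems. Because the
minimizer is exact, the energy never increases within a sliding pass;
anatomical landmarks carry no sliding degrees of freedom and are returned
bit-identical.

The schedule is 3 outer passes of (superimpose → slide) plus a final
superimposition; this is the common fixed small schedule, and the
per-pass energies are recorded in `GPAResult.bending_trace`. The
`residual_trace` records the *final* superimposition phase only: sliding
optimizes bending energy, not the Procrustes residual, so a trace spanning
slide steps would not be monotone.

Template transfer is TPS warp on the fixed (anatomical + curve) landmarks
followed by exact closest-point projection onto the target surface
(vectorized point-triangle distance, ties broken by lowest face index for
determinism). Digitization repeatability uses the conventional 0.05 mm
(50 µm) deviation bound between two trials.

## Procrustes analysis

Partial Procrustes superimposition: every configuration is centered and
scaled to unit centroid size; rotations are proper only. Left-side
configurations must be mirrored to the right-side convention before
pooling (a reflection step inside GPA would erase chirality). The
consensus is initialized from the first specimen; order independence of
the converged consensus is a property test. Convergence is a relative
residual change below 1e-14 (defaults max_iter = 1000) — tight, because
the consensus moves much more slowly than the residual. Outlier screening
uses squared full-Procrustes distance to the consensus with the
Q3 + 1.5·IQR rule.

## Statistics

PCA is on the covariance of Procrustes coordinates (no correlation
scaling). PLS centers each block, scales covariance by n−1, and takes %
covariation from squared singular values. The permutation test permutes
rows of the second block only and reports (1 + #{perm ≥ obs})/(n_perm + 1),
so p is never exactly zero; the PLS permutation statistic is the RV
coefficient. Default 10 000 permutations (999 in the bundled pipeline
configs for speed). Welch's unequal-variance t is used for all two-sample
comparisons, two-sided. Mann-Whitney U enumerates the exact null only for
tie-free pooled samples of ≤ 12 values, otherwise the tie-corrected normal
approximation with continuity correction — this bounds runtime
deterministically. The regression R² between domain volume and organ size
pools genotypes within an organ type (one trend line per organ type);
per-genotype regressions remain a caller choice.

## Synthetic generator

The bud is a smoothly deformed icosphere: proximo-distal length
450 + 250·stage µm, antero-posterior half-width 300 µm with a smooth
anterior-biased asymmetry 0.15·stage, dorso-ventral half-height 260 µm.
The mutant group applies the group effect as PD shortening (−18% per unit
effect), DV thickening (+20%) and loss of AP asymmetry — i.e. a younger,
thicker bud. The expression domain is a distal-rim shell: voxels within
60 µm of the surface and beyond 70% of the PD extent are the moderate
shell (grey 90), a 34 µm/78% subset is the strong core (grey 30), tissue
sits at 150 and background at 255; the mutant thickens and extends both.
The grey anchors are chosen so the 1/3–2/3 rule lands between strata, which
makes threshold-rule tests analytic. Defaults: landmark jitter and voxel
noise SD 2 (µm / grey), spacing 10 µm (12–16 µm in tests and the
acceptance study to keep grids small; results are spacing-robust for these
geometries).

Voxelization is an exact voxel-centre inside test (z-column parity fill
with crossing deduplication); surface-touching voxels are counted by their
centre only, which keeps voxel-count volumes unbiased (analytic ball
within 2%).

What the generator does **not** emulate: imaging physics (projection
artefacts, depth-dependent attenuation), intensity calibration drift
across scans, staining chemistry variability, or biologically realistic
growth fields. Passing the synthetic end-to-end tests therefore shows the
*pipeline* recovers planted geometric/volumetric effects under additive
noise — not that any particular biological contrast will be detectable.

## Problem sizes

The test suite and acceptance study run at deliberately small scale chosen
as representative rather than exhaustive: grids of roughly 50–70 voxels
per axis (12–16 µm spacing), 41-landmark limb schemes, 2 × 10 specimens for
the end-to-end study, 999 permutations per test and 200 replicates for the
type-I-error calibration.

## Deposited-data reanalysis

`optmorph.pipeline.analyze_deposited_tables(dir)` recomputes RV, PLS1 %
covariation, per-period Welch t and pooled R² from coordinate/size tables
in the documented CSV dialect (`<fore|hind>_limb_procrustes.csv`,
`<fore|hind>_domain_procrustes.csv` with `specimen_id` + coordinate
columns; `sizes.csv` with `limb_type, period, genotype,
limb_centroid_size_um, dusp6_volume_um3`). The source archives ship as
zip/Excel supplementary downloads and are not redistributed; conversion to
these CSVs is documentation, not code. The "long-centroid size" column
present in the deposited files has no documented definition and is ignored.

## Known limitations

* No missing-landmark estimation; configurations must be complete.
* Sliding is against the consensus (not the template); software packages
  differ here and small numerical differences with template-sliding
  implementations are expected.
* The threshold scan assumes a single dominant stained structure per
  masked volume; multi-domain co-expression analysis is out of scope.
* NRRD support covers raw encoding only (no gzip), and DICOM/proprietary
  scanner formats are not read.
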