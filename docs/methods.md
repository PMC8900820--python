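# Methods

This note records the models, conventions and numerical choices behind
`polyclust`, in the spirit of a software methods section: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Reflection data model

A data set is one crystal's unique reflections: Miller indices with
structure-factor amplitudes F and standard uncertainties σF, a unit cell,
a Laue group and a resolution range. Amplitudes, not intensities, are the
stored quantity; an intensity column in the HKL text dialect is converted
on read by F = √max(I, 0), σF = σI/(2F). This truncation is not a Bayesian
(French–Wilson) treatment; for the clustering purpose only the ranking and
correlation of amplitudes matter, so the simpler rule suffices. Correlation
can optionally be computed on squared amplitudes (`cc_on="intensities"`)
since upstream pipelines differ in which quantity they correlate; the two
choices give nearly identical trees at the noise levels studied here.

**Symmetry.** Laue groups are explicit finite sets of 3×3 integer matrices,
hard-coded for −1, 2/m (unique axis b), mmm and 4/mmm and closed under
composition; every group contains the inversion, so Friedel mates are
equivalent. The asymmetric-unit representative of an index is the
lexicographically greatest member of its orbit — deterministic,
group-agnostic, and free of per-group boundary tables. Internally indices
are packed into order-preserving 64-bit integer keys (supporting |h| <
2048), which makes orbit reduction, uniqueness and intersection cheap
vector operations.

**Merging equivalents** combines observations within an orbit by the
inverse-variance-weighted mean, with σ_merged = (Σ σᵢ⁻²)^(−1/2); Fisher
information is conserved per orbit.

**Completeness** is the fraction of theoretically possible unique ASU
indices in a resolution shell that were observed. The denominator is an
exhaustive enumeration of the hkl box bounded by |hᵢ| ≤ |aᵢ|/d_min (an
exact bound), filtered to the shell with relative tolerance 10⁻⁶ and mapped
to the ASU. Exact but O(box volume): appropriate for desk-scale resolution
limits, not for enumerating a virus crystal at 1 Å.

## Two-factor clustering

**Coarse stage.** The distance between two cells is the Euclidean norm of
(Δa, Δb, Δc, w·Δα, w·Δβ, w·Δγ). The angle weight w defaults to
0.25 Å/degree so a 4° angle difference counts like 1 Å of edge; for the
tetragonal crystals this package targets, all angles are 90° and w is
inert. Cells are assumed consistently indexed — no Niggli/G6 reduction or
re-indexing-ambiguity handling is attempted. Ward linkage on this matrix,
cut at a height (Å) or into a requested number of clusters, gives the
coarse partition.

**Fine stage.** Pairwise Pearson CC over the intersection of observed
unique indices; pairs sharing fewer than `min_common` reflections (default
30 — Pearson on a handful of points is noise) are flagged rather than
scored, and their distance is set to the matrix maximum plus a small
epsilon so the tree remains connected while such pairs merge last. Sets
below `min_completeness` (default 0.70) are excluded before CC and
reported as unassigned with the reason. The penalty variant multiplies CC
by the matched fraction w = 2·n_common/(nᵢ+nⱼ) inside the radical,
d = √(1 − CC·w), which lets usable trees be built from sets at much lower
completeness; it is off by default.

**Ward linkage** is implemented directly as the Lance–Williams recurrence
with Ward coefficients on squared distances,

    d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖ d²(i,j)] / (nᵢ+nⱼ+nₖ),

with merge heights reported as the square root, so heights live on the
same scale as d = √(1−CC) and cut values are directly interpretable.
Among equal-height candidate merges the lexicographically smallest node
pair merges first, making output deterministic. Ward admits no inversions,
so heights are non-decreasing and cutting at any height is well defined.
The implementation is verified against an independent reference
implementation (merge heights and cophenetic matrices to 10⁻⁹).

**Cut heights.** Dendrogram heights are not normalised. A useful property
of Ward-on-√(1−CC) at this noise structure: within a homogeneous subgroup
all pairwise distances concentrate near √(1−CC_within), and heights stay
near that value as the subgroup assembles, then jump sharply when two
subgroups (cross-CC much lower) merge. With the default study conditions
(within-CC ≈ 0.95, between ≈ 0.5) the within-heights sit near 0.23 and the
between-merges above 1.3, so the default cut height of 1.0 separates
subgroups robustly across a wide range of subgroup sizes. Automatic cut
selection is deliberately out of scope — on real data the cut is chosen by
inspecting the derived structures; count-based cuts are provided for when
the number of states is known.

## Cluster merging

Per-set scale factors are fitted by alternating least squares: given
current per-index means ⟨F⟩ᵢ, each scale kⱼ minimises Σᵢ(F_ij − kⱼ⟨F⟩ᵢ)²;
means are then recomputed from scaled amplitudes; convergence when the
largest relative scale change is below 10⁻⁸ (cap 20 sweeps); scales are
normalised to geometric mean 1. The merged amplitude per unique index is
the inverse-variance-weighted mean of the (scaled) member amplitudes.
R_merge = Σ|F − ⟨F⟩| / ΣF over multiply-observed indices uses the
conventional *unweighted* mean — a deliberate asymmetry with the weighted
merged output, matching how the statistic is normally quoted. R_merge on
amplitudes from simulated data is not comparable to intensity-based
R_merge values from real pipelines. The merged cell is the unweighted mean
of member cells; the resolution range spans the members.

## Minimum-volume enclosing ellipsoids

The MVE of a Cα point cloud is computed by Khachiyan-style barycentric
ascent with Wolfe–Atwood away steps: point weights u are pushed toward the
worst-violating point or pulled off an over-weighted support point until
the relative violation is below `tol` (default 10⁻⁶), with Sherman–Morrison
rank-1 updates of the inverse and a periodic full refresh for stability.
Away steps give linear convergence where the plain multiplicative update
is sublinear. Degenerate clouds — a single point, collinear or coplanar
sets, anything with affine rank < 3 — are solved exactly in their affine
subspace and lifted back with ε·I (ε = 10⁻⁴ Å²) on the flat directions, so
every cluster yields a drawable, finite-volume ellipsoid whose in-plane
shape is still the true MVE. Reported per ellipsoid: center, shape matrix
A (membership (p−c)ᵀA(p−c) ≤ 1), volume (4π/3)/√det A, and semi-axes.

## Ensemble diagnostics

Cα traces are read from PDB ATOM records by fixed-column parsing: one Cα
per residue, highest-occupancy altloc first, ties broken by altloc
identifier; missing residues (unresolved loops) are simply absent; a
malformed record raises an error naming the line. Structures are
superposed by least-squares rigid (Kabsch) superposition over shared
residues — a rigid substitute for flexible alignment, adequate for
mostly-rigid structures whose differences are confined to short segments.
For collinear point sets the rotation is not unique; the SVD construction
still returns one optimal proper rotation. The displacement profile is,
per residue, the maximum pairwise Cα distance across the ensemble ("the
largest value per residue"); the ellipsoid diagnostic encloses the Cα
positions of each cluster at one residue, and clusters count as separable
states when the ellipsoids are small relative to the spacing of their
centers.

## Synthetic data

The generator emulates a multi-crystal collection from a tetragonal
protein with cell polymorphs and conformational substates:

- **Cell groups** (default: a = 111.4 Å carrying 3 amplitude subgroups
  with weight 118/146, and a = 114.5 Å carrying 2 subgroups with weight
  28/146; c ≈ 52 Å; Laue group 4/mmm) define the coarse structure. Set
  counts are apportioned deterministically by largest remainder so every
  subgroup is populated.
- **Master amplitudes** per cell group are F = √I with I ~ Exp(1) — a
  Wilson-like intensity distribution, the simplest physically flavored
  choice. The clustering method only sees ranks and correlations, so
  distributional fidelity beyond that is not attempted.
- **Subgroups** independently redraw a fraction ρ of the master
  amplitudes. Two sets from different subgroups therefore share an
  expected (1−ρ)² of their signal.
- **Per crystal**: cell = group cell + N(0, σ_cell²) on a and c (a = b
  enforced), an arbitrary overall scale (log-normal, σ = 0.1), observed
  F = F·(1+N(0, σ_F²)) clipped at 0, σ_obs = σ_F·F + floor, and a
  uniform-random kept fraction drawn from the completeness range (default
  0.8–1.0). Resolution limit d_min = 3.0 Å (≈ 6.9·10³ unique reflections
  per crystal) keeps full-scale runs at desk scale; the clustering
  behaviour is unchanged at higher resolution, only slower.
- A single seeded random stream with documented draw order (masters, then
  subgroup redraws, then per-set draws) makes every run bit-reproducible.

Under this scheme the expected full-overlap Pearson CC between
same-subgroup crystals is CC_within = v/(v+σ_F²) with
v = Var(F)/E[F²] = 1 − π/4 ≈ 0.2146, and between subgroups
CC_between ≈ (1−ρ)²·CC_within. The defaults σ_F = 0.1063 and ρ = 0.2746
are calibrated analytically from these forms to the study conditions
CC_within ≈ 0.95 and CC_between ≈ 0.5. Note that pairs simulated from one
seed share the master draw, so the master contributes a common random
factor to all CCs of that run; statistical checks of the closed forms
replicate over seeds, not pairs.

The coordinate generator plants a shared 200-residue backbone trace with
one mobile segment (default residues 139–146): each cluster displaces the
segment along a well-separated cluster-specific direction with magnitude
ramping linearly to `displacement` (default 3 Å) at the last mobile
residue, plus isotropic N(0, 0.1² Å²) jitter per coordinate modeling
refinement noise.

**What the synthetic benchmarks show — and don't.** Exact recovery of the
planted partition (ARI 1.0 at 146 crystals; ARI ≥ 0.9 for every seed at 40
crystals over 20 seeds) demonstrates that the pipeline implements the
scheme correctly and that the distance/linkage/cut machinery separates
states whose CC contrast matches the study conditions. Real data add
effects the generator omits: resolution-dependent noise and Wilson-B
differences between crystals, non-isomorphism that correlates cell and
amplitude changes, radiation damage, misindexing, and partial wedges with
structured (not uniform-random) incompleteness. Passing these benchmarks
therefore validates the software, not the universal adequacy of a fixed
cut height on arbitrary real data.

## Defaults at a glance

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `angle_weight` | 0.25 | Å/degree | 4° ≈ 1 Å; inert for tetragonal cells |
| `min_completeness` | 0.70 | fraction | CC needs a reasonably complete set |
| `min_common` | 30 | reflections | small-sample Pearson is unstable |
| `cut_height` (fine) | 1.0 | √(1−CC) | between within-(≈0.23) and between-(≳1.3) heights |
| cell cut | 2.0 | Å | between cell jitter (≈0.2) and polymorph gap (≈3.5) |
| MVE `tol` | 10⁻⁶ | relative | volume accurate to ~6·tol |
| MVE ε | 10⁻⁴ | Å² | drawable ellipsoids for flat clouds |
| `sigma_f` | 0.1063 | relative | targets CC_within ≈ 0.95 |
| `rho` | 0.2746 | fraction | targets CC_between ≈ 0.5 |
| `sigma_cell` | 0.1 | Å | indexing-level cell scatter |
| `dmin` | 3.0 | Å | desk-scale problem size |

## Known limitations

- Only Laue groups −1, 2/m, mmm and 4/mmm are built in; others are
  rejected with a clear error. No space-group logic, systematic absences,
  or anisotropic scaling.
- No re-indexing ambiguity resolution: all inputs must be consistently
  indexed.
- The completeness denominator enumerates the full hkl box — exact but not
  intended for very large cells at very high resolution.
- Scaling is a single multiplicative factor per set (no resolution- or
  B-factor-dependent terms).
- The fine-stage cut height is a user decision; no automatic model
  selection is provided.
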