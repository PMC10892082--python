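# Methods

## Model

The chain is n tangent hard spheres: diameter σ, bond length fixed to σ
exactly, so consecutive spheres touch and the hard-core condition applies to
all pairs with |i−j| ≥ 2. A square-well attraction of range R_att = 1.6σ and
depth ε acts between the same non-adjacent pairs, so the total energy is
−ε × (number of non-adjacent pairs within R_att) — a non-positive integer in
units of ε. Defaults: n = 80, σ = b = 3.81 Å (the mean Cα–Cα distance of a
trans peptide), ε = 1.

## Monte Carlo

Four move types are drawn with equal probabilities, all of which preserve
bond lengths to machine precision because they are rigid rotations or end
re-grafts:

- **crankshaft** — rotate one interior bead about the chord between its two
  neighbours by an angle uniform in (−π, π]. The conditional measure of the
  fixed-bond ensemble on this circle is uniform, so the move is symmetric.
- **endpoint** — regrow an end bead in a direction uniform on the sphere at
  distance b from its neighbour.
- **reptation** — remove a bead from one end and regrow it at the other end
  in a uniform direction (slithering snake).
- **pivot** — apply a rotation uniform over SO(3) (quaternion method) to the
  shorter side of a randomly chosen interior bead. Rotating the shorter side
  halves the expected cost without changing the sampled distribution.

Candidates violating the hard core are rejected outright (relative tolerance
1e−9 on σ, absorbing rotation round-off on exactly tangent pairs); otherwise
the standard Metropolis rule applies. At infinite temperature every
self-avoiding candidate is accepted, which samples uniformly over tangent
self-avoiding chains. Correctness of the whole kernel stack is established
two ways in the tests: the θ distribution of short chains matches plain
rejection sampling (an exact oracle), and the contact probability of the
three-bead chain matches its closed-form Boltzmann value.

Energy updates are move-local: single-bead moves and reptation touch O(n)
pairs; a pivot touches only moved×fixed cross pairs, since rigid rotation
leaves intra-segment distances unchanged. At n = 80 these incremental
updates in compiled (numba) loops outperform a cell list, whose bookkeeping
only pays off for much larger chains; the running contact count is asserted
against a full recount in the tests.

## Replica exchange and WHAM

The default temperature ladder follows the meshes 0.3–0.5 (step 0.02),
0.5–1.0 (step 0.05), 1.0–4.0 (step 0.2) in reduced units k_BT/ε — 36 rungs,
finer where the specific heat varies fastest. Neighbour swaps use
min(1, exp(Δβ·ΔE)), attempted every `swap_stride` sweeps (default 100; a
sweep is n move attempts), alternating even and odd pairs. Desk-scale runs
thin the ladder (every other rung below 0.5, then 0.1 and 0.5 spacings → 17
rungs) and shorten the swap stride to 10 so replicas still exchange often
within short runs.

WHAM iterates the standard self-consistent equations for the density of
states on the discrete energy levels (no binning is needed for a square
well), in log space with logsumexp, until the per-run free-energy shifts
change by < 1e−8; non-convergence raises with the residual. The specific
heat per bead is C_V/Nk_B = (⟨E²⟩−⟨E⟩²)/(nT²) by reweighting. The estimator
is validated against the closed-form two-level system and against the direct
fluctuation estimator at single temperatures.

## Geometry conventions

- Angles are degrees externally, radians internally. θ is measured at the
  middle point of a triplet; straight = 180°. The dihedral μ is signed,
  right-handed about the p2→p3 axis (the field has no single convention; a
  mirrored convention would flip the sign of μ everywhere).
- A triplet is collinear (R = ∞, X = 0) when 4A/(abc) < 1e−12 Å⁻¹; a quartet
  is coplanar when the determinant of the equidistant-centre system falls
  below the same relative threshold. These are robust infinite-radius
  detectors, not physical parameters.
- Circumsphere centres come from Cramer's rule on the 3×3 system
  2(p_i−p_1)·c = |p_i|²−|p_1|²; the centre's equidistance residual is below
  1e−9 relative in tests.
- Nearest non-local contacts: for each i, the j minimising the distance
  subject to |i−j| ≥ min_sep (default 3); ties break to the smallest j.
  Monomers of chains shorter than 2·min_sep that admit no partner are
  omitted. The near/far flag uses 6 Å, where the protein radial distribution
  function has a pronounced minimum.
- End monomers have no interior triplet and are excluded from local-radius
  statistics (NaN in per-residue tables).

## Histogram modes and fit windows

Characteristic scales are modes of fixed-width histograms anchored at zero:
0.02 Å bins for the local radius, 0.04 Å for the non-local contact distance
— fine enough to resolve the 0.01-Å precision of the reported scales while
tolerating sampling noise. The local-radius histogram ignores values above
30 Å: the near-straight tail is unbounded (R → ∞ as θ → 180°) and cannot
contain the mode. Power-law slopes are least-squares fits of log P versus
log X over the dimensionless window Xb ∈ [0.05, 0.5]; the asymptotic
exponent statement holds for Xb ≪ 1 only, and the correction term grows as
(Xb)², so the window upper edge trades bias against statistics and is a
configuration parameter.

## Synthetic data

The generators define the study conditions rather than emulate any specific
dataset:

- d-dimensional fixed-bond walks (uniform directions via normalised
  Gaussians) realise p(θ) ∝ sin^(d−2)θ exactly; the constrained walk pins
  the first two steps to a plane and frees the last, which lowers the
  quartet CDF exponent below the plain-3D value 1 (measured ≈ 0.8).
- The ideal helix uses the canonical α-helix Cα parameters — 1.5 Å rise,
  2.3 Å radius, 100° twist per residue — implying a bond of 3.83 Å and
  θ ≈ 91.8°, close to the helical geometry of real residues; its nearest
  non-local contact sits at separation 3 and ≈ 5.05 Å.
- Sheets are planar zigzag strands with θ = 120° stacked at 4.8 Å spacing (a
  fixture calibration placing cross-strand contacts in the hydrogen-bonded
  β range, not a physical claim), joined by exact-bond turn constructions;
  long parallel-topology turns detour out of the sheet plane.
- These fixtures carry ground-truth labels but no hydrogen-bond physics,
  side chains or sequence content: tests passing on them demonstrate the
  statistics pipeline, not biological realism. Loop-region geometry in real
  proteins (bimodal local radii) has no generative description here; loop
  labels on fixtures mark turns only.

## Protein ingestion

Cα traces are read from PDB-format files with gemmi (first model,
highest-occupancy altloc). Chains carrying backbone atoms must carry N, CA
and C for every residue; CA-only trace files (e.g. this package's own
output) are accepted as traces. A consecutive Cα distance above 4.5 Å is a
chain break: reject (default) or keep the longest contiguous segment.
Peptide-bond isomers are classified from the consecutive Cα distance with a
3.4 Å threshold — the midpoint of the trans (≈3.81 Å) and cis (≈2.95 Å)
populations — or from the actual ω dihedral when full backbones are present
(|ω| ≤ 90° → cis). Secondary-structure classes come from DSSP output files
(H → alpha by default, configurable to HGI; E → beta; else loop). DSSP is
not reimplemented; the (θ, μ)-window fallback exists only so the pipeline
runs without external tools, warns when used, and is not a DSSP substitute
in any validated sense. Per-class length scales enforce the pure-triplet
rule: a triplet counts for a class only when all three residues carry that
label.

## Problem sizes

Power-law fits use 10⁶ walks; distribution tests 10⁵. The
infinite-temperature ensemble samples 2000–10000 snapshots of the 80-bead
chain, 10–20 sweeps apart after 2000 burn-in sweeps. The low-temperature
ensemble uses the thinned 17-rung ladder, ~4×10⁴ sweeps per replica, with
snapshots at k_BT/ε = 0.3 taken every 10 sweeps after one quarter burn-in.
These sizes resolve the histogram modes to their bin width; the specific
heat of the collapse transition, by contrast, needs orders of magnitude more
sampling to localise its peak, so the WHAM pipeline is validated on the
exactly solvable two-level system and the polymer C_V curve is reported
without a peak-location claim at desk scale.

## Known limitations

- The infinite-temperature local-radius distribution measured here decreases
  monotonically from the hard-sphere floor b/√3 ≈ 2.20 Å, so its histogram
  mode sits at 2.21–2.25 Å for any reasonable bin width, and the nearest
  non-local contact mode sits at 7.1–7.3 Å. Published characteristic scales
  for this ensemble differ (2.47 / 7.72 Å); the discrepancy survives every
  binning convention we scanned and an exact-oracle validation of the
  sampler, and is documented rather than tuned away.
- Single-process execution; replicas run sequentially within a block (an
  optional thread pool would not change results).
- No finite-size scaling across n, no knot detection, no continuum-tube
  thickness machinery.
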