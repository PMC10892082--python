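# tangentchain

Geometry statistics and Monte Carlo for comparing a generic coarse-grained
polymer — a chain of tangent hard spheres with a short-range square-well
attraction — against the geometry of protein backbones.

## Who this is for

Researchers in polymer physics and structural bioinformatics who want to
quantify how a chain molecule organizes itself locally and non-locally:
how tightly it bends, how close distant parts of the chain approach each
other, and how those two length scales differ between a featureless polymer
and the helix/sheet architecture of proteins.

## The model and the statistics

**Tangent-sphere chain.** n hard spheres of diameter σ with the bond length
constrained to σ, so consecutive spheres touch. Non-adjacent pairs
(|i−j| ≥ 2) interact through a square well: energy −ε when their distance is
≤ R_att = 1.6σ, zero beyond, infinite inside the hard core. Sampling uses
crankshaft, reptation, endpoint and pivot moves with Metropolis acceptance;
replica exchange over a ladder of reduced temperatures k_BT/ε equilibrates
the collapsed low-temperature phase, and the weighted histogram analysis
method (WHAM) turns the multi-temperature energy traces into a density of
states and the specific heat per bead C_V/Nk_B.

**Geometry kernels.** For any ordered chain of points (simulated chains,
random walks, or protein Cα traces with bond b ≈ 3.81 Å):

- the three-body radius — the circumcircle radius R = abc/4A of a point
  triplet; for consecutive triplets this is the local radius of curvature
  R = b/(2 cos(θ/2)), where θ is the bond-bending angle (θ = 180° is locally
  straight, and tangency forbids θ < 60°);
- the four-body radius — the circumsphere radius of a quartet, from the
  linear system for the equidistant center; coplanar quartets are flagged
  infinite;
- cumulative distributions of the inverse radius X = 1/R and their log-log
  slopes: for d-dimensional fixed-bond walks, p(θ) ∝ sin^(d−2)θ implies
  CDF(X) ∝ X^(d−1) at small X — exactly (Xb/2)² in three dimensions;
- (θ, μ) maps of bond-bending versus dihedral angles;
- nearest non-local contact maps: for each monomer i the closest monomer j
  with |i−j| ≥ 3, flagged near/far at 6 Å;
- characteristic length scales: histogram modes of the local radius and the
  nearest non-local contact distance, per structural class if labels are
  present.

**Inputs.** Everything runs on synthetic data (d-dimensional fixed-bond
walks, uniform ball points, ideal α-helix / β-sheet Cα traces with
ground-truth labels). Real protein chains can be ingested from PDB-format
files (Cα traces, cis/trans classification from the consecutive Cα distance)
with per-residue classes parsed from DSSP output.

## Worked example

```python
import numpy as np
from tangentchain import SquareWellModel, run_infinite_temperature
from tangentchain import length_scale_modes
from tangentchain.conformation import Conformation
from tangentchain.pipeline import walk_triplet_slope

# power-law slope of the inverse-circumradius CDF of two-step 3D walks
print(round(walk_triplet_slope(1_000_000, seed=1)["slope"], 4))
# 2.0093  -> the predicted exponent d - 1 = 2

# characteristic length scales of the 80-bead tangent chain at T = infinity
model = SquareWellModel(n=80)   # sigma = b = 3.81 A, R_att = 1.6 sigma
samples = run_infinite_temperature(model, 2000, seed=7)
confs = [Conformation(c, bond_length=model.sigma) for c in samples]
print(length_scale_modes(confs))
# (2.31, 7.46)  -> local-radius mode just above the hard-sphere floor
#                  b/sqrt(3) = 2.20 A; nearest non-local contacts ~7.5 A
#                  (2000 snapshots; at 10^4 snapshots these modes settle
#                  near 2.21-2.25 and 7.2)
```

The same quantities are available from the command line:

```
tangentchain sample-walks --order 3 --n-samples 1000000 --seed 1 --out walks/
tangentchain table1 --ensemble low --n-samples 2000 --seed 1
tangentchain contact-map chain.xyz --out contacts.csv
```

Every experiment prints a JSON summary carrying its seed and a configuration
hash; re-running with the same seed reproduces the output byte for byte.

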