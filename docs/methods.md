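# Methods

## Ground-truth accessibility

Accessible surface area is computed by Shrake–Rupley numerical quadrature:
each atom's van der Waals sphere (Bondi element radii: C 1.70, N 1.55,
O 1.52, P 1.80 Å) is inflated by the solvent probe radius, covered with a
deterministic Fibonacci point lattice (default 960 points per atom), and a
point counts as exposed when it lies outside every neighbouring inflated
sphere.  The atom's area is the exposed fraction times 4π(r+p)²; residue
ASA sums its atoms.  The lattice is deterministic, so results carry no
random seed; neighbour culling uses a k-d tree.

**Probe radius.**  The default is 0.75 Å — a probe *diameter* of 1.5 Å
taken literally.  Because the conventional water probe is 1.4 Å *radius*,
the parameter is exposed (`AsaConfig.probe_radius`) rather than hard-coded;
both conventions are one flag apart.

**Quadrature accuracy.**  Against closed forms the quadrature is well
inside 2%: an isolated sphere reproduces 4π(r+p)² to better than 0.1%, and
two overlapping equal spheres match the spherical-cap formula
A = 4πR² − 2πR(R − d/2) to under 0.5% across the full overlap range.
Convergence is assessed on the exposed-fraction scale (change relative to
the atom's full sphere area): doubling the point count moves no atom by
more than 1% of its sphere area.  A nearly-buried atom's exposed area can
be arbitrarily small, so its *own* area is not a meaningful error scale —
the boundary of the buried region is sampled at O(n^−1/2) resolution and
the absolute, not relative, error is what the lattice controls.

**Completeness filter.**  A residue is usable for training only when it and
both sequence neighbours (one, at chain ends) contain their complete
heavy-atom inventory; validity at the termini requires only the neighbours
that exist, since the purpose of the rule — locally complete geometry — is
satisfied there with one neighbour.  The chain's first residue may lack the
5′-phosphate group (routinely absent from crystal models).  Hydrogens are
never expected: inputs are crystallographic and the calculation is
heavy-atom only.  Ground-truth normalized values above 1 (ASA > 400 Å²) are
*not* clipped, preserving invertibility; clipping applies only to model
predictions.

## Sequence profile

Counts include the query row, so the query base never has a zero count even
before pseudocounts.  Gap characters contribute to no base; IUPAC ambiguity
codes contribute fractional counts split equally among compatible bases;
T maps to U.  The −log uses the natural base: any other base is an affine
rescaling absorbed without trace by the (−1,1) min–max normalization, whose
anchors are the min and max over the training profiles, stored with the
model and applied with clamping at prediction time.  Degenerate bounds
(p_lo = p_hi) map everything to 0 with a warning.

## Regression

`sklearn.svm.SVR` (libsvm) with RBF kernel; defaults C = 1, γ = 1/n_features,
ε = 0.1 — the library defaults, since tuned values are dataset-dependent and
found by the built-in grid search (C ∈ 2⁻³…2⁷, γ ∈ 2⁻⁹…2¹, log-2 spaced,
ties toward smaller C then smaller γ, pooled CV Pearson r as the
objective).  The solver tolerance is tightened to 1e-6 so the converged
solution — and hence predictions — is independent of training-row order to
≈1e-9.  Predictions are clipped to [0, 1.25] normalized (500 Å²): a small
overshoot allowance avoids censoring genuinely large accessible areas while
keeping outputs on a physical scale.  Models pickle to a single
version-stamped archive holding the regressor, config, encoder mode and
profile bounds; reload reproduces predictions bit-identically.

Cross-validation assigns whole chains to folds (shuffle by seed, near-equal
split), so no chain appears on both sides of any fold and every position is
predicted exactly once by a model that never saw its chain.

## Synthetic data: what it emulates, what it does not

The generators exist so the entire pipeline is testable without downloads;
all draws come from `numpy.random.default_rng(seed)` and are byte-stable.

* **Toy chains** place residues (~8 named heavy atoms each, simplified
  inventories) along a 6 Å random walk with a 1.5 Å global minimum atom
  spacing — enough geometry to exercise quadrature, aggregation and the
  completeness filter, with deliberately no base pairing, helices or
  realistic sugar–phosphate chemistry.
* **Regression chains** (default 60 chains of 40–70 nt, the scale of the
  small-RNA fraction of typical training sets) carry targets that are a
  fixed random linear map of the local one-hot window (half-width 3),
  standardized to mean 0.35 / sd 0.15 — matching the scale of real
  normalized accessibilities (mean base ASA ≈ 140 Å² / 400) — plus Gaussian
  noise of sd 0.08, clipped to [0, 1].  Fivefold chain-level CV recovers
  pooled r ≈ 0.85; shuffling targets collapses it to |r| ≲ 0.05.
* **Conservation chains** plant a latent burial indicator (probability 0.4)
  that both lowers the target by 0.30 and freezes the column in a
  30-homolog alignment (other columns mutate at rate 0.3), while the
  sequence itself carries only a ±0.05 base-identity effect.  Profile
  features can read burial off conservation; one-hot features cannot —
  yielding the expected profile > sequence ordering of CV correlations.
* **SNV tables** plant log₁₀(MAF) = −3 + 2.2 × predicted ASA (times
  lognormal noise when requested), capped at MAF 0.5.  The link is affine
  on the log scale, so noise-free equal-occupancy bin means are collinear
  and the bin-level r is exactly 1.
* **DMS tracks** share a lognormal positional bias across the denature,
  in vitro and in vivo conditions; only the in vivo rate is additionally
  scaled by (0.3 + exposure).  After max-normalization, fragment averaging
  and the denature ratio, the in vivo fragments correlate positively with
  planted exposure while in vitro fragments do not — the directional
  contrast the normalization is designed to expose.

Passing these tests demonstrates that the machinery recovers signal it is
pointed at under controlled conditions; it does not certify accuracy on
real structures, where signal strength, homolog depth, alignment quality
and structural redundancy differ.

## Downstream procedures: numerical choices

* DMS: reads are max-normalized *before* fragment averaging; fragments are
  strictly non-overlapping 50-base blocks with the trailing partial block
  dropped; "null counts" means a fragment mean of exactly zero; the
  ≥4000-reacted-bases mRNA filter is a configurable input filter.
* MAF bins: stable sort with original-order tie-breaking; with n not
  divisible by the bin count the first (n mod bins) bins take one extra
  record; log base 10 (base only rescales the averaged axis, leaving r
  unchanged); mean of log(MAF), not log of mean MAF; records with MAF ≤ 0
  are rejected with a logged count; strata smaller than the bin count are
  skipped, not merged.
* Boundary profiles: offsets −50…+49 with offset 0 the first base of the
  downstream region; transcripts with any region under 100 bases are
  excluded and counted.

## Problem sizes

The test suite and the results script run their CV experiments at 60
chains (≈3300 positions, 324 features) and 40 conservation chains (2400
positions), sizes at which the planted effects are comfortably detectable
and a full fivefold CV completes in seconds.

## Known limitations

* The area quadrature samples the buried-region boundary at O(n^−1/2); atoms
  with a sliver of exposure carry the largest relative error.
* Upstream homology search, variant annotation and transcript model
  selection are out of scope: the profile, SNV and transcript adapters
  consume externally produced alignments/tables.
* Modified nucleotides are handled by a small parent-base table; unlisted
  modifications are skipped rather than guessed.
* Prof-mode prediction handles one query per call (an alignment is per
  query by nature).
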