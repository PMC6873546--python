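# Methods

## Distance-dependent knowledge-based potential

The potential is the inverse-Boltzmann log-ratio
`dE(d) = -RT ln(f_obs(d) / f_ref(d))`, tabulated per unordered residue-pair
type (210 types for the 20 standard amino acids) and per half-open distance
bin `[low, high)`.  Atom pairs are typed by their residues' amino-acid
identities only, so the pair-type decomposition of a structure's total
energy is exact: summing the 210 components of the energy vector equals
summing per-contact energies, and the conventional 1/2 factor of the
double sum is realised by enumerating each unordered atom pair once.
Per-atom-name typing (as in all-atom potentials of the DOPE/DFIRE family)
is deliberately out of scope: residue-level typing is what makes the
210-variable analysis exact.

**Contact schemes.**  A contact is an atom pair with `d < cutoff` (strict)
and sequence separation `|i - j| > min_seq_sep` (exclusive).  Two presets
mirror common definitions: `dbni_like_scheme()` (6 Å cutoff, non-local
`min_seq_sep = 5`, Delaunay-tessellation edge filter over the heavy-atom
point set) and `dfire_like_scheme()` (15 Å, no separation filter).  The
tessellation filter is a generic Delaunay edge filter — it can only remove
contacts, never add them — and is not a reproduction of any published
tessellated potential.  `atom_mode` chooses all heavy atoms or one center
per residue (Cβ, falling back to Cα); hydrogens are always excluded.

**Reference states.**  "averaged": the product of the count table's
marginals (the pair-type-independent distance profile scaled to each pair's
total), which cancels any distance shape shared by all pair types;
"power-law": per-bin weight proportional to `r^alpha · width` at the bin
center, an ideal-gas-like density (`alpha = 1.61` is the customary
finite-size exponent; `alpha = 0` gives a uniform distance reference).
Both are normalized so every pair row sums to that pair's observed total,
which makes the potential invariant to rescaling all counts.

**Tunable parameters.**  Bin width 0.5 Å by default (conventional for
distance-dependent potentials); pseudocount ε = 0.01 added to every cell
(keeps the logarithm finite); `RT = 1` so energies are in RT units — every
downstream quantity (rankings, Z-scores, eigenvectors, contributions) is
invariant to this global scale.

## Energy vectors and the TE matrix

Row *i* of the TE matrix is the 210-dimensional pair-type energy vector of
structure *i*; its row sum is the structure's total energy.  The selection
operates on the column-centered matrix (CTE): subtracting column (variable)
means is the convention under which the sample covariance
`U^T U / (n - 1)` is meaningful.  A row-centering variant is exposed
(`center_rows`) for completeness but is not part of the default analysis,
since variable selection from a covariance of samples requires variable
centering.  A seeded row-subsampling utility supports running the selection
on a random subset of structures.

## Principal-interaction extraction

On the CTE matrix: eigendecompose the covariance (symmetrized input,
`numpy.linalg.eigh`, eigenvalues sorted non-increasing, negatives below
-1e-9 relative rejected, small negatives clipped to zero); variance
proportions `t_j = 100 λ_j / Σλ`; `m` = smallest integer whose cumulative
proportion reaches 80% (a 1e-12 slack absorbs floating-point rounding at
exact thresholds); contributions `C_kj = 100 V_j(k)² / Σ_k V_j(k)²`
(sign-invariant, columns sum to 100); totals
`total_k = Σ_{j≤m} C_kj λ_j`; threshold `τ = Σ_{j≤m} (100/p) λ_j`.
τ equals the mean of the totals — an algebraic identity asserted on every
run.  Selection is *strictly* greater than τ, so an exactly uniform
contribution profile selects nothing.

Numerical notes and edge cases:

- Degenerate eigenvalue ties: the component order among equal eigenvalues
  follows `eigh`; `m` depends only on cumulative sums, which are
  tie-order-invariant, and totals aggregate over all retained components.
  (When a tie straddles the m-boundary the aggregate can depend on the
  arbitrary basis chosen within the eigenspace; exact ties of that kind do
  not arise for continuous data.)
- The "uniform design selects nothing" degeneracy holds exactly only when
  all components are retained (`m = p`); with components dropped, even an
  isotropic covariance yields a non-uniform aggregate.  The test suite
  exercises the `m = p` regime with a Hadamard design.
- The procedure is generalized to any variable count `p` (the `100/p`
  uniform contribution reads `1/2.1` per eigenvalue at `p = 210`), so
  reduced-alphabet test hooks work unchanged.
- Selection is invariant to positive rescaling of the energies, row
  permutation, row duplication, and eigenvector sign flips (all tested).

`PrincipalInteractionSelector` wraps the chain as a scikit-learn feature
selector (centering internally by default); `select_principal` is the
functional form operating on an already-centered matrix.

## Decoy evaluation

Six criteria per decoy set, computed on plain score/RMSD arrays:

- **Top1** — native strictly lowest; ties count as failure (logged).
- **Z-score** — `(mean(decoys) − native) / sd(decoys)`, sample sd (n−1),
  decoys only (the native is not part of the reference distribution).
- **RMSD of the minimum** — Cα RMSD of the minimum-energy structure to the
  native (0 when the native wins); score ties broken toward lower RMSD.
- **PC** — Pearson correlation between decoy energies and RMSDs.
- **F.E.** — 20% fraction enrichment: overlap of the `max(1, floor(0.2 N))`
  lowest-RMSD and lowest-score decoys divided by `0.04 N`; range [0, 5],
  attaining 5 exactly at perfect overlap.
- **Z-score_b** — Z-score of the lowest-RMSD decoy, identified by RMSD
  (never by score), with it and the native excluded from the reference
  mean/sd.

The PI statistic is the fraction of *atomic contacts* (not pair types, not
energy) whose pair type is in the mask, over all contacts the scheme
admits, reported per structure and aggregated as mean ± sd.  Provided
per-decoy RMSD files take precedence over internally computed superposition
RMSD so published decoy-set tables can be honored exactly.

Cα RMSD uses optimal least-squares rigid superposition (Kabsch, with the
determinant correction) by default, since decoys are not guaranteed
pre-aligned; a no-superposition mode exists.  Residues are paired
positionally and pairs lacking a Cα in either structure are dropped.

The success curve (Top1 versus the number of top-ranked pair types used)
exploits linearity: energies under a top-k mask are cumulative sums of
ranking-ordered energy-vector entries, so the full 210-point curve costs
one energy vector per structure.

## Synthetic data

The generators emulate the three inputs the method needs:

- **Chains** (`generate_chain`): self-avoiding random walks of
  single-center residues at fixed 3.8 Å spacing (the Cα virtual bond),
  excluded volume 3.0 Å, with a mild centroid bias (`compactness = 0.3`)
  so chains fold back and develop the non-local contacts globular proteins
  have; sequences are uniform random over the 20 amino acids.
- **Decoy ladders** (`generate_decoy_ladder`): per-atom isotropic Gaussian
  noise with per-decoy magnitudes, realized Cα RMSD recorded.  This is
  crude relative to fragment-assembly decoys but produces the monotone
  geometry-degradation the evaluation criteria probe.
- **Planted matrices** (`generate_planted_matrix`): independent Gaussian
  columns, a designated subset with higher variance, emulating the
  covariance structure the selection assumes.

All generators are pure functions of their specs, seed included.

## The end-to-end synthetic study

`run_synthetic_pipeline` trains on 20 chains of length 30, extracts
principal interactions from their TE matrix, and evaluates 10 decoy
ladders (20 decoys each, noise 2–6 Å) built on the first 10 natives.
Its potential settings differ from the real-data defaults, for reasons
specific to what the generator produces:

- **Uniform distance reference (power-law, α = 0).**  Generated sequences
  are random and independent of geometry, so all pair types share one
  distance profile and the "averaged" reference cancels it exactly,
  leaving a potential with no signal by construction.  The discriminative
  signal at this scale is the occupancy profile itself — a bond peak at
  3.8 Å, an empty excluded-volume region, compact-shell structure — and a
  uniform reference turns exactly that into favorable native bins and a
  repulsive short range.
- **1.0 Å bins, 6 Å cutoff, pseudocount 1.0.**  Twenty chains of length 30
  yield only a few thousand contacts across 210 pair types; finer bins or
  a small pseudocount leave most cells empty, and the resulting
  unseen-cell penalties dominate scoring with noise rather than signal.
  The coarser table and stronger smoothing keep per-cell statistics
  meaningful at this training-set size.
- **Targets drawn from the training natives.**  With a training set this
  small every structure is needed for the statistics; the decoy ladders
  perturb training natives rather than held-out ones.

What passing this study shows: the trained potential separates intact
compact geometry from coordinate-noise perturbations (native Top1, positive
energy–RMSD correlation), and the principal-interaction subset preserves
that discrimination at roughly half the contacts.  What it does not show:
transfer to held-out structures, realistic decoy physics, sequence-specific
energetics (random sequences carry no evolutionary signal), or any claim
about which particular pair types are principal in real proteins — the
principal set of random-sequence chains reflects sampling structure, not
folding chemistry.

## Known limitations

- PDB input only (first model, one chain); no mmCIF, no complexes.
- Residue-level pair typing; no orientation or multi-body terms.
- The Delaunay filter is a generic edge filter over heavy atoms.
- The PI denominator counts all contacts passing the full scheme; whether
  a non-local filter should apply to the denominator as well is a
  convention, fixed here to "all scheme contacts".
- Binning, pseudocount and RT for published potentials vary by author; the
  trained tables here approximate contact definitions (cutoffs, separation
  filters) but make no claim of numeric equivalence with published DBNI,
  DFIRE or DOPE parameter tables.
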