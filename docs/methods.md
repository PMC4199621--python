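# Methods

## Scope and model

`h4screen` implements a two-stage virtual screen for hH4R antagonists:
a ligand-based stage (descriptor-range filters learned by Iterative
Stochastic Elimination, combined into the Molecular Bioactivity Index)
and a structure-based stage (docking-pose triage by electrostatic-energy
clustering and carboxylate-contact scoring), joined by a consensus
selection. Receptor modelling, molecular dynamics and the docking run
itself are out of scope: poses enter the pipeline as coordinate/energy
bundles produced elsewhere (or by the synthetic generator).

## Descriptor panel

Eleven 2D descriptors, all computable from the molecular graph:
molecular weight (Da), formal charge (e), nitrogen/oxygen/aromatic-atom
counts, H-bond donors and acceptors, logP, ring count, rotatable bonds,
and fractional negative VdW surface area (`fasa_neg`, 0–1). RDKit
supplies the primitives. Two descriptors are explicit approximations:

* `logp` is the Crippen atom-contribution estimate;
* `fasa_neg` is the Labute-ASA fraction carried by atoms with negative
  Gasteiger partial charge, with implicit-hydrogen area counted as
  non-negative. Labute per-atom areas can overshoot the total by ~1%
  on pure alkanes, so the value is bounded by ~1.01 rather than 1.

Both differ numerically from the commercial MOE descriptors that
originally motivated the panel; absolute thresholds on these two
descriptors (e.g. the 0.42 bound of the three-rule model) therefore
transfer only qualitatively to structures, and the learning machinery
treats them as ordinary continuous features. Molecules are used as
written in the input SMILES; no protonation model is applied, so charge
states are the data-preparation step's responsibility.

## Rule filters

Three fixed rule sets, all bounds inclusive: Lipinski (HBD ≤ 5,
HBA ≤ 10, MW ≤ 500, logP ≤ 5), Oprea lead-likeness (MW ≤ 450,
−3.5 ≤ logP ≤ 4.5, rings ≤ 4, rotatable bonds ≤ 10, HBD ≤ 5, HBA ≤ 8 —
rotatable bonds standing in for "non-terminal single bonds"), and the
three-rule antagonist model (charge = +1, 3 ≤ N ≤ 7, fasa_neg ≤ 0.42).
The nitrogen count includes all nitrogen atoms regardless of charge
state.

## MCC convention

Filter quality is MCC on *class-normalised* counts: per-class pass
percentages are used as a 2×2 table with equal class weight
(tp = PA, fn = 100 − PA, fp = PNA, tn = 100 − PNA). This is the only
convention under which per-class rates of 87%/5% yield 0.82 regardless
of the 78-vs-9000 class imbalance of a real screening deck; raw-count
MCC is available separately (`evaluate_counts`). Any zero factor in the
denominator gives MCC 0 by convention.

## Discretisation and ISE

Descriptor axes are discretised at pooled empirical quantiles (deciles
by default); integer descriptors get floored integer cut-points, and
duplicated quantiles collapse. Bins are closed on the right: a value on
a cut-point belongs to the lower bin, and the binary encoding is the
concatenated one-hot bin membership.

ISE treats each descriptor's lower and upper interval edge as a
variable whose values are bin indices. Per iteration it samples
`sample_size` random filters (descriptor subset of size
`subset_min..subset_max`, admissible (low, high) pair per descriptor),
scores them, and compares value frequencies between the worst and best
`worst_fraction`/`best_fraction` tails: a value whose worst-minus-best
frequency margin exceeds `elimination_margin` is removed (never below
one value per variable; an emptied space is a hard error with an
iteration trace). When the surviving space counts at most
`exhaustive_limit` filters — the count is computed exactly via the
elementary-symmetric-polynomial recurrence — it is enumerated
exhaustively. Defaults: sample_size 1000, tails 0.1, margin 0.1,
exhaustive limit 10⁵, subset size 3–6, ≤ 50 iterations, ensemble floor
MCC ≥ 0.6, deduplication by exact constraint equality. These are
desk-scale defaults chosen for tractability, documented here rather
than claimed canonical; all flow from an explicit integer seed.

## MBI

For an ensemble of n filters, a molecule scores

    MBI = (1/n) Σ_i [ δ_Ai · PA_i / max(PNA_i, ε) − δ_NAi · NNA_i / max(NA_i, ε) ],

with δ_Ai = 1 iff the molecule passes filter i and δ_NAi = 1 − δ_Ai.
PA/PNA is the pass-side efficiency factor (how much more often actives
pass than non-actives); NNA/NA penalises failing a filter that
identifies non-actives well. ε = 0.5 percentage points caps the ratios
when a training set yields zero false positives or negatives. The
normalisation by n and the use of plain (not log) ratios are design
choices; the formula is isolated in one function so an alternative form
is a one-line change. Ranking is by descending MBI with deterministic
ties (n_passed, then id); the focused set is the top 1% by default
(configurable; the synthetic pipeline uses 10% because its library is
three orders of magnitude smaller than a real deck).

## Pose triage

* **Best pose** per compound = minimal total docked energy, ties broken
  by pose rank. Interpreting "best" by total energy rather than by
  electrostatic energy is a design choice.
* **EE clustering**: exact 1-D k-means (k = 3 by default, matching the
  three energy groups such populations show). Because 1-D SSE-optimal
  clusters are contiguous in value order, the global optimum is found
  by dynamic programming on the sorted values with prefix sums. An
  initialised Lloyd iteration was considered and rejected: on random
  small instances it missed the contiguous-partition optimum in roughly
  a third of cases, while the DP is deterministic, O(k·n²), and exact.
  Cluster boundaries are midpoints between adjacent centroids; filter
  thresholds are re-derived per pose population rather than fixed
  constants (published values such as −3.16 or −1.1/−4 kcal/mol are
  population-specific).
* **Distance score**: per anchor residue (D3.32, E5.46), an interaction
  is a minimum distance strictly below 4.0 Å between any polar heavy
  ligand atom (N or O only; sulfur excluded) and any side-chain
  carboxylate oxygen (OD1/OD2, OE1/OE2; the carboxylate carbon is
  excluded). Score = number of interacting residues ∈ {0, 1, 2}.
* **Combined filter**: EE cluster membership AND distance score ≥
  threshold — conjunctive because the two criteria are close to
  orthogonal in practice.
* **Enrichment**: EF = active pass % / reference pass %, the reference
  percentage taken as the mean over seeded sub-sampling folds drawn
  without replacement (20 folds by default; 100 folds of 137 compounds
  in the synthetic end-to-end run). A zero reference rate flags the EF
  as infinite rather than raising.
* **Consensus**: pose-filter passers ordered by MBI rank, truncated to
  11 by default.

## Synthetic data

`gen_descriptor_set` plants a descriptor-interval rule: actives satisfy
it with probability 1 − label_noise, decoys with a background rate, and
every violating record is forced outside at least one interval (choosing
only descriptors whose distribution extends past it), so the ground
truth flags are exact. The default population mirrors the reported
antagonist property profile — charge +1 dominant, N ∈ {3..7}, MW ~
N(280, 60) truncated ≥ 100 Da, logP ~ N(2.2, 1), fasa_neg ~ N(0.30,
0.06) on [0,1] — with broader decoys. Setting label_noise = 0.13 and
background = 0.05 reproduces the 87%/5% → MCC 0.82 regime in
expectation.

`gen_pose_set` plants binders (rate 0.2 among actives, 0.01 among the
reference set by default — analytic EF 20) whose rank-1 pose carries a
polar nitrogen 2.5–3.8 Å from a carboxylate oxygen of *each* anchor
residue, with EE ~ N(−4.5, 0.5) kcal/mol; non-binders sit ≥ 5 Å away
with EE ~ N(−0.5, 0.7). Distance supports are disjoint by construction
so planted truth ⇔ distance score 2 exactly. Rank-1 poses always have
strictly minimal docked energy, making best-pose selection exact.

What the generators do **not** emulate: real descriptor correlations
(descriptors are drawn independently per class), chemically valid
structures behind the vectors, docking-energy/geometry coupling, pose
diversity within a compound, or receptor flexibility. Passing tests
therefore demonstrate correctness of the machinery and recoverability
of planted signal at realistic sizes — not prospective performance on
real decks.

## Numerical choices and degenerate inputs

Closed intervals throughout; interval conversions from bins use the
closed-right convention (integer descriptors shift the lower edge by
+1). Constant descriptors are flagged degenerate and never constrained.
Filter-ensemble ties and rankings all break deterministically. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline derives per-stage seeds from
one master seed via `SeedSequence`. Problem sizes in the test suite and
the synthetic end-to-end run (hundreds of actives, thousands of decoys,
≤ 16 poses per compound) were chosen as the smallest at which the
planted statistical effects are comfortably resolvable.

## Known limitations

* MOE-descriptor-dependent published artefacts (the exact 48 filters,
  the 46-of-78 diversity count at S < 0.7, absolute fasa_neg
  thresholds on real structures) are not reproducible and are treated
  qualitatively.
* The MBI's algebraic form is fixed here by the documented efficiency
  -factor reading; alternatives (log-ratios, unnormalised sums) would
  change absolute scores but rarely the ranking near the top.
* `read_pose_bundle` pairs PDB models with CSV rows by order; it does
  not parse native AutoDock DLG files.
* Greedy leader diversity filtering is order-dependent by design (first
  molecule always retained).
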