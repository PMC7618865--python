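# Methods

This note records the models and procedures tedkit implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Consensus segmentation

Each chain arrives with three choppings (one per segmentation method). The
procedure is:

1. **Pairwise matching.** For each pair of methods, a one-to-one matching
   between their domains maximising total residue-set IoU, restricted to
   pairs with IoU ≥ `iou_min`. For up to 7 domains per chopping the
   optimum is found by exhaustive enumeration with a deterministic
   lexicographic tie-break; beyond that the Hungarian algorithm
   (`scipy.optimize.linear_sum_assignment`) takes over. Matching is
   oriented by domain content before solving, so it is symmetric in its
   two arguments and the whole consensus is invariant to the order of the
   three input choppings.
2. **Grouping.** A triple of domains matched consistently across all three
   pairings forms a high-confidence group. Remaining matched pairs are
   taken greedily by descending IoU (ties broken on domain content, again
   for input-order invariance) as medium groups. If transitivity fails
   (A~B, B~C, not A~C) the best pair wins and the third domain is left
   unmatched.
3. **Per-residue vote.** A residue belongs to the consensus domain when at
   least two of a high group's three domains contain it, or both domains
   of a medium group. Voting can make residue sets discontinuous; segments
   are recomputed from the final set.
4. **Length filter.** Voted groups shorter than `min_len` residues are
   dropped; their residues, and all unmatched domains' residues, become
   non-domain residues (NDR).

Parameters: `iou_min` = 0.7 (dimensionless; keeps a 2-vs-1 split of a
two-domain chain non-agreeing, which is the intended notion of
"disagreement" between parsers), `min_len` = 25 residues (a conventional
lower bound for a structural domain).

The same vote machinery, with "methods" replaced by cluster members and a
strict-majority rule, provides the cluster-level consensus segmentation in
the redundancy module; there the high/medium tiers record full versus
partial member support.

## Classification bookkeeping

Structure-search hits carry a normalised score on [0, 1]; hits scoring
below `score_min` = 0.5 are ignored. The best full-code hit gives an
H-level label; failing that, the best topology-depth hit or any
nearest-neighbour hit gives a T-level label (nearest-neighbour matches are
never trusted to superfamily depth). Ties break on higher score, then on
the lexicographic code string — the convention chosen so that equal-score
hits resolve the same way on every platform.

HMM validation is a three-way verdict: exact C.A.T.H agreement confirms
the superfamily; C.A.T agreement with a differing or absent H digit
confirms the fold; anything else is unconfirmed (or `no_hmm_hit` when no
HMM evidence exists). plDDT bins follow the AFDB colouring convention with
closed lower bounds: ≥90, [70, 90), [50, 70), <50.

## Rigid-body geometry

Superposition is the Kabsch algorithm via SVD of the cross-covariance of
the centred point sets, with the determinant correction that restricts the
solution to proper rotations — mirror images are never matched by
reflection. Inputs with fewer than 3 points, or whose second principal
moment vanishes (collinear clouds, where the rotation about the common
axis is undetermined), are rejected.

**Globularity** is Rg(observed) / Rg_expected(n) with
Rg_expected(n) = 2.2 · n^0.38 Å, a Flory-type scaling for compact
globular domains. Scores above `glob_max` = 1.5 flag extended or poorly
packed choppings. This geometric heuristic is the toolkit's domain-quality
filter; it is deliberately simple, rigid-motion invariant, and exposed in
configuration.

**Internal symmetry.** For each shift s in [`min_shift`, n − `min_shift`]
the chain window 1..n−s is Kabsch-superposed onto 1+s..n. Aligned pairs
within `dist_cutoff` = 4 Å contribute 1 / (1 + (d/d0)²) with
d0 = `dist_cutoff`/2, so an exact repeat counts its whole window while
incidental 3–4 Å contacts contribute little; a hard count was tried first
and rejected because chance contacts and near-period shifts dominate its
null. The Z-score compares the best shift's score against the mean and SD
of all scanned shifts that are *not multiples of the best shift*: the
harmonics of a true period score highly themselves and belong to the
signal, not the null. The null SD is floored at 2 weighted pairs — a
Z-score against an essentially flat null is meaningless, and the best of
~n scanned shifts sits 2.5–3 raw SDs above the mean by selection alone.
`min_shift` = 8 excludes trivial near-diagonal self-alignment. The
repeat gate is Z > 9 (strict). This scan is a deliberately non-iterative
stand-in for dedicated symmetry-detection programs: it reports shift
periodicity and a detection Z-score, not point-group order.

## Interactions and CIO

Contact: ≥ `min_pairs` = 3 Cα–Cα pairs within `dist_max` = 8 Å
(conventional Cα contact-map values). Favourable PAE: the symmetrised mean
of the two inter-domain blocks ≤ `pae_max` = 10 Å. Both thresholds are
configuration-exposed. Only consensus domains with H-level labels form
instances.

CIO is the mean resultant length of unit inter-centre-of-mass vectors
after bringing all instances into a common frame: the master is the
instance whose reference domain has the most residues (tie: smallest
instance id); the reference domain within an instance is the one whose
superfamily code sorts first, and for homotypic pairs the larger domain,
then the smaller domain id. Length-mismatched references are aligned on
their common-length prefix; instances sharing less than half the master's
length are dropped with a warning. Mean resultant length was chosen
because it is the standard directional-statistics concentration measure
on [0, 1]: 1 for identical directions, ≈ n^{-1/2} for uniform ones, and
differences of ~0.3 are meaningful — exactly the properties the CIO score
is used for. One vector per instance is used, also for homotypic pairs.

Hub classes tile the integers: <4 small, 4–7 medium, ≥8 large. (The
source material is ambiguous about 4; placing it in "medium" makes the
three classes a partition.)

## Novelty ranking

The anomaly score of a query embedding is
100 × ECDF(d_k(query)), where d_k is the Euclidean distance to the k-th
nearest reference and the ECDF (right-continuous) is built from every
reference's own leave-one-out d_k. k = 5 by default. The score depends
only on pairwise distances, hence is invariant under any common orthogonal
transform of the embedding space, and a query beyond every
reference-to-reference distance scores exactly 100. This is a clean,
assumption-light density-based ranking with the same range and orientation
as trained-network novelty scores ("close to 100" = most novel); it is not
a re-implementation of any trained model. Triage order is quality filter
first, then symmetry gate, then scoring, mirroring the stage layout of the
workflow it models.

## Redundancy

Maximum pairwise RMSD is exact (all unordered pairs, Kabsch-superposed)
up to 50 members; larger clusters use a medoid-anchored two-sweep
approximation (farthest member from the medoid, then farthest from that),
flagged as inexact in the output. The medoid minimises the sum of
superposed RMSDs to all other members, first index winning ties.
Averaging member coordinates was rejected as a "consensus structure"
because it creates non-physical geometry; the medoid plus the
majority-vote consensus chopping carry the same information safely.

## Synthetic generators

All generators are pure functions of (parameters, seed) and bit-reproducible.

- **Chains** are compact random walks with 3.8 Å Cα steps confined to a
  sphere of radius 2.5 · n^0.38 Å per domain, joined by 5-residue extended
  linkers; plDDT is drawn uniform in 90–98 inside domains and 30–50 in
  linkers. This reproduces the length scales, compactness and confidence
  contrasts that the tested statistics read — not secondary structure,
  sterics or energetics. Passing tests therefore demonstrate correctness
  of the geometry- and bookkeeping-level algorithms, not performance on
  real predicted structures.
- **Cn rings** replicate one random-walk unit by rotation of 360/n about a
  common axis; the symmetry is exact by construction (consecutive units
  are not covalently re-joined, which the Cα-level statistics never see).
- **PAE matrices** are block-constant (intra vs inter level) with optional
  truncated Gaussian noise, mimicking the block structure of real PAE maps
  without their asymmetric long-range texture.
- **Orientation ensembles** place a tag-along domain along directions
  drawn von Mises–Fisher with concentration κ about a mean direction
  (κ = 0 uniform, κ = ∞ exact copies), slide it into contact, and apply a
  random global rigid motion per instance so the CIO alignment machinery
  is genuinely exercised.
- **Redundant clusters** are jittered copies (σ = 0.05 Å) of one chain;
  divergent clusters additionally rotate everything C-terminal of the
  first linker residue by 30° about a random hinge axis, which produces
  maximum pairwise RMSDs of several Å — comfortably across the 1 Å
  divergence threshold, as sub-Å jitter is comfortably below it.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 200 random
chopping triples (≤ 300 residues, ≤ 5 domains each) for the consensus
brute-force comparison; orientation ensembles of up to 1000 instances;
C2/C6/C11 rings of 80–132 residues plus 100 random 120-residue chains for
the symmetry suite; 200 three-member clusters for the divergence recovery;
and 20-chain suites for end-to-end determinism. These sizes keep every
statistic's sampling error far from its decision boundary while the whole
suite completes in well under a minute.

Every stochastic step takes an explicit seed or NumPy `Generator`; the
pipeline's outputs are pure functions of (inputs, configuration), and the
run summary embeds a SHA-256 digest of the configuration.

## Known limitations

- Cα-only geometry; no all-atom RMSD, no side-chain packing.
- The globularity heuristic and the k-NN novelty score are simple
  geometric/statistical stand-ins for trained quality and novelty
  networks; their rankings agree with intuition on synthetic data but are
  not calibrated against curated domain sets.
- The symmetry scan detects shift periodicity only; it does not identify
  the point group, handle nested repeats, or iterate the alignment.
- Consensus semantics are defined for exactly three methods (high = all,
  medium = all but one).
- Inter-chain (quaternary) interactions are out of scope; instances are
  intra-chain only.
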