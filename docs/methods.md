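# Methods

## Systems and composition arithmetic

A simulated system contains `n_peptide` cyclic dihistidine peptides
(Cyclo-HH, modeled as neutral: a cyclic dipeptide has no free termini),
`n_drug` copies of one drug with integer net charge `q_d`, `n_zn` Zn²⁺,
and neutralizing counterions in a cubic periodic box of edge L (default
83 Å). Neutralization follows the convention used when building such
systems: nitrate absorbs the Zn²⁺ charge and any negative drug charge
(`n_no3 = 2·n_zn + q_d·n_drug` for `q_d < 0`, else `2·n_zn`), and chloride
balances positive drugs (`n_cl = q_d·n_drug` for `q_d > 0`). The reference
setup of 48 peptides, 12 drugs, and 48 Zn²⁺ therefore carries 96 NO₃⁻ for
a neutral drug, 72 NO₃⁻ for a −2 drug, and 96 NO₃⁻ + 12 Cl⁻ for a +1 drug,
with an initial drug:peptide ratio of 0.25. Solvent is implicit throughout.

## Cluster detection

Components interact when any inter-atom minimum-image distance is
*strictly* below the contact cutoff d_c (default 3.5 Å). Strictness at the
cutoff is a measure-zero convention, fixed so that the detector is exactly
reproducible against an all-pairs oracle. Candidate atom pairs come from a
periodic k-d tree; the result is provably independent of the acceleration
structure because every candidate is re-checked with the exact
minimum-image distance. Clusters are connected components with ≥ 2 members
(a lone molecule is not an assembly); the size filter default of 31 encodes
"more than 30 components", and both the cutoff and the threshold are
configurable. Only cubic orthorhombic boxes are supported, and the cutoff
must be < L/2 for the minimum-image convention to be valid.

Unwrapping translates each cluster into one contiguous copy: components are
first made whole (atoms re-gathered around a reference atom, valid because
every template is far smaller than L/2), then a breadth-first traversal
shifts each newly visited component by the lattice vector realizing the
minimum-image displacement to its placed neighbor. Inconsistent shifts on a
cross edge mean the cluster percolates the box; this is reported as an
error rather than silently truncated.

## Per-cluster statistics

Composition percentages, drug-count summaries (fractions of clusters with
0/≥1/≥2 drugs), percent of all system drugs inside a cluster, and
drug:peptide / Zn:peptide ratios are direct counts. The radius of gyration
uses uniform atom weights (the coarse pseudo-atoms carry no masses; this
deliberately differs from mass-weighted conventions in MD tooling).

SASA uses the Shrake–Rupley construction: each atom inflated by the probe
radius r_p is sampled with n deterministic Fibonacci-lattice sphere points
(default 960; no RNG, so SASA is bit-reproducible), and a point is
accessible when outside every other inflated atom. The burial ratio of a
component divides its SASA computed against all atoms of its cluster by
its SASA in isolation, so 100 % means fully exposed. The isolated-component
denominator is a deliberate design choice: it gives the ratio a fixed,
interpretable scale. Occluders are cluster atoms only — solvent is
implicit and non-cluster components are excluded, mirroring a per-cluster
analysis. The default probe radius of 2.6 Å is a stand-in for an
isopropanol-sized solvent probe and is configurable; at 960 points the
single-sphere area is exact to ≪ 1 % and two-sphere buried caps to < 2 %.

## Interaction motifs

Pair probabilities count contact edges by unordered kind pair over all
clusters, excluding the electrostatically repulsive Zn²⁺–Zn²⁺ and
NO₃⁻–NO₃⁻ pairs, and normalize to 1; conditional profiles (partner
distribution given a peptide or drug endpoint) are also emitted.

A mediated triplet is a middle component (peptide, drug, Zn²⁺, or NO₃⁻)
with two distinct peptide/drug neighbors in the contact graph. Labels are
flank–middle–flank with a peptide flank written first (PND ≡ DNP); the 12
canonical patterns are PPP, PDP, PPD, PDD, DPD, DDD, PZP, PZD, DZD, PNP,
PND, DND. Every unordered neighbor pair counts (a triangle of peptides
yields PPP three times, once per middle), and flanks need not be in contact
with each other — concurrent interactions are counted explicitly. Two
normalizations are exported because the appropriate denominator is a
genuine modeling choice: per-cluster normalization averaged with equal
cluster weight (the default), and pooled raw counts over all clusters.
Ion mediation probability is the fraction of components of a kind with
≥ 2 peptide/drug neighbors, averaged over clusters containing that kind.

Chemical-group contacts attribute each peptide/drug contact to the named
atom groups involved (peptide: two imidazole groups and the
diketopiperazine ring; drug: charged/polar/hydrophobic groups), counted
once per (group instance, partner instance) and normalized per source
group. The shipped group map is a coarse default and fully user-overridable.

## Synthetic generators

The generators produce frames with the statistical structure the analysis
assumes; they are not force-field simulations.

**Templates.** Coarse rigid pseudo-atom molecules: peptide = 10 atoms
(4-atom diketopiperazine ring + two 3-atom imidazole groups, ~8.6 Å span),
drug = 8 atoms in charged/polar/hydrophobic groups, Zn²⁺/Cl⁻ = 1 atom,
NO₃⁻ = 4 atoms. Enough structure for group attribution and SASA without
any parameterization.

**Planted configurations.** Clusters are grown one component at a time at
a minimum inter-atom distance in [σ, d_c) from a previously placed member
(σ = 2.0 Å hard core), so connectivity at the cutoff holds by
construction; bulky components are placed before ions because decorating a
dense ion blob with a 10-atom molecule has a vanishing acceptance rate.
Growth is confined to a ball of radius L/4 around the anchor, which bounds
cluster extent below L/2 — clusters can straddle the periodic boundary
(anchors are uniform over the box) but can never touch their own periodic
image or percolate. Distinct clusters and scattered components stay more
than d_c + 1 Å apart, so the planted partition is exactly the contact
partition. Placement is rejection sampling with a bounded attempt count;
an over-packed box raises an error instead of looping.

**Monte Carlo co-assembly.** Single-component rigid-body Metropolis moves
(translation uniform in ±3 Å per axis, rotation up to 45°) with a
square-well pair potential: infinite below the hard core σ = 2.0 Å,
−ε(kind_a, kind_b) when the minimum inter-atom distance lies inside
[σ, r_w), zero beyond. The well range r_w equals the contact cutoff so
"interacting" means the same thing to the generator and the analyzer.
Like-charged ion pairs (Zn–Zn, NO₃–NO₃) may not attract and carry a +2 kT
penalty inside the well, mirroring their exclusion from the pair
statistics. Energies are tracked incrementally and audited against full
recomputation. Affinity presets encode three qualitative drug behaviours
on top of a shared peptide/ion background (ε(P,P)=2.5, ε(P,Z)=ε(P,N)=
ε(Z,N)=3.0 kT): *nitrate-coordinating* (ε(D,N)=4, ε(D,P)=2.5, ε(D,D)=2 kT),
*zinc-coordinating* (ε(D,Z)=4 instead), and *inert* (all drug wells zero).
The background strengths were chosen once so that the reference
composition assembles clusters well past the size-31 analysis threshold
within ~100 sweeps at kT=1; they are conditions of the synthetic study,
not fitted quantities.

What the MC generator does *not* emulate: solvent structure, hydrogen-bond
directionality, polarization/charge transfer at Zn²⁺, conformational
flexibility, NPT volume fluctuations, and realistic kinetics. Passing
parameter-recovery tests therefore shows that the analysis pipeline
faithfully measures planted interaction structure — not that any particular
real drug behaves as modeled.

## Parameter-recovery experiments

The benchmark experiments run the reference +1-drug composition
(216 components) for 80 MC sweeps, sampling every 20 sweeps and discarding
the first sample as burn-in; 10 seeds per condition. These problem sizes
are the package's chosen benchmark scale — large enough for assembly past
the size-31 threshold, small enough to run routinely. Encapsulation
summaries are evaluated over clusters of size ≥ 31, the same focus the
analysis applies to real trajectories: the per-cluster probability of
containing a drug is only a meaningful affinity readout on genuinely
co-assembled aggregates (a high-affinity run concentrates all drugs in one
large cluster surrounded by small drug-free satellites, which *lowers* the
naive all-cluster fraction). The mediation signature is evaluated
cross-condition — DND+PND higher in nitrate-coordinating than
zinc-coordinating ensembles and vice versa for DZD+PZD — because peptides
coordinate NO₃⁻ in every condition, so nitrate-mediated motifs are never
rare in absolute terms.

## Classifier

Features are standardized with training-set mean/sd only (constant features
pass through unscaled); one linear-kernel SVC (C = 1.0) is fitted per class
pair; prediction is by majority vote with ties broken toward the lowest
class index. Linear kernel and C are defaults, not claims about the best
kernel — they make the binary learners' feature weights directly
inspectable, which is the point of the feature-weight report. Models
serialize to JSON (weights, intercepts, standardization, class order) and
reload without sklearn state.

## Numerical choices and degenerate inputs

- Ties at exactly the contact cutoff are excluded (strict `<`).
- Clusters of size < 3 have no triplets; empty tables propagate as zeros
  in feature vectors.
- Ratios for peptide-free clusters are NaN with a warning, not an error.
- A single-cluster size bin reports sd = 0 with an explicit
  `sd_defined = False` flag.
- Empty cluster lists raise in the summary functions (an ensemble with no
  clusters is a caller-level decision, recorded as 0 in the benchmark
  experiments).
- All randomness flows through one `numpy` Generator per call, seeded
  explicitly; identical seeds give bitwise-identical trajectories, and the
  pipeline manifest records seeds and content digests per stage.

## Known limitations

- The contact criterion is purely geometric; no hydrogen-bond geometry or
  energetic weighting.
- No cross-frame cluster tracking (no residence times or growth kinetics).
- SASA is sampled, not analytic (Lee–Richards is out of scope); accuracy is
  bounded by the point count.
- The group map and drug templates are coarse stand-ins; group-level
  results on real systems require a user-supplied map matching the actual
  chemistry.
- Only cubic boxes; triclinic cells are unsupported.
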