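# Methods

## Model

`caindex` treats a comparative-anatomy dataset as a character matrix over
(species × muscle × parameter) cells. Four parameters are scored per
muscle — innervation, origin, insertion, vascularization — each as a
relative-frequency concordance RF ∈ [0, 1]. Within one species, RF is the
fraction of specimens showing the normal pattern, (N − nv)/N. Across
species, RF expresses concordance with a designated reference species:
1 when the pattern is identical, 0 when the parameter (or the whole
muscle) is absent or fully divergent, fractional for partial differences
such as an extra head of origin or a missing tendon slip.

The per-muscle summary is the pondered average of frequencies,
PAF = Σ wᵢ·RFᵢ / Σ wᵢ, with default weights innervation 3, origin 2,
insertion 2, vascularization 1. The weights encode an assumption, not an
estimate: nerve supply is the most phylogenetically conservative parameter
and arterial supply the least, so discordance in innervation should move
the index most. The weights are configurable (`WeightScheme`); all outputs
are invariant to scaling the weights by a common factor, so only their
ratios matter.

The Comparative Anatomy Index between two species for one muscle is
CAI = |PAF₁ − PAF₂|. It is a pseudometric on PAF values (symmetric,
non-negative, triangle inequality; distinct RF vectors can share a PAF and
hence sit at distance zero). Group CAI (GCAI) is the unweighted arithmetic
mean of the member muscles' CAIs — every muscle counts equally regardless
of size or functional importance. Bands: CAI = 0 is *highly similar*, and
the intervals (0, 0.200], (0.200, 0.650], (0.650, 1] are *similar*,
*somewhat similar*, *dissimilar*. The source tables label the knot values
themselves with the lower band (0.20 is "similar", 0.250 is "somewhat
similar"), so the intervals are implemented upper-closed, with exact zero
exclusive to the top band.

A documented convention handles highly polymorphic structures: a muscle
known to vary within a species (the human palmaris longus, absent in ~10%
of the population) can have its RF vector shrunk by per-parameter fractional
decreases (`AdjustmentSpec`; the study convention is 10% on innervation and
vascularization, 50% on origin and insertion, reflecting where the
variation concentrates). The operation is provided exactly as stated; note
that for the palmaris longus the published CAI (0.425) does not equal the
mechanically adjusted value (0.3), which is why that cell ships as an
override (below).

## The packaged study dataset

`load_fixture()` returns the capuchin forearm matrix: reference *Cebus*,
comparisons *Homo*, *Pan*, *Papio*; 5 superficial flexors, 3 deep flexors,
11 extensors (muscle spellings follow the source tables verbatim, with a
synonyms map for display). Each of the 57 comparison cells is tagged:

- **derivable** (39 cells): a unique binary/absent RF encoding reproduces
  the published CAI exactly under weights (3, 2, 2, 1). This covers every
  CAI = 0 cell (all-1 vectors), the single-parameter differences (e.g.
  flexor carpi radialis vs Homo, vascularization only, CAI 1/8), and the
  two muscles scored as inexistent (all-0 vectors, CAI 1).
- **override** (18 cells): the published CAI admits no recoverable RF
  decomposition at total weight 8 (e.g. the repeated extensor value 0.22,
  published in an antecedent study under its own conventions, or the 0.375
  "heads of origin" cells whose second counted parameter is unstated).
  These cells carry the published value verbatim, are flagged
  `from_override` in every result, and are logged as warnings whenever a
  report consumes them. Where a single consistent reading exists it is
  stored as the cell's RF vector (palmaris longus vs Homo:
  0.9/0.5/0.0/0.9; flexor digitorum profundus vs Pan: insertion RF 0.75)
  but is never asserted as ground truth.

Because overrides are defined only against the reference species, the
all-pairs distance matrix refuses to silently mix them: it raises unless
`ignore_overrides=True`, in which case distances are recomputed from the
stored RF vectors and the result is an exploratory view rather than a
published quantity.

## Synthetic data

`generate_matrix(SyntheticSpec(...))` emulates the statistical structure of
such a study: one all-concordant reference species and comparison species
whose parameters diverge independently. Per cell and parameter, divergence
occurs with probability `flip_probs[parameter]`; a divergence is full
(RF = 0) or, with probability `partial_prob`, partial (RF uniform on the
open unit interval — no empirical distribution for partial concordance is
available, so the choice is conventional and configurable). Non-divergent
cells carry specimen-level sampling: RF = (N − nv)/N with
nv ~ Binomial(`n_specimens`, `variation_prob`), which quantizes RF to
multiples of 1/N as real specimen samples do.

Defaults mirror the study's scale and are fixed once: 3 comparison
species, 5 muscles per group, 8 specimens (the study's sample size),
variation probability 0.1 (the human palmaris-longus absence rate), flip
probabilities 0.05/0.15/0.15/0.30 ordered inversely to the weights'
stability assumption, partial probability 0.2, seed 0. A single
pseudo-random stream is seeded once per call and consumed in a fixed,
documented order (species-major, muscle-minor, parameters in canonical
order), so matrices are bit-reproducible across platforms.

In the full-flip regime (`partial_prob = variation_prob = 0`) the mean CAI
against the reference has the closed form Σ wᵢ·pᵢ / Σ wᵢ (every RF deficit
is one-sided, so the expected absolute difference equals the expected
deficit); `expected_cai` also accepts a `variation_prob` term via
E[RFᵢ] = (1 − pᵢ)(1 − v). `recover_flip_probs` inverts generated matrices
by counting RF = 0 cells per parameter, an unbiased binomial estimator in
the same regime. What passing synthetic tests show is calibration of the
machinery — not that real anatomical divergence is independent across
parameters or species; the generator has no phylogenetic correlation
between comparison species, by design.

## Numerical choices

- PAF accumulates the weighted sum first and divides once, so eighths are
  exact in binary floating point under the default integer weights.
- Band classification applies a 1e-9 tolerance at the knots, protecting
  values that are exact eighths analytically but rounded in float.
- Reported values are rounded half-up (`round_half_up`, via `decimal`) to
  3 decimals in report tables; comparisons against published values are
  made at each value's printed precision (0.41666… matches a printed
  0.417; 0.02083… matches a printed 0.02).
- GCAI equals the member mean to ≤ 1e-12 and is invariant to member order.
- UPGMA ties (equal minimum distances) merge the pair whose sorted cluster
  names sort first; newick children are emitted in name order; branch
  lengths are written at 6 decimals. PHYLIP export uses the classic
  10-character name field at 6 decimals.

## Problem sizes

The simulation checks use 10,000 cells for the mean-CAI/closed-form
comparison (3-standard-error criterion) and 200 replicate matrices
(3,000 cells) for flip-probability recovery; both complete in seconds and
their acceptance bands come from binomial sampling theory, not tuning.

## Limitations

- Nineteen muscles, four parameters, three comparisons: the dataset is a
  desk-scale encoding of published tables, not a specimen-level database,
  and 18 of 57 cells rest on published values that cannot be re-derived
  from stated encodings.
- The index has no significance test; bands are descriptive conventions.
- GCAI's equal weighting of member muscles, and CAI's insensitivity to
  *which* parameters differ once the weighted sum is fixed (a pseudometric,
  not a metric), are inherent to the statistic.
- The distance matrix and UPGMA tree are phenetic conveniences; they do not
  infer phylogeny, and for override cells they rely on unverifiable RF
  readings.
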