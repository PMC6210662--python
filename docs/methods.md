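# Methods

## The model

`mtshazard` treats chemical hazard prioritization as one-class anomaly
scoring. A reference group ("unit space" or Mahalanobis space) of
relatively low-hazard chemicals defines what "unremarkable" looks like;
every chemical is then scored by how far its ten-dimensional quantified
hazard profile sits from that reference, accounting for the correlation
between endpoints. The further a chemical is from the low-hazard center,
the higher its management priority.

### Quantification

The ten variables are the GHS health endpoints after merging the three
acute-inhalation routes: acute toxicity (oral, dermal, inhalation), skin
corrosion/irritation, serious eye damage/irritation, germ-cell
mutagenicity, carcinogenicity, reproductive toxicity, and specific target
organ toxicity after single and repeated exposure. Categories map to
points (dimensionless):

| outcome | points |
| --- | --- |
| Category n (n = 1..5) | 100/n |
| Not Classified | 10 |
| Classification Not Possible | 30 |
| Not Applicable | 1 |

Classification Not Possible sits near Category 3 deliberately: a data gap
is not evidence of no hazard, and scoring it like Category 2 would
overweight it while scoring it like Not Classified would launder missing
data into safety. Every constant is overridable via
`QuantificationScheme` (and in the CLI config), because the final ranking
is sensitive to this mapping — that sensitivity is a known caveat of the
approach, not something the package can remove.

The "most conservative" order used for the inhalation merge is the
descending-score order of this table:
Cat 1 > Cat 2 > Cat 3 > Classification Not Possible > Cat 4 > Cat 5 >
Not Classified > Not Applicable. No published convention pins down where
Classification Not Possible falls in this merge; tying the order to the
quantification scheme keeps the two notions of "worse" consistent, and a
custom scheme moves the merge order with it.

Sub-categories 1A/1B normalize to Category 1, matching their severity
under GHS and the fact that the scheme scores only "Category 1". Empty or
unrecognized cells become Classification Not Possible with a warning
(strict mode rejects them instead), consistent with "insufficient
information".

### Unit space

Selection criteria (all configurable in `SelectionCriteria`): zero
Category 1 endpoints, zero Category 2 endpoints, total score ≤ 280
points. The threshold is inclusive (`280 or less`); sources are
inconsistent between "≤ 280" and "< 280", so the bound and its
inclusivity are both parameters. The worked example: a chemical with nine
Not Classified and one Classification Not Possible totals 9·10 + 30 =
120 and is admitted.

Fitting uses plain sample statistics: per-variable mean, standard
deviation with the n−1 divisor, and the sample Pearson correlation matrix
R of the standardized member scores. At least k + 2 members are required
(k = 10 variables) or selection aborts with advice to relax the criteria.

### Scaled Mahalanobis distance

MD(x) = zᵀ R⁻¹ z / k with z the member-standardized profile. This is the
classical scaled MTS form; the scaling by k makes the statistic
dimension-free and yields the identity Σ members MD = (n−1)·k / k·n, i.e.
mean member MD = (n−1)/n, which the tests assert to 1e−8 and which is a
useful online check that a fitted space and its scorer agree. Because the
published MD values for the original 3000-chemical application cannot be
re-derived without that dataset, the constant factor is configurable in
effect: an unscaled distance is `md * ref.k`.

Numerical choices:

- **Singularity.** If the smallest eigenvalue of R is below 1e−10 times
  the largest, the Moore–Penrose pseudoinverse replaces the inverse (with
  a warning). Eigenvalue inflation was rejected because it silently
  distorts every distance.
- **Degenerate variables.** Zero-variance variables are excluded from z
  and from k, recorded in `ReferenceSpace.degenerate`. Scoring never
  divides by a zero SD.
- **Ties and determinism.** Ranks are competition ranks on descending MD
  (ties share a rank, the next is skipped). Nothing in the module is
  randomized; results are reproducible bit-for-bit.
- Unit-space members are scored against the reference fitted on all
  members (single-pass, no leave-one-out), matching the intended
  screening workflow.

### Grading

Four class-interval methods cut the MD distribution into k = 4 ordered
grades (grade 4 = most hazardous). Intervals are half-open [low, high)
with the final class closed; a value exactly on a break goes up.

- *Equal interval*: breaks at min + i(max−min)/k.
- *Quantile*: type-1 (inverse empirical CDF) quantiles; each break is the
  smallest value of the next class, so tied values never split and
  distinct-valued inputs differ in class size by at most one.
- *Jenks natural breaks*: exact Fisher–Jenks dynamic program minimizing
  total within-class squared deviation, run on the unique values weighted
  by multiplicity (O(k·u²)); this guarantees ties share a class and is
  verified against brute-force enumeration in the tests.
- *Geometric interval*: multiplicative (log-equal) breaks
  min·(max/min)^(i/k); for non-positive minima the scores are shifted by
  1 − min, cut, and shifted back. The name covers several conventions in
  the GIS literature and none is canonical; the multiplicative rule is
  this package's documented choice and the classifier dispatch makes
  alternatives pluggable.

Degenerate (constant) inputs collapse to a single grade with a warning
rather than erroring, since a screening run should survive a pathological
batch.

### Agreement and validation

External CRS scores (e.g. EURAM, CHEMS) are opaque numeric columns — the
package never computes them. Score-level agreement uses the sample
Pearson correlation with a two-sided t test (n−2 df), unadjusted for
multiple comparisons. Grade-level agreement uses Cohen's kappa in the
disagreement-weight formulation κ = 1 − Σw·o / Σw·e with
w_ij = (|i−j|/(k−1))^p, p ∈ {1, 2}, and 0/1 weights for the unweighted
case; this is algebraically identical to the agreement-weight form and
gives one code path for all three weightings. A table with all mass in a
single cell has zero expected disagreement; κ is defined as 1 there, with
a warning. Weighted kappa typically (not provably) grows with the weight
exponent on near-monotone tables; the tests treat that only as a soft
expectation.

Regulatory validation counts, among chemicals on a regulatory list (one
CAS per line, `#` comments), the fraction graded 3–4 (true positives) and
the same fraction among unlisted chemicals (false positives). Group
summaries report arithmetic means with Student-t 95% confidence
intervals — t rather than normal because regulatory subgroups are
routinely tiny (n = 3–5), where the difference is material; singleton
groups are flagged with an undefined interval.

## The synthetic-data generator

Real GHS tables provide ordinal categories with a characteristic pairwise
correlation pattern in their quantified scores (skin/eye ≈ 0.70, acute
oral/dermal ≈ 0.60, STOT single/repeated ≈ 0.53) and a substantial rate
of data gaps. The minimal generative structure reproducing both is a
latent-Gaussian threshold model: each chemical draws a correlated
standard-normal latent severity vector (Cholesky factor of a target
correlation matrix, eigendecomposition at the semi-definite boundary),
and each coordinate is discretized through per-variable ascending
thresholds into exactly the categories that variable defines. Default
thresholds put the Category 1/2 region above z = 1.645 (≈5% of background
cells), which keeps a usable low-hazard normal group. Cells are then
independently masked to Classification Not Possible (default p = 0.25,
reflecting pervasive data gaps in real classification tables) or Not
Applicable (default p = 0.05). The default latent correlation encodes the
strong pairs above, moderate CMR-endpoint associations and a weak 0.05
background.

Planted hazards (default 10) are forced to the top defined category on a
uniformly drawn 6–10 of the ten variables; the remaining cells follow the
background process. They carry ground-truth labels so recovery — all
planted hazards in the top decile of MD ranks — is checkable end to end.

What the generator does **not** emulate: the marginal category
frequencies of any real inventory, missingness that is *informative*
(in practice data gaps concentrate in less-studied chemicals), physical
or environmental hazard classes, and real CAS numbering. Passing tests
therefore demonstrate that the pipeline's statistics behave as designed
under a controlled data-generating process — not that the resulting
ranking of any real inventory is toxicologically validated. One seeded
`numpy` generator drives each run; the seed is recorded in the run
manifest and CSV output is byte-reproducible.

Two fixture sets anchor the synthetic world to published reality: the
flutolanil low-hazard profile (nine Not Classified, one Classification
Not Possible; the data-gap endpoint is placed on acute inhalation — the
source does not name it and the total is unaffected) and ten well-known
extreme-hazard chemicals (sulfur mustard, nitrogen mustard, aziridine,
sodium dichromate, diethyl sulfate, chloromethyl methyl ether, phenol,
captafol, 1,4-dichloro-2-butene, dieldrin) with their GHS category
profiles, used as extreme-profile probes rather than as numeric MD
targets.

## Problem sizes

The test suite and `scripts/acceptance.py` run populations of 120–5000
chemicals (3000 for the end-to-end planted-hazard check, mirroring the
scale of a national inventory screen; 5000 where correlation estimates
need tight sampling error; 100 seeds × 120 chemicals for the
planted-vs-background expectation). The whole suite completes in a few
seconds on one CPU.

## Known limitations

- Rankings depend on the quantification constants; there is no
  data-driven calibration of the category scores in this package.
- The conservativeness position of Classification Not Possible in the
  inhalation merge is a modeling choice (tied to its 30-point score).
- The geometric-interval algorithm is a convention, not a standard.
- No variable-selection step (orthogonal arrays / signal-to-noise ratios
  from the broader MTS toolbox) is included: the scope is the distance
  ranking itself.
- Covariance-shrinkage estimators for small or noisy unit spaces are out
  of scope; the pseudoinverse fallback only addresses exact singularity.
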