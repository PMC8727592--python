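# Methods

## Model

A mixed-cell sample's methylation profile is treated as a linear blend of
its constituent cell types' profiles. For beta values y over a set of
signature CpGs and a signature matrix X whose column k holds cell type k's
mean beta at those CpGs, the composition w is estimated by constrained
least squares:

    ŵ = argmin_w ‖y − Xw‖²   subject to   w ≥ 0

optionally with Σw ≤ 1 or Σw = 1. The linearity assumption holds exactly
for beta values under equal per-cell DNA content (a mixture's methylated
fraction at a CpG is the cell-count-weighted mean of its constituents);
deviations come from measurement noise, probe chemistry and cell types
absent from the panel. The default imposes no sum constraint: with an
informative panel the estimated sums land near one on their own, and how
far they stray is a useful diagnostic. Any renormalisation to exactly one
is left to the caller as an explicit step, since raw solver outputs are
what the validation metrics consume.

Solvers are deterministic throughout: Lawson–Hanson NNLS for the
nonnegative case, ordinary least squares otherwise. The sum-to-one case
with nonnegativity is solved by NNLS on a penalty-augmented system (an
extra row of weight ρ = 10⁶·max|X| enforcing Σw = 1, followed by exact
renormalisation of the O(ρ⁻²) slack); without nonnegativity by the KKT
linear system. Σw ≤ 1 uses the convex KKT logic: if the unconstrained-sum
optimum satisfies the bound it is returned, otherwise the constraint binds
and the problem reduces to the equality case.

## Signature probe selection

For each cell type, each probe is scored by a pooled-variance two-group
comparison of that type's reference samples against all other reference
samples. The statistic is reported as F = t² with 1 and n − 2 degrees of
freedom; Δβ is the difference of group means. Probes with zero pooled
variance are assigned F = ∞, p = 0 when the means differ and F = 0, p = 1
when they do not. Missing betas are dropped probe-wise.

Selection first restricts to p < 1 × 10⁻⁸, then ranks. Mode "both" takes
the top 50 probes by Δβ among positive deltas (hypermethylated in the
type) and the top 50 among negative deltas; mode "any" takes the top 100
by |Δβ|. Ties break by larger |Δβ|, then smaller p, then lexicographic
probe id, so selection is invariant to input order. Per-type lists may
share probes; the design matrix keeps one copy of each (deduplicated
union). When fewer significant candidates exist than requested, the
shortfall is allowed and logged; a cell type with no significant candidate
at all is an error. Whether "both" should rank by Δβ or by p within
direction is genuinely open; this implementation ranks by Δβ and records
the choice in the signature metadata so either convention can be compared.

## Quality control

Samples with mean detection p-value > 0.01 are removed first (a failing
sample must not doom probes), then probes that fail detection
(p > 0.01) in at least one retained sample or carry an exclusion flag
(SNP at the interrogated CpG, sex-chromosome location, cross-reactive
design). Removal reasons are attributed to the first matching cause in the
fixed order detection → SNP → sex → cross-reactive, so report counts are
disjoint and deterministic. Probes absent from the annotation are treated
as unflagged and noted in the report.

Normalisation is cross-sample quantile normalisation: each sample is
mapped onto the mean empirical quantile function across samples
(interpolated onto a common grid when missingness makes counts unequal),
optionally within probe-design strata. This is a deliberate stand-in for
subset quantile normalisation: it provides the same monotone cross-sample
harmonisation while leaving the exact SQN internals out of scope, which is
also why probe counts derived from public array archives are not expected
to be bit-reproducible here. Normalisation runs after probe filtering, and
the QC report records that ordering.

## Synthetic data

The generator emulates a sorted-cell reference study and its validation
mixtures.

* **Profiles.** Background probes share one mean across cell types, drawn
  from an equal mixture of Beta(0.5, 5) and Beta(5, 0.5) — the bimodal
  landscape of methylation arrays. Each cell type receives
  `n_signature_per_type` planted hypermethylated and as many
  hypomethylated probes; at a planted probe the other types share a common
  mean and the owning type's mean differs by at least `delta` (default
  0.5). No planted probe discriminates more than one type.
* **Individuals.** An individual's beta at a probe with cell-type mean m
  is Beta(ms, (1 − m)s) with precision s, i.e. variance m(1 − m)/(1 + s).
  Means are clipped to [0.005, 0.995] before parameterisation to keep Beta
  parameters positive, so the infinite-precision limit is the clipped
  mean. Gaussian noise is avoided because betas live on [0, 1].
* **Pools.** Pooling equal DNA masses averages methylation fractions, so a
  pool column is the arithmetic mean of its member columns and records the
  summed number of contributing individuals.
* **Mixtures.** True weights are Dirichlet draws; the default
  concentration (6.4, 2.4, 0.8, 0.2) mirrors the macrophage-dominant,
  epithelial-scarce composition typical of lavage fluid. Observed betas
  are Beta noise around the weight-blended means at `noise_precision`
  (default 200; purified-replicate noise levels are not published, so this
  default is a package choice recorded in every manifest). Each mixture
  may carry an unprofiled DNA-free fraction (default uniform on
  [0.1, 0.5], mirroring cytometry runs that identify 50–90% of events);
  it scales the simulated "original" cytometry truth but never touches the
  methylation signal, reproducing the distinction between compositions
  over all events and compositions rescaled to the DNA-bearing types.
* **Detection p-values.** Passing entries uniform on [0, 0.005], failing
  entries uniform on (0.01, 1], with a configurable failure rate.

What the simulation does not model: probe-chemistry intensity effects
(Type I/II differences beyond an optional stratum label), batch effects
beyond a label, cell subtypes within a panel type, and spatially
correlated noise. Passing tests on synthetic data therefore demonstrate
the correctness of the algorithms under the stated noise model, not
robustness to every artefact of real arrays.

## Validation metrics

* **Flow rescaling.** Cytometry percentages over the four profiled types
  are divided by their sum (×100), putting cytometry on the same footing
  as methylation estimates, which cannot see DNA-free cells.
* **MSE.** Mean squared error on the fraction² scale, by cell type
  (averaging over samples) or by subject (averaging over cell types). The
  per-subject reading is the one consistent with published per-subject
  composition tables; both are computed.
* **Bland–Altman.** difference = estimate − truth; bias is the mean
  difference, limits of agreement bias ± 1.96 SD, summarised per cell type
  and overall.
* **Invariant probes.** Probes with within-type mean beta ≥ 0.95 in every
  type (or ≤ 0.05 in every type) should stay on the same side of 0.5 in
  mixtures of those types; the per-mixture consistent fraction quantifies
  whether unprofiled nucleated cells are present. Relaxing the thresholds
  can only grow the probe set.
* **Pooling regression.** OLS of per-sample variance across all retained
  probes (not just signature probes, since the question is global
  representativeness) on pool size; slope, adjusted R² and the slope's
  two-sided p are returned. A constant response is reported as slope 0,
  p = 1 rather than an undefined ratio.
* **Classical MDS.** Torgerson scaling of Euclidean distances on the
  top-variance probes (default 1000), with per-dimension variance
  fractions; purified types should separate in the leading dimensions.

## Numerical choices and degenerate inputs

Tolerances: signature-equality constraint verified to max(tol, 10⁻⁶);
round-trip I/O asserted to 10⁻¹² (beta) and 10⁻⁹ (proportions);
rank-deficient designs and empty probe intersections are errors rather
than silent pseudo-inverses. Missing betas never propagate: QC means skip
them, statistics drop them probe-wise, and projection drops them pairwise
per sample so one bad probe costs only that sample's observation.
Single-sample matrices pass through normalisation unchanged with a
warning. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give bit-identical outputs, and the CLI writes the seed
and all parameters into a JSON manifest.

## Problem sizes

The test-suite and acceptance computations use 1,500–5,000 probes, 2–3
reference samples per cell type and 4–20 mixtures. These sizes leave every
statistical check well-powered for its tolerance (e.g. 60 planted
candidates per direction against a 50/100-probe request; 20 mixtures for a
per-cell-type MSE bound of 0.005) while keeping the whole suite fast;
results are insensitive to scaling the probe count up.

## Known limitations

* The projection assumes every nucleated cell type in the mixture is in
  the panel; a missing type's weight is absorbed by the most similar panel
  column (tested directionally with a macrophage-like fifth type).
* Equal-variance statistics without moderation are intentionally classical;
  very small reference groups (n = 2) make the 10⁻⁸ threshold demanding,
  which the shortfall logging surfaces.
* The quantile-normalisation stand-in equalises full beta distributions
  across samples; with few probes or strongly divergent panels this can
  slightly distort signature contrasts.
* Proportion estimates are compositional; downstream EWAS adjustment and
  any renormalisation policy are out of scope.
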