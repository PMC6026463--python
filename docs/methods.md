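# Methods

`isodiet` reconstructs the diet of a consumer from triple stable-isotope
measurements (δ¹³C, δ¹⁵N, δ³⁴S, all in ‰ against VPDB, air-N₂ and VCDT
respectively) of the consumer's tissue and of its candidate prey, with
optional gut-content information as prior knowledge. The default
configuration carries the published summary statistics of a Baltic Sea
winter-diet study of the Velvet Scoter (*Melanitta fusca*), in which five
soft-bottom macrozoobenthos end-members (the isopod *Saduria entomon*, the
shrimp *Crangon crangon*, the bivalve *Macoma balthica*, a pooled
*Mya arenaria* + *Cerastoderma glaucum* group, and polychaetes) are mixed
to explain the blood values of live-caught scoters.

## Lipid normalization

Lipids are depleted in ¹³C, so lipid-rich prey tissue biases δ¹³C low.
Carbon values of source tissue with C:N mass ratio above 3.5 (the standard
gate for aquatic organisms) are corrected arithmetically:

    δ13C = δ13C_untreated − 3.32 + 0.99 × C:N

At or below the gate the value passes through unchanged. The correction is
applied per sample before group averaging; although the formula is linear,
correcting rounded group means instead changes second-decimal digits.
Consumer blood is never corrected.

One caveat carried by the built-in dataset: the published corrected mean
for *M. balthica* (−21.5) is not reproducible from its printed untreated
mean and C:N (the formula gives −21.37); the corrected means used here are
recomputed at full precision from the untreated means, and *Macoma* is
excluded from exact-match tests. Corrected-column SDs are taken as
published, since per-sample corrections cannot be reconstructed from
summary rows.

## Trophic enrichment factors

A TEF (λ ± τ, ‰) is the expected isotopic shift between diet and consumer
tissue; it is added to each source before mixing. Four named sets are
built:

| set | δ¹³C | δ¹⁵N | δ³⁴S |
|---|---|---|---|
| model0 | per-source, −0.199·δ¹³C_source − 3.986 | 2.25 ± 0.01 | 0 ± 0 |
| modelA | 1.0 ± 0.2 | 4.5 ± 0.2 | 0 ± 0 |
| modelB | 0.4 ± 0.17 | 2.67 ± 0.7 | 0 ± 0 |
| modelC | mean of the model0 values ± 0.01 | 2.25 ± 0.01 | 0 ± 0 |

The model0 carbon uncertainty is first-order propagation of the
source-mean standard error through the linear function (|slope|·SE). The
nitrogen TEF uncertainty is quoted two ways in the source literature (0.01
in the fitted models, 0.20 in running text); the default is 0.01 with a
`nitrogen_sd` override. The sulphur TEF is zero everywhere because the
mean reported trophic shift for sulphur does not differ significantly from
zero. Evaluated at the five end-members, the model0 carbon TEFs span −0.2
to 0.4 ‰ and average 0.17 ‰.

Pooling of the two indistinguishable bivalves uses the unweighted average
of their corrected means and the equal-weight two-component
Gaussian-mixture SD when only summary rows are available
(`pool_summaries`); when raw samples exist, `pool_groups` recomputes the
statistics over the union of samples instead.

## Mixing-polygon validation

A consumer can only be explained as a mixture if it lies inside the convex
hull of the TEF-corrected sources. Because sources and TEFs are uncertain,
the hull is iterated: each of `n_iter` (default 1500) iterations draws
every source position per tracer from Normal(mean + λ, √(SD² + τ²)) and
takes the convex hull of the K points. A consumer's inclusion probability
is the fraction of hulls containing it (boundary inclusive — conservative
retention). With three tracers the polygons are built in the three
pairwise projections, matching the biplot representation of the original
analysis rather than a 3-D hull; a consumer is retained only if its
probability is ≥ 0.05 (the 95% mixing region) in **all three**
projections. Whether the original exclusion rule was per-projection or
joint is not documented; any-projection failure is this package's default
and is configurable through the threshold. Source spread uses the group SD
(not the SE of the mean), composed with the TEF SD in quadrature. One
seeded RNG stream per projection, derived from a master seed, makes the
gate exactly reproducible.

Degenerate draws (collinear points) are treated as zero-area regions with
boundary-only inclusion.

## The mixing model

The likelihood is the classic Dirichlet-prior mixing formulation: for
consumer i and tracer j,

    X_ij ~ Normal( Σ_k p_k (μ_jk + λ_jk),
                   Σ_k p_k² (ω_jk² + τ_jk²) + σ_j² )

with diet proportions p on the K-simplex, source means/SDs μ/ω, TEFs λ/τ
and a per-tracer residual SD σ_j. The p² variance weighting follows the
fully hierarchical convention of the model family this replicates;
alternative mixing models weight variances by p instead, which matters for
uneven diets. σ_j absorbs consumer-level variation the source + TEF
variance cannot explain; with few consumers it is weakly identified, so it
carries a half-Normal prior with scale 1 ‰ (configurable; 0 removes the
term).

Priors: Dirichlet(α) on p. α = (1,…,1) is the uninformative default.
Gut-content priors set α = c·q where q are the gut proportions mapped onto
the model sources and c is the total concentration (default c = K, so a
uniform composition reproduces the flat prior exactly). Components are
floored at ε = 0.01 before rescaling to total c, so sources absent from
guts (soft-bodied prey digests away) keep positive prior mass. The
original analysis does not document its prior encoding; this construction
is the package's own choice, surfaced in configuration.

Sampling is random-walk Metropolis-within-Gibbs on the additive-log-ratio
transform of p (K−1 coordinates updated as one block; the Dirichlet
density combines with the transform Jacobian to Σ α_k log p_k) plus
per-tracer log-σ updates. Proposal scales adapt toward 25% (block) and 44%
(scalar) acceptance during burn-in only, so retained draws come from a
fixed kernel. Defaults: 40 000 iterations, 10 000 burn-in, thinning 10
(the original MCMC settings are unstated). Effective sample sizes are
computed per component; ESS < 100 triggers a warning but still returns the
result — near-zero α components mix slowly in ALR coordinates and their
posteriors are pinned near zero anyway. Summaries are the posterior mean,
SD and empirical 2.5–97.5 percentile interval in percent (percentiles, not
HPD, matching the published interval style).

Exact label-permutation equivariance does not hold draw-for-draw (the ALR
transform distinguishes the reference coordinate), but posterior summaries
are permutation-equivariant to within Monte Carlo error, which is what the
test suite asserts.

## Gut-content metrics

From per-bird prey records the composition table reports per taxon: total
wet weight (g) and percent, ash-free dry weight (organic matter, g and
percent), and frequency of occurrence (distinct birds containing the
taxon, as a percent of all birds analysed — birds with empty guts count in
the denominator). AFDW may be derived from wet weight by a taxon-specific
conversion fraction in (0, 1]. Trace items published as "<0.01 g" are
carried as zero weight, which is the reading that reproduces the published
percentages at two decimals.

Mapping gut taxa to model sources is an input, not an inference. The
default study mapping sends the unidentifiable mollusc mass
(36% of wet weight) to the bivalve end-members in proportion to their
identified weights, and drops fish and trace gastropods; this choice
reproduces the published direction of the prior effects (the isopod rises,
the shrimp and polychaetes collapse to a few percent).

## Synthetic data

The generator emulates the study's statistical structure rather than any
individual record: per-taxon source samples at the published means, SDs
and (unequal) per-tracer sample sizes; consumers built by the forward
mixing equation x_j = Σ_k p*_k (s_k + c_k) + ε with fresh source and TEF
draws per consumer (process error — the same variance structure the model
assumes) plus residual noise of SD 0.3 ‰ per tracer, a round value of the
order of the analytical repeatabilities; and gut tables with per-taxon
Bernoulli presence (probabilities from the published occurrence
frequencies), lognormal weights around the published mean
weight-per-occurrence, and a digestibility multiplier that deletes
soft-bodied taxa from the observable record. The default true diet p* =
(0.09, 0.13, 0.52, 0.08, 0.18) is the published flat-prior posterior mean,
with one component nudged by 0.01 because the rounded percentages sum to
99.

What passing synthetic tests does **not** show: real consumers are mobile
and may not be at isotopic equilibrium with local sources; tracer values
within an individual are correlated (the generator draws them from the
mixing structure, the consumer emulator from independent truncated
marginals); and real gut contents have bird-level covariance the Bernoulli
model lacks. Parameter-recovery results therefore validate the inference
machinery, not field accuracy.

## Replication fidelity and problem sizes

Deterministic stages reproduce the published values at printed precision
(corrected carbon means at 1 d.p. except *Macoma*; TEF span and mean;
composition percentages at 2 d.p.). The posterior stage cannot be
reproduced exactly: the individual consumer values and the original MCMC
settings were never published. The replication run therefore emulates 7
consumers from the published per-tracer mean/SD/min–max by truncated
Normals under a fixed seed and checks the pooled-bivalve flat-prior
posterior mean against the published 52% within the published posterior SD
(±9). Under the high literature TEF set (modelA) the emulated consumers'
inclusion probabilities collapse to roughly a third of their model0 values
but fewer of them are excluded outright than in the original data — the
marginal emulation regresses individuals toward the centroid — so the test
suite asserts the directional collapse, not the published exclusion count.

Default problem sizes (40 k MCMC iterations, 1500 polygon iterations,
50-replicate coverage experiments at 10 k iterations each) are chosen so
the complete suite runs in a few minutes on one CPU while keeping Monte
Carlo error well inside every asserted tolerance.
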