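# Methods

## The gene-conversion coalescent (`coalescent_gc`)

The simulator runs the exact ancestral process for a sample of `n`
haplotypes over a genome of `L` bp, with time in units of 2·N_e generations.
Lineages carry their ancestral material as integer interval sets tagged with
descendant bitmasks. Three event classes compete:

- coalescence at rate k(k−1)/2 for k live lineages — segment lists merge,
  masks union, and any stretch whose mask reaches all samples has found its
  local MRCA and is dropped;
- gene-conversion initiation at rate (ρ/2)·L per lineage — an initiation
  point is uniform on the genome, the tract covers `tract_length` bp
  truncated at the sequence end, and the lineage splits into tract and
  complement carriers. Events whose tract fails to split the lineage's
  material change nothing and are skipped (rate thinning); the recorded
  event count is therefore the count of *effective* conversions, exactly
  zero when ρ = 0;
- mutation at rate (θ/2) per ancestral-material site, placed on distinct
  integer positions (infinite sites, with rejection of collisions; the
  guard requiring L to comfortably exceed the expected number of
  segregating sites keeps rejections rare).

Tract length is fixed per run, not geometric — matching a training design
in which each simulation draws one tract length. The construction is the
full ancestral recombination graph, not a sequentially Markovian
approximation; at the package's desk scale (L ≤ 50 kb, ρL ≤ ~200) the event
count stays in the tens of thousands and a run costs milliseconds to a few
hundred milliseconds. The test suite spot-checks the engine against
msprime's gene-conversion coalescent on mean S, mean π and the
recombination-shrunk variance of S.

Degenerate inputs: θ = 0 is allowed (no mutations); ρ = 0 falls back to a
plain Kingman genealogy; an event budget aborts pathological parameter
combinations with an error naming them.

## The transmission model and its closed form (`transmission_model`)

Hosts form a haploid Wright–Fisher population of size N_H, each carrying
N_S symbiont cells. Per generation: every symbiont switches to a uniformly
chosen other host with probability H; every next-generation host draws a
parent host and refounds its symbiont population through a bottleneck of
`b` cells (sampled with replacement) regrown instantly to N_S; newborn
cells gain Poisson(μ_g) mutations, each unique (infinite alleles with
difference counting — the model tracks a forest of mutation events, not
sequences, which suffices for pairwise-difference statistics at a fraction
of the cost; sequence emission is delegated to `synthetic_data`).

Populations are observed mid-generation, after switching, so a sampled host
holds both inherited and immigrant cells. Backward in time a pair of
lineages is either co-hosted (S) or split (D). With

- c_S = 1/b + (1 − 1/b)/N_S (coalescence through the shared bottleneck or
  founder coancestry),
- q = (1−H)² + H²/(N_H−1) (a same-pool pair stays co-hosted across one
  switching step),
- s = 2H(1−H)/(N_H−1) + H²(N_H−2)/(N_H−1)² (a split pair becomes co-hosted),

the expected coalescence times solve

```
T_S = 1 + (1 − c_S)[q·T_S + (1−q)·T_D]
T_D = 1 + (1/N_H)(1 − 1/N_S)[q·T_S + (1−q)·T_D] + (1 − 1/N_H)[s·T_S + (1−s)·T_D]
```

and expected pairwise differences are 2μ_g·(s·T_S + (1−s)·T_D) between
hosts and 2μ_g·(q·T_S + (1−q)·T_D) within one. The derivation is exact for
the discrete chain up to one approximation: the post-switch pool size is
treated as exactly N_S (error O(Var(pool)/N_S³)). In the H → 1 limit q ≈ s
and within- equals between-host diversity — the well-mixed regime in which
the structured model collapses toward a single panmictic coalescent; at
H = 0 with b = 1, T_S = 1 and hosts become internal clones while remaining
differentiated from each other.

Forward runs start clonal and burn in for max(10·N_H·N_S, 8·E[T_D])
generations, so the initial state is forgotten with high probability; the
stationarity floor 10·N_H·N_S is enforced on user-supplied burn-ins.
Host switching is global-uniform (no migration topology), and a host
emptied by switching is simply not available as a parent that generation.

The validation grid pairs the closed form against the forward simulation on
six (N_H, N_S, H) settings spanning H = 0.02 to H = 1 at N_H ≤ 100,
N_S ≤ 10, b = N_S//2, with μ_g set per setting so expected pairwise
differences sit at a handful of segregating sites — large enough to measure,
small enough that the replicate-mean's standard error stays well inside the
two-difference agreement band. The default bottleneck elsewhere is 30
cells, the order allocated to an oocyte during vertical transmission.

## Summary statistics (`sumstats`)

π is the mean pairwise difference count divided by the usable (non-gap,
non-N) length; Watterson's θ is S/(a_{n−1}·L_usable); Tajima's D uses the
standard 1989 constants and returns an explicit undefined sentinel at
S = 0. Folded spectra count minor alleles at biallelic sites. The
four-gamete profile considers unordered pairs of non-singleton biallelic
sites (minor count ≥ 2), asks whether all four haplotypic combinations
occur, and bins by distance into half-open bins (0,10], (10,10²], …,
(10⁵,10⁶]; empty bins are reported as missing, never as zero, and pairs
beyond the last edge are excluded and counted. F_ST is Hudson's estimator
as a ratio of sums across sites (with the finite-sample within-population
correction when haplotype counts are supplied), with a percentile bootstrap
over sites. Bootstrapping sites understates uncertainty when sites share
one genealogy — a caveat that matters for single-replicate forward-model
output, which carries no within-genome recombination.

## Regression ABC (`abc_rf`)

Priors: θ log-uniform on (3×10⁻⁵, 10⁻²), ρ log-uniform on (10⁻⁶, 10⁻²),
tract length uniform on (1, 10⁵) rounded to bp; a drawn tract longer than
the simulated genome is truncated by the simulator's own end-clipping, and
the *target* remains the drawn ρ·l. Features are π, Watterson's θ and the
six four-gamete bin proportions, with empty bins imputed to 0 plus a
missingness indicator each (14 features). Degenerate training rows (S = 0)
are kept, so the forest sees the prior's low-information floor.

One `RandomForestRegressor` per target — θ natural-scale, ρ·l as
log₁₀(ρ·l) — with 500 trees, `min_samples_leaf=5`, `max_features=0.33`
(chosen by out-of-bag score on the default training run; results are flat
across nearby settings). Point estimates are forest means. Intervals
combine two variance components: the infinitesimal-jackknife estimate of
the forest's own sampling variance (computed from bootstrap membership
counts, with the finite-B bias correction) and the out-of-bag residual
variance calibrated locally in ten quantile bins of the prediction. The
residual component dominates — forest predictions are far more certain than
they are accurate — and on 200 held-out simulations the resulting 95%
intervals cover truth for ~95% of draws on both targets.

Recovery at the desk scale (2,000 training simulations, n = 10, L = 20 kb):
out-of-bag rank correlation ≈ 0.97 for θ and ≈ 0.72 for log₁₀(ρ·l). The
ρ·l figure is an information limit of the 20 kb genome, not of the
estimator: in the lowest θ decade a 20 kb alignment holds too few
non-singleton SNP pairs to populate the four-gamete bins (rank correlation
0.52 there vs 0.82 in the top decade), and gradient boosting on the same
features does no better. Genome-scale data (megabases) do not have this
floor. Models are serialized with a feature-contract checksum and refuse
observations whose sample size differs from the training sample size.

r/m = ρ·l · θ_recombinant/θ_genome; when recombination happens within the
population, donor fragments are as diverse as the genome at large and
r/m = ρ·l.

## Within-host analysis (`intrahost`)

The caller takes decoded pileup columns and applies, in order: a coverage
window (depth within one standard deviation of the genome-wide mean), an
indel-proximity exclusion (default 5 bp around any indel-bearing column;
the window is a package choice, exposed as a flag), and a one-sided
binomial test — call the site when P(X ≥ alt count | depth, error rate) <
α, default α = 0.05 per site with an optional Bonferroni mode. The error
rate is fixed or derived per column from mean phred error. Per-site
within-host diversity is 2p(1−p)·d/(d−1) averaged over usable sites. By
construction the per-site rule admits up to α false calls on error-only
columns — the Bonferroni mode is the right choice when the quantity of
interest is the variant list rather than error-calibrated counts.

The read-backed four-gamete test tallies, for every pair of sites
co-observed on single read pairs, the counts of the four allelic
configurations. A pair is flagged as carrying all four gametes only when
total observations ≥ 100 and every configuration's proportion strictly
exceeds 0.05; pairs under the observation floor are reported but never
flagged. Observations carrying a base outside the site's two alleles
(default: the two most common observed bases) are discarded and counted.
Because pooled reads sample many more chromosomes than per-host consensus
sequences, the read-backed failure proportion is bounded below by the
consensus-based one on the same loci — a property the tests assert.

## Synthetic data (`synthetic_data`)

Generators are seed-deterministic and emit JSON manifests. Reads are drawn
as proper pairs from weighted haplotype mixtures with independent uniform
substitution errors (no indel errors, no GC bias, no duplicates, no mapping
error — so passing tests certify the statistical machinery, not robustness
to real sequencing artifacts); the pileup is assembled from the emitted
reads themselves, making depth accounting exact, and quality strings encode
the true error rate so phred-derived and fixed error modes agree. The
metapopulation generator emits consensus-like haplotypes either from the
panmictic coalescent (arbitrary host labels) or from forward transmission
runs (host labels carry real structure); forward-run sequences place each
mutation event at a distinct uniform genome position. Fixture F1 — four
100 bp haplotypes with three biallelic sites and eleven total pairwise
differences — is the shared hand-checked example (π = 0.018333…,
θ_W = 0.016364…, D ≈ 1.09).

## Numerical and scale choices

Desk-scale defaults throughout: 20 kb genomes, samples of 10, 2,000
training simulations, 100-replicate agreement grids. These sizes make every
check cheap to re-run while leaving each assertion statistically
comfortable (bounds sit several standard errors from their thresholds,
except where noted above). Monte Carlo checks state their uncertainty the
same way: replicate-level bootstrap where sites are linked, standard errors
of replicate means elsewhere. All randomness flows from explicit integer
seeds; derived seeds stay below 2³¹.

## Known limitations

- The forward transmission model tracks mutation counts, not sequences, and
  has no within-genome recombination; single-replicate genome-wide
  statistics therefore fluctuate with one shared genealogy.
- The gene-conversion ARG is exact but not built for genome-scale (Mb)
  simulation; the estimator's accuracy on 20 kb windows is information-
  limited at low diversity (quantified above).
- The four-gamete statistics assume infinite sites; recurrent mutation at a
  site would mimic recombination.
- Fst bootstrap intervals are over sites, not genealogies.
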