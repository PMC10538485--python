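# Methods

## Model

The pairwise sequentially Markovian coalescent (SMC) treats the coalescence
time (TMRCA) `T` of two homologous haplotypes as a Markov chain along the
genome. Time is measured in coalescent units of `2·Ne` generations, so the
equilibrium distribution of `T` at any single site is Exp(1) = Γ(1, 1).
Per base pair:

- **Transition.** With probability `1 − e^{−ρT}` (ρ = 4·Ne·r per bp) a
  recombination detaches one lineage at a height `u` uniform on `(0, T)`;
  the detached lineage re-coalesces at rate 1, giving a new TMRCA
  `u + Exp(1)`. Otherwise `T` is unchanged. The continuous part of the
  transition density is `q(t|s) = (1/s)(e^{min(s,t)} − 1)e^{−t}`, with an
  atom of weight `e^{−ρs}` at `t = s`. The continuous-time flux-balance
  identity `∫ s·q(t|s)e^{−s} ds = t·e^{−t}` holds exactly; the per-bp
  discretization preserves the Exp(1) marginal to `O(ρ²)`.

- **Emission.** A site is heterozygous with the linearized Poisson
  probability kernel `t^y e^{−θt}` (θ = 4·Ne·μ per bp, y ∈ {0, 1}); missing
  sites carry no likelihood. Against a gamma state this is conjugate:
  Γ(α, β) becomes Γ(α + y, β + θ).

The decoder represents every forward and backward density as a single gamma
distribution Γ(α, β), addressed equivalently by `(l_mu, l_cv) = (log10 mean,
log10 CV)`. The full posterior at a position is
Γ(α_f + α_b − 1, β_f + β_b − 1): the product of the forward and backward
gammas divided by the Exp(1) prior.

## Flow field and gamma projection

One transition step maps Γ(α, β) to the compound distribution
`p_{α,β}(t) = ∫ p(t|s) f_{α,β}(s) ds`. Its first two moments have closed
forms via the conditional moments `E[t|s] = e^{−ρs}s + (1−e^{−ρs})(s/2+1)`,
`E[t²|s] = e^{−ρs}s² + (1−e^{−ρs})(s²/3+s+2)` and the exponential-tilting
identity `e^{−ρs}f_{α,β}(s) = (β/(β+ρ))^α f_{α,β+ρ}(s)`. The default
projection back onto the gamma family is moment matching
(`α' = m²/v, β' = m/v`); a KL projection (matching `E[T]` and `E[log T]`,
quadrature-based) is available as `gamma_project(..., method="kl")` for
sensitivity analysis — on the data regimes tested the two are practically
indistinguishable. The constants in the closed forms are grouped through
`1 − c = −expm1(α·log1p(ρ/β))` so that concentrated low-mean states do not
lose their tiny variance to floating-point cancellation.

The projection is evaluated once per node of a fixed grid: 51 `l_mu` values
on `[−5, 2]` and 67 `l_cv` values on `[−2, 0.694]` at the spacing of a
50-point grid on `[−2, 0]`, so `l_cv = 0` (the stationary prior) is a node.
Off-grid states are clipped into the grid range and bilinearly interpolated
in `(l_mu, l_cv)` (log-space interpolation preserves positivity). The
extension of the CV axis above 1 is deliberate: see *Tracking very recent
coalescence* below.

## Locus skipping: run-resolved caches

Observation sequences are cut into segments ending at each het site, each
output position, and every `max_len` bp (default 10,000); inside a segment
only the counts of missing and hom base pairs matter, and the pass advances
over a whole segment with two cached lookups plus one terminal update.

The caches map every grid node and run length `n ∈ [1, max_len]` to the
gamma state after `n` (transition, hom-emission) steps (`hom` table) or `n`
transition-only steps (`missing` table). Two builders exist:

- `method="exact"` (default): the `n`-step run operator is resolved on an
  auxiliary time grid (512 geometric bins spanning `10^{−7}`–`200`
  coalescent units) by propagating the discretized transition matrix with
  interleaved emission weights, and the result is moment-projected to a
  gamma per (node, n). Because the moment vectors `Mⁿ·t^k` are shared by
  all nodes, the build costs `O(bins²·max_len + nodes·bins·max_len)`
  (~25 s at defaults) and is serialized for reuse.
- `method="iterated"`: composes `n` one-step flow-field projections, so a
  cached entry is bit-identical to `n` sequential
  `apply_flow`/`emission_update` calls (useful as a reference and for
  verifying the interpolation kernels).

The run-resolved builder is the package's resolution of a genuinely open
design point, and it is load-bearing. Iterating the one-step gamma
projection stalls on long homozygous stretches: each transition hands a
fraction `≈ ρ·m` of mass to a resampled component with mean ≈ 1, the single
gamma re-absorbs that tail every base pair, and the posterior mean locks at
the equilibrium `ρ/(ρ+θ)` (≈ 0.44 at the default rates) instead of
descending. The exact filter — verified directly against a discretized-HMM
reference — descends essentially like the conjugate update `Γ(1, 1+nθ)`
because the resampled tail is crushed by the subsequent emissions.
Resolving whole runs before projecting reproduces that behavior: within a
lookup the tail dynamics are exact, and projection error no longer
compounds per base pair. The same analysis shows the descending state is
over-dispersed (CV 2–4.6), which is why the grid's CV axis extends above 1;
clamping CV at 1 at segment boundaries re-stalls the descent.

### Tracking very recent coalescence

With the run-resolved caches and the extended grid, posterior means on data
whose true TMRCAs are ~100× smaller than the decoding parameters assume
land on the correct scale (hundreds of generations rather than thousands) —
the continuous state space spans the grid's seven decades of mean. The
positional resolution within such data is limited by the information
content itself: a discretized exact-posterior reference on the same
simulations attains only modest position-wise correlation, and this decoder
tracks a few percent below that reference.

At `ρ = 0` the transition is the identity and skipping uses the exact
conjugate fast path, so the whole decoder reproduces the closed-form
posterior to floating precision.

### Combination of over-dispersed passes

When both passes are heavy (`α_f + α_b ≤ 1`, reachable inside long
homozygous runs), the combined gamma is improper; the combined shape is
clamped at 0.01 (the clamp count is recorded on the track). The clamp
preserves the very-recent scale of such positions; raising the floor was
checked against the discretized exact reference and only degrades accuracy.

## Forward/backward structure

The forward state recorded at an output position conditions on all
observations up to and including that position. The backward pass runs the
same forward machinery on the reversed sequence, recording the state after
the observations strictly downstream of the position, then applies exactly
one extra flow-field transition. Forward and backward therefore condition
on disjoint observation sets that cover the data once, which makes the
ρ = 0 combined posterior exactly the full-data conjugate closed form (this
fixes the placement of the extra transition, which is otherwise a free
choice).

## Synthetic data

`simulate_smc_pair` draws the decoder's own generative process
(run-length-encoded), with a `scale` factor emulating simulation at
`Ne·scale`: both the recombination probability `1 − e^{−ρ·t_scaled}` and
the het probability `1 − e^{−θ·t_scaled}` see the rescaled time, matching
the physics of changing the effective population size with fixed per-bp
rates. It is the oracle for decoder-recovery tests. What it does not
emulate: real data's non-Markovian correlation structure (every simulated
recombination resamples the TMRCA, whereas in a real ancestral
recombination graph many recombinations leave the pairwise TMRCA
unchanged), variable mutation rate, genotyping error, and phasing error, so
decoder accuracy measured on it is conservative relative to
coalescent-simulator data.

`simulate_msprime_pair` delegates to msprime for benchmark-grade data
(constant size or the three-population out-of-Africa demography coded from
its published parameters: N_A=7300, N_AF=12300, N_B=2100, CEU/CHB growth
0.4%/0.55% per generation from sizes 1000/510 at the 848-generation split,
splits at 5600 and 8800 generations, symmetric migration 25/3/1.9/9.6 ×
10⁻⁵). `human_like_rate_map` builds a heterogeneous recombination map —
~2-kb hotspots every ~60 kb carrying 80% of crossovers, Mb-scale lognormal
background variation (σ = 0.7), normalized to a 1 cM/Mb genome average —
because accuracy benchmarks on a *constant* map are bounded well below the
values this class of methods attains on human-map data (map heterogeneity
leaves long cold, easily tracked tracts). The map parameters follow
published descriptions of human genetic maps and are fixed.

`simulate_sweep_panel` is a star-genealogy approximation of a selective
sweep: each haplotype carries an independent SMC-evolving time-to-root;
carriers' times are capped at `sweep_tmrca` at the sweep center, the cap
releasing linearly with distance out to `sweep_window`; mutations are
private to branches (every variant a singleton), giving pairwise het
probability `1 − e^{−θ(t_i+t_j)/2}` and truth TMRCA `(t_i+t_j)/2`. It
supports ranking/ROC evaluation of the scan statistic, not allele-frequency
based statistics.

## Selection scan

The statistic at a position is the fraction of haplotype pairs whose
posterior-mean TMRCA is below `T` generations (default threshold ladder
500…500,000), optionally averaged over a window (0/10 kb/100 kb defaults).
Genome-scan mode ranks non-overlapping 100-kb windows and marks the top
0.1% quantile as candidates, with thresholds expressible in years (4500 yr
at 30 yr/generation ≡ 150 generations). ROC/AUC evaluation uses
scikit-learn.

## Problem sizes and defaults

Benchmarks decode 30 Mb at 1-kb output spacing (30,000 positions; a few
seconds per pair after the one-time ~25 s cache build). Tests use shorter
caches (≤ 2,000 bp) and 1–4 Mb simulations; the sweep evaluation uses
12-haplotype, 1-Mb panels over 20 seeds. Defaults: θ = 0.00075, ρ = 0.0006
(μ = 1.25×10⁻⁸, r = 10⁻⁸, Ne = 15,000), generation time 30 yr, cache
10 kb, float32 cache storage (the auxiliary build runs in float64).

## Known limitations

- Constant-population-size transition model only; demographic
  misspecification biases absolute times (relative structure is preserved).
- The single-gamma representation cannot hold bimodal posteriors; positions
  inside long homozygous runs whose true TMRCA is deep are called recent.
- Chained cache lookups (runs crossing segment boundaries) re-project the
  state to a gamma at each boundary; within-run dynamics are exact but
  cross-boundary descent is slightly slowed.
- The time-grid discretization of the cache builder leaves a ~0.1–0.5%
  bias on cached means (visible as the stationary state drifting by ~1e-3
  over thousands of missing sites).
- Cross-individual pairs require phased genotypes; phasing error is not
  modeled.
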