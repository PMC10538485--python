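# gammasmc

Ultrafast inference of the posterior distribution of pairwise coalescence
times (TMRCA) along a genome, for population geneticists who need
per-position TMRCA estimates across many haplotype pairs — for studying
population structure, dating coalescence events, or scanning for recent
positive selection.

## The method

The TMRCA `T` of two haplotypes follows the sequentially Markovian
coalescent (SMC) along the genome: per base pair, a recombination occurs
with probability `1 − e^{−ρT}` and resamples `T` (detach at `u ~ U(0, T)`,
re-coalesce at `u + Exp(1)`); each site is heterozygous with probability
governed by `θT` (θ = 4Neμ, ρ = 4Ner per bp; time in units of 2Ne
generations). Classical SMC decoders (PSMC and descendants) discretize time
into `O(T)` intervals and pay that factor at every site.

This package instead keeps every forward and backward density inside the
two-parameter gamma family Γ(α, β), updated in O(1) per step:

- **Emission** is Poisson–gamma conjugate: Γ(α, β) → Γ(α + y, β + θ) for a
  hom (y=0) or het (y=1) site.
- **Transition** pushes Γ(α, β) through the SMC kernel and projects the
  compound distribution back to a gamma. The projection is precomputed once
  as a *flow field* on a grid of (log₁₀ mean, log₁₀ CV) and bilinearly
  interpolated, so a decoding step is a table lookup.
- **Locus skipping**: runs of identical observations (hom or missing) are
  advanced with a single cached lookup per run; the caches resolve each
  n-step run operator exactly on an auxiliary discretized time grid before
  projecting, so posterior means can descend freely on long homozygous
  stretches (see `docs/methods.md`).
- The **posterior** at a position is Γ(α_f + α_b − 1, β_f + β_b − 1) from
  the forward and backward states.

Because the state space is continuous and the grid spans seven decades of
posterior mean, very small and very large TMRCAs are representable, which
makes the decoder robust to scale misspecification of θ and ρ.

The derived selection statistic is the fraction of haplotype pairs at a
position whose posterior-mean TMRCA falls below a threshold of `T`
generations: recent positive sweeps enrich this fraction near the selected
site.

## Worked example

`examples/decode_simulated_pair.py` simulates 5 Mb of the pairwise SMC
process (θ = 0.00075, ρ = 0.0006, Ne = 15,000), decodes the posterior every
1 kb, and prints:

```
simulated 5,000,000 bp: 3721 het sites, 3009 true TMRCA segments
decoded 5,000 positions
r^2(truth, posterior mean) = 0.524
mean absolute error        = 14,189 generations

pos (bp)    true TMRCA    posterior mean    90% interval (generations)
      500        72,126          81,329    [34,015, 145,108]
  625,500        40,466          44,512    [13,466, 90,182]
1,250,500        64,598          32,242    [7,590, 70,816]
...
```

Each output position carries a full gamma posterior (here summarized by its
mean and 90% interval), not just a point estimate. The r² on this
simulator is a few percent below the exact-posterior ceiling for the same
data — the gamma projection costs little relative to the information
available. On misspecified data (`examples/scale_misspecification.py`,
true TMRCAs 100× smaller than the decoder assumes):

```
true TMRCA scale:     median      173 generations
inferred TMRCA scale: median      212 generations
(a decoder unable to descend below its prior would sit near 13,200 generations)
```

And the sweep scan (`examples/selection_scan_demo.py`, 66 pairs, sweep
forcing carrier coalescence ~900 generations ago at 500 kb):

```
fraction of pairs with TMRCA < 2000 generations:
  at the sweep center : 0.785
  genome-wide median  : 0.030
statistic peaks at 498,500 bp (true sweep at 500,000 bp)
```

`examples/decode_vcf.py` shows the file-based path: phased VCF in,
θ estimated from average heterozygosity, binary + TSV posteriors out.

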