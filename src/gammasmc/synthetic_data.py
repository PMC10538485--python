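"""Simulators producing pair data with known TMRCA paths.

Three generators:

* :func:`simulate_smc_pair` draws a pairwise TMRCA path from the same SMC
  kernel the decoder models (Exp(1) prior; per-bp recombination probability
  1 - e^{-rho t}; on recombination the detached lineage re-coalesces above a
  uniform point), emitting het sites with probability 1 - e^{-theta t}.  The
  truth path is exact run-length data, so decoder accuracy can be measured
  without external tools.  A ``scale`` factor rescales the TMRCAs (and with
  them both emission and recombination probabilities) to emulate simulating
  at a different effective population size than the decoder assumes.

* :func:`simulate_sweep_panel` builds a haplotype panel under a star-genealogy
  approximation of a selective sweep: each haplotype carries an independent
  SMC-evolving time-to-root, carriers' times are capped near the sweep
  center (the cap releasing linearly with distance), and mutations are
  private to each branch.  This is a deliberately simplified stand-in for a
  forward or coalescent sweep simulator, sufficient for ranking/ROC
  evaluation of the selection statistic.

* :func:`simulate_msprime_pair` delegates to msprime for coalescent
  simulations with standard population-genetic parameters (including the
  three-population out-of-Africa demography), returning observations and the
  true TMRCA per position in generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .core_model import Observation

__all__ = [
    "SimulatedPair",
    "SweepPanel",
    "simulate_smc_pair",
    "simulate_misspecified",
    "simulate_sweep_panel",
    "simulate_msprime_pair",
    "out_of_africa_3pop_demography",
    "write_panel_vcf",
]


@dataclass
class SimulatedPair:
    """A pairwise SMC realization with its exact truth path.

    ``breakpoints[k]`` is the first bp of the k-th constant-TMRCA run and
    ``tmrcas[k]`` its TMRCA in coalescent units of the *decoding* model
    (i.e. already multiplied by ``scale``).
    """

    length: int
    breakpoints: np.ndarray
    tmrcas: np.ndarray
    obs: np.ndarray
    theta: float
    rho: float
    scale: float
    seed: int

    def tmrca_at(self, positions: Sequence[int]) -> np.ndarray:
        """True (scaled) TMRCA at the given bp positions."""
        idx = np.searchsorted(self.breakpoints, np.asarray(positions), side="right") - 1
        return self.tmrcas[idx]


def simulate_smc_pair(length: int, theta: float, rho: float, scale: float = 1.0,
                      seed: int = 0) -> SimulatedPair:
    """Draw one haplotype pair from the pairwise SMC process.

    The underlying path is Exp(1)-distributed in model units; ``scale``
    multiplies it, so both the per-bp recombination probability
    1 - e^{-rho * t_scaled} and the het probability 1 - e^{-theta * t_scaled}
    see the rescaled time (simulating at effective size Ne*scale while theta
    and rho stay quoted at the decoder's Ne).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    breakpoints: List[int] = []
    tmrcas: List[float] = []
    het_chunks: List[np.ndarray] = []
    t_model = rng.exponential()
    pos = 0
    while pos < length:
        t_scaled = t_model * scale
        p_rec = -math.expm1(-rho * t_scaled)
        if p_rec > 0.0:
            run = min(int(rng.geometric(p_rec)), length - pos)
        else:
            run = length - pos
        breakpoints.append(pos)
        tmrcas.append(t_scaled)
        p_het = -math.expm1(-theta * t_scaled)
        k = rng.binomial(run, p_het)
        if k:
            het_chunks.append(pos + rng.choice(run, size=k, replace=False))
        pos += run
        if pos < length:
            u = rng.uniform(0.0, t_model)
            t_model = u + rng.exponential()
    obs = np.zeros(length, dtype=np.uint8)
    if het_chunks:
        obs[np.concatenate(het_chunks)] = Observation.HET
    return SimulatedPair(length, np.asarray(breakpoints), np.asarray(tmrcas),
                         obs, theta, rho, scale, seed)


def simulate_misspecified(length: int, theta: float, rho: float, factor: float,
                          seed: int = 0) -> SimulatedPair:
    """Simulate with true TMRCAs ``factor`` times smaller than the decoder assumes."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return simulate_smc_pair(length, theta, rho, scale=1.0 / factor, seed=seed)


# ---------------------------------------------------------------------------
# sweep panel (star genealogy)
# ---------------------------------------------------------------------------

_CAP_RELEASE = 4.0  # cap value at the window edge, in coalescent units


@dataclass
class SweepPanel:
    """Haplotype panel with per-haplotype times-to-root and private mutations."""

    n_haplotypes: int
    length: int
    sweep_pos: int
    sweep_tmrca: float
    sweep_window: int
    carriers: np.ndarray            # bool per haplotype
    hap_breakpoints: List[np.ndarray]
    hap_times: List[np.ndarray]     # neutral (uncapped) times-to-root
    hap_mutations: List[np.ndarray] # sorted bp positions of private mutations
    theta: float
    rho: float
    seed: int

    def _cap(self, positions: np.ndarray) -> np.ndarray:
        d = np.abs(np.asarray(positions, dtype=float) - self.sweep_pos)
        cap = np.full(len(d), np.inf)
        inside = d < self.sweep_window
        cap[inside] = self.sweep_tmrca + (d[inside] / self.sweep_window) * _CAP_RELEASE
        return cap

    def hap_time_at(self, i: int, positions: Sequence[int]) -> np.ndarray:
        """Time-to-root of haplotype ``i`` at the given positions (capped if carrier)."""
        positions = np.asarray(positions)
        idx = np.searchsorted(self.hap_breakpoints[i], positions, side="right") - 1
        t = self.hap_times[i][idx]
        if self.carriers[i]:
            t = np.minimum(t, self._cap(positions))
        return t

    def pair_tmrca_at(self, i: int, j: int, positions: Sequence[int]) -> np.ndarray:
        """Truth TMRCA of the (i, j) pair: mean of the two times-to-root."""
        return 0.5 * (self.hap_time_at(i, positions) + self.hap_time_at(j, positions))

    def pair_obs(self, i: int, j: int) -> np.ndarray:
        """Per-bp observation sequence for the (i, j) pair.

        Mutations are private to branches, so the pair is het wherever either
        haplotype carries a mutation.
        """
        obs = np.zeros(self.length, dtype=np.uint8)
        obs[self.hap_mutations[i]] = Observation.HET
        obs[self.hap_mutations[j]] = Observation.HET
        return obs

    def pairs(self) -> List[Tuple[int, int]]:
        n = self.n_haplotypes
        return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _simulate_root_path(length: int, rho: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """One haplotype's time-to-root evolving by the SMC kernel (run-length)."""
    bp: List[int] = []
    ts: List[float] = []
    t = rng.exponential()
    pos = 0
    while pos < length:
        p_rec = -math.expm1(-rho * t)
        run = min(int(rng.geometric(p_rec)), length - pos) if p_rec > 0 else length - pos
        bp.append(pos)
        ts.append(t)
        pos += run
        if pos < length:
            t = rng.uniform(0.0, t) + rng.exponential()
    return np.asarray(bp), np.asarray(ts)


def _draw_mutations(bp: np.ndarray, ts: np.ndarray, length: int, cap_fn, theta: float,
                    rng) -> np.ndarray:
    """Private mutation positions for one branch, Poisson at rate theta*t/2 per bp."""
    ends = np.append(bp[1:], length)
    out: List[np.ndarray] = []
    for a, b, t in zip(bp, ends, ts):
        if cap_fn is None:
            p = -math.expm1(-0.5 * theta * t)
            k = rng.binomial(b - a, p)
            if k:
                out.append(a + rng.choice(b - a, size=k, replace=False))
        else:
            x = np.arange(a, b)
            t_eff = np.minimum(t, cap_fn(x))
            p = -np.expm1(-0.5 * theta * t_eff)
            hits = rng.random(b - a) < p
            if hits.any():
                out.append(x[hits])
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(out))


def simulate_sweep_panel(n_haplotypes: int, length: int, sweep_pos: int,
                         carrier_fraction: float, sweep_tmrca: float,
                         theta: float, rho: float, seed: int = 0,
                         sweep_window: int = 200_000) -> SweepPanel:
    """Star-genealogy panel with a sweep-like depression of carrier TMRCAs.

    Each haplotype i evolves an independent time-to-root t_i(x); the first
    ``round(carrier_fraction * n)`` haplotypes are carriers whose t_i is
    capped at ``sweep_tmrca`` at the sweep center, the cap rising linearly
    with distance until it is inactive beyond ``sweep_window`` bp.  Mutations
    are private to branches (every variant is a singleton), so the pairwise
    het probability is 1 - e^{-theta (t_i + t_j)/2} and the recorded truth
    TMRCA is (t_i + t_j)/2.  Non-carrier haplotypes consume seed streams
    independent of ``carrier_fraction``, so a panel with carrier_fraction=0
    is identical to a neutral panel.
    """
    if not (0.0 <= carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must be in [0, 1]")
    if not (0 < sweep_tmrca < 1):
        raise ValueError("sweep_tmrca must be in (0, 1) coalescent units")
    if n_haplotypes < 2 or length < 1:
        raise ValueError("need at least 2 haplotypes and positive length")
    n_carriers = int(round(carrier_fraction * n_haplotypes))
    carriers = np.zeros(n_haplotypes, dtype=bool)
    carriers[:n_carriers] = True
    panel = SweepPanel(n_haplotypes, length, sweep_pos, sweep_tmrca, sweep_window,
                       carriers, [], [], [], theta, rho, seed)
    for i in range(n_haplotypes):
        rng = np.random.default_rng([seed, i])
        bp, ts = _simulate_root_path(length, rho, rng)
        panel.hap_breakpoints.append(bp)
        panel.hap_times.append(ts)
        cap_fn = panel._cap if carriers[i] else None
        panel.hap_mutations.append(_draw_mutations(bp, ts, length, cap_fn, theta, rng))
    return panel


def write_panel_vcf(panel: SweepPanel, path, chrom: str = "1") -> None:
    """Write the panel as a phased VCF (pairs of haplotypes form diploids)."""
    if panel.n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes to form diploid samples")
    n_samples = panel.n_haplotypes // 2
    sites: dict[int, set] = {}
    for i, muts in enumerate(panel.hap_mutations):
        for p in muts:
            sites.setdefault(int(p), set()).add(i)
    names = [f"s{k}" for k in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={panel.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for pos in sorted(sites):
            carriers = sites[pos]
            gts = []
            for k in range(n_samples):
                a = 1 if 2 * k in carriers else 0
                b = 1 if 2 * k + 1 in carriers else 0
                gts.append(f"{a}|{b}")
            fh.write(f"{chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# msprime adapter
# ---------------------------------------------------------------------------


def human_like_rate_map(length: int, mean_rate: float = 1e-8, seed: int = 0,
                        block: int = 1_000_000, broad_sigma: float = 0.7,
                        hotspot_spacing: int = 60_000, hotspot_width: int = 2_000,
                        hotspot_share: float = 0.8):
    """Synthetic recombination map with human-map-like heterogeneity.

    Two scales of variation, with magnitudes taken from published
    descriptions of human genetic maps: fine-scale hotspots (~2 kb wide,
    ~60 kb apart, carrying ~80% of all crossovers) and Mb-scale lognormal
    background variation (sigma ~ 0.7 across 1-Mb blocks, covering cold
    regions and warm chromosome arms).  The realized map is rescaled so its
    genome-wide mean equals ``mean_rate``.  Returns an msprime.RateMap.
    """
    import msprime

    rng = np.random.default_rng(seed)
    nb = int(np.ceil(length / block))
    broad = np.exp(rng.normal(-0.5 * broad_sigma ** 2, broad_sigma, nb))
    pos = [0]
    rate = []
    p = 0
    while p < length:
        blk = min(p // block, nb - 1)
        bg = broad[blk] * mean_rate * (1.0 - hotspot_share)
        gap = max(int(rng.exponential(hotspot_spacing)), 100)
        b = min(p + gap, length)
        pos.append(b)
        rate.append(bg)
        if b == length:
            break
        h = min(b + hotspot_width, length)
        hot = broad[blk] * mean_rate * hotspot_share * hotspot_spacing / hotspot_width
        pos.append(h)
        rate.append(hot)
        p = h
    rm = msprime.RateMap(position=pos, rate=rate)
    scale = mean_rate / rm.mean_rate
    return msprime.RateMap(position=pos, rate=[r * scale for r in rate])


def out_of_africa_3pop_demography():
    """Three-population out-of-Africa demography (Gutenkunst et al. 2009).

    African, European and East Asian populations with an African expansion,
    an out-of-Africa bottleneck, a European/Asian split with exponential
    growth, and symmetric migration.  Times in generations (25 yr/gen in the
    original publication's conversion).
    """
    import msprime

    N_A, N_AF, N_B = 7300, 12300, 2100
    N_EU0, N_AS0 = 1000, 510
    r_EU, r_AS = 0.004, 0.0055
    T_AF, T_B, T_EU_AS = 8800, 5600, 848
    demography = msprime.Demography()
    demography.add_population(name="YRI", initial_size=N_AF)
    demography.add_population(name="CEU", initial_size=N_EU0 * math.exp(r_EU * T_EU_AS),
                              growth_rate=r_EU)
    demography.add_population(name="CHB", initial_size=N_AS0 * math.exp(r_AS * T_EU_AS),
                              growth_rate=r_AS)
    demography.add_population(name="OOA", initial_size=N_B)
    demography.add_population(name="AMH", initial_size=N_AF)
    demography.add_population(name="ANC", initial_size=N_A)
    demography.set_symmetric_migration_rate(["YRI", "CEU"], 3e-5)
    demography.set_symmetric_migration_rate(["YRI", "CHB"], 1.9e-5)
    demography.set_symmetric_migration_rate(["CEU", "CHB"], 9.6e-5)
    demography.add_population_split(time=T_EU_AS, derived=["CEU", "CHB"], ancestral="OOA")
    demography.add_symmetric_migration_rate_change(time=T_EU_AS,
                                                   populations=["YRI", "OOA"], rate=25e-5)
    # at the out-of-Africa time the bottleneck population rejoins the African
    # lineage (size N_AF), whose size drops to the ancestral N_A at T_AF
    demography.add_population_split(time=T_B, derived=["YRI", "OOA"], ancestral="AMH")
    demography.add_population_split(time=T_AF, derived=["AMH"], ancestral="ANC")
    return demography


def simulate_msprime_pair(length: int, mu: float, r, Ne: float | None = None,
                          demography=None, population: str | None = None,
                          seed: int = 1) -> Tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """One diploid simulated with msprime; returns (obs, tmrca_in_generations).

    Either ``Ne`` (constant population size) or a ``demography`` (with the
    sampling ``population`` name) must be given.  ``r`` may be a constant
    rate or an msprime.RateMap (e.g. from :func:`human_like_rate_map`).  The
    second return value maps bp positions to the true pairwise TMRCA in
    generations.
    """
    import msprime

    if (Ne is None) == (demography is None):
        raise ValueError("give exactly one of Ne or demography")
    kwargs = dict(recombination_rate=r, random_seed=seed)
    if not hasattr(r, "position"):  # a RateMap already fixes the length
        kwargs["sequence_length"] = length
    if demography is not None:
        samples = {population: 1}
        ts = msprime.sim_ancestry(samples=samples, demography=demography, **kwargs)
    else:
        ts = msprime.sim_ancestry(samples=1, population_size=Ne, **kwargs)
    mts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1)

    obs = np.zeros(length, dtype=np.uint8)
    for var in mts.variants():
        g = var.genotypes
        if g[0] != g[1]:
            obs[int(var.site.position)] = Observation.HET

    left = np.fromiter((t.interval.left for t in ts.trees()), dtype=float)
    tmrca = np.fromiter((t.tmrca(0, 1) for t in ts.trees()), dtype=float)

    def tmrca_at(positions) -> np.ndarray:
        idx = np.searchsorted(left, np.asarray(positions, dtype=float), side="right") - 1
        return tmrca[idx]

    return obs, tmrca_at
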