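"""Detect a simulated selective sweep with the recent-coalescence statistic.

Builds a star-genealogy sweep panel (12 haplotypes, 1 Mb, sweep at the
center forcing carrier coalescence ~900 generations ago), decodes all 66
haplotype pairs, and scans for positions where an excess of pairs shows a
posterior-mean TMRCA below 2,000 generations.
"""

import numpy as np

from gammasmc import (
    ModelParams,
    build_flow_field,
    build_skip_cache,
    decode_pair,
    simulate_sweep_panel,
)
from gammasmc.selection_scan import recent_fraction_profile, windowed_statistic

theta, rho, Ne = 0.00075, 0.0006, 15_000
length = 1_000_000
sweep_pos = length // 2

grid = build_flow_field(rho)
cache = build_skip_cache(grid, theta, max_len=10_000)
params = ModelParams(theta=theta, rho=rho, Ne=Ne)

panel = simulate_sweep_panel(12, length, sweep_pos, carrier_fraction=0.9,
                             sweep_tmrca=0.03, theta=theta, rho=rho, seed=1,
                             sweep_window=150_000)
targets = np.arange(500, length, 2000)
tracks = [decode_pair(panel.pair_obs(i, j), targets, params, cache, grid,
                      pair=(i, j))
          for i, j in panel.pairs()]

T = 2000  # generations
positions, profile = recent_fraction_profile(tracks, T)
at_sweep = windowed_statistic(profile, positions, 10_000, sweep_pos)
genome_median = np.median(profile)

print(f"decoded {len(tracks)} pairs at {len(targets)} positions")
print(f"fraction of pairs with TMRCA < {T} generations:")
print(f"  at the sweep center : {at_sweep:.3f}")
print(f"  genome-wide median  : {genome_median:.3f}")
peak = positions[np.argmax(profile)]
print(f"statistic peaks at {peak:,} bp (true sweep at {sweep_pos:,} bp)")
# Carrier pairs coalesce at the forced sweep time near the center, so the
# recent fraction spikes there and sits near the carrier-pair fraction
# (0.9^2 ~ 0.74 of pairs); neutral background positions stay close to the
# coalescent prior's P(TMRCA < 2000 gen) ~ 0.06.
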