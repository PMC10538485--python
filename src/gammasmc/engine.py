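"""Posterior decoding of pairwise TMRCA along a chromosome.

The observation sequence of a haplotype pair (hom/het/missing per bp) is cut
into segments that end at each het site, at each user-requested output
position, and at a maximal length; inside a segment only the counts of
missing and hom base pairs are kept, and the forward pass advances over a
whole segment with two cached flow-field lookups plus one terminal update.

The backward density is computed by running the same forward machinery on
the reversed sequence and pushing each recorded state through one extra
flow-field transition, so that the forward state at an output position
conditions on observations up to and including that position and the
backward state on everything strictly after it.  Their product divided by
the Exp(1) prior is the combined posterior Gamma(alpha+alpha'-1,
beta+beta'-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core_model import GammaState, ModelParams, Observation
from .flow_field import FlowFieldGrid, SkipCache, _bilinear_one

__all__ = [
    "SegmentSequence",
    "PosteriorTrack",
    "segment_observations",
    "forward_pass",
    "backward_pass",
    "decode_pair",
]

TERM_HET = 0
TERM_TARGET = 1
TERM_CAP = 2
TERM_END = 3

_KIND_NAMES = {TERM_HET: "het", TERM_TARGET: "target-site",
               TERM_CAP: "length-cap", TERM_END: "chromosome-end"}


@dataclass
class SegmentSequence:
    """Tiling of an interval into decode segments.

    Segments are 0-based half-open [start, end); the last bp of each segment
    carries the terminal observation ``terminal_y`` and the preceding
    ``end - 1 - start`` bp are summarized by ``n_missing`` and ``n_hom``.
    """

    length: int
    starts: np.ndarray
    ends: np.ndarray
    n_missing: np.ndarray
    n_hom: np.ndarray
    terminal_y: np.ndarray     # Observation value at end-1
    terminal_kind: np.ndarray  # TERM_* code
    targets: np.ndarray        # sorted output positions (bp)
    # index into `targets` if this segment's terminal bp is a target, else -1
    target_index: np.ndarray
    obs: np.ndarray            # the underlying per-bp observation sequence
    max_len: int = 10_000


def segment_observations(obs: np.ndarray, targets: Sequence[int],
                         max_len: int = 10_000) -> SegmentSequence:
    """Cut an observation sequence at het sites, targets and every max_len bp.

    ``obs`` is a per-bp uint8 array with values Observation.HOM/HET/MISSING.
    ``targets`` must be sorted, unique, and inside [0, len(obs)).
    """
    obs = np.asarray(obs, dtype=np.uint8)
    L = len(obs)
    targets = np.asarray(targets, dtype=np.int64)
    if len(targets) and (np.any(np.diff(targets) <= 0)):
        raise ValueError("targets must be sorted and unique")
    if len(targets) and (targets[0] < 0 or targets[-1] >= L):
        raise ValueError("targets must lie inside the observed interval")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    het_pos = np.flatnonzero(obs == Observation.HET)
    cut_ends = np.union1d(np.union1d(het_pos + 1, targets + 1),
                          np.array([L], dtype=np.int64)) if L else np.array([], dtype=np.int64)
    # enforce the length cap
    ends: List[int] = []
    prev = 0
    for e in cut_ends:
        e = int(e)
        while e - prev > max_len:
            prev += max_len
            ends.append(prev)
        ends.append(e)
        prev = e
    ends_arr = np.asarray(ends, dtype=np.int64)
    starts = np.concatenate([[0], ends_arr[:-1]]) if len(ends_arr) else ends_arr

    cum_missing = np.concatenate([[0], np.cumsum(obs == Observation.MISSING)])
    n_missing = cum_missing[ends_arr - 1] - cum_missing[starts]
    n_hom = (ends_arr - 1 - starts) - n_missing
    terminal_y = obs[ends_arr - 1] if len(ends_arr) else np.array([], dtype=np.uint8)

    target_index = np.full(len(ends_arr), -1, dtype=np.int64)
    if len(targets):
        idx = np.searchsorted(targets, ends_arr - 1)
        hit = (idx < len(targets)) & (targets[np.minimum(idx, len(targets) - 1)] == ends_arr - 1)
        target_index[hit] = idx[hit]

    kind = np.full(len(ends_arr), TERM_CAP, dtype=np.int8)
    kind[terminal_y == Observation.HET] = TERM_HET
    kind[target_index >= 0] = TERM_TARGET
    if len(ends_arr) and ends_arr[-1] == L:
        # chromosome end wins only if the last bp is not itself het/target
        if kind[-1] == TERM_CAP:
            kind[-1] = TERM_END
    return SegmentSequence(L, starts, ends_arr, n_missing, n_hom,
                           terminal_y, kind, targets, target_index, obs, max_len)


# ---------------------------------------------------------------------------
# hot-path helpers operating on raw (l_mu, l_cv) coordinates
# ---------------------------------------------------------------------------


def _emission_coords(lm: float, lc: float, y: int, theta: float) -> Tuple[float, float]:
    alpha = float(np.power(10.0, -2.0 * lc))
    beta = alpha / float(np.power(10.0, lm)) + theta
    if y:
        alpha += 1.0
        lc = float(-0.5 * np.log10(alpha))
    return float(np.log10(alpha / beta)), lc


def _skip_coords(cache: SkipCache, lm: float, lc: float,
                 n_missing: int, n_hom: int) -> Tuple[float, float]:
    if cache.rho == 0.0:
        # exact conjugacy: transitions are the identity without recombination
        if n_hom:
            alpha = float(np.power(10.0, -2.0 * lc))
            beta = alpha / float(np.power(10.0, lm)) + n_hom * cache.theta
            lm = float(np.log10(alpha / beta))
        return lm, lc
    ax1, ax2 = cache.grid._l_mu_list, cache.grid._l_cv_list
    for table, total in ((cache.missing, n_missing), (cache.hom, n_hom)):
        remaining = total
        while remaining > 0:
            chunk = min(remaining, cache.max_len)
            if cache.layout == "full":
                lm, lc = _bilinear_one(ax1, ax2, table[chunk], lm, lc)
            else:
                rem_chunk = chunk
                for n in sorted(cache.lengths, reverse=True):
                    while rem_chunk >= n:
                        lm, lc = _bilinear_one(ax1, ax2, table[cache._table_index(n)], lm, lc)
                        rem_chunk -= n
            remaining -= chunk
    return lm, lc


def _run_forward(segments: SegmentSequence, cache: SkipCache, grid: FlowFieldGrid,
                 theta: float) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Forward pass over segments; returns (l_mu, l_cv) at each target."""
    ax1, ax2 = grid._l_mu_list, grid._l_cv_list
    lm, lc = 0.0, 0.0  # Gamma(1, 1) prior
    out = np.empty((len(segments.targets), 2), dtype=float)
    miss = int(Observation.MISSING)
    for k in range(len(segments.ends)):
        nm = int(segments.n_missing[k])
        nh = int(segments.n_hom[k])
        if nm or nh:
            lm, lc = _skip_coords(cache, lm, lc, nm, nh)
        # terminal bp: one transition, plus an emission unless missing
        lm, lc = _bilinear_one(ax1, ax2, grid.values, lm, lc)
        y = int(segments.terminal_y[k])
        if y != miss:
            lm, lc = _emission_coords(lm, lc, y, theta)
        ti = segments.target_index[k]
        if ti >= 0:
            out[ti, 0] = lm
            out[ti, 1] = lc
    return out, (lm, lc)


def _check_compatible(cache: SkipCache, grid: FlowFieldGrid, theta: float) -> None:
    if cache.grid is not grid and cache.rho != grid.rho:
        raise ValueError("skip cache and flow field were built for different rho")
    if not np.isclose(cache.theta, theta):
        raise ValueError(f"skip cache was built for theta={cache.theta}, decoding with {theta}")


def forward_pass(segments: SegmentSequence, cache: SkipCache, grid: FlowFieldGrid,
                 theta: float) -> List[GammaState]:
    """Forward gamma states at each target position.

    The state recorded at a target includes the emission at the target site
    itself (if non-missing).
    """
    _check_compatible(cache, grid, theta)
    coords, _ = _run_forward(segments, cache, grid, theta)
    return [GammaState.from_log_coords(lm, lc) for lm, lc in coords]


def backward_pass(segments: SegmentSequence, cache: SkipCache, grid: FlowFieldGrid,
                  theta: float) -> List[GammaState]:
    """Backward gamma states at each target position.

    Computed as a forward pass over the reversed observation sequence up to
    (but excluding) each target site, followed by one extra flow-field
    transition; the backward state therefore conditions exactly on the
    observations strictly after the target.
    """
    _check_compatible(cache, grid, theta)
    obs = segments.obs
    L = segments.length
    targets = segments.targets
    ax1, ax2 = grid._l_mu_list, grid._l_cv_list

    # reversed-sequence record positions: the state after the observations
    # strictly after target p is the reversed prefix of length L-1-p, i.e.
    # the state after reversed index L-2-p.  p = L-1 maps to the prior.
    rev_targets = (L - 2 - targets)[::-1]
    rev_targets = rev_targets[rev_targets >= 0]
    seg_rev = segment_observations(obs[::-1], rev_targets, max_len=segments.max_len)
    coords, _ = _run_forward(seg_rev, cache, grid, theta)

    out: List[GammaState] = []
    n_kept = len(rev_targets)
    for pos_idx in range(len(targets)):
        if targets[pos_idx] == L - 1:
            lm, lc = 0.0, 0.0  # no downstream observations: the prior
        else:
            # targets ascending in p maps to rev_targets descending
            lm, lc = coords[n_kept - 1 - pos_idx]
        lm, lc = _bilinear_one(ax1, ax2, grid.values, lm, lc)
        out.append(GammaState.from_log_coords(lm, lc))
    return out


#: floor for the combined posterior shape when both passes are heavily
#: over-dispersed (alpha_f + alpha_b - 1 <= 0); the product of two such
#: gamma densities over the prior is not normalizable, so the combined state
#: is clamped to a boundary gamma that preserves the (very recent) scale.
COMBINED_ALPHA_FLOOR = 0.01


@dataclass
class PosteriorTrack:
    """Per-pair posterior gamma parameters at the output positions."""

    pair: Tuple
    positions: np.ndarray
    fwd_alpha: np.ndarray
    fwd_beta: np.ndarray
    bwd_alpha: np.ndarray
    bwd_beta: np.ndarray
    alpha: np.ndarray  # combined posterior
    beta: np.ndarray
    mean_coal: np.ndarray
    mean_generations: np.ndarray | None = None
    mean_years: np.ndarray | None = None
    n_clamped: int = 0  # positions where the combined shape hit the floor


def decode_pair(obs: np.ndarray, targets: Sequence[int], params: ModelParams,
                cache: SkipCache, grid: FlowFieldGrid, max_len: int = 10_000,
                pair: Tuple = (0, 1)) -> PosteriorTrack:
    """Full posterior decoding of one haplotype pair.

    Runs the forward and backward passes, combines them position-wise into
    Gamma(alpha+alpha'-1, beta+beta'-1), and converts posterior means to
    generations/years when ``params.Ne`` is set.  Deterministic given its
    inputs.
    """
    theta, _ = params.require_rates()
    obs = np.asarray(obs, dtype=np.uint8)
    targets = np.asarray(targets, dtype=np.int64)
    segs = segment_observations(obs, targets, max_len=max_len)
    fwd = forward_pass(segs, cache, grid, theta)
    bwd = backward_pass(segs, cache, grid, theta)

    fa = np.array([s.alpha for s in fwd])
    fb = np.array([s.beta for s in fwd])
    ba = np.array([s.alpha for s in bwd])
    bb = np.array([s.beta for s in bwd])
    ca = fa + ba - 1.0
    cb = fb + bb - 1.0
    # when both passes are over-dispersed (alpha < 1/2 each) the gamma
    # product over the prior is improper; clamp to the boundary shape
    clamped = (ca < COMBINED_ALPHA_FLOOR) | (cb <= 0.0)
    ca = np.maximum(ca, COMBINED_ALPHA_FLOOR)
    cb = np.maximum(cb, 1e-12)
    mean_coal = ca / cb
    gens = years = None
    if params.Ne is not None:
        gens = mean_coal * 2.0 * params.Ne
        years = gens * params.generation_time
    return PosteriorTrack(pair, targets, fa, fb, ba, bb, ca, cb, mean_coal, gens, years,
                          int(clamped.sum()))
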