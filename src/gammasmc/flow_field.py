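"""Precomputed flow field and run-length skip caches.

One SMC transition step maps a gamma forward density Gamma(alpha, beta) to a
compound distribution which is projected back onto the gamma family.  The
mapping F: (alpha, beta) -> (alpha', beta') is evaluated once on a fixed grid
of (l_mu, l_cv) = (log10 mean, log10 CV) coordinates — by default 51 l_mu
values on [-5, 2] and 50 l_cv values on [-2, 0] — and off-grid states are
clipped to the grid range and bilinearly interpolated.  Because the grid is
laid out in log coordinates, the same field serves TMRCAs spanning seven
decades.

On top of the field sit two caches for locus skipping: for every grid node
and every run length n up to ``max_len``, the image of n repeated
(transition, hom-emission) steps and of n repeated transition-only (missing)
steps.  A stretch of identical observations then costs a single interpolated
lookup instead of n sequential updates.

Interpolation is deliberately performed on the (l_mu, l_cv) images rather
than on raw (alpha, beta): log-space interpolation preserves positivity and
matches the geometry of the grid.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import special

from .core_model import GammaState, gamma_project

__all__ = [
    "GridSpec",
    "FlowFieldGrid",
    "SkipCache",
    "build_flow_field",
    "apply_flow",
    "build_skip_cache",
    "skip",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridSpec:
    """Layout of the (l_mu, l_cv) grid.

    The default extends the coefficient of variation above 1 (l_cv up to
    ~0.69, CV up to ~5): on long homozygous stretches the exact SMC filter
    is strongly over-dispersed (a sharp recent bulk plus a tail of
    recombination escapes), and confining the gamma representation to
    CV <= 1 pins the posterior mean near rho/(rho+theta) instead of letting
    it descend — which destroys inference of very recent coalescence times.
    The 17 extra l_cv nodes keep the spacing of a 50-point grid on [-2, 0],
    so l_cv = 0 (the stationary prior) remains a grid node.
    """

    n_l_mu: int = 51
    l_mu_min: float = -5.0
    l_mu_max: float = 2.0
    n_l_cv: int = 67
    l_cv_min: float = -2.0
    l_cv_max: float = 34.0 / 49.0

    def axes(self) -> Tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(self.l_mu_min, self.l_mu_max, self.n_l_mu),
            np.linspace(self.l_cv_min, self.l_cv_max, self.n_l_cv),
        )


@dataclass(frozen=True)
class TimeGridSpec:
    """Auxiliary discretized time grid used to resolve run-length operators.

    ``n_bins`` geometric bins on [t_min, t_max] (coalescent units).  Only the
    cache builder uses it; decoding never touches the discretization.
    """

    n_bins: int = 512
    t_min: float = 1e-7
    t_max: float = 200.0

    def edges(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_bins + 1)


# ---------------------------------------------------------------------------
# bilinear interpolation kernels
#
# Two implementations of the same arithmetic: a vectorized one used to build
# caches and a scalar one used in the per-segment decoding loop.  They share
# index semantics (searchsorted right, minus one) and operation order, so a
# scalar lookup is bit-identical to the corresponding vectorized lane.
# ---------------------------------------------------------------------------


def _bilinear_many(ax1: np.ndarray, ax2: np.ndarray, table: np.ndarray,
                   x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Clip (x, y) into the axes and bilinearly interpolate ``table``.

    ``table`` has shape (len(ax1), len(ax2), k); returns shape x.shape + (k,).
    """
    x = np.clip(x, ax1[0], ax1[-1])
    y = np.clip(y, ax2[0], ax2[-1])
    i = np.clip(np.searchsorted(ax1, x, side="right") - 1, 0, len(ax1) - 2)
    j = np.clip(np.searchsorted(ax2, y, side="right") - 1, 0, len(ax2) - 2)
    fx = ((x - ax1[i]) / (ax1[i + 1] - ax1[i]))[..., None]
    fy = ((y - ax2[j]) / (ax2[j + 1] - ax2[j]))[..., None]
    v00 = table[i, j]
    v10 = table[i + 1, j]
    v01 = table[i, j + 1]
    v11 = table[i + 1, j + 1]
    return ((1.0 - fx) * (1.0 - fy) * v00 + fx * (1.0 - fy) * v10
            + (1.0 - fx) * fy * v01 + fx * fy * v11)


def _bilinear_one(ax1_list: list, ax2_list: list, table: np.ndarray,
                  x: float, y: float) -> Tuple[float, float]:
    """Scalar twin of :func:`_bilinear_many` for tables with k = 2."""
    lo1, hi1 = ax1_list[0], ax1_list[-1]
    lo2, hi2 = ax2_list[0], ax2_list[-1]
    if x < lo1:
        x = lo1
    elif x > hi1:
        x = hi1
    if y < lo2:
        y = lo2
    elif y > hi2:
        y = hi2
    i = bisect_right(ax1_list, x) - 1
    if i < 0:
        i = 0
    elif i > len(ax1_list) - 2:
        i = len(ax1_list) - 2
    j = bisect_right(ax2_list, y) - 1
    if j < 0:
        j = 0
    elif j > len(ax2_list) - 2:
        j = len(ax2_list) - 2
    fx = (x - ax1_list[i]) / (ax1_list[i + 1] - ax1_list[i])
    fy = (y - ax2_list[j]) / (ax2_list[j + 1] - ax2_list[j])
    w00 = (1.0 - fx) * (1.0 - fy)
    w10 = fx * (1.0 - fy)
    w01 = (1.0 - fx) * fy
    w11 = fx * fy
    t0 = table[i, j]
    t1 = table[i + 1, j]
    t2 = table[i, j + 1]
    t3 = table[i + 1, j + 1]
    out0 = w00 * float(t0[0]) + w10 * float(t1[0]) + w01 * float(t2[0]) + w11 * float(t3[0])
    out1 = w00 * float(t0[1]) + w10 * float(t1[1]) + w01 * float(t2[1]) + w11 * float(t3[1])
    return out0, out1


def _hom_emission_logcoords(l_mu, l_cv, theta: float):
    """Hom-site emission Gamma(a, b) -> Gamma(a, b + theta) in log coords.

    alpha (hence CV) is unchanged; only the mean shrinks:
    mu' = alpha / (alpha/mu + theta).
    """
    alpha = 10.0 ** (-2.0 * np.asarray(l_cv))
    mu = 10.0 ** np.asarray(l_mu)
    new_mu = alpha / (alpha / mu + theta)
    return np.log10(new_mu), l_cv


@dataclass
class FlowFieldGrid:
    """One-transition-step images F(node) on the (l_mu, l_cv) grid."""

    l_mu_axis: np.ndarray
    l_cv_axis: np.ndarray
    values: np.ndarray  # (n_l_mu, n_l_cv, 2): image (l_mu', l_cv') per node
    rho: float
    # python-float axis copies for the scalar hot path
    _l_mu_list: list = field(default_factory=list, repr=False)
    _l_cv_list: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._l_mu_list:
            self._l_mu_list = [float(v) for v in self.l_mu_axis]
            self._l_cv_list = [float(v) for v in self.l_cv_axis]

    def node_state(self, i: int, j: int) -> GammaState:
        return GammaState.from_log_coords(float(self.l_mu_axis[i]), float(self.l_cv_axis[j]))

    def save(self, path) -> None:
        header = json.dumps({"version": FORMAT_VERSION, "rho": self.rho})
        np.savez_compressed(path, header=np.array(header), l_mu_axis=self.l_mu_axis,
                            l_cv_axis=self.l_cv_axis, values=self.values)

    @classmethod
    def load(cls, path) -> "FlowFieldGrid":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header["version"] != FORMAT_VERSION:
                raise ValueError(f"unsupported flow-field file version {header['version']}")
            return cls(z["l_mu_axis"], z["l_cv_axis"], z["values"], float(header["rho"]))


def build_flow_field(rho: float, grid_spec: GridSpec | None = None) -> FlowFieldGrid:
    """Evaluate the gamma projection of one transition step at every node.

    The build depends only on rho (not on theta or the data) and is reused
    across runs.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    spec = grid_spec or GridSpec()
    l_mu_axis, l_cv_axis = spec.axes()
    values = np.empty((len(l_mu_axis), len(l_cv_axis), 2), dtype=float)
    for i, lm in enumerate(l_mu_axis):
        for j, lc in enumerate(l_cv_axis):
            state = GammaState.from_log_coords(float(lm), float(lc))
            try:
                img = gamma_project(state, rho)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"flow-field projection failed at node (l_mu={lm}, l_cv={lc})"
                ) from exc
            values[i, j, 0] = img.l_mu
            values[i, j, 1] = img.l_cv
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values).all(axis=2))[0]
        raise RuntimeError(
            f"non-finite flow-field image at node (l_mu={l_mu_axis[bad[0]]}, "
            f"l_cv={l_cv_axis[bad[1]]})"
        )
    return FlowFieldGrid(l_mu_axis, l_cv_axis, values, rho)


def _gamma_entropy(alpha: float, beta: float) -> float:
    return float(alpha - np.log(beta) + special.gammaln(alpha)
                 + (1.0 - alpha) * special.digamma(alpha))


def apply_flow(grid: FlowFieldGrid, state: GammaState,
               entropy_guard: bool = False, entropy_slack: float = 0.0) -> GammaState:
    """Push a state through one transition step via the precomputed field.

    The state's (l_mu, l_cv) coordinates are clipped into the grid range and
    the stored images of the four surrounding nodes are bilinearly
    interpolated.  With ``entropy_guard`` the image is rejected (the clipped
    input is kept) if its differential entropy exceeds the pre-transition
    entropy by more than ``entropy_slack``; the guard is off by default.
    """
    lm, lc = state.l_mu, state.l_cv
    if not (np.isfinite(lm) and np.isfinite(lc)):
        raise ValueError(f"non-finite state coordinates (l_mu={lm}, l_cv={lc})")
    out0, out1 = _bilinear_one(grid._l_mu_list, grid._l_cv_list, grid.values, lm, lc)
    if entropy_guard:
        pre = GammaState.from_log_coords(
            min(max(lm, grid._l_mu_list[0]), grid._l_mu_list[-1]),
            min(max(lc, grid._l_cv_list[0]), grid._l_cv_list[-1]),
        )
        post = GammaState.from_log_coords(out0, out1)
        if _gamma_entropy(post.alpha, post.beta) > _gamma_entropy(pre.alpha, pre.beta) + entropy_slack:
            return pre
    return GammaState.from_log_coords(out0, out1)


@dataclass
class SkipCache:
    """Cached n-step images for hom and missing runs, per grid node.

    ``hom[n]`` holds, for each node, the (l_mu, l_cv) image of the posterior
    after a run of n homozygous sites (n transition steps each followed by a
    hom emission); ``missing[n]`` after n transition steps alone (missing
    sites carry no emission, so that table is independent of theta).
    ``lengths`` lists the cached step counts: all of 1..max_len in the
    default "full" layout, powers of two in the low-memory "doubling" layout
    (longer runs are composed greedily at query time).

    ``method`` records how the tables were built: "exact" resolves the
    n-step run operator on an auxiliary discretized time grid and projects
    the result to a gamma per (node, n) — so within-run tail dynamics are
    handled without compounding per-step projection error — while
    "iterated" composes n one-step flow-field projections (each entry then
    equals n sequential apply_flow/emission updates exactly).
    """

    grid: FlowFieldGrid
    theta: float
    max_len: int
    lengths: List[int]
    hom: np.ndarray      # (len(lengths)+1 or max_len+1, n1, n2, 2); index 0 unused
    missing: np.ndarray
    layout: str = "full"
    method: str = "exact"

    @property
    def rho(self) -> float:
        return self.grid.rho

    def _table_index(self, n: int) -> int:
        if self.layout == "full":
            return n
        return self.lengths.index(n) + 1

    def save(self, path) -> None:
        header = json.dumps({
            "version": FORMAT_VERSION, "rho": self.rho, "theta": self.theta,
            "max_len": self.max_len, "layout": self.layout, "lengths": self.lengths,
            "method": self.method,
        })
        np.savez_compressed(path, header=np.array(header),
                            l_mu_axis=self.grid.l_mu_axis, l_cv_axis=self.grid.l_cv_axis,
                            grid_values=self.grid.values, hom=self.hom, missing=self.missing)

    @classmethod
    def load(cls, path) -> "SkipCache":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header["version"] != FORMAT_VERSION:
                raise ValueError(f"unsupported cache file version {header['version']}")
            grid = FlowFieldGrid(z["l_mu_axis"], z["l_cv_axis"], z["grid_values"],
                                 float(header["rho"]))
            return cls(grid, float(header["theta"]), int(header["max_len"]),
                       [int(n) for n in header["lengths"]], z["hom"], z["missing"],
                       header["layout"], header.get("method", "exact"))


def smc_transition_matrix(rho: float, time_grid: TimeGridSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretized one-step SMC transition on the auxiliary time grid.

    Returns (edges, representative values, row-stochastic matrix).  Row i
    holds the atom e^{-rho t_i} on the diagonal plus the binned continuous
    resample kernel.
    """
    edges = time_grid.edges()
    reps = np.sqrt(edges[:-1] * edges[1:])
    n = len(reps)

    def cont_cdf(t, s):
        t = np.minimum(t, 700.0)
        out = np.where(
            t <= s,
            (t - 1 + np.exp(-t)) / s,
            (s - 1 + np.exp(-s)) / s
            + np.expm1(np.minimum(s, 700.0)) * (np.exp(-s) - np.exp(-t)) / s,
        )
        return np.where(t <= 0, 0.0, out)

    A = np.zeros((n, n))
    for i in range(n):
        s = reps[i]
        w = np.exp(-rho * s)
        A[i] = (1.0 - w) * np.diff(cont_cdf(edges, s))
        A[i, i] += w
    A /= A.sum(axis=1, keepdims=True)
    return edges, reps, A


def _discretize_node_gammas(alphas: np.ndarray, betas: np.ndarray,
                            edges: np.ndarray) -> np.ndarray:
    """Bin masses of Gamma(alpha_k, beta_k) on the time grid, per node."""
    cdf = special.gammainc(alphas[:, None], betas[:, None] * edges[None, :])
    V = np.diff(cdf, axis=1)
    return V / np.maximum(V.sum(axis=1, keepdims=True), 1e-300)


def _build_exact_tables(grid: FlowFieldGrid, theta: float, max_len: int,
                        dtype, time_grid: TimeGridSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Resolve n-step run operators on the time grid, project to gamma.

    For each n the exact n-step operator (transition matrix interleaved with
    per-site emission weights) is applied in the discretized basis; the
    resulting distribution started from each grid-node gamma is
    moment-projected back to (l_mu, l_cv).  Because the moment vectors
    M^n r^k are shared across nodes, the cost is O(n_bins^2 * max_len +
    n_nodes * n_bins * max_len).
    """
    edges, reps, A = smc_transition_matrix(grid.rho, time_grid)
    n1, n2 = len(grid.l_mu_axis), len(grid.l_cv_axis)
    lm0, lc0 = np.meshgrid(grid.l_mu_axis, grid.l_cv_axis, indexing="ij")
    alphas = (10.0 ** (-2.0 * lc0)).ravel()
    betas = alphas / 10.0 ** lm0.ravel()
    V = _discretize_node_gammas(alphas, betas, edges)

    out = []
    for emission in (np.exp(-theta * reps), None):  # hom, then missing
        M = A * emission[None, :] if emission is not None else A
        y0 = np.ones(len(reps))
        y1 = reps.copy()
        y2 = reps ** 2
        Y0 = np.empty((len(reps), max_len))
        Y1 = np.empty_like(Y0)
        Y2 = np.empty_like(Y0)
        for n in range(max_len):
            y0 = M @ y0
            y1 = M @ y1
            y2 = M @ y2
            sc = y0.max()
            y0 /= sc
            y1 /= sc
            y2 /= sc
            Y0[:, n] = y0
            Y1[:, n] = y1
            Y2[:, n] = y2
        Z0 = V @ Y0
        m1 = (V @ Y1) / Z0
        var = np.maximum((V @ Y2) / Z0 - m1 ** 2, 1e-300)
        table = np.empty((max_len + 1, n1 * n2, 2), dtype=dtype)
        table[0, :, 0] = lm0.ravel()
        table[0, :, 1] = lc0.ravel()
        table[1:, :, 0] = np.log10(m1).T
        table[1:, :, 1] = (-0.5 * np.log10(m1 * m1 / var)).T
        out.append(table.reshape(max_len + 1, n1, n2, 2))
    return out[0], out[1]


def build_skip_cache(grid: FlowFieldGrid, theta: float, max_len: int = 10_000,
                     dtype=np.float32, layout: str = "full", method: str = "exact",
                     time_grid: TimeGridSpec | None = None,
                     memory_cap_bytes: int = 4 << 30) -> SkipCache:
    """Precompute n-step hom/missing run images at every grid node.

    ``method="exact"`` (default) resolves each run-length operator on the
    auxiliary discretized time grid and gamma-projects per (node, n): the
    recombination-escape tail is then crushed by the accumulated emissions
    inside the table rather than being re-absorbed into the gamma at every
    base pair, which is what lets posterior means descend on long
    homozygous stretches.  ``method="iterated"`` composes one-step
    flow-field projections; its entries equal n sequential
    apply_flow/emission_update calls bit-for-bit (with a float64 table).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if layout == "full":
        lengths = list(range(1, max_len + 1))
        n_slots = max_len + 1
    elif layout == "doubling":
        lengths = []
        n = 1
        while n <= max_len:
            lengths.append(n)
            n *= 2
        n_slots = len(lengths) + 1
    else:
        raise ValueError(f"unknown cache layout {layout!r}")

    n1, n2 = len(grid.l_mu_axis), len(grid.l_cv_axis)
    est = 2 * n_slots * n1 * n2 * 2 * np.dtype(dtype).itemsize
    if est > memory_cap_bytes:
        raise MemoryError(
            f"skip cache would need ~{est / 1e9:.1f} GB (> cap {memory_cap_bytes / 1e9:.1f} GB); "
            f"reduce max_len or use layout='doubling'"
        )

    if method == "exact":
        hom_full, missing_full = _build_exact_tables(grid, theta, max_len, dtype,
                                                     time_grid or TimeGridSpec())
        if layout == "full":
            hom, missing = hom_full, missing_full
        else:
            sel = np.concatenate([[0], lengths])
            hom, missing = hom_full[sel], missing_full[sel]
        return SkipCache(grid, theta, max_len, lengths, hom, missing, layout, method)

    if method != "iterated":
        raise ValueError(f"unknown cache method {method!r}")

    hom = np.empty((n_slots, n1, n2, 2), dtype=dtype)
    missing = np.empty((n_slots, n1, n2, 2), dtype=dtype)
    hom[0] = missing[0] = np.stack(
        np.meshgrid(grid.l_mu_axis, grid.l_cv_axis, indexing="ij"), axis=-1)

    lm0, lc0 = np.meshgrid(grid.l_mu_axis, grid.l_cv_axis, indexing="ij")
    state_h = np.stack([lm0, lc0], axis=-1).astype(float)
    state_m = state_h.copy()
    slot = 1
    for n in range(1, max_len + 1):
        state_m = _bilinear_many(grid.l_mu_axis, grid.l_cv_axis, grid.values,
                                 state_m[..., 0], state_m[..., 1])
        step = _bilinear_many(grid.l_mu_axis, grid.l_cv_axis, grid.values,
                              state_h[..., 0], state_h[..., 1])
        new_lm, new_lc = _hom_emission_logcoords(step[..., 0], step[..., 1], theta)
        state_h = np.stack([new_lm, new_lc], axis=-1)
        if layout == "full" or n in lengths:
            missing[slot] = state_m
            hom[slot] = state_h
            slot += 1
    return SkipCache(grid, theta, max_len, lengths, hom, missing, layout, method)


def _decompose(n: int, lengths: List[int]) -> List[int]:
    """Greedy decomposition of a run length into cached lengths."""
    parts = []
    remaining = n
    for cand in sorted(lengths, reverse=True):
        while remaining >= cand:
            parts.append(cand)
            remaining -= cand
    if remaining:
        raise ValueError(f"cannot decompose run of {n} with cached lengths {lengths}")
    return parts


def skip(cache: SkipCache, state: GammaState, n_missing: int, n_hom: int) -> GammaState:
    """Advance a state over a run of missing then hom sites via the caches.

    Each lookup clips the state into the grid and bilinearly interpolates the
    cached n-step images; runs longer than ``max_len`` are chained in
    ``max_len``-sized chunks.
    """
    if n_missing < 0 or n_hom < 0:
        raise ValueError("run lengths must be non-negative")
    if cache.rho == 0.0:
        # no recombination: transitions are the identity and a hom run is
        # exactly the iterated Poisson-gamma conjugate update
        return GammaState(state.alpha, state.beta + n_hom * cache.theta)
    lm, lc = state.l_mu, state.l_cv
    ax1, ax2 = cache.grid._l_mu_list, cache.grid._l_cv_list
    for table, total in ((cache.missing, n_missing), (cache.hom, n_hom)):
        remaining = total
        while remaining > 0:
            chunk = min(remaining, cache.max_len)
            if cache.layout == "full":
                lm, lc = _bilinear_one(ax1, ax2, table[chunk], lm, lc)
            else:
                for part in _decompose(chunk, cache.lengths):
                    lm, lc = _bilinear_one(ax1, ax2, table[cache._table_index(part)], lm, lc)
            remaining -= chunk
    return GammaState.from_log_coords(lm, lc)
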