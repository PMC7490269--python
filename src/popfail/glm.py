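"""Point-process generalized linear models for spike-train encoding.

Each cell's conditional intensity is

    rate(t) = f( k . x(t)  +  h . y_self(t-)  +  sum_j c_j . y_j(t-)  +  dc )

where ``k`` is a rank-one spatiotemporal stimulus filter (outer product of a
spatial pixel profile and a temporal kernel), ``h`` a spike-history filter,
``c_j`` pairwise coupling filters from neighboring cells, and ``f`` the
logexp2 nonlinearity f(g) = log(1 + exp(g))^2.  Temporal, history, and
coupling filters are parameterized in a raised-cosine basis of 8 functions
log-spaced in time.  Spikes are Poisson counts per bin, strictly causal in
all spike-feedback terms.  The module supports both simulation (sequential
bin-by-bin sampling with feedback) and maximum-likelihood fitting (L-BFGS
with alternating rank-one updates of the spatial and temporal parts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "CosineBasis",
    "GLMParams",
    "GLMPopulation",
    "SpikeRaster",
    "GLMFitConfig",
    "logexp2",
    "conditional_intensity",
    "simulate_spikes",
    "fit_cell",
    "fit_glm",
    "compute_psth",
    "explained_variance",
]


def logexp2(g: np.ndarray | float) -> np.ndarray | float:
    """Softplus-squared nonlinearity: f(g) = log(1 + exp(g))^2.

    Smooth, nonnegative, monotone; overflow-safe via logaddexp (softplus -> g
    for large g, so f(g) ~ g^2 there; f(0) = (log 2)^2).
    """
    s = np.logaddexp(0.0, g)
    return s * s


@dataclass
class CosineBasis:
    """Raised-cosine bumps log-spaced in time (n_funcs columns).

    ``matrix`` has shape (support_bins, n_funcs); each column is nonnegative
    and the columns tile [0, support] with peaks spaced evenly in
    log(t + time_warp).
    """

    n_funcs: int
    support: float  # seconds
    dt: float
    time_warp: float = 0.01
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        nb = max(2, int(round(self.support / self.dt)))
        t = (np.arange(nb) + 0.5) * self.dt
        x = np.log(t + self.time_warp)
        first, last = x[0], x[-1]
        peaks = np.linspace(first, last, self.n_funcs)
        delta = (last - first) / max(self.n_funcs - 1, 1)
        arg = np.clip((x[:, None] - peaks[None, :]) * np.pi / (2 * delta), -np.pi, np.pi)
        self.matrix = 0.5 * (np.cos(arg) + 1.0)

    @property
    def support_bins(self) -> int:
        return self.matrix.shape[0]

    def kernel(self, weights: np.ndarray) -> np.ndarray:
        """Filter in time bins: matrix @ weights."""
        return self.matrix @ np.asarray(weights, dtype=float)


@dataclass
class GLMParams:
    """Parameters of one cell.

    ``coupling_weights`` maps neighbor cell index -> basis weights; an empty
    dict means the independent model.  The stimulus filter is rank one:
    outer(temporal_kernel, spatial_filter).
    """

    spatial_filter: np.ndarray
    temporal_weights: np.ndarray
    history_weights: np.ndarray
    coupling_weights: dict[int, np.ndarray] = field(default_factory=dict)
    dc: float = 0.0

    def __post_init__(self) -> None:
        self.spatial_filter = np.asarray(self.spatial_filter, dtype=float)
        self.temporal_weights = np.asarray(self.temporal_weights, dtype=float)
        self.history_weights = np.asarray(self.history_weights, dtype=float)
        self.coupling_weights = {
            int(k): np.asarray(v, dtype=float) for k, v in self.coupling_weights.items()
        }

    @property
    def is_independent(self) -> bool:
        return not self.coupling_weights

    def spatiotemporal_filter(self, stim_basis: CosineBasis) -> np.ndarray:
        """(support_bins, n_pixels) rank-one stimulus filter."""
        return np.outer(stim_basis.kernel(self.temporal_weights), self.spatial_filter)


@dataclass
class SpikeRaster:
    """Binned spike counts: (n_trials, n_cells, n_bins) nonnegative integers."""

    counts: np.ndarray
    dt: float
    trial_type: str = "non-repeated"
    cell_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_trials, n_cells, n_bins)")
        if (self.counts < 0).any():
            raise ValueError("spike counts must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def rebin(self, new_dt: float) -> "SpikeRaster":
        """Aggregate counts into coarser bins (new_dt must be a multiple of dt)."""
        factor = int(round(new_dt / self.dt))
        if factor < 1 or abs(factor * self.dt - new_dt) > 1e-9:
            raise ValueError("new_dt must be an integer multiple of dt")
        nb = (self.n_bins // factor) * factor
        c = self.counts[:, :, :nb].reshape(self.n_trials, self.n_cells, -1, factor)
        return SpikeRaster(
            counts=c.sum(axis=3),
            dt=new_dt,
            trial_type=self.trial_type,
            cell_positions=self.cell_positions,
        )


@dataclass
class GLMPopulation:
    """A set of cells sharing filter bases, bin width and geometry.

    ``neighbor_graph[i]`` lists cells whose spikes feed cell i's coupling
    filters; a coupling weight may exist only for listed edges.
    """

    cells: list[GLMParams]
    positions: np.ndarray
    dt: float
    stim_basis: CosineBasis
    hist_basis: CosineBasis
    coup_basis: CosineBasis
    neighbor_graph: dict[int, list[int]] = field(default_factory=dict)
    pixel_grid: tuple[int, int] = (3, 3)
    center_cell: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for i, cell in enumerate(self.cells):
            allowed = set(self.neighbor_graph.get(i, []))
            extra = set(cell.coupling_weights) - allowed
            if extra:
                raise ValueError(f"cell {i} has coupling filters outside neighbor_graph: {extra}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_pixels(self) -> int:
        return self.pixel_grid[0] * self.pixel_grid[1]

    def independent_copy(self) -> "GLMPopulation":
        """Same cells with all coupling filters removed (graph kept empty)."""
        cells = [
            GLMParams(
                spatial_filter=c.spatial_filter.copy(),
                temporal_weights=c.temporal_weights.copy(),
                history_weights=c.history_weights.copy(),
                coupling_weights={},
                dc=c.dc,
            )
            for c in self.cells
        ]
        return GLMPopulation(
            cells=cells,
            positions=self.positions.copy(),
            dt=self.dt,
            stim_basis=self.stim_basis,
            hist_basis=self.hist_basis,
            coup_basis=self.coup_basis,
            neighbor_graph={},
            pixel_grid=self.pixel_grid,
            center_cell=self.center_cell,
        )


# ---------------------------------------------------------------------------
# drive computation


def upsample_stimulus(stimulus, dt: float, n_bins: int | None = None) -> np.ndarray:
    """Signed-contrast stimulus at bin resolution: (n_bins, n_pixels) in {-1,+1}.

    Each movie frame is held constant over the bins it spans (zero-order hold,
    works for any refresh/dt ratio).
    """
    x = stimulus.contrast().reshape(stimulus.frames, -1)
    if n_bins is None:
        n_bins = int(round(stimulus.duration / dt))
    frame_idx = np.minimum(
        (np.arange(n_bins) * dt * stimulus.refresh).astype(int), stimulus.frames - 1
    )
    return x[frame_idx]


def _causal_conv(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """out[t] = sum_{tau>=0} kernel[tau] signal[t - tau], same length as signal."""
    return np.convolve(signal, kernel)[: len(signal)]


def _spike_feedback(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Strictly causal feedback: out[t] = sum_{tau>=1} kernel[tau-1] counts[t-tau]."""
    full = np.convolve(counts, kernel)[: len(counts)]
    out = np.empty_like(full)
    out[0] = 0.0
    out[1:] = full[:-1]
    return out


def stimulus_drive(
    population: GLMPopulation, cell: int, stim_bins: np.ndarray
) -> np.ndarray:
    """k . x(t) for one cell given the upsampled stimulus (n_bins, n_pixels)."""
    p = population.cells[cell]
    s = stim_bins @ p.spatial_filter
    kt = population.stim_basis.kernel(p.temporal_weights)
    return _causal_conv(s, kt)


def feedback_drive(
    population: GLMPopulation, cell: int, counts: np.ndarray
) -> np.ndarray:
    """History plus coupling drive from observed spike counts (n_cells, n_bins)."""
    p = population.cells[cell]
    h = population.hist_basis.kernel(p.history_weights)
    drive = _spike_feedback(counts[cell].astype(float), h)
    for j, w in p.coupling_weights.items():
        ck = population.coup_basis.kernel(w)
        drive += _spike_feedback(counts[j].astype(float), ck)
    return drive


def conditional_intensity(
    population: GLMPopulation,
    cell: int,
    stimulus,
    spike_history: np.ndarray | None = None,
) -> np.ndarray:
    """Rate trace (Hz) of one cell conditioned on stimulus and observed spikes.

    ``spike_history`` is an (n_cells, n_bins) count array; spike terms are
    strictly causal (the bin's own count never feeds its rate).
    """
    stim_bins = upsample_stimulus(stimulus, population.dt)
    n_bins = len(stim_bins)
    g = stimulus_drive(population, cell, stim_bins) + population.cells[cell].dc
    if spike_history is not None:
        spike_history = np.asarray(spike_history)
        if spike_history.shape[1] != n_bins:
            raise ValueError("spike history misaligned with stimulus bins")
        g += feedback_drive(population, cell, spike_history)
    return logexp2(g)


# ---------------------------------------------------------------------------
# simulation


def simulate_spikes(
    population: GLMPopulation,
    stimulus,
    n_trials: int,
    seed: int | np.random.Generator,
    max_rate_warn: float = 0.9,
) -> SpikeRaster:
    """Sample Poisson spike counts bin by bin with history/coupling feedback."""
    rng = np.random.default_rng(seed)
    dt = population.dt
    stim_bins = upsample_stimulus(stimulus, dt)
    n_bins = len(stim_bins)
    n_cells = population.n_cells

    base = np.empty((n_cells, n_bins))
    for i in range(n_cells):
        base[i] = stimulus_drive(population, i, stim_bins) + population.cells[i].dc

    h_k = [population.hist_basis.kernel(c.history_weights) for c in population.cells]
    coup = []  # (source, target, kernel)
    for i, c in enumerate(population.cells):
        for j, w in c.coupling_weights.items():
            coup.append((j, i, population.coup_basis.kernel(w)))
    max_len = max(
        [len(k) for k in h_k] + [len(k) for _, _, k in coup] + [1]
    )

    counts = np.zeros((n_trials, n_cells, n_bins), dtype=np.int16)
    warned = False
    for trial in range(n_trials):
        fb = np.zeros((n_cells, n_bins + max_len + 1))
        for t in range(n_bins):
            rate = logexp2(base[:, t] + fb[:, t])
            lam = rate * dt
            if not warned and np.any(lam >= max_rate_warn):
                warnings.warn(
                    "rate*dt exceeds %.2f; consider a smaller dt" % max_rate_warn
                )
                warned = True
            if np.any(lam > 1e6):
                raise FloatingPointError(
                    "rate overflow during simulation (max rate %.3g Hz)" % (lam.max() / dt)
                )
            y = rng.poisson(lam)
            if y.any():
                counts[trial, :, t] = y
                for i in np.nonzero(y)[0]:
                    k = h_k[i]
                    fb[i, t + 1 : t + 1 + len(k)] += y[i] * k
                for src, tgt, k in coup:
                    if y[src]:
                        fb[tgt, t + 1 : t + 1 + len(k)] += y[src] * k
    return SpikeRaster(
        counts=counts,
        dt=dt,
        trial_type="non-repeated" if n_trials == 1 else "repeated",
        cell_positions=population.positions,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GLMFitConfig:
    n_basis: int = 8
    stim_support: float = 0.10  # s
    hist_support: float = 0.10
    coup_support: float = 0.05
    max_alternations: int = 8
    inner_maxiter: int = 120
    tol: float = 1e-6
    seed: int = 0
    init: str = "sta"  # or "random"
    # Smoothness penalty on the stimulus temporal kernel.  The stimulus is
    # piecewise-constant over frames much longer than a time bin, so the
    # likelihood has near-null directions (frame-rate ringing of the
    # temporal kernel); penalizing the kernel's second difference selects
    # the smooth representative without shrinking history or coupling
    # weights, whose magnitudes carry meaning.
    temporal_smoothness: float = 10.0


def _poisson_nll_and_grad(theta, X, y, dt, n, P=None):
    """Negative Poisson log-likelihood per bin and gradient for linear drive.

    ``P`` (optional, PSD) adds a quadratic penalty theta' P theta.
    """
    g = X @ theta
    s = np.logaddexp(0.0, g)
    s = np.maximum(s, 1e-12)
    sig = expit(g)
    f = s * s
    nll = -(y @ np.log(f) - dt * f.sum()) / n
    # d nll/d g = -(2 y sig/s - 2 dt s sig)/n
    gg = -(2.0 * y * sig / s - 2.0 * dt * s * sig) / n
    grad = X.T @ gg
    if P is not None:
        Pt = P @ theta
        nll += float(theta @ Pt)
        grad = grad + 2.0 * Pt
    return nll, grad


def _sta_init(y, stim_bins, stim_basis: CosineBasis):
    """Rank-one init from the spike-triggered average projected onto the basis."""
    L = stim_basis.support_bins
    n, n_pix = stim_bins.shape
    nsp = y.sum()
    if nsp == 0:
        return None
    sta = np.zeros((L, n_pix))
    spikes = np.nonzero(y)[0]
    for lag in range(L):
        idx = spikes - lag
        idx = idx[idx >= 0]
        if len(idx):
            sta[lag] = y[idx + lag] @ stim_bins[idx]
    sta /= nsp
    u, s, vt = np.linalg.svd(sta, full_matrices=False)
    temporal = u[:, 0] * s[0]
    spatial = vt[0]
    tw, *_ = np.linalg.lstsq(stim_basis.matrix, temporal, rcond=None)
    return spatial, tw


def fit_cell(
    y: np.ndarray,
    stim_bins: np.ndarray,
    dt: float,
    stim_basis: CosineBasis,
    hist_basis: CosineBasis,
    coup_basis: CosineBasis | None = None,
    neighbor_counts: dict[int, np.ndarray] | None = None,
    config: GLMFitConfig | None = None,
) -> tuple[GLMParams, float]:
    """Maximum-likelihood fit of one cell's GLM.

    Returns (params, final mean log-likelihood per bin).  The rank-one
    stimulus filter is handled by alternating L-BFGS updates of the spatial
    profile and of everything else (temporal, history, coupling, dc);
    alternation stops when the relative log-likelihood gain drops below
    ``config.tol``.
    """
    config = config or GLMFitConfig()
    neighbor_counts = neighbor_counts or {}
    rng = np.random.default_rng(config.seed)
    n, n_pix = stim_bins.shape
    y = np.asarray(y, dtype=float)

    # spike-feedback design matrices (fixed throughout)
    H = np.column_stack(
        [_spike_feedback(y, hist_basis.matrix[:, j]) for j in range(hist_basis.matrix.shape[1])]
    )
    neigh_ids = sorted(neighbor_counts)
    C_blocks = []
    for j in neigh_ids:
        cj = np.asarray(neighbor_counts[j], dtype=float)
        C_blocks.append(
            np.column_stack(
                [
                    _spike_feedback(cj, coup_basis.matrix[:, k])
                    for k in range(coup_basis.matrix.shape[1])
                ]
            )
        )

    nb = stim_basis.matrix.shape[1]
    mean_rate = max(y.mean() / dt, 0.1)
    dc0 = float(np.log(np.expm1(np.sqrt(mean_rate))))

    if config.init == "sta":
        init = _sta_init(y, stim_bins, stim_basis)
    else:
        init = None
    if init is None:
        spatial = 0.01 * rng.standard_normal(n_pix)
        tw = 0.01 * rng.standard_normal(nb)
    else:
        spatial, tw = init
        nrm = np.linalg.norm(spatial)
        if nrm > 0:
            spatial = spatial / nrm
            tw = tw * nrm
    hw = np.zeros(hist_basis.matrix.shape[1])
    cws = [np.zeros(coup_basis.matrix.shape[1]) for _ in neigh_ids]
    dc = dc0

    def temporal_design():
        s = stim_bins @ spatial
        cols = [
            _causal_conv(s, stim_basis.matrix[:, j]) for j in range(nb)
        ]
        return np.column_stack(cols)

    def spatial_design():
        kt = stim_basis.kernel(tw)
        cols = [_causal_conv(stim_bins[:, p], kt) for p in range(n_pix)]
        return np.column_stack(cols)

    def loglik(g):
        s = np.maximum(np.logaddexp(0.0, g), 1e-12)
        f = s * s
        return float(y @ np.log(f) - dt * f.sum()) / n

    # quadratic smoothness penalty on the temporal-kernel block only
    n_theta = nb + H.shape[1] + sum(b.shape[1] for b in C_blocks) + 1
    P = None
    if config.temporal_smoothness > 0.0:
        B = stim_basis.matrix
        D = np.diff(np.eye(B.shape[0]), n=2, axis=0)
        DB = D @ B
        P = np.zeros((n_theta, n_theta))
        P[:nb, :nb] = config.temporal_smoothness * (DB.T @ DB)

    last_ll = -np.inf
    for alternation in range(config.max_alternations):
        # --- step B: temporal + history + coupling + dc
        T = temporal_design()
        X = np.column_stack([T, H] + C_blocks + [np.ones(n)])
        theta0 = np.concatenate([tw, hw] + cws + [[dc]])
        res = minimize(
            _poisson_nll_and_grad,
            theta0,
            args=(X, y, dt, n, P),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.inner_maxiter},
        )
        theta = res.x
        pos = 0
        tw = theta[pos : pos + nb]
        pos += nb
        hw = theta[pos : pos + H.shape[1]]
        pos += H.shape[1]
        for k in range(len(cws)):
            cws[k] = theta[pos : pos + C_blocks[k].shape[1]]
            pos += C_blocks[k].shape[1]
        dc = float(theta[pos])

        # --- step A: spatial profile
        S = spatial_design()
        offset = (
            H @ hw
            + sum(C_blocks[k] @ cws[k] for k in range(len(cws)))
            + dc
        )
        def nll_spatial(th):
            g = S @ th + offset
            sfp = np.maximum(np.logaddexp(0.0, g), 1e-12)
            sig = expit(g)
            f = sfp * sfp
            nll = -(y @ np.log(f) - dt * f.sum()) / n
            gg = -(2.0 * y * sig / sfp - 2.0 * dt * sfp * sig) / n
            return nll, S.T @ gg

        res2 = minimize(
            nll_spatial,
            spatial,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.inner_maxiter},
        )
        spatial = res2.x

        # fix the rank-one scale/sign split: unit-norm spatial, sign by max-|.| entry
        nrm = np.linalg.norm(spatial)
        if nrm > 0:
            sign = np.sign(spatial[np.argmax(np.abs(spatial))]) or 1.0
            spatial = spatial / (nrm * sign)
            tw = tw * (nrm * sign)

        ll = loglik(
            spatial_design() @ spatial
            + H @ hw
            + sum(C_blocks[k] @ cws[k] for k in range(len(cws)))
            + dc
        )
        if ll < last_ll - 1e-12:
            warnings.warn("log-likelihood decreased across alternation")
        if np.isfinite(last_ll) and abs(ll - last_ll) < config.tol * max(abs(ll), 1e-12):
            last_ll = ll
            break
        last_ll = ll
    else:
        if config.max_alternations > 2:
            warnings.warn("GLM fit did not converge; returning best-so-far")

    params = GLMParams(
        spatial_filter=spatial,
        temporal_weights=tw,
        history_weights=hw,
        coupling_weights={j: cws[k] for k, j in enumerate(neigh_ids)},
        dc=dc,
    )
    return params, last_ll


def fit_glm(
    raster: SpikeRaster,
    stimulus,
    config: GLMFitConfig | None = None,
    coupled: bool = False,
    neighbor_graph: dict[int, list[int]] | None = None,
    positions: np.ndarray | None = None,
    cells: list[int] | None = None,
) -> GLMPopulation:
    """Fit independent or coupled GLMs to a non-repeated raster.

    For the coupled model each cell is regressed on its own history plus the
    observed spikes of its ``neighbor_graph`` neighbors (point-process
    factorization: cells can be fit one at a time).
    """
    if raster.n_trials != 1:
        raise ValueError("fitting expects a single non-repeated trial")
    config = config or GLMFitConfig()
    dt = raster.dt
    stim_bins = upsample_stimulus(stimulus, dt, n_bins=raster.n_bins)
    stim_basis = CosineBasis(config.n_basis, config.stim_support, dt)
    hist_basis = CosineBasis(config.n_basis, config.hist_support, dt)
    coup_basis = CosineBasis(config.n_basis, config.coup_support, dt)
    counts = raster.counts[0]
    n_cells = counts.shape[0]
    cells = list(range(n_cells)) if cells is None else cells
    graph = neighbor_graph or {}
    fitted = []
    for i in cells:
        neigh = (
            {j: counts[j] for j in graph.get(i, []) if j != i} if coupled else {}
        )
        params, _ = fit_cell(
            counts[i],
            stim_bins,
            dt,
            stim_basis,
            hist_basis,
            coup_basis,
            neighbor_counts=neigh,
            config=config,
        )
        fitted.append(params)
    if positions is not None:
        pos = np.atleast_2d(positions)
    elif raster.cell_positions is not None:
        pos = np.atleast_2d(raster.cell_positions)[cells]
    else:
        pos = np.zeros((len(cells), 2))
    rows, cols = stimulus.grid
    return GLMPopulation(
        cells=fitted,
        positions=pos,
        dt=dt,
        stim_basis=stim_basis,
        hist_basis=hist_basis,
        coup_basis=coup_basis,
        neighbor_graph={k: v for k, v in (graph or {}).items()} if coupled else {},
        pixel_grid=(rows, cols),
    )


# ---------------------------------------------------------------------------
# model evaluation


def compute_psth(raster: SpikeRaster, bin_width: float = 0.005) -> np.ndarray:
    """Trial-averaged firing rate (Hz) per cell: (n_cells, n_psth_bins)."""
    rb = raster.rebin(bin_width) if bin_width != raster.dt else raster
    return rb.counts.mean(axis=0) / bin_width


def explained_variance(predicted_psth: np.ndarray, observed_psth: np.ndarray) -> float:
    """1 - var(observed - predicted) / var(observed); reported raw (can be < 0)."""
    predicted_psth = np.asarray(predicted_psth, dtype=float)
    observed_psth = np.asarray(observed_psth, dtype=float)
    v = observed_psth.var()
    if v == 0:
        raise ValueError("observed PSTH has zero variance")
    return float(1.0 - (observed_psth - predicted_psth).var() / v)
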