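"""Linear-Gaussian receptive-field populations on hexagonal mosaics.

A population of model neurons with circular receptive fields (RFs) tiled on a
hexagonal grid responds to a binary pixel stimulus.  Each neuron's signal is
the stimulus filtered linearly through its RF (0 Hz when fully covered by
black, ``max_rate`` when fully covered by white), and its noise is additive
Gaussian with variance equal to the mean rate (Poisson scaling), correlated
between cells with an exponentially distance-decaying coefficient.

The product of this module is a :class:`GaussianEnsemble`: the mean-difference
vector and covariance matrices of the observables (neuron rates plus the known
outer pixels of a stimulus patch) between the two conditions "central pixel
white" and "central pixel black".  The discriminability module consumes these
triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import PatchStatistics

__all__ = [
    "HexGrid",
    "RFGridConfig",
    "NoiseModel",
    "GaussianEnsemble",
    "build_hex_grid",
    "rf_pixel_weights",
    "rf_signal",
    "noise_covariance",
    "assemble_ensemble",
    "two_cell_ensemble",
]


@dataclass
class HexGrid:
    centers: np.ndarray  # (n, 2), micrometers
    spacing: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))

    @property
    def n_neurons(self) -> int:
        return len(self.centers)

    def pairwise_distances(self) -> np.ndarray:
        d = self.centers[:, None, :] - self.centers[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))


def build_hex_grid(n_rings: int, spacing: float) -> HexGrid:
    """Central cell plus ``n_rings`` hexagonal shells; 1 + 3*r*(r+1) cells."""
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    pts = [(0.0, 0.0)]
    # axial hex coordinates -> cartesian
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            s = -q - r
            ring = max(abs(q), abs(r), abs(s))
            if ring == 0 or ring > n_rings:
                continue
            x = spacing * (q + r / 2.0)
            y = spacing * (np.sqrt(3.0) / 2.0) * r
            pts.append((x, y))
    return HexGrid(centers=np.array(pts), spacing=spacing)


@dataclass
class RFGridConfig:
    """Geometry and gain of the circular-RF grid model.

    rf_diameter: RF diameter in um (default 250, equal to the pixel size).
    max_rate: firing rate in Hz when the RF is fully covered by white.
    pixel_size: stimulus pixel side in um.
    """

    rf_diameter: float = 250.0
    max_rate: float = 30.0
    pixel_size: float = 250.0
    quadrature: int = 64  # sub-samples per axis for circle-square overlap

    def __post_init__(self) -> None:
        if self.rf_diameter <= 0 or self.max_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("rf_diameter, max_rate, pixel_size must be positive")

    def overlap(self, spacing: float) -> float:
        """Dimensionless RF overlap = rf_diameter / grid spacing."""
        return self.rf_diameter / spacing


@dataclass
class NoiseModel:
    """Exponentially distance-decaying pairwise noise correlation.

    rho(d) = rho_max * exp(-d / lambda_c) for d > 0, rho(0) = 1.  For
    rho_max < 1 the implied correlation matrix on distinct points carries a
    positive nugget (1 - rho_max) on the diagonal and is positive definite.
    """

    rho_max: float
    lambda_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_max < 1.0):
            raise ValueError("rho_max must be in [0, 1)")
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be positive")

    def correlation(self, distances: np.ndarray) -> np.ndarray:
        rho = self.rho_max * np.exp(-np.asarray(distances, dtype=float) / self.lambda_c)
        rho = np.where(np.asarray(distances) == 0.0, 1.0, rho)
        return rho


@dataclass
class GaussianEnsemble:
    """(delta_mu, Q, Q_d) triple for a two-condition linear-Gaussian problem.

    Observables are ordered [neurons..., outer pixels...].  ``mu_white`` and
    ``mu_black`` are retained for Monte-Carlo checks; samples in either
    condition are drawn from N(mu_condition, Q).
    """

    delta_mu: np.ndarray
    Q: np.ndarray
    Q_d: np.ndarray
    n_neurons: int
    labels: list[str] = field(default_factory=list)
    mu_white: np.ndarray | None = None
    mu_black: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_mu = np.asarray(self.delta_mu, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.Q_d = np.asarray(self.Q_d, dtype=float)
        n = len(self.delta_mu)
        if self.Q.shape != (n, n) or self.Q_d.shape != (n, n):
            raise ValueError("Q and Q_d must be square and match delta_mu")
        if not self.labels:
            self.labels = [f"neuron_{i}" for i in range(self.n_neurons)] + [
                f"pixel_{i}" for i in range(n - self.n_neurons)
            ]

    @property
    def n_observables(self) -> int:
        return len(self.delta_mu)

    @property
    def neuron_indices(self) -> np.ndarray:
        return np.arange(self.n_neurons)

    @property
    def pixel_indices(self) -> np.ndarray:
        return np.arange(self.n_neurons, self.n_observables)

    def restrict(self, indices: np.ndarray) -> "GaussianEnsemble":
        """Sub-ensemble over a subset of observables (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        n_neu = int(np.sum(indices < self.n_neurons))
        return GaussianEnsemble(
            delta_mu=self.delta_mu[indices],
            Q=self.Q[np.ix_(indices, indices)],
            Q_d=self.Q_d[np.ix_(indices, indices)],
            n_neurons=n_neu,
            labels=[self.labels[i] for i in indices],
            mu_white=None if self.mu_white is None else self.mu_white[indices],
            mu_black=None if self.mu_black is None else self.mu_black[indices],
            meta=dict(self.meta),
        )

    def sample(self, condition: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n observations from N(mu_condition, Q)."""
        mu = self.mu_white if condition == "white" else self.mu_black
        if mu is None:
            raise ValueError("per-condition means not available on this ensemble")
        L = np.linalg.cholesky(self.Q)
        z = rng.standard_normal((n, self.n_observables))
        return mu + z @ L.T


def rf_pixel_weights(
    config: RFGridConfig,
    rf_center: np.ndarray,
    pixel_centers: np.ndarray,
    require_covered: bool = True,
) -> np.ndarray:
    """Fraction of a circular RF's area overlapping each square pixel.

    Deterministic sub-pixel quadrature: the RF's bounding box is divided into
    ``quadrature x quadrature`` cells, cells inside the circle are assigned to
    the pixel containing their midpoint.  Weights sum to 1 when the pixel grid
    covers the RF; with ``require_covered`` a partially uncovered RF raises.
    """
    r = config.rf_diameter / 2.0
    m = config.quadrature
    ax = (np.arange(m) + 0.5) / m * config.rf_diameter - r
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    inside = (xx ** 2 + yy ** 2) <= r ** 2
    px = xx[inside] + rf_center[0]
    py = yy[inside] + rf_center[1]
    half = config.pixel_size / 2.0
    weights = np.zeros(len(pixel_centers))
    claimed = np.zeros(len(px), dtype=bool)
    for i, (cx, cy) in enumerate(pixel_centers):
        sel = (
            (px >= cx - half)
            & (px < cx + half)
            & (py >= cy - half)
            & (py < cy + half)
        )
        weights[i] = sel.sum()
        claimed |= sel
    total = len(px)
    if require_covered and not claimed.all():
        raise ValueError(
            "RF at %s extends outside the pixel grid (%.1f%% uncovered)"
            % (rf_center, 100.0 * (1 - claimed.mean()))
        )
    return weights / total


def rf_signal(
    config: RFGridConfig,
    rf_center: np.ndarray,
    frame: np.ndarray,
    pixel_centers: np.ndarray,
) -> float:
    """Linear RF response to one binary frame, in Hz.

    ``frame`` is the flat vector of pixel intensities in {0,1} matching
    ``pixel_centers``.  All-black -> 0 Hz, all-white -> max_rate.
    """
    frame = np.asarray(frame, dtype=float).ravel()
    w = rf_pixel_weights(config, np.asarray(rf_center, dtype=float), pixel_centers)
    if w.sum() == 0:
        raise ValueError("RF entirely outside the stimulus")
    return float(config.max_rate * w @ frame)


def noise_covariance(
    grid: HexGrid, mean_rates: np.ndarray, noise_model: NoiseModel
) -> np.ndarray:
    """Sigma_ij = rho(d_ij) sqrt(r_i r_j), Sigma_ii = r_i (Poisson scaling)."""
    rates = np.asarray(mean_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("mean rates must be nonnegative")
    rho = noise_model.correlation(grid.pairwise_distances())
    sig = rho * np.sqrt(np.outer(rates, rates))
    np.fill_diagonal(sig, rates)
    eig = np.linalg.eigvalsh(sig)
    if rates.max() > 0 and eig.min() < -1e-8 * np.trace(sig):
        raise ValueError(
            "noise covariance not PSD for rho_max=%.3f lambda_c=%.1f"
            % (noise_model.rho_max, noise_model.lambda_c)
        )
    return sig


def _patch_pixel_centers(patch_stats: PatchStatistics, pixel_size: float) -> np.ndarray:
    return patch_stats.pixel_offsets_um(pixel_size)


def assemble_ensemble(
    config: RFGridConfig,
    grid: HexGrid,
    noise_model: NoiseModel,
    patch_stats: PatchStatistics,
    noise_at: str = "averaged",
) -> GaussianEnsemble:
    """Build the (delta_mu, Q, Q_d) ensemble for decoding the central pixel.

    Observables: neuron rates (Hz) followed by the outer (non-decoded) pixel
    intensities.  Per center-pixel condition c in {white, black}:

      neuron mean   mu_i(c) = max_rate * sum_p w_ip m_p(c)
      stim-driven   S       = W C W^T  (C = conditional pixel covariance)
      noise         N       = rho(d) sqrt(r_i r_j) at Poisson-scaled rates

    Q averages over the two conditions; by default the noise term is evaluated
    once at condition-averaged rates (``noise_at='averaged'``), with
    ``noise_at='per-condition'`` averaging two per-condition noise matrices
    instead.  Q_d zeroes the *noise* part of the neuron-neuron off-diagonal,
    leaving stimulus-driven (signal) covariance intact.
    """
    if noise_at not in ("averaged", "per-condition"):
        raise ValueError("noise_at must be 'averaged' or 'per-condition'")
    pix = _patch_pixel_centers(patch_stats, config.pixel_size)
    n_neu = grid.n_neurons
    p2 = patch_stats.patch_size ** 2
    W = np.zeros((n_neu, p2))
    for i, c in enumerate(grid.centers):
        W[i] = config.max_rate * rf_pixel_weights(config, c, pix)
    C = patch_stats.cond_cov
    outer = patch_stats.outer_indices

    mu_neu_w = W @ patch_stats.cond_mean_white
    mu_neu_b = W @ patch_stats.cond_mean_black
    rates_avg = 0.5 * (mu_neu_w + mu_neu_b)

    S_nn = W @ C @ W.T
    S_np = (W @ C)[:, outer]
    S_pp = C[np.ix_(outer, outer)]

    if noise_at == "averaged":
        N = noise_covariance(grid, rates_avg, noise_model)
    else:
        N = 0.5 * (
            noise_covariance(grid, np.maximum(mu_neu_w, 0), noise_model)
            + noise_covariance(grid, np.maximum(mu_neu_b, 0), noise_model)
        )
    N_diag = np.diag(np.diag(N))

    n_obs = n_neu + len(outer)
    Q = np.zeros((n_obs, n_obs))
    Q[:n_neu, :n_neu] = S_nn + N
    Q[:n_neu, n_neu:] = S_np
    Q[n_neu:, :n_neu] = S_np.T
    Q[n_neu:, n_neu:] = S_pp
    Q_d = Q.copy()
    Q_d[:n_neu, :n_neu] = S_nn + N_diag

    dmu = np.concatenate(
        [
            mu_neu_w - mu_neu_b,
            (patch_stats.cond_mean_white - patch_stats.cond_mean_black)[outer],
        ]
    )
    mu_w = np.concatenate([mu_neu_w, patch_stats.cond_mean_white[outer]])
    mu_b = np.concatenate([mu_neu_b, patch_stats.cond_mean_black[outer]])

    try:
        np.linalg.cholesky(Q + 0.0)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular Q; consider regularizing the pixel block of the patch "
            "statistics (e.g. add a small ridge to cond_cov)"
        ) from err

    return GaussianEnsemble(
        delta_mu=dmu,
        Q=Q,
        Q_d=Q_d,
        n_neurons=n_neu,
        mu_white=mu_w,
        mu_black=mu_b,
        meta={
            "rho_max": noise_model.rho_max,
            "lambda_c": noise_model.lambda_c,
            "spacing": grid.spacing,
            "overlap": config.overlap(grid.spacing),
            "noise_at": noise_at,
        },
    )


def two_cell_ensemble(
    mu_s1: np.ndarray, mu_s2: np.ndarray, noise_corr: float
) -> GaussianEnsemble:
    """Two neurons discriminating two stimuli under Poisson-scaled noise.

    Per-condition covariance has diag = rates and off-diagonal
    ``noise_corr * sqrt(r1 r2)``; Q averages the two conditions and Q_d is the
    diagonal of Q.  Negative noise correlations are allowed here (unlike the
    grid model). The ensemble is flagged "same-sign" when the product of the
    two mean-difference entries is positive (signal and noise correlation of
    the same sign is the failure-prone configuration).
    """
    mu1 = np.asarray(mu_s1, dtype=float)
    mu2 = np.asarray(mu_s2, dtype=float)
    if mu1.shape != (2,) or mu2.shape != (2,):
        raise ValueError("mu_s1 and mu_s2 must be length-2 rate vectors")
    if np.any(mu1 <= 0) or np.any(mu2 <= 0):
        raise ValueError("rates must be positive")
    if not (-1.0 < noise_corr < 1.0):
        raise ValueError("|noise_corr| must be < 1")

    def cov(r):
        c = np.diag(r).astype(float)
        c[0, 1] = c[1, 0] = noise_corr * np.sqrt(r[0] * r[1])
        return c

    Q = 0.5 * (cov(mu1) + cov(mu2))
    dmu = mu1 - mu2
    same_sign = bool(dmu[0] * dmu[1] * noise_corr > 0)
    return GaussianEnsemble(
        delta_mu=dmu,
        Q=Q,
        Q_d=np.diag(np.diag(Q)),
        n_neurons=2,
        mu_white=mu1,
        mu_black=mu2,
        meta={"noise_corr": noise_corr, "same_sign": same_sign},
    )
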