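"""Linear discriminability of two stimulus conditions, with and without
knowledge of noise correlations.

For Gaussian observables with mean difference delta_mu and common covariance
Q, the optimal linear readout achieves

    d^2 = delta_mu' Q^{-1} delta_mu.

A mismatched readout optimized under the independence-assuming covariance Q_d
but evaluated under the true Q achieves

    d_d^2 = (delta_mu' Q_d^{-1} delta_mu)^2 / (delta_mu' Q_d^{-1} Q Q_d^{-1} delta_mu),

which never exceeds d^2 (Cauchy-Schwarz) and equals it when Q_d = Q.  The
single-cell baseline restricts the observables to one neuron plus the known
outer pixels and applies the optimal readout there.  "Population failure" is
the regime where the independence-assuming population readout falls below the
single-cell baseline: d_d^2 < d_single^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .linear_population import (
    GaussianEnsemble,
    HexGrid,
    NoiseModel,
    RFGridConfig,
    assemble_ensemble,
    build_hex_grid,
    two_cell_ensemble,
)
from .stimuli import PatchStatistics

__all__ = [
    "DiscriminabilityResult",
    "FailureMap",
    "d2_optimal",
    "d2_mismatched",
    "d2_single",
    "evaluate_ensemble",
    "sweep_two_cell",
    "sweep_grid_model",
]


def _chol_solve(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    try:
        c = cho_factor(M, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrix is not positive definite") from err
    return cho_solve(c, v, check_finite=False)


def d2_optimal(ensemble: GaussianEnsemble) -> float:
    """d^2 of the optimal linear readout: delta_mu' Q^{-1} delta_mu."""
    dmu = ensemble.delta_mu
    return float(dmu @ _chol_solve(ensemble.Q, dmu))


def d2_mismatched(ensemble: GaussianEnsemble) -> float:
    """d^2 of the readout optimized under Q_d but evaluated under Q."""
    dmu = ensemble.delta_mu
    w = _chol_solve(ensemble.Q_d, dmu)
    num = float(dmu @ w) ** 2
    den = float(w @ ensemble.Q @ w)
    if den <= 0:
        raise ValueError("degenerate mismatched readout variance")
    return num / den


def d2_single(ensemble: GaussianEnsemble, neuron_index: int) -> float:
    """Optimal d^2 using one neuron plus all pixel observables."""
    if not (0 <= neuron_index < ensemble.n_neurons):
        raise IndexError("neuron_index out of range")
    idx = np.concatenate([[neuron_index], ensemble.pixel_indices])
    return d2_optimal(ensemble.restrict(idx))


@dataclass
class DiscriminabilityResult:
    d2_coupled: float
    d2_independent: float
    d2_single: float
    single_index: int

    @property
    def improvement_pct(self) -> float:
        """Percent gain of the correlation-aware over the independent readout."""
        return 100.0 * (self.d2_coupled / self.d2_independent - 1.0)

    @property
    def failure(self) -> bool:
        """Independence-assuming population strictly below the single cell."""
        return self.d2_independent < self.d2_single

    @property
    def single_cell_deficit_pct(self) -> float:
        """100 * (1 - d_independent^2 / d_single^2); positive under failure."""
        return 100.0 * (1.0 - self.d2_independent / self.d2_single)


def evaluate_ensemble(
    ensemble: GaussianEnsemble, single_index: int = 0
) -> DiscriminabilityResult:
    res = DiscriminabilityResult(
        d2_coupled=d2_optimal(ensemble),
        d2_independent=d2_mismatched(ensemble),
        d2_single=d2_single(ensemble, single_index),
        single_index=single_index,
    )
    # numerical guards for the exact inequalities (soft tolerance, then assert)
    tol = 1e-9 * max(1.0, res.d2_coupled)
    if res.d2_independent > res.d2_coupled + tol:
        raise AssertionError("mismatch inequality violated: d_d^2 > d^2")
    if res.d2_single > res.d2_coupled + tol:
        raise AssertionError("nesting violated: d_single^2 > d^2")
    return res


@dataclass
class FailureMap:
    """Tidy per-grid-point discriminability results."""

    table: pd.DataFrame
    axes: dict

    def failure_points(self) -> pd.DataFrame:
        return self.table[self.table["failure"]]

    def max_single_cell_deficit_pct(self) -> float:
        return float(self.table["single_cell_deficit_pct"].max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_two_cell(
    signal_corr_grid: np.ndarray,
    noise_corr_grid: np.ndarray,
    base_rate: float = 20.0,
    delta_norm: float = 10.0,
) -> FailureMap:
    """Sign-rule map for the two-cell model.

    Signal correlation s in (-1, 1) is realized by rotating the
    mean-difference vector at fixed magnitude: delta_mu = m (cos phi, sin phi)
    with phi = arcsin(s)/2, so s = +1 points along (1,1) (both cells increase
    together), s = -1 along (1,-1), and s = 0 leaves cell 2 uninformative.
    Cell 1 is always the (weakly) better single cell under this mapping.
    """
    rows = []
    for s in np.asarray(signal_corr_grid, dtype=float):
        if not (-1.0 < s < 1.0):
            raise ValueError("signal correlations must lie in (-1, 1)")
        phi = np.arcsin(s) / 2.0
        dmu = delta_norm * np.array([np.cos(phi), np.sin(phi)])
        mu1 = np.array([base_rate, base_rate]) + dmu / 2.0
        mu2 = np.array([base_rate, base_rate]) - dmu / 2.0
        for c in np.asarray(noise_corr_grid, dtype=float):
            ens = two_cell_ensemble(mu1, mu2, c)
            r = evaluate_ensemble(ens, single_index=0)
            rows.append(
                {
                    "signal_corr": s,
                    "noise_corr": c,
                    "d2_coupled": r.d2_coupled,
                    "d2_independent": r.d2_independent,
                    "d2_single": r.d2_single,
                    "improvement_pct": r.improvement_pct,
                    "single_cell_deficit_pct": r.single_cell_deficit_pct,
                    "failure": r.failure,
                    "same_sign": ens.meta["same_sign"],
                }
            )
    return FailureMap(
        table=pd.DataFrame(rows),
        axes={
            "signal_corr": np.asarray(signal_corr_grid, float),
            "noise_corr": np.asarray(noise_corr_grid, float),
        },
    )


def sweep_grid_model(
    overlap_grid: np.ndarray,
    rho_grid: np.ndarray,
    lambda_grid: np.ndarray,
    patch_stats: PatchStatistics,
    config: RFGridConfig | None = None,
    n_rings: int = 3,
    noise_at: str = "averaged",
) -> FailureMap:
    """Full-factorial sweep over RF overlap, peak correlation, and spatial scale.

    ``overlap_grid`` is rf_diameter / spacing (1 = abutting RFs);
    ``lambda_grid`` is in micrometers.  The central neuron (index 0) is the
    single-cell baseline.  PSD failures at a grid point mark that point
    invalid rather than aborting the sweep.
    """
    config = config or RFGridConfig()
    rows = []
    for ov in np.asarray(overlap_grid, dtype=float):
        if ov <= 0:
            raise ValueError("overlap values must be positive")
        spacing = config.rf_diameter / ov
        grid = build_hex_grid(n_rings, spacing)
        for rho in np.asarray(rho_grid, dtype=float):
            for lam in np.asarray(lambda_grid, dtype=float):
                row = {
                    "overlap": ov,
                    "spacing": spacing,
                    "rho_max": rho,
                    "lambda_c": lam,
                }
                try:
                    if rho == 0.0:
                        nm = NoiseModel(rho_max=0.0, lambda_c=max(lam, 1e-9))
                    else:
                        nm = NoiseModel(rho_max=rho, lambda_c=lam)
                    ens = assemble_ensemble(config, grid, nm, patch_stats, noise_at)
                    r = evaluate_ensemble(ens, single_index=0)
                    row.update(
                        d2_coupled=r.d2_coupled,
                        d2_independent=r.d2_independent,
                        d2_single=r.d2_single,
                        improvement_pct=r.improvement_pct,
                        single_cell_deficit_pct=r.single_cell_deficit_pct,
                        failure=r.failure,
                        valid=True,
                    )
                except ValueError as err:
                    row.update(
                        d2_coupled=np.nan,
                        d2_independent=np.nan,
                        d2_single=np.nan,
                        improvement_pct=np.nan,
                        single_cell_deficit_pct=np.nan,
                        failure=False,
                        valid=False,
                        error=str(err),
                    )
                rows.append(row)
    return FailureMap(
        table=pd.DataFrame(rows),
        axes={
            "overlap": np.asarray(overlap_grid, float),
            "rho_max": np.asarray(rho_grid, float),
            "lambda_c": np.asarray(lambda_grid, float),
        },
    )
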