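"""Sample-weighted least-squares SVM regression tuned by particle swarm.

The weighted LS-SVM solves one linear KKT system

    [[0, 1^T], [1, Omega + diag(1/(gamma * v_i))]] . [b; alpha] = [0; y]

with kernel matrix Omega_ij = k(x_i, x_j) and per-sample weights v_i that
rescale each residual's penalty (small v_i ~ discounting an outlier).
The "optimized sample-weighted" variant (OSWLS-SVM) searches the weight
vector and the kernel/regularization hyperparameters jointly with a
global-best particle swarm, minimizing the RMSE on a separate monitoring
(validation) set, then refits at the best position.

Kernels: RBF k(x, x') = exp(-||x - x'||^2 / sigma2) (default) or linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

DEFAULT_N_CYCLES = 70
DEFAULT_SWARM_SIZE = 30
DEFAULT_W_MIN = 1e-3
DEFAULT_LOG10_GAMMA_BOUNDS = (-2.0, 6.0)
DEFAULT_LOG10_SIGMA2_BOUNDS = (-2.0, 6.0)


@dataclass
class PSOConfig:
    """Global-best PSO settings.

    Only the 70-cycle count is dictated by the study design; swarm size,
    inertia schedule (linear 0.9 -> 0.4), acceleration coefficients
    c1 = c2 = 2 and the 20 %-of-range velocity clamp follow common PSO
    practice.
    """

    n_cycles: int = DEFAULT_N_CYCLES
    swarm_size: int = DEFAULT_SWARM_SIZE
    inertia: tuple[float, float] = (0.9, 0.4)
    c1: float = 2.0
    c2: float = 2.0
    vmax_frac: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")


@dataclass
class WLSSVMModel:
    """Solved weighted LS-SVM: dual coefficients, bias and kernel settings."""

    support_data: np.ndarray
    alpha: np.ndarray
    b: float
    gamma: float
    kernel: str
    sigma2: float | None
    weights: np.ndarray
    validation_rmse: float | None = None
    pso_trace: np.ndarray | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.support_data.shape[1]:
            raise ValueError(
                f"expected {self.support_data.shape[1]} variables, got shape {X_new.shape}"
            )
        K = _kernel_matrix(X_new, self.support_data, self.kernel, self.sigma2)
        return K @ self.alpha + self.b


def _kernel_matrix(X1: np.ndarray, X2: np.ndarray, kernel: str, sigma2: float | None) -> np.ndarray:
    if kernel == "linear":
        return X1 @ X2.T
    if kernel == "rbf":
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("RBF kernel requires sigma2 > 0")
        return np.exp(-cdist(X1, X2, "sqeuclidean") / sigma2)
    raise ValueError(f"unknown kernel {kernel!r}")


def _solve_kkt(omega: np.ndarray, y: np.ndarray, gamma: float, weights: np.ndarray):
    n = y.size
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = omega + np.diag(1.0 / (gamma * weights))
    rhs = np.concatenate([[0.0], y])
    try:
        sol = solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise np.linalg.LinAlgError(
            "singular KKT system; try a smaller gamma or jitter the weights"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            "singular KKT system; try a smaller gamma or jitter the weights"
        )
    return float(sol[0]), sol[1:]


def wlssvm_solve(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    gamma: float,
    kernel: str = "rbf",
    sigma2: float | None = 1.0,
    weights: np.ndarray | None = None,
) -> WLSSVMModel:
    """Solve the weighted LS-SVM KKT system on the calibration data.

    The dual residuals satisfy e_i = alpha_i / (gamma * v_i).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if X_cal.shape[0] != y_cal.size:
        raise ValueError("X_cal and y_cal row counts differ")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if weights is None:
        weights = np.ones(y_cal.size)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != y_cal.size:
        raise ValueError("weights length must equal the calibration size")
    if np.any(weights <= 0):
        raise ValueError("all sample weights must be positive")
    omega = _kernel_matrix(X_cal, X_cal, kernel, sigma2)
    b, alpha = _solve_kkt(omega, y_cal, gamma, weights)
    return WLSSVMModel(
        support_data=X_cal.copy(),
        alpha=alpha,
        b=b,
        gamma=float(gamma),
        kernel=kernel,
        sigma2=None if kernel == "linear" else float(sigma2),
        weights=weights.copy(),
    )


def wlssvm_predict(model: WLSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`WLSSVMModel.predict`."""
    return model.predict(X_new)


def pso_minimize(objective, bounds, config: PSOConfig | None = None):
    """Global-best PSO over a box.

    `bounds` is a (d, 2) array of (low, high) per dimension.  Cycle 1
    evaluates the uniformly initialized swarm; each later cycle applies the
    inertia + cognitive + social velocity update (velocities clamped,
    positions clipped to the box) and re-evaluates.  A NaN objective value
    is treated as +inf with a warning.  Returns ``(best_position,
    best_value, trace)`` where ``trace[c]`` is the global best after cycle
    c+1 (non-increasing).
    """
    config = config or PSOConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (d, 2) array")
    if not np.all(np.isfinite(bounds)) or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("bounds must be finite with high > low")
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    vmax = config.vmax_frac * span
    rng = np.random.default_rng(config.seed)

    def evaluate(positions: np.ndarray) -> np.ndarray:
        vals = np.empty(positions.shape[0])
        for i, pos in enumerate(positions):
            v = float(objective(pos))
            if np.isnan(v):
                warnings.warn("NaN objective value treated as +inf", stacklevel=3)
                v = np.inf
            vals[i] = v
        return vals

    x = lo + rng.random((config.swarm_size, d)) * span
    v = (2.0 * rng.random((config.swarm_size, d)) - 1.0) * vmax
    f = evaluate(x)
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    w0, w1 = config.inertia
    for cycle in range(1, config.n_cycles):
        frac = cycle / (config.n_cycles - 1) if config.n_cycles > 1 else 1.0
        w = w0 + (w1 - w0) * frac
        r1 = rng.random((config.swarm_size, d))
        r2 = rng.random((config.swarm_size, d))
        v = w * v + config.c1 * r1 * (pbest_x - x) + config.c2 * r2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = evaluate(x)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)
    return gbest_x, gbest_f, np.asarray(trace)


def oswls_svm_train(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    pso: PSOConfig | None = None,
    kernel: str = "rbf",
    w_min: float = DEFAULT_W_MIN,
    log10_gamma_bounds: tuple[float, float] = DEFAULT_LOG10_GAMMA_BOUNDS,
    log10_sigma2_bounds: tuple[float, float] = DEFAULT_LOG10_SIGMA2_BOUNDS,
) -> WLSSVMModel:
    """Optimized sample-weighted LS-SVM.

    The PSO searches ``n_cal`` per-sample weights in [w_min, 1] plus
    log10(gamma) (and log10(sigma2) for the RBF kernel), minimizing the
    RMSE of the calibration model on the monitoring (validation) set.  The
    weight lower bound keeps the KKT system nonsingular.  Returns the model
    refit at the best position, with the monitoring RMSE and the PSO trace
    attached.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_val.shape[0] == 0:
        raise ValueError("validation (monitoring) set must not be empty")
    if X_cal.shape[1] != X_val.shape[1]:
        raise ValueError("calibration and validation variable counts differ")
    pso = pso or PSOConfig()
    n = y_cal.size
    is_rbf = kernel == "rbf"
    if not is_rbf and kernel != "linear":
        raise ValueError(f"unknown kernel {kernel!r}")

    d_cal = cdist(X_cal, X_cal, "sqeuclidean") if is_rbf else None
    d_val = cdist(X_val, X_cal, "sqeuclidean") if is_rbf else None
    lin_cal = X_cal @ X_cal.T if not is_rbf else None
    lin_val = X_val @ X_cal.T if not is_rbf else None

    bounds = [(w_min, 1.0)] * n + [log10_gamma_bounds]
    if is_rbf:
        bounds.append(log10_sigma2_bounds)

    def objective(pos: np.ndarray) -> float:
        weights = pos[:n]
        gamma = 10.0 ** pos[n]
        if is_rbf:
            sigma2 = 10.0 ** pos[n + 1]
            omega = np.exp(-d_cal / sigma2)
            k_val = np.exp(-d_val / sigma2)
        else:
            omega, k_val = lin_cal, lin_val
        try:
            b, alpha = _solve_kkt(omega, y_cal, gamma, weights)
        except np.linalg.LinAlgError:
            return np.inf
        resid = y_val - (k_val @ alpha + b)
        return float(np.sqrt(np.mean(resid**2)))

    best, best_val, trace = pso_minimize(objective, np.asarray(bounds), pso)
    model = wlssvm_solve(
        X_cal,
        y_cal,
        gamma=10.0 ** best[n],
        kernel=kernel,
        sigma2=10.0 ** best[n + 1] if is_rbf else None,
        weights=best[:n],
    )
    model.validation_rmse = float(best_val)
    model.pso_trace = trace
    return model
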