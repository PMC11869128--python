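"""Multi-fidelity Gaussian-process surrogate over (molecule, fidelity) pairs.

Model
-----
Assay outcomes at every fidelity are modeled jointly by an exact GP with an
intrinsic-coregionalization kernel: the covariance between pair ``(x, f)``
and pair ``(x', f')`` is

    k((x,f), (x',f')) = a * B[f, f'] * T(x, x')

where ``T`` is the Tanimoto similarity of the molecules' binary fingerprints
(a valid PSD kernel on bit vectors), ``a > 0`` an amplitude, and ``B`` an
F x F positive-semidefinite coregionalization matrix parameterized as a
rank-2 factor plus a positive diagonal, ``B = L L^T + diag(exp(d))``.  Each
fidelity carries its own Gaussian noise variance.  Training values are
z-scored per fidelity inside the model; the effective correlation between
fidelities at a given point in chemical space emerges through posterior
conditioning on nearby observations at each fidelity.

Hyperparameters (a, L, d, per-fidelity noise) maximize the log marginal
likelihood via multi-start L-BFGS with analytic gradients, on a seeded
subsample of the training set when it is large.  The GP itself is exact (no
sparse approximations), which caps practical training sizes at a few
thousand pairs.

Value orientation: all fidelities are assumed already converted so that
HIGHER = BETTER (docking-like scores negated, IC50 expressed as pIC50);
the campaign layer performs that conversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .chemio import tanimoto_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FidelitySchedule",
    "Observation",
    "Prediction",
    "SurrogateConfig",
    "SurrogateState",
    "kernel_matrix",
    "fit_surrogate",
    "predict",
    "predict_batch",
    "pool_posterior",
    "scaled_prediction",
    "scale_prediction_arrays",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FidelitySchedule:
    """Ordered fidelity levels with dimensionless relative costs and a budget.

    Costs must be strictly increasing with level and the highest-fidelity
    cost must be 1.0 (the unit in which the per-iteration budget is stated).
    """

    levels: tuple[tuple[str, float], ...]
    budget: float

    def __post_init__(self):
        costs = [c for _, c in self.levels]
        if not costs:
            raise ValueError("schedule needs at least one fidelity level")
        if any(b <= a for a, b in zip(costs, costs[1:])):
            raise ValueError(f"fidelity costs must be strictly increasing: {costs}")
        if abs(costs[-1] - 1.0) > 1e-12:
            raise ValueError("highest-fidelity cost must be normalized to 1.0")
        if self.budget <= 0:
            raise ValueError("budget must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def costs(self) -> np.ndarray:
        return np.array([c for _, c in self.levels])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.levels)

    @property
    def highest(self) -> int:
        return len(self.levels) - 1

    @classmethod
    def default(cls, budget: float = 10.0) -> "FidelitySchedule":
        """Docking / single-point / dose-response at relative costs 0.01 / 0.2 / 1.0."""
        return cls(levels=(("low", 0.01), ("medium", 0.2), ("high", 1.0)), budget=budget)


@dataclass(frozen=True)
class Observation:
    """One measurement: molecule id, fidelity index (0 = lowest), value.

    The value is in canonical orientation (higher = better).
    """

    molecule_id: str
    fidelity: int
    value: float

    def __post_init__(self):
        if self.fidelity < 0:
            raise ValueError("fidelity index must be >= 0")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite observation value for {self.molecule_id}")


@dataclass
class Prediction:
    """Posterior mean/variance in assay units, plus acquisition-scaled fields."""

    mean: float
    variance: float
    scaled_mean: float | None = None
    scaled_variance: float | None = None


@dataclass(frozen=True)
class SurrogateConfig:
    n_restarts: int = 5
    max_iter: int = 100
    max_fit_points: int = 256
    noise_floor: float = 1e-6  # variance floor in standardized units
    rank: int = 2


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------


def kernel_matrix(
    fps_a: np.ndarray,
    fps_b: np.ndarray,
    amplitude: float,
    B: np.ndarray,
    fidelities_a: np.ndarray,
    fidelities_b: np.ndarray,
) -> np.ndarray:
    """Cross-covariance K[(x,f),(x',f')] = amplitude * B[f,f'] * T(x,x')."""
    fps_a = np.atleast_2d(np.asarray(fps_a))
    fps_b = np.atleast_2d(np.asarray(fps_b))
    fa = np.asarray(fidelities_a, dtype=int)
    fb = np.asarray(fidelities_b, dtype=int)
    if fps_a.shape[0] != fa.shape[0] or fps_b.shape[0] != fb.shape[0]:
        raise ValueError("fingerprint / fidelity count mismatch")
    T = tanimoto_matrix(fps_a, fps_b)
    return amplitude * B[np.ix_(fa, fb)] * T


# ---------------------------------------------------------------------------
# fitted state
# ---------------------------------------------------------------------------


@dataclass
class SurrogateState:
    """A fitted multi-fidelity GP, with the cached training factorization."""

    observations: list[Observation]
    ids: list[str]  # per observation
    X: np.ndarray  # (m, n_bits) training fingerprints
    f: np.ndarray  # (m,) fidelity index per observation
    amplitude: float
    B: np.ndarray  # (F, F) coregionalization matrix, PSD
    noises: np.ndarray  # (F,) noise variances, standardized units
    y_mean: np.ndarray  # (F,) per-fidelity standardization mean
    y_sd: np.ndarray  # (F,) per-fidelity standardization sd
    n_levels: int
    log_marginal_likelihood: float = float("nan")
    _y_std: np.ndarray = field(default=None, repr=False)
    _chol: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    # -- factorization ------------------------------------------------------
    def _factorize(self) -> None:
        y = np.array([o.value for o in self.observations])
        self._y_std = (y - self.y_mean[self.f]) / self.y_sd[self.f]
        K = kernel_matrix(self.X, self.X, self.amplitude, self.B, self.f, self.f)
        K[np.diag_indices_from(K)] += self.noises[self.f]
        try:
            self._chol = cholesky(K, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"training covariance singular even after noise floor "
                f"(m={len(self.f)}, min noise={self.noises.min():.2e}); "
                "check for exactly duplicated (molecule, fidelity) observations"
            ) from exc
        self._alpha = cho_solve((self._chol, True), self._y_std)

    def with_observations(
        self, extra: Sequence[Observation], fingerprints: Mapping[str, np.ndarray]
    ) -> "SurrogateState":
        """Condition on extra observations without refitting hyperparameters."""
        obs = list(self.observations) + list(extra)
        ids = self.ids + [o.molecule_id for o in extra]
        Xe = np.vstack([self.X] + [fingerprints[o.molecule_id][None, :] for o in extra])
        fe = np.concatenate([self.f, [o.fidelity for o in extra]]).astype(int)
        st = SurrogateState(
            observations=obs, ids=ids, X=Xe, f=fe,
            amplitude=self.amplitude, B=self.B.copy(), noises=self.noises.copy(),
            y_mean=self.y_mean.copy(), y_sd=self.y_sd.copy(), n_levels=self.n_levels,
            log_marginal_likelihood=self.log_marginal_likelihood,
        )
        st._factorize()
        return st

    # -- persistence --------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write a JSON manifest plus an array sidecar (``<prefix>.json/.npz``)."""
        prefix = Path(prefix)
        manifest = {
            "n_levels": self.n_levels,
            "amplitude": self.amplitude,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "ids": self.ids,
            "observations": [
                {"molecule_id": o.molecule_id, "fidelity": o.fidelity, "value": o.value}
                for o in self.observations
            ],
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
        np.savez(
            prefix.with_suffix(".npz"),
            X=self.X, f=self.f, B=self.B, noises=self.noises,
            y_mean=self.y_mean, y_sd=self.y_sd, amplitude=np.array([self.amplitude]),
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "SurrogateState":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        arrays = np.load(prefix.with_suffix(".npz"))
        st = cls(
            observations=[Observation(**o) for o in manifest["observations"]],
            ids=list(manifest["ids"]),
            X=arrays["X"], f=arrays["f"].astype(int),
            amplitude=float(arrays["amplitude"][0]),
            B=arrays["B"], noises=arrays["noises"],
            y_mean=arrays["y_mean"], y_sd=arrays["y_sd"],
            n_levels=int(manifest["n_levels"]),
            log_marginal_likelihood=float(manifest["log_marginal_likelihood"]),
        )
        st._factorize()
        return st


# ---------------------------------------------------------------------------
# marginal likelihood and fitting
# ---------------------------------------------------------------------------


def _unpack(theta: np.ndarray, n_levels: int, rank: int):
    i = 0
    log_a = theta[i]; i += 1
    L = theta[i : i + n_levels * rank].reshape(n_levels, rank); i += n_levels * rank
    log_d = theta[i : i + n_levels]; i += n_levels
    log_s = theta[i : i + n_levels]
    return np.exp(log_a), L, np.exp(log_d), np.exp(log_s)


def _nll_and_grad(theta, T, fids, y, n_levels, rank, noise_floor):
    a, L, d, s = _unpack(theta, n_levels, rank)
    s = np.maximum(s, noise_floor)
    B = L @ L.T + np.diag(d)
    m = len(y)
    Bff = B[np.ix_(fids, fids)]
    K = a * Bff * T
    K[np.diag_indices_from(K)] += s[fids]
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    alpha = cho_solve((c, low), y)
    nll = 0.5 * y @ alpha + np.sum(np.log(np.diag(c))) + 0.5 * m * np.log(2 * np.pi)
    Kinv = cho_solve((c, low), np.eye(m))
    W = Kinv - np.outer(alpha, alpha)  # grad_p = 0.5 * sum(W * dK_p)

    grad = np.zeros_like(theta)
    i = 0
    # d/d log_a : a * Bff * T
    grad[i] = 0.5 * np.sum(W * (a * Bff * T)); i += 1
    # d/d L[p,q] : dB[f_i,f_j] = 1[f_i=p] L[f_j,q] + 1[f_j=p] L[f_i,q]
    fid_onehot = np.eye(n_levels)[fids]  # (m, F)
    Lf = L[fids]  # (m, rank)
    WT = W * T * a
    for p in range(n_levels):
        mask_p = fid_onehot[:, p]  # (m,)
        for q in range(rank):
            dB = np.outer(mask_p, Lf[:, q]) + np.outer(Lf[:, q], mask_p)
            grad[i] = 0.5 * np.sum(WT * dB); i += 1
    # d/d log_d[p] : dB = d_p on (p,p) block
    for p in range(n_levels):
        mask_p = fid_onehot[:, p]
        grad[i] = 0.5 * d[p] * np.sum(WT * np.outer(mask_p, mask_p)); i += 1
    # d/d log_s[f] : s_f on diagonal entries of fidelity f
    Wdiag = np.diag(W)
    for p in range(n_levels):
        grad[i] = 0.5 * s[p] * np.sum(Wdiag[fids == p]); i += 1
    return nll, grad


def fit_surrogate(
    observations: Sequence[Observation],
    fingerprints: Mapping[str, np.ndarray],
    n_levels: int,
    config: SurrogateConfig = SurrogateConfig(),
    seed: int = 0,
) -> SurrogateState:
    """Fit kernel hyperparameters by multi-start maximum marginal likelihood.

    ``fingerprints`` maps molecule id -> binary fingerprint. When the
    training set exceeds ``config.max_fit_points`` the likelihood is
    maximized on a seeded subsample; the returned state conditions on the
    full training set with the fitted hyperparameters.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("fit_surrogate needs at least one observation")
    ids = [o.molecule_id for o in observations]
    X = np.vstack([fingerprints[i] for i in ids])
    f = np.array([o.fidelity for o in observations], dtype=int)
    if f.max() >= n_levels:
        raise ValueError("observation fidelity index out of range")
    y_raw = np.array([o.value for o in observations])

    y_mean = np.zeros(n_levels)
    y_sd = np.ones(n_levels)
    for lv in range(n_levels):
        sel = f == lv
        if sel.sum() >= 1:
            y_mean[lv] = y_raw[sel].mean()
        if sel.sum() >= 2:
            sd = y_raw[sel].std(ddof=1)
            if sd > 1e-12:
                y_sd[lv] = sd
    y = (y_raw - y_mean[f]) / y_sd[f]

    rng = np.random.default_rng(seed)
    m = len(observations)
    if m > config.max_fit_points:
        sub = np.sort(rng.choice(m, size=config.max_fit_points, replace=False))
    else:
        sub = np.arange(m)
    T_sub = tanimoto_matrix(X[sub])
    f_sub, y_sub = f[sub], y[sub]

    rank = config.rank
    n_params = 1 + n_levels * rank + 2 * n_levels
    bounds = (
        [(np.log(0.05), np.log(5.0))]
        + [(-3.0, 3.0)] * (n_levels * rank)
        + [(np.log(1e-3), np.log(3.0))] * n_levels
        + [(np.log(config.noise_floor), np.log(1.0))] * n_levels
    )

    def make_start(r: int) -> np.ndarray:
        theta = np.zeros(n_params)
        if r == 0:
            theta[0] = 0.0
            theta[1 : 1 + n_levels * rank] = np.tile([0.7, 0.1], n_levels)[: n_levels * rank]
            theta[1 + n_levels * rank : 1 + n_levels * rank + n_levels] = np.log(0.3)
            theta[-n_levels:] = np.log(0.05)
        else:
            for j, (lo, hi) in enumerate(bounds):
                theta[j] = rng.uniform(lo, hi)
        return theta

    best = None
    for r in range(max(1, config.n_restarts)):
        theta0 = make_start(r)
        res = minimize(
            _nll_and_grad, theta0, jac=True,
            args=(T_sub, f_sub, y_sub, n_levels, rank, config.noise_floor),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, L, d, s = _unpack(best.x, n_levels, rank)
    s = np.maximum(s, config.noise_floor)
    state = SurrogateState(
        observations=observations, ids=ids, X=X, f=f,
        amplitude=float(a), B=L @ L.T + np.diag(d), noises=s,
        y_mean=y_mean, y_sd=y_sd, n_levels=n_levels,
        log_marginal_likelihood=float(-best.fun),
    )
    state._factorize()
    return state


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_batch(
    state: SurrogateState, fps: np.ndarray, fidelities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance (assay units) at many (molecule, fidelity) pairs."""
    if state._chol is None:
        raise ValueError("surrogate state is not fitted")
    fps = np.atleast_2d(np.asarray(fps))
    fq = np.asarray(fidelities, dtype=int)
    Ks = kernel_matrix(fps, state.X, state.amplitude, state.B, fq, state.f)
    mean_std = Ks @ state._alpha
    V = solve_triangular(state._chol, Ks.T, lower=True)
    prior = state.amplitude * state.B[fq, fq]
    var_std = np.maximum(prior - np.sum(V * V, axis=0), 0.0)
    mean = mean_std * state.y_sd[fq] + state.y_mean[fq]
    var = var_std * state.y_sd[fq] ** 2
    return mean, var


def predict(state: SurrogateState, fp: np.ndarray, fidelity: int) -> Prediction:
    """Posterior prediction at a single (molecule, fidelity) pair."""
    mean, var = predict_batch(state, np.asarray(fp)[None, :], np.array([fidelity]))
    return Prediction(mean=float(mean[0]), variance=float(var[0]))


def pool_posterior(
    state: SurrogateState,
    mol_fps: np.ndarray,
    pair_mol_idx: np.ndarray,
    pair_fid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior (mean vector, full covariance) over a pool of pairs.

    The pool is given as unique molecule fingerprints ``mol_fps`` plus, per
    pair, an index into those molecules and a fidelity level.  Returning the
    full covariance lets the batch selector perform exact rank-1 fantasy
    updates without refactorizing the training kernel at every step.
    Outputs are in assay units.
    """
    if state._chol is None:
        raise ValueError("surrogate state is not fitted")
    mi = np.asarray(pair_mol_idx, dtype=int)
    fq = np.asarray(pair_fid, dtype=int)
    T_mol = tanimoto_matrix(mol_fps)
    K_pool = state.amplitude * state.B[np.ix_(fq, fq)] * T_mol[np.ix_(mi, mi)]
    T_cross = tanimoto_matrix(mol_fps, state.X)
    Ks = state.amplitude * state.B[np.ix_(fq, state.f)] * T_cross[mi, :]
    mean_std = Ks @ state._alpha
    V = solve_triangular(state._chol, Ks.T, lower=True)
    cov_std = K_pool - V.T @ V
    sd_q = state.y_sd[fq]
    mean = mean_std * sd_q + state.y_mean[fq]
    cov = cov_std * np.outer(sd_q, sd_q)
    return mean, cov


# ---------------------------------------------------------------------------
# acquisition-facing scaling
# ---------------------------------------------------------------------------

_DEGENERATE_LOGGED = False


def scale_prediction_arrays(
    means: np.ndarray,
    variances: np.ndarray,
    fidelities: np.ndarray,
    pool_min: np.ndarray,
    pool_max: np.ndarray,
    costs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized TVR scaling: mean min-max'd to [0,1] per fidelity over the
    candidate pool; variance divided by the squared pool range and by the
    fidelity's relative cost, so cheap assays carry inflated variance.

    A degenerate pool (max == min at some fidelity) maps every mean to 0.5
    and leaves the variance divided by cost only.
    """
    global _DEGENERATE_LOGGED
    fq = np.asarray(fidelities, dtype=int)
    rng_f = pool_max - pool_min
    degenerate = rng_f[fq] <= 0
    if degenerate.any() and not _DEGENERATE_LOGGED:
        logger.info("scaled_prediction: degenerate pool range, using scaled_mean=0.5")
        _DEGENERATE_LOGGED = True
    safe_rng = np.where(rng_f[fq] > 0, rng_f[fq], 1.0)
    scaled_mean = np.where(
        degenerate, 0.5, np.clip((means - pool_min[fq]) / safe_rng, 0.0, 1.0)
    )
    scaled_var = (variances / safe_rng**2) / costs[fq]
    return scaled_mean, np.maximum(scaled_var, 0.0)


def scaled_prediction(
    state: SurrogateState,
    pool_stats: tuple[np.ndarray, np.ndarray],
    fp: np.ndarray,
    fidelity: int,
    schedule: FidelitySchedule,
) -> Prediction:
    """Predict at one pair and attach the scaled mean/variance fields.

    ``pool_stats`` is the (per-fidelity min, per-fidelity max) of posterior
    means over the current candidate pool, recomputed each iteration.
    """
    p = predict(state, fp, fidelity)
    pool_min, pool_max = pool_stats
    sm, sv = scale_prediction_arrays(
        np.array([p.mean]), np.array([p.variance]), np.array([fidelity]),
        np.asarray(pool_min), np.asarray(pool_max), schedule.costs,
    )
    p.scaled_mean = float(sm[0])
    p.scaled_variance = float(sv[0])
    return p
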