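"""Panel graphical VAR: likelihood, estimation, structure search, fit indices.

The model decomposes multi-wave panel data into three networks:

* a within-person *temporal* network — directed lag-1 effects ``B`` of every
  node on every node one wave later;
* a within-person *contemporaneous* network — partial correlations of the
  same-wave innovations, derived from the innovation precision ``K_zeta``;
* a *between-person* network — partial correlations of the stable person
  trait means, derived from the trait precision ``K_B``.

Observation model for person ``i`` at wave ``t``::

    y_it = mu + eta_i + u_it,     eta_i ~ N(0, inv(K_B))
    u_it = B u_{i,t-1} + zeta_it, zeta_it ~ N(0, inv(K_zeta))

with ``u_i1`` drawn from the stationary VAR(1) distribution, so the stacked
``T*p`` vector is multivariate normal with block covariance
``Sigma_B + B^{s-t} Sigma_0`` (``s >= t``), where ``Sigma_0`` solves the
discrete Lyapunov equation.

Estimation follows the statsmodels Model/Results idiom: build a
:class:`PanelGVAR` from a :class:`~clpn.data.PanelDataset`, call
:meth:`PanelGVAR.fit`, and read estimates, fit indices, networks and
standard errors off the returned :class:`PanelGVARResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import PanelDataset, NodeSpec

__all__ = [
    "PGVARParameters",
    "NetworkSet",
    "FitIndices",
    "StructureMasks",
    "PanelGVAR",
    "PanelGVARResults",
    "ConvergenceError",
    "stationary_covariance",
    "implied_moments",
    "fiml_loglik",
    "fit_saturated",
    "fit_pgvar",
    "networks_from_params",
    "moment_estimate",
    "structure_search",
    "select_structure",
    "masks_at_penalty",
    "fit_indices",
]


class ConvergenceError(RuntimeError):
    """Raised when the optimizer exhausts its iteration budget.

    Carries the best parameter vector seen so far and the gradient norm so a
    caller can inspect or restart.
    """

    def __init__(self, msg, best_params=None, grad_norm=None):
        super().__init__(msg)
        self.best_params = best_params
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# parameter containers


def _check_spd(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() <= 0:
        raise ValueError(f"{name} must be positive definite (min eig {w.min():.3g})")


@dataclass
class PGVARParameters:
    """Free parameters of the panel GVAR model.

    ``B[k, j]`` is the effect of node ``j`` at wave t-1 on node ``k`` at
    wave t.  ``K_zeta`` and ``K_B`` are the within-innovation and
    between-person precision matrices (their scaled negative off-diagonals
    are the contemporaneous / between partial correlations).
    """

    mu: np.ndarray
    B: np.ndarray
    K_zeta: np.ndarray
    K_B: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.B = np.asarray(self.B, dtype=float)
        self.K_zeta = np.asarray(self.K_zeta, dtype=float)
        self.K_B = np.asarray(self.K_B, dtype=float)
        p = self.mu.size
        for M, nm in ((self.B, "B"), (self.K_zeta, "K_zeta"), (self.K_B, "K_B")):
            if M.shape != (p, p):
                raise ValueError(f"{nm} must be {p}x{p}")

    @property
    def n_nodes(self) -> int:
        return self.mu.size

    @property
    def sigma_zeta(self) -> np.ndarray:
        return np.linalg.inv(self.K_zeta)

    @property
    def sigma_B(self) -> np.ndarray:
        return np.linalg.inv(self.K_B)

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.B))))

    def validate(self) -> None:
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                f"B is non-stationary (spectral radius {self.spectral_radius():.3f} >= 1)"
            )
        _check_spd(self.K_zeta, "K_zeta")
        _check_spd(self.K_B, "K_B")


@dataclass
class NetworkSet:
    """The three estimated networks on a common node set.

    ``temporal`` holds standardized directed lag-1 coefficients
    (row = target, column = source); ``contemporaneous`` and ``between`` are
    symmetric partial-correlation matrices with zero diagonal.
    """

    temporal: np.ndarray
    contemporaneous: np.ndarray
    between: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.temporal = np.asarray(self.temporal, dtype=float)
        self.contemporaneous = np.asarray(self.contemporaneous, dtype=float)
        self.between = np.asarray(self.between, dtype=float)
        p = self.temporal.shape[0]
        if not self.node_names:
            self.node_names = [f"x{j + 1}" for j in range(p)]
        for M, nm in (
            (self.contemporaneous, "contemporaneous"),
            (self.between, "between"),
        ):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{nm} network must be exactly symmetric")
            if np.abs(np.diag(M)).max() > 1e-12:
                raise ValueError(f"{nm} network must have zero diagonal")
            off = M[~np.eye(p, dtype=bool)]
            if off.size and np.abs(off).max() >= 1.0:
                raise ValueError(f"{nm} partial correlations must lie in (-1, 1)")

    def matrix(self, which: str) -> np.ndarray:
        return getattr(self, which)


@dataclass
class FitIndices:
    """SEM-style global fit indices of the fitted model vs. saturated and
    independence baselines."""

    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90_low: float
    rmsea_ci90_high: float
    log_likelihood: float


@dataclass
class StructureMasks:
    """Boolean free-parameter masks (True = edge free, False = fixed to 0).

    Diagonals (autoregressions, precision diagonals) are always free; the
    symmetric masks apply to off-diagonal precision entries.
    """

    b_mask: np.ndarray
    kzeta_mask: np.ndarray
    kb_mask: np.ndarray

    @classmethod
    def dense(cls, p: int) -> "StructureMasks":
        full = np.ones((p, p), dtype=bool)
        return cls(full.copy(), full.copy(), full.copy())

    @classmethod
    def empty(cls, p: int) -> "StructureMasks":
        eye = np.eye(p, dtype=bool)
        return cls(eye.copy(), eye.copy(), eye.copy())

    def __post_init__(self):
        p = self.b_mask.shape[0]
        eye = np.eye(p, dtype=bool)
        self.b_mask = np.asarray(self.b_mask, dtype=bool) | eye
        for nm in ("kzeta_mask", "kb_mask"):
            m = np.asarray(getattr(self, nm), dtype=bool)
            m = (m | m.T) | eye  # symmetric, diagonal always free
            setattr(self, nm, m)

    @property
    def n_nodes(self) -> int:
        return self.b_mask.shape[0]


# ---------------------------------------------------------------------------
# implied moment structure


def stationary_covariance(B: np.ndarray, Sigma_zeta: np.ndarray) -> np.ndarray:
    """Stationary covariance Sigma_0 of the VAR(1) deviations.

    Solves the discrete Lyapunov equation ``Sigma_0 = B Sigma_0 B' +
    Sigma_zeta``.
    """
    B = np.asarray(B, dtype=float)
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 1.0:
        raise ValueError(f"non-stationary B: spectral radius {rho:.4f} >= 1")
    S0 = linalg.solve_discrete_lyapunov(B, np.asarray(Sigma_zeta, dtype=float))
    return 0.5 * (S0 + S0.T)


def implied_moments(
    params: PGVARParameters, n_waves: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the stacked ``T*p`` observation vector.

    Block ``(s, t)`` of the covariance is ``Sigma_B + B^{s-t} Sigma_0`` for
    ``s >= t`` (transposed below the diagonal).
    """
    if n_waves < 2:
        raise ValueError("n_waves must be >= 2")
    p = params.n_nodes
    Sigma_zeta = params.sigma_zeta
    Sigma_B = params.sigma_B
    S0 = stationary_covariance(params.B, Sigma_zeta)
    # lag blocks B^k Sigma_0 for k = 0..T-1
    lag = [S0]
    for _ in range(n_waves - 1):
        lag.append(params.B @ lag[-1])
    cov = np.empty((n_waves * p, n_waves * p))
    for s in range(n_waves):
        for t in range(n_waves):
            blk = Sigma_B + (lag[s - t] if s >= t else lag[t - s].T)
            cov[s * p : (s + 1) * p, t * p : (t + 1) * p] = blk
    cov = 0.5 * (cov + cov.T)
    mean = np.tile(params.mu, n_waves)
    return mean, cov


# ---------------------------------------------------------------------------
# likelihoods


def _pattern_groups(mask2d: np.ndarray) -> dict[bytes, np.ndarray]:
    """Group person row indices by identical missingness pattern."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(mask2d):
        groups.setdefault(row.tobytes(), []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


_LOG2PI = float(np.log(2.0 * np.pi))


def fiml_loglik(params: PGVARParameters, data: PanelDataset) -> float:
    """Full-information log-likelihood of the panel under the model.

    Sums, over persons, the multivariate-normal log density of each person's
    observed sub-vector under the implied moments restricted to the observed
    coordinates; missing coordinates are marginalized out exactly.
    """
    mean, cov = implied_moments(params, data.n_waves)
    return _fiml_loglik_moments(mean, cov, data)


def _fiml_loglik_moments(mean, cov, data: PanelDataset) -> float:
    vals, mask = data.stacked()
    ll = 0.0
    for key, idx in _pattern_groups(mask).items():
        obs = np.frombuffer(key, dtype=bool)
        if not obs.any():
            continue
        sub = cov[np.ix_(obs, obs)]
        try:
            cf = linalg.cho_factor(sub, lower=True)
        except linalg.LinAlgError:
            raise linalg.LinAlgError(
                f"singular restricted covariance for person index {int(idx[0])}"
            )
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        dev = vals[np.ix_(idx, np.flatnonzero(obs))] - mean[obs]
        solved = linalg.cho_solve(cf, dev.T)
        quad = np.sum(dev.T * solved)
        k = int(obs.sum())
        ll += -0.5 * (idx.size * (k * _LOG2PI + logdet) + quad)
    return float(ll)


def _saturated_loglik(mean, cov, data: PanelDataset) -> float:
    return _fiml_loglik_moments(mean, cov, data)


def fit_saturated(
    data: PanelDataset, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, float]:
    """Unstructured FIML mean and covariance of the stacked vector.

    Complete data give the closed-form sample mean and 1/n covariance;
    otherwise EM is run to convergence.  Returns ``(mean, cov, loglik)``.
    """
    vals, mask = data.stacked()
    n, k = vals.shape
    if n < k and mask.all():
        warnings.warn(
            "fewer persons than stacked coordinates: saturated covariance is "
            "rank-deficient",
            UserWarning,
        )
    if mask.all():
        mean = vals.mean(axis=0)
        dev = vals - mean
        cov = dev.T @ dev / n
        try:
            linalg.cho_factor(cov)
        except linalg.LinAlgError:
            raise linalg.LinAlgError(
                "saturated covariance is not invertible (fewer persons than "
                "stacked coordinates?)"
            )
        ll = _fiml_loglik_moments(mean, cov, data)
        return mean, cov, ll

    # EM for the MVN with arbitrary missingness, persons grouped by pattern
    x = np.where(mask, vals, 0.0)
    mean = np.array(
        [vals[mask[:, c], c].mean() if mask[:, c].any() else 0.0 for c in range(k)]
    )
    var = np.array(
        [
            vals[mask[:, c], c].var() if mask[:, c].sum() > 1 else 1.0
            for c in range(k)
        ]
    )
    cov = np.diag(np.maximum(var, 1e-3))
    groups = _pattern_groups(mask)
    ll_prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(k)
        sum_xx = np.zeros((k, k))
        for key, idx in groups.items():
            obs = np.frombuffer(key, dtype=bool)
            mis = ~obs
            o = np.flatnonzero(obs)
            m = np.flatnonzero(mis)
            xo = vals[np.ix_(idx, o)]
            if m.size == 0:
                sum_x += xo.sum(axis=0)
                sum_xx[np.ix_(o, o)] += xo.T @ xo
                continue
            Soo = cov[np.ix_(o, o)]
            Smo = cov[np.ix_(m, o)]
            cf = linalg.cho_factor(Soo, lower=True)
            gain = linalg.cho_solve(cf, Smo.T).T  # Smo Soo^-1
            xm = mean[m] + (xo - mean[o]) @ gain.T
            cond = cov[np.ix_(m, m)] - gain @ Smo.T
            full = np.zeros((idx.size, k))
            full[:, o] = xo
            full[:, m] = xm
            sum_x += full.sum(axis=0)
            sum_xx += full.T @ full
            sum_xx[np.ix_(m, m)] += idx.size * cond
        mean = sum_x / n
        cov = sum_xx / n - np.outer(mean, mean)
        cov = 0.5 * (cov + cov.T)
        ll = _fiml_loglik_moments(mean, cov, data)
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll
    try:
        linalg.cho_factor(cov)
    except linalg.LinAlgError:
        raise linalg.LinAlgError("saturated covariance is not invertible")
    return mean, cov, ll


def _independence_loglik(data: PanelDataset) -> tuple[float, int]:
    """FIML loglik and free-parameter count of the independence baseline
    (diagonal covariance, free means)."""
    vals, mask = data.stacked()
    k = vals.shape[1]
    ll = 0.0
    for c in range(k):
        y = vals[mask[:, c], c]
        if y.size == 0:
            continue
        v = max(y.var(), 1e-12)
        ll += -0.5 * y.size * (_LOG2PI + np.log(v) + 1.0)
    return float(ll), 2 * k


# ---------------------------------------------------------------------------
# moment (method-of-moments) estimator — consistent, closed form


def _nearest_pd(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    lo = floor * max(abs(w).max(), 1e-12)
    return (V * np.maximum(w, lo)) @ V.T


def moment_estimate(
    mean: np.ndarray, cov: np.ndarray, n_waves: int, n_nodes: int
) -> PGVARParameters:
    """Closed-form method-of-moments estimate from saturated stacked moments.

    Averages same-lag wave blocks ``A_k`` of the stacked covariance and
    solves the model's moment equations ``A_k = Sigma_B + B^k Sigma_0``:
    ``B = (A1 - A2)(A0 - A1)^-1``, ``Sigma_0 = (I - B)^-1 (A0 - A1)``,
    ``Sigma_B = A0 - Sigma_0``.  No person-mean centering is involved, so
    the estimator avoids small-T centering bias; it serves as the structure
    -search input, the ML starting value, and the fast bootstrap refit.
    """
    T, p = n_waves, n_nodes
    blocks = lambda s, t: cov[s * p : (s + 1) * p, t * p : (t + 1) * p]
    A = []
    for lag in range(T):
        stack = [blocks(s, s - lag) for s in range(lag, T)]
        A.append(np.mean(stack, axis=0))
    A[0] = 0.5 * (A[0] + A[0].T)
    mu = mean.reshape(T, p).mean(axis=0)
    if T >= 3:
        D0, D1 = A[0] - A[1], A[1] - A[2]
        B = np.linalg.solve(D0.T, D1.T).T  # (A1-A2)(A0-A1)^-1
        rho = np.max(np.abs(np.linalg.eigvals(B)))
        if rho >= 0.98:  # shrink toward stationarity for noisy draws
            B = B * (0.95 / rho)
        S0 = np.linalg.solve(np.eye(p) - B, D0)
        S0 = _nearest_pd(S0)
    else:
        # T = 2 cannot separate lag decay from trait level by block
        # averaging; fall back to an even within/lag split
        B = 0.5 * np.linalg.solve(A[0].T, A[1].T).T
        rho = np.max(np.abs(np.linalg.eigvals(B)))
        if rho >= 0.98:
            B = B * (0.95 / rho)
        S0 = _nearest_pd(0.5 * A[0])
    # eigenvalue floor at 2% of the largest keeps noisy small-sample
    # estimates invertible and the implied precision well conditioned
    Sigma_zeta = _nearest_pd(S0 - B @ S0 @ B.T, floor=0.02)
    Sigma_B = _nearest_pd(A[0] - S0, floor=0.02)
    return PGVARParameters(
        mu=mu,
        B=B,
        K_zeta=np.linalg.inv(Sigma_zeta),
        K_B=np.linalg.inv(Sigma_B),
    )


# ---------------------------------------------------------------------------
# networks


def networks_from_params(
    params: PGVARParameters, temporal_standardization: str = "stationary"
) -> NetworkSet:
    """Derive the three networks from model parameters.

    Contemporaneous / between edges are partial correlations
    ``-K[j,k] / sqrt(K[jj] K[kk])``.  Temporal edges are lag-1 coefficients
    standardized by stationary within-person SDs,
    ``B[k,j] sqrt(Sigma0[jj] / Sigma0[kk])`` (default), or by the residual
    SD (``temporal_standardization="residual"``), the partial-directed-
    correlation flavour.
    """

    def _partial(K):
        d = np.sqrt(np.diag(K))
        R = -K / np.outer(d, d)
        np.fill_diagonal(R, 0.0)
        return 0.5 * (R + R.T)

    S0 = stationary_covariance(params.B, params.sigma_zeta)
    s = np.sqrt(np.diag(S0))
    if temporal_standardization == "stationary":
        temporal = params.B * np.outer(1.0 / s, s)
    elif temporal_standardization == "residual":
        r = np.sqrt(np.diag(params.sigma_zeta))
        temporal = params.B * np.outer(1.0 / r, s)
    else:
        raise ValueError(
            "temporal_standardization must be 'stationary' or 'residual'"
        )
    return NetworkSet(
        temporal=temporal,
        contemporaneous=_partial(params.K_zeta),
        between=_partial(params.K_B),
    )


# ---------------------------------------------------------------------------
# fit indices


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    if df <= 0 or n <= 0:
        return 0.0, 0.0
    a = (1.0 - level) / 2.0

    def _find(prob):
        # noncentrality lambda with P(X2_{df,lam} <= chi2) = prob
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
        if f(0.0) < 0.0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0.0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0.0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = _find(1.0 - a)  # cdf = 0.95 -> lower bound
    lam_hi = _find(a)  # cdf = 0.05 -> upper bound
    lo = np.sqrt(max(lam_lo, 0.0) / (df * n))
    hi = np.sqrt(max(lam_hi, 0.0) / (df * n))
    return float(min(lo, hi)), float(max(lo, hi))


def fit_indices(
    model_loglik: float,
    model_df: int,
    saturated_loglik: float,
    baseline_loglik: float,
    baseline_df: int,
    n: int,
) -> FitIndices:
    """CFI, TLI and RMSEA from model, saturated and independence logliks."""
    chi_m = max(2.0 * (saturated_loglik - model_loglik), 0.0)
    chi_b = max(2.0 * (saturated_loglik - baseline_loglik), 0.0)
    num = max(chi_m - model_df, 0.0)
    den = max(chi_b - baseline_df, chi_m - model_df, 0.0)
    if den <= 0.0:
        cfi = 1.0
    else:
        cfi = 1.0 - num / den
    if chi_b <= baseline_df:
        warnings.warn("baseline chi-square <= its df; CFI clamped", UserWarning)
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if baseline_df > 0 and model_df > 0 and chi_b / baseline_df != 1.0:
        tli = ((chi_b / baseline_df) - (chi_m / model_df)) / (
            (chi_b / baseline_df) - 1.0
        )
    else:
        tli = 1.0
    if model_df > 0:
        rmsea = float(np.sqrt(max(chi_m - model_df, 0.0) / (model_df * n)))
        lo, hi = _rmsea_ci(chi_m, model_df, n)
    else:
        rmsea, lo, hi = 0.0, 0.0, 0.0
    return FitIndices(
        chi_square=float(chi_m),
        df=int(model_df),
        cfi=cfi,
        tli=float(tli),
        rmsea=rmsea,
        rmsea_ci90_low=lo,
        rmsea_ci90_high=hi,
        log_likelihood=float(model_loglik),
    )


# ---------------------------------------------------------------------------
# parameter vector <-> structured parameters


class _ParamMap:
    """Maps between the flat optimizer vector and PGVARParameters under a
    structure mask.  Precision diagonals are log-parameterized; off-diagonals
    enter directly."""

    def __init__(self, p: int, masks: StructureMasks):
        self.p = p
        self.masks = masks
        self.b_idx = np.argwhere(masks.b_mask)  # (k, j) pairs
        tril = np.tril(np.ones((p, p), dtype=bool), k=-1)
        self.kz_idx = np.argwhere(masks.kzeta_mask & tril)
        self.kb_idx = np.argwhere(masks.kb_mask & tril)
        self.n_free = (
            p + len(self.b_idx) + 2 * p + len(self.kz_idx) + len(self.kb_idx)
        )

    def pack(self, params: PGVARParameters) -> np.ndarray:
        p = self.p
        out = [params.mu]
        out.append(params.B[self.b_idx[:, 0], self.b_idx[:, 1]])
        for K, idx in ((params.K_zeta, self.kz_idx), (params.K_B, self.kb_idx)):
            out.append(np.log(np.diag(K)))
            out.append(K[idx[:, 0], idx[:, 1]] if len(idx) else np.empty(0))
        return np.concatenate(out)

    def unpack(self, theta: np.ndarray) -> PGVARParameters:
        p = self.p
        pos = 0
        mu = theta[pos : pos + p]
        pos += p
        B = np.zeros((p, p))
        nb = len(self.b_idx)
        B[self.b_idx[:, 0], self.b_idx[:, 1]] = theta[pos : pos + nb]
        pos += nb
        Ks = []
        for idx in (self.kz_idx, self.kb_idx):
            K = np.diag(np.exp(theta[pos : pos + p]))
            pos += p
            m = len(idx)
            if m:
                K[idx[:, 0], idx[:, 1]] = theta[pos : pos + m]
                K[idx[:, 1], idx[:, 0]] = theta[pos : pos + m]
            pos += m
            Ks.append(K)
        return PGVARParameters(mu=mu, B=B, K_zeta=Ks[0], K_B=Ks[1])

    def component_labels(self) -> list[tuple[str, int, int]]:
        """(component, row, col) per flat-parameter position."""
        labels = [("mu", j, j) for j in range(self.p)]
        labels += [("B", int(k), int(j)) for k, j in self.b_idx]
        for comp, idx in (("K_zeta", self.kz_idx), ("K_B", self.kb_idx)):
            labels += [(comp + "_logdiag", j, j) for j in range(self.p)]
            labels += [(comp, int(i), int(j)) for i, j in idx]
        return labels


# ---------------------------------------------------------------------------
# the Model / Results classes


class PanelGVAR:
    """Panel graphical VAR model for a :class:`~clpn.data.PanelDataset`.

    Parameters
    ----------
    data : PanelDataset
        Rescaled panel data (>= 2 waves; >= 3 recommended so lag-1 dynamics
        and trait variance separate cleanly).
    structure : StructureMasks, optional
        Free-edge masks; dense (unpruned) by default.

    Examples
    --------
    >>> model = PanelGVAR(dataset)
    >>> res = model.fit()
    >>> res.networks.temporal.shape
    (p, p)
    """

    def __init__(self, data: PanelDataset, structure: StructureMasks | None = None):
        self.data = data
        p = data.n_nodes
        self.structure = structure if structure is not None else StructureMasks.dense(p)
        if self.structure.n_nodes != p:
            raise ValueError("structure mask size does not match data")
        self._map = _ParamMap(p, self.structure)
        self._saturated: tuple[np.ndarray, np.ndarray, float] | None = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        person_col: str = "person",
        wave_col: str = "wave",
        nodes: list[NodeSpec] | None = None,
        structure: StructureMasks | None = None,
    ) -> "PanelGVAR":
        """Build the model from a long-format DataFrame."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        from .data import read_panel

        data = read_panel(
            buf, layout="long", node_specs=nodes,
            person_col=person_col, wave_col=wave_col,
        )
        return cls(data, structure=structure)

    # -- pieces ---------------------------------------------------------

    def saturated(self):
        if self._saturated is None:
            self._saturated = fit_saturated(self.data)
        return self._saturated

    def start_params(self) -> PGVARParameters:
        mean, cov, _ = self.saturated()
        est = moment_estimate(mean, cov, self.data.n_waves, self.data.n_nodes)
        return self._project(est)

    def _project(self, params: PGVARParameters) -> PGVARParameters:
        """Zero out masked entries, keeping precisions PD."""
        B = np.where(self.structure.b_mask, params.B, 0.0)
        Kz = _nearest_pd(np.where(self.structure.kzeta_mask, params.K_zeta, 0.0))
        Kb = _nearest_pd(np.where(self.structure.kb_mask, params.K_B, 0.0))
        return PGVARParameters(mu=params.mu, B=B, K_zeta=Kz, K_B=Kb)

    def loglik(self, params: PGVARParameters) -> float:
        return fiml_loglik(params, self.data)

    def _objective_moments(self, mean_s, cov_s, n):
        T, p = self.data.n_waves, self.data.n_nodes
        pm = self._map
        big = 1e12

        def f(theta):
            params = pm.unpack(theta)
            try:
                rho = np.max(np.abs(np.linalg.eigvals(params.B)))
                if rho >= 0.999:
                    return big * (1.0 + rho)
                m, S = implied_moments(params, T)
                cf = linalg.cho_factor(S, lower=True)
            except (linalg.LinAlgError, ValueError):
                return big
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            d = mean_s - m
            tr = np.sum(linalg.cho_solve(cf, cov_s) * np.eye(len(m)))
            quad = d @ linalg.cho_solve(cf, d)
            val = 0.5 * n * (logdet + tr + quad)
            if not np.isfinite(val):
                return big
            return val

        return f

    def _objective_direct(self):
        pm = self._map
        big = 1e12

        def f(theta):
            params = pm.unpack(theta)
            try:
                rho = np.max(np.abs(np.linalg.eigvals(params.B)))
                if rho >= 0.999:
                    return big * (1.0 + rho)
                return -fiml_loglik(params, self.data)
            except (linalg.LinAlgError, ValueError):
                return big

        return f

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        start: PGVARParameters | None = None,
        compute_se: str | bool = "auto",
        maxiter: int = 2000,
        gtol: float = 1e-5,
        ftol: float = 1e-9,
        temporal_standardization: str = "stationary",
    ) -> "PanelGVARResults":
        """Maximize the full-information likelihood.

        ``method="twostage"`` fits the structured model to the saturated
        FIML moments (exact ML for complete data); ``method="direct"``
        maximizes the per-person FIML likelihood itself (slower, exact under
        missingness); ``"auto"`` picks twostage.  Standard errors come from
        a finite-difference observed-information matrix when ``compute_se``
        is true (or "auto" with a modest parameter count).
        """
        if method == "auto":
            method = "twostage"
        mean_s, cov_s, ll_sat = self.saturated()
        if start is None:
            start = self.start_params()
        theta0 = self._map.pack(start)
        if method == "twostage":
            obj = self._objective_moments(mean_s, cov_s, self.data.n_persons)
        elif method == "direct":
            obj = self._objective_direct()
        else:
            raise ValueError(f"unknown method {method!r}")
        res = optimize.minimize(
            obj,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
        )
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not res.success and res.nit >= maxiter:
            raise ConvergenceError(
                f"optimizer hit the {maxiter}-iteration budget "
                f"(gradient norm {grad_norm:.3g})",
                best_params=self._map.unpack(res.x),
                grad_norm=grad_norm,
            )
        params = self._map.unpack(res.x)
        ll = self.loglik(params)
        ll_base, q_base = _independence_loglik(self.data)
        T, p = self.data.n_waves, self.data.n_nodes
        n_moments = T * p + T * p * (T * p + 1) // 2
        df_m = n_moments - self._map.n_free
        df_b = n_moments - q_base
        fi = fit_indices(ll, df_m, ll_sat, ll_base, df_b, self.data.n_persons)
        nets = networks_from_params(params, temporal_standardization)

        cov_theta = None
        se_warn = False
        want_se = compute_se is True or (
            compute_se == "auto" and self._map.n_free <= 150
        )
        if want_se:
            H = _numeric_hessian(obj, res.x)
            try:
                cov_theta = np.linalg.inv(H)
                if np.any(np.diag(cov_theta) <= 0):
                    se_warn = True
            except np.linalg.LinAlgError:
                se_warn = True
            if se_warn:
                warnings.warn(
                    "observed information not positive definite; standard "
                    "errors are unreliable",
                    UserWarning,
                )

        return PanelGVARResults(
            model=self,
            params=params,
            theta=res.x,
            fit_indices=fi,
            networks=nets,
            log_likelihood=ll,
            saturated_loglik=ll_sat,
            cov_theta=cov_theta,
            se_flagged=se_warn,
            converged=bool(res.success),
            n_iter=int(res.nit),
            method=method,
        )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Forward-difference Hessian, ~n(n+3)/2 function evaluations."""
    n = x.size
    h = eps * np.maximum(np.abs(x), 1.0)
    f0 = f(x)
    fi = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fi[i] = f(x + e)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            e = np.zeros(n)
            e[i] += h[i]
            e[j] += h[j]
            fij = f(x + e)
            H[i, j] = H[j, i] = (fij - fi[i] - fi[j] + f0) / (h[i] * h[j])
    return H


@dataclass
class PanelGVARResults:
    """Fitted panel GVAR: estimates, networks, fit indices, uncertainty."""

    model: PanelGVAR
    params: PGVARParameters
    theta: np.ndarray
    fit_indices: FitIndices
    networks: NetworkSet
    log_likelihood: float
    saturated_loglik: float
    cov_theta: np.ndarray | None = None
    se_flagged: bool = False
    converged: bool = True
    n_iter: int = 0
    method: str = "twostage"

    # -- uncertainty ----------------------------------------------------

    def _theta_se(self) -> np.ndarray | None:
        if self.cov_theta is None:
            return None
        d = np.diag(self.cov_theta)
        return np.sqrt(np.maximum(d, 0.0))

    def edge_pvalues(self) -> dict[tuple[str, int, int], float]:
        """Wald p-values for every free edge, keyed by
        ``(network, row, col)``; temporal keys are (target, source),
        undirected keys have row < col."""
        se = self._theta_se()
        if se is None:
            raise ValueError(
                "no parameter covariance available; refit with compute_se=True "
                "or use bootstrap p-values"
            )
        labels = self.model._map.component_labels()
        out: dict[tuple[str, int, int], float] = {}
        for pos, (comp, i, j) in enumerate(labels):
            if comp == "B":
                key = ("temporal", i, j)
            elif comp == "K_zeta":
                key = ("contemporaneous", min(i, j), max(i, j))
            elif comp == "K_B":
                key = ("between", min(i, j), max(i, j))
            else:
                continue
            z = self.theta[pos] / se[pos] if se[pos] > 0 else np.inf
            out[key] = float(2.0 * stats.norm.sf(abs(z)))
        return out

    def bootstrap(self, n_reps: int = 1000, seed: int = 0, **kwargs):
        """Case bootstrap of the fitted model; see
        :func:`clpn.stability.bootstrap`."""
        from .stability import bootstrap as _boot

        return _boot(self.model.data, n_reps=n_reps, seed=seed, point_fit=self, **kwargs)

    # -- presentation ---------------------------------------------------

    def network_frame(self) -> pd.DataFrame:
        """All edges of the three networks as a tidy DataFrame."""
        names = self.model.data.node_names
        p = len(names)
        rows = []
        for k in range(p):
            for j in range(p):
                rows.append(
                    {
                        "network": "temporal",
                        "source": names[j],
                        "target": names[k],
                        "weight": self.networks.temporal[k, j],
                    }
                )
        for which in ("contemporaneous", "between"):
            M = self.networks.matrix(which)
            for i in range(p):
                for j in range(i + 1, p):
                    rows.append(
                        {
                            "network": which,
                            "source": names[i],
                            "target": names[j],
                            "weight": M[i, j],
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        fi = self.fit_indices
        d = self.model.data
        lines = [
            "Panel GVAR results",
            "==================",
            f"persons: {d.n_persons}   waves: {d.n_waves}   nodes: {d.n_nodes}",
            f"method: {self.method}   converged: {self.converged} "
            f"({self.n_iter} iterations)",
            f"log-likelihood: {self.log_likelihood:.3f}   "
            f"saturated: {self.saturated_loglik:.3f}",
            f"chi2({fi.df}) = {fi.chi_square:.3f}   CFI = {fi.cfi:.3f}   "
            f"TLI = {fi.tli:.3f}",
            f"RMSEA = {fi.rmsea:.4f}  90% CI [{fi.rmsea_ci90_low:.4f}, "
            f"{fi.rmsea_ci90_high:.4f}]",
            "",
            "Largest standardized edges per network:",
        ]
        frame = self.network_frame()
        for which in ("temporal", "contemporaneous", "between"):
            sub = frame[frame.network == which]
            sub = sub.reindex(sub.weight.abs().sort_values(ascending=False).index)
            top = sub.head(5)
            lines.append(f"  {which}:")
            for _, r in top.iterrows():
                arrow = "->" if which == "temporal" else "--"
                lines.append(
                    f"    {r.source} {arrow} {r.target}: {r.weight:+.3f}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# structure search (sparse-to-dense penalty path, EBIC selection, refit)


def _glasso_pattern(R: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero pattern and precision from the graphical lasso at penalty alpha."""
    from sklearn.covariance import graphical_lasso
    from sklearn.exceptions import ConvergenceWarning

    p = R.shape[0]
    if alpha < 1e-10:
        K = np.linalg.inv(_nearest_pd(R))
        return np.ones((p, p), dtype=bool), K
    try:
        with warnings.catch_warnings():
            # a loose dual gap is irrelevant for the zero pattern
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, K = graphical_lasso(R, alpha=alpha, max_iter=200)
    except FloatingPointError:
        return np.eye(p, dtype=bool), np.diag(1.0 / np.diag(R))
    scale = np.abs(np.diag(K)).max()
    mask = np.abs(K) > 1e-8 * scale
    np.fill_diagonal(mask, True)
    return mask | mask.T, K


def _corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def masks_at_penalty(
    est: PGVARParameters, penalty: float
) -> StructureMasks:
    """Structure masks implied by one penalty level.

    Glasso zero patterns for the two precision networks (on the correlation
    scale) plus a matched threshold on standardized lag-1 coefficients.
    """
    Rz = _corr(_nearest_pd(est.sigma_zeta))
    Rb = _corr(_nearest_pd(est.sigma_B))
    kz_mask, _ = _glasso_pattern(Rz, penalty)
    kb_mask, _ = _glasso_pattern(Rb, penalty)
    W = networks_from_params(est).temporal
    b_mask = np.abs(W) >= penalty
    np.fill_diagonal(b_mask, True)
    return StructureMasks(b_mask=b_mask, kzeta_mask=kz_mask, kb_mask=kb_mask)


def _precision_ebic(K, mask, R, n_eff, p, gamma):
    Km = np.where(mask, K, 0.0)
    Km = _nearest_pd(Km, floor=1e-8)
    sign, logdet = np.linalg.slogdet(Km)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n_eff * (logdet - np.sum(R * Km))
    E = int(np.triu(mask, k=1).sum())
    return -2.0 * ll + E * np.log(n_eff) + 4.0 * gamma * E * np.log(p)


def _restricted_temporal(b_mask, S0, C1):
    """Masked lag-1 coefficients and innovation covariance from moments.

    Rows of ``B`` are re-solved as restricted regressions on the retained
    predictors; the innovation covariance is the residual covariance of
    those projections.  ``C1[k, :] = cov(u_t[k], u_{t-1})``.
    """
    p = S0.shape[0]
    Br = np.zeros((p, p))
    for k in range(p):
        s = np.flatnonzero(b_mask[k])
        Br[k, s] = np.linalg.solve(S0[np.ix_(s, s)], C1[k, s])
    Vr = S0 - Br @ C1.T - C1 @ Br.T + Br @ S0 @ Br.T
    return Br, _nearest_pd(0.5 * (Vr + Vr.T), floor=1e-6)


def _temporal_ebic(b_mask, est, S0, C1, n_waves, sample_cov, logdet_s, n, p, gamma):
    """EBIC of a candidate lag-1 structure from the stacked observed moments.

    The deviance is the maximum-likelihood discrepancy between the stacked
    T*p sample covariance and the covariance implied by the masked model
    (restricted rows re-solved from moments, other components held at the
    dense estimate).  Scoring the observed stacked covariance — rather than
    a pseudo-likelihood that pretends the latent within-person deviations
    are directly observed — keeps the per-edge deviance on the chi-square
    scale, so the ``log n`` penalty is calibrated.
    """
    Br, Vr = _restricted_temporal(b_mask, S0, C1)
    try:
        params = PGVARParameters(
            mu=est.mu, B=Br, K_zeta=np.linalg.inv(Vr), K_B=est.K_B
        )
        _, sigma = implied_moments(params, n_waves)
    except (ValueError, np.linalg.LinAlgError):
        return np.inf
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    tp = n_waves * p
    f_ml = logdet - logdet_s + np.trace(np.linalg.solve(sigma, sample_cov)) - tp
    npar = int(b_mask.sum() - p)  # autoregressions always free
    return n * f_ml + npar * np.log(n) + 4.0 * gamma * npar * np.log(p)


def _penalty_path(offmax: float, n_models: int) -> np.ndarray:
    """Log-spaced penalties, bracketed so the empty and dense candidates are
    always on the path (the top level sits just above the largest edge)."""
    top = max(offmax, 1e-3) * (1.0 + 1e-6)
    lams = np.geomspace(top, top / 100.0, max(n_models - 1, 1))
    return np.append(lams, 0.0)


def select_structure(
    est: PGVARParameters,
    n_persons: int,
    n_waves: int,
    n_models: int = 100,
    gamma: float = 0.5,
    sample_cov: np.ndarray | None = None,
) -> StructureMasks:
    """EBIC-selected structure masks from a parameter estimate.

    Each network walks its own ``n_models`` log-spaced penalty levels from
    empty to dense — the graphical lasso for the two precision networks, a
    matched threshold on standardized lag-1 coefficients for the temporal
    network — and independently keeps the candidate minimizing its EBIC
    (``gamma`` is the EBIC hyper-parameter).  The temporal EBIC is scored
    against the stacked T*p sample covariance (``sample_cov``; when omitted,
    the covariance implied by the dense estimate stands in, turning the
    deviance into a likelihood ratio against the dense model).
    """
    p = est.n_nodes
    n = n_persons
    n_within = n * (n_waves - 1)

    Rz = _corr(_nearest_pd(est.sigma_zeta))
    Rb = _corr(_nearest_pd(est.sigma_B))
    S0 = stationary_covariance(est.B, est.sigma_zeta)
    C1 = est.B @ S0  # rows: cov(u_t, u_{t-1})
    W = networks_from_params(est).temporal
    if sample_cov is None:
        _, sample_cov = implied_moments(est, n_waves)
    sign_s, logdet_s = np.linalg.slogdet(sample_cov)
    if sign_s <= 0:
        sample_cov = _nearest_pd(sample_cov)
        _, logdet_s = np.linalg.slogdet(sample_cov)

    best_kz: tuple[float, np.ndarray | None] = (np.inf, None)
    best_kb: tuple[float, np.ndarray | None] = (np.inf, None)
    best_b: tuple[float, np.ndarray | None] = (np.inf, None)
    for lam in _penalty_path(np.abs(Rz - np.eye(p)).max(), n_models):
        kz_mask, Kz = _glasso_pattern(Rz, lam)
        e = _precision_ebic(Kz, kz_mask, Rz, n_within, p, gamma)
        if e < best_kz[0]:
            best_kz = (e, kz_mask)
    for lam in _penalty_path(np.abs(Rb - np.eye(p)).max(), n_models):
        kb_mask, Kb = _glasso_pattern(Rb, lam)
        e = _precision_ebic(Kb, kb_mask, Rb, n, p, gamma)
        if e < best_kb[0]:
            best_kb = (e, kb_mask)
    for lam in _penalty_path(np.abs(W - np.diag(np.diag(W))).max(), n_models):
        b_mask = np.abs(W) >= lam
        np.fill_diagonal(b_mask, True)
        e = _temporal_ebic(
            b_mask, est, S0, C1, n_waves, sample_cov, logdet_s, n, p, gamma
        )
        if e < best_b[0]:
            best_b = (e, b_mask)
    if best_kz[1] is None or best_kb[1] is None or best_b[1] is None:
        warnings.warn("structure search selected the empty model", UserWarning)
        masks = StructureMasks.empty(p)
    else:
        masks = StructureMasks(best_b[1], best_kz[1], best_kb[1])
    n_cross = (
        int(masks.b_mask.sum() - p)
        + int(np.triu(masks.kzeta_mask, 1).sum())
        + int(np.triu(masks.kb_mask, 1).sum())
    )
    if n_cross == 0:
        warnings.warn(
            "selected structure has no cross edges (intercept-only network)",
            UserWarning,
        )
    return masks


def structure_search(
    data: PanelDataset,
    n_models: int = 100,
    gamma: float = 0.5,
    refit: bool = True,
    **fit_kwargs,
) -> tuple[StructureMasks, "PanelGVARResults | None"]:
    """Sparse-to-dense structure selection with EBIC, then unpenalized refit.

    Builds ``n_models`` penalty levels per network — the graphical lasso for
    the two precision networks, a matched threshold for the temporal
    coefficients — scores each candidate structure by EBIC (``gamma=0.5``),
    and refits the winning structure *without* penalty so the reported edges
    are non-regularized estimates.
    """
    model = PanelGVAR(data)
    mean_s, cov_s, _ = model.saturated()
    T, p = data.n_waves, data.n_nodes
    est = moment_estimate(mean_s, cov_s, T, p)
    masks = select_structure(
        est, data.n_persons, T, n_models=n_models, gamma=gamma, sample_cov=cov_s
    )
    results = None
    if refit:
        results = PanelGVAR(data, structure=masks).fit(**fit_kwargs)
    return masks, results


def fit_pgvar(
    data: PanelDataset,
    structure: StructureMasks | None = None,
    **fit_kwargs,
) -> PanelGVARResults:
    """Fit the (optionally masked) panel GVAR by maximum likelihood.

    Functional facade over :class:`PanelGVAR`; the returned results object
    carries ``params``, ``fit_indices`` and ``networks``.
    """
    return PanelGVAR(data, structure=structure).fit(**fit_kwargs)
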