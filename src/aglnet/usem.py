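"""Unified structural equation model (uSEM) over lagged ROI blocks.

The model treats the stacked vector [eta_t, eta_{t+1}] of p ROI signals at
consecutive scans as the observed variables.  The lagged block eta_t is
exogenous with a freely estimated covariance; the current block obeys

    eta_{t+1} = A eta_{t+1} + Phi eta_t + zeta,

so contemporaneous directed paths (A, zero diagonal) and lag-1 directed
paths (Phi) are estimated simultaneously.  With B = (I - A)^-1 and
exogenous covariance S_xx the implied covariance of the 2p-vector is

    Sigma_xx = S_xx
    Sigma_yx = B Phi S_xx
    Sigma_yy = B (Phi S_xx Phi' + Psi) B',   Psi = diag(psi).

Estimation minimizes the maximum-likelihood discrepancy
F = log|Sigma| + tr(S Sigma^-1) - log|S| - 2p over the free parameters;
chi2 = (n_effective - 1) F at the optimum.  Model search frees one fixed
path at a time, chosen by the largest Lagrange-multiplier modification
index, until the four conventional fit criteria are all met
(RMSEA < .05, SRMR < .05, NNFI > .95, CFI > .95), then prunes
non-significant paths (|z| < 1.96) and refits once.

`UnifiedSEM` (fixed free-parameter masks) and `USEMSearch` (automatic
search) follow scikit-learn estimator conventions: constructor parameters
are hyper-parameters, `fit` accepts an n x 2p array of lagged pair rows,
and results live in trailing-underscore attributes.  `fit_covariance`
accepts a pooled covariance directly, which is the primary entry point
for group analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .simulate import ROITimeSeries, DEFAULT_ROI_NAMES

__all__ = [
    "LaggedCovariance",
    "USEMModel",
    "FitIndices",
    "SearchTrace",
    "NetworkEdge",
    "NetworkReport",
    "UnifiedSEM",
    "USEMSearch",
    "build_lagged_covariance",
    "pool_group_covariance",
    "implied_covariance",
    "fit_model",
    "fit_indices",
    "modification_indices",
    "automatic_search",
    "export_network",
]

Z_PRUNE_DEFAULT = 1.96


# --------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class LaggedCovariance:
    """Pooled 2p x 2p covariance of [eta_t, eta_{t+1}] with effective n.

    Variable order is [lagged block, current block]; n_effective is the
    pooled pair count minus the number of subjects (one sample-mean
    degree of freedom per subject).
    """

    S: np.ndarray
    n_effective: int
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    n_subjects: int = 1
    pair_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        p2 = 2 * len(self.roi_names)
        if S.shape != (p2, p2):
            raise ValueError(f"covariance must be {p2}x{p2}, got {S.shape}")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "S", (S + S.T) / 2)

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)


@dataclass(frozen=True)
class USEMModel:
    """Fitted uSEM parameter matrices and their free-parameter masks."""

    A: np.ndarray
    Phi: np.ndarray
    psi: np.ndarray  # residual variances of the current block
    exog_cov: np.ndarray  # covariance of the lagged (exogenous) block
    free_mask_a: np.ndarray
    free_mask_phi: np.ndarray
    se_a: np.ndarray
    se_phi: np.ndarray
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def n_free_paths(self) -> int:
        return int(self.free_mask_a.sum() + self.free_mask_phi.sum())


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    rmsea: float
    srmr: float
    nnfi: float
    cfi: float
    n_effective: int
    saturated: bool = False

    def meets(
        self,
        rmsea_max: float = 0.05,
        srmr_max: float = 0.05,
        nnfi_min: float = 0.95,
        cfi_min: float = 0.95,
    ) -> bool:
        return (
            self.rmsea < rmsea_max
            and self.srmr < srmr_max
            and self.nnfi > nnfi_min
            and self.cfi > cfi_min
        )


@dataclass
class SearchStep:
    kind: str  # 'contemporaneous' | 'lagged'
    target: str
    source: str
    modification_index: float
    fit: FitIndices


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)
    stop_reason: str = ""
    pruned: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    kind: str  # 'contemporaneous' | 'lagged'
    weight: float
    se: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.weight))


@dataclass(frozen=True)
class NetworkReport:
    edges: tuple[NetworkEdge, ...]
    fit: FitIndices
    roi_names: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind,
                    "weight": e.weight,
                    "se": e.se,
                    "sign": e.sign,
                }
                for e in self.edges
            ],
            columns=["source", "target", "kind", "weight", "se", "sign"],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.roi_names)
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind, weight=e.weight, se=e.se)
        return g

    def to_dot(self) -> str:
        """Graphviz DOT text: solid edges positive, dotted negative,
        dashed style-suffix for lagged paths."""
        lines = ["digraph connectivity {"]
        for roi in self.roi_names:
            lines.append(f'  "{roi}";')
        for e in self.edges:
            style = "solid" if e.weight >= 0 else "dotted"
            extra = ', constraint=true' if e.kind == "contemporaneous" else ""
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[label="{e.weight:.3f}", style={style}, kind="{e.kind}"{extra}];'
            )
        lines.append("}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# covariance construction


def build_lagged_covariance(
    series: ROITimeSeries,
    condition_filter: set[str] | None = None,
) -> tuple[np.ndarray, int]:
    """2p x 2p covariance of consecutive-scan pairs for one subject.

    The subject's ROI columns are standardized over the filtered scans,
    then (t, t+1) pairs are formed only within contiguous same-condition
    segments (no pair spans a condition boundary).  Default filter keeps
    task scans only.
    """
    if condition_filter is None:
        condition_filter = {"task"}
    data = series.data
    keep_scans = np.array(
        [c in condition_filter for c in series.schedule.condition_labels]
    )
    used = data[keep_scans]
    if used.shape[0] < 3:
        raise ValueError("too few scans after condition filtering")
    mu = used.mean(axis=0)
    sd = used.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant ROI signal; cannot standardize")
    z = (data - mu) / sd

    pairs = []
    for condition, start, stop in series.schedule.segments():
        if condition not in condition_filter:
            continue
        for t in range(start, stop - 1):
            pairs.append(np.concatenate([z[t], z[t + 1]]))
    n_pairs = len(pairs)
    if n_pairs < 10:
        raise ValueError(f"only {n_pairs} usable lagged pairs (need >= 10)")
    X = np.asarray(pairs)
    S = np.cov(X, rowvar=False, ddof=1)
    return S, n_pairs


def pool_group_covariance(
    per_subject: list[np.ndarray],
    pair_counts: list[int],
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES,
) -> LaggedCovariance:
    """Pair-count-weighted average of per-subject lagged covariances.

    n_effective = sum(pair_counts) - n_subjects.
    """
    if not per_subject:
        raise ValueError("need at least one subject")
    if len(per_subject) != len(pair_counts):
        raise ValueError("per_subject and pair_counts length mismatch")
    p2 = 2 * len(roi_names)
    mats = []
    for S in per_subject:
        S = np.asarray(S, dtype=float)
        if S.shape != (p2, p2):
            raise ValueError(f"expected {p2}x{p2} matrices, got {S.shape}")
        mats.append(S)
    weights = np.asarray(pair_counts, dtype=float)
    pooled = np.einsum("i,ijk->jk", weights / weights.sum(), np.asarray(mats))
    return LaggedCovariance(
        S=pooled,
        n_effective=int(weights.sum()) - len(mats),
        roi_names=roi_names,
        n_subjects=len(mats),
        pair_counts=tuple(int(c) for c in pair_counts),
    )


def group_lagged_covariance(
    group: list[ROITimeSeries],
    condition_filter: set[str] | None = None,
) -> LaggedCovariance:
    """Convenience: per-subject lagged covariances pooled into one matrix."""
    mats, counts = [], []
    for series in group:
        S, n = build_lagged_covariance(series, condition_filter)
        mats.append(S)
        counts.append(n)
    return pool_group_covariance(mats, counts, group[0].roi_names)


# --------------------------------------------------------------------------
# likelihood machinery


def _implied_blocks(A, Phi, psi, S_xx):
    p = A.shape[0]
    B = np.linalg.inv(np.eye(p) - A)
    Syx = B @ Phi @ S_xx
    M = Phi @ S_xx @ Phi.T + np.diag(psi)
    Syy = B @ M @ B.T
    top = np.hstack([S_xx, Syx.T])
    bottom = np.hstack([Syx, Syy])
    sigma = np.vstack([top, bottom])
    return (sigma + sigma.T) / 2, B, M


def implied_covariance(model: USEMModel) -> np.ndarray:
    """Model-implied covariance of [eta_t, eta_{t+1}]."""
    p = model.n_roi
    if abs(np.linalg.det(np.eye(p) - model.A)) < 1e-12:
        raise np.linalg.LinAlgError("(I - A) is singular at the estimate")
    sigma, _, _ = _implied_blocks(model.A, model.Phi, model.psi, model.exog_cov)
    return sigma


class _Parameterization:
    """Maps a flat parameter vector to (S_xx, psi, A, Phi) and provides
    per-parameter derivative matrices of the implied covariance."""

    def __init__(self, p: int, free_a: np.ndarray, free_phi: np.ndarray):
        self.p = p
        self.free_a = free_a.astype(bool)
        self.free_phi = free_phi.astype(bool)
        if self.free_a.shape != (p, p) or self.free_phi.shape != (p, p):
            raise ValueError("free masks must be p x p")
        if np.any(np.diag(self.free_a)):
            raise ValueError("diagonal of A cannot be freed")
        self.exog_idx = [(a, b) for a in range(p) for b in range(a + 1)]
        self.a_idx = [
            (i, j) for i in range(p) for j in range(p) if self.free_a[i, j]
        ]
        self.phi_idx = [
            (i, j) for i in range(p) for j in range(p) if self.free_phi[i, j]
        ]
        self.n_exog = len(self.exog_idx)
        self.n_psi = p
        self.n_free = self.n_exog + self.n_psi + len(self.a_idx) + len(self.phi_idx)

    def unpack(self, theta: np.ndarray):
        p = self.p
        S_xx = np.zeros((p, p))
        for k, (a, b) in enumerate(self.exog_idx):
            S_xx[a, b] = S_xx[b, a] = theta[k]
        psi = theta[self.n_exog : self.n_exog + p]
        A = np.zeros((p, p))
        off = self.n_exog + p
        for k, (i, j) in enumerate(self.a_idx):
            A[i, j] = theta[off + k]
        off += len(self.a_idx)
        Phi = np.zeros((p, p))
        for k, (i, j) in enumerate(self.phi_idx):
            Phi[i, j] = theta[off + k]
        return S_xx, psi, A, Phi

    def pack(self, S_xx, psi, A, Phi) -> np.ndarray:
        theta = np.empty(self.n_free)
        for k, (a, b) in enumerate(self.exog_idx):
            theta[k] = S_xx[a, b]
        theta[self.n_exog : self.n_exog + self.p] = psi
        off = self.n_exog + self.p
        for k, (i, j) in enumerate(self.a_idx):
            theta[off + k] = A[i, j]
        off += len(self.a_idx)
        for k, (i, j) in enumerate(self.phi_idx):
            theta[off + k] = Phi[i, j]
        return theta

    def dsigma_list(self, S_xx, psi, A, Phi, B, M):
        """Derivative of the implied 2p x 2p covariance for each free
        parameter, plus extra A/Phi candidates appended by the caller."""
        return [
            self._dsigma(kind, ij, S_xx, psi, A, Phi, B, M)
            for kind, ij in self.param_tags()
        ]

    def param_tags(self):
        tags = [("exog", ij) for ij in self.exog_idx]
        tags += [("psi", (r, r)) for r in range(self.p)]
        tags += [("a", ij) for ij in self.a_idx]
        tags += [("phi", ij) for ij in self.phi_idx]
        return tags

    def _dsigma(self, kind, ij, S_xx, psi, A, Phi, B, M):
        p = self.p
        d = np.zeros((2 * p, 2 * p))
        if kind == "exog":
            a, b = ij
            dS = np.zeros((p, p))
            dS[a, b] = dS[b, a] = 1.0
            dSyx = B @ Phi @ dS
            dSyy = B @ Phi @ dS @ Phi.T @ B.T
            d[:p, :p] = dS
        elif kind == "psi":
            r, _ = ij
            dSyx = np.zeros((p, p))
            dSyy = np.outer(B[:, r], B[:, r])
        elif kind == "a":
            i, j = ij
            dB = np.outer(B[:, i], B[j, :])
            dSyx = dB @ Phi @ S_xx
            half = dB @ M @ B.T
            dSyy = half + half.T
        elif kind == "phi":
            i, j = ij
            E = np.zeros((p, p))
            E[i, j] = 1.0
            dSyx = B @ E @ S_xx
            half = B @ (E @ S_xx @ Phi.T) @ B.T
            dSyy = half + half.T
        else:  # pragma: no cover
            raise ValueError(kind)
        d[p:, :p] = dSyx
        d[:p, p:] = dSyx.T
        d[p:, p:] = (dSyy + dSyy.T) / 2
        return d


def _ml_discrepancy(S, sigma):
    """F = log|Sigma| + tr(S Sigma^-1) - log|S| - k, or inf if not PD."""
    k = S.shape[0]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, None
    logdet_sigma = 2 * np.sum(np.log(np.diag(chol)))
    sigma_inv = np.linalg.inv(sigma)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")
    F = logdet_sigma + float(np.sum(S * sigma_inv)) - logdet_s - k
    return F, sigma_inv


def _candidate_dsigma(kind, ij, S_xx, Phi, B, M, p):
    """dSigma for a *fixed* path candidate, reusing the parameterization
    formulas (kind is 'a' or 'phi')."""
    helper = _Parameterization(p, np.zeros((p, p), bool), np.zeros((p, p), bool))
    return helper._dsigma(kind, ij, S_xx, None, None, Phi, B, M)


# --------------------------------------------------------------------------
# estimators


class UnifiedSEM(BaseEstimator):
    """ML estimation of a uSEM with fixed free-parameter masks.

    Parameters
    ----------
    free_a, free_phi : array-like of bool, shape (p, p), or None
        Masks of estimated contemporaneous / lagged paths (row = target).
        ``free_a=None`` frees nothing; ``free_phi="ar"`` frees the
        autoregressive diagonal only (the conventional baseline model).
    tol : float
        Convergence tolerance on the discrepancy function F.
    n_restarts : int
        Jittered restarts attempted on non-convergence.

    Fitted attributes: ``model_`` (USEMModel), ``fit_indices_``,
    ``discrepancy_``, ``chi2_``, ``df_``, ``implied_cov_``,
    ``n_effective_``, ``converged_``.
    """

    def __init__(
        self,
        free_a=None,
        free_phi="ar",
        tol: float = 1e-8,
        n_restarts: int = 5,
    ):
        self.free_a = free_a
        self.free_phi = free_phi
        self.tol = tol
        self.n_restarts = n_restarts

    # -- mask resolution ---------------------------------------------------
    def _masks(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        def resolve(spec, diag_free):
            if spec is None:
                return np.zeros((p, p), dtype=bool)
            if isinstance(spec, str):
                if spec == "ar":
                    return np.eye(p, dtype=bool)
                if spec == "full":
                    m = np.ones((p, p), dtype=bool)
                    if not diag_free:
                        np.fill_diagonal(m, False)
                    return m
                raise ValueError(f"unknown mask spec {spec!r}")
            m = np.asarray(spec, dtype=bool).copy()
            if m.shape != (p, p):
                raise ValueError(f"mask must be {p}x{p}")
            return m

        free_a = resolve(self.free_a, diag_free=False)
        if np.any(np.diag(free_a)):
            raise ValueError("diagonal of A cannot be freed")
        free_phi = resolve(self.free_phi, diag_free=True)
        return free_a, free_phi

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit from an n x 2p array of lagged pair rows [eta_t, eta_{t+1}]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be n x 2p")
        p = X.shape[1] // 2
        S = np.cov(X, rowvar=False, ddof=1)
        names = tuple(f"ROI{i + 1}" for i in range(p))
        data = LaggedCovariance(S=S, n_effective=X.shape[0], roi_names=names)
        return self.fit_covariance(data)

    def fit_covariance(self, data: LaggedCovariance, start_model: USEMModel | None = None):
        """Fit from a pooled lagged covariance (primary group entry point).

        ``start_model`` optionally warm-starts the optimizer (used by the
        search loop so refits of nested models are monotone in F).
        """
        S = data.S
        p = data.n_roi
        n = data.n_effective
        eigmin = float(np.linalg.eigvalsh(S).min())
        if eigmin <= 1e-10:
            raise ValueError(
                f"pooled covariance is not positive definite (min eig {eigmin:.2e})"
            )
        free_a, free_phi = self._masks(p)
        par = _Parameterization(p, free_a, free_phi)

        S_xx = S[:p, :p]
        S_yx = S[p:, :p]
        S_yy = S[p:, p:]
        # regression-based starting values
        Phi_ols = S_yx @ np.linalg.inv(S_xx)
        Phi0 = np.where(free_phi, Phi_ols, 0.0)
        A0 = np.zeros((p, p))
        resid = S_yy - S_yx @ np.linalg.inv(S_xx) @ S_yx.T
        psi0 = np.clip(np.diag(resid), 0.05 * np.diag(S_yy), None)
        if start_model is not None:
            theta0 = par.pack(
                start_model.exog_cov,
                np.clip(start_model.psi, 1e-6, None),
                np.where(free_a, start_model.A, 0.0),
                np.where(free_phi, start_model.Phi, 0.0),
            )
        else:
            theta0 = par.pack(S_xx.copy(), psi0, A0, Phi0)

        def objective(theta):
            S_xx_, psi_, A_, Phi_ = par.unpack(theta)
            p_ = par.p
            eye = np.eye(p_)
            if abs(np.linalg.det(eye - A_)) < 1e-12:
                return 1e12, np.zeros_like(theta)
            sigma, B, M = _implied_blocks(A_, Phi_, psi_, S_xx_)
            F, sigma_inv = _ml_discrepancy(S, sigma)
            if not np.isfinite(F):
                return 1e12, np.zeros_like(theta)
            G = sigma_inv - sigma_inv @ S @ sigma_inv
            grads = np.array(
                [
                    float(np.sum(G * d))
                    for d in par.dsigma_list(S_xx_, psi_, A_, Phi_, B, M)
                ]
            )
            return F, grads

        lower = np.full(par.n_free, -np.inf)
        # keep residual variances and exogenous variances positive
        for k, (a, b) in enumerate(par.exog_idx):
            if a == b:
                lower[k] = 1e-8
        lower[par.n_exog : par.n_exog + p] = 1e-8
        bounds = [(lo, None) if np.isfinite(lo) else (None, None) for lo in lower]

        rng = np.random.default_rng(0)
        best = None
        for attempt in range(self.n_restarts + 1):
            start = theta0 if attempt == 0 else theta0 * (
                1 + 0.1 * rng.normal(size=theta0.shape)
            )
            res = optimize.minimize(
                objective,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun - self.tol:
                best = res
            if best.fun < 1e11 and np.max(np.abs(best.jac)) < 1e-5:
                break
        if best is None or best.fun >= 1e11:
            raise RuntimeError(
                "uSEM estimation failed to find a positive-definite solution; "
                f"optimizer trace: {best}"
            )
        self.converged_ = bool(np.max(np.abs(best.jac)) < 1e-3)
        theta = best.x
        F = max(float(best.fun), 0.0)
        S_xx_, psi_, A_, Phi_ = par.unpack(theta)
        sigma, B, M = _implied_blocks(A_, Phi_, psi_, S_xx_)

        # standard errors from the inverse expected information
        se_a = np.zeros((p, p))
        se_phi = np.zeros((p, p))
        info = _information_matrix(par, theta, sigma, n)
        try:
            cov_theta = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_theta = np.linalg.pinv(info)
        variances = np.clip(np.diag(cov_theta), 0.0, None)
        tags = par.param_tags()
        for k, (kind, (i, j)) in enumerate(tags):
            if kind == "a":
                se_a[i, j] = np.sqrt(variances[k])
            elif kind == "phi":
                se_phi[i, j] = np.sqrt(variances[k])

        self.model_ = USEMModel(
            A=A_,
            Phi=Phi_,
            psi=psi_,
            exog_cov=S_xx_,
            free_mask_a=par.free_a,
            free_mask_phi=par.free_phi,
            se_a=se_a,
            se_phi=se_phi,
            roi_names=data.roi_names,
        )
        self.discrepancy_ = F
        self.n_effective_ = n
        self.implied_cov_ = sigma
        n_moments = p * (2 * p + 1)  # 2p(2p+1)/2
        self.df_ = max(n_moments - par.n_free, 0)
        self.chi2_ = (n - 1) * F
        chi2_null, df_null = _null_model(S, n)
        self.fit_indices_ = fit_indices(
            self.chi2_, self.df_, chi2_null, df_null, S, sigma, n
        )
        self._par = par
        self._data = data
        return self


def _information_matrix(par: _Parameterization, theta, sigma, n) -> np.ndarray:
    """Expected information ((n-1)/2) tr(Sigma^-1 dSigma_a Sigma^-1 dSigma_b)."""
    S_xx_, psi_, A_, Phi_ = par.unpack(theta)
    _, B, M = _implied_blocks(A_, Phi_, psi_, S_xx_)
    sigma_inv = np.linalg.inv(sigma)
    ds = par.dsigma_list(S_xx_, psi_, A_, Phi_, B, M)
    W = [sigma_inv @ d for d in ds]
    m = len(W)
    info = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            info[a, b] = info[b, a] = np.sum(W[a] * W[b].T)
    return (n - 1) / 2 * info


def _null_model(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence model over the 2p observed variables."""
    k = S.shape[0]
    sigma0 = np.diag(np.diag(S))
    F0, _ = _ml_discrepancy(S, sigma0)
    df0 = k * (k + 1) // 2 - k
    return (n - 1) * F0, df0


def fit_indices(
    chi2: float,
    df: int,
    chi2_null: float,
    df_null: int,
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    n_effective: int,
) -> FitIndices:
    """Conventional SEM fit indices.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    SRMR  = RMS of standardized residual covariances (diagonal included);
    NNFI  = ((chi2_null/df_null) - (chi2/df)) / ((chi2_null/df_null) - 1);
    CFI   = 1 - max(chi2 - df, 0) / max(chi2_null - df_null, chi2 - df, 0).
    A saturated model (df = 0) reports RMSEA 0, NNFI 1, CFI 1 with the
    ``saturated`` flag set.
    """
    if df < 0:
        raise ValueError("df must be >= 0")
    d = np.sqrt(np.outer(np.diag(sample_cov), np.diag(sample_cov)))
    resid = (sample_cov - implied_cov) / d
    tri = resid[np.tril_indices_from(resid)]
    srmr = float(np.sqrt(np.mean(tri**2)))
    if df == 0:
        return FitIndices(
            chi2=chi2,
            df=0,
            rmsea=0.0,
            srmr=srmr,
            nnfi=1.0,
            cfi=1.0,
            n_effective=n_effective,
            saturated=True,
        )
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_effective - 1))))
    # Incremental indices measure improvement over the independence model;
    # when that null model is itself close to the data (null-model RMSEA
    # below the conventional 0.158 informativeness bound) the improvement
    # ratio is pure sampling noise, so NNFI and CFI are vacuously 1.
    rmsea_null = np.sqrt(
        max(chi2_null - df_null, 0.0) / (df_null * (n_effective - 1))
    )
    if rmsea_null < 0.158:
        nnfi = 1.0
        cfi = 1.0
    else:
        null_ratio = chi2_null / df_null
        if null_ratio <= 1:
            nnfi = 1.0
        else:
            nnfi = float((null_ratio - chi2 / df) / (null_ratio - 1))
        denom = max(chi2_null - df_null, chi2 - df, 0.0)
        cfi = 1.0 if denom == 0 else float(1.0 - max(chi2 - df, 0.0) / denom)
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        rmsea=rmsea,
        srmr=srmr,
        nnfi=nnfi,
        cfi=max(0.0, min(cfi, 1.0)),
        n_effective=n_effective,
    )


def modification_indices(
    fitted: UnifiedSEM, data: LaggedCovariance | None = None
) -> list[dict]:
    """Lagrange-multiplier statistic (expected chi2 drop) for every fixed
    path in A and Phi, ranked descending.

    Ties break contemporaneous before lagged, then row-major order.  The
    univariate score statistic is s_j^2 / (I_jj - I_jf I_ff^-1 I_fj),
    with the score and information evaluated at the restricted optimum.
    """
    model = fitted.model_
    par: _Parameterization = fitted._par
    if data is None:
        data = fitted._data
    S = data.S
    n = fitted.n_effective_
    p = model.n_roi
    sigma = fitted.implied_cov_
    sigma_inv = np.linalg.inv(sigma)
    G = sigma_inv - sigma_inv @ S @ sigma_inv
    _, B, M = _implied_blocks(model.A, model.Phi, model.psi, model.exog_cov)

    candidates = []
    for i in range(p):
        for j in range(p):
            if i != j and not model.free_mask_a[i, j]:
                candidates.append(("a", (i, j)))
    for i in range(p):
        for j in range(p):
            if not model.free_mask_phi[i, j]:
                candidates.append(("phi", (i, j)))
    if not candidates:
        return []

    theta = par.pack(model.exog_cov, model.psi, model.A, model.Phi)
    ds_free = par.dsigma_list(model.exog_cov, model.psi, model.A, model.Phi, B, M)
    W_free = [sigma_inv @ d for d in ds_free]
    m = len(W_free)
    I_ff = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            I_ff[a, b] = I_ff[b, a] = np.sum(W_free[a] * W_free[b].T)
    I_ff *= (n - 1) / 2
    I_ff_inv = np.linalg.pinv(I_ff)

    results = []
    for rank_kind, (kind, (i, j)) in enumerate(candidates):
        d = _candidate_dsigma(
            kind, (i, j), model.exog_cov, model.Phi, B, M, p
        )
        score = -(n - 1) / 2 * float(np.sum(G * d))
        W_j = sigma_inv @ d
        I_jj = (n - 1) / 2 * float(np.sum(W_j * W_j.T))
        I_jf = (n - 1) / 2 * np.array(
            [float(np.sum(W_j * W.T)) for W in W_free]
        )
        denom = I_jj - I_jf @ I_ff_inv @ I_jf
        mi = 0.0 if denom <= 1e-12 else max(score**2 / denom, 0.0)
        results.append(
            {
                "kind": "contemporaneous" if kind == "a" else "lagged",
                "target": model.roi_names[i],
                "source": model.roi_names[j],
                "i": i,
                "j": j,
                "mi": float(mi),
            }
        )
    # descending MI; ties contemporaneous first, then row-major
    results.sort(
        key=lambda r: (-r["mi"], 0 if r["kind"] == "contemporaneous" else 1,
                       r["i"], r["j"])
    )
    return results


class USEMSearch(BaseEstimator):
    """Automatic uSEM model search with fit-criterion stopping and pruning.

    Starting from a baseline model (all p autoregressive lagged paths
    free), the search repeatedly frees the fixed path with the largest
    modification index and refits, stopping once RMSEA < rmsea_max,
    SRMR < srmr_max, NNFI > nnfi_min and CFI > cfi_min all hold (or no
    candidate / max_steps).  Free paths with |z| < z_prune are then
    pruned and the model refit once.

    Fitted attributes: ``estimator_`` (final UnifiedSEM), ``model_``,
    ``fit_indices_``, ``trace_`` (SearchTrace), ``report_``
    (NetworkReport), ``stop_reason_``.
    """

    def __init__(
        self,
        rmsea_max: float = 0.05,
        srmr_max: float = 0.05,
        nnfi_min: float = 0.95,
        cfi_min: float = 0.95,
        z_prune: float = Z_PRUNE_DEFAULT,
        max_steps: int = 20,
        baseline: str = "ar",
        tol: float = 1e-8,
    ):
        self.rmsea_max = rmsea_max
        self.srmr_max = srmr_max
        self.nnfi_min = nnfi_min
        self.cfi_min = cfi_min
        self.z_prune = z_prune
        self.max_steps = max_steps
        self.baseline = baseline
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        p = X.shape[1] // 2
        S = np.cov(X, rowvar=False, ddof=1)
        names = tuple(f"ROI{i + 1}" for i in range(p))
        return self.fit_covariance(
            LaggedCovariance(S=S, n_effective=X.shape[0], roi_names=names)
        )

    def _criteria_met(self, fit: FitIndices) -> bool:
        return fit.meets(self.rmsea_max, self.srmr_max, self.nnfi_min, self.cfi_min)

    def fit_covariance(self, data: LaggedCovariance):
        p = data.n_roi
        if self.baseline == "ar":
            free_a = np.zeros((p, p), dtype=bool)
            free_phi = np.eye(p, dtype=bool)
        elif self.baseline == "empty":
            free_a = np.zeros((p, p), dtype=bool)
            free_phi = np.zeros((p, p), dtype=bool)
        else:
            raise ValueError(f"baseline must be 'ar' or 'empty', got {self.baseline!r}")

        trace = SearchTrace()
        est = UnifiedSEM(free_a=free_a, free_phi=free_phi, tol=self.tol)
        est.fit_covariance(data)
        prev_chi2 = est.chi2_
        stop_reason = None
        for step in range(self.max_steps):
            if self._criteria_met(est.fit_indices_):
                stop_reason = "criteria-met"
                break
            mis = modification_indices(est)
            if not mis:
                stop_reason = "no-candidate"
                break
            top = mis[0]
            if top["kind"] == "contemporaneous":
                free_a[top["i"], top["j"]] = True
            else:
                free_phi[top["i"], top["j"]] = True
            warm = est.model_
            est = UnifiedSEM(free_a=free_a, free_phi=free_phi, tol=self.tol)
            est.fit_covariance(data, start_model=warm)
            # nested models: freeing a path can never raise the optimum
            if est.chi2_ > prev_chi2 + 1e-6 * max(prev_chi2, 1.0):
                raise RuntimeError(
                    f"chi2 increased after freeing {top}: "
                    f"{prev_chi2:.6f} -> {est.chi2_:.6f}"
                )
            prev_chi2 = est.chi2_
            trace.steps.append(
                SearchStep(
                    kind=top["kind"],
                    target=top["target"],
                    source=top["source"],
                    modification_index=top["mi"],
                    fit=est.fit_indices_,
                )
            )
        else:
            stop_reason = (
                "criteria-met" if self._criteria_met(est.fit_indices_) else "max-steps"
            )

        # single post-hoc prune of non-significant paths, then one refit
        model = est.model_
        pruned: list[tuple[str, str, str]] = []
        with np.errstate(divide="ignore", invalid="ignore"):
            z_a = np.where(model.se_a > 0, np.abs(model.A) / model.se_a, np.inf)
            z_phi = np.where(
                model.se_phi > 0, np.abs(model.Phi) / model.se_phi, np.inf
            )
        new_a = model.free_mask_a & (z_a >= self.z_prune)
        new_phi = model.free_mask_phi & (z_phi >= self.z_prune)
        for i in range(p):
            for j in range(p):
                if model.free_mask_a[i, j] and not new_a[i, j]:
                    pruned.append(
                        ("contemporaneous", data.roi_names[j], data.roi_names[i])
                    )
                if model.free_mask_phi[i, j] and not new_phi[i, j]:
                    pruned.append(("lagged", data.roi_names[j], data.roi_names[i]))
        if pruned:
            est = UnifiedSEM(free_a=new_a, free_phi=new_phi, tol=self.tol)
            est.fit_covariance(data)
        trace.stop_reason = stop_reason
        trace.pruned = pruned

        self.estimator_ = est
        self.model_ = est.model_
        self.fit_indices_ = est.fit_indices_
        self.trace_ = trace
        self.stop_reason_ = stop_reason
        self.report_ = export_network(est.model_, est.fit_indices_)
        return self


def export_network(model: USEMModel, fit: FitIndices) -> NetworkReport:
    """Edge list of the surviving free paths.

    ``A[i, j]`` (respectively ``Phi[i, j]``) maps to a directed edge from
    ROI j to ROI i of kind contemporaneous (lagged).
    """
    edges = []
    p = model.n_roi
    for kind, mat, se, mask in (
        ("contemporaneous", model.A, model.se_a, model.free_mask_a),
        ("lagged", model.Phi, model.se_phi, model.free_mask_phi),
    ):
        for i in range(p):
            for j in range(p):
                if mask[i, j]:
                    edges.append(
                        NetworkEdge(
                            source=model.roi_names[j],
                            target=model.roi_names[i],
                            kind=kind,
                            weight=float(mat[i, j]),
                            se=float(se[i, j]),
                        )
                    )
    return NetworkReport(edges=tuple(edges), fit=fit, roi_names=model.roi_names)


# --------------------------------------------------------------------------
# thin functional wrappers


def fit_model(
    data: LaggedCovariance, free_mask_a, free_mask_phi
) -> tuple[USEMModel, FitIndices]:
    est = UnifiedSEM(free_a=free_mask_a, free_phi=free_mask_phi)
    est.fit_covariance(data)
    return est.model_, est.fit_indices_


def automatic_search(
    data: LaggedCovariance, **config
) -> tuple[USEMModel, FitIndices, SearchTrace]:
    search = USEMSearch(**config)
    search.fit_covariance(data)
    return search.model_, search.fit_indices_, search.trace_
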