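"""Constrained low-rank covariance model with disjoint network support.

Each run's covariance is modelled as Sigma = W G W' + v I where W is a
shared p-by-k loading matrix constrained to be entrywise non-negative,
column-orthonormal, and with at most one non-zero entry per row, so each
column of W is a disjoint brain network.  G is the run's k-by-k latent
covariance (its diagonal holds the brain network activities, BNAs) and v
the run's isotropic noise variance.

Fitting minimizes the Gaussian discrepancy

    sum_i  p log 2pi + log det Sigma_i + tr(Sigma_i^{-1} K_i)

(the negative log-likelihood up to a factor) by block-coordinate descent:
exact closed-form (G, v) updates at fixed W, and projected-gradient W
updates with a backtracking line search.  The projection clips negatives,
keeps each row's largest entry, and renormalizes columns — for a matrix
with disjoint row support the column normalization is exactly the polar
re-orthonormalization.  The number of networks k is selected by the
discrepancy on held-out runs, split by subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .preprocess import CovarianceStructure

__all__ = [
    "LoadingMatrix",
    "RunLatent",
    "MHAModel",
    "fit_objective",
    "estimate_run_params",
    "project_runs",
    "fit_mha",
    "select_k",
    "networks_from_W",
]

V_MIN = 1e-8


@dataclass
class LoadingMatrix:
    """Non-negative orthonormal p-by-k loading matrix with disjoint row support."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2D")
        self.validate()

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def validate(self, atol: float = 1e-6) -> None:
        if np.any(self.W < -atol):
            raise ValueError("W has negative entries")
        gram = self.W.T @ self.W
        if not np.allclose(gram, np.eye(self.k), atol=atol):
            raise ValueError("W columns are not orthonormal")
        if np.any((self.W > atol).sum(axis=1) > 1):
            raise ValueError("a row of W has more than one non-zero entry")

    def support(self) -> np.ndarray:
        """Network index per ROI (-1 for ROIs assigned to no network)."""
        nz = self.W > 0
        out = np.full(self.p, -1, dtype=int)
        rows, cols = np.nonzero(nz)
        out[rows] = cols
        return out

    def n_assigned_rois(self) -> int:
        return int((self.W > 0).any(axis=1).sum())


@dataclass
class RunLatent:
    """Per-run latent covariance G (k-by-k, PSD) and noise variance v > 0."""

    G: np.ndarray
    v: float
    run_id: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.v <= 0:
            raise ValueError("v must be positive")

    @property
    def bna(self) -> np.ndarray:
        """Brain network activities: the diagonal of G."""
        return np.diag(self.G).copy()


@dataclass
class MHAModel:
    loading: LoadingMatrix
    run_latents: list[RunLatent]
    objective_trace: list[float]
    seed: int
    converged: bool
    run_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loading.k

    def to_json(self, path: str | Path) -> None:
        doc = {
            "W": self.loading.W.tolist(),
            "runs": [
                {"run_id": rl.run_id, "G": rl.G.tolist(), "v": rl.v,
                 "degenerate": rl.degenerate}
                for rl in self.run_latents
            ],
            "objective_trace": self.objective_trace,
            "seed": self.seed,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "MHAModel":
        doc = json.loads(Path(path).read_text())
        latents = [RunLatent(G=np.array(r["G"]), v=r["v"], run_id=r["run_id"],
                             degenerate=r.get("degenerate", False))
                   for r in doc["runs"]]
        return cls(loading=LoadingMatrix(np.array(doc["W"])), run_latents=latents,
                   objective_trace=doc["objective_trace"], seed=doc["seed"],
                   converged=doc["converged"], run_ids=[r["run_id"] for r in doc["runs"]])


def _as_K(K: CovarianceStructure | np.ndarray) -> np.ndarray:
    if isinstance(K, CovarianceStructure):
        return K.K
    return np.asarray(K, dtype=float)


def _as_W(W: LoadingMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, LoadingMatrix):
        return W.W
    return np.asarray(W, dtype=float)


def fit_objective(W: LoadingMatrix | np.ndarray, G: np.ndarray, v: float,
                  K: CovarianceStructure | np.ndarray) -> float:
    """Per-run Gaussian discrepancy p log 2pi + log det Sigma + tr(Sigma^-1 K).

    Smaller is better; the model log-likelihood is (-t/2) times this value.
    """
    Wm, Km = _as_W(W), _as_K(K)
    p = Wm.shape[0]
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if v <= 0:
        raise ValueError("v must be positive")
    sigma = Wm @ G @ Wm.T + v * np.eye(p)
    try:
        c, low = linalg.cho_factor(sigma, check_finite=False)
    except linalg.LinAlgError as exc:  # cannot occur for v > 0, PSD G
        raise linalg.LinAlgError("singular model covariance") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    trace_term = float(np.trace(linalg.cho_solve((c, low), Km, check_finite=False)))
    return p * np.log(2.0 * np.pi) + logdet + trace_term


def estimate_run_params(W: LoadingMatrix | np.ndarray, K: CovarianceStructure | np.ndarray,
                        run_id: str = "", v_min: float = V_MIN) -> RunLatent:
    """Exact minimizer of the per-run discrepancy over (G PSD, v > 0) at fixed W.

    Writing M = W' K W with eigenvalues lambda_j and r = tr K - tr M, the
    optimal latent spectrum is max(lambda_j - v, 0) in the eigenbasis of M,
    and v solves v = (r + sum of the lambda_j below v) / (p - k + #below);
    the admissible regime is found by scanning the sorted spectrum.  When no
    eigenvalue falls below v this reduces to v = r / (p - k).
    """
    Wm, Km = _as_W(W), _as_K(K)
    p, k = Wm.shape
    if k >= p:
        raise ValueError(f"need k < p, got k={k}, p={p}")
    M = Wm.T @ Km @ Wm
    M = (M + M.T) / 2.0
    lam, U = np.linalg.eigh(M)  # ascending
    r = float(np.trace(Km) - np.trace(M))

    degenerate = False
    if r <= 0:
        v = v_min
        degenerate = True
    else:
        v = r / (p - k)  # m = 0 regime
        csum = 0.0
        for m in range(k + 1):
            if m > 0:
                csum += lam[m - 1]
            cand = (r + csum) / (p - k + m)
            lower_ok = m == 0 or lam[m - 1] < cand
            upper_ok = m == k or lam[m] >= cand
            if lower_ok and upper_ok:
                v = cand
                break
        v = max(v, v_min)

    G = (U * np.maximum(lam - v, 0.0)) @ U.T
    G = (G + G.T) / 2.0
    return RunLatent(G=G, v=v, run_id=run_id, degenerate=degenerate)


def project_runs(W: LoadingMatrix | np.ndarray,
                 Ks: list[CovarianceStructure | np.ndarray],
                 run_ids: list[str] | None = None) -> list[RunLatent]:
    """Closed-form (G, v) for each covariance at a fixed, already-fitted W."""
    if run_ids is None:
        run_ids = [str(i) for i in range(len(Ks))]
    return [estimate_run_params(W, K, run_id=rid) for K, rid in zip(Ks, run_ids)]


def _project_W(W: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Project onto {W >= 0, one non-zero per row, unit columns}.

    Disjoint-support columns are mutually orthogonal, so normalizing each
    column is the exact polar re-orthonormalization.  An all-zero column is
    repaired by reassigning the weakest-row entry (seeded) so the fit can
    continue; callers relying on pure restarts pass rng=None and get an error.
    """
    W = np.maximum(W, 0.0)
    best = np.argmax(W, axis=1)
    mask = np.zeros_like(W, dtype=bool)
    mask[np.arange(W.shape[0]), best] = True
    W = np.where(mask, W, 0.0)
    norms = np.linalg.norm(W, axis=0)
    for j in np.nonzero(norms == 0)[0]:
        if rng is None:
            raise _EmptyNetworkError(j)
        donor_counts = (W > 0).sum(axis=0)
        donors = np.nonzero(donor_counts > 1)[0]
        if donors.size == 0:
            raise _EmptyNetworkError(j)
        col = rng.choice(donors)
        rows = np.nonzero(W[:, col] > 0)[0]
        row = rows[np.argmin(W[rows, col])]
        W[row, :] = 0.0
        W[row, j] = 1.0
        norms = np.linalg.norm(W, axis=0)
    return W / norms


class _EmptyNetworkError(RuntimeError):
    def __init__(self, column: int):
        super().__init__(f"network column {column} lost all ROIs during projection")
        self.column = column


def _total_objective(W: np.ndarray, latents: list[RunLatent],
                     Ks: list[np.ndarray]) -> float:
    return sum(fit_objective(W, rl.G, rl.v, K) for rl, K in zip(latents, Ks))


def _objective_gradient(W: np.ndarray, latents: list[RunLatent],
                        Ks: list[np.ndarray]) -> np.ndarray:
    p = W.shape[0]
    grad = np.zeros_like(W)
    eye = np.eye(p)
    for rl, K in zip(latents, Ks):
        sigma = W @ rl.G @ W.T + rl.v * eye
        c, low = linalg.cho_factor(sigma, check_finite=False)
        S_inv_W = linalg.cho_solve((c, low), W, check_finite=False)
        S_inv_K = linalg.cho_solve((c, low), K, check_finite=False)
        grad += 2.0 * (S_inv_W - S_inv_K @ S_inv_W) @ rl.G
    return grad


def _spectral_init(K_mean: np.ndarray, k: int, rng: np.random.Generator,
                   perturb: bool) -> np.ndarray:
    lam, vecs = np.linalg.eigh(K_mean)
    top = vecs[:, np.argsort(lam)[::-1][:k]]
    if perturb:
        Q = linalg.qr(rng.standard_normal((k, k)))[0]
        top = top @ Q
    return _project_W(np.abs(top), rng)


def fit_mha(Ks: list[CovarianceStructure | np.ndarray], k: int, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-6, n_restarts: int = 10,
            run_ids: list[str] | None = None) -> MHAModel:
    """Fit the shared loading matrix W and per-run (G, v) for ``k`` networks.

    Block-coordinate descent with a monotone objective: closed-form latent
    updates alternate with projected-gradient W steps accepted only when
    they decrease the summed discrepancy (backtracking line search).  The
    best of ``n_restarts`` seeded initializations is returned; restart 0
    starts from the top-k eigenvectors of the mean covariance, later ones
    from seeded orthogonal rotations of that basis.
    """
    K_list = [_as_K(K) for K in Ks]
    p = K_list[0].shape[0]
    if any(K.shape != (p, p) for K in K_list):
        raise ValueError("all covariance structures must share p")
    if not 1 <= k < p:
        raise ValueError(f"need 1 <= k < p, got k={k}, p={p}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if run_ids is None:
        run_ids = [str(i) for i in range(len(K_list))]

    K_mean = np.mean(K_list, axis=0)
    root = np.random.default_rng(seed)
    restart_seeds = root.integers(0, 2**31 - 1, size=n_restarts)

    best: tuple[float, np.ndarray, list[RunLatent], list[float], bool] | None = None
    for r, rseed in enumerate(restart_seeds):
        rng = np.random.default_rng(rseed)
        W = _spectral_init(K_mean, k, rng, perturb=(r > 0))
        latents = [estimate_run_params(W, K, rid) for K, rid in zip(K_list, run_ids)]
        obj = _total_objective(W, latents, K_list)
        trace = [obj]
        converged = False
        for _ in range(max_iter):
            grad = _objective_gradient(W, latents, K_list)
            gnorm = np.linalg.norm(grad)
            improved_W = False
            if gnorm > 0:
                step = 1.0 / gnorm
                for _ in range(30):
                    W_try = _project_W(W - step * grad, rng)
                    obj_try = _total_objective(W_try, latents, K_list)
                    if obj_try < obj - 1e-12:
                        W, obj = W_try, obj_try
                        improved_W = True
                        break
                    step /= 2.0
            latents = [estimate_run_params(W, K, rid) for K, rid in zip(K_list, run_ids)]
            new_obj = _total_objective(W, latents, K_list)
            obj = min(obj, new_obj)
            trace.append(obj)
            rel = (trace[-2] - trace[-1]) / max(abs(trace[-2]), 1.0)
            if not improved_W and rel < tol:
                converged = True
                break
        if best is None or obj < best[0]:
            best = (obj, W, latents, trace, converged)

    assert best is not None
    _, W, latents, trace, converged = best
    return MHAModel(loading=LoadingMatrix(W), run_latents=latents,
                    objective_trace=trace, seed=seed, converged=converged,
                    run_ids=list(run_ids))


def heldout_objective(model_W: LoadingMatrix | np.ndarray,
                      Ks: list[CovarianceStructure | np.ndarray]) -> float:
    """Summed discrepancy of unseen runs at a fixed W, with per-run (G, v)."""
    K_list = [_as_K(K) for K in Ks]
    total = 0.0
    for K in K_list:
        rl = estimate_run_params(model_W, K)
        total += fit_objective(model_W, rl.G, rl.v, K)
    return total


def select_k(train: list[CovarianceStructure | np.ndarray],
             heldout: list[CovarianceStructure | np.ndarray],
             k_grid: list[int], seed: int = 0, tie_delta_frac: float = 0.01,
             return_models: bool = False, **fit_kwargs):
    """Choose the number of networks by held-out discrepancy.

    Fits one model per k on ``train``, scores each on ``heldout`` (closed-form
    per-run latents at the fitted W), and returns the argmin together with the
    min-max normalized curve: the smallest held-out discrepancy (best
    likelihood) maps to 0 and the largest to 1.  Ties within
    ``tie_delta_frac`` of the curve range are broken toward the k whose W
    assigns more ROIs to networks.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if not heldout:
        raise ValueError("held-out set is empty")
    k_grid = list(k_grid)
    models: dict[int, MHAModel] = {}
    raw: dict[int, float] = {}
    for k in k_grid:
        model = fit_mha(train, k, seed=seed, **fit_kwargs)
        models[k] = model
        raw[k] = heldout_objective(model.loading, heldout)

    vals = np.array([raw[k] for k in k_grid])
    vrange = vals.max() - vals.min()
    if vrange == 0:
        curve = {k: 0.0 for k in k_grid}
    else:
        curve = {k: float((raw[k] - vals.min()) / vrange) for k in k_grid}

    delta = tie_delta_frac * vrange
    candidates = [k for k in k_grid if raw[k] <= vals.min() + delta]
    k_best = max(candidates,
                 key=lambda k: (models[k].loading.n_assigned_rois(), -k))
    if return_models:
        return k_best, curve, models
    return k_best, curve


def networks_from_W(loading: LoadingMatrix, atlas) -> list:
    """Materialize each column of W as a brain network of ROIs with centroids."""
    from .matching import BrainNetwork

    if loading.p != atlas.p:
        raise ValueError(f"W has {loading.p} rows but atlas has {atlas.p} ROIs")
    networks = []
    for j in range(loading.k):
        rows = np.nonzero(loading.W[:, j] > 0)[0]
        rows = np.sort(rows)
        networks.append(BrainNetwork(network_index=j,
                                     roi_indices=set(int(i) for i in rows),
                                     centroids=atlas.centroids[rows].copy()))
    return networks
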