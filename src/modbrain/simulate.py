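"""Synthetic data with known ground truth for every pipeline stage.

Runs are drawn from the model's own generative process: a shared
non-negative orthonormal disjoint-support loading matrix W, a per-run
diagonal latent covariance G whose entries scatter around a
condition-dependent mean level, and isotropic Gaussian noise of per-run
variance v.  Each time column is sampled independently as x = W z + eps,
z ~ N(0, G), eps ~ N(0, v I).  The default configuration mirrors the study
design this package targets: 156 runs of 500 time points at TR = 2.4 s,
six anesthetic conditions distributed unevenly across five subjects, with
each condition acquired only in its subset of subjects.

Columns are i.i.d. (the model likelihood assumes exchangeable time points);
an optional AR(1) switch adds temporal autocorrelation for robustness
experiments only.  A toy blob atlas supports end-to-end spatial runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas, RunTimeSeries, atlas_from_array
from .mha import LoadingMatrix

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "GroundTruth",
    "simulate_loading_matrix",
    "simulate_runs",
    "simulate_toy_atlas",
]

CONDITIONS = (
    "awake",
    "ketamine-deep",
    "propofol-moderate",
    "propofol-deep",
    "sevoflurane-moderate",
    "sevoflurane-deep",
)

# which subjects each condition was acquired in (study design: five animals,
# three per arousal state, so no subject covers every condition)
_CONDITION_SUBJECTS = {
    "awake": ("A", "K", "J"),
    "ketamine-deep": ("K", "R", "L"),
    "propofol-moderate": ("K", "R", "J"),
    "propofol-deep": ("K", "R", "J"),
    "sevoflurane-moderate": ("L", "R", "J"),
    "sevoflurane-deep": ("L", "R", "J"),
}

# mean BNA level per network under each condition: network 0 (and, weaker,
# network 3) carries the awake-vs-anesthesia contrast, mirroring the kind of
# network the method is meant to surface; moderate sedation sits between
# awake and deep levels so the dosage ordering is decodable
_DEFAULT_EFFECTS = {
    "awake": (5.0, 2.0, 2.0, 4.0),
    "ketamine-deep": (1.0, 2.5, 2.0, 1.0),
    "propofol-moderate": (2.5, 2.0, 2.0, 2.5),
    "propofol-deep": (1.0, 1.5, 2.5, 1.0),
    "sevoflurane-moderate": (2.5, 2.5, 1.5, 2.5),
    "sevoflurane-deep": (1.0, 2.0, 3.0, 1.0),
}


def _default_runs_per_condition() -> dict[str, int]:
    # 156 runs over six conditions
    return {"awake": 31, "ketamine-deep": 25, "propofol-moderate": 25,
            "propofol-deep": 25, "sevoflurane-moderate": 25, "sevoflurane-deep": 25}


@dataclass
class SimulationConfig:
    p: int = 82
    k_true: int = 4
    n_subjects: int = 5
    runs_per_condition: dict[str, int] = field(default_factory=_default_runs_per_condition)
    t: int = 500
    tr_seconds: float = 2.4
    condition_effects: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS))
    bna_dispersion: float = 0.2
    noise_v_range: tuple[float, float] = (0.1, 0.3)
    coverage: float = 1.0
    seed: int = 0
    subject_sigma: float = 0.0   # sd of a per-subject multiplicative BNA factor
    ar_coeff: float = 0.0        # AR(1) coefficient for robustness tests only
    latent_offdiag: float = 0.0  # adds cross-network latent correlation

    def __post_init__(self) -> None:
        if not self.k_true < self.p:
            raise ValueError("need k_true < p")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if any(c < 1 for c in self.runs_per_condition.values()):
            raise ValueError("every condition needs at least one run")
        for cond, eff in self.condition_effects.items():
            if len(eff) != self.k_true:
                raise ValueError(f"effect vector for {cond!r} must have length k_true")
            if any(e < 0 for e in eff):
                raise ValueError("effect vectors must be non-negative")


@dataclass
class GroundTruth:
    W_true: LoadingMatrix
    G_true: list[np.ndarray]
    v_true: list[float]
    subjects: list[str]
    conditions: list[str]
    run_ids: list[str]

    def bna_matrix(self) -> np.ndarray:
        """True N-by-k table of per-run network activities (diagonals of G)."""
        return np.array([np.diag(G) for G in self.G_true])


def simulate_loading_matrix(p: int, k: int, coverage: float = 1.0,
                            seed: int = 0) -> LoadingMatrix:
    """Random disjoint-support non-negative orthonormal loading matrix.

    ``coverage`` is the fraction of ROIs assigned to some network; the rest
    get all-zero rows.  Every network receives at least one ROI.
    """
    if k >= p:
        raise ValueError("need k < p")
    n_assigned = int(round(coverage * p))
    if n_assigned < k:
        raise ValueError(f"coverage {coverage} assigns {n_assigned} ROIs < k={k} networks")
    rng = np.random.default_rng(seed)
    rows = rng.permutation(p)[:n_assigned]
    membership = np.concatenate([np.arange(k), rng.integers(0, k, size=n_assigned - k)])
    W = np.zeros((p, k))
    W[rows, membership] = rng.uniform(0.5, 1.5, size=n_assigned)
    W /= np.linalg.norm(W, axis=0)
    return LoadingMatrix(W)


def simulate_runs(config: SimulationConfig) -> tuple[list[RunTimeSeries], GroundTruth]:
    """Draw a full dataset (time series + ground truth) from the model."""
    rng = np.random.default_rng(config.seed)
    loading = simulate_loading_matrix(config.p, config.k_true, config.coverage,
                                      seed=int(rng.integers(2**31 - 1)))
    W = loading.W

    study_pool = ["A", "J", "K", "L", "R"]
    if config.n_subjects <= len(study_pool):
        subjects_pool = study_pool[:config.n_subjects]
    else:
        subjects_pool = study_pool + [f"S{i}" for i in range(config.n_subjects - len(study_pool))]
    subject_factor = {s: float(np.exp(rng.normal(0.0, config.subject_sigma)))
                      for s in subjects_pool}

    runs: list[RunTimeSeries] = []
    G_true: list[np.ndarray] = []
    v_true: list[float] = []
    subjects: list[str] = []
    conditions: list[str] = []
    run_ids: list[str] = []

    idx = 0
    for cond, count in config.runs_per_condition.items():
        effect = np.asarray(config.condition_effects[cond], dtype=float)
        allowed = [s for s in _CONDITION_SUBJECTS.get(cond, subjects_pool)
                   if s in subjects_pool] or subjects_pool
        for r in range(count):
            subject = allowed[r % len(allowed)]
            g_diag = np.maximum(
                rng.normal(effect * subject_factor[subject], config.bna_dispersion), 0.0)
            G = np.diag(g_diag)
            if config.latent_offdiag > 0:
                off = rng.normal(0.0, config.latent_offdiag,
                                 size=(config.k_true, config.k_true))
                off = (off + off.T) / 2.0
                np.fill_diagonal(off, 0.0)
                G = G + off
                lam, U = np.linalg.eigh(G)
                G = (U * np.maximum(lam, 0.0)) @ U.T
            v = float(rng.uniform(*config.noise_v_range))

            z = rng.multivariate_normal(np.zeros(config.k_true), G, size=config.t).T
            eps = rng.normal(0.0, np.sqrt(v), size=(config.p, config.t))
            X = W @ z + eps
            if config.ar_coeff:
                phi = config.ar_coeff
                for s in range(1, config.t):
                    X[:, s] = phi * X[:, s - 1] + np.sqrt(1 - phi**2) * X[:, s]

            rid = f"run{idx:03d}"
            runs.append(RunTimeSeries(X=X, subject=subject, condition=cond,
                                      tr_seconds=config.tr_seconds, run_id=rid))
            G_true.append(G)
            v_true.append(v)
            subjects.append(subject)
            conditions.append(cond)
            run_ids.append(rid)
            idx += 1

    truth = GroundTruth(W_true=loading, G_true=G_true, v_true=v_true,
                        subjects=subjects, conditions=conditions, run_ids=run_ids)
    return runs, truth


def simulate_toy_atlas(p: int, grid_extent: int = 16, seed: int = 0) -> Atlas:
    """p compact cubic ROIs placed on a regular 3D grid (identity-scaled affine)."""
    cell = 3  # 2-voxel blob plus a 1-voxel gap
    cells_per_axis = grid_extent // cell
    capacity = cells_per_axis**3
    if capacity < p:
        raise ValueError(f"grid extent {grid_extent} fits only {capacity} ROIs < p={p}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(capacity)[:p]
    labels = np.zeros((grid_extent,) * 3, dtype=np.int32)
    for j, cidx in enumerate(order):
        cx, rem = divmod(int(cidx), cells_per_axis**2)
        cy, cz = divmod(rem, cells_per_axis)
        x, y, z = cx * cell, cy * cell, cz * cell
        labels[x:x + 2, y:y + 2, z:z + 2] = j + 1
    return atlas_from_array(labels, affine=np.eye(4))
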