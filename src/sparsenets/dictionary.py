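"""Online (mini-batch) dictionary learning with unit-ball atom constraints.

The whole-brain signal matrix S (m×n) is factorized as S ≈ Dα where D is an
m×k dictionary whose columns ("atoms") are temporal activity patterns
constrained to the ℓ2 unit ball, and α is the k×n sparse coefficient matrix:

    min_{D∈C, α}  ½‖S − Dα‖_F² + λ‖α‖₁,    C = {D : ‖d_j‖₂ ≤ 1 ∀j}.

Training alternates mini-batch sparse coding with block coordinate descent
on D driven by the accumulated sufficient statistics A = Σ α_i α_iᵀ and
B = Σ s_i α_iᵀ, so one pass over the atoms minimizes the quadratic
surrogate ½tr(DᵀD A) − tr(Dᵀ B) under the unit-ball constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import InsufficientDataError, ShapeError
from .io import SignalMatrix
from .sparse_coding import lasso_objective, sparse_code_all

__all__ = [
    "Dictionary",
    "ODLConfig",
    "SurrogateStats",
    "ODLFit",
    "default_lam",
    "init_dictionary",
    "update_dictionary",
    "surrogate_value",
    "learn_dictionary",
]

#: guard against division by a vanishing A_jj in the atom update
UPDATE_EPS = 1e-12
#: atom usage below this marks the atom as dead for the epoch
DEAD_ATOM_TOL = 1e-12


@dataclass(frozen=True)
class Dictionary:
    """The m×k learned basis; each column is one network's temporal pattern."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        object.__setattr__(self, "atoms", atoms)
        if atoms.ndim != 2:
            raise ShapeError(f"atoms must be 2D, got shape {atoms.shape}")

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        return self.atoms.shape[1]

    def atom_norms(self) -> np.ndarray:
        return np.linalg.norm(self.atoms, axis=0)


@dataclass
class ODLConfig:
    """Training configuration.

    ``lam=None`` resolves to :func:`default_lam` on the training data.  The
    over-complete regime k > m, k ≪ n is the intended operating point and is
    warned about (not enforced) when violated.
    """

    k: int = 400
    lam: float | None = None
    batch_size: int = 256
    n_epochs: int = 5
    seed: int = 0
    init: str = "columns"
    track_objective: bool = True
    #: atoms more coherent than this are treated as duplicates and one is
    #: re-seeded at epoch end (None disables the check)
    max_coherence: float | None = 0.9

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.n_epochs < 0:
            raise ValueError(f"n_epochs must be >= 0, got {self.n_epochs}")
        if self.lam is not None and self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")


@dataclass
class SurrogateStats:
    """Accumulated sufficient statistics of the online algorithm."""

    A: np.ndarray  # k×k, Σ α αᵀ
    B: np.ndarray  # m×k, Σ s αᵀ
    t: int = 0  # samples seen

    @classmethod
    def zeros(cls, m: int, k: int) -> "SurrogateStats":
        return cls(A=np.zeros((k, k)), B=np.zeros((m, k)), t=0)

    def accumulate(self, batch: np.ndarray, codes: np.ndarray) -> None:
        self.A += codes @ codes.T
        self.B += batch @ codes.T
        self.t += batch.shape[1]


@dataclass
class ODLFit:
    """Outcome of a training run; unpacks as ``(dictionary, coefficients)``."""

    dictionary: Dictionary
    coefficients: np.ndarray
    lam: float
    objective: float
    epoch_objectives: list[float] = field(default_factory=list)
    sampled_indices: np.ndarray | None = None

    def __iter__(self):
        yield self.dictionary
        yield self.coefficients


def default_lam(S) -> float:
    """Dimension-aware sparsity weight: median column norm divided by √m."""
    data = S.data if isinstance(S, SignalMatrix) else np.asarray(S, dtype=float)
    m = data.shape[0]
    return float(np.median(np.linalg.norm(data, axis=0)) / np.sqrt(m))


def _as_data(S) -> np.ndarray:
    return S.data if isinstance(S, SignalMatrix) else np.asarray(S, dtype=float)


def init_dictionary(S, k: int, seed: int = 0) -> Dictionary:
    """Initialize atoms as k distinct data columns projected to the unit ball."""
    data = _as_data(S)
    n = data.shape[1]
    if n < k:
        raise InsufficientDataError(f"need at least k={k} columns, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    atoms = data[:, idx].copy()
    norms = np.linalg.norm(atoms, axis=0)
    atoms /= np.maximum(norms, 1.0)
    return Dictionary(atoms=atoms)


def surrogate_value(D: Dictionary | np.ndarray, stats: SurrogateStats) -> float:
    """Quadratic surrogate ½tr(DᵀDA) − tr(DᵀB) (constant terms omitted)."""
    atoms = getattr(D, "atoms", D)
    return float(0.5 * np.sum((atoms @ stats.A) * atoms) - np.sum(atoms * stats.B))


def update_dictionary(D: Dictionary, stats: SurrogateStats) -> Dictionary:
    """One block-coordinate-descent pass over the atoms.

    For atom j:  u_j = (b_j − D a_j) / max(A_jj, ε) + d_j, then project
    u_j onto the unit ball.  Atoms with A_jj = 0 have b_j = D a_j = 0 and
    are left unchanged.  The surrogate objective never increases.
    """
    if stats.t < 1:
        raise ValueError("cannot update dictionary before any samples are seen")
    if not (np.isfinite(stats.A).all() and np.isfinite(stats.B).all()):
        raise ValueError("non-finite surrogate statistics")
    atoms = getattr(D, "atoms", D).copy()
    A, B = stats.A, stats.B
    k = atoms.shape[1]
    for j in range(k):
        ajj = A[j, j]
        if ajj <= DEAD_ATOM_TOL:
            continue
        u = (B[:, j] - atoms @ A[:, j]) / max(ajj, UPDATE_EPS) + atoms[:, j]
        atoms[:, j] = u / max(1.0, np.linalg.norm(u))
    return Dictionary(atoms=atoms)


def _find_duplicate_atoms(
    atoms: np.ndarray, stats: SurrogateStats, max_coherence: float
) -> np.ndarray:
    """Indices of atoms too coherent with a better-used atom.

    For every pair with |cosine| above ``max_coherence`` the atom with the
    smaller accumulated usage A_jj loses.  Near-duplicate atoms split the
    coefficient mass of one network over several rows, diluting its spatial
    map, so one of each pair is re-seeded.
    """
    norms = np.linalg.norm(atoms, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = atoms / safe
    gram = np.abs(unit.T @ unit)
    np.fill_diagonal(gram, 0.0)
    usage = np.diag(stats.A)
    k = atoms.shape[1]
    losers = set()
    for j in range(k):
        if j in losers:
            continue
        for i in range(j + 1, k):
            if i in losers or gram[i, j] <= max_coherence:
                continue
            losers.add(i if usage[i] <= usage[j] else j)
    return np.array(sorted(losers), dtype=int)


def _reseed_atoms(
    atoms: np.ndarray,
    targets: np.ndarray,
    batch: np.ndarray,
    codes: np.ndarray,
    stats: SurrogateStats,
) -> np.ndarray:
    """Replace the given atoms by the batch's worst-reconstructed signals."""
    if targets.size == 0:
        return atoms
    errors = np.sum((batch - atoms @ codes) ** 2, axis=0)
    order = np.argsort(errors)[::-1]
    for rank, j in enumerate(targets):
        col = batch[:, order[rank % len(order)]]
        norm = np.linalg.norm(col)
        if norm <= 0:
            continue
        atoms[:, j] = col / norm
        stats.A[j, :] = 0.0
        stats.A[:, j] = 0.0
        stats.B[:, j] = 0.0
    return atoms


def learn_dictionary(
    S,
    cfg: ODLConfig,
    callback: Callable[[Dictionary], None] | None = None,
) -> ODLFit:
    """Train the dictionary by mini-batch online learning.

    Each epoch visits the columns of S in a seeded shuffled order; every
    mini-batch is sparse-coded against the current dictionary, the surrogate
    statistics are accumulated, and the atoms are updated under the
    unit-ball constraint.  Atoms never used during an epoch are replaced by
    the worst-reconstructed signals of the epoch's final batch.  The final
    coefficient matrix is a full sparse coding of S against the trained
    dictionary.  Fixed seed ⇒ bitwise-reproducible trajectory.

    ``callback(D)`` — if given — is invoked after every dictionary update.
    """
    data = _as_data(S)
    m, n = data.shape
    if cfg.k <= m or cfg.k * 10 > n:
        warnings.warn(
            f"k={cfg.k} is outside the recommended over-complete regime "
            f"(k > m={m} and k << n={n})",
            stacklevel=2,
        )
    lam = default_lam(data) if cfg.lam is None else float(cfg.lam)
    D = init_dictionary(data, cfg.k, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    stats = SurrogateStats.zeros(m, cfg.k)
    epoch_objectives: list[float] = []
    alpha: np.ndarray | None = None

    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        used = np.zeros(cfg.k, dtype=bool)
        batch = codes = None
        for start in range(0, n, cfg.batch_size):
            batch = data[:, order[start : start + cfg.batch_size]]
            codes = sparse_code_all(batch, D, lam)
            used |= np.abs(codes).max(axis=1) > DEAD_ATOM_TOL
            stats.accumulate(batch, codes)
            D = update_dictionary(D, stats)
            if callback is not None:
                callback(D)
        if batch is not None:
            # epoch-end maintenance: re-seed dead atoms, then duplicates
            targets = list(np.flatnonzero(~used))
            if cfg.max_coherence is not None:
                dup = _find_duplicate_atoms(D.atoms, stats, cfg.max_coherence)
                targets += [j for j in dup if j not in targets]
            atoms = _reseed_atoms(
                D.atoms.copy(), np.array(targets, dtype=int), batch, codes, stats
            )
            D = Dictionary(atoms=atoms)
        if cfg.track_objective or epoch == cfg.n_epochs - 1:
            alpha = sparse_code_all(data, D, lam)
            if cfg.track_objective:
                epoch_objectives.append(lasso_objective(data, D.atoms, alpha, lam))
    if alpha is None:  # n_epochs == 0: codes of the initial dictionary
        alpha = sparse_code_all(data, D, lam)
    objective = lasso_objective(data, D.atoms, alpha, lam)
    return ODLFit(
        dictionary=D,
        coefficients=alpha,
        lam=lam,
        objective=objective,
        epoch_objectives=epoch_objectives,
    )
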