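"""Voxel-sampling speedup for dictionary training.

Training cost scales with the number of voxel columns, but the temporal
patterns of large functional networks are carried by many voxels each, so a
random subset of columns suffices to learn the dictionary.  The speedup
trains on a sampled subset and then sparse-codes *all* voxels against the
learned dictionary, so the spatial maps still cover the whole brain.
``ratio = 1`` reduces exactly (bitwise) to plain training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .errors import InsufficientDataError
from .dictionary import ODLConfig, ODLFit, default_lam, learn_dictionary
from .io import SignalMatrix
from .sparse_coding import lasso_objective, sparse_code_all

__all__ = ["SamplingConfig", "sample_columns", "learn_dictionary_sampled"]


@dataclass(frozen=True)
class SamplingConfig:
    """Fraction of voxel columns used for dictionary training."""

    ratio: float = 0.25
    seed: int = 0
    strategy: str = "uniform"

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError(f"ratio must be in (0, 1], got {self.ratio}")
        if self.strategy != "uniform":
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")


def sample_columns(S, cfg: SamplingConfig, min_columns: int = 1):
    """Uniform random subset of columns without replacement.

    Returns ``(subset, indices)`` where ``indices`` maps subset columns back
    to the original column positions (sorted ascending).  ``ratio = 1``
    returns the identity subset.
    """
    is_sm = isinstance(S, SignalMatrix)
    data = S.data if is_sm else np.asarray(S, dtype=float)
    n = data.shape[1]
    if cfg.ratio == 1.0:
        return S, np.arange(n)
    size = int(round(cfg.ratio * n))
    if size < min_columns:
        raise InsufficientDataError(
            f"sampling {size} of {n} columns is below the required {min_columns}"
        )
    rng = np.random.default_rng(cfg.seed)
    indices = np.sort(rng.choice(n, size=size, replace=False))
    if is_sm:
        subset = _dc_replace(
            S, data=data[:, indices].copy(), voxel_index=S.voxel_index[indices]
        )
    else:
        subset = data[:, indices].copy()
    return subset, indices


def learn_dictionary_sampled(
    S, odl_cfg: ODLConfig, s_cfg: SamplingConfig, callback=None
) -> ODLFit:
    """Train on a column subset, then sparse-code the full signal matrix.

    λ is resolved on the full matrix so that sampled and unsampled runs
    solve the same coding problem.  With ``ratio = 1`` the result is
    bitwise-identical to :func:`learn_dictionary`.
    """
    subset, indices = sample_columns(S, s_cfg, min_columns=odl_cfg.k)
    lam = default_lam(S) if odl_cfg.lam is None else float(odl_cfg.lam)
    cfg = _dc_replace_cfg(odl_cfg, lam)
    fit = learn_dictionary(subset, cfg, callback=callback)
    if s_cfg.ratio == 1.0:
        fit.sampled_indices = indices
        return fit
    alpha = sparse_code_all(S, fit.dictionary, lam)
    data = S.data if isinstance(S, SignalMatrix) else np.asarray(S, dtype=float)
    return ODLFit(
        dictionary=fit.dictionary,
        coefficients=alpha,
        lam=lam,
        objective=lasso_objective(data, fit.dictionary.atoms, alpha, lam),
        epoch_objectives=fit.epoch_objectives,
        sampled_indices=indices,
    )


def _dc_replace_cfg(cfg: ODLConfig, lam: float) -> ODLConfig:
    out = ODLConfig(
        k=cfg.k,
        lam=lam,
        batch_size=cfg.batch_size,
        n_epochs=cfg.n_epochs,
        seed=cfg.seed,
        init=cfg.init,
        track_objective=cfg.track_objective,
    )
    return out
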