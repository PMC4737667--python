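"""Model/Results interface over the decomposition.

``SparseNetworkModel`` holds the (normalized) whole-brain signal matrix and
the decomposition settings; ``fit()`` runs online dictionary learning —
optionally on a voxel subsample — and returns a ``SparseNetworkResults``
carrying the dictionary, the sparse coefficient matrix, per-epoch
objectives, the reconstructed network components, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dictionary import ODLConfig, ODLFit, learn_dictionary
from .io import SignalMatrix, load_fmri, normalize_signals, save_volume
from .mapping import DEFAULT_Z_THRESH, NetworkComponent, build_components, component_summary
from .matching import MatchResult, TemplateSet, match_components
from .sampling import SamplingConfig, learn_dictionary_sampled

__all__ = ["SparseNetworkModel", "SparseNetworkResults"]


class SparseNetworkModel:
    """Sparse dictionary decomposition of a whole-brain signal matrix.

    Parameters
    ----------
    signals : SignalMatrix
        The m×n data matrix (time points × voxels).
    k : int
        Number of dictionary atoms (candidate networks).
    lam : float, optional
        ℓ1 sparsity weight; defaults to median column norm / √m.
    sampling_ratio : float
        Fraction of voxel columns used for dictionary training; 1.0 trains
        on every voxel.  The final coefficients always cover all voxels.
    normalize : bool
        Detrend + standardize voxel time series before fitting.
    """

    def __init__(
        self,
        signals: SignalMatrix,
        k: int = 400,
        lam: float | None = None,
        batch_size: int = 256,
        n_epochs: int = 5,
        sampling_ratio: float = 1.0,
        normalize: bool = True,
        track_objective: bool = True,
    ) -> None:
        self.signals = normalize_signals(signals) if normalize else signals
        self.k = k
        self.lam = lam
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.sampling_ratio = sampling_ratio
        self.track_objective = track_objective

    @classmethod
    def from_nifti(
        cls, bold_path: str | Path, mask_path: str | Path, **kwargs
    ) -> "SparseNetworkModel":
        """Build the model straight from a 4D BOLD image and a brain mask."""
        return cls(load_fmri(bold_path, mask_path), **kwargs)

    def fit(self, seed: int = 0, callback=None) -> "SparseNetworkResults":
        cfg = ODLConfig(
            k=self.k,
            lam=self.lam,
            batch_size=self.batch_size,
            n_epochs=self.n_epochs,
            seed=seed,
            track_objective=self.track_objective,
        )
        if self.sampling_ratio < 1.0:
            fit = learn_dictionary_sampled(
                self.signals,
                cfg,
                SamplingConfig(ratio=self.sampling_ratio, seed=seed),
                callback=callback,
            )
        else:
            fit = learn_dictionary(self.signals, cfg, callback=callback)
        return SparseNetworkResults(model=self, fit=fit, seed=seed)


@dataclass
class SparseNetworkResults:
    """Fitted decomposition: D, α, objectives, spatial maps, matching."""

    model: SparseNetworkModel
    fit: ODLFit
    seed: int
    _components: dict = field(default_factory=dict, repr=False)

    @property
    def dictionary(self):
        return self.fit.dictionary

    @property
    def coefficients(self) -> np.ndarray:
        return self.fit.coefficients

    @property
    def lam(self) -> float:
        return self.fit.lam

    @property
    def objective(self) -> float:
        return self.fit.objective

    @property
    def epoch_objectives(self) -> list[float]:
        return self.fit.epoch_objectives

    def components(self, z_thresh: float = DEFAULT_Z_THRESH) -> list[NetworkComponent]:
        """Reconstructed spatial maps, one per atom (cached per threshold)."""
        key = float(z_thresh)
        if key not in self._components:
            s = self.model.signals
            self._components[key] = build_components(
                self.dictionary, self.coefficients, s.mask, s.voxel_index, z_thresh
            )
        return self._components[key]

    def component_table(self, z_thresh: float = DEFAULT_Z_THRESH):
        return component_summary(self.components(z_thresh))

    def match(
        self,
        templates: TemplateSet,
        z_thresh: float = DEFAULT_Z_THRESH,
        min_overlap: float = 0.05,
        method: str = "jaccard",
    ) -> MatchResult:
        """Assign components to resting-state-network templates."""
        return match_components(
            self.components(z_thresh), templates, min_overlap=min_overlap, method=method
        )

    def save_maps(
        self, outdir: str | Path, z_thresh: float = DEFAULT_Z_THRESH
    ) -> list[Path]:
        """Write each component's z-map and binary map as NIfTI."""
        outdir = Path(outdir)
        mask = self.model.signals.mask
        width = max(3, len(str(self.dictionary.k - 1)))
        paths = []
        for c in self.components(z_thresh):
            base = f"component_{c.index:0{width}d}"
            paths.append(save_volume(c.z_map, mask, outdir / f"{base}_z.nii.gz"))
            paths.append(
                save_volume(
                    c.binary_map.astype(np.uint8),
                    mask,
                    outdir / f"{base}_bin.nii.gz",
                    dtype=np.uint8,
                )
            )
        return paths

    def summary(self) -> str:
        s = self.model.signals
        comps = self.components()
        nnz = np.count_nonzero(np.abs(self.coefficients) > 1e-10)
        lines = [
            "Sparse network decomposition",
            "=" * 44,
            f"{'Time points (m)':<28}{s.n_timepoints:>16}",
            f"{'Voxels (n)':<28}{s.n_voxels:>16}",
            f"{'Atoms (k)':<28}{self.dictionary.k:>16}",
            f"{'Sparsity weight λ':<28}{self.lam:>16.6g}",
            f"{'Epochs':<28}{self.model.n_epochs:>16}",
            f"{'Batch size':<28}{self.model.batch_size:>16}",
            f"{'Sampling ratio':<28}{self.model.sampling_ratio:>16.2f}",
            f"{'Seed':<28}{self.seed:>16}",
            f"{'Final objective':<28}{self.objective:>16.6g}",
            f"{'Mean nonzeros per voxel':<28}{nnz / s.n_voxels:>16.3f}",
            f"{'Non-empty components':<28}{sum(c.n_active > 0 for c in comps):>16}",
            "=" * 44,
        ]
        return "\n".join(lines)
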