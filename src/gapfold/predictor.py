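"""Backend contract for structure prediction plus a deterministic mock.

The pipeline never talks to a neural network directly: it hands a
:class:`PredictionRequest` to a backend and receives
:class:`PredictionResult` objects whose distograms are validated at this
boundary (symmetry, normalization) rather than trusted.  The mock
backend fabricates outputs consistent with a known ground-truth complex
so the full pipeline is testable without GPUs or weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.stats import norm

from gapfold.msa_engine import MergedMSA
from gapfold.structures_io import Complex
from gapfold.template_engine import MergedTarget, TemplateFeatures

logger = logging.getLogger(__name__)

DEFAULT_MODEL_IDS = (1, 3)

# Conventional distogram binning: 64 bins over 2.3125-21.6875 Å with
# open outer bins.  Carried explicitly in every Distogram so downstream
# integration never assumes it.
AF2_BIN_EDGES = np.linspace(2.3125, 21.6875, 63)


class BackendUnavailableError(RuntimeError):
    """Raised when the requested backend cannot run in this environment."""


@dataclass
class PredictionRequest:
    merged: MergedTarget
    msa: MergedMSA
    template_features: TemplateFeatures | None
    model_ids: list[int] = field(default_factory=lambda: list(DEFAULT_MODEL_IDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.model_ids:
            raise ValueError("model_ids must be non-empty")
        if any(m < 1 or m > 5 for m in self.model_ids):
            raise ValueError(f"model_ids must be in 1..5, got {self.model_ids}")


@dataclass
class Distogram:
    """Per-pair probability distribution over binned distances.

    ``bin_edges`` are the interior edges (first bin open below, last
    open above), so there are ``len(bin_edges) + 1`` bins.
    """

    bin_edges: np.ndarray  # (n_edges,) increasing, Å
    probs: np.ndarray  # (L, L, n_edges + 1)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.probs.ndim != 3 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("probs must have shape (L, L, n_bins)")
        if self.probs.shape[2] != len(self.bin_edges) + 1:
            raise ValueError("probs bin dimension must equal len(bin_edges) + 1")

    @property
    def n_positions(self) -> int:
        return self.probs.shape[0]

    def validate(self, atol: float = 1e-6) -> None:
        if np.any(self.probs < -atol):
            raise ValueError("distogram contains negative probabilities")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("distogram rows must sum to 1")
        if not np.allclose(self.probs, self.probs.transpose(1, 0, 2), atol=atol):
            raise ValueError("distogram must be symmetric in its position axes")


@dataclass
class PredictionResult:
    coords: dict[str, np.ndarray]  # atom name -> (L, 3); at least CA and CB
    distogram: Distogram
    ptm: float
    model_id: int
    relaxed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ptm <= 1.0:
            raise ValueError(f"ptm must be in [0, 1], got {self.ptm}")
        if "CA" not in self.coords or "CB" not in self.coords:
            raise ValueError("coords must contain CA and CB arrays")


@runtime_checkable
class Backend(Protocol):
    """Anything that turns a PredictionRequest into PredictionResults."""

    name: str

    def run(self, request: PredictionRequest) -> list[PredictionResult]: ...

    def metadata(self) -> dict: ...


def predict(request: PredictionRequest, backend: Backend) -> list[PredictionResult]:
    """Run the backend and validate its outputs at the contract boundary."""
    results = backend.run(request)
    if len(results) != len(request.model_ids):
        raise ValueError(
            f"backend returned {len(results)} results for "
            f"{len(request.model_ids)} requested models"
        )
    n = len(request.merged)
    for result in results:
        result.distogram.validate()
        for name, arr in result.coords.items():
            if arr.shape != (n, 3):
                raise ValueError(
                    f"model {result.model_id}: {name} coords shape {arr.shape}, "
                    f"expected ({n}, 3)"
                )
            if np.isnan(arr).any():
                raise ValueError(f"model {result.model_id}: NaN in {name} coords")
    return results


class MockBackend:
    """Deterministic fake backend built from a ground-truth complex.

    Coordinates are the truth coordinates (plus optional Gaussian noise)
    mapped through the merge layout; the distogram concentrates mass in
    the bin containing each (possibly noisy) pairwise distance, spread
    over neighbouring bins when ``noise_scale > 0``.  The reported pTM
    is fixed.  Bin edges are chosen so common contact cutoffs (8 Å)
    fall exactly on an edge, making zero-noise contact integration
    exact.
    """

    name = "mock"

    def __init__(
        self,
        truth: Complex,
        noise_scale: float = 0.0,
        ptm_value: float = 0.9,
        bin_width: float = 0.25,
        max_edge: float = 24.0,
    ) -> None:
        if noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 <= ptm_value <= 1.0:
            raise ValueError("ptm_value must be in [0, 1]")
        self.truth = truth
        self.noise_scale = float(noise_scale)
        self.ptm_value = float(ptm_value)
        self.bin_edges = np.arange(bin_width, max_edge + bin_width / 2, bin_width)

    def metadata(self) -> dict:
        return {
            "backend": self.name,
            "noise_scale": self.noise_scale,
            "ptm_value": self.ptm_value,
            "n_bin_edges": int(len(self.bin_edges)),
        }

    def _truth_order(self, merged: MergedTarget) -> list[int]:
        """Match truth chains to merged chains by exact sequence, in order."""
        remaining = list(range(len(self.truth.chains)))
        order: list[int] = []
        for k in range(merged.n_chains):
            target_seq = merged.sequence[merged.chain_slice(k)]
            for idx in remaining:
                if self.truth.chains[idx].sequence == target_seq:
                    order.append(idx)
                    remaining.remove(idx)
                    break
            else:
                raise ValueError(
                    f"mock backend: no truth chain matches merged chain {k} "
                    f"(sequence {target_seq[:12]}...)"
                )
        return order

    def _distogram(self, cb: np.ndarray) -> Distogram:
        dist = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
        edges = self.bin_edges
        n_bins = len(edges) + 1
        if self.noise_scale == 0.0:
            idx = np.searchsorted(edges, dist, side="right")
            probs = np.zeros(dist.shape + (n_bins,))
            flat = probs.reshape(-1, n_bins)
            flat[np.arange(flat.shape[0]), idx.ravel()] = 1.0
        else:
            # discretized Gaussian around each distance
            cdf = norm.cdf(edges[None, None, :], loc=dist[:, :, None], scale=self.noise_scale)
            probs = np.concatenate(
                [cdf[..., :1], np.diff(cdf, axis=-1), 1.0 - cdf[..., -1:]], axis=-1
            )
        probs = 0.5 * (probs + probs.transpose(1, 0, 2))  # enforce exact symmetry
        return Distogram(bin_edges=edges, probs=probs)

    def run(self, request: PredictionRequest) -> list[PredictionResult]:
        merged = request.merged
        order = self._truth_order(merged)
        cb_true = np.concatenate([self.truth.chains[i].cb_coords for i in order])
        ca_true = np.concatenate([self.truth.chains[i].ca_coords for i in order])
        results = []
        for model_id in request.model_ids:
            rng = np.random.default_rng([request.seed, model_id])
            if self.noise_scale > 0:
                cb = cb_true + rng.normal(scale=self.noise_scale, size=cb_true.shape)
                ca = ca_true + rng.normal(scale=self.noise_scale, size=ca_true.shape)
            else:
                cb = cb_true.copy()
                ca = ca_true.copy()
            results.append(
                PredictionResult(
                    coords={"CA": ca, "CB": cb},
                    distogram=self._distogram(cb),
                    ptm=self.ptm_value,
                    model_id=model_id,
                )
            )
        return results


def mock_backend_from_truth(
    truth: Complex, noise_scale: float = 0.0, ptm_value: float = 0.9
) -> MockBackend:
    """Convenience constructor mirroring the backend factory contract."""
    return MockBackend(truth, noise_scale=noise_scale, ptm_value=ptm_value)


class AlphaFold2Adapter:
    """Adapter stub for a real AlphaFold2 installation (optional).

    Passes the merged pseudo-chain as a monomeric target with unmasked
    template features to an external AF2 install.  Not exercised by the
    test surface; raises a clear error when the installation is absent.
    """

    name = "alphafold2"

    def __init__(self, installation_path: str | None = None) -> None:
        self.installation_path = installation_path

    def metadata(self) -> dict:
        return {"backend": self.name, "installation_path": self.installation_path}

    def run(self, request: PredictionRequest) -> list[PredictionResult]:
        raise BackendUnavailableError(
            "No AlphaFold2 installation is configured. Point the backend at an "
            "existing AF2 install (models 1 and 3 with template inputs) or use "
            "the mock backend for offline runs."
        )
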