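"""Spatial kinematic synergy extraction by principal component analysis.

The source matrix X (channels x concatenated averaged movements) is
modeled as X = W C + residual, with W the spatial synergy loadings
(orthonormal columns) and C the time-varying activation signals.  PCA
yields, for every rank N, the factorization minimizing the Frobenius
reconstruction error (Eckart-Young).  Row means are removed before the
decomposition and restored on reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._common import CHANNELS
from .preprocessing import SourceMatrix

__all__ = [
    "SynergyDecomposition",
    "extract",
    "select_components",
    "reconstruct",
    "reconstruction_error",
    "project",
    "save_decomposition",
    "load_decomposition",
]


@dataclass
class SynergyDecomposition:
    """PCA factorization of a source matrix.

    ``loadings`` (j x N) holds unit-norm, orthogonal spatial patterns,
    sign-fixed so the largest-magnitude entry of each column is
    positive; ``activations`` (N x samples) the corresponding signals;
    ``variance_fraction`` the per-component share of total variance
    (descending); ``n_retained`` the number of components selected by
    the explained-variance rule.
    """

    loadings: np.ndarray
    activations: np.ndarray
    channel_means: np.ndarray
    variance_fraction: np.ndarray
    n_retained: int
    channel_names: tuple[str, ...] = CHANNELS

    @property
    def W(self) -> np.ndarray:
        """Retained loadings (j x n_retained)."""
        return self.loadings[:, : self.n_retained]

    @property
    def C(self) -> np.ndarray:
        """Retained activation signals (n_retained x samples)."""
        return self.activations[: self.n_retained]


def _fix_signs(w: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-positive sign convention (fallback: largest-entry positive).

    A smooth functional of the loadings keeps the convention stable
    across runs, libraries and small data perturbations, which is what
    makes one subject's synergy matrix usable with another subject's
    trained decoder.
    """
    for k in range(w.shape[1]):
        col = w[:, k]
        total = col.sum()
        anchor = total if abs(total) > 1e-8 else col[np.argmax(np.abs(col))]
        if anchor < 0:
            w[:, k] = -col
            c[k] = -c[k]
    return w, c


def extract(
    source: SourceMatrix | np.ndarray,
    n_components: int | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> SynergyDecomposition:
    """Decompose a source matrix into spatial synergies and activations.

    Accepts either a :class:`SourceMatrix` or a raw (j x samples) array.
    The thin SVD of the row-centered matrix gives the eigenvectors of
    the channel covariance (loadings) and the activation signals
    C = W^T (X - means).  ``n_components`` defaults to all j components;
    ``n_retained`` is initialized to ``n_components`` and may be
    tightened afterwards with :func:`select_components`.
    """
    x = source.values if isinstance(source, SourceMatrix) else np.asarray(source, float)
    j, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("source must have at least 2 columns")
    if n_components is None:
        n_components = j
    if not 1 <= n_components <= j:
        raise ValueError(f"n_components must be in [1, {j}], got {n_components}")
    if channel_names is None:
        channel_names = (
            source.normalization.channel_names
            if isinstance(source, SourceMatrix)
            else tuple(f"ch{i}" for i in range(j))
        )

    means = x.mean(axis=1)
    xc = x - means[:, None]
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("source matrix has zero variance")
    variance_fraction = s**2 / total
    w = u[:, :n_components]
    c = w.T @ xc
    w, c = _fix_signs(w, c)
    return SynergyDecomposition(
        loadings=w,
        activations=c,
        channel_means=means,
        variance_fraction=variance_fraction[:n_components],
        n_retained=n_components,
        channel_names=tuple(channel_names),
    )


def select_components(
    decomp: SynergyDecomposition, threshold: float = 0.85
) -> int:
    """Smallest N whose cumulative variance fraction strictly exceeds
    ``threshold`` (the "at least >85%" retention rule)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cumulative = np.cumsum(decomp.variance_fraction)
    above = np.flatnonzero(cumulative > threshold + 1e-12)
    if above.size == 0:
        return len(decomp.variance_fraction)
    return int(above[0]) + 1


def reconstruct(
    w: np.ndarray,
    c: np.ndarray,
    channel_means: np.ndarray,
    rows: slice | np.ndarray | None = None,
) -> np.ndarray:
    """means + W C for the requested channel rows (default all)."""
    w = np.atleast_2d(np.asarray(w, float))
    c = np.atleast_2d(np.asarray(c, float))
    if w.shape[1] != c.shape[0]:
        raise ValueError(f"W has {w.shape[1]} components but C has {c.shape[0]} rows")
    channel_means = np.asarray(channel_means, float)
    if rows is not None:
        w = w[rows]
        channel_means = channel_means[rows]
    return channel_means[:, None] + w @ c


def reconstruction_error(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Frobenius norm of the residual X - X_hat."""
    x = np.asarray(x, float)
    x_hat = np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.linalg.norm(x - x_hat, "fro"))


def project(
    signals: np.ndarray, decomp: SynergyDecomposition, n_components: int | None = None
) -> np.ndarray:
    """Least-squares activation signals for new data given the loadings.

    C = W^T (X - means), restricted to the retained components (or the
    first ``n_components``).  Applied to the training source matrix this
    reproduces the stored activations exactly.
    """
    signals = np.asarray(signals, float)
    if signals.shape[0] != decomp.loadings.shape[0]:
        raise ValueError(
            f"signals have {signals.shape[0]} rows, expected {decomp.loadings.shape[0]}"
        )
    n = decomp.n_retained if n_components is None else n_components
    w = decomp.loadings[:, :n]
    return w.T @ (signals - decomp.channel_means[:, None])


def save_decomposition(decomp: SynergyDecomposition, path: str | Path) -> None:
    """Serialize a decomposition as JSON (matrices plus metadata), so a
    subject's synergy matrix can be shipped independently of any model."""
    payload = {
        "channel_names": list(decomp.channel_names),
        "loadings": decomp.loadings.tolist(),
        "activations": decomp.activations.tolist(),
        "channel_means": decomp.channel_means.tolist(),
        "variance_fraction": decomp.variance_fraction.tolist(),
        "n_retained": int(decomp.n_retained),
    }
    Path(path).write_text(json.dumps(payload))


def load_decomposition(path: str | Path) -> SynergyDecomposition:
    payload = json.loads(Path(path).read_text())
    return SynergyDecomposition(
        loadings=np.array(payload["loadings"]),
        activations=np.array(payload["activations"]),
        channel_means=np.array(payload["channel_means"]),
        variance_fraction=np.array(payload["variance_fraction"]),
        n_retained=payload["n_retained"],
        channel_names=tuple(payload["channel_names"]),
    )
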