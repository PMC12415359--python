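"""Genomic relationship matrices G = M M^T / m from standardized codings.

With columns standardized by their theoretical HWE moments, each column has
(population) unit variance, so the mean diagonal of G tends to 1 and the
mean off-diagonal to 0 for unrelated HWE individuals as the marker count m
grows.  The same construction applied to the additive coding gives G_A and
to each dominance coding its dominance GRM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encodings import StandardizedMatrix

__all__ = ["GRM", "build_grm", "grm_diagnostics", "save_grm", "load_grm"]


@dataclass
class GRM:
    """Symmetric n x n relationship matrix tagged with its encoding."""

    matrix: np.ndarray
    encoding: str
    n_markers: int

    def __post_init__(self):
        G = np.asarray(self.matrix, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.matrix = G

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_grm(M: StandardizedMatrix) -> GRM:
    """G = M M^T / m for a standardized coding matrix."""
    if not isinstance(M, StandardizedMatrix):
        raise TypeError("build_grm expects a StandardizedMatrix")
    vals = M.values
    m = vals.shape[1]
    if m < 1:
        raise ValueError("need at least one marker")
    G = vals @ vals.T / m
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GRM(G, M.encoding, m)


def grm_diagnostics(G: GRM) -> dict:
    """Summary statistics: mean diagonal/off-diagonal, eigenvalue range."""
    A = G.matrix if isinstance(G, GRM) else np.asarray(G, float)
    n = A.shape[0]
    diag = np.diag(A)
    off_sum = A.sum() - diag.sum()
    eig = np.linalg.eigvalsh(A)
    return {
        "n": n,
        "mean_diag": float(diag.mean()),
        "mean_offdiag": float(off_sum / (n * (n - 1))) if n > 1 else 0.0,
        "min_eigenvalue": float(eig[0]),
        "max_eigenvalue": float(eig[-1]),
        "condition": float(eig[-1] / eig[0]) if eig[0] > 0 else np.inf,
    }


def save_grm(G: GRM, path, sample_ids=None) -> None:
    """Whitespace-delimited square matrix with an ID header line."""
    ids = (
        [str(s) for s in sample_ids]
        if sample_ids is not None
        else [f"I{i}" for i in range(G.n)]
    )
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        np.savetxt(fh, G.matrix, fmt="%.10g")


def load_grm(path, encoding: str = "unknown", n_markers: int = 0):
    """Read a matrix written by :func:`save_grm`; returns (GRM, ids)."""
    with open(path) as fh:
        ids = fh.readline().split()
        A = np.loadtxt(fh)
    A = np.atleast_2d(A)
    if A.shape != (len(ids), len(ids)):
        raise ValueError("GRM file dimensions do not match its header")
    return GRM(A, encoding, n_markers), ids
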