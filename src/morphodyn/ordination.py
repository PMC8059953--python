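"""Morphospace construction: tangent projection, PCA, and axis selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import AlignedShapes


@dataclass
class Ordination:
    """PCA morphospace of Procrustes-aligned shapes.

    ``scores[i, j]`` is taxon i's score on axis j; ``loadings[:, j]`` is the
    orthonormal axis vector in (tangent-projected) coordinate space.
    """

    taxa: list[str]
    scores: np.ndarray       # (n, r)
    eigenvalues: np.ndarray  # (r,) non-increasing
    var_prop: np.ndarray     # eigenvalue / sum(eigenvalues)
    mean_shape: np.ndarray   # (k, 2) consensus
    loadings: np.ndarray     # (2k, r)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.taxa, columns=cols)

    def scores_for(self, taxa: list[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa]
        return self.scores[idx]


def principal_components(aligned: AlignedShapes, tangent: bool = True) -> Ordination:
    """PCA of vectorized aligned coordinates about the consensus.

    With ``tangent=True`` (default) each aligned configuration is first
    orthogonally projected onto the tangent space at the consensus (the
    component along the unit consensus vector is removed), the standard
    linearisation of Kendall shape space.  Axes are ordered by non-increasing
    eigenvalue; the sign of each axis is fixed so that its largest-magnitude
    loading is positive.
    """
    n = aligned.n
    if n < 3:
        raise ValueError("PCA needs at least 3 taxa")
    x = aligned.as_matrix().astype(float)           # (n, 2k)
    consensus = aligned.mean_shape.reshape(-1)
    if tangent:
        c = consensus / np.linalg.norm(consensus)
        x = x - np.outer(x @ c, c)
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s ** 2 / (n - 1)
    r = min(n - 1, centered.shape[1])
    eig = eig[:r]
    vt = vt[:r]
    scores = centered @ vt.T
    # deterministic sign convention
    for j in range(r):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
            scores[:, j] = -scores[:, j]
    total = eig.sum()
    var_prop = eig / total if total > 0 else np.zeros_like(eig)
    return Ordination(taxa=list(aligned.taxa), scores=scores, eigenvalues=eig,
                      var_prop=var_prop, mean_shape=aligned.mean_shape.copy(),
                      loadings=vt.T)


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading axes whose variance share exceeds the broken-stick
    expectation.

    For p eigenvalues, the expected share of the i-th largest segment of a
    randomly broken stick is ``(1/p) * sum_{m=i..p} 1/m``.  Axes are retained
    while the observed proportion strictly exceeds this expectation, stopping
    at the first failure.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(eig < 0) or eig.sum() <= 0:
        raise ValueError("eigenvalues must be non-negative and not all zero")
    p = eig.size
    obs = eig / eig.sum()
    harmonic = np.cumsum(1.0 / np.arange(p, 0, -1))[::-1]  # sum_{m=i..p} 1/m
    expect = harmonic / p
    count = 0
    for i in range(p):
        if obs[i] > expect[i]:
            count += 1
        else:
            break
    return count
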