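"""PCA over colour spectra and sign-aligned PC1 scores.

One PCA per HSV channel, on the covariance of individuals' spectra (bins
share frequency units, so no per-bin rescaling).  The first component
summarises inter-individual colour variation; its sign is aligned so the
score has a fixed biological reading: for hue, positive scores mean more
mass in the green interval; for saturation and value, scores increase with
the individual's mean channel level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import CHANNELS, ColourSpectrum

__all__ = [
    "GREEN_HUE_INTERVAL",
    "SpectrumMatrix",
    "PCAResult",
    "spectra_to_matrix",
    "fit_pca",
    "align_pc1_sign",
    "score_pc1",
]

# hue interval (degrees) used to orient the hue PC1: green vs orange-yellow
GREEN_HUE_INTERVAL = (90.0, 150.0)


@dataclass
class SpectrumMatrix:
    """Stacked spectra: one row of bin frequencies per individual."""

    channel: str
    individual_ids: list[str]
    bin_edges: np.ndarray
    matrix: np.ndarray  # (n_individuals, n_bins), rows sum to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (individuals x bins)")
        if len(self.individual_ids) != self.matrix.shape[0]:
            raise ValueError("individual_ids must align with matrix rows")
        if self.matrix.shape[1] != self.bin_edges.size - 1:
            raise ValueError("bin_edges must match matrix columns")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PCAResult:
    """Centered, unscaled PCA of a spectrum matrix."""

    channel: str
    bin_edges: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_bins), orthonormal rows
    explained_fraction: np.ndarray


def spectra_to_matrix(spectra: list[ColourSpectrum]) -> SpectrumMatrix:
    """Stack per-individual spectra (shared channel and bins) into a matrix."""
    if not spectra:
        raise ValueError("no spectra")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.channel != ref.channel or not np.array_equal(s.bin_edges, ref.bin_edges):
            raise ValueError("spectra mix channels or bin edges")
    return SpectrumMatrix(
        channel=ref.channel,
        individual_ids=[s.individual_id for s in spectra],
        bin_edges=ref.bin_edges.copy(),
        matrix=np.vstack([s.frequencies for s in spectra]),
    )


def fit_pca(sm: SpectrumMatrix) -> PCAResult:
    """Covariance PCA via thin SVD of the centered spectrum matrix.

    Requires at least 3 individuals.  A matrix of identical rows has no
    variance; all explained fractions are returned as 0.
    """
    X = sm.matrix
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 individuals")
    if p < 2:
        raise ValueError("PCA requires at least 2 bins")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals**2 / (n - 1)
    total = variances.sum()
    explained = variances / total if total > 0 else np.zeros_like(variances)
    return PCAResult(
        channel=sm.channel,
        bin_edges=sm.bin_edges.copy(),
        mean_spectrum=mean,
        loadings=vt,
        explained_fraction=explained,
    )


def _pc1_sign(pca: PCAResult, sm: SpectrumMatrix) -> float:
    pc1 = pca.loadings[0]
    mids = 0.5 * (pca.bin_edges[:-1] + pca.bin_edges[1:])
    if pca.channel == "H":
        lo, hi = GREEN_HUE_INTERVAL
        green = (mids >= lo) & (mids <= hi)
        s = pc1[green].sum()
    else:
        raw = (sm.matrix - pca.mean_spectrum) @ pc1
        channel_means = sm.matrix @ mids
        s = float(np.cov(raw, channel_means)[0, 1]) if raw.std() > 0 else 0.0
    return -1.0 if s < 0 else 1.0


def align_pc1_sign(pca: PCAResult, sm: SpectrumMatrix) -> PCAResult:
    """Fix the arbitrary PC1 sign so scores are biologically oriented.

    Hue: the summed PC1 loading over green bins (90-150 degrees) is made
    positive.  Saturation / value: the correlation between scores and the
    individuals' mean channel level is made positive.
    """
    if pca.channel not in CHANNELS:
        raise ValueError(f"unknown channel {pca.channel!r}")
    sign = _pc1_sign(pca, sm)
    loadings = pca.loadings.copy()
    loadings[0] *= sign
    return PCAResult(
        channel=pca.channel,
        bin_edges=pca.bin_edges,
        mean_spectrum=pca.mean_spectrum,
        loadings=loadings,
        explained_fraction=pca.explained_fraction,
    )


def score_pc1(pca: PCAResult, sm: SpectrumMatrix) -> np.ndarray:
    """Sign-aligned PC1 score per individual: centered projection onto PC1."""
    if sm.matrix.shape[1] != pca.loadings.shape[1]:
        raise ValueError("bin count mismatch between PCA and spectrum matrix")
    if not np.array_equal(sm.bin_edges, pca.bin_edges):
        raise ValueError("bin edges mismatch between PCA and spectrum matrix")
    aligned = align_pc1_sign(pca, sm)
    return (sm.matrix - aligned.mean_spectrum) @ aligned.loadings[0]
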