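"""Multivariate interaction measure (MIM) connectivity in source space.

MIM couples two multidimensional source spaces through the imaginary
part of their cross-spectrum and is therefore blind to instantaneous
linear mixing (volume conduction): a real-valued cross-spectral block
gives exactly zero.  For voxels i, j with 3-D source cross-spectral
blocks S_ij the measure is

    MIM(i, j) = tr[ (Re S_ii)^-1 Im S_ij (Re S_jj)^-1 (Im S_ij)^T ]

which equals the sum of the three eigenvalues of that product and is
invariant to any non-singular real remixing within each voxel's 3-D
space.  Voxel-to-whole-brain connectivity is the average of a voxel's
MIM with all other voxels (self-pairs excluded: MIM measures
interactions between distinct areas, not within them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DataError
from .source import BandSpectra, InverseOperator, VoxelStatMap, voxel_permutation_test

__all__ = [
    "VoxelCrossSpectrum",
    "ConnectivityMap",
    "voxel_cross_spectrum",
    "mim_pair",
    "mim_voxel_to_whole_brain",
    "mim_contrast_and_test",
]

logger = logging.getLogger("thetareg")

#: relative ridge added to near-singular Re(S_ii) blocks
EPS_REG = 1e-12


@dataclass
class VoxelCrossSpectrum:
    """Band cross-spectrum over all voxels' 3-D source coefficients.

    ``matrix`` is (3V, 3V) complex (band-averaged) or (n_bins, 3V, 3V)
    when per-bin spectra are retained; block (i, j) is
    ``matrix[..., 3i:3i+3, 3j:3j+3]``.
    """

    matrix: np.ndarray
    n_voxels: int
    bins: np.ndarray
    band_averaged: bool = True

    def block(self, i: int, j: int) -> np.ndarray:
        m = self.matrix if self.band_averaged else self.matrix.mean(axis=0)
        return m[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class ConnectivityMap:
    """Per-voxel scalar: average MIM of that voxel with all other voxels."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise DataError("non-finite connectivity values")


def voxel_cross_spectrum(
    operator: InverseOperator,
    spectra: BandSpectra,
    band_average: bool = True,
) -> VoxelCrossSpectrum:
    """Project channel spectra to source space and form the trial-averaged
    cross-spectral blocks (averaged over the 11 band bins by default)."""
    if spectra.coefficients.shape[1] != operator.weights.shape[2]:
        raise DataError("channel count mismatch between spectra and operator")
    n_trials = spectra.coefficients.shape[0]
    if n_trials < 2:
        raise DataError("need at least 2 trials for a cross-spectrum")
    n_v = operator.weights.shape[0]
    # source coefficients: (trials, V, 3, bins) -> (trials*? , 3V) per bin
    src = np.einsum("voc,tcb->tvob", operator.weights, spectra.coefficients)
    flat = src.reshape(n_trials, 3 * n_v, len(spectra.bins))
    if band_average:
        a = flat.transpose(2, 0, 1).reshape(-1, 3 * n_v)  # (bins*trials, 3V)
        S = a.T @ a.conj() / a.shape[0]  # S[p, q] = E[a_p a_q*]
        return VoxelCrossSpectrum(S, n_v, spectra.bins, True)
    mats = np.empty((len(spectra.bins), 3 * n_v, 3 * n_v), complex)
    for b in range(len(spectra.bins)):
        a = flat[:, :, b]
        mats[b] = a.T @ a.conj() / n_trials
    return VoxelCrossSpectrum(mats, n_v, spectra.bins, False)


def _check_hermitian(S: np.ndarray, tol: float = 1e-8) -> None:
    dev = np.abs(S - S.conj().T).max()
    scale = max(np.abs(S).max(), 1e-30)
    if dev > tol * scale:
        raise DataError(f"cross-spectral block not Hermitian (relative deviation {dev / scale:.2e})")


def _reg_inv(real_block: np.ndarray) -> np.ndarray:
    tr = np.trace(real_block)
    ridge = EPS_REG * max(tr, 1e-300)
    try:
        cond = np.linalg.cond(real_block)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        logger.info("regularising near-singular Re(S_ii) block (cond=%.2e)", cond)
        real_block = real_block + ridge * np.eye(3)
    return np.linalg.inv(real_block)


def mim_pair(S_ii: np.ndarray, S_jj: np.ndarray, S_ij: np.ndarray) -> float:
    """MIM between two 3-D source spaces from their cross-spectral blocks.

    Equals the sum of the three eigenvalues of
    (Re S_ii)^-1 Im S_ij (Re S_jj)^-1 (Im S_ij)^T; always >= 0 and
    symmetric in (i, j).
    """
    S_ii = np.asarray(S_ii)
    S_jj = np.asarray(S_jj)
    S_ij = np.asarray(S_ij, complex)
    _check_hermitian(S_ii)
    _check_hermitian(S_jj)
    P_i = _reg_inv(np.real(S_ii))
    P_j = _reg_inv(np.real(S_jj))
    im = np.imag(S_ij)
    return float(np.trace(P_i @ im @ P_j @ im.T))


def _whole_brain_mim(matrix: np.ndarray, n_v: int) -> np.ndarray:
    """Vectorised voxel-to-whole-brain MIM for one (3V, 3V) cross-spectrum.

    Uses tr(P_i B P_j B^T) = ||R_i^T B R_j||_F^2 with P = R R^T.
    """
    blocks = matrix.reshape(n_v, 3, n_v, 3)
    re_diag = np.real(np.einsum("ioip->iop", blocks))  # (V, 3, 3)
    # PSD square roots of the inverses via eigendecomposition
    vals, vecs = np.linalg.eigh(re_diag)
    tr = np.einsum("ioo->i", re_diag)
    floor = EPS_REG * np.maximum(tr, 1e-300)
    vals = np.maximum(vals, floor[:, None])
    R = np.einsum("vij,vj,vkj->vik", vecs, 1 / np.sqrt(vals), vecs)  # R = P^{1/2}
    Q = np.imag(blocks)
    Y = np.einsum("ioa,iajb,jbp->iojp", R.transpose(0, 2, 1), Q, R)
    mim = np.einsum("iojp,iojp->ij", Y, Y)
    np.fill_diagonal(mim, 0.0)
    return mim.sum(axis=1) / max(n_v - 1, 1)


def mim_voxel_to_whole_brain(cross_spectrum: VoxelCrossSpectrum) -> ConnectivityMap:
    """Average MIM of each voxel with all other voxels (self excluded)."""
    n_v = cross_spectrum.n_voxels
    if n_v < 2:
        raise DataError("need at least 2 voxels")
    if cross_spectrum.band_averaged:
        values = _whole_brain_mim(cross_spectrum.matrix, n_v)
    else:
        per_bin = [_whole_brain_mim(m, n_v) for m in cross_spectrum.matrix]
        values = np.mean(per_bin, axis=0)
    return ConnectivityMap(values)


def mim_contrast_and_test(
    maps_a: dict,
    maps_b: dict,
    conditions: tuple[str, str] = ("reappraise", "maintain"),
    n_perm: int = 10_000,
    seed: int | None = 0,
    tails: str = "two",
    voxel_positions: np.ndarray | None = None,
) -> VoxelStatMap:
    """Group inference on the per-participant condition contrast of
    voxel-to-whole-brain MIM maps.

    ``maps_a`` / ``maps_b`` map condition name to (participants × voxels)
    arrays for the two groups; the contrast is first minus second
    condition, tested with the voxel-wise permutation test.
    """
    c1, c2 = conditions
    contrast_a = np.asarray(maps_a[c1], float) - np.asarray(maps_a[c2], float)
    contrast_b = np.asarray(maps_b[c1], float) - np.asarray(maps_b[c2], float)
    return voxel_permutation_test(
        contrast_a, contrast_b, n_perm=n_perm, seed=seed, tails=tails,
        voxel_positions=voxel_positions)
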