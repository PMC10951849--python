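"""Spherical head model and analytic EEG forward solution.

The forward model is a single homogeneous conducting sphere with an
insulating exterior.  Sensors sit on the sphere surface at standard
10/10 montage angles; sources live on a "cortical shell" grid strictly
inside the sphere, with three orthogonal dipole orientations per voxel.

The surface potential of a current dipole ``p`` at radius ``b`` inside a
sphere of radius ``R`` and conductivity ``sigma`` has the classical
closed form obtained by summing the Legendre expansion

    V = 1/(4*pi*sigma*R^2) * sum_n (2n+1)/n * f^(n-1)
            * [ n (p.rhat0) P_n(c) + p.(rhat - c*rhat0) P_n'(c) ]

with f = b/R and c the cosine of the angle between electrode and dipole
position; the sums over n have closed forms via the Legendre generating
function (including the well-known logarithmic term), which is what
:func:`sphere_dipole_potential` evaluates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTICAP64_LABELS",
    "HeadModel",
    "Leadfield",
    "make_head_model",
    "generate_leadfield",
    "sphere_dipole_potential",
]

#: 64-channel actiCAP roster (extended 10/20 positions; FCz is the
#: recording reference and not a data channel).
ACTICAP64_LABELS = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
]

#: brain conductivity, S/m
CONDUCTIVITY = 0.33

#: gain unit conversion: dipole moments are in nAm, potentials in microvolt
_NAM_TO_AM = 1e-9
_V_TO_UV = 1e6


class GeometryError(ValueError):
    """Raised when source/sensor geometry violates the sphere model."""


@dataclass
class HeadModel:
    """Spherical sensor/source geometry.

    channel positions are head-centred metres on the sensor sphere;
    voxel positions are metres on the cortical-shell grid.
    ``voxel_positions_mm`` gives the nominal MNI-like coordinates.
    """

    channel_labels: list[str]
    channel_positions: np.ndarray  # (n_channels, 3), m
    voxel_positions: np.ndarray    # (n_voxels, 3), m
    radius: float                  # sensor sphere radius, m

    def __post_init__(self) -> None:
        self.channel_positions = np.asarray(self.channel_positions, float)
        self.voxel_positions = np.asarray(self.voxel_positions, float)
        if not np.isfinite(self.channel_positions).all():
            raise GeometryError("non-finite channel positions")
        if not np.isfinite(self.voxel_positions).all():
            raise GeometryError("non-finite voxel positions")
        r = np.linalg.norm(self.voxel_positions, axis=1)
        if self.n_voxels and r.max() >= self.radius:
            raise GeometryError(
                "voxel on or outside the sensor sphere "
                f"(max voxel radius {r.max():.4f} m >= {self.radius:.4f} m)"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    @property
    def voxel_positions_mm(self) -> np.ndarray:
        return self.voxel_positions * 1e3

    def nearest_voxel(self, point_mm) -> int:
        """Index of the grid voxel nearest a nominal mm coordinate."""
        p = np.asarray(point_mm, float) / 1e3
        return int(np.argmin(np.linalg.norm(self.voxel_positions - p, axis=1)))


@dataclass
class Leadfield:
    """Dipole-to-scalp gain: ``gain[v, o, c]`` in µV per nAm.

    Average reference has been applied: every (voxel, orientation) row
    sums to zero over channels.
    """

    gain: np.ndarray  # (n_voxels, 3, n_channels)
    head_model: HeadModel

    def project(self, voxel: int, moment: np.ndarray) -> np.ndarray:
        """Scalp topography (µV) of a dipole ``moment`` (nAm, 3-vector)."""
        return np.asarray(moment, float) @ self.gain[voxel]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    s = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


def _standard_positions(labels: list[str]) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            montage = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer mne
            montage = mne.channels.make_standard_montage("colin27_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise GeometryError(f"labels not in standard montage: {missing}")
    return np.array([pos[l] for l in labels], float)


def make_head_model(
    n_voxels: int = 400,
    channel_labels: list[str] | None = None,
    shell_fraction: float = 0.75,
    min_z_fraction: float = -0.5,
) -> HeadModel:
    """Build the default spherical head model.

    Parameters
    ----------
    n_voxels
        Number of source voxels on the cortical shell (default 400;
        configurable up to the full-resolution 2839 grid).
    channel_labels
        Montage roster; defaults to the 64-channel actiCAP layout.
    shell_fraction
        Cortical shell radius as a fraction of the sensor sphere radius.
    min_z_fraction
        Voxels with z below this fraction of the radius are discarded
        (no cortex at the bottom of the sphere).
    """
    labels = list(channel_labels) if channel_labels is not None else list(ACTICAP64_LABELS)
    raw = _standard_positions(labels)
    # centre on the best-fit sphere and project sensors radially onto it
    centre = raw.mean(axis=0)
    centred = raw - centre
    radius = float(np.linalg.norm(centred, axis=1).mean())
    sensors = centred / np.linalg.norm(centred, axis=1, keepdims=True) * radius

    # oversample the Fibonacci shell so the inferior cut still leaves n_voxels
    shell_r = shell_fraction * radius
    n_try = n_voxels
    while True:
        pts = _fibonacci_sphere(n_try) * shell_r
        keep = pts[:, 2] >= min_z_fraction * radius
        if keep.sum() >= n_voxels:
            pts = pts[keep][:n_voxels]
            break
        n_try = int(n_try * 1.3) + 8
    return HeadModel(labels, sensors, pts, radius)


def sphere_dipole_potential(
    dipole_pos: np.ndarray,
    moment: np.ndarray,
    sensor_pos: np.ndarray,
    radius: float,
    sigma: float = CONDUCTIVITY,
) -> np.ndarray:
    """Closed-form surface potential (V) of a dipole in a conducting sphere.

    ``dipole_pos`` metres (inside the sphere), ``moment`` Am,
    ``sensor_pos`` (n, 3) metres on the surface.
    """
    r0 = np.asarray(dipole_pos, float)
    q = np.asarray(moment, float)
    sens = np.atleast_2d(np.asarray(sensor_pos, float))
    b = np.linalg.norm(r0)
    if b >= radius:
        raise GeometryError(f"dipole at radius {b:.4f} m not inside sphere {radius:.4f} m")
    rhat = sens / np.linalg.norm(sens, axis=1, keepdims=True)
    k = 1.0 / (4 * np.pi * sigma * radius**2)

    if b < 1e-9 * radius:
        # central dipole: only the n=1 term survives
        return k * 3.0 * (rhat @ q)

    rhat0 = r0 / b
    f = b / radius
    c = rhat @ rhat0
    d = np.sqrt(1 - 2 * f * c + f * f)
    u = 1 - f * c + d
    # sum_{n>=1} (2n+1) f^(n-1) P_n(c)
    s_rad = 2 * (c - f) / d**3 + (1 / d - 1) / f
    # sum_{n>=1} (2n+1)/n f^(n-1) P_n'(c)
    s_tan = 2 / d**3 + (1 + d) / (d * u)
    q_rad = q @ rhat0
    q_tan = (rhat - c[:, None] * rhat0) @ q  # = (q . that) * sin(theta)
    return k * (q_rad * s_rad + q_tan * s_tan)


def generate_leadfield(head_model: HeadModel, seed: int = 0) -> Leadfield:
    """Average-referenced analytic sphere leadfield (µV per nAm).

    Deterministic given geometry; ``seed`` is accepted for interface
    uniformity but the analytic solution involves no randomness.
    """
    n_v, n_c = head_model.n_voxels, head_model.n_channels
    gain = np.empty((n_v, 3, n_c))
    eye = np.eye(3)
    unit = _NAM_TO_AM * _V_TO_UV
    for v in range(n_v):
        for o in range(3):
            gain[v, o] = sphere_dipole_potential(
                head_model.voxel_positions[v], eye[o],
                head_model.channel_positions, head_model.radius,
            ) * unit
    gain -= gain.mean(axis=2, keepdims=True)  # average reference
    return Leadfield(gain, head_model)
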