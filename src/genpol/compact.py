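"""Full-pol target vectors and general compact-polarimetric synthesis.

A compact-polarimetric (CP) radar transmits a single fully polarized wave
and receives two orthogonal linear components.  The transmit state is a
polarization ellipse with orientation theta in [-pi/2, pi/2] and
ellipticity chi in [-pi/4, pi/4]; its Jones vector is

    a = cos(theta) cos(chi) - j sin(theta) sin(chi)
    b = sin(theta) cos(chi) + j cos(theta) sin(chi),   |a|^2 + |b|^2 = 1.

Scattering off a target with Sinclair matrix S gives the received wave
(a S_HH + b S_HV, b S_VV + a S_VH).  Whenever a != 0 and b != 0 the
per-channel normalized backscatter vector

    E1 = S_HH + (b/a) S_HV,    E2 = S_VV + (a/b) S_VH

isolates the target's co-polar response; the classic pi/4 (45 deg linear
transmit) and CTLR (right-circular transmit, linear receive) modes are the
special cases (theta, chi) = (pi/4, 0) and (0, -pi/4).

Second-order statistics are sliding-window ensemble averages of vector
outer products: the 3x3 Pauli coherency T3 for quad-pol data, and the
2x2 covariance C2 / coherency T2 for CP data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from genpol.exceptions import DomainError, UnsupportedModeError, ValidationError
from genpol.filtering import boxcar
from genpol.io import ScatteringImage

_EPS_AB = 1e-8  # singular-transmit guard on |a|, |b|

SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# transmit wave
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransmitWave:
    """Fully polarized transmit state (theta, chi) with Jones amplitudes."""

    theta: float
    chi: float
    a: complex
    b: complex

    @property
    def is_admissible(self) -> bool:
        """True when both channel amplitudes clear the singular guard."""
        return abs(self.a) > _EPS_AB and abs(self.b) > _EPS_AB


def transmit_wave(theta: float, chi: float) -> TransmitWave:
    """Build the transmit ellipse Jones vector for (theta, chi) in radians."""
    if not -np.pi / 2 - 1e-12 <= theta <= np.pi / 2 + 1e-12:
        raise DomainError(f"theta={theta} outside [-pi/2, pi/2]")
    if not -np.pi / 4 - 1e-12 <= chi <= np.pi / 4 + 1e-12:
        raise DomainError(f"chi={chi} outside [-pi/4, pi/4]")
    a = np.cos(theta) * np.cos(chi) - 1j * np.sin(theta) * np.sin(chi)
    b = np.sin(theta) * np.cos(chi) + 1j * np.cos(theta) * np.sin(chi)
    return TransmitWave(float(theta), float(chi), complex(a), complex(b))


PI4_WAVE = (np.pi / 4, 0.0)
CTLR_WAVE = (0.0, -np.pi / 4)   # right-circular transmit


def mode_wave(mode: str) -> TransmitWave:
    """Transmit wave of a named classic CP mode ('pi4' or 'ctlr')."""
    if mode == "pi4":
        return transmit_wave(*PI4_WAVE)
    if mode == "ctlr":
        return transmit_wave(*CTLR_WAVE)
    raise DomainError(f"unknown CP mode {mode!r}")


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

@dataclass
class CPField:
    """Normalized two-channel CP backscatter rasters E1, E2."""

    e1: np.ndarray
    e2: np.ndarray
    wave: TransmitWave

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=np.complex128)
        self.e2 = np.asarray(self.e2, dtype=np.complex128)
        if self.e1.shape != self.e2.shape:
            raise ValidationError("E1/E2 shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.e1.shape

    def k1(self) -> np.ndarray:
        """Per-pixel (E1, E2) vectors, shape (..., 2)."""
        return np.stack([self.e1, self.e2], axis=-1)

    def k2(self) -> np.ndarray:
        """Per-pixel Pauli-like (E1+E2, E1-E2)/sqrt(2) vectors."""
        return np.stack([(self.e1 + self.e2) / SQRT2,
                         (self.e1 - self.e2) / SQRT2], axis=-1)


@dataclass
class HermitianField:
    """Per-pixel d x d Hermitian second-order matrix raster.

    kind is one of C2 / T2 / T3; window records the ensemble-averaging
    scale (0 for a global average).
    """

    entries: np.ndarray
    kind: str
    window: int

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=np.complex128)
        if e.ndim != 4 or e.shape[-1] != e.shape[-2]:
            raise ValidationError("entries must have shape (rows, cols, d, d)")
        if self.kind not in ("C2", "T2", "T3"):
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        self.entries = e

    @property
    def dim(self) -> int:
        return self.entries.shape[-1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape[:2]

    def diagonal(self) -> np.ndarray:
        """Real diagonal, shape (rows, cols, d)."""
        d = np.einsum("...ii->...i", self.entries)
        return d.real

    def trace(self) -> np.ndarray:
        return self.diagonal().sum(axis=-1)

    def validate(self) -> None:
        e = self.entries
        h = np.abs(e - np.conj(np.swapaxes(e, -1, -2)))
        scale = np.maximum(np.abs(e).max(axis=(-1, -2), keepdims=True), 1e-300)
        if (h / scale).max() > 1e-10:
            raise ValidationError("field is not Hermitian to tolerance")
        diag = self.diagonal()
        tr = np.maximum(self.trace(), 1e-300)
        if (diag.min(axis=-1) / tr).min() < -1e-10:
            raise ValidationError("negative diagonal entries beyond tolerance")


def _averaged_outer(k: np.ndarray, window: int | None) -> np.ndarray:
    """Ensemble-average <k k*T>: sliding boxcar, or global mean if window
    is None (returns a 1x1 field)."""
    d = k.shape[-1]
    outer = k[..., :, None] * np.conj(k[..., None, :])
    if window is None:
        return outer.mean(axis=(0, 1))[None, None, :, :]
    if window == 1:
        return outer
    out = np.empty_like(outer)
    for i in range(d):
        for j in range(d):
            out[..., i, j] = boxcar(outer[..., i, j], window)
    return out


# ---------------------------------------------------------------------------
# full-pol operations
# ---------------------------------------------------------------------------

def fp_target_vector(img: ScatteringImage) -> np.ndarray:
    """Pauli target vector (S_HH+S_VV, S_HH-S_VV, 2 S_HV)/sqrt(2).

    Reciprocity is applied by averaging the two cross channels first.
    Returns an array of shape (rows, cols, 3).
    """
    hv = 0.5 * (img.shv + img.svh)
    return np.stack([img.shh + img.svv, img.shh - img.svv, 2.0 * hv],
                    axis=-1) / SQRT2


def fp_coherency(img: ScatteringImage, window: int | None = 7) -> HermitianField:
    """3x3 Pauli coherency T3 = <k k*T> with a sliding boxcar average.

    window=None averages over the whole raster (1x1 output field).
    """
    _check_window(window, img.shape)
    k = fp_target_vector(img)
    t3 = _averaged_outer(k, window)
    return HermitianField(t3, kind="T3", window=window or 0)


def rotate_scattering(img: ScatteringImage, phi: float) -> ScatteringImage:
    """Rotate the Sinclair matrix about the line of sight: S' = R S R^T."""
    c, s = np.cos(phi), np.sin(phi)
    shh = c * c * img.shh - c * s * (img.shv + img.svh) + s * s * img.svv
    svv = s * s * img.shh + c * s * (img.shv + img.svh) + c * c * img.svv
    shv = c * s * img.shh + c * c * img.shv - s * s * img.svh - c * s * img.svv
    svh = c * s * img.shh - s * s * img.shv + c * c * img.svh - c * s * img.svv
    return ScatteringImage(shh, shv, svh, svv, date_tag=img.date_tag,
                           pixel_spacing=img.pixel_spacing)


# ---------------------------------------------------------------------------
# compact-pol operations
# ---------------------------------------------------------------------------

def classic_cp_vector(img: ScatteringImage, mode: str) -> np.ndarray:
    """Scattering vector of a named classic CP mode, shape (rows, cols, 2).

    pi4:  (S_HH + S_HV, S_VV + S_HV) / sqrt(2)
    ctlr: (S_HH - i S_HV, S_HV - i S_VV) / sqrt(2)
    """
    hv = 0.5 * (img.shv + img.svh)
    if mode == "pi4":
        return np.stack([img.shh + hv, img.svv + hv], axis=-1) / SQRT2
    if mode == "ctlr":
        return np.stack([img.shh - 1j * hv, hv - 1j * img.svv], axis=-1) / SQRT2
    raise DomainError(f"unknown CP mode {mode!r}")


def general_cp_field(img: ScatteringImage, wave: TransmitWave) -> CPField:
    """Synthesize the normalized CP channels E1, E2 for an arbitrary
    admissible transmit ellipse."""
    if not wave.is_admissible:
        raise UnsupportedModeError(
            f"transmit (theta={wave.theta:.4f}, chi={wave.chi:.4f}) has "
            f"|a|={abs(wave.a):.2e}, |b|={abs(wave.b):.2e}; the normalized "
            "CP vector requires a != 0 and b != 0")
    hv = 0.5 * (img.shv + img.svh)
    e1 = img.shh + (wave.b / wave.a) * hv
    e2 = img.svv + (wave.a / wave.b) * hv
    return CPField(e1, e2, wave)


def normalize_received(k: np.ndarray, wave: TransmitWave) -> CPField:
    """Undo the per-channel transmit amplitudes of a received-wave vector
    (e.g. a classic-mode scattering vector) to recover (E1, E2)."""
    if not wave.is_admissible:
        raise UnsupportedModeError("cannot normalize a singular transmit state")
    return CPField(k[..., 0] / wave.a, k[..., 1] / wave.b, wave)


def cp_second_order(cp: CPField, window: int | None = 7
                    ) -> tuple[HermitianField, HermitianField]:
    """Covariance C2 = <k1 k1*T> and coherency T2 = <k2 k2*T>.

    The two share their trace (total power) exactly; window=None gives a
    global 1x1 average.
    """
    _check_window(window, cp.shape)
    c2 = HermitianField(_averaged_outer(cp.k1(), window), "C2", window or 0)
    t2 = HermitianField(_averaged_outer(cp.k2(), window), "T2", window or 0)
    return c2, t2


def _check_window(window: int | None, shape: tuple[int, int]) -> None:
    if window is None:
        return
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be odd and >= 1, got {window}")
    if window > min(shape):
        raise DomainError(
            f"window {window} exceeds raster extent {shape}")
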