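"""Fresnel transfer-matrix reflectance of a Kretschmann prism/metal/medium stack.

This module is the physics oracle and synthetic-data generator of the
package. Light travels from a high-index prism through thin metal films
(chromium adhesion layer + gold) into the bulk medium; reflectance versus
internal incidence angle shows the onset of total internal reflection at the
critical angle and, for TM polarization, the surface-plasmon dip at the
resonance angle. Reflectance is computed with the standard 2x2
characteristic-matrix method for stratified media.

Default optical constants (overridable everywhere):

* BK7 prism n = 1.5125 at 770 nm.
* Gold relative permittivity eps = -20.5 + 1.4i near 770 nm (standard
  handbook tabulations, e.g. Johnson & Christy interpolated).
* Chromium n = 3.1 + 3.3i near 770 nm (handbook value).
* Water n = 1.333, air n = 1.000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DetectorGeometry, RawImageSet, SPRCurve

__all__ = [
    "OpticalStack",
    "NoiseSpec",
    "DetectorGeometry",
    "GOLD_INDEX_770NM",
    "CHROMIUM_INDEX_770NM",
    "BK7_INDEX_770NM",
    "WATER_INDEX",
    "AIR_INDEX",
    "kretschmann_stack",
    "default_geometry",
    "fresnel_reflectance",
    "simulate_spr_curve",
    "theoretical_critical_angle",
    "synthesize_image_set",
]

#: Gold complex refractive index at 770 nm, from eps = -20.5 + 1.4i.
GOLD_INDEX_770NM: complex = complex(np.sqrt(complex(-20.5, 1.4)))
#: Chromium complex refractive index near 770 nm (handbook tabulation).
CHROMIUM_INDEX_770NM: complex = 3.1 + 3.3j
#: BK7 prism refractive index at 770 nm.
BK7_INDEX_770NM: float = 1.5125
WATER_INDEX: float = 1.333
AIR_INDEX: float = 1.000


@dataclass(frozen=True)
class OpticalStack:
    """Prism / thin layers / semi-infinite bulk, at a single wavelength.

    Parameters
    ----------
    prism_index : float
        Real refractive index of the incidence half-space (the prism).
    layers : sequence of (complex, float)
        Thin films between prism and bulk, as ``(refractive index,
        thickness in nm)`` pairs ordered from the prism side. May be empty
        (bare two-medium interface).
    bulk_index : float
        Real refractive index of the exit half-space (the sample medium).
        Must be below ``prism_index`` so total internal reflection exists.
    wavelength_nm : float
        Vacuum wavelength in nm.
    """

    prism_index: float
    layers: tuple[tuple[complex, float], ...] = ()
    bulk_index: float = WATER_INDEX
    wavelength_nm: float = 770.0

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        layers = tuple((complex(n), float(d)) for n, d in self.layers)
        for i, (n, d) in enumerate(layers):
            if not d > 0:
                raise ValueError(f"layer {i} thickness must be > 0 nm, got {d}")
            if n.imag < 0:
                raise ValueError(f"layer {i} has gain (Im n < 0): {n}")
        if not self.prism_index > self.bulk_index:
            raise ValueError(
                "prism_index must exceed bulk_index for total internal "
                f"reflection to be reachable ({self.prism_index} <= {self.bulk_index})"
            )
        if self.bulk_index <= 0:
            raise ValueError(f"bulk_index must be > 0, got {self.bulk_index}")
        object.__setattr__(self, "layers", layers)

    def with_bulk(self, bulk_index: float) -> "OpticalStack":
        """Copy of the stack with a different bulk medium."""
        return OpticalStack(self.prism_index, self.layers, bulk_index, self.wavelength_nm)

    def with_adlayer(self, n: complex, thickness_nm: float) -> "OpticalStack":
        """Copy with an extra film appended on the bulk side (an adsorbed layer)."""
        if thickness_nm == 0:
            return self
        return OpticalStack(
            self.prism_index,
            self.layers + ((complex(n), float(thickness_nm)),),
            self.bulk_index,
            self.wavelength_nm,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model for synthetic frames.

    Additive Gaussian dark noise (``dark_sd`` counts around ``dark_offset``)
    plus a multiplicative Gaussian shot-like term (``shot_sd`` relative) on
    the illuminated frames. A fixed ``seed`` makes frame synthesis
    bit-reproducible.
    """

    dark_offset: float = 100.0
    dark_sd: float = 0.0
    shot_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_sd < 0 or self.shot_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.dark_offset < 0:
            raise ValueError("dark_offset must be >= 0")


def kretschmann_stack(
    bulk_index: float = WATER_INDEX,
    gold_nm: float = 50.0,
    chromium_nm: float = 2.0,
    prism_index: float = BK7_INDEX_770NM,
    gold_index: complex = GOLD_INDEX_770NM,
    chromium_index: complex = CHROMIUM_INDEX_770NM,
    wavelength_nm: float = 770.0,
) -> OpticalStack:
    """Default sensor-chip stack: prism / Cr 2 nm / Au 50 nm / bulk."""
    return OpticalStack(
        prism_index=prism_index,
        layers=((chromium_index, chromium_nm), (gold_index, gold_nm)),
        bulk_index=bulk_index,
        wavelength_nm=wavelength_nm,
    )


def default_geometry(start_deg: float, n_pixels: int = 1280, span_deg: float = 7.296) -> DetectorGeometry:
    """Instrument geometry: 7.296 degrees across 1280 columns (0.0057 deg/px)."""
    return DetectorGeometry(n_pixels=n_pixels, span_deg=span_deg, start_deg=start_deg)


def _kz(n, beta, k0):
    """Normal wavevector component in a medium of index n; Im(kz) >= 0."""
    kz = k0 * np.sqrt(n * n - beta * beta + 0j)
    # principal sqrt already has Im >= 0 except on the negative real axis
    # boundary; enforce decaying evanescent waves explicitly.
    return np.where(kz.imag < 0, -kz, kz)


def fresnel_reflectance(stack: OpticalStack, angle_deg, polarization: str = "TM"):
    """Reflectance |r|^2 of the stack at the given internal incidence angle(s).

    Parameters
    ----------
    stack : OpticalStack
    angle_deg : float or array
        Incidence angle(s) inside the prism at the stack base, in degrees,
        strictly within (0, 90).
    polarization : {"TM", "TE"}
        TM (p) excites surface plasmons; TE (s) is the normalization channel.

    Returns
    -------
    float or ndarray
        Reflectance in [0, 1] for passive media, same shape as ``angle_deg``.
    """
    pol = polarization.upper()
    if pol not in ("TM", "TE"):
        raise ValueError(f"polarization must be 'TM' or 'TE', got {polarization!r}")
    scalar = np.isscalar(angle_deg)
    theta = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    if np.any(theta <= 0) or np.any(theta >= 90):
        raise ValueError("incidence angle must lie strictly within (0, 90) degrees")

    k0 = 2.0 * math.pi / stack.wavelength_nm  # 1/nm
    n0 = stack.prism_index
    ns = stack.bulk_index
    beta = n0 * np.sin(np.radians(theta))  # conserved tangential index

    def admittance(n, kz):
        return kz / (n * n) if pol == "TM" else kz

    kz0 = _kz(n0, beta, k0)
    kzs = _kz(ns, beta, k0)
    q0 = admittance(n0, kz0)
    qs = admittance(ns, kzs)

    # characteristic matrix product over the thin films, prism side first
    m11 = np.ones_like(beta, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for n_layer, d_nm in stack.layers:
        kz = _kz(n_layer, beta, k0)
        q = admittance(n_layer, kz)
        delta = kz * d_nm
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, -1j * s / q
        a21, a22 = -1j * q * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )

    num = q0 * (m11 + m12 * qs) - (m21 + m22 * qs)
    den = q0 * (m11 + m12 * qs) + (m21 + m22 * qs)
    r = num / den
    refl = np.abs(r) ** 2
    if not np.all(np.isfinite(refl)):
        raise ValueError("non-finite reflectance; stack is nonphysical")
    return float(refl[0]) if scalar else refl


def simulate_spr_curve(stack: OpticalStack, geometry: DetectorGeometry) -> SPRCurve:
    """Noise-free TM/TE reflectance-ratio curve across the detector window.

    This is exactly what the dark/TE/TM image normalization recovers from an
    ideal instrument, so it serves as ground truth for the whole pipeline.
    """
    angles = geometry.angles()
    if angles[0] <= 0 or angles[-1] >= 90:
        raise ValueError(
            f"detector window [{angles[0]:.3f}, {angles[-1]:.3f}] deg outside (0, 90)"
        )
    r_tm = fresnel_reflectance(stack, angles, "TM")
    r_te = fresnel_reflectance(stack, angles, "TE")
    if np.any(r_te <= 0):
        raise ValueError("TE reflectance vanished; ratio curve undefined")
    return SPRCurve(angles_deg=angles, values=r_tm / r_te)


def theoretical_critical_angle(n_bulk: float, n_prism: float) -> float:
    """Critical angle arcsin(n_bulk / n_prism), in degrees."""
    if not 0 < n_bulk < n_prism:
        raise ValueError(
            f"need 0 < n_bulk < n_prism for a critical angle, got {n_bulk}, {n_prism}"
        )
    return math.degrees(math.asin(n_bulk / n_prism))


def synthesize_image_set(
    stack: OpticalStack,
    geometry: DetectorGeometry,
    n_rows: int = 1024,
    noise: NoiseSpec | None = None,
    scale: float = 1000.0,
) -> RawImageSet:
    """Synthetic dark/TE/TM frame triplet whose normalization yields the curve.

    Each column carries the Fresnel reflectance of its incidence angle times
    ``scale`` counts, on top of the dark offset; noise per :class:`NoiseSpec`.
    With zero noise, ``(tm - dark) / (te - dark)`` recovers
    :func:`simulate_spr_curve` exactly.
    """
    if n_rows < 1:
        raise ValueError(f"n_rows must be >= 1, got {n_rows}")
    noise = noise or NoiseSpec()
    angles = geometry.angles()
    r_tm = fresnel_reflectance(stack, angles, "TM")
    r_te = fresnel_reflectance(stack, angles, "TE")

    shape = (n_rows, geometry.n_pixels)
    dark_clean = np.full(shape, noise.dark_offset)
    te_clean = noise.dark_offset + scale * np.broadcast_to(r_te, shape)
    tm_clean = noise.dark_offset + scale * np.broadcast_to(r_tm, shape)

    if noise.dark_sd == 0 and noise.shot_sd == 0:
        return RawImageSet(dark=dark_clean, te=te_clean.copy(), tm=tm_clean.copy())

    rng = np.random.default_rng(noise.seed)
    dark = dark_clean + noise.dark_sd * rng.standard_normal(shape)
    te = te_clean * (1.0 + noise.shot_sd * rng.standard_normal(shape))
    te += noise.dark_sd * rng.standard_normal(shape)
    tm = tm_clean * (1.0 + noise.shot_sd * rng.standard_normal(shape))
    tm += noise.dark_sd * rng.standard_normal(shape)
    return RawImageSet(
        dark=np.clip(dark, 0, None),
        te=np.clip(te, 0, None),
        tm=np.clip(tm, 0, None),
    )
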