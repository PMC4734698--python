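"""Gabor filter bank for per-pixel texture features.

A two-dimensional Gabor filter is a Gaussian envelope modulated by a complex
sinusoidal plane wave:

    G(x, y) = (f^2 / (pi * gamma * eta))
              * exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
              * exp(j (2 pi f x' + phi))

with the rotated frame x' = x cos(theta) + y sin(theta),
y' = -x sin(theta) + y cos(theta). ``f`` is the spatial frequency in
cycles/pixel, ``theta`` the orientation of the wave normal, ``phi`` the phase
offset, ``sigma`` the Gaussian standard deviation and ``gamma``/``eta`` the
spatial aspect parameters.

The bank varies frequency and orientation only: five frequencies in a
geometric series starting at 0.25 cycles/pixel with ratio 1/2 (so every term
stays below Nyquist) crossed with eight orientations from 0 to 7*pi/8 in
pi/8 steps — forty filters. The per-pixel feature is the magnitude of the
complex filter response (phase-invariant), optionally smoothed by a Gaussian
matched to the kernel scale (Gabor-energy convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import ndimage

from .io import IHCImage

NYQUIST = 0.5


@dataclass(frozen=True)
class GaborBankConfig:
    """Parameters of the filter bank.

    ``sigma_coeff`` sets the frequency-dependent envelope width
    ``sigma = sigma_coeff / f`` (default 0.56, approximately the one-octave
    half-response bandwidth convention). ``truncate`` is the kernel support
    half-width in units of sigma. ``smooth_factor`` scales the
    post-magnitude Gaussian smoothing (sigma_smooth = smooth_factor * sigma);
    0 disables it.
    """

    f0: float = 0.25
    ratio: float = 0.5
    n_freqs: int = 5
    n_orients: int = 8
    gamma: float = 2.0
    eta: float = 2.0
    phi: float = 0.0
    sigma_coeff: float = 0.56
    truncate: float = 3.0
    smooth_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.n_freqs < 1 or self.n_orients < 1:
            raise ValueError("bank must contain at least one filter")
        if not (0 < self.f0 < NYQUIST):
            raise ValueError("f0 must lie in (0, 0.5) cycles/pixel")
        bad = [f for f in self.frequencies if not (0 < f < NYQUIST)]
        if bad:
            raise ValueError(f"frequencies {bad} are outside (0, Nyquist)")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.f0 * self.ratio**k for k in range(self.n_freqs))

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(k * math.pi / self.n_orients for k in range(self.n_orients))

    @property
    def bank_size(self) -> int:
        return self.n_freqs * self.n_orients

    def sigma_for(self, f: float) -> float:
        return self.sigma_coeff / f


@dataclass(frozen=True)
class GaborKernel:
    """A sampled complex Gabor kernel (odd side length, centered)."""

    values: np.ndarray  # complex128, square, odd side
    f: float
    theta: float
    sigma: float

    @property
    def real_part(self) -> np.ndarray:
        return self.values.real

    @property
    def imag_part(self) -> np.ndarray:
        return self.values.imag

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PixelFeatureStack:
    """Per-pixel response magnitudes, shape (height, width, bank_size)."""

    values: np.ndarray
    config: GaborBankConfig

    @property
    def n_features(self) -> int:
        return int(self.values.shape[2])

    def as_points(self) -> np.ndarray:
        """Flatten to an (n_pixels, n_features) matrix (row-major order)."""
        h, w, d = self.values.shape
        return self.values.reshape(h * w, d)


def gabor_kernel(f: float, theta: float, config: GaborBankConfig | None = None) -> GaborKernel:
    """Sample one complex Gabor kernel on an odd-sided square grid.

    The support is truncated at ``truncate * sigma`` pixels from the center
    (the envelope decays along the slower axis with scale sigma).
    """
    config = config or GaborBankConfig()
    if not (0 < f < NYQUIST):
        raise ValueError(f"frequency {f} outside (0, Nyquist)")
    sigma = config.sigma_for(f)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = int(math.ceil(config.truncate * sigma))
    coords = np.arange(-half, half + 1, dtype=np.float64)
    # x runs along columns, y along rows (row-major image convention)
    y, x = np.meshgrid(coords, coords, indexing="ij")
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    amp = f**2 / (math.pi * config.gamma * config.eta)
    envelope = np.exp(-(xp**2 + config.gamma**2 * yp**2) / (2.0 * sigma**2))
    carrier = np.exp(1j * (2.0 * math.pi * f * xp + config.phi))
    return GaborKernel(values=amp * envelope * carrier, f=f, theta=theta, sigma=sigma)


def build_bank(config: GaborBankConfig | None = None) -> list[GaborKernel]:
    """Build the full bank, ordered frequency-major, orientation-minor."""
    config = config or GaborBankConfig()
    return [
        gabor_kernel(f, theta, config)
        for f in config.frequencies
        for theta in config.orientations
    ]


# FFTs of kernels are identical across images of the same shape; cache them
# keyed by (config, image shape). Kept small: one entry per distinct shape.
_FFT_CACHE: dict[tuple, tuple] = {}


def _bank_ffts(config: GaborBankConfig, fft_shape: tuple[int, int]):
    key = (config, fft_shape)
    if key not in _FFT_CACHE:
        kernels = build_bank(config)
        ffts = [spfft.fft2(k.values, fft_shape) for k in kernels]
        if len(_FFT_CACHE) > 8:
            _FFT_CACHE.clear()
        _FFT_CACHE[key] = (kernels, ffts)
    return _FFT_CACHE[key]


def extract_pixel_features(
    image: IHCImage | np.ndarray,
    config: GaborBankConfig | None = None,
    smooth: bool = True,
) -> PixelFeatureStack:
    """Filter the image with the whole bank and return response magnitudes.

    The image is globally standardized (subtract mean, divide by std) before
    filtering so the DC level cannot dominate; a constant image therefore
    yields an all-zero feature stack. Convolution uses reflect padding at the
    borders and is computed in the frequency domain (linearly, via explicit
    zero padding), which agrees with direct spatial convolution to floating
    point accuracy.
    """
    config = config or GaborBankConfig()
    px = image.pixels if isinstance(image, IHCImage) else np.asarray(image)
    h, w = px.shape
    img = px.astype(np.float64)
    std = img.std()
    img = (img - img.mean()) / std if std > 0 else np.zeros_like(img)

    sigma_max = config.sigma_for(min(config.frequencies))
    half_max = int(math.ceil(config.truncate * sigma_max))
    side_max = 2 * half_max + 1
    if side_max > min(h, w):
        raise ValueError(
            f"largest kernel ({side_max} px) exceeds image size {px.shape}; "
            "use a larger image or raise the minimum bank frequency"
        )

    pad = half_max
    padded = np.pad(img, pad, mode="reflect")
    ph, pw = padded.shape
    fft_shape = (
        spfft.next_fast_len(ph + side_max - 1),
        spfft.next_fast_len(pw + side_max - 1),
    )
    kernels, kernel_ffts = _bank_ffts(config, fft_shape)
    img_fft = spfft.fft2(padded, fft_shape)

    out = np.empty((h, w, len(kernels)), dtype=np.float32)
    for i, (kern, kfft) in enumerate(zip(kernels, kernel_ffts)):
        full = spfft.ifft2(img_fft * kfft)
        # center crop: 'same' w.r.t. padded image, then strip the reflect pad
        off = (kern.side - 1) // 2 + pad
        resp = full[off : off + h, off : off + w]
        mag = np.abs(resp)
        if smooth and config.smooth_factor > 0:
            mag = ndimage.gaussian_filter(
                mag, sigma=config.smooth_factor * kern.sigma, mode="reflect"
            )
        out[:, :, i] = mag.astype(np.float32)
    return PixelFeatureStack(values=out, config=config)
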