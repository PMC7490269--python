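"""Binary visual stimuli and their conditional patch statistics.

The encoding and decoding models in this package are driven by two stimulus
classes: spatiotemporal binary checkerboard noise (each pixel an independent
fair coin per frame) and binarized grayscale images whose spatial statistics
mimic natural scenes.  For discriminability analyses the relevant summary of
a stimulus ensemble is the set of *conditional patch statistics*: the mean of
each outer pixel in a small patch, and the pixel-pixel covariance of the
outer pixels, conditioned on the state of the central (decoded) pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMovie",
    "PatchStatistics",
    "generate_white_noise",
    "binarize_image",
    "sample_patch_statistics",
    "white_noise_patch_statistics",
    "generate_surrogate_natural_images",
    "spatial_power_spectrum",
]


@dataclass
class StimulusMovie:
    """Binary checkerboard movie.

    values: uint8 array of shape (frames, rows, cols) with entries in {0, 1}
        (0 = black, 1 = white; physical contrast mapping is presentation-layer).
    pixel_size: side of one square stimulus pixel, micrometers.
    refresh: frame rate in Hz.
    """

    values: np.ndarray
    pixel_size: float
    refresh: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 3:
            raise ValueError("values must be (frames, rows, cols)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("stimulus values must be strictly binary")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.refresh <= 0:
            raise ValueError("refresh must be positive")

    @property
    def frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def duration(self) -> float:
        """Movie duration in seconds."""
        return self.frames / self.refresh

    def contrast(self) -> np.ndarray:
        """Signed contrast in {-1, +1} (black = -1, white = +1), float64."""
        return self.values.astype(np.float64) * 2.0 - 1.0


@dataclass
class PatchStatistics:
    """Conditional statistics of square pixel patches around a decoded pixel.

    Arrays are laid out over the full flattened ``patch_size x patch_size``
    patch (row-major).  The central entry of the conditional means equals the
    conditioning value (1 for white, 0 for black); the central row/column of
    ``cond_cov`` is exactly zero because conditioning removes that pixel's
    variance.  ``cond_cov`` is the average of the white- and black-conditioned
    covariances.
    """

    patch_size: int
    cond_mean_white: np.ndarray
    cond_mean_black: np.ndarray
    cond_cov: np.ndarray
    n_patches: int

    def __post_init__(self) -> None:
        p2 = self.patch_size ** 2
        if self.patch_size % 2 != 1:
            raise ValueError("patch_size must be odd")
        for name in ("cond_mean_white", "cond_mean_black"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (p2,):
                raise ValueError(f"{name} must have length patch_size**2")
            setattr(self, name, v)
        self.cond_cov = np.asarray(self.cond_cov, dtype=float)
        if self.cond_cov.shape != (p2, p2):
            raise ValueError("cond_cov must be (patch_size**2, patch_size**2)")

    @property
    def center_index(self) -> int:
        return (self.patch_size ** 2) // 2

    @property
    def outer_indices(self) -> np.ndarray:
        idx = np.arange(self.patch_size ** 2)
        return idx[idx != self.center_index]

    def pixel_offsets_um(self, pixel_size: float) -> np.ndarray:
        """(p^2, 2) physical offsets of patch pixel centers from the center pixel."""
        half = self.patch_size // 2
        ax = (np.arange(self.patch_size) - half) * pixel_size
        xx, yy = np.meshgrid(ax, ax, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])


def generate_white_noise(
    frames: int,
    grid: tuple[int, int],
    seed: int | np.random.Generator,
    pixel_size: float = 252.0,
    refresh: float = 30.0,
) -> StimulusMovie:
    """Non-repeated binary checkerboard noise: iid fair Bernoulli per pixel-frame."""
    rows, cols = grid
    if frames < 1 or rows < 1 or cols < 1:
        raise ValueError("frames and grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(frames, rows, cols), dtype=np.uint8)
    return StimulusMovie(values=values, pixel_size=pixel_size, refresh=refresh)


def binarize_image(image: np.ndarray) -> np.ndarray:
    """Threshold a grayscale image about its median: strictly above -> 1.

    Raises on a constant image, where a median split is degenerate.
    """
    image = np.asarray(image, dtype=float)
    med = np.median(image)
    if np.all(image == image.flat[0]):
        raise ValueError("cannot binarize a constant image")
    return (image > med).astype(np.uint8)


def _conditional_moments(patches: np.ndarray, center: int):
    """Per-condition means and covariances of flattened binary patches."""
    means, covs, counts = {}, {}, {}
    for state in (0, 1):
        sel = patches[patches[:, center] == state]
        counts[state] = len(sel)
        if len(sel) < 2:
            raise ValueError(
                "too few patches with center state %d; increase n_patches" % state
            )
        means[state] = sel.mean(axis=0)
        covs[state] = np.cov(sel, rowvar=False, ddof=0)
    return means, covs, counts


def sample_patch_statistics(
    images: list[np.ndarray] | np.ndarray,
    patch_size: int,
    n_patches: int,
    seed: int | np.random.Generator,
) -> PatchStatistics:
    """Estimate conditional patch statistics from binary images.

    Per image, ``n_patches`` patch locations are drawn uniformly (with
    replacement) over valid top-left corners; patches are split by the state
    of their central pixel, conditional means and covariances are computed
    per state, the two covariances are averaged, and finally statistics are
    averaged across images with equal weight.
    """
    if patch_size % 2 != 1:
        raise ValueError("patch_size must be odd")
    if n_patches < patch_size ** 2:
        raise ValueError("n_patches must be at least patch_size**2")
    rng = np.random.default_rng(seed)
    images = [np.asarray(im) for im in images]
    p2 = patch_size ** 2
    center = p2 // 2
    mean_w = np.zeros(p2)
    mean_b = np.zeros(p2)
    cov = np.zeros((p2, p2))
    for im in images:
        if not np.isin(im, (0, 1)).all():
            raise ValueError("images must be binary; call binarize_image first")
        h, w = im.shape
        if h < patch_size or w < patch_size:
            raise ValueError("patch larger than image")
        r = rng.integers(0, h - patch_size + 1, size=n_patches)
        c = rng.integers(0, w - patch_size + 1, size=n_patches)
        # gather flattened patches
        dr, dc = np.meshgrid(
            np.arange(patch_size), np.arange(patch_size), indexing="ij"
        )
        patches = im[r[:, None] + dr.ravel()[None, :], c[:, None] + dc.ravel()[None, :]]
        patches = patches.astype(float)
        means, covs, _ = _conditional_moments(patches, center)
        mean_w += means[1]
        mean_b += means[0]
        cov += 0.5 * (covs[0] + covs[1])
    n_im = len(images)
    mean_w /= n_im
    mean_b /= n_im
    cov /= n_im
    # conditioning removes all center-pixel (co)variance exactly
    cov[center, :] = 0.0
    cov[:, center] = 0.0
    cov = 0.5 * (cov + cov.T)
    return PatchStatistics(
        patch_size=patch_size,
        cond_mean_white=mean_w,
        cond_mean_black=mean_b,
        cond_cov=cov,
        n_patches=n_patches * n_im,
    )


def white_noise_patch_statistics(patch_size: int) -> PatchStatistics:
    """Exact conditional patch statistics of iid Bernoulli(1/2) checkerboard noise.

    Outer means are 1/2 regardless of the center state, and the conditional
    covariance is (1/4)*I on the outer pixels.
    """
    if patch_size % 2 != 1:
        raise ValueError("patch_size must be odd")
    p2 = patch_size ** 2
    center = p2 // 2
    mean_w = np.full(p2, 0.5)
    mean_b = np.full(p2, 0.5)
    mean_w[center] = 1.0
    mean_b[center] = 0.0
    cov = 0.25 * np.eye(p2)
    cov[center, center] = 0.0
    return PatchStatistics(
        patch_size=patch_size,
        cond_mean_white=mean_w,
        cond_mean_black=mean_b,
        cond_cov=cov,
        n_patches=0,
    )


def generate_surrogate_natural_images(
    n_images: int,
    size: int,
    spectral_exponent: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Synthetic grayscale images with 1/f^beta spatial power spectra.

    Gaussian random fields built in Fourier space with amplitude
    ``(fx^2 + fy^2)^(-beta/2)`` and random phases. They stand in for a natural
    image corpus when estimating binarized patch statistics: like natural
    scenes they concentrate power at low spatial frequencies, but they lack
    edges, occlusions and higher-order structure.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f2 = fx ** 2 + fy ** 2
    amp = np.zeros_like(f2)
    nonzero = f2 > 0
    # power ~ amplitude^2, so halve the exponent again to get a 1/f^beta
    # POWER spectrum from the Fourier amplitude
    amp[nonzero] = f2[nonzero] ** (-spectral_exponent / 4.0)
    images = []
    for _ in range(n_images):
        phase = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
        field = np.fft.ifft2(amp * phase).real
        images.append(field)
    return images


def spatial_power_spectrum(images: list[np.ndarray] | np.ndarray):
    """Radially averaged spatial power spectrum, DC excluded.

    Returns (radii, spectrum): integer radial bins (cycles/image) and the
    mean over images of the binned squared Fourier magnitude.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    size = images[0].shape[0]
    if any(im.shape != images[0].shape for im in images):
        raise ValueError("images must share a common shape")
    fy = np.fft.fftfreq(size) * size
    fx = np.fft.fftfreq(images[0].shape[1]) * images[0].shape[1]
    rad = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    rbin = np.round(rad).astype(int)
    maxbin = rbin.max()
    acc = np.zeros(maxbin + 1)
    for im in images:
        power = np.abs(np.fft.fft2(im - im.mean())) ** 2
        acc += np.bincount(rbin.ravel(), weights=power.ravel(), minlength=maxbin + 1)
    counts = np.bincount(rbin.ravel(), minlength=maxbin + 1) * len(images)
    with np.errstate(invalid="ignore"):
        spec = acc / counts
    radii = np.arange(1, maxbin + 1)
    return radii, spec[1:]
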