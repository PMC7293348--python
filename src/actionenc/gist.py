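"""Gist scene descriptors: multi-scale oriented energy on a coarse grid.

Each grayscale frame is resized to a working resolution, local-contrast
normalized, and filtered in the frequency domain by a bank of oriented
log-Gabor filters at 4 spatial scales with 12, 8, 6 and 4 orientations
from fine to coarse (30 filters).  Filter power is pooled as the mean
squared response magnitude in each cell of an 8x8 grid, yielding a
30 x 64 = 1,920-dimensional descriptor per frame.  Frame descriptors are
reduced by PCA and the first 20 component scores averaged within each
video.

The orientation counts per scale are (12, 8, 6, 4): a 4-scale bank is the
only layout consistent with 1,920 / 64 = 30 filters, and the coarsest
scale carries the fewest orientations, continuing the fine-to-coarse
taper.  This is configurable through FilterBankSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .config import DataError


@dataclass(frozen=True)
class FilterBankSpec:
    """Log-Gabor bank layout.

    center_frequencies are cycles/image at the working resolution, fine to
    coarse; orientations_per_scale gives the evenly spaced orientation
    count at each scale.
    """

    center_frequencies: tuple[float, ...] = (64.0, 32.0, 16.0, 8.0)
    orientations_per_scale: tuple[int, ...] = (12, 8, 6, 4)
    working_size: int = 256
    grid: int = 8
    bandwidth_sigma: float = 0.55          # sd of log-frequency envelope
    orientation_sigma_factor: float = 0.5  # sd = factor * pi / n_orient

    def __post_init__(self) -> None:
        if len(self.center_frequencies) != len(self.orientations_per_scale):
            raise DataError("one orientation count per scale required")

    @property
    def n_filters(self) -> int:
        return int(sum(self.orientations_per_scale))

    @property
    def descriptor_length(self) -> int:
        return self.n_filters * self.grid ** 2

    def filter_table(self) -> list[dict]:
        """Per-filter metadata, fine to coarse, orientation-major."""
        rows = []
        for si, (f0, n_ori) in enumerate(zip(self.center_frequencies,
                                             self.orientations_per_scale)):
            for oi in range(n_ori):
                rows.append({"scale": si, "cycles_per_image": f0,
                             "orientation": np.pi * oi / n_ori})
        return rows


DEFAULT_SPEC = FilterBankSpec()


def build_filter_bank(spec: FilterBankSpec = DEFAULT_SPEC) -> np.ndarray:
    """Frequency-domain transfer functions, (n_filters, N, N) real.

    Single-lobe (analytic) log-Gabors: Gaussian in log radial frequency
    around each scale's center, Gaussian in direction around each
    orientation.  The bank is jointly normalized so the summed squared
    transfer never exceeds 1, giving a Parseval bound: total filter-bank
    energy <= total image spectral energy.
    """
    n = spec.working_size
    f = np.fft.fftfreq(n) * n                 # cycles/image
    fx, fy = np.meshgrid(f, f, indexing="xy")
    fr = np.hypot(fx, fy)
    phi = np.arctan2(fy, fx)
    bank = np.empty((spec.n_filters, n, n))
    i = 0
    with np.errstate(divide="ignore"):
        log_fr = np.where(fr > 0, np.log(fr), -np.inf)
    for f0, n_ori in zip(spec.center_frequencies,
                         spec.orientations_per_scale):
        radial = np.exp(-((log_fr - np.log(f0)) ** 2)
                        / (2 * spec.bandwidth_sigma ** 2))
        radial[fr == 0] = 0.0
        sigma_theta = spec.orientation_sigma_factor * np.pi / n_ori
        for oi in range(n_ori):
            theta = np.pi * oi / n_ori
            dphi = np.angle(np.exp(1j * (phi - theta)))   # wrap to [-pi, pi]
            bank[i] = radial * np.exp(-dphi ** 2 / (2 * sigma_theta ** 2))
            i += 1
    total = np.sqrt((bank ** 2).sum(axis=0)).max()
    if total > 0:
        bank /= max(total, 1.0)
    return bank


def _to_working(frame: np.ndarray, n: int) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise DataError("gist expects a 2-D grayscale frame")
    if not np.all(np.isfinite(frame)):
        raise DataError("frame contains non-finite values")
    if min(frame.shape) < 64:
        raise DataError("frame must be at least 64x64")
    if frame.shape != (n, n):
        frame = ndimage.zoom(frame, (n / frame.shape[0], n / frame.shape[1]),
                             order=1, grid_mode=True, mode="nearest")
    return frame


def _contrast_normalize(frame: np.ndarray) -> np.ndarray:
    """Remove the mean and divide by a local energy estimate."""
    f = frame - frame.mean()
    local = np.sqrt(ndimage.gaussian_filter(f ** 2, sigma=frame.shape[0] / 16))
    return f / (local + 0.1 * max(f.std(), 1e-12) + 1e-12)


def gist_frame(frame: np.ndarray, bank: np.ndarray | None = None,
               spec: FilterBankSpec = DEFAULT_SPEC) -> np.ndarray:
    """Gist descriptor of one frame.

    Pools |filter response|^2 as the mean over each cell of the spatial
    grid; output is filter-major (fine-to-coarse, then orientation), cells
    row-major within each filter block.
    """
    if bank is None:
        bank = build_filter_bank(spec)
    n = spec.working_size
    g = spec.grid
    img = _contrast_normalize(_to_working(frame, n))
    F = np.fft.fft2(img)
    desc = np.empty(spec.descriptor_length)
    cell = n // g
    for m in range(bank.shape[0]):
        power = np.abs(np.fft.ifft2(F * bank[m])) ** 2
        pooled = power.reshape(g, cell, g, cell).mean(axis=(1, 3))
        desc[m * g * g:(m + 1) * g * g] = pooled.ravel()
    return desc


def gist_frames(frames: np.ndarray, spec: FilterBankSpec = DEFAULT_SPEC
                ) -> np.ndarray:
    """Descriptors for a stack of frames (frames x H x W)."""
    bank = build_filter_bank(spec)
    return np.stack([gist_frame(f, bank=bank, spec=spec) for f in frames])


def gist_video_pcs(frames_by_video: np.ndarray,
                   n_components: int = 20,
                   spec: FilterBankSpec = DEFAULT_SPEC,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-video gist feature matrix.

    frames_by_video: (videos, frames, H, W).  All frame descriptors are
    pooled, reduced by PCA, and the first ``n_components`` component
    scores averaged across each video's frames.  Returns
    (videos x n_components matrix, explained-variance ratios of the
    retained components).
    """
    frames_by_video = np.asarray(frames_by_video, dtype=float)
    n_videos, n_frames = frames_by_video.shape[:2]
    total = n_videos * n_frames
    if total <= n_components:
        raise DataError(
            f"{total} frames cannot support {n_components} components")
    bank = build_filter_bank(spec)
    desc = np.stack([
        gist_frame(frames_by_video[v, t], bank=bank, spec=spec)
        for v in range(n_videos) for t in range(n_frames)])
    pca = PCA(n_components=n_components, svd_solver="auto",
              random_state=0).fit(desc)
    scores = pca.transform(desc).reshape(n_videos, n_frames, n_components)
    return scores.mean(axis=1), pca.explained_variance_ratio_
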