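"""Configuration objects and error taxonomy for the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any


class ConfigError(ValueError):
    """Invalid configuration (bad counts, proportions, missing paths)."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    The defaults emulate the condition-rich group experiment the pipeline
    analyzes: 60 everyday actions, each depicted by one video exemplar per
    set in two video sets, responses split into odd and even runs, and
    9-12 online raters per rating experiment.

    Parameters
    ----------
    n_videos_per_set:
        Number of action conditions per video set (60).
    n_sets:
        Number of video sets; fixed at 2 (each action has one exemplar
        per set).
    n_splits:
        Number of run splits; fixed at 2 (odd/even runs).
    n_voxels:
        Total voxels simulated, including unreliable noise voxels.
    n_networks:
        Number of planted tuning networks among the signal voxels.
    fraction_noise_voxels:
        Proportion of voxels carrying no stimulus-driven signal.
    n_raters:
        Raters per video in each behavioral rating experiment.
    frame_size:
        Side length in pixels of generated grayscale video frames.
    n_frames_per_video:
        Frames generated per video for the gist stage.
    noise_signal_ratio:
        Run-noise standard deviation for a signal voxel, as a fraction of
        that voxel's across-condition signal standard deviation.  The
        default 0.5 puts expected within-set split-half reliability of
        signal voxels at 1/(1+0.5^2) = 0.8, with noise voxels near 0,
        reproducing the qualitative shape of an empirical reliability
        curve (steep rise, then plateau).
    tuning_jitter:
        Standard deviation of per-voxel tuning jitter around the network
        tuning vector, expressed as a fraction of the tuning norm.
    exemplar_jitter:
        Standard deviation of the per-set perturbation of each action's
        rating prototype; the two sets share actions but differ in
        exemplar videos.
    signal_strength:
        Norm of each network tuning vector.
    seed:
        Base seed; all generator randomness derives from it.
    """

    n_videos_per_set: int = 60
    n_sets: int = 2
    n_splits: int = 2
    n_voxels: int = 2000
    n_networks: int = 5
    fraction_noise_voxels: float = 0.3
    n_raters: int = 12
    frame_size: int = 128
    n_frames_per_video: int = 4
    noise_signal_ratio: float = 0.5
    tuning_jitter: float = 0.1
    exemplar_jitter: float = 0.05
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_videos_per_set", "n_voxels", "n_networks",
                     "n_raters", "frame_size", "n_frames_per_video"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_sets != 2:
            raise ConfigError("n_sets is fixed at 2")
        if self.n_splits != 2:
            raise ConfigError("n_splits is fixed at 2 (odd/even)")
        if not 0.0 <= self.fraction_noise_voxels <= 1.0:
            raise ConfigError("fraction_noise_voxels must lie in [0, 1]")
        for name in ("noise_signal_ratio", "tuning_jitter",
                     "exemplar_jitter", "signal_strength"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    mode is "synthetic" (default; inputs generated with planted ground
    truth) or "real" (inputs read from ``ratings_path``, ``responses_path``
    and ``frames_path``).
    """

    mode: str = "synthetic"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    ratings_path: str | None = None
    responses_path: str | None = None
    frames_path: str | None = None
    out_dir: str = "actionenc_out"
    # stage parameters
    variance_threshold: float = 0.95
    cutoff_grid_start: float = -1.0
    cutoff_grid_stop: float = 0.9
    cutoff_grid_step: float = 0.05
    n_lambdas: int = 100
    folds: int = 10
    q_threshold: float = 0.01
    k: int = 5
    k_range: tuple[int, int] = (2, 20)
    replicates: int = 10
    max_iter: int = 500
    n_shuffles: int = 100
    gist_n_components: int = 20
    stages: tuple[str, ...] = (
        "simulate", "features", "reliability", "encoding",
        "clustering", "gist", "prefmap",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError("mode must be 'synthetic' or 'real'")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if not 0 < self.variance_threshold <= 1:
            raise ConfigError("variance_threshold must lie in (0, 1]")
        if self.n_lambdas < 2:
            raise ConfigError("n_lambdas must be at least 2")
        if self.folds < 2:
            raise ConfigError("folds must be at least 2")
        if not 0 < self.q_threshold < 1:
            raise ConfigError("q_threshold must lie in (0, 1)")
        if self.k < 1:
            raise ConfigError("k must be positive")
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]
        if len(self.k_range) != 2 or self.k_range[0] < 2 \
                or self.k_range[1] < self.k_range[0]:
            raise ConfigError("k_range must be (lo, hi) with 2 <= lo <= hi")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["k_range"] = list(d["k_range"])
        return d

    def hash(self) -> str:
        """Stable hash of the full configuration, used for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
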