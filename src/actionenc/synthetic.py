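"""Synthetic study generator with planted ground truth.

Everything the pipeline consumes — per-rater binary feature ratings,
per-voxel condition responses in two video sets with odd/even run splits,
and grayscale video frames — can be generated here with known structure:
rating prototypes drawn from a small archetype library (so the ratings PCA
has recoverable low-rank structure), voxel responses driven by a small
number of planted tuning networks plus Gaussian run noise, and frames
containing oriented gratings or localized blobs with recorded parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SyntheticConfig
from .reliability import VoxelResponseSet

# 20 effectors on the clickable body map (lateralization already collapsed:
# "hands" covers left, right or both).
BODY_PARTS = (
    "eyes", "nose", "mouth", "ears", "head", "neck", "shoulders", "chest",
    "torso", "back", "arms", "elbows", "forearms", "hands", "fingers",
    "waist", "butt", "legs", "knees", "feet",
)

# The five yes/no action-target questions.
TARGETS = ("object", "another_person", "actor", "near_space", "far_space")

# Archetype library: (body-part prototype, target prototype) pairs.  Each
# prototype is a Bernoulli probability vector.  Seven distinct body-part
# patterns with five target patterns give the averaged ratings a low-rank
# structure comparable to real rating data (a handful of components carry
# ~95% of the variance).
_B = {name: i for i, name in enumerate(BODY_PARTS)}
_T = {name: i for i, name in enumerate(TARGETS)}


def _body_proto(**parts: float) -> np.ndarray:
    p = np.full(len(BODY_PARTS), 0.02)
    for name, v in parts.items():
        p[_B[name]] = v
    return p


def _target_proto(**targets: float) -> np.ndarray:
    p = np.full(len(TARGETS), 0.02)
    for name, v in targets.items():
        p[_T[name]] = v
    return p


ARCHETYPES: tuple[tuple[np.ndarray, np.ndarray], ...] = (
    # fine manipulation: hands/fingers on near objects (knitting, writing)
    (_body_proto(hands=0.97, fingers=0.95, arms=0.8, forearms=0.7,
                 eyes=0.9),
     _target_proto(object=0.97, near_space=0.92)),
    # coarse object handling: arms and hands, near space (laundry, cooking)
    (_body_proto(hands=0.95, arms=0.95, forearms=0.85, shoulders=0.6,
                 torso=0.5, eyes=0.85),
     _target_proto(object=0.95, near_space=0.95)),
    # upper-body action in near space (golfing, sweeping)
    (_body_proto(arms=0.95, shoulders=0.9, torso=0.85, back=0.7,
                 hands=0.9, waist=0.6, eyes=0.7),
     _target_proto(object=0.7, near_space=0.95, far_space=0.5)),
    # whole-body locomotion toward far space (running, soccer)
    (_body_proto(legs=0.97, feet=0.95, knees=0.9, torso=0.85, arms=0.7,
                 waist=0.6, butt=0.5),
     _target_proto(far_space=0.97, near_space=0.3)),
    # person-directed social action (shaking hands, talking)
    (_body_proto(eyes=0.95, mouth=0.9, head=0.9, ears=0.7, hands=0.6,
                 arms=0.5, neck=0.5),
     _target_proto(another_person=0.97, actor=0.5)),
    # actor-directed / self-care (washing face, laughing)
    (_body_proto(head=0.95, eyes=0.85, mouth=0.85, nose=0.7, hands=0.8,
                 neck=0.6),
     _target_proto(actor=0.97, near_space=0.5)),
    # seated observation / minimal movement (reading, watching)
    (_body_proto(eyes=0.97, head=0.7, hands=0.5, torso=0.4),
     _target_proto(object=0.8, near_space=0.7, actor=0.4)),
)


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic voxel response set.

    network_label is 0 for pure-noise voxels and 1..K for network voxels;
    tuning_matrix holds the K network tuning vectors over the F design
    features; signal_sd / noise_sd are the per-voxel across-condition
    signal standard deviation and run-noise standard deviation.
    """

    network_label: np.ndarray
    tuning_matrix: np.ndarray
    signal_sd: np.ndarray
    noise_sd: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.tuning_matrix)):
            raise ValueError("tuning_matrix must be finite")
        if np.any(self.noise_sd < 0) or np.any(self.signal_sd < 0):
            raise ValueError("standard deviations must be nonnegative")

    @property
    def reliable_mask(self) -> np.ndarray:
        return self.network_label > 0


@dataclass
class RatingTensors:
    """Per-rater binary ratings for one rating variant.

    body: videos x 20 body parts x raters; target: videos x 5 targets x
    raters.  Prototypes (the latent Bernoulli probabilities) are kept for
    test assertions.
    """

    body: np.ndarray
    target: np.ndarray
    body_prototypes: np.ndarray
    target_prototypes: np.ndarray
    video_ids: list[str]
    variant: str


def _video_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"a{a:02d}_set{s}" for s in range(1, cfg.n_sets + 1)
            for a in range(cfg.n_videos_per_set)]


def _prototypes(cfg: SyntheticConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-video involvement prototypes (videos x features).

    Each action gets an archetype (cycled) plus per-action jitter; the two
    exemplar videos of an action (one per set) perturb that prototype
    independently, so sets correlate strongly but not perfectly.
    """
    n_act = cfg.n_videos_per_set
    body = np.empty((cfg.n_sets * n_act, len(BODY_PARTS)))
    tgt = np.empty((cfg.n_sets * n_act, len(TARGETS)))
    for a in range(n_act):
        bp, tp = ARCHETYPES[a % len(ARCHETYPES)]
        bp = np.clip(bp + rng.normal(0, 0.03, bp.shape), 0.01, 0.99)
        # the five target questions vary more independently across actions
        # (an action can have several targets), so per-action variation is
        # larger than for body parts
        tp = np.clip(tp + rng.normal(0, 0.15, tp.shape), 0.01, 0.99)
        for s in range(cfg.n_sets):
            i = s * n_act + a
            body[i] = np.clip(
                bp + rng.normal(0, cfg.exemplar_jitter, bp.shape), 0.01, 0.99)
            tgt[i] = np.clip(
                tp + rng.normal(0, cfg.exemplar_jitter, tp.shape), 0.01, 0.99)
    return body, tgt


def generate_ratings(cfg: SyntheticConfig,
                     prototypes: tuple[np.ndarray, np.ndarray] | None = None,
                     ) -> dict[str, RatingTensors]:
    """Simulate the four online rating experiments.

    Returns a dict with keys "involvement" and "visibility", each a
    RatingTensors of independent Bernoulli draws around per-video
    prototypes.  Visibility prototypes are a noisy superset of the
    involvement prototypes (whatever is involved tends to be visible, plus
    incidental visible features), so the two variants correlate imperfectly.

    ``prototypes`` overrides the involvement (body, target) prototype
    matrices, mainly for degenerate-case tests.
    """
    rng = np.random.default_rng([int(cfg.seed), 1])
    vids = _video_ids(cfg)
    if prototypes is None:
        body_p, tgt_p = _prototypes(cfg, rng)
    else:
        body_p, tgt_p = (np.asarray(p, dtype=float) for p in prototypes)
        if body_p.shape != (len(vids), len(BODY_PARTS)) \
                or tgt_p.shape != (len(vids), len(TARGETS)):
            raise ConfigError("prototype shape does not match configuration")

    # visibility: involvement attenuated, plus baseline visibility and
    # independent incidental content (off-screen involved parts, visible
    # uninvolved parts), so the two variants correlate imperfectly
    vis_body_p = np.clip(
        0.5 * body_p + 0.28 + rng.normal(0, 0.22, body_p.shape), 0.0, 1.0)
    vis_tgt_p = np.clip(
        0.5 * tgt_p + 0.28 + rng.normal(0, 0.22, tgt_p.shape), 0.0, 1.0)
    if prototypes is not None:
        # degenerate prototypes propagate verbatim to visibility
        vis_body_p, vis_tgt_p = body_p, tgt_p

    out = {}
    for variant, bp, tp in (("involvement", body_p, tgt_p),
                            ("visibility", vis_body_p, vis_tgt_p)):
        body = (rng.random((len(vids), len(BODY_PARTS), cfg.n_raters))
                < bp[:, :, None]).astype(np.int8)
        tgt = (rng.random((len(vids), len(TARGETS), cfg.n_raters))
               < tp[:, :, None]).astype(np.int8)
        out[variant] = RatingTensors(body, tgt, bp, tp, vids, variant)
    return out


def generate_voxel_responses(cfg: SyntheticConfig,
                             design_by_set: dict[int, np.ndarray],
                             ) -> tuple[VoxelResponseSet, GroundTruth]:
    """Simulate per-voxel response magnitudes with planted network tuning.

    For a voxel v in network n, the response to video i of set s in either
    run split is ``design_s[i] @ (tuning[n] + jitter_v) + eps`` with
    eps ~ N(0, noise_sd_v^2) drawn independently per split (and set).
    Noise voxels carry no stimulus-driven signal.  Run-noise sd is
    ``cfg.noise_signal_ratio`` times the voxel's across-condition signal
    sd (noise voxels use the median signal-voxel scale).
    """
    designs = {}
    for s in range(1, cfg.n_sets + 1):
        if s not in design_by_set:
            raise ConfigError(f"design for set {s} missing")
        X = np.asarray(design_by_set[s], dtype=float)
        if X.shape[0] != cfg.n_videos_per_set:
            raise ConfigError(
                f"design for set {s} has {X.shape[0]} rows, expected "
                f"{cfg.n_videos_per_set}")
        designs[s] = X
    n_feat = designs[1].shape[1]
    if any(X.shape[1] != n_feat for X in designs.values()):
        raise ConfigError("design matrices must share feature dimension")

    rng = np.random.default_rng([int(cfg.seed), 2])
    n_noise = int(round(cfg.fraction_noise_voxels * cfg.n_voxels))
    n_signal = cfg.n_voxels - n_noise
    labels = np.zeros(cfg.n_voxels, dtype=int)
    if n_signal:
        labels[n_noise:] = 1 + (np.arange(n_signal) % cfg.n_networks)
    rng.shuffle(labels)

    tuning = rng.normal(size=(cfg.n_networks, n_feat))
    tuning *= cfg.signal_strength / np.linalg.norm(tuning, axis=1,
                                                   keepdims=True)

    # per-voxel tuning = network tuning + jitter (sd = tuning_jitter *
    # tuning norm, split across components)
    voxel_tuning = np.zeros((cfg.n_voxels, n_feat))
    sig = labels > 0
    if sig.any():
        base = tuning[labels[sig] - 1]
        comp_sd = (cfg.tuning_jitter * np.linalg.norm(base, axis=1)
                   / np.sqrt(n_feat))
        voxel_tuning[sig] = base + rng.normal(size=base.shape) \
            * comp_sd[:, None]

    clean = {s: voxel_tuning @ designs[s].T for s in designs}  # voxels x vids
    signal_sd = np.std(np.concatenate(list(clean.values()), axis=1), axis=1)
    scale = np.median(signal_sd[sig]) if sig.any() else 1.0
    noise_sd = np.where(sig, cfg.noise_signal_ratio * signal_sd,
                        max(scale, 1e-12))

    responses = {}
    for s in designs:
        for split in ("odd", "even"):
            eps = rng.normal(size=clean[s].shape) * noise_sd[:, None]
            responses[(s, split)] = clean[s] + eps

    side = int(np.ceil(cfg.n_voxels ** (1 / 3)))
    coords = np.array(list(np.ndindex(side, side, side))[:cfg.n_voxels])
    data = VoxelResponseSet(
        responses=responses,
        voxel_coords=coords,
        mask_shape=(side, side, side),
        condition_ids={s: [f"a{a:02d}" for a in range(cfg.n_videos_per_set)]
                       for s in designs},
    )
    truth = GroundTruth(network_label=labels, tuning_matrix=tuning,
                        signal_sd=signal_sd, noise_sd=noise_sd,
                        seed=cfg.seed)
    return data, truth


def generate_frames(cfg: SyntheticConfig
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate grayscale frame stacks with controlled low-level structure.

    Returns (frames, params): frames is (videos, frames, H, W) in [0, 1];
    params records each video's content type, orientation (radians),
    spatial frequency (cycles/image) and blob position for test assertions.
    Gratings drift in phase across frames; blobs jitter in position.
    """
    if cfg.frame_size < 64:
        raise ConfigError("frame_size must be at least 64 (8x8 pooling grid)")
    rng = np.random.default_rng([int(cfg.seed), 3])
    vids = _video_ids(cfg)
    n = cfg.frame_size
    yy, xx = np.mgrid[0:n, 0:n] / n
    frames = np.empty((len(vids), cfg.n_frames_per_video, n, n))
    rows = []
    orientations = np.linspace(0, np.pi, 12, endpoint=False)
    freqs = np.array([64.0, 32.0, 16.0, 8.0])  # cycles per image
    for i, vid in enumerate(vids):
        kind = "grating" if i % 2 == 0 else "blob"
        theta = float(rng.choice(orientations))
        f = float(rng.choice(freqs))
        cx, cy = rng.uniform(0.2, 0.8, size=2)
        for t in range(cfg.n_frames_per_video):
            if kind == "grating":
                phase = 2 * np.pi * t / max(cfg.n_frames_per_video, 1)
                img = 0.5 + 0.4 * np.cos(
                    2 * np.pi * f * (xx * np.cos(theta) + yy * np.sin(theta))
                    + phase)
            else:
                jx = cx + 0.02 * rng.standard_normal()
                jy = cy + 0.02 * rng.standard_normal()
                r2 = (xx - jx) ** 2 + (yy - jy) ** 2
                img = 0.25 + 0.6 * np.exp(-r2 / (2 * 0.05 ** 2))
            frames[i, t] = np.clip(img, 0.0, 1.0)
        rows.append({"video_id": vid, "kind": kind, "orientation": theta,
                     "cycles_per_image": f, "cx": cx, "cy": cy})
    return frames, pd.DataFrame(rows)
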