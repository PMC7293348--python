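"""Readers and writers at the pipeline's I/O boundary.

Voxel-indexed quantities travel internally as flat per-voxel tables and
are written as NIfTI volumes (via nibabel) only at the boundary, with a
JSON sidecar recording voxel order, condition labels and geometry so that
write + read round-trips exactly.  Ratings and tabular artifacts are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .config import DataError
from .features import DesignMatrix, FeatureSpace, RatingMatrix
from .reliability import VoxelResponseSet


def _embed(values: np.ndarray, coords: np.ndarray,
           shape: tuple[int, int, int], fill: float = np.nan) -> np.ndarray:
    vol_shape = tuple(shape) + values.shape[1:]
    vol = np.full(vol_shape, fill, dtype=float)
    vol[tuple(coords.T)] = values
    return vol


def write_voxel_map(path: str | Path, values: np.ndarray,
                    coords: np.ndarray, shape: tuple[int, int, int],
                    affine: np.ndarray | None = None,
                    fill: float = np.nan) -> None:
    """Write a per-voxel vector (or voxels x k matrix) as a NIfTI volume."""
    vol = _embed(np.asarray(values, dtype=float), coords, shape, fill)
    nib.save(nib.Nifti1Image(vol, affine if affine is not None
                             else np.eye(4)), str(path))


def write_response_set(data: VoxelResponseSet, out_dir: str | Path) -> None:
    """Write a VoxelResponseSet as one 4-D NIfTI per (set, split) plus a
    sidecar JSON carrying voxel order and condition labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (s, split), mat in data.responses.items():
        write_voxel_map(out / f"responses_set{s}_{split}.nii.gz", mat,
                        data.voxel_coords, data.mask_shape, data.affine)
    sidecar = {
        "layout": "one 4-D volume per (set, split); 4th axis = conditions",
        "keys": [[s, split] for s, split in sorted(data.responses)],
        "voxel_coords": data.voxel_coords.tolist(),
        "mask_shape": list(data.mask_shape),
        "condition_ids": {str(s): ids for s, ids in data.condition_ids.items()},
        "affine": data.affine.tolist(),
    }
    (out / "responses.json").write_text(json.dumps(sidecar))


def read_response_set(in_dir: str | Path) -> VoxelResponseSet:
    out = Path(in_dir)
    sidecar_path = out / "responses.json"
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    side = json.loads(sidecar_path.read_text())
    for key in ("keys", "voxel_coords", "mask_shape", "condition_ids"):
        if key not in side:
            raise DataError(f"sidecar missing field '{key}'")
    coords = np.asarray(side["voxel_coords"], dtype=int)
    responses = {}
    for s, split in side["keys"]:
        img = nib.load(str(out / f"responses_set{s}_{split}.nii.gz"))
        vol = np.asarray(img.dataobj, dtype=float)
        mat = vol[tuple(coords.T)]
        n_cond = len(side["condition_ids"][str(s)])
        if mat.shape[1] != n_cond:
            raise DataError(
                f"set {s} {split}: volume has {mat.shape[1]} conditions, "
                f"sidecar lists {n_cond} condition_ids")
        responses[(int(s), split)] = mat
    return VoxelResponseSet(
        responses=responses, voxel_coords=coords,
        mask_shape=tuple(side["mask_shape"]),
        condition_ids={int(s): ids
                       for s, ids in side["condition_ids"].items()},
        affine=np.asarray(side["affine"]))


def write_ratings_csv(path: str | Path, tensor: np.ndarray,
                      feature_names: list[str], video_ids: list[str]) -> None:
    """Long-format per-rater ratings: video_id, rater_id, feature, value."""
    n_vid, n_feat, n_rat = tensor.shape
    vid_idx, feat_idx, rat_idx = np.meshgrid(
        np.arange(n_vid), np.arange(n_feat), np.arange(n_rat), indexing="ij")
    df = pd.DataFrame({
        "video_id": np.asarray(video_ids)[vid_idx.ravel()],
        "rater_id": rat_idx.ravel(),
        "feature": np.asarray(feature_names)[feat_idx.ravel()],
        "value": tensor.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_ratings_csv(path: str | Path
                     ) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of write_ratings_csv; preserves first-seen ordering."""
    df = pd.read_csv(path)
    required = {"video_id", "rater_id", "feature", "value"}
    if not required.issubset(df.columns):
        raise DataError(
            f"ratings CSV missing columns {sorted(required - set(df.columns))}")
    if not df["value"].isin([0, 1]).all():
        raise DataError("ratings CSV field 'value' must be binary")
    vids = list(dict.fromkeys(df["video_id"]))
    feats = list(dict.fromkeys(df["feature"]))
    raters = sorted(df["rater_id"].unique())
    tensor = np.full((len(vids), len(feats), len(raters)), np.nan)
    vi = {v: i for i, v in enumerate(vids)}
    fi = {f: i for i, f in enumerate(feats)}
    ri = {r: i for i, r in enumerate(raters)}
    tensor[df["video_id"].map(vi), df["feature"].map(fi),
           df["rater_id"].map(ri)] = df["value"]
    return tensor, feats, vids


def write_rating_matrix(path_prefix: str | Path, rm: RatingMatrix) -> None:
    p = Path(path_prefix)
    pd.DataFrame(rm.values, index=rm.video_ids,
                 columns=rm.feature_names).to_csv(f"{p}.csv",
                                                  index_label="video_id")
    Path(f"{p}.json").write_text(json.dumps({"variant": rm.variant}))


def write_feature_space(path_prefix: str | Path, fs: FeatureSpace) -> None:
    p = Path(path_prefix)
    cols = [f"pc{j + 1}" for j in range(fs.n_components_retained)]
    pd.DataFrame(fs.scores, index=fs.video_ids, columns=cols).to_csv(
        f"{p}_scores.csv", index_label="video_id")
    pd.DataFrame(fs.loadings, index=fs.feature_names, columns=cols).to_csv(
        f"{p}_loadings.csv", index_label="feature")
    Path(f"{p}.json").write_text(json.dumps({
        "name": fs.name,
        "n_components_retained": fs.n_components_retained,
        "variance_threshold": fs.variance_threshold,
        "explained_variance": fs.explained_variance.tolist(),
        "feature_means": fs.feature_means.tolist(),
        "feature_names": fs.feature_names,
    }))


def write_design_matrix(path_prefix: str | Path, dm: DesignMatrix) -> None:
    p = Path(path_prefix)
    cols = [f"{prov['space']}_c{prov['component']}"
            for prov in dm.column_provenance]
    pd.DataFrame(dm.values, index=dm.video_ids, columns=cols).to_csv(
        f"{p}.csv", index_label="video_id")
    Path(f"{p}.json").write_text(json.dumps({
        "column_provenance": dm.column_provenance, "set_id": dm.set_id,
        "video_ids": dm.video_ids}))


def read_design_matrix(path_prefix: str | Path) -> DesignMatrix:
    p = Path(path_prefix)
    side = json.loads(Path(f"{p}.json").read_text())
    df = pd.read_csv(f"{p}.csv", index_col="video_id")
    if list(df.index) != side["video_ids"]:
        raise DataError("design CSV video order disagrees with sidecar "
                        "video_ids")
    return DesignMatrix(values=df.to_numpy(),
                        column_provenance=side["column_provenance"],
                        video_ids=side["video_ids"],
                        set_id=side["set_id"])


def write_cluster_solution(path_prefix: str | Path, sol: ClusterSolution,
                           coords: np.ndarray,
                           shape: tuple[int, int, int]) -> None:
    p = Path(path_prefix)
    vol = _embed(sol.labels.astype(float)[:, None], coords, shape,
                 fill=0.0)[..., 0]
    nib.save(nib.Nifti1Image(vol.astype(np.int16), np.eye(4)),
             f"{p}_labels.nii.gz")
    pd.DataFrame(sol.centroids).to_csv(f"{p}_centroids.csv", index_label="cluster")
    meta = {"k": sol.k, "inertia": sol.inertia,
            "diagnostics": sol.diagnostics,
            "labels": sol.labels.tolist()}
    if sol.colors is not None:
        meta["colors"] = sol.colors.tolist()
    Path(f"{p}.json").write_text(json.dumps(meta))


def read_cluster_solution(path_prefix: str | Path) -> ClusterSolution:
    p = Path(path_prefix)
    meta = json.loads(Path(f"{p}.json").read_text())
    centroids = pd.read_csv(f"{p}_centroids.csv",
                            index_col="cluster").to_numpy()
    colors = np.asarray(meta["colors"]) if "colors" in meta else None
    return ClusterSolution(labels=np.asarray(meta["labels"], dtype=int),
                           centroids=centroids, k=int(meta["k"]),
                           inertia=float(meta["inertia"]),
                           diagnostics=meta.get("diagnostics", {}),
                           colors=colors)


def write_curve(path: str | Path, curve: pd.DataFrame) -> None:
    curve.to_csv(path, index=False)
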