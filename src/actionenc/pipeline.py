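"""End-to-end orchestration of the encoding pipeline.

Stage order: simulate/ingest -> feature spaces -> reliability ->
encoding + screening -> clustering (+ d' robustness) -> gist ->
preference maps.  Every run writes a provenance manifest carrying the
config hash and seeds; in synthetic mode a rerun with an identical config
reproduces identical outputs, and a ground-truth comparison report is
included.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .clustering import (coassignment_dprime, k_diagnostics,
                         kmeans_correlation, match_centroids, mds_colors,
                         shuffled_baseline)
from .config import ConfigError, DataError, PipelineConfig
from .encoding import fit_encoding
from .features import (average_ratings, combine_spaces, feature_correlations,
                       fit_pca, rdm_correlation)
from .gist import gist_video_pcs
from .prefmaps import preference_map
from .reliability import reliability_curve, select_cutoff
from .synthetic import (generate_frames, generate_ratings,
                        generate_voxel_responses, BODY_PARTS, TARGETS)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for machine-readable reports."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _build_designs(ratings, cfg: PipelineConfig, variant: str):
    """Average -> per-space PCA -> combined design, split per video set."""
    rt = ratings[variant]
    body_rm = average_ratings(rt.body, list(BODY_PARTS), rt.video_ids,
                              variant=variant)
    tgt_rm = average_ratings(rt.target, list(TARGETS), rt.video_ids,
                             variant=variant)
    body_fs = fit_pca(body_rm, cfg.variance_threshold,
                      name=f"{variant}_body")
    tgt_fs = fit_pca(tgt_rm, cfg.variance_threshold,
                     name=f"{variant}_target")
    dm = combine_spaces(body_fs, tgt_fs)
    n = cfg.synthetic.n_videos_per_set
    per_set = {1: dm.values[:n], 2: dm.values[n:2 * n]}
    return {"body_space": body_fs, "target_space": tgt_fs, "design": dm,
            "design_by_set": per_set}


def _reliability_stage(data, cfg: PipelineConfig):
    cutoffs = np.round(np.arange(cfg.cutoff_grid_start,
                                 cfg.cutoff_grid_stop + 1e-9,
                                 cfg.cutoff_grid_step), 10)
    out = {}
    for scheme in ("across_set", "within_set"):
        res = reliability_curve(data, cutoffs=cutoffs, scheme=scheme)
        res.selected_cutoff = select_cutoff(res.curve)
        out[scheme] = res
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the artifact bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    stage = "init"
    try:
        # ---- simulate / ingest -------------------------------------
        stage = "simulate"
        scfg = config.synthetic
        if config.mode == "synthetic":
            ratings = generate_ratings(scfg)
            results["ratings"] = ratings
        else:
            ratings = _ingest_real_ratings(config)
            results["ratings"] = ratings

        # ---- feature spaces ----------------------------------------
        stage = "features"
        feats = {v: _build_designs(ratings, config, v)
                 for v in ("involvement", "visibility")}
        results["features"] = feats
        inv = feats["involvement"]
        results["feature_correlations"] = feature_correlations(inv["design"])
        for v in feats:
            aio.write_design_matrix(out_dir / f"design_{v}",
                                    feats[v]["design"])

        # responses need the involvement design in synthetic mode
        stage = "simulate"
        if config.mode == "synthetic":
            data, truth = generate_voxel_responses(
                scfg, inv["design_by_set"])
            results["truth"] = truth
        else:
            data = aio.read_response_set(config.responses_path)
            truth = None
        results["responses"] = data
        aio.write_response_set(data, out_dir / "responses")

        # ---- reliability -------------------------------------------
        if "reliability" in config.stages:
            stage = "reliability"
            rel = _reliability_stage(data, config)
            results["reliability"] = rel
            for scheme, res in rel.items():
                aio.write_curve(out_dir / f"reliability_curve_{scheme}.csv",
                                res.curve)
                aio.write_voxel_map(out_dir / f"reliability_{scheme}.nii.gz",
                                    res.voxel_r[:, None], data.voxel_coords,
                                    data.mask_shape)
        else:
            rel = None

        # ---- encoding ----------------------------------------------
        fits = None
        if "encoding" in config.stages:
            stage = "encoding"
            if rel is None:
                raise DataError("encoding requires the reliability stage")
            across = rel["across_set"]
            reliable = across.surviving(across.selected_cutoff)
            results["reliable_mask"] = reliable
            resp = {s: data.split_average(s)[reliable] for s in data.sets}
            fits = fit_encoding(inv["design_by_set"], resp,
                                n_lambdas=config.n_lambdas,
                                folds=config.folds,
                                q_threshold=config.q_threshold)
            results["encoding"] = fits
            table = pd.DataFrame({
                "voxel": np.flatnonzero(reliable),
                **{f"r_cv_train{s}": fits[s].r_cv for s in fits},
                **{f"lambda_train{s}": fits[s].lambda_per_voxel
                   for s in fits},
                "included": fits[data.sets[0]].included_mask,
            })
            table.to_csv(out_dir / "encoding_table.csv", index=False)

        # ---- clustering --------------------------------------------
        if "clustering" in config.stages and fits is not None:
            stage = "clustering"
            included = fits[data.sets[0]].included_mask
            sols = {}
            rng = np.random.default_rng([config.seed, 10])
            for s in data.sets:
                sol = kmeans_correlation(fits[s].weights[included],
                                         config.k,
                                         replicates=config.replicates,
                                         max_iter=config.max_iter, seed=rng)
                sol.colors = mds_colors(sol.centroids)
                sols[s] = sol
            s1, s2 = data.sets[:2]
            both = sols[s1].included & sols[s2].included
            dp = coassignment_dprime(sols[s1].labels[both],
                                     sols[s2].labels[both])
            base = shuffled_baseline(sols[s1].labels[both],
                                     sols[s2].labels[both],
                                     n_shuffles=config.n_shuffles,
                                     seed=config.seed)
            pairing, pair_r = match_centroids(sols[s1], sols[s2])
            diag = k_diagnostics(fits[s1].weights[included],
                                 k_range=range(config.k_range[0],
                                               config.k_range[1] + 1),
                                 replicates=config.replicates,
                                 max_iter=config.max_iter,
                                 seed=config.seed)
            resp_sol = kmeans_correlation(
                data.split_average(s1)[results["reliable_mask"]][included],
                config.k, replicates=config.replicates,
                max_iter=config.max_iter,
                seed=np.random.default_rng([config.seed, 11]))
            results["clustering"] = {
                "solutions": sols, "cross_set_dprime": dp,
                "shuffled_baseline": base,
                "centroid_pairing": pairing,
                "centroid_correlations": pair_r,
                "k_diagnostics": diag["table"],
                "response_solution": resp_sol,
                "feature_vs_response_dprime": coassignment_dprime(
                    sols[s1].labels[sols[s1].included & resp_sol.included],
                    resp_sol.labels[sols[s1].included & resp_sol.included],
                ).dprime,
            }
            coords_inc = data.voxel_coords[results["reliable_mask"]][included]
            for s in data.sets:
                aio.write_cluster_solution(out_dir / f"clusters_set{s}",
                                           sols[s], coords_inc,
                                           data.mask_shape)
            pd.DataFrame(diag["table"]).to_csv(
                out_dir / "k_diagnostics.csv", index=False)

        # ---- gist --------------------------------------------------
        gist_scores = None
        if "gist" in config.stages:
            stage = "gist"
            if config.mode == "synthetic":
                frames, frame_params = generate_frames(scfg)
            else:
                frames = np.load(config.frames_path)
                frame_params = None
            gist_scores, gist_evr = gist_video_pcs(
                frames, n_components=config.gist_n_components)
            results["gist"] = {"scores": gist_scores,
                               "explained_variance": gist_evr,
                               "frame_params": frame_params}
            pd.DataFrame(gist_scores).to_csv(out_dir / "gist_pcs.csv",
                                             index=False)
            n = scfg.n_videos_per_set
            results["gist_rdm_r"] = {
                s: rdm_correlation(
                    inv["design_by_set"][s],
                    gist_scores[(s - 1) * n:s * n])
                for s in (1, 2)}

        # ---- preference maps ---------------------------------------
        if "prefmap" in config.stages and fits is not None:
            stage = "prefmap"
            prefs = {}
            # involvement vs visibility on across-set reliable voxels
            vis_fits = fit_encoding(
                feats["visibility"]["design_by_set"],
                {s: data.split_average(s)[results["reliable_mask"]]
                 for s in data.sets},
                n_lambdas=config.n_lambdas, folds=config.folds,
                q_threshold=config.q_threshold)
            s1 = data.sets[0]
            prefs["involvement_vs_visibility"] = preference_map(
                fits[s1].r_cv, vis_fits[s1].r_cv,
                ("involvement", "visibility"))
            # gist vs involvement features on within-set reliable voxels
            if gist_scores is not None and rel is not None:
                within = rel["within_set"]
                wmask = within.surviving(within.selected_cutoff)
                resp_w = {s: data.split_average(s)[wmask]
                          for s in data.sets}
                n = scfg.n_videos_per_set
                gist_by_set = {s: gist_scores[(s - 1) * n:s * n]
                               for s in (1, 2)}
                gist_fits = fit_encoding(
                    gist_by_set, resp_w, n_lambdas=config.n_lambdas,
                    folds=config.folds, q_threshold=config.q_threshold)
                feat_fits_w = fit_encoding(
                    inv["design_by_set"], resp_w,
                    n_lambdas=config.n_lambdas, folds=config.folds,
                    q_threshold=config.q_threshold)
                prefs["gist_vs_features"] = preference_map(
                    gist_fits[s1].r_cv, feat_fits_w[s1].r_cv,
                    ("gist", "features"))
            results["preference_maps"] = prefs

        # ---- ground-truth report -----------------------------------
        if config.mode == "synthetic" and truth is not None:
            stage = "truth_report"
            report = {}
            if rel is not None:
                across = rel["across_set"]
                sel = across.surviving(across.selected_cutoff)
                planted = truth.reliable_mask
                tp = int((sel & planted).sum())
                report["reliability_precision"] = tp / max(int(sel.sum()), 1)
                report["reliability_recall"] = tp / max(int(planted.sum()), 1)
                report["selected_cutoff"] = across.selected_cutoff
            if "clustering" in results:
                inc_global = np.flatnonzero(results["reliable_mask"])[
                    fits[data.sets[0]].included_mask]
                gt_labels = truth.network_label[inc_global]
                sol = results["clustering"]["solutions"][data.sets[0]]
                report["truth_dprime"] = coassignment_dprime(
                    gt_labels, sol.labels).dprime
            results["truth_report"] = report
            (out_dir / "truth_report.json").write_text(
                json.dumps(report, indent=2))

        # ---- provenance manifest -----------------------------------
        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "stages_run": list(config.stages),
            "artifacts": sorted(p.name for p in out_dir.iterdir()
                                if p.name != "manifest.json"),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest,
                                                          indent=2))
        results["manifest"] = manifest
    except Exception as exc:  # noqa: BLE001 - report and re-raise per stage
        report = {"stage": stage, "error": str(exc),
                  "type": type(exc).__name__}
        (out_dir / "error.json").write_text(json.dumps(report, indent=2))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return results


def _ingest_real_ratings(config: PipelineConfig):
    """Adapter for deposited rating CSVs.

    Expects ``ratings_path`` to contain <variant>_body.csv and
    <variant>_target.csv in the long (video_id, rater_id, feature, value)
    format for variants "involvement" and "visibility".
    """
    from .synthetic import RatingTensors
    root = Path(config.ratings_path or "")
    if not root.exists():
        raise ConfigError(f"ratings_path {root} does not exist")
    out = {}
    for variant in ("involvement", "visibility"):
        body, bfeat, vids = aio.read_ratings_csv(
            root / f"{variant}_body.csv")
        tgt, tfeat, vids2 = aio.read_ratings_csv(
            root / f"{variant}_target.csv")
        if vids != vids2:
            raise DataError(f"{variant}: body and target CSVs list "
                            "different videos")
        out[variant] = RatingTensors(
            body=body, target=tgt,
            body_prototypes=np.full((len(vids), len(bfeat)), np.nan),
            target_prototypes=np.full((len(vids), len(tfeat)), np.nan),
            video_ids=vids, variant=variant)
    return out
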