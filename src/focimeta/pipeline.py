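"""End-to-end orchestration of the contrastive meta-analysis pipeline.

The full chain is: read/simulate foci -> convert to MNI -> (optional) ALE with
permutation thresholding -> k-means + elbow -> cluster-by-label contrast ->
overlap filtering -> cluster-ID classification -> ROI cubes.  Every stage
writes its artifact into the output directory and the run ends with a
manifest (parameter echo, seeds, per-stage row counts, library versions) that
fully determines re-execution.  A run may also start from a K x 2 contingency
table, skipping the spatial stages - that path is exact given published count
tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ale, classify, cluster, contrast, io, roi, synthetic
from .exceptions import ConfigError, StageError
from .grid import default_grid, save_nifti

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the published analysis settings."""

    # input: exactly one of foci_path / contingency_path / synthetic
    foci_path: str | None = None
    foci_dialect: str = "tsv"
    foci_label: int | None = None
    contingency_path: str | None = None
    synthetic: dict | None = None            # SyntheticSpec kwargs or {'preset': 'brand_study'}
    tal_variant: str = "lancaster_spm"
    # ALE
    run_ale: bool = False
    voxel_size: float = 2.0
    fwhm: float = 10.0
    n_perm: int = 1000
    cluster_forming_p: float = 1e-4
    cluster_fwe_p: float = 0.05
    connectivity: int = 26
    # clustering
    k: int | str = "auto"
    k_min: int = 1
    k_max: int = 40
    ratio: float = 0.1
    offset: int = 2
    n_restarts: int = 10
    # contrast
    sig_alpha: float = 0.1
    overlap_p: float = 0.45
    # classifier
    model_specs: tuple = ("gradient_boosted_trees", "random_forest", "logistic")
    n_folds: int = 5
    # ROI
    roi_edge: float = 18.0
    # bookkeeping
    seed: int = 0
    out_dir: str = "focimeta_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "model_specs" in raw:
            raw["model_specs"] = tuple(raw["model_specs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["model_specs"] = list(self.model_specs)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _load_foci(config: RunConfig, outdir: Path, manifest: dict) -> pd.DataFrame:
    if config.foci_path:
        foci = io.read_foci_table(config.foci_path, config.foci_dialect,
                                  label=config.foci_label)
    elif config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        preset = spec_kwargs.pop("preset", None)
        if preset == "brand_study":
            spec = synthetic.brand_study_spec(seed=config.seed)
        elif preset is None:
            if "clusters" in spec_kwargs:
                spec_kwargs["clusters"] = tuple(
                    synthetic.PlantedCluster(**c) for c in spec_kwargs["clusters"]
                )
            spec_kwargs.setdefault("seed", config.seed)
            spec = synthetic.SyntheticSpec(**spec_kwargs)
        else:
            raise ConfigError(f"unknown synthetic preset {preset!r}")
        foci, truth = synthetic.generate(spec)
        truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        manifest["synthetic_centers"] = truth.centers.tolist()
    else:
        raise ConfigError("config needs foci_path, contingency_path or synthetic")
    foci = io.convert_to_mni(foci, config.tal_variant)
    io.write_foci_table(foci, outdir / "foci_mni.tsv")
    io.summarize(foci).to_csv(outdir / "descriptives.csv", index=False)
    manifest["n_foci"] = len(foci)
    manifest["n_foci_label1"] = int((foci["label"] == 1).sum())
    manifest["n_foci_label0"] = int((foci["label"] == 0).sum())
    return foci


def _run_ale_stage(config: RunConfig, foci: pd.DataFrame, outdir: Path,
                   manifest: dict) -> None:
    grid = default_grid(voxel_size=config.voxel_size)
    kernel = ale.build_kernel(fwhm_override=config.fwhm,
                              voxel_size=config.voxel_size)
    for label in (1, 0):
        sub = foci[foci["label"] == label]
        if not len(sub):
            continue
        ma_maps = [
            ale.compute_ma_map(block[["x", "y", "z"]].to_numpy(), kernel, grid)
            for _, block in sub.groupby("study_id", sort=False)
        ]
        ale_map = ale.compute_ale_map(ma_maps)
        counts = sub.groupby("study_id", sort=False).size().tolist()
        null = ale.sample_null(counts, kernel, grid, n_perm=config.n_perm,
                               seed=config.seed + label,
                               cluster_forming_p=config.cluster_forming_p,
                               connectivity=config.connectivity)
        thresholded, rows = ale.threshold_ale(
            ale_map, null, grid, config.cluster_forming_p,
            config.cluster_fwe_p, config.connectivity)
        save_nifti(ale_map, grid, outdir / f"ale_label{label}.nii.gz")
        save_nifti(thresholded, grid, outdir / f"ale_label{label}_thresh.nii.gz")
        ale.report_to_frame(rows).to_csv(
            outdir / f"ale_label{label}_clusters.csv", index=False)
        manifest[f"ale_label{label}_clusters"] = len(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": _versions(),
    }
    manifest["config"]["model_specs"] = list(config.model_specs)

    stage = "input"
    try:
        if config.contingency_path:
            raw = pd.read_csv(config.contingency_path, sep=None, engine="python")
            cols = {c.lower(): c for c in raw.columns}
            table = contrast.make_contingency(
                raw[cols.get("cluster_id", raw.columns[0])],
                raw[cols.get("label1", cols.get("branded"))].to_numpy(),
                raw[cols.get("label0", cols.get("unbranded"))].to_numpy(),
            )
            foci = None
        else:
            foci = _load_foci(config, outdir, manifest)
            if config.run_ale:
                stage = "ale"
                _run_ale_stage(config, foci, outdir, manifest)
            stage = "cluster"
            km = cluster.ElbowKMeans(
                n_clusters=config.k, k_min=config.k_min, k_max=config.k_max,
                ratio=config.ratio, offset=config.offset,
                n_restarts=config.n_restarts, random_state=config.seed,
            ).fit(foci[["x", "y", "z"]].to_numpy())
            cluster.centroid_table(km.model_).to_csv(outdir / "centroids.csv")
            if km.elbow_report_ is not None:
                km.elbow_report_.to_csv(outdir / "elbow.csv", index=False)
            foci = foci.copy()
            foci["cluster_id"] = [f"cl_{i}" for i in km.labels_]
            foci.to_csv(outdir / "foci_clustered.tsv", sep="\t", index=False)
            manifest["k"] = int(km.n_clusters_)
            manifest["sse"] = float(km.inertia_)
            table = contrast.build_contingency(foci["cluster_id"], foci["label"])

        stage = "contrast"
        con = contrast.ClusterContrast(config.sig_alpha, config.overlap_p)
        con.fit_table(table)
        report = con.report_.join(con.contingency_)
        report.to_csv(outdir / "contrast.csv")
        manifest["chi2"] = con.chi2_
        manifest["chi2_dof"] = con.dof_
        manifest["chi2_p"] = con.pvalue_
        manifest["overlapped_clusters"] = con.roles("overlapped")
        manifest["label1_dominant"] = con.roles("label1_dominant")
        manifest["label0_dominant"] = con.roles("label0_dominant")

        stage = "filter"
        retained = con.contingency_.drop(index=con.roles("overlapped"))
        if foci is not None:
            filtered = con.transform(foci)
            filtered.to_csv(outdir / "foci_filtered.tsv", sep="\t", index=False)
            X, y = classify.encode_onehot(filtered)
        else:
            X, y = classify.dataset_from_contingency(retained)
        manifest["n_surviving"] = int(len(y))
        manifest["n_surviving_label1"] = int(y.sum())

        stage = "classify"
        reports = [
            classify.crossval_evaluate(X, y, spec, n_folds=config.n_folds,
                                       seed=config.seed)
            for spec in config.model_specs
        ]
        eval_df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
        eval_df = eval_df.sort_values("auc", ascending=False).reset_index(drop=True)
        eval_df.to_csv(outdir / "evaluation.csv", index=False)
        manifest["best_model"] = eval_df.loc[0, "model_spec"]
        manifest["best_auc"] = float(eval_df.loc[0, "auc"])
        manifest["proportion_score_auc"] = classify.proportion_score_auc(retained)
        tree_specs = [s for s in config.model_specs
                      if s in ("gradient_boosted_trees", "random_forest")]
        if tree_specs:
            model = classify.make_classifier(tree_specs[0], seed=config.seed)
            model.fit(np.asarray(X, float), y)
            imp = classify.feature_importance(model, list(X.columns))
            imp.to_csv(outdir / "importance.csv")
            manifest["top_feature"] = imp.index[0]

        stage = "roi"
        if foci is not None:
            cubes, cube_rows = [], []
            for role in ("label1_dominant", "label0_dominant"):
                for cid in con.roles(role):
                    members = foci[foci["cluster_id"] == cid]
                    if len(members) < 2:
                        continue
                    rng_df = roi.sigma_range(members[["x", "y", "z"]].to_numpy())
                    center = rng_df["centroid"].to_numpy()
                    cube = roi.build_cube(center, edge=config.roi_edge)
                    cubes.append((role, cid, cube))
                    cube_rows.append({
                        "cluster_id": cid, "role": role,
                        "center_x": center[0], "center_y": center[1],
                        "center_z": center[2], "edge_mm": config.roi_edge,
                    })
            if cube_rows:
                pd.DataFrame(cube_rows).to_csv(outdir / "roi_cubes.csv", index=False)
                grid = default_grid(voxel_size=config.voxel_size)
                for role in ("label1_dominant", "label0_dominant"):
                    sel = [c for r, _, c in cubes if r == role]
                    if sel:
                        vol = roi.rasterize_union(sel, grid)
                        save_nifti(vol.astype(np.float32), grid,
                                   outdir / f"roi_{role}.nii.gz")
                manifest["n_roi_cubes"] = len(cube_rows)
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        if isinstance(err, StageError):
            raise
        raise StageError(stage, str(err)) from err

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("focimeta", "numpy", "scipy", "pandas", "scikit-learn", "xgboost"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
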