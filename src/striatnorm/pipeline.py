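"""Run configuration and end-to-end orchestration.

``run_all`` executes simulate -> intensity-normalize -> ROI extraction ->
ROI correlations -> voxel-wise GLM with permutation FWE -> normative
modelling, writing every product plus a manifest (config, per-stage seeds,
sha256 of each output) so a rerun with the same config is bit-identical.

A single base seed fans out to per-stage seeds by a fixed counter scheme
(``stage_seed = seed + STAGE_OFFSETS[stage]``), so any stage can be rerun
in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import normative as nm
from . import preprocess as pp
from . import roistats as rs
from . import synthetic as syn
from . import voxelwise as vw
from .plots import plot_centiles

__all__ = ["RunConfig", "run_all", "STAGE_OFFSETS"]

log = logging.getLogger("striatnorm")

STAGE_OFFSETS = {"simulate": 0, "volumes": 100, "voxelwise": 200, "normative": 300}


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results"
    alpha: float = 0.001
    extent: int = 50
    n_perm: int = 500
    quantiles: tuple[float, ...] = nm.DEFAULT_QUANTILES
    regions: tuple[str, ...] = syn.REGIONS
    volumes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.extent < 1:
            raise ValueError("extent must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if any(not 0 < q < 1 for q in self.quantiles):
            raise ValueError("quantiles must lie in (0, 1)")
        unknown = set(self.regions) - set(syn.REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("quantiles", "regions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the results directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        outputs.append(p)
        return p

    # -- simulate ----------------------------------------------------------
    log.info("stage simulate")
    s_seed = config.seed + STAGE_OFFSETS["simulate"]
    cohort = syn.generate_cohort(seed=s_seed)
    roi_table = syn.generate_roi_suv(cohort, seed=s_seed + 1)
    write_csv(cohort, "cohort.csv")
    write_csv(roi_table, "roi_table.csv")

    atlas = syn.generate_atlas()
    pp.save_atlas(atlas, out / "atlas.nii.gz")
    outputs += [out / "atlas.nii.gz", out / "atlas_labels.json"]

    extracted = None
    if config.volumes:
        log.info("stage volumes: generate + intensity-normalize + extract")
        v_seed = config.seed + STAGE_OFFSETS["volumes"]
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        norm_vols = []
        rows = []
        for i, row in cohort.iterrows():
            roi_values = {r: roi_table.loc[i, r] for r in syn.REGIONS}
            vol = syn.generate_pet_volume(row, roi_values, atlas, seed=v_seed + i)
            norm = pp.intensity_normalize(vol)
            pp.save_volume(norm, vol_dir / f"{row.subject_id}_norm.nii.gz")
            outputs.append(vol_dir / f"{row.subject_id}_norm.nii.gz")
            norm_vols.append(norm)
            means = pp.extract_roi_means(norm, atlas)
            means.pop("parenchyma", None)
            rows.append({"subject_id": row.subject_id, "age": row.age, "sex": row.sex,
                         **means, "global_mean": pp.global_mean(norm, atlas)})
        extracted = pd.DataFrame(rows)
        write_csv(extracted, "roi_extracted.csv")

    # -- ROI correlations --------------------------------------------------
    log.info("stage roistats")
    corr_input = extracted if extracted is not None else roi_table
    results = rs.pearson_age_correlation(corr_input, regions=config.regions)
    results += rs.sex_stratified_correlation(corr_input, regions=config.regions)
    write_csv(rs.results_frame(results), "roi_correlations.csv")

    # -- voxel-wise GLM ----------------------------------------------------
    if config.volumes:
        log.info("stage voxelwise: GLM + permutation FWE + clusters")
        x_seed = config.seed + STAGE_OFFSETS["voxelwise"]
        design = vw.build_design(cohort, extracted["global_mean"].to_numpy())
        mask = atlas.labels > 0
        stat = vw.fit_glm(norm_vols, design, mask)
        thr = vw.permutation_fwe(
            norm_vols, design, mask, n_perm=config.n_perm, alpha=config.alpha,
            seed=x_seed,
        )
        clusters = vw.cluster_table(stat, thr, extent=config.extent)
        tmap = pp.PETVolume(np.nan_to_num(stat.t), affine=stat.affine, units="normalized")
        pp.save_volume(tmap, out / "tmap_age.nii.gz")
        outputs.append(out / "tmap_age.nii.gz")
        (out / "fwe_threshold.json").write_text(
            json.dumps({"alpha": config.alpha, "n_perm": config.n_perm,
                        "df": stat.df, "threshold_abs_t": thr}, indent=1)
        )
        outputs.append(out / "fwe_threshold.json")
        write_csv(vw.clusters_frame(clusters), "clusters.csv")

    # -- normative model ---------------------------------------------------
    log.info("stage normative")
    n_seed = config.seed + STAGE_OFFSETS["normative"]
    nres = nm.run_normative(roi_table, regions=config.regions, seed=n_seed,
                            quantiles=config.quantiles)
    zrows = []
    for region, res in nres.items():
        model_json = {
            "region": region,
            "basis": {"order": res.model.basis.order,
                      "n_interior_knots": res.model.basis.n_interior_knots,
                      "age_min": res.model.basis.age_min,
                      "age_max": res.model.basis.age_max},
            "m_w": res.model.m_w.tolist(),
            "S_w": res.model.S_w.tolist(),
            "alpha": res.model.alpha,
            "beta": res.model.beta,
            "warp": {"a": res.model.warp.a, "b": res.model.warp.b},
            "nlml": res.model.nlml,
            "ev_train": res.ev_train,
            "ev_test": res.ev_test,
        }
        p = out / f"normative_{region}.json"
        p.write_text(json.dumps(model_json, indent=1))
        outputs.append(p)
        curves = pd.DataFrame({"age": res.centile_ages})
        for q, c in sorted(res.centile_curves.items()):
            curves[f"q{q * 100:g}"] = c
        write_csv(curves, f"centiles_{region}.csv")
        rep = res.test_report
        for sid, z in zip(rep.subject_id, rep.z):
            zrows.append({"region": region, "subject_id": sid, "z": z,
                          "extreme_positive": bool(z > 2), "extreme_negative": bool(z < -2)})
        plot_centiles(res, roi_table, out / f"centiles_{region}.png")
        outputs.append(out / f"centiles_{region}.png")
    write_csv(pd.DataFrame(zrows), "zscores.csv")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "stage_seeds": {k: config.seed + v for k, v in STAGE_OFFSETS.items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("wrote %d outputs to %s", len(outputs), out)
    return out
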