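"""End-to-end pipeline: aggregate -> parcellate -> symmetry -> stats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import io as cio
from .config import RunConfig
from .parcellation import (combine_bilateral, per_scan_densities,
                           per_scan_fields)
from .popmap import (DetectabilityCriteria, PASSAGE_FIELD, ThresholdScheme,
                     classify_detectability, normalize_streamlines,
                     population_average)
from .stats import bh_fdr, fit_lme, voxelwise_lme
from .symmetry import paired_voxel_values, symmetry_table

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("aggregate", "parcellate", "symmetry", "stats")


def _run_id(config: RunConfig, data_dir: Path) -> str:
    # identical analysis settings + identical inputs -> identical run id,
    # regardless of where the directories live
    settings = {k: v for k, v in config.to_dict().items()
                if k not in ("data_dir", "out_dir")}
    h = hashlib.sha256(json.dumps(settings, sort_keys=True).encode())
    for name in ("grid.json", "counts.tsv", "metadata.tsv"):
        p = data_dir / name
        if p.exists():
            h.update(p.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested pipeline stages and write their artifacts.

    Stages always run in order and later stages recompute what they need
    from earlier ones in memory, so any prefix-closed subset of stages is
    valid.  Outputs are fully determined by (inputs, config).
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    last = max(STAGES.index(s) for s in stages)
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scans, metadata, grid = cio.read_dataset(data_dir)
    scheme = ThresholdScheme.from_values(config.thresholds)
    criteria = DetectabilityCriteria(peak_high=config.peak_high,
                                     peak_low=config.peak_low,
                                     mean_min=config.mean_min)

    # ---- aggregate ------------------------------------------------------- #
    left_maps = [normalize_streamlines(s) for s in scans if s.side == "left"]
    right_maps = [normalize_streamlines(s) for s in scans if s.side == "right"]
    pop_l = population_average(left_maps, scheme, config.sample_unit)
    pop_r = population_average(right_maps, scheme, config.sample_unit)
    detect = classify_detectability(pop_l, pop_r, criteria)
    if "aggregate" in stages:
        cio.write_pop_map(out / "pmap_left.tsv", pop_l)
        cio.write_pop_map(out / "pmap_right.tsv", pop_r)
        detect.to_csv(out / "detectability.tsv", sep="\t", index=False)
        (out / "detectability_criteria.json").write_text(json.dumps({
            "peak_high": criteria.peak_high, "peak_low": criteria.peak_low,
            "mean_min": criteria.mean_min}, sort_keys=True))
    pf_areas = list(detect.loc[detect["class"] == PASSAGE_FIELD, "area_id"])

    fields = {}
    size_tables = []
    if last >= STAGES.index("parcellate"):
        for area in pf_areas:
            fields[area] = combine_bilateral(pop_l, pop_r, area,
                                             config.bilateral_threshold)
            size_tables.append(per_scan_fields(
                scans, metadata, area, scheme, config.bilateral_threshold,
                mode=config.field_size_mode))
        sizes = (pd.concat(size_tables, ignore_index=True) if size_tables
                 else pd.DataFrame())
        if "parcellate" in stages:
            rows = []
            for area, fld in fields.items():
                vox = fld.grid.voxels[fld.grid.extract(fld.mask).astype(bool)]
                for x, y in vox:
                    rows.append({"area_id": area, "voxel_x": int(x),
                                 "voxel_y": int(y)})
            pd.DataFrame(rows, columns=["area_id", "voxel_x", "voxel_y"]
                         ).to_csv(out / "fields.tsv", sep="\t", index=False)
            cio.write_boundaries(out / "boundaries.json", fields)
            sizes.to_csv(out / "field_sizes.tsv", sep="\t", index=False)
            for area, fld in fields.items():
                cio.write_nifti_map(out / f"field_{area}.nii",
                                    fld.mask.astype(float), grid)

    if "symmetry" in stages:
        sym = symmetry_table(pop_l, pop_r, band=config.slope_band,
                             r2_min=config.r2_min)
        sym.to_csv(out / "symmetry.tsv", sep="\t", index=False)
        pair_frames = []
        for area in pop_l.areas:
            pairs = paired_voxel_values(pop_l, pop_r, area)
            if len(pairs):
                pair_frames.append(pd.DataFrame(
                    {"area_id": area, "p_left": pairs[:, 0],
                     "p_right": pairs[:, 1]}))
        pairs_out = (pd.concat(pair_frames, ignore_index=True) if pair_frames
                     else pd.DataFrame(columns=["area_id", "p_left", "p_right"]))
        pairs_out.to_csv(out / "symmetry_pairs.tsv", sep="\t", index=False)

    if "stats" in stages and pf_areas and config.field_size_mode == "per_scan":
        # field-size models: one LME per area, FDR across areas per term
        fs_rows = []
        for area in pf_areas:
            tab = sizes[sizes["area_id"] == area]
            res = fit_lme(tab, fixed=config.lme_terms, outcome="size_voxels")
            for _, r in res.terms.iterrows():
                if r["term"] == "intercept":
                    continue
                fs_rows.append({"area_id": area, "term": r["term"],
                                "estimate": r["estimate"], "se": r["se"],
                                "t": r["t"], "p": r["p"],
                                "converged": res.converged})
        fs = pd.DataFrame(fs_rows)
        fs["q"] = float("nan")
        fs["significant"] = False
        for term in fs["term"].unique():
            idx = fs.index[(fs["term"] == term) & fs["converged"]]
            if len(idx):
                rep = bh_fdr(fs.loc[idx, "p"].to_numpy(), alpha=config.alpha,
                             family=f"field_size:{term}",
                             ids=list(fs.loc[idx, "area_id"]))
                fs.loc[idx, "q"] = rep.q
                fs.loc[idx, "significant"] = rep.significant
        fs.to_csv(out / "field_size_lme.tsv", sep="\t", index=False)

        # voxelwise density models within each requested field
        vox_areas = (list(config.voxelwise_areas) if config.voxelwise_areas
                     else pf_areas)
        vw_frames = []
        for area in vox_areas:
            if area not in fields:
                continue
            dens = per_scan_densities(scans, metadata, area,
                                      fields[area].mask, scheme)
            res = voxelwise_lme(dens, fixed=config.lme_terms,
                                outcome="density", alpha=config.alpha,
                                family=area)
            frame = res.table.copy()
            frame.insert(0, "area_id", area)
            vw_frames.append(frame)
        if vw_frames:
            pd.concat(vw_frames, ignore_index=True).to_csv(
                out / "voxelwise_lme.tsv", sep="\t", index=False)

    manifest = {
        "run_id": _run_id(config, data_dir),
        "config": config.to_dict(),
        "stages": list(stages),
        "n_scans": len({(s.subject_id, s.scan_age) for s in scans}),
        "n_subjects": int(metadata["subject_id"].nunique()),
        "passage_field_areas": pf_areas,
        "threshold_scheme": [float(v) for v in scheme.values],
        "fdr_families": {"field_size": "all passage-field areas per term",
                         "voxelwise": "all converged voxels of one area per term"},
        "fit_method": "maximum likelihood, residual-df t approximation",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out
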