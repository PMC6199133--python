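"""Configuration-driven orchestration of the full analysis.

A pipeline run processes, per specimen: optional median filtering ->
threshold scan -> expression-domain extraction (with physical volume) ->
then, per analysis group: side mirroring, GPA with sliding semilandmarks,
centroid sizes, PCA, two-block PLS between organ-shape and domain-shape
blocks with RV and a permutation test, and univariate group comparisons.
Grouping (developmental period, limb type, ...) is data carried by the
manifest, not code.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import expression_domain as ed
from . import io_formats as iof
from . import morphostats as ms
from . import procrustes as pr
from .synthetic import (
    MUTANT,
    WILDTYPE,
    SyntheticSpec,
    make_expression_volume,
    make_limb_bud,
)

log = logging.getLogger("optmorph.pipeline")

LIMB = "limb"
DOMAIN = "expression_domain"


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``PipelineConfig.from_yaml``)."""

    specimens: list[dict]
    landmarks_csv: str | None = None
    output_dir: str = "optmorph_out"
    seed: int = 0
    n_permutations: int = 999
    n_levels: int = ed.DEFAULT_N_LEVELS
    v_min: int = ed.DEFAULT_V_MIN
    f_max: float = ed.DEFAULT_F_MAX
    polarity: str = iof.DARK_STAIN
    median_radius: int = 0
    sliding: bool = True
    slide_iterations: int = 3
    base_dir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.get("threshold", {})
        sld = raw.get("sliding", {})
        return cls(
            specimens=raw.get("specimens", []),
            landmarks_csv=raw.get("landmarks_csv"),
            output_dir=raw.get("output_dir", "optmorph_out"),
            seed=int(raw.get("seed", 0)),
            n_permutations=int(raw.get("n_permutations", 999)),
            n_levels=int(thr.get("n_levels", ed.DEFAULT_N_LEVELS)),
            v_min=int(thr.get("v_min", ed.DEFAULT_V_MIN)),
            f_max=float(thr.get("f_max", ed.DEFAULT_F_MAX)),
            polarity=thr.get("polarity", iof.DARK_STAIN),
            median_radius=int(raw.get("filter", {}).get("radius", 0)),
            sliding=bool(sld.get("enabled", True)),
            slide_iterations=int(sld.get("iterations", 3)),
            base_dir=os.path.dirname(os.path.abspath(path)),
            extra=raw,
        )


def _resolve(base: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(base, path)


def _content_key(payload: bytes, params: dict) -> str:
    h = hashlib.sha256()
    h.update(payload)
    h.update(json.dumps(params, sort_keys=True).encode())
    return h.hexdigest()


def _extract_stage(
    volume: iof.Volume, mask, config: PipelineConfig, cache_dir: str, sid: str
) -> dict:
    """Threshold scan + domain extraction for one specimen, content-cached."""
    params = {
        "n_levels": config.n_levels, "v_min": config.v_min,
        "f_max": config.f_max, "median_radius": config.median_radius,
    }
    key = _content_key(np.ascontiguousarray(volume.grid).tobytes(), params)
    cache_file = os.path.join(cache_dir, f"{key}.json")
    if os.path.exists(cache_file):
        with open(cache_file, "r", encoding="utf-8") as fh:
            cached = json.load(fh)
        log.info("extract %s: cache hit %s", sid, key[:12])
        return cached
    if config.median_radius >= 1:
        volume = iof.filter_volume(volume, "median", config.median_radius)
    scan = ed.threshold_scan(
        volume, mask=mask, n_levels=config.n_levels,
        v_min=config.v_min, f_max=config.f_max,
    )
    g_last = ed.last_visible_grey(scan)
    t_high, t_moderate = ed.expression_thresholds(g_last)
    high = ed.extract_domain(volume, t_high, "high", config.v_min, mask=mask)
    moderate = ed.extract_domain(
        volume, t_moderate, "moderate", config.v_min, mask=mask
    )
    result = {
        "g_last": g_last, "t_high": t_high, "t_moderate": t_moderate,
        "high_volume_um3": high.volume_um3,
        "moderate_volume_um3": moderate.volume_um3,
    }
    os.makedirs(cache_dir, exist_ok=True)
    with open(cache_file, "w", encoding="utf-8") as fh:
        json.dump(result, fh, sort_keys=True)
    log.info(
        "extract %s: g_last=%.4g t_high=%.4g t_moderate=%.4g v_high=%.6g um3",
        sid, g_last, t_high, t_moderate, high.volume_um3,
    )
    return result


def _shape_block(
    sets: list[iof.LandmarkSet], config: PipelineConfig
) -> tuple[pr.GPAResult, np.ndarray]:
    """Mirror left sides, run (sliding) GPA and flatten Procrustes coords."""
    arrays = []
    for ls in sets:
        pts = ls.points
        if ls.side == "left":
            pts = pr.mirror_configuration(pts, "xz")
        arrays.append(iof.LandmarkSet(
            specimen_id=ls.specimen_id, structure=ls.structure, side="right",
            group=ls.group, points=pts, roles=list(ls.roles),
            curve_ids=list(ls.curve_ids), ordinals=list(ls.ordinals),
            landmark_ids=list(ls.landmark_ids),
        ))
    topology = None
    if config.sliding and any(
        r != iof.ROLE_ANATOMICAL for r in arrays[0].roles
    ):
        topology = pr.SlidingTopology.from_landmarks(
            arrays[0], closed_curves={"outline"}
        )
    result = pr.gpa(
        arrays, sliding=topology, slide_iterations=config.slide_iterations
    )
    flat = result.aligned.reshape(len(arrays), -1)
    return result, flat


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns (and writes) the report."""
    os.makedirs(config.output_dir, exist_ok=True)
    cache_dir = os.path.join(config.output_dir, "cache")
    report: dict = {"seed": config.seed, "specimens": {}, "analyses": {}}

    landmark_index: dict[tuple[str, str], iof.LandmarkSet] = {}
    if config.landmarks_csv:
        path = _resolve(config.base_dir, config.landmarks_csv)
        for ls in iof.read_landmarks(path, "csv"):
            landmark_index[(ls.specimen_id, ls.structure)] = ls

    volumes_rows = []
    for spec_row in config.specimens:
        sid = spec_row["specimen_id"]
        entry = {k: v for k, v in spec_row.items() if k not in ("volume", "tissue_mask")}
        if "volume" in spec_row:
            vol_path = _resolve(config.base_dir, spec_row["volume"])
            if not os.path.exists(vol_path):
                raise FileNotFoundError(
                    f"specimen {sid}: volume not found: {vol_path}"
                )
            volume = iof.read_volume(vol_path, polarity=config.polarity)
            mask = None
            if "tissue_mask" in spec_row:
                mask_path = _resolve(config.base_dir, spec_row["tissue_mask"])
                if not os.path.exists(mask_path):
                    raise FileNotFoundError(
                        f"specimen {sid}: tissue mask not found: {mask_path}"
                    )
                mask = iof.read_volume(mask_path).grid.astype(bool)
            try:
                entry.update(_extract_stage(volume, mask, config, cache_dir, sid))
            except ValueError as exc:
                raise ValueError(f"specimen {sid}: {exc}") from exc
            volumes_rows.append({"specimen_id": sid, **{
                k: entry[k] for k in (
                    "g_last", "t_high", "t_moderate",
                    "high_volume_um3", "moderate_volume_um3",
                )
            }})
        report["specimens"][sid] = entry

    if volumes_rows:
        pd.DataFrame(volumes_rows).to_csv(
            os.path.join(config.output_dir, "domain_volumes.csv"), index=False
        )

    by_analysis: dict[str, list[dict]] = {}
    for spec_row in config.specimens:
        by_analysis.setdefault(
            str(spec_row.get("analysis_group", "all")), []
        ).append(spec_row)

    for name, rows in sorted(by_analysis.items()):
        analysis = _run_analysis(name, rows, landmark_index, report, config)
        if analysis:
            report["analyses"][name] = analysis

    report_path = os.path.join(config.output_dir, "report.json")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    log.info("report written to %s", report_path)
    return report


def _run_analysis(
    name: str,
    rows: list[dict],
    landmark_index: dict,
    report: dict,
    config: PipelineConfig,
) -> dict:
    analysis: dict = {}
    limb_sets = [
        landmark_index[(r["specimen_id"], LIMB)]
        for r in rows if (r["specimen_id"], LIMB) in landmark_index
    ]
    domain_sets = [
        landmark_index[(r["specimen_id"], DOMAIN)]
        for r in rows if (r["specimen_id"], DOMAIN) in landmark_index
    ]
    groups = {r["specimen_id"]: str(r.get("group", "")) for r in rows}

    blocks: dict[str, tuple[pr.GPAResult, np.ndarray, list[str]]] = {}
    for label, sets in ((LIMB, limb_sets), (DOMAIN, domain_sets)):
        if len(sets) < 2:
            continue
        result, flat = _shape_block(sets, config)
        ids = result.specimen_ids
        blocks[label] = (result, flat, ids)
        pca_res = ms.pca(flat)
        analysis[f"{label}_pca_percent_variance"] = [
            round(float(v), 6) for v in pca_res.percent_variance[:5]
        ]
        analysis[f"{label}_centroid_sizes"] = {
            sid: float(cs) for sid, cs in zip(ids, result.centroid_sizes)
        }
        pr.export_procrustes_csv(result, os.path.join(
            config.output_dir, f"{name}_{label}_procrustes.csv"
        ))
        labels = np.array([groups[s] for s in ids])
        if len(np.unique(labels)) == 2:
            p = ms.permutation_test(
                ms.group_mean_distance, labels, flat,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            analysis[f"{label}_group_shape_permutation_p"] = float(p)
            scores = pca_res.scores[:, 0]
            analysis[f"{label}_pc1_by_group"] = {
                str(g): [float(scores[i]) for i in np.flatnonzero(labels == g)]
                for g in np.unique(labels)
            }
            sizes = result.centroid_sizes
            a = sizes[labels == np.unique(labels)[0]]
            b = sizes[labels == np.unique(labels)[1]]
            if len(a) >= 2 and len(b) >= 2:
                t = ms.welch_t(a, b)
                analysis[f"{label}_size_welch_t"] = {
                    "t": t.statistic, "df": t.df, "p": t.p_value,
                }

    if LIMB in blocks and DOMAIN in blocks:
        limb_res, limb_flat, limb_ids = blocks[LIMB]
        dom_res, dom_flat, dom_ids = blocks[DOMAIN]
        common = [s for s in limb_ids if s in dom_ids]
        if len(common) >= 3:
            xi = [limb_ids.index(s) for s in common]
            yi = [dom_ids.index(s) for s in common]
            pls = ms.pls_two_block(
                limb_flat[xi], dom_flat[yi],
                n_permutations=config.n_permutations, seed=config.seed,
            )
            analysis["pls"] = {
                "rv": pls.rv,
                "permutation_p": pls.permutation_p,
                "pls1_percent_covariation": float(pls.percent_covariation[0]),
            }
            vols = {
                r["specimen_id"]: report["specimens"][r["specimen_id"]].get(
                    "high_volume_um3"
                )
                for r in rows if r["specimen_id"] in report["specimens"]
            }
            cs = dict(zip(limb_ids, limb_res.centroid_sizes))
            pairs = [
                (cs[s], vols[s]) for s in common
                if vols.get(s) is not None
            ]
            if len(pairs) >= 3:
                x, y = zip(*pairs)
                try:
                    analysis["volume_vs_size_r2"] = ms.linear_r2(x, y)
                except ValueError:
                    pass
    return analysis


# ---------------------------------------------------------------------------
# synthetic dataset on disk
# ---------------------------------------------------------------------------

def simulate_dataset(
    out_dir: str,
    n_per_group: int = 6,
    stage: float = 1.0,
    group_effect: float = 1.0,
    noise_sd: float = 2.0,
    spacing: float = 12.0,
    seed: int = 0,
    write_volumes: bool = True,
) -> str:
    """Write a synthetic two-group dataset and its pipeline config.

    Returns the path of the generated YAML config.  Each specimen gets a
    stained volume (NRRD), a tissue mask (NRRD), limb and domain landmark
    rows in a shared CSV, a surface mesh (PLY) and a ground-truth JSON.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    all_sets: list[iof.LandmarkSet] = []
    manifest = []
    truths = {}
    for gi, group in enumerate((WILDTYPE, MUTANT)):
        for j in range(n_per_group):
            sid = f"{group[:2]}{j}"
            spec = SyntheticSpec(
                stage=stage + 0.1 * float(rng.normal()),
                group_effect=group_effect,
                noise_sd=noise_sd, spacing=spacing,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            mesh, limb_lms = make_limb_bud(spec, group)
            limb_lms = iof.LandmarkSet(
                specimen_id=sid, structure=LIMB, side="right", group=group,
                points=limb_lms.points, roles=list(limb_lms.roles),
                curve_ids=list(limb_lms.curve_ids),
                ordinals=list(limb_lms.ordinals),
                landmark_ids=list(limb_lms.landmark_ids),
            )
            all_sets.append(limb_lms)
            row = {"specimen_id": sid, "group": group, "side": "right",
                   "analysis_group": "all"}
            if write_volumes:
                volume, truth = make_expression_volume(mesh, spec, group)
                vol_name = f"{sid}_stain.nrrd"
                mask_name = f"{sid}_mask.nrrd"
                iof.write_volume(iof.Volume(
                    grid=volume.grid.astype(np.float32),
                    spacing=volume.spacing, origin=volume.origin,
                    polarity=volume.polarity,
                ), os.path.join(out_dir, vol_name))
                iof.write_volume(iof.Volume(
                    grid=truth["tissue_mask"].astype(np.uint8),
                    spacing=volume.spacing, origin=volume.origin,
                ), os.path.join(out_dir, mask_name))
                row["volume"] = vol_name
                row["tissue_mask"] = mask_name
                truths[sid] = {
                    k: v for k, v in truth.items() if k != "tissue_mask"
                }
                dom_lms = _domain_landmarks(sid, group, volume, truth)
                if dom_lms is not None:
                    all_sets.append(dom_lms)
            iof.write_mesh(mesh, os.path.join(out_dir, f"{sid}_limb.ply"))
            manifest.append(row)
    iof.write_landmarks(all_sets, os.path.join(out_dir, "landmarks.csv"))
    with open(os.path.join(out_dir, "ground_truth.json"), "w",
              encoding="utf-8") as fh:
        json.dump(truths, fh, sort_keys=True, indent=1)
    config = {
        "seed": int(seed),
        "output_dir": "results",
        "landmarks_csv": "landmarks.csv",
        "n_permutations": 999,
        "threshold": {"n_levels": 64, "v_min": 50, "f_max": 0.5,
                      "polarity": "dark-stain"},
        "sliding": {"enabled": True, "iterations": 2},
        "specimens": manifest,
    }
    cfg_path = os.path.join(out_dir, "config.yaml")
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path


def _domain_landmarks(sid, group, volume, truth) -> iof.LandmarkSet | None:
    """Cheap domain landmarking: extremal + quantile points of the core mask."""
    mask = None
    try:
        grid = volume.grid
        mask = grid <= 50.0
    except Exception:  # noqa: BLE001
        return None
    idx = np.argwhere(mask)
    if len(idx) < 12:
        return None
    pts = idx * np.asarray(volume.spacing) + np.asarray(volume.origin)
    sel = []
    for axis in range(3):
        sel.append(pts[np.argmin(pts[:, axis])])
        sel.append(pts[np.argmax(pts[:, axis])])
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    quant = pts[order][np.linspace(0, len(pts) - 1, 10).astype(int)]
    points = np.vstack(sel + [quant])
    return iof.LandmarkSet(
        specimen_id=sid, structure=DOMAIN, side="right", group=group,
        points=points,
    )


# ---------------------------------------------------------------------------
# deposited-data reanalysis
# ---------------------------------------------------------------------------

def analyze_deposited_tables(directory: str) -> dict:
    """Recompute integration statistics from deposited coordinate tables.

    Expects, per limb type ``fore``/``hind`` (CSV, one row per specimen):
    ``<type>_limb_procrustes.csv`` and ``<type>_domain_procrustes.csv``
    (columns: ``specimen_id`` then coordinate columns), plus ``sizes.csv``
    with columns ``limb_type, period, genotype, limb_centroid_size_um,
    dusp6_volume_um3``.  Returns RV, PLS1 % covariation, per-period Welch t
    on size and volume, and pooled R² per limb type.
    """
    out: dict = {}
    for limb_type in ("fore", "hind"):
        lp = os.path.join(directory, f"{limb_type}_limb_procrustes.csv")
        dp = os.path.join(directory, f"{limb_type}_domain_procrustes.csv")
        if not (os.path.exists(lp) and os.path.exists(dp)):
            continue
        limb = pd.read_csv(lp).set_index("specimen_id").sort_index()
        dom = pd.read_csv(dp).set_index("specimen_id").sort_index()
        common = limb.index.intersection(dom.index)
        x = limb.loc[common].to_numpy(dtype=float)
        y = dom.loc[common].to_numpy(dtype=float)
        pls = ms.pls_two_block(x, y, n_permutations=999, seed=0)
        out[f"{limb_type}_rv"] = pls.rv
        out[f"{limb_type}_pls1_percent"] = float(pls.percent_covariation[0])
        out[f"{limb_type}_pls_p"] = pls.permutation_p
    sizes_path = os.path.join(directory, "sizes.csv")
    if os.path.exists(sizes_path):
        sizes = pd.read_csv(sizes_path)
        for (limb_type, period), sub in sizes.groupby(["limb_type", "period"]):
            geno = sorted(sub["genotype"].unique())
            if len(geno) != 2:
                continue
            a = sub.loc[sub["genotype"] == geno[0]]
            b = sub.loc[sub["genotype"] == geno[1]]
            for col, tag in (
                ("limb_centroid_size_um", "size"),
                ("dusp6_volume_um3", "volume"),
            ):
                t = ms.welch_t(a[col], b[col])
                out[f"{limb_type}_{period}_{tag}_welch"] = {
                    "t": t.statistic, "df": t.df, "p": t.p_value,
                }
        for limb_type, sub in sizes.groupby("limb_type"):
            try:
                out[f"{limb_type}_r2"] = ms.linear_r2(
                    sub["limb_centroid_size_um"], sub["dusp6_volume_um3"]
                )["r2"]
            except ValueError:
                pass
    return out
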