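"""End-to-end orchestration of the two analyses.

* :func:`run_localization` — fluorescence + transmission stacks →
  vessel graph → deposits/lesions → nearest-vessel diameters → summary.
* :func:`run_cohort` — histology manifest and/or animal table →
  per-animal quantification → group summaries, ANOVA/Tukey, correlations.

Every output directory gets a ``run_report.yaml`` carrying the seed, the
full parameter echo, and a config hash; two runs with equal hashes produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import __version__
from .localization import (
    AnalysisParams,
    cluster_deposits_to_lesions,
    diameter_distribution,
    nearest_vessels,
    records_to_frame,
    segment_deposits,
)
from .segmentation import SauvolaParams, clean_mask, iterative_selection_threshold
from .stats import anova_tukey, pearson_correlation, summarize_groups
from .tracing import build_vessel_graph, prune_graph, skeletonize_vasculature

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "localize_stacks", "run_localization", "run_cohort"]


@dataclass
class RunConfig:
    """Run-wide configuration; every parameter block in one place."""

    out_dir: str = "results"
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fluor_path: str | None = None
    trans_path: str | None = None
    animals_path: str | None = None
    manifest_path: str | None = None
    sauvola: SauvolaParams = field(default_factory=SauvolaParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    vessel_min_component: int = 27  # voxels
    vessel_closing_radius: float = 1.0  # µm
    min_branch_length: float = 5.0  # µm
    stats_design: str = "one-way"  # or "two-way" (infusion × drug)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sauvola" in raw:
            raw["sauvola"] = SauvolaParams(**raw["sauvola"])
        if "analysis" in raw:
            raw["analysis"] = AnalysisParams(**raw["analysis"])
        for key in ("spacing",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_report(cfg: RunConfig, out: Path, extra: dict) -> None:
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "parameters": cfg.to_dict(),
    }
    report.update(extra)
    with open(out / "run_report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)


def segment_vasculature(
    fluor: np.ndarray, cfg: RunConfig, exclude: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Global iterative-selection threshold on the fluorescence stack, with
    cleanup.  ``exclude`` voxels (deposit regions, where absorbing
    hemosiderin masks the vessel signal) are removed before tracing so no
    phantom vessel ends are created inside lesions."""
    res = iterative_selection_threshold(fluor)
    mask = fluor > res.threshold
    if exclude is not None and exclude.any():
        mask &= ~ndi.binary_dilation(exclude, iterations=1)
    mask = clean_mask(
        mask,
        min_component_size=cfg.vessel_min_component,
        closing_radius=cfg.vessel_closing_radius,
        spacing=cfg.spacing,
    )
    return mask, res.threshold


def localize_stacks(
    fluor: np.ndarray,
    trans: np.ndarray,
    cfg: RunConfig | None = None,
) -> dict:
    """Run the 3D localization analysis on in-memory stacks.

    Returns a dict with the vessel graph, deposits, lesions, nearest-vessel
    records, the pooled diameter summary, and the chosen thresholds.
    """
    if cfg is None:
        cfg = RunConfig()
    if fluor.shape != trans.shape:
        raise ValueError(
            f"channel shape mismatch: fluorescence {fluor.shape} vs "
            f"transmission {trans.shape}"
        )
    deposits = segment_deposits(
        trans, spacing=cfg.spacing, sauvola=cfg.sauvola, params=cfg.analysis
    )
    deposit_mask = np.zeros(trans.shape, dtype=bool)
    for d in deposits:
        deposit_mask[tuple(d.voxels.T)] = True
    vessel_mask, threshold = segment_vasculature(fluor, cfg, exclude=deposit_mask)
    skeleton = skeletonize_vasculature(vessel_mask, cfg.spacing)
    graph = build_vessel_graph(skeleton, vessel_mask, cfg.spacing)
    graph = prune_graph(graph, cfg.min_branch_length)
    lesions = cluster_deposits_to_lesions(deposits, cfg.analysis)
    diam_cache: dict[int, float] = {}
    records = []
    if graph.segments:
        for d in deposits:
            records.append(
                nearest_vessels(
                    d.centroid,
                    graph,
                    cfg.analysis,
                    deposit_id=d.id,
                    segment_diameters=diam_cache,
                )
            )
    summary = diameter_distribution(records, cfg.analysis) if records else None
    return {
        "vessel_threshold": threshold,
        "vessel_mask": vessel_mask,
        "graph": graph,
        "deposits": deposits,
        "lesions": lesions,
        "records": records,
        "summary": summary,
    }


def run_localization(
    config: RunConfig,
    fluor: np.ndarray | None = None,
    trans: np.ndarray | None = None,
) -> dict:
    """File-level wrapper: load TIFF stacks, run, write the artifact set.

    Writes deposits.csv, lesions.csv, nearest_vessels.csv, histogram.csv,
    summary.json, vessel nodes/edges CSVs and run_report.yaml into
    ``config.out_dir``.
    """
    import tifffile

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fluor is None:
        if config.fluor_path is None or config.trans_path is None:
            raise ValueError("either arrays or fluor/trans paths are required")
        fluor = tifffile.imread(config.fluor_path).astype(np.float64)
        trans = tifffile.imread(config.trans_path).astype(np.float64)
    result = localize_stacks(fluor, trans, config)

    dep_rows = [
        {
            "deposit_id": d.id,
            "z_um": d.centroid[0],
            "y_um": d.centroid[1],
            "x_um": d.centroid[2],
            "volume_um3": d.volume,
            "lesion_id": d.parent_lesion,
        }
        for d in result["deposits"]
    ]
    pd.DataFrame(
        dep_rows, columns=["deposit_id", "z_um", "y_um", "x_um", "volume_um3", "lesion_id"]
    ).to_csv(out / "deposits.csv", index=False)
    les_rows = [
        {
            "lesion_id": l.id,
            "n_deposits": len(l.deposit_ids),
            "z_um": l.centroid[0],
            "y_um": l.centroid[1],
            "x_um": l.centroid[2],
            "axial_extent_um": l.axial_extent,
        }
        for l in result["lesions"]
    ]
    pd.DataFrame(
        les_rows,
        columns=["lesion_id", "n_deposits", "z_um", "y_um", "x_um", "axial_extent_um"],
    ).to_csv(out / "lesions.csv", index=False)
    records_to_frame(result["records"]).to_csv(out / "nearest_vessels.csv", index=False)
    nodes, edges = result["graph"].to_frames()
    nodes.to_csv(out / "vessel_nodes.csv", index=False)
    edges.to_csv(out / "vessel_edges.csv", index=False)

    summary = result["summary"]
    if summary is not None:
        pd.DataFrame(
            {
                "bin_left_um": summary["histogram_edges_um"][:-1],
                "bin_right_um": summary["histogram_edges_um"][1:],
                "count": summary["histogram_counts"],
            }
        ).to_csv(out / "histogram.csv", index=False)
        blob = {
            "n": summary["n"],
            "min_um": summary["min_um"],
            "max_um": summary["max_um"],
            "fraction_below_cutoff": summary["fraction_below_cutoff"],
            "capillary_cutoff_um": config.analysis.capillary_cutoff,
        }
    else:
        blob = {"n": 0, "fraction_below_cutoff": None}
    blob["seed"] = config.seed
    blob["config_hash"] = config.config_hash()
    with open(out / "summary.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
    _write_report(
        config,
        out,
        {
            "vessel_threshold": float(result["vessel_threshold"]),
            "n_deposits": len(result["deposits"]),
            "n_lesions": len(result["lesions"]),
            "n_segments": len(result["graph"].segments),
        },
    )
    return result


def quantify_manifest(manifest: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Quantify every section listed in a manifest
    (animal_id, section_id, path, pixel_size) → per-section table."""
    import tifffile

    from .histology import enumerate_cmh, segment_prussian_blue_rgb, tissue_area

    missing = [p for p in manifest["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing images: {missing}")
    rows = []
    for _, rec in manifest.iterrows():
        img = tifffile.imread(rec["path"]).astype(float)
        px = float(rec["pixel_size"])
        mask = segment_prussian_blue_rgb(img)
        count, total_area, _ = enumerate_cmh(mask, px)
        area = tissue_area(img, px)
        rows.append(
            {
                "animal_id": rec["animal_id"],
                "section_id": rec["section_id"],
                "cmh_count": count,
                "cmh_total_area_um2": total_area,
                "tissue_area_cm2": area,
            }
        )
    return pd.DataFrame(rows)


def run_cohort(config: RunConfig, animals: pd.DataFrame | None = None) -> dict:
    """Cohort analysis: optional per-section quantification, then group
    summaries, ANOVA/Tukey and the correlation panel.

    Writes summaries.csv, comparisons.csv, correlations.csv (and, with a
    manifest, sections.csv / animal_density.csv) plus run_report.yaml.
    """
    from .histology import cmh_density

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    extra: dict = {}

    if animals is None:
        if config.animals_path is None:
            raise ValueError("an animals table (or animals_path) is required")
        animals = pd.read_csv(config.animals_path)
    animals = animals.copy()

    if config.manifest_path is not None:
        manifest = pd.read_csv(config.manifest_path)
        if manifest.empty:
            raise ValueError("empty histology manifest")
        sections = quantify_manifest(manifest, config)
        sections.to_csv(out / "sections.csv", index=False)
        dens = (
            sections.groupby("animal_id")
            .apply(
                lambda g: cmh_density(g["cmh_count"], g["tissue_area_cm2"]),
                include_groups=False,
            )
            .rename("cmh_density")
            .reset_index()
        )
        dens.to_csv(out / "animal_density.csv", index=False)
        animals = animals.drop(columns=["cmh_density"], errors="ignore").merge(
            dens, on="animal_id", how="left"
        )
        extra["n_sections"] = len(sections)

    variables = [
        v
        for v in ("cmh_density", "map_final", "iba1_fraction", "cd206_ratio")
        if v in animals.columns
    ]
    summaries = []
    for v in variables:
        for s in summarize_groups(animals, v):
            summaries.append(
                {
                    "variable": v,
                    "group": s.group,
                    "n": s.n,
                    "mean": s.mean,
                    "sem": s.sem,
                }
            )
    pd.DataFrame(summaries).to_csv(out / "summaries.csv", index=False)

    if config.stats_design == "two-way":
        animals["infusion"] = [
            "AngII" if g.startswith("AngII") else "PBS" for g in animals["group"]
        ]
        animals["drug"] = [g.split("-", 1)[1] for g in animals["group"]]
        factors = ["infusion", "drug"]
    else:
        factors = ["group"]
    comp_frames = []
    for v in variables:
        try:
            res = anova_tukey(animals, v, factors)
        except ValueError as err:
            logger.warning("ANOVA skipped for %s: %s", v, err)
            continue
        tuk = res["tukey"].copy()
        tuk.insert(0, "variable", v)
        comp_frames.append(tuk)
    if comp_frames:
        pd.concat(comp_frames, ignore_index=True).to_csv(
            out / "comparisons.csv", index=False
        )

    corr_rows = []
    for xv, yv in (
        ("cmh_density", "map_final"),
        ("cmh_density", "iba1_fraction"),
        ("cmh_density", "cd206_ratio"),
    ):
        if xv in animals.columns and yv in animals.columns:
            sub = animals[[xv, yv]].dropna()
            if len(sub) >= 3 and sub[xv].std() > 0 and sub[yv].std() > 0:
                r, p = pearson_correlation(sub[xv], sub[yv])
                corr_rows.append({"x": xv, "y": yv, "n": len(sub), "r": r, "p": p})
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
    _write_report(config, out, extra)
    return {
        "animals": animals,
        "summaries": pd.DataFrame(summaries),
        "comparisons": comp_frames[0] if len(comp_frames) == 1 else comp_frames,
        "correlations": pd.DataFrame(corr_rows),
    }
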