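"""End-to-end orchestration: simulate -> analyze -> compare.

``run_analyze`` walks a subject table (CSV columns ``subject_id,
water_ppm, tf_ul1, tf_ur1, capture_index, image_path, mask_path`` or the
long per-tooth table written by the population generator), applies the
mask exclusion rules, runs the requested method(s) per tooth and emits a
long metrics table.  ``run_end_to_end`` chains a rendered synthetic
population, the analysis, and the statistics report into one output
directory; a fixed seed reproduces the whole report byte-for-byte.
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

from . import fluorosis_stats as fs
from .blur_method import BlurParams, run_blur
from .hull_method import HullParams, run_hull
from .image_model import read_image, read_mask_set, extract_green
from .mask_tools import check_analyzable, locate_gingival_point, select_reference_area
from .synthetic_phantoms import PopulationSpec, make_population

logger = logging.getLogger("fluoroquant")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration serialized alongside every output."""

    method: str = "both"  # blur | hull | both
    blur: BlurParams = field(default_factory=BlurParams)
    hull: HullParams = field(default_factory=HullParams)
    scheme: fs.WaterIntervalScheme = field(default_factory=fs.WaterIntervalScheme)
    mm_per_pixel: float | None = None
    max_gap_frac: float = 0.05
    patch_px: int = 9
    seed: int = 0
    n_per_interval: int = 6
    repeat_fraction: float = 0.25
    phantom_size: tuple[int, int] = (120, 180)

    def __post_init__(self) -> None:
        if self.method not in ("blur", "hull", "both"):
            raise ValueError("method must be 'blur', 'hull' or 'both'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = list(self.scheme.boundaries)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def analyze_capture(
    image_path: str | Path,
    mask_path: str | Path,
    config: RunConfig = RunConfig(),
) -> tuple[list[dict], object]:
    """Analyze one capture; returns per-tooth metric rows and the report."""
    image = read_image(image_path)
    masks = read_mask_set(mask_path, image)
    report = check_analyzable(
        masks, max_gap_frac=config.max_gap_frac, subject_id=image.subject_id
    )
    rows: list[dict] = []
    if not report.analyzable:
        return rows, report
    green = extract_green(image)
    point = locate_gingival_point(masks)
    references = select_reference_area(masks, point, green, config.patch_px)
    for mask in masks:
        row: dict = {"tooth": mask.tooth_label}
        if config.method in ("blur", "both"):
            metrics, _ = run_blur(
                green, mask, references[mask.tooth_label], config.blur, config.mm_per_pixel
            )
            row.update(
                area_blur=metrics.area,
                delta_f_blur=metrics.delta_f,
                delta_q_blur=metrics.delta_q,
                n_lesion_px_blur=metrics.n_lesion_px,
                area_unit_blur=metrics.area_unit,
            )
        if config.method in ("hull", "both"):
            metrics, _ = run_hull(green, mask, config.hull)
            row.update(
                area_ch=metrics.area,
                delta_f_ch=metrics.delta_f,
                delta_q_ch=metrics.delta_q,
                n_lesion_px_ch=metrics.n_lesion_px,
            )
        rows.append(row)
    return rows, report


def run_analyze(
    subjects: pd.DataFrame | str | Path,
    config: RunConfig = RunConfig(),
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Analyze every capture of a subject table.

    One output row per subject × capture × tooth × method family; excluded
    captures are retained with ``excluded=True`` and their reason (for
    auditability) rather than dropped.  Per-subject failures are recorded
    and the run continues; if every capture fails, raises.
    """
    if not isinstance(subjects, pd.DataFrame):
        subjects = pd.read_csv(subjects, comment="#")
    captures = subjects.drop_duplicates(subset=["subject_id", "capture_index"])
    out_rows: list[dict] = []
    n_failed = 0
    for _, cap in captures.iterrows():
        meta = {
            k: cap[k]
            for k in ("subject_id", "water_ppm", "water_interval", "capture_index")
            if k in cap.index
        }
        if "water_ppm" in meta and "water_interval" not in meta:
            meta["water_interval"] = fs.assign_interval(meta["water_ppm"], config.scheme)
        tf_by_tooth = {}
        sub = subjects[
            (subjects["subject_id"] == cap["subject_id"])
            & (subjects["capture_index"] == cap["capture_index"])
        ]
        if "tooth" in sub.columns and "tf" in sub.columns:
            tf_by_tooth = dict(zip(sub["tooth"], sub["tf"]))
        elif {"tf_ur1", "tf_ul1"}.issubset(sub.columns):
            tf_by_tooth = {"UR1": cap["tf_ur1"], "UL1": cap["tf_ul1"]}
        try:
            rows, report = analyze_capture(cap["image_path"], cap["mask_path"], config)
        except Exception as exc:
            n_failed += 1
            logger.error("subject %s: analysis failed: %s", meta.get("subject_id"), exc)
            out_rows.append(
                {**meta, "excluded": True, "exclusion_reason": f"error: {exc}"}
            )
            continue
        if not rows:
            out_rows.append(
                {
                    **meta,
                    "excluded": True,
                    "exclusion_reason": "+".join(report.reasons),
                }
            )
            continue
        for row in rows:
            out_rows.append(
                {
                    **meta,
                    "tooth": row["tooth"],
                    "tf": tf_by_tooth.get(row["tooth"], np.nan),
                    "excluded": False,
                    "exclusion_reason": "",
                    **{k: v for k, v in row.items() if k != "tooth"},
                }
            )
    if captures.shape[0] and n_failed == captures.shape[0]:
        raise RuntimeError("analysis failed for every capture")
    df = pd.DataFrame(out_rows)
    if out_csv is not None:
        _write_csv_with_header(df, out_csv, config)
    return df


def _write_csv_with_header(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fluoroquant config_hash={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def run_end_to_end(config: RunConfig = RunConfig(), out_dir: str | Path = "report") -> Path:
    """simulate -> analyze -> compare, writing the full report directory.

    Outputs: ``subjects.csv`` (+ images/masks), ``metrics.csv``,
    ``descriptives.csv``, ``pairwise_pvalues.csv``, ``correlations.csv``,
    ``icc.csv``, ``roc_points.csv``, ``report.txt`` and ``config.json``.
    Deterministic for a fixed config (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=1) + "\n"
    )
    pop_spec = PopulationSpec(
        n_per_interval=config.n_per_interval,
        repeat_fraction=config.repeat_fraction,
        seed=config.seed,
    )
    if pop_spec.n_per_interval < 5:
        logger.warning("small sample: n_per_interval=%d", pop_spec.n_per_interval)
    subjects = make_population(
        pop_spec, render="images", out_dir=out_dir / "images",
        phantom_size=config.phantom_size,
    )
    subjects.to_csv(out_dir / "subjects.csv", index=False)
    metrics = run_analyze(subjects, config, out_csv=out_dir / "metrics.csv")
    analyzed = metrics[~metrics["excluded"].astype(bool)]
    report = fs.dose_response_report(analyzed)
    report["descriptives"].to_csv(out_dir / "descriptives.csv")
    pair_rows = []
    for metric, sep in report["separation"].items():
        adj = sep["p_adjusted"]
        for i in adj.index:
            for j in adj.columns:
                if i < j and not np.isnan(adj.loc[i, j]):
                    pair_rows.append(
                        {
                            "metric": metric,
                            "interval_a": i,
                            "interval_b": j,
                            "p_raw": sep["p_raw"].loc[i, j],
                            "p_adjusted": adj.loc[i, j],
                            "levene_p": sep["levene_p"],
                            "path": sep["path"],
                        }
                    )
    pd.DataFrame(pair_rows).to_csv(out_dir / "pairwise_pvalues.csv", index=False)
    report["correlations"].to_csv(out_dir / "correlations.csv", index=False)
    report["icc"].to_csv(out_dir / "icc.csv", index=False)
    roc_rows = []
    for metric, roc in report["roc"].items():
        frame = roc.to_frame()
        frame.insert(0, "metric", metric)
        frame["auc"] = roc.auc
        roc_rows.append(frame)
    if roc_rows:
        pd.concat(roc_rows, ignore_index=True).to_csv(
            out_dir / "roc_points.csv", index=False
        )
    else:
        (out_dir / "roc_points.csv").write_text("metric,threshold,sensitivity,specificity,auc\n")
    (out_dir / "report.txt").write_text(fs.render_report_text(report))
    return out_dir
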