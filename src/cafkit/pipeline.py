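"""End-to-end orchestration: config, cohort analysis, map analysis.

A run reproduces the analysis flow on synthetic or user data: scoring
inputs -> subset classification -> (optionally) serial-section subset
maps -> case-control statistics. Configuration is a single YAML file
with per-module blocks; the seed is mandatory and every stage is
deterministic given it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .maps import SubsetMap, classify_tiles, render_map
from .registration import fit_landmark_warp, warp_image
from .stains import StainModel, unmix_stains
from .stats import MatchSpec, compare_groups, cox_model, km_logrank, match_controls
from .subtyping import (
    MARKERS,
    DecisionTreeSpec,
    MarkerPanel,
    default_tree,
    enrich_cohort,
)
from .synthetic import (
    CohortParams,
    MarkerReference,
    SectionSimParams,
    SerialSectionSet,
    generate_cohort,
    generate_serial_sections,
)
from .tiling import tile_features

__all__ = ["RunConfig", "run_pipeline", "analyze_sections", "analyze_cohort"]

_MODES = ("cohort", "map", "full-synthetic")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (one YAML file, per-module blocks)."""

    mode: str
    seed: int
    cohort: dict = field(default_factory=dict)
    sections: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.seed is None:
            raise ValueError("config field 'seed' is mandatory")
        if self.mode == "map" and "sections_dir" in self.paths:
            pass  # loading existing sections: metadata carries um_per_pixel
        elif self.mode == "map" and not self.sections:
            if "um_per_pixel" not in self.map:
                raise ValueError("map mode requires 'um_per_pixel' in the map block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config field 'seed' is mandatory")
        known = {k: raw[k] for k in ("cohort", "sections", "map", "stats", "paths") if k in raw}
        return cls(mode=raw.get("mode", "full-synthetic"), seed=int(raw["seed"]), **known)


def analyze_sections(
    sections: SerialSectionSet,
    tree: DecisionTreeSpec | None = None,
    warp_kind: str = "tps",
    smoothing: float = 0.1,
    coverage_threshold: float = 0.5,
) -> dict[str, Any]:
    """Serial-section stack -> tile-level CAF subset map.

    Registers every non-reference marker section onto the reference via
    its landmarks, unmixes the DAB channel, measures mean tile OD,
    classifies stromal tiles with section-set quartile thresholds, and
    (when ground truth is attached) scores tile-label accuracy on
    stromal tiles.
    """
    tree = tree or default_tree()
    od_images: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    clamp_rates: dict[str, float] = {}
    for marker, img in sections.images.items():
        if marker == sections.reference_marker:
            aligned = img
            residuals[marker] = 0.0
        else:
            warp = fit_landmark_warp(
                sections.landmarks[marker], kind=warp_kind, smoothing=smoothing
            )
            residuals[marker] = warp.residual
            aligned = warp_image(img, warp, fill=255.0)
        unmixed = unmix_stains(aligned, sections.stain)
        clamp_rates[marker] = unmixed.clamp_rate
        od_images[marker] = unmixed.od[..., 1]  # DAB channel

    features = tile_features(
        od_images,
        sections.grid,
        epithelium_mask=sections.epithelium_mask,
        coverage_threshold=coverage_threshold,
    )
    subset_map = classify_tiles(features, sections.grid, tree=tree)
    out: dict[str, Any] = {
        "map": subset_map,
        "registration_residuals": residuals,
        "clamp_rates": clamp_rates,
        "proportions": subset_map.proportions.to_dict(),
    }
    if sections.truth is not None:
        truth = sections.truth.set_index("tile_id")["label"]
        out["accuracy_vs_truth"] = subset_map.accuracy_vs(truth)
    return out


def analyze_cohort(
    cohort: pd.DataFrame,
    seed: int,
    reference: MarkerReference | None = None,
    match_spec: MatchSpec | None = None,
    tree: DecisionTreeSpec | None = None,
) -> dict[str, Any]:
    """Cohort table -> subset enrichment, matching, group tests, Cox.

    Expects the column layout written by the synthetic cohort generator
    (``hscore_<marker>``, ``cd4_density`` etc.). Thresholds for subset
    calls are fitted on the cohort unless a marker reference supplies
    them.
    """
    panels = [
        MarkerPanel(**{m: row[f"hscore_{m}"] for m in MARKERS})
        for _, row in cohort.iterrows()
    ]
    thresholds = reference.thresholds if reference is not None else None
    labels, dist = enrich_cohort(panels, thresholds=thresholds, tree=tree)
    df = cohort.copy()
    df["caf_subset"] = labels
    df["caf_s1"] = (df["caf_subset"] == "CAF-S1").astype(int)

    cases = df[df["case"]]
    pool = df[~df["case"] & ~df["distant_event"]]
    pairs, unmatched = match_controls(cases, pool, spec=match_spec, seed=seed)
    matched_ids = set(pairs["case_id"]) | set(pairs["control_id"])
    matched = df[df["id"].isin(matched_ids)].copy()

    out: dict[str, Any] = {
        "subset_distribution_pct": dist.to_dict(),
        "n_cases_matched": int(len(pairs)),
        "n_unmatched": len(unmatched),
    }

    if len(pairs) >= 3:
        mc, mk = matched[matched["case"]], matched[~matched["case"]]
        comparisons = {}
        for col in ("cd4_density", "cd8_density", "macrophage_density", "vessel_fraction"):
            res = compare_groups(mc[col], mk[col])
            comparisons[col] = {
                "test": res.test,
                "p": res.pvalue,
                "median_cases": float(mc[col].median()),
                "median_controls": float(mk[col].median()),
            }
        out["group_comparisons"] = comparisons

        surv = matched.rename(
            columns={"time_to_event": "time", "distant_event": "event"}
        )
        groups = {
            "CAF-S1": surv[surv["caf_s1"] == 1],
            "other": surv[surv["caf_s1"] == 0],
        }
        if all(len(g) > 0 for g in groups.values()) and surv["event"].any():
            km = km_logrank(groups)
            out["km_logrank"] = {"chi2": km.chi2, "p": km.pvalue}

        for col in ("cd4_density", "macrophage_density", "vessel_fraction"):
            med = surv[col].median()
            surv[f"{col}_high"] = (surv[col] >= med).astype(int)
        covs = [
            "caf_s1",
            "cd4_density_high",
            "macrophage_density_high",
            "vessel_fraction_high",
        ]
        try:
            cox = cox_model(surv, covs, mode="multivariate")
            out["cox_table"] = cox.table.to_dict(orient="records")
        except ValueError as exc:
            out["cox_table_error"] = str(exc)
    return out


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Any]:
    """Execute a full run and write the report bundle.

    Artifacts (per mode): cohort.csv + truth.csv + analysis results;
    subset map PNG + per-tile TSV; summary.json listing every artifact
    and the resolved defaults. Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "mode": config.mode,
        "seed": config.seed,
        "artifacts": [],
        "resolved": {
            "tree_provenance": default_tree().provenance,
            "match_spec": vars(MatchSpec()),
            "tps_smoothing": config.map.get("smoothing", 0.1),
        },
    }

    def emit(name: str) -> Path:
        summary["artifacts"].append(name)
        return out / name

    if config.mode in ("cohort", "full-synthetic"):
        params = CohortParams(**{**config.cohort, "seed": config.seed})
        reference = MarkerReference.generate(params.seed)
        cohort, truth = generate_cohort(params, reference=reference)
        cohort.to_csv(emit("cohort.csv"), index=False)
        truth.to_csv(emit("cohort_truth.csv"), index=False)
        summary["cohort"] = analyze_cohort(
            cohort, seed=config.seed, reference=reference
        )

    if config.mode in ("map", "full-synthetic"):
        if "sections_dir" in config.paths:
            stain = StainModel()
            sections = SerialSectionSet.load(config.paths["sections_dir"], stain=stain)
        else:
            sparams = SectionSimParams(**{**config.sections, "seed": config.seed})
            sections = generate_serial_sections(sparams)
        res = analyze_sections(
            sections,
            smoothing=config.map.get("smoothing", 0.1),
            coverage_threshold=config.map.get("coverage_threshold", 0.5),
        )
        subset_map: SubsetMap = res.pop("map")
        subset_map.tiles.to_csv(emit("tiles.tsv"), sep="\t", index=False)
        from PIL import Image

        Image.fromarray(render_map(subset_map)).save(emit("subset_map.png"))
        summary["map"] = res

    _write_json(emit("summary.json"), summary)
    # Closure check: every artifact the report references exists.
    missing = [a for a in summary["artifacts"] if not (out / a).exists()]
    if missing:
        raise RuntimeError(f"artifact manifest incomplete: {missing}")
    return summary
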