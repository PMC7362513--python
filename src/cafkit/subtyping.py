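"""CAF subset classification from marker panels.

Four cancer-associated-fibroblast subsets (CAF-S1..S4) are defined by
quartile-level expression of five stromal markers (FAP, aSMA, CD29,
FSP1, PDGFRb). A sample -- a tumor described by H-scores, or an image
tile described by mean DAB optical densities -- is binned per marker
against the population quartiles (Neg < Q1 <= Low < med <= Med < Q3 <=
Hi) and assigned a subset either by an ordered decision tree or by
nearest-archetype matching against the published subset profiles.

The decision tree and the profiles are configuration (YAML), not code;
the defaults ship with the package and can be replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MARKERS",
    "TILE_MARKERS",
    "LEVELS",
    "SUBSETS",
    "SUBSET_COLORS",
    "MarkerPanel",
    "MarkerThresholds",
    "QuantileThresholds",
    "DecisionRule",
    "DecisionTreeSpec",
    "SubsetProfiles",
    "default_tree",
    "default_profiles",
    "fit_quantile_thresholds",
    "bin_marker",
    "bin_panel",
    "classify_subset",
    "enrich_cohort",
]

MARKERS = ("fap", "sma", "cd29", "fsp1", "pdgfrb")
#: Markers available at tile level (serial sections image only these four).
TILE_MARKERS = ("cd29", "fap", "sma", "fsp1")
LEVELS = ("Neg", "Low", "Med", "Hi")
SUBSETS = ("CAF-S1", "CAF-S2", "CAF-S3", "CAF-S4")

#: Rendering colors: CAF-S1 red, CAF-S2 orange, CAF-S3 green, CAF-S4 blue.
SUBSET_COLORS = {
    "CAF-S1": "#E41A1C",
    "CAF-S2": "#FF7F00",
    "CAF-S3": "#4DAF4A",
    "CAF-S4": "#377EB8",
    "masked": "#808080",
    "edge": "#000000",
}

#: Archetype tie-break priority (activated subsets first).
TIE_PRIORITY = ("CAF-S1", "CAF-S4", "CAF-S3", "CAF-S2")


@dataclass(frozen=True)
class MarkerPanel:
    """Per-sample marker values; H-scores (tumor) or mean DAB OD (tile).

    Markers not measured are ``None``; tile mode typically carries only
    CD29, FAP, SMA and FSP1.
    """

    fap: float | None = None
    sma: float | None = None
    cd29: float | None = None
    fsp1: float | None = None
    pdgfrb: float | None = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            v = float(v)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"marker {f.name}: value must be finite and >= 0")
            object.__setattr__(self, f.name, v)

    def markers(self) -> dict[str, float]:
        """Mapping of the measured markers only."""
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass(frozen=True)
class MarkerThresholds:
    """Q1 / median / Q3 for one marker, in the panel's units."""

    q1: float
    med: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.med <= self.q3:
            raise ValueError(
                f"thresholds must be ordered q1 <= med <= q3, "
                f"got ({self.q1}, {self.med}, {self.q3})"
            )


class QuantileThresholds(dict):
    """Mapping marker name -> :class:`MarkerThresholds`."""

    def __init__(self, per_marker: Mapping[str, MarkerThresholds]):
        for k, v in per_marker.items():
            if not isinstance(v, MarkerThresholds):
                v = MarkerThresholds(*v)
            self[k] = v


@dataclass(frozen=True)
class DecisionRule:
    marker: str
    threshold: str  # "q1" | "med" | "q3"
    op: str  # "ge" | "lt"
    subset: str

    def __post_init__(self) -> None:
        if self.threshold not in ("q1", "med", "q3"):
            raise ValueError(f"unknown threshold name {self.threshold!r}")
        if self.op not in ("ge", "lt"):
            raise ValueError(f"unknown comparator {self.op!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass(frozen=True)
class DecisionTreeSpec:
    """Ordered decision list: first matching rule assigns its subset."""

    rules: tuple[DecisionRule, ...]
    default: str
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.default not in SUBSETS:
            raise ValueError(f"unknown default subset {self.default!r}")
        for r in self.rules:
            if r.marker not in MARKERS:
                raise ValueError(f"tree references unknown marker {r.marker!r}")

    @property
    def markers(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rules:
            if r.marker not in seen:
                seen.append(r.marker)
        return tuple(seen)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecisionTreeSpec":
        rules = tuple(
            DecisionRule(
                marker=str(r["marker"]).lower(),
                threshold=str(r["threshold"]),
                op=str(r.get("op", "ge")),
                subset=str(r["subset"]),
            )
            for r in d["rules"]
        )
        return cls(
            rules=rules,
            default=str(d["default"]),
            provenance=str(d.get("provenance", "user")),
        )

    @classmethod
    def from_yaml(cls, path) -> "DecisionTreeSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "rules": [
                {
                    "marker": r.marker,
                    "threshold": r.threshold,
                    "op": r.op,
                    "subset": r.subset,
                }
                for r in self.rules
            ],
            "default": self.default,
        }


def _expand_band(band: str) -> frozenset[str]:
    """'Low-Hi' -> {Low, Med, Hi}; single names pass through."""
    band = band.strip()
    if "-" in band:
        lo, hi = band.split("-")
        i, j = LEVELS.index(lo), LEVELS.index(hi)
        if i > j:
            raise ValueError(f"band {band!r} is not ordered")
        return frozenset(LEVELS[i : j + 1])
    if band not in LEVELS:
        raise ValueError(f"unknown level {band!r}")
    return frozenset({band})


class SubsetProfiles(dict):
    """Mapping subset -> {marker -> frozenset of permitted bins}."""

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubsetProfiles":
        out = cls()
        for subset, markers in d.items():
            if subset not in SUBSETS:
                raise ValueError(f"unknown subset {subset!r}")
            out[subset] = {
                str(m).lower(): _expand_band(str(b)) for m, b in markers.items()
            }
        if len({tuple(sorted((m, tuple(sorted(b))) for m, b in p.items()))
                for p in out.values()}) != len(out):
            raise ValueError("subset profiles must be pairwise distinct")
        return out

    @classmethod
    def from_yaml(cls, path) -> "SubsetProfiles":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _data_text(name: str) -> str:
    return (resources.files("cafkit") / "data" / name).read_text()


def default_tree() -> DecisionTreeSpec:
    """The packaged default decision tree (profile-consistent)."""
    return DecisionTreeSpec.from_dict(yaml.safe_load(_data_text("default_tree.yaml")))


def default_profiles() -> SubsetProfiles:
    """The packaged quartile-bin archetype profiles of CAF-S1..S4."""
    return SubsetProfiles.from_dict(yaml.safe_load(_data_text("subset_profiles.yaml")))


def fit_quantile_thresholds(
    values: Mapping[str, Sequence[float]]
) -> QuantileThresholds:
    """25/50/75% linear-interpolation quantiles per marker.

    Each marker needs at least 4 finite values; NaNs are rejected rather
    than silently dropped.
    """
    out = {}
    for marker, v in values.items():
        arr = np.asarray(v, dtype=float)
        if arr.size < 4:
            raise ValueError(f"marker {marker}: need >= 4 values, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"marker {marker}: values must be finite")
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        out[marker] = MarkerThresholds(float(q1), float(med), float(q3))
    return QuantileThresholds(out)


def bin_marker(value: float, thresholds: MarkerThresholds) -> str:
    """Neg if v < Q1; Low if Q1 <= v < med; Med if med <= v < Q3; Hi if v >= Q3."""
    v = float(value)
    if v < thresholds.q1:
        return "Neg"
    if v < thresholds.med:
        return "Low"
    if v < thresholds.q3:
        return "Med"
    return "Hi"


def bin_panel(panel: MarkerPanel, thresholds: QuantileThresholds) -> dict[str, str]:
    """Bin every measured marker of a panel."""
    bins = {}
    for marker, v in panel.markers().items():
        if marker not in thresholds:
            raise KeyError(f"no thresholds fitted for marker {marker!r}")
        bins[marker] = bin_marker(v, thresholds[marker])
    return bins


def _classify_tree(
    panel: MarkerPanel, thresholds: QuantileThresholds, tree: DecisionTreeSpec
) -> str:
    measured = panel.markers()
    for rule in tree.rules:
        if rule.marker not in measured:
            raise KeyError(
                f"decision tree references marker {rule.marker!r} "
                f"missing from the panel"
            )
        if rule.marker not in thresholds:
            raise KeyError(f"no thresholds for marker {rule.marker!r}")
        t = getattr(thresholds[rule.marker], rule.threshold)
        v = measured[rule.marker]
        hit = v >= t if rule.op == "ge" else v < t
        if hit:
            return rule.subset
    return tree.default


def _classify_archetype(
    panel: MarkerPanel,
    thresholds: QuantileThresholds,
    profiles: SubsetProfiles,
    priority: Sequence[str] = TIE_PRIORITY,
) -> str:
    bins = bin_panel(panel, thresholds)
    best, best_score = None, -1
    for subset in priority:
        profile = profiles[subset]
        score = sum(
            1 for m, b in bins.items() if m in profile and b in profile[m]
        )
        if score > best_score:
            best, best_score = subset, score
    assert best is not None
    return best


def classify_subset(
    panel: MarkerPanel,
    thresholds: QuantileThresholds,
    tree: DecisionTreeSpec | None = None,
    mode: str = "tree",
    profiles: SubsetProfiles | None = None,
) -> str:
    """Assign one CAF subset to a marker panel.

    ``mode="tree"`` traverses the ordered decision list (default: the
    packaged tree); ``mode="archetype"`` picks the subset whose profile
    matches the most marker bins, ties broken by the fixed priority
    S1 > S4 > S3 > S2.
    """
    if mode == "tree":
        return _classify_tree(panel, thresholds, tree or default_tree())
    if mode == "archetype":
        return _classify_archetype(panel, thresholds, profiles or default_profiles())
    raise ValueError(f"unknown classification mode {mode!r}")


def enrich_cohort(
    panels: Sequence[MarkerPanel],
    thresholds: QuantileThresholds | None = None,
    tree: DecisionTreeSpec | None = None,
    mode: str = "tree",
) -> tuple[list[str], pd.Series]:
    """Classify every tumor of a cohort and report the subset distribution.

    Quartile thresholds are fitted on the cohort itself unless external
    (e.g. learning-set) thresholds are supplied. Returns the per-tumor
    labels and the distribution as percentages summing to 100.
    """
    if len(panels) == 0:
        raise ValueError("empty cohort")
    if thresholds is None:
        by_marker: dict[str, list[float]] = {}
        for p in panels:
            for m, v in p.markers().items():
                by_marker.setdefault(m, []).append(v)
        thresholds = fit_quantile_thresholds(by_marker)
    labels = [classify_subset(p, thresholds, tree=tree, mode=mode) for p in panels]
    counts = pd.Series(labels).value_counts()
    dist = counts.reindex(SUBSETS, fill_value=0) / len(labels) * 100.0
    return labels, dist
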