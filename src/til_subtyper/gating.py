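"""Declarative hierarchical gating of cytometry event tables.

A :class:`GatingTree` is a DAG of single-marker threshold gates loaded from a
YAML config.  Events are classified by conjunction of gate predicates along
each node's path from the root; populations are named references to nodes.
The packaged default config encodes a 26-marker NSCLC TIL panel resolving 30
populations (23 base immune cell types plus 7 functional-marker overlays).

Gate semantics, relative to the per-channel thresholds ``(negative,
positive)``:

* ``positive`` / ``high`` — intensity >= positive threshold
* ``negative`` — intensity < positive threshold (complement of positive, so a
  +/- split partitions its parent)
* ``low`` — negative threshold <= intensity < positive threshold ("dim"
  expression such as HLA-DRlo or FOXP3lo)

Thresholds are fixed values from the config; no automatic gate inference is
performed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GateNode",
    "GatingTree",
    "PopulationCounts",
    "GatingConfigError",
    "load_gating_config",
    "default_gating_tree",
    "enumerate_populations",
    "gate_events",
    "counts_wide",
    "write_counts_csv",
    "read_counts_csv",
]

_POLARITIES = ("positive", "negative", "low", "high")


class GatingConfigError(ValueError):
    """Raised when a gating config fails structural validation."""


@dataclass(frozen=True)
class GateNode:
    node_id: str
    parent_id: str  # "root" for top-level gates
    marker: str
    polarity: str


@dataclass(frozen=True)
class PopulationDef:
    population_id: str
    node_id: str
    category: str
    parent_population: str | None = None
    myeloid: bool = False
    label: str = ""


@dataclass
class GatingTree:
    """Validated gate hierarchy plus population definitions."""

    markers: list[str]
    scatter: list[str]
    viability: str
    thresholds: dict[str, tuple[float, float]]
    default_thresholds: tuple[float, float]
    nodes: dict[str, GateNode]
    populations: list[PopulationDef]
    cd45_node: str
    feature_presets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def channels(self) -> list[str]:
        return self.markers + self.scatter + [self.viability]

    def population(self, population_id: str) -> PopulationDef:
        for p in self.populations:
            if p.population_id == population_id:
                return p
        raise KeyError(population_id)

    def thresholds_for(self, channel: str) -> tuple[float, float]:
        return self.thresholds.get(channel, self.default_thresholds)

    def node_path(self, node_id: str) -> list[GateNode]:
        """Gate chain from the root down to ``node_id``."""
        path: list[GateNode] = []
        cur = node_id
        while cur != "root":
            node = self.nodes[cur]
            path.append(node)
            cur = node.parent_id
        return list(reversed(path))


@dataclass
class PopulationCounts:
    """Per-population event counts for one sample."""

    sample_id: str
    counts: dict[str, int]
    total_cd45: int

    def as_series(self) -> pd.Series:
        s = pd.Series(self.counts, dtype="int64")
        s.loc["total_cd45"] = self.total_cd45
        s.name = self.sample_id
        return s


def _parse_threshold_entry(entry) -> tuple[float, float]:
    neg, pos = float(entry["negative"]), float(entry["positive"])
    if not neg < pos:
        raise GatingConfigError(
            f"negative threshold {neg} must be below positive threshold {pos}"
        )
    return neg, pos


def _validate(tree: GatingTree) -> None:
    known_channels = set(tree.channels)
    for node in tree.nodes.values():
        if node.marker not in known_channels:
            raise GatingConfigError(
                f"gate {node.node_id!r} references unknown marker {node.marker!r}"
            )
        if node.polarity not in _POLARITIES:
            raise GatingConfigError(
                f"gate {node.node_id!r} has invalid polarity {node.polarity!r}"
            )
        if node.parent_id != "root" and node.parent_id not in tree.nodes:
            raise GatingConfigError(
                f"gate {node.node_id!r} references missing parent {node.parent_id!r}"
            )
    # cycle check: every node must reach root
    for node_id in tree.nodes:
        seen = set()
        cur = node_id
        while cur != "root":
            if cur in seen:
                raise GatingConfigError(f"cycle detected through gate {cur!r}")
            seen.add(cur)
            cur = tree.nodes[cur].parent_id
    pop_ids = [p.population_id for p in tree.populations]
    dupes = {p for p in pop_ids if pop_ids.count(p) > 1}
    if dupes:
        raise GatingConfigError(f"duplicate population ids: {sorted(dupes)}")
    for pop in tree.populations:
        if pop.node_id not in tree.nodes:
            raise GatingConfigError(
                f"population {pop.population_id!r} references missing gate "
                f"{pop.node_id!r}"
            )
        if pop.parent_population is not None and pop.parent_population not in pop_ids:
            raise GatingConfigError(
                f"population {pop.population_id!r} references missing parent "
                f"population {pop.parent_population!r}"
            )
    if tree.cd45_node not in tree.nodes:
        raise GatingConfigError(f"cd45_node {tree.cd45_node!r} is not a gate")
    for preset, pops in tree.feature_presets.items():
        missing = [p for p in pops if p not in pop_ids]
        if missing:
            raise GatingConfigError(
                f"feature preset {preset!r} lists unknown populations {missing}"
            )


def load_gating_config(path: str | Path) -> GatingTree:
    """Load and validate a gating tree from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _tree_from_dict(raw)


def _tree_from_dict(raw: dict) -> GatingTree:
    try:
        panel = raw["panel"]
        markers = list(panel["markers"])
        scatter = list(panel.get("scatter", []))
        viability = panel["viability"]
        thresholds_raw = dict(raw.get("thresholds", {}))
        nodes_raw = raw["nodes"]
        pops_raw = raw["populations"]
        cd45_node = raw["cd45_node"]
    except KeyError as exc:  # pragma: no cover - malformed configs
        raise GatingConfigError(f"missing config section: {exc}") from exc

    default_thresholds = _parse_threshold_entry(
        thresholds_raw.pop("default", {"negative": 1.5, "positive": 2.5})
    )
    thresholds = {
        ch: _parse_threshold_entry(entry) for ch, entry in thresholds_raw.items()
    }
    nodes: dict[str, GateNode] = {}
    for entry in nodes_raw:
        node = GateNode(
            node_id=entry["id"],
            parent_id=entry["parent"],
            marker=entry["marker"],
            polarity=entry["polarity"],
        )
        if node.node_id in nodes:
            raise GatingConfigError(f"duplicate gate id {node.node_id!r}")
        nodes[node.node_id] = node
    populations = [
        PopulationDef(
            population_id=entry["id"],
            node_id=entry["node"],
            category=entry["category"],
            parent_population=entry.get("parent_population"),
            myeloid=bool(entry.get("myeloid", False)),
            label=entry.get("label", entry["id"]),
        )
        for entry in pops_raw
    ]
    tree = GatingTree(
        markers=markers,
        scatter=scatter,
        viability=viability,
        thresholds=thresholds,
        default_thresholds=default_thresholds,
        nodes=nodes,
        populations=populations,
        cd45_node=cd45_node,
        feature_presets={
            k: list(v) for k, v in raw.get("feature_presets", {}).items()
        },
    )
    _validate(tree)
    return tree


def default_gating_tree() -> GatingTree:
    """The packaged 26-marker / 30-population NSCLC TIL gating tree."""
    ref = importlib.resources.files("til_subtyper.data") / "default_gates.yaml"
    return _tree_from_dict(yaml.safe_load(ref.read_text()))


def enumerate_populations(tree: GatingTree) -> list[str]:
    """Ordered population ids (config order, which follows the hierarchy)."""
    return [p.population_id for p in tree.populations]


def _node_mask(
    tree: GatingTree, events: pd.DataFrame, node_id: str, cache: dict[str, np.ndarray]
) -> np.ndarray:
    if node_id == "root":
        return np.ones(len(events), dtype=bool)
    if node_id in cache:
        return cache[node_id]
    node = tree.nodes[node_id]
    parent = _node_mask(tree, events, node.parent_id, cache)
    x = events[node.marker].to_numpy()
    neg, pos = tree.thresholds_for(node.marker)
    if node.polarity in ("positive", "high"):
        own = x >= pos
    elif node.polarity == "negative":
        own = x < pos
    else:  # low
        own = (x >= neg) & (x < pos)
    mask = parent & own
    cache[node_id] = mask
    return mask


def gate_events(
    events: pd.DataFrame, tree: GatingTree, sample_id: str = "sample"
) -> PopulationCounts:
    """Classify events through the gate hierarchy and count populations.

    ``events`` must contain every panel channel as a column.  An empty table
    yields all-zero counts.
    """
    missing = [c for c in tree.channels if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing channels: {missing}")
    cache: dict[str, np.ndarray] = {}
    counts = {
        p.population_id: int(_node_mask(tree, events, p.node_id, cache).sum())
        for p in tree.populations
    }
    total_cd45 = int(_node_mask(tree, events, tree.cd45_node, cache).sum())
    return PopulationCounts(sample_id=sample_id, counts=counts, total_cd45=total_cd45)


def counts_wide(counts: list[PopulationCounts]) -> pd.DataFrame:
    """Stack per-sample counts into a samples x populations frame.

    The frame carries one column per population plus ``total_cd45``.
    """
    if not counts:
        return pd.DataFrame()
    df = pd.DataFrame([c.as_series() for c in counts])
    df.index.name = "sample_id"
    return df


def write_counts_csv(counts: list[PopulationCounts], path: str | Path) -> None:
    """Write tidy counts (sample_id, population_id, count) to CSV."""
    rows = []
    for c in counts:
        for pop, n in c.counts.items():
            rows.append((c.sample_id, pop, n))
        rows.append((c.sample_id, "total_cd45", c.total_cd45))
    pd.DataFrame(rows, columns=["sample_id", "population_id", "count"]).to_csv(
        path, index=False
    )


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    """Read tidy counts CSV back into the wide samples x populations frame."""
    tidy = pd.read_csv(path)
    wide = tidy.pivot(index="sample_id", columns="population_id", values="count")
    wide.columns.name = None
    return wide
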