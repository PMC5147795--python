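"""Which features drive the classifier?

Post-hoc analyses of a repeated-CV run with internal SVM-RFE: how often
each feature was selected across all internal training folds, quartile
summaries of those counts by event class, a hierarchical breakdown of
the frequently selected features (event class -> axis -> binocular mode
-> parameter, with duration broken out as a separate temporal tree),
and min-max-normalized per-group distributions of chosen features for
box-plot style comparison of the HR and LR groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import ProtocolResult
from .features import FeatureSchema, parse_feature_id

__all__ = [
    "SelectionFrequencyTable",
    "BreakdownNode",
    "selection_frequencies",
    "frequency_summary",
    "hierarchical_breakdown",
    "normalized_group_distributions",
    "plot_selection_frequencies",
    "plot_group_distributions",
]

logger = logging.getLogger(__name__)

#: A selection-frequency table is a pandas Series: index = feature id,
#: value = number of training folds in which the feature was selected.
SelectionFrequencyTable = pd.Series

_QUANTILE_NAMES = ("min", "q1", "median", "q3", "max")


def selection_frequencies(
    result: ProtocolResult, schema: FeatureSchema, n: int | None = None
) -> SelectionFrequencyTable:
    """Count, per feature, the training folds that selected it.

    ``n`` picks the feature-subset size of interest (default: the run's
    best-accuracy size).  Counts range from 0 to folds x repetitions.
    """
    if result.protocol.fs_method != "rfe":
        raise ValueError("selection frequencies require an RFE run")
    if list(result.feature_ids) != schema.ids:
        raise ValueError("schema does not match the features the protocol ran on")
    if n is None:
        n = result.best_n
    counts = np.zeros(len(schema), dtype=int)
    for fr in result.fold_records:
        if n not in fr.selected:
            raise ValueError(f"subset size {n} not in the evaluated grid")
        counts[fr.selected[n]] += 1
    return pd.Series(counts, index=schema.ids, name="selection_count")


def frequency_summary(
    table: SelectionFrequencyTable, schema: FeatureSchema, by: str = "event_class"
) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) of counts per group.

    Quartiles use linear interpolation between order statistics.  The
    grouping (default: the four event classes) partitions the features,
    so each feature contributes to exactly one row.
    """
    if len(table) == 0:
        raise ValueError("empty frequency table")
    groups: dict[str, list[int]] = {}
    for fid, count in table.items():
        key = getattr(parse_feature_id(fid), by)
        key = "Dur" if key is None else key
        groups.setdefault(key, []).append(count)
    rows = {
        key: dict(
            zip(
                _QUANTILE_NAMES,
                np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear"),
            )
        )
        for key, vals in groups.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(_QUANTILE_NAMES)]


@dataclass
class BreakdownNode:
    """One level of the hierarchical breakdown; a node's frequency is the
    sum of its children's."""

    name: str
    level: str
    frequency: int
    n_features: int
    children: list["BreakdownNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "level": self.level,
            "frequency": int(self.frequency),
            "n_features": int(self.n_features),
            "children": [c.to_dict() for c in self.children],
        }


def _build_tree(
    items: list[tuple[tuple[str, ...], int]], levels: tuple[str, ...], name: str, level: str
) -> BreakdownNode:
    node = BreakdownNode(
        name=name,
        level=level,
        frequency=sum(c for _, c in items),
        n_features=len(items),
    )
    if not levels or not items:
        return node
    branches: dict[str, list[tuple[tuple[str, ...], int]]] = {}
    for keys, count in items:
        branches.setdefault(keys[0], []).append((keys[1:], count))
    for key in sorted(branches):
        node.children.append(_build_tree(branches[key], levels[1:], key, levels[0]))
    return node


def hierarchical_breakdown(
    table: SelectionFrequencyTable, threshold: int, schema: FeatureSchema
) -> dict:
    """Break the frequently selected features down the taxonomy.

    Keeps features with count strictly greater than ``threshold``
    ("majority of folds" = more than half of folds x repetitions) and
    accumulates their selection frequencies down event class -> axis ->
    binocular mode -> parameter for the spatial features, and down event
    class alone for the duration (temporal) features.

    Returns a dict with the two trees, the share of the schema passing
    the threshold (percent), and per-event-class shares of the selected
    features computed both as share of feature count and as share of
    accumulated frequency (the two readings of "percent related to").
    """
    if not 0 <= threshold:
        raise ValueError("threshold must be >= 0")
    passing = table[table > threshold]
    spatial: list[tuple[tuple[str, ...], int]] = []
    temporal: list[tuple[tuple[str, ...], int]] = []
    for fid, count in passing.items():
        d = parse_feature_id(fid)
        if d.parameter == "Dur":
            temporal.append(((d.event_class,), int(count)))
        else:
            spatial.append(
                ((d.event_class, d.axis, d.mode, d.parameter), int(count))
            )

    class_features: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for fid, count in passing.items():
        cls = parse_feature_id(fid).event_class
        class_features[cls] = class_features.get(cls, 0) + 1
        class_counts[cls] = class_counts.get(cls, 0) + int(count)
    total_count = int(passing.sum())
    return {
        "threshold": int(threshold),
        "n_selected": int(len(passing)),
        "share_of_schema_pct": 100.0 * len(passing) / len(schema),
        "accumulated_frequency": total_count,
        "spatial": _build_tree(
            spatial, ("event_class", "axis", "mode", "parameter"), "spatial", "root"
        ),
        "temporal": _build_tree(temporal, ("event_class",), "temporal", "root"),
        "class_share_of_features_pct": {
            c: 100.0 * v / len(passing) for c, v in sorted(class_features.items())
        }
        if len(passing)
        else {},
        "class_share_of_frequency_pct": {
            c: 100.0 * v / total_count for c, v in sorted(class_counts.items())
        }
        if total_count
        else {},
    }


def normalized_group_distributions(
    feature_matrix: pd.DataFrame,
    feature_ids: list[str],
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature, per-group five-number summaries on a pooled 0-1 scale.

    Each requested feature is min-max normalized over both groups pooled
    (per-group scaling would erase between-group contrasts), then
    summarized per group for box-plot rendering.  Constant features map
    to all zeros and are flagged in the ``constant`` column.
    """
    if labels is None:
        if "label" not in feature_matrix.columns:
            raise ValueError("need a 'label' column or explicit labels")
        labels = feature_matrix["label"].to_numpy()
    labels = np.asarray(labels)
    missing = [f for f in feature_ids if f not in feature_matrix.columns]
    if missing:
        raise KeyError(f"features not in matrix: {missing}")
    rows = []
    for fid in feature_ids:
        values = feature_matrix[fid].to_numpy(float)
        lo, hi = float(values.min()), float(values.max())
        constant = hi == lo
        if constant:
            logger.warning("feature %s is constant; normalized values set to 0", fid)
            norm = np.zeros_like(values)
        else:
            norm = (values - lo) / (hi - lo)
        for group in sorted(set(labels.tolist())):
            vals = norm[labels == group]
            q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
            rows.append(
                {
                    "feature": fid,
                    "group": group,
                    **dict(zip(_QUANTILE_NAMES, q)),
                    "constant": constant,
                }
            )
    return pd.DataFrame(rows).set_index(["feature", "group"])


def plot_selection_frequencies(table: SelectionFrequencyTable, path: str) -> None:
    """Bar plot of selection counts grouped by event class (debug/report aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [parse_feature_id(f).event_class for f in table.index]
    colors = {"PF": "#1f77b4", "RF": "#ff7f0e", "PS": "#2ca02c", "RS": "#d62728"}
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(table)), table.to_numpy(), color=[colors[c] for c in classes])
    ax.set_xlabel("feature index (grouped by event class)")
    ax.set_ylabel("training folds selected")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_distributions(summaries: pd.DataFrame, path: str) -> None:
    """Box-style plot of normalized per-group feature distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = summaries.index.get_level_values("feature").unique()
    groups = summaries.index.get_level_values("group").unique()
    width = 0.35
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(features)), 4))
    for gi, group in enumerate(groups):
        for fi, feat in enumerate(features):
            row = summaries.loc[(feat, group)]
            x = fi + (gi - (len(groups) - 1) / 2) * width
            ax.bxp(
                [
                    {
                        "whislo": row["min"],
                        "q1": row["q1"],
                        "med": row["median"],
                        "q3": row["q3"],
                        "whishi": row["max"],
                        "fliers": [],
                    }
                ],
                positions=[x],
                widths=width * 0.9,
                showfliers=False,
            )
    ax.set_xticks(range(len(features)))
    ax.set_xticklabels(features, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("normalized value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
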