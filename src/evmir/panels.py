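"""Cross-compartment comparison of significant-miRNA panels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .de import FilterSpec


@dataclass
class Panel:
    """An ordered set of significant features for one compartment."""

    compartment: str
    features: list[str]
    records: pd.DataFrame  # per-feature DE statistics, indexed by feature
    filter_spec: FilterSpec = field(default_factory=FilterSpec)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("panel features must be unique")
        missing = set(self.features) - set(self.records.index)
        if missing:
            raise ValueError(f"panel features without DE records: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.features)


class VennCounts(NamedTuple):
    only_a: int
    only_b: int
    both: int


def venn_counts(panel_a: Panel, panel_b: Panel) -> VennCounts:
    """Two-set Venn partition of the panel name sets."""
    a, b = set(panel_a.features), set(panel_b.features)
    both = a & b
    return VennCounts(only_a=len(a - both), only_b=len(b - both), both=len(both))


def intersect_panels(panel_a: Panel, panel_b: Panel) -> pd.DataFrame:
    """Table of features common to both panels.

    One row per (compartment, feature) pair, carrying each compartment's
    DE statistics and a flag marking whether the fold-change direction
    agrees between compartments.  Features appear in the order of
    ``panel_a``.
    """
    common = [f for f in panel_a.features if f in set(panel_b.features)]
    blocks = []
    for panel in (panel_a, panel_b):
        block = panel.records.loc[common].copy()
        block.insert(0, "compartment", panel.compartment)
        blocks.append(block)
    table = pd.concat(blocks)
    agree = {
        f: bool(
            panel_a.records.at[f, "fold_change"] * panel_b.records.at[f, "fold_change"]
            > 0
        )
        for f in common
    }
    table["direction_agreement"] = [agree[f] for f in table.index]
    table.index.name = "feature"
    return table
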