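"""Marker panel definitions.

A MIBI acquisition profiles dozens of antibody markers; each image channel
carries one marker.  Markers fall into two working categories: *functional*
proteins, whose expression reflects the functional state of a cell (e.g.
PD-1, IDO, Ki67), and *lineage* proteins used to assign cell identity (e.g.
CD45, Pan-Keratin).  A small subset of the functional markers — PD-1, PD-L1,
IDO and Lag3 — are immunotherapy targets and are singled out as the
*immunoregulatory* set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("functional", "lineage", "other")

#: Immune-checkpoint / immunoregulatory proteins considered as
#: immunotherapy targets; the default `immunoregulatory` flag.
DEFAULT_IMMUNOREGULATORY = frozenset({"PD-1", "PD-L1", "IDO", "Lag3"})


class PanelError(ValueError):
    """Raised when a marker panel is inconsistent with the data it describes."""


@dataclass(frozen=True)
class Marker:
    """One panel entry: a named marker bound to an image channel."""

    name: str
    channel_index: int
    category: str = "functional"
    immunoregulatory: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PanelError(f"unknown category {self.category!r} for marker {self.name!r}")
        if self.immunoregulatory and self.category != "functional":
            raise PanelError(
                f"marker {self.name!r}: immunoregulatory markers must be functional"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of markers mapping names to image channels.

    Invariants enforced at construction: unique names, unique channel
    indices, immunoregulatory ⊆ functional.
    """

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise PanelError("duplicate marker names in panel")
        chans = [m.channel_index for m in self.markers]
        if len(set(chans)) != len(chans):
            raise PanelError("duplicate channel indices in panel")
        if any(c < 0 for c in chans):
            raise PanelError("negative channel index")

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        categories: Sequence[str] | None = None,
        immunoregulatory: Iterable[str] | None = None,
    ) -> "MarkerPanel":
        """Build a panel from marker names in channel order.

        If ``immunoregulatory`` is None the default set (PD-1, PD-L1, IDO,
        Lag3) is flagged wherever present.
        """
        if categories is None:
            categories = ["functional"] * len(names)
        ir = DEFAULT_IMMUNOREGULATORY if immunoregulatory is None else set(immunoregulatory)
        markers = tuple(
            Marker(n, i, c, immunoregulatory=(n in ir and c == "functional"))
            for i, (n, c) in enumerate(zip(names, categories, strict=True))
        )
        return cls(markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def functional_names(self) -> list[str]:
        return [m.name for m in self.markers if m.category == "functional"]

    @property
    def lineage_names(self) -> list[str]:
        return [m.name for m in self.markers if m.category == "lineage"]

    @property
    def immunoregulatory_names(self) -> list[str]:
        return [m.name for m in self.markers if m.immunoregulatory]

    def index(self, name: str) -> int:
        """Position of ``name`` in panel order (not the channel index)."""
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise PanelError(f"marker {name!r} not in panel")

    def channel(self, name: str) -> int:
        return self.markers[self.index(name)].channel_index

    def validate_channel_count(self, n_channels: int) -> None:
        if n_channels != len(self.markers):
            raise PanelError(
                f"image has {n_channels} channels but panel describes {len(self.markers)} markers"
            )
        bad = [m.name for m in self.markers if m.channel_index >= n_channels]
        if bad:
            raise PanelError(f"channel indices out of range for markers {bad}")

    def intersection(self, other: "MarkerPanel") -> list[str]:
        """Marker names shared with another panel, in this panel's order.

        Used to compare cohorts profiled with different assays (e.g. the
        healthy-breast panel shares six proteins with the tumor panel).
        """
        theirs = set(other.names)
        return [n for n in self.names if n in theirs]

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "name": [m.name for m in self.markers],
                "channel_index": [m.channel_index for m in self.markers],
                "category": [m.category for m in self.markers],
                "immunoregulatory": [int(m.immunoregulatory) for m in self.markers],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path)
        required = {"name", "channel_index", "category"}
        missing = required - set(df.columns)
        if missing:
            raise PanelError(f"panel CSV missing columns {sorted(missing)}")
        if "immunoregulatory" not in df.columns:
            df["immunoregulatory"] = [
                int(n in DEFAULT_IMMUNOREGULATORY) for n in df["name"]
            ]
        markers = tuple(
            Marker(
                str(r["name"]),
                int(r["channel_index"]),
                str(r["category"]),
                bool(int(r["immunoregulatory"])),
            )
            for _, r in df.iterrows()
        )
        return cls(markers)
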