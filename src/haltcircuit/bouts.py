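"""Labeled behavioral episodes and boolean run-finding helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BoutTable", "bool_runs"]


@dataclass
class BoutTable:
    """Episodes ``(t_start, t_end, label)`` plus per-episode scalar metrics.

    Episodes of one label must not overlap; intervals are half-open in
    seconds.
    """

    episodes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["t_start", "t_end", "label"]
        )
    )

    def __post_init__(self) -> None:
        df = self.episodes
        if len(df):
            if (df["t_end"] <= df["t_start"]).any():
                raise ValueError("every episode needs t_start < t_end")
            for label, grp in df.groupby("label"):
                g = grp.sort_values("t_start")
                if (g["t_start"].values[1:] < g["t_end"].values[:-1]).any():
                    raise ValueError(f"overlapping {label!r} episodes")

    def __len__(self) -> int:
        return len(self.episodes)

    def with_label(self, label: str) -> pd.DataFrame:
        df = self.episodes
        return df[df["label"] == label].reset_index(drop=True)

    @property
    def durations(self) -> np.ndarray:
        return (self.episodes["t_end"] - self.episodes["t_start"]).to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Long format ``t_start,t_end,label,metric,value``."""
        base = ["t_start", "t_end", "label"]
        extra = [c for c in self.episodes.columns if c not in base]
        rows = []
        for _, r in self.episodes.iterrows():
            if extra:
                for m in extra:
                    rows.append((r.t_start, r.t_end, r.label, m, r[m]))
            else:
                rows.append((r.t_start, r.t_end, r.label, "", np.nan))
        pd.DataFrame(
            rows, columns=["t_start", "t_end", "label", "metric", "value"]
        ).to_csv(path, index=False)

    @classmethod
    def from_runs(
        cls,
        runs: list[tuple[int, int]],
        fs: float,
        label: str,
        **metrics: list,
    ) -> "BoutTable":
        """Build from half-open frame-index runs at sample rate ``fs`` Hz."""
        df = pd.DataFrame(
            {
                "t_start": [a / fs for a, _ in runs],
                "t_end": [b / fs for _, b in runs],
                "label": label,
            }
        )
        for k, v in metrics.items():
            df[k] = v
        return cls(df)


def bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs [start, stop)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
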