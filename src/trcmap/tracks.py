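"""Fixed-step genomic signal tracks.

A :class:`SignalTrack` stores one numeric value per fixed-width window
anchored at coordinate 0 of each chromosome (bedGraph-like, dense).
Window ``i`` covers the half-open interval ``[i*step, (i+1)*step)``.
Used for EdU-HU replication signal, EU nascent-transcription signal and
binned break coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    step: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], step: int) -> "SignalTrack":
        return cls(
            step=step,
            values={c: np.zeros(-(-size // step)) for c, size in chrom_sizes.items()},
        )

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a base position; 0 outside the covered range."""
        if chrom not in self.values:
            return 0.0
        i = int(pos) // self.step
        v = self.values[chrom]
        if i < 0 or i >= len(v):
            return 0.0
        return float(v[i])

    def window(self, chrom: str, start: int, end: int, n_points: int) -> np.ndarray:
        """Resample ``[start, end)`` to ``n_points`` evenly spaced positions.

        Positions outside the chromosome contribute 0 (zero-padding).
        """
        if end <= start:
            raise ValueError("window end must exceed start")
        positions = start + (np.arange(n_points) + 0.5) * (end - start) / n_points
        out = np.zeros(n_points)
        if chrom not in self.values:
            return out
        v = self.values[chrom]
        idx = (positions // self.step).astype(int)
        ok = (idx >= 0) & (idx < len(v)) & (positions >= 0)
        out[ok] = v[idx[ok]]
        return out

    def to_bedgraph(self, path) -> None:
        """Write as bedGraph, dropping zero-valued windows."""
        rows = []
        for chrom in sorted(self.values):
            v = self.values[chrom]
            (nz,) = np.nonzero(v)
            for i in nz:
                rows.append((chrom, i * self.step, (i + 1) * self.step, v[i]))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bedgraph(
        cls, path, chrom_sizes: dict[str, int], step: int
    ) -> "SignalTrack":
        """Load a bedGraph onto a fixed-step grid.

        Each bedGraph interval is assigned to the windows it covers;
        partially covered windows take a length-weighted contribution.
        """
        track = cls.zeros(chrom_sizes, step)
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        for row in df.itertuples(index=False):
            if row.chrom not in track.values:
                continue
            v = track.values[row.chrom]
            first, last = int(row.start) // step, (int(row.end) - 1) // step
            for i in range(max(first, 0), min(last, len(v) - 1) + 1):
                lo = max(row.start, i * step)
                hi = min(row.end, (i + 1) * step)
                v[i] += row.value * (hi - lo) / step
        return track
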