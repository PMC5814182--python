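"""Mapped mate-pair fragments: the atomic input of the pipeline.

A fragment is one long-insert library molecule observed as two mapped ends,
each a (chromosome, position, strand) triple. Fragment collections are held
as a pandas DataFrame with the columns in :data:`FRAGMENT_COLUMNS`; ends are
stored in canonical order (genome chromosome order, then position) so that
downstream clustering is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate.genome import GenomeModel

FRAGMENT_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "name"]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class MappedFragment:
    """A single fragment; collections use the DataFrame form instead."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    name: str = ""

    def as_row(self) -> dict:
        return {
            "chrom1": self.chrom1,
            "pos1": self.pos1,
            "strand1": self.strand1,
            "chrom2": self.chrom2,
            "pos2": self.pos2,
            "strand2": self.strand2,
            "name": self.name,
        }


def empty_fragment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom1": pd.Series(dtype=object),
            "pos1": pd.Series(dtype=np.int64),
            "strand1": pd.Series(dtype=object),
            "chrom2": pd.Series(dtype=object),
            "pos2": pd.Series(dtype=np.int64),
            "strand2": pd.Series(dtype=object),
            "name": pd.Series(dtype=object),
        }
    )


def frame_from_fragments(fragments) -> pd.DataFrame:
    """Build a fragment frame from an iterable of :class:`MappedFragment`."""
    rows = [f.as_row() for f in fragments]
    if not rows:
        return empty_fragment_frame()
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def canonicalize(frame: pd.DataFrame, genome: "GenomeModel") -> pd.DataFrame:
    """Return a copy with each fragment's ends in canonical order.

    End 1 is the end on the earlier chromosome in genome order, breaking
    ties by position. Also validates chromosomes, positions and strands.
    """
    frame = frame.reset_index(drop=True).copy()
    rank = genome.rank
    unknown = set(frame["chrom1"]).union(frame["chrom2"]) - set(rank)
    if unknown:
        known = ", ".join(genome.names)
        raise ValueError(f"unknown chromosome(s) {sorted(unknown)}; known: {known}")
    for col in ("strand1", "strand2"):
        bad = ~frame[col].isin(STRANDS)
        if bad.any():
            raise ValueError(f"invalid strand value(s) in column {col}: {sorted(frame.loc[bad, col].unique())}")
    lengths = genome.lengths
    for chrom_col, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        lim = frame[chrom_col].map(lengths).to_numpy()
        pos = frame[pos_col].to_numpy()
        bad = (pos < 0) | (pos >= lim)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"fragment {frame['name'].iat[i]!r}: position {pos[i]} outside "
                f"chromosome {frame[chrom_col].iat[i]!r}"
            )

    r1 = frame["chrom1"].map(rank).to_numpy()
    r2 = frame["chrom2"].map(rank).to_numpy()
    p1 = frame["pos1"].to_numpy()
    p2 = frame["pos2"].to_numpy()
    swap = (r2 < r1) | ((r2 == r1) & (p2 < p1))
    if swap.any():
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            va, vb = frame[a].to_numpy().copy(), frame[b].to_numpy().copy()
            frame.loc[swap, a] = vb[swap]
            frame.loc[swap, b] = va[swap]
    frame["pos1"] = frame["pos1"].astype(np.int64)
    frame["pos2"] = frame["pos2"].astype(np.int64)
    return frame
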