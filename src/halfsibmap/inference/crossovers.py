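"""Crossover records from decoded transmission paths.

A crossover is an origin switch between consecutive informative markers
of one meiosis; its position is reported as the bp interval flanked by
those markers, with the event placed at the interval midpoint for
downstream trait computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import DecodedPaths

CROSSOVER_COLUMNS = [
    "progeny", "parent", "parent_sex", "chrom",
    "left_idx", "right_idx", "left_bp", "right_bp", "midpoint_bp",
]


def locate_crossovers(paths: DecodedPaths) -> pd.DataFrame:
    """One record per origin switch, flanked by the nearest informative markers."""
    rows = []
    pos = paths.markers.pos_bp
    chrom = paths.markers.chrom
    for j in range(paths.state.shape[0]):
        g = np.flatnonzero(paths.informative[j])
        if g.size < 2:
            continue
        o = paths.state[j, g]
        same = chrom[g[:-1]] == chrom[g[1:]]
        sw = (o[:-1] != o[1:]) & same
        for a, b in zip(g[:-1][sw], g[1:][sw]):
            left, right = int(pos[a]), int(pos[b])
            rows.append(
                (
                    paths.progeny_ids[j],
                    paths.parent_ids[j],
                    paths.sex,
                    int(chrom[a]),
                    int(a),
                    int(b),
                    left,
                    right,
                    (left + right) // 2,
                )
            )
    return pd.DataFrame(rows, columns=CROSSOVER_COLUMNS)


def first_origins(paths: DecodedPaths) -> np.ndarray:
    """Decoded origin at the first informative marker per meiosis x chromosome.

    Returns (M, n_chrom) int8 with -1 where a meiosis has no informative
    marker on a chromosome; chromosome order follows the marker map.
    """
    chroms = paths.markers.chromosomes()
    slices = paths.markers.chrom_slices()
    M = paths.state.shape[0]
    out = np.full((M, chroms.size), -1, dtype=np.int8)
    for ci, c in enumerate(chroms):
        s = slices[int(c)]
        info = paths.informative[:, s]
        has = info.any(axis=1)
        first = np.argmax(info, axis=1)
        out[has, ci] = paths.state[has, s.start + first[has]]
    return out


def crossover_counts(records: pd.DataFrame, progeny_ids: np.ndarray) -> pd.Series:
    """Genome-wide crossover count per meiosis (0 for progeny without records)."""
    counts = records.groupby("progeny").size() if len(records) else pd.Series(dtype=int)
    return counts.reindex(progeny_ids, fill_value=0).astype(int)


def near_double_crossover_stats(
    records: pd.DataFrame, threshold_bp: int = 2_000_000
) -> pd.Series:
    """Proportion of crossovers in a near-double pair, per chromosome.

    Two crossovers of the same meiosis on the same chromosome whose
    midpoints lie closer than ``threshold_bp`` are both counted as near
    doubles; the proportion is relative to all crossovers on that
    chromosome.
    """
    if len(records) == 0:
        return pd.Series(dtype=float)
    df = records.reset_index(drop=True).sort_values(
        ["progeny", "parent_sex", "chrom", "midpoint_bp"], kind="stable"
    )
    mid = df["midpoint_bp"].to_numpy()
    same = (
        (df["progeny"].to_numpy()[1:] == df["progeny"].to_numpy()[:-1])
        & (df["parent_sex"].to_numpy()[1:] == df["parent_sex"].to_numpy()[:-1])
        & (df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1])
    )
    close = same & (np.abs(mid[1:] - mid[:-1]) < threshold_bp)
    flag = np.zeros(len(df), dtype=bool)
    flag[:-1] |= close
    flag[1:] |= close
    return df.assign(near=flag).groupby("chrom")["near"].mean()
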