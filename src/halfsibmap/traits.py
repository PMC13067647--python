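"""Parental recombination phenotypes: crossover count and allelic shuffling.

Two traits summarise a parent's recombination activity across its scored
meioses:

* ``nco`` — mean genome-wide crossover count over progeny, an absolute
  measure of recombination activity.
* ``shuffling`` — intra-chromosomal allelic shuffling

      r_i = (1/n_i) * sum_j sum_k 2 p_kj (1 - p_kj) L_k^2,

  where p_kj is the proportion of chromosome k (in physical length)
  transmitted to progeny j from the parent's first homolog, and L_k is
  the relative chromosome length (marker span over total autosomal
  span).  2p(1-p) is the chance that two uniformly drawn loci of the
  chromosome carry different grand-parental origins, so r_i is a relative
  measure of how thoroughly one meiosis shuffles linked alleles; it is
  invariant to the arbitrary homolog labelling.

Chromosome ends are taken at the first/last marker and segment
breakpoints at crossover midpoints, consistent with midpoint placement
of crossover events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .maps import PhysicalMap


def transmitted_proportion(
    midpoints_bp: np.ndarray, first_origin: int, span: tuple[int, int]
) -> float:
    """Fraction of a chromosome's physical length inherited from homolog 1.

    ``midpoints_bp`` are the crossover midpoints of one meiosis on the
    chromosome (any order); origin alternates between segments starting
    from ``first_origin`` at the left end; ``span`` is (first_bp,
    last_bp) of the chromosome's markers.
    """
    left, right = span
    if right <= left:
        raise ValueError("chromosome span must have positive length")
    if first_origin not in (0, 1):
        raise ValueError("first_origin must be 0 or 1")
    mids = np.sort(np.asarray(midpoints_bp, dtype=float))
    mids = mids[(mids > left) & (mids < right)]
    edges = np.concatenate([[left], mids, [right]])
    seg = np.diff(edges)
    origins = (first_origin + np.arange(seg.size)) % 2
    return float(seg[origins == 0].sum() / (right - left))


def shuffling_from_proportions(p: np.ndarray, L: np.ndarray) -> float:
    """r_i = (1/n_i) sum_j sum_k 2 p (1-p) L_k^2 over progeny j and chromosomes k.

    ``p`` is (n_progeny, n_chrom) with NaN where a progeny lacks a decoded
    path on a chromosome; such progeny are skipped entirely (n_i adjusted).
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    L = np.asarray(L, dtype=float)
    ok = ~np.isnan(p).any(axis=1)
    if not ok.any():
        raise ValueError("no progeny with complete chromosome coverage")
    contrib = 2.0 * p[ok] * (1.0 - p[ok]) * L[None, :] ** 2
    return float(contrib.sum(axis=1).mean())


def proportions_from_records(
    records: pd.DataFrame,
    first_origin: np.ndarray,
    progeny_ids: np.ndarray,
    markers: PhysicalMap,
) -> np.ndarray:
    """Per-progeny, per-chromosome transmitted proportions from crossover records.

    ``first_origin`` is (n_progeny, n_chrom) as produced during decoding
    (or from simulation truth); NaN is returned where it is -1.
    """
    chroms = markers.chromosomes()
    slices = markers.chrom_slices()
    spans = {
        int(c): (int(markers.pos_bp[s.start]), int(markers.pos_bp[s.stop - 1]))
        for c, s in slices.items()
    }
    row = {pid: i for i, pid in enumerate(progeny_ids)}
    col = {int(c): k for k, c in enumerate(chroms)}
    mids: dict[tuple[int, int], list[float]] = {}
    for pid, c, m in zip(records["progeny"], records["chrom"], records["midpoint_bp"]):
        if pid in row:
            mids.setdefault((row[pid], col[int(c)]), []).append(float(m))
    P = np.full((progeny_ids.size, chroms.size), np.nan)
    for j in range(progeny_ids.size):
        for k, c in enumerate(chroms):
            fo = int(first_origin[j, k])
            if fo < 0:
                continue
            P[j, k] = transmitted_proportion(
                np.asarray(mids.get((j, k), []), dtype=float), fo, spans[int(c)]
            )
    return P


def parent_trait_table(
    records: pd.DataFrame,
    first_origin: np.ndarray,
    progeny_ids: np.ndarray,
    parent_ids: np.ndarray,
    markers: PhysicalMap,
    sex: str = "male",
    zscore: bool = True,
) -> pd.DataFrame:
    """Per-parent table of crossover count and shuffling.

    ``records``/``first_origin``/``progeny_ids``/``parent_ids`` come from
    one decoded inference run (or from simulation truth).  The shuffling
    column is additionally centred and scaled over the table when
    ``zscore`` is set, as is usual before mixed-model analysis.
    """
    L_by_chrom = markers.relative_lengths()
    L = np.array([L_by_chrom[int(c)] for c in markers.chromosomes()])
    P = proportions_from_records(records, first_origin, progeny_ids, markers)
    counts = (
        records.groupby("progeny").size().reindex(progeny_ids, fill_value=0).to_numpy()
    )
    rows = []
    for parent in pd.unique(parent_ids):
        sel = parent_ids == parent
        ok = sel & ~np.isnan(P).any(axis=1)
        if not ok.any():
            continue
        nco = float(counts[sel].mean())
        shuf = shuffling_from_proportions(P[ok], L)
        rows.append((parent, sex, int(ok.sum()), nco, shuf))
    out = pd.DataFrame(rows, columns=["parent", "sex", "n_progeny", "nco", "shuffling"])
    if zscore and len(out) > 1 and out["shuffling"].std(ddof=1) > 0:
        out["shuffling_z"] = (
            out["shuffling"] - out["shuffling"].mean()
        ) / out["shuffling"].std(ddof=1)
    else:
        out["shuffling_z"] = 0.0
    return out


def crossover_count(progeny_totals: np.ndarray) -> float:
    """Mean genome-wide crossover count over a parent's scored progeny."""
    totals = np.asarray(progeny_totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no decoded progeny")
    return float(totals.mean())


def traits_from_truth(dataset, parent_sex: str = "male", zscore: bool = True) -> pd.DataFrame:
    """Parent trait table computed from simulation truth (no inference).

    Useful as an oracle and for generating phenotypes for the
    quantitative-genetics layer without running the estimators.
    """
    sub = dataset.crossovers[dataset.crossovers["parent_sex"] == parent_sex].copy()
    sub["midpoint_bp"] = (sub["left_bp"] + sub["right_bp"]) // 2
    prog = dataset.ids[dataset.progeny_index]
    ped = dataset.pedigree.set_index("id")
    parent_col = "sire" if parent_sex == "male" else "dam"
    parents = ped.loc[prog, parent_col].to_numpy(dtype=object)
    fo = (
        dataset.paternal_start_origin
        if parent_sex == "male"
        else dataset.maternal_start_origin
    )
    return parent_trait_table(
        sub, fo, prog, parents, dataset.markers, sex=parent_sex, zscore=zscore
    )
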