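"""Physical and genetic marker maps, map quality scores and map comparison.

A :class:`PhysicalMap` orders biallelic SNP markers by (chromosome, bp).
A :class:`GeneticMap` attaches cumulative genetic coordinates in Morgan
units to those markers; coordinates restart at 0 on every chromosome and
are obtained by accumulating per-interval recombination rates between
adjacent markers.  No mapping function (Haldane/Kosambi) is applied
anywhere: adjacent-interval rates are summed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class PhysicalMap:
    """Marker order and physical (bp) coordinates on one or more autosomes.

    Positions are 1-based bp and must be strictly increasing within a
    chromosome.  Intervals between adjacent markers are indexed by their
    left marker: interval ``j`` joins markers ``j`` and ``j + 1`` and only
    exists when both lie on the same chromosome (see :attr:`intra`).
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.marker_id.shape != self.chrom.shape or self.chrom.shape != self.pos_bp.shape:
            raise ValueError("marker_id, chrom and pos_bp must have equal length")
        if np.any(self.pos_bp < 0):
            raise ValueError("physical positions must be non-negative")
        if len(np.unique(self.marker_id)) != self.n_markers:
            raise ValueError("duplicated marker ids")
        d = np.diff(self.pos_bp)
        same = self.chrom[:-1] == self.chrom[1:]
        if np.any(d[same] <= 0):
            raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_markers(self) -> int:
        return self.marker_id.size

    @property
    def intra(self) -> np.ndarray:
        """Boolean mask over the q-1 adjacent pairs: True within a chromosome."""
        return self.chrom[:-1] == self.chrom[1:]

    @property
    def interval_bp(self) -> np.ndarray:
        """bp length of each adjacent interval (0 across chromosome joins)."""
        d = np.diff(self.pos_bp)
        d[~self.intra] = 0
        return d

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous marker index range per chromosome."""
        out: dict[int, slice] = {}
        for c in self.chromosomes():
            idx = np.flatnonzero(self.chrom == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def chrom_span_bp(self) -> dict[int, int]:
        """Physical span (first to last marker) per chromosome."""
        return {c: int(self.pos_bp[s.stop - 1] - self.pos_bp[s.start])
                for c, s in self.chrom_slices().items()}

    def relative_lengths(self) -> dict[int, float]:
        """Relative chromosome length L_k = span_k / total autosomal span."""
        spans = self.chrom_span_bp()
        total = sum(spans.values())
        if total <= 0:
            raise ValueError("zero total physical span")
        return {c: s / total for c, s in spans.items()}

    def subset(self, keep: np.ndarray) -> "PhysicalMap":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return PhysicalMap(self.marker_id[keep], self.chrom[keep], self.pos_bp[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_id, "chrom": self.chrom, "bp": self.pos_bp}
        )


@dataclass
class GeneticMap:
    """Cumulative genetic coordinates (Morgan) for the markers of a PhysicalMap.

    ``coord[i]`` is the map position of marker i; the first marker of every
    chromosome sits at 0.  ``sex`` and ``population`` are free-form labels
    used when comparing maps across sexes or breeds.
    """

    markers: PhysicalMap
    coord: np.ndarray
    sex: str = "male"
    population: str = ""
    n_undefined_intervals: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.shape[0] != self.markers.n_markers:
            raise ValueError("coord length must equal marker count")
        r = self.rates()
        if np.any(r[self.markers.intra] < -1e-12):
            raise ValueError("genetic coordinates must be nondecreasing within chromosome")

    @classmethod
    def from_rates(
        cls,
        markers: PhysicalMap,
        rates: np.ndarray,
        sex: str = "male",
        population: str = "",
        n_undefined: int = 0,
    ) -> "GeneticMap":
        """Accumulate per-interval recombination rates into map coordinates."""
        rates = np.asarray(rates, dtype=np.float64)
        if rates.shape[0] != markers.n_markers - 1:
            raise ValueError("need one rate per adjacent marker pair")
        if np.any(rates[markers.intra] < 0):
            raise ValueError("negative recombination rate")
        coord = np.zeros(markers.n_markers)
        for _, s in markers.chrom_slices().items():
            r = rates[s.start : s.stop - 1]
            coord[s.start + 1 : s.stop] = np.cumsum(r)
        return cls(markers, coord, sex=sex, population=population,
                   n_undefined_intervals=n_undefined)

    def rates(self) -> np.ndarray:
        """Per-interval rates recovered as coordinate differences (0 across chromosomes)."""
        r = np.diff(self.coord)
        r[~self.markers.intra] = 0.0
        return r

    def chrom_lengths(self) -> dict[int, float]:
        return {c: float(self.coord[s.stop - 1]) for c, s in self.markers.chrom_slices().items()}

    def total_length(self) -> float:
        """Genome-wide map length in Morgan (sum over chromosomes)."""
        return float(sum(self.chrom_lengths().values()))

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """Restrict to a marker subset, re-accumulating coordinates.

        The rate attributed to a retained interval is the summed rate of the
        original intervals it spans, so total map length is preserved when
        only interior markers are dropped.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sub = self.markers.subset(keep)
        coord = np.zeros(keep.size)
        for c, s in sub.chrom_slices().items():
            idx = keep[s.start : s.stop]
            coord[s.start : s.stop] = self.coord[idx] - self.coord[idx[0]]
        return GeneticMap(sub, coord, sex=self.sex, population=self.population)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.to_frame()
        df[f"cM_{self.sex}"] = self.coord * 100.0
        return df


def accumulate_map(markers: PhysicalMap, rates: np.ndarray, sex: str = "male",
                   population: str = "") -> GeneticMap:
    """Map coordinates as accumulation of recombination rate between adjacent SNPs.

    Undefined (NaN) rates are imputed as 0, biasing the map length down
    rather than leaving it undefined; the count is recorded on the map.
    """
    rates = np.asarray(rates, dtype=np.float64).copy()
    undefined = np.isnan(rates) & markers.intra
    rates[np.isnan(rates)] = 0.0
    return GeneticMap.from_rates(markers, rates, sex=sex, population=population,
                                 n_undefined=int(undefined.sum()))


def map_accuracy(est: GeneticMap, true: GeneticMap) -> float:
    """acc = estimated / true total map length."""
    _check_same_markers(est, true)
    d_q = true.total_length()
    if d_q <= 0:
        raise ValueError("true map has zero length")
    return est.total_length() / d_q


def map_mse(est: GeneticMap, true: GeneticMap) -> float:
    """Mean squared error of estimated map positions over all q markers (Morgan^2)."""
    _check_same_markers(est, true)
    return float(np.mean((est.coord - true.coord) ** 2))


def _check_same_markers(a: GeneticMap, b: GeneticMap) -> None:
    if a.markers.n_markers != b.markers.n_markers or np.any(
        a.markers.marker_id != b.markers.marker_id
    ):
        raise ValueError("maps must be defined on the same marker set")


def cm_per_mbp(gmap: GeneticMap) -> dict[int, float]:
    """Per-chromosome ratio of genetic length (cM) to physical length (Mbp)."""
    out = {}
    for c, span in gmap.markers.chrom_span_bp().items():
        if span <= 0:
            raise ValueError(f"chromosome {c} has zero physical span")
        out[c] = 100.0 * gmap.chrom_lengths()[c] / (span / 1e6)
    return out


def shared_marker_matrix(maps: list[GeneticMap], what: str = "coord"):
    """Stack maps on their shared marker set.

    Returns (labels, matrix) where row p holds map p's coordinates
    (``what='coord'``) or adjacent-interval rates (``what='rates'``) at the
    markers present in every map, ordered by (chrom, bp).
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    shared = set(maps[0].markers.marker_id)
    for m in maps[1:]:
        shared &= set(m.markers.marker_id)
    if not shared:
        raise ValueError("maps share no markers")
    rows, labels = [], []
    for m in maps:
        keep = np.isin(m.markers.marker_id, list(shared))
        sub = m.subset(keep)
        rows.append(sub.coord if what == "coord" else sub.rates()[sub.markers.intra])
        labels.append(f"{m.population}_{m.sex}".strip("_"))
    return labels, np.vstack(rows)


def map_pca(maps: list[GeneticMap], n_components: int = 2):
    """Principal components of the recombination matrix.

    One row of adjacent-interval recombination rates per (sex, population)
    map, restricted to shared markers; columns are centered but not scaled
    (all entries share Morgan units).  Returns (labels, scores,
    explained_variance_ratio).
    """
    from sklearn.decomposition import PCA

    labels, mat = shared_marker_matrix(maps, what="rates")
    n_components = min(n_components, len(maps), mat.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(mat)
    return labels, scores, pca.explained_variance_ratio_


def map_hclust(maps: list[GeneticMap], method: str = "average"):
    """Hierarchical clustering of maps on the L2 norm of coordinate differences.

    Average linkage by default; deterministic leaf order.  Returns
    (labels, linkage_matrix, leaf_order).
    """
    labels, mat = shared_marker_matrix(maps, what="coord")
    dist = pdist(mat, metric="euclidean")
    link = hierarchy.linkage(dist, method=method, optimal_ordering=False)
    leaves = hierarchy.leaves_list(link)
    return labels, link, [labels[i] for i in leaves]
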