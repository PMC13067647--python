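"""Synthetic half-sib populations with known haplotypes and crossovers.

Stands in for restricted real livestock data: paternal half-sib families
produced by mating N sires to a pool of dams, SNP genotypes on one or more
autosomes, sex-specific per-interval recombination rates, and random or
block-systematic missingness.  Every meiosis records its true crossover
intervals, so downstream estimators can be scored against truth.

Model choices
-------------
* Founders are in linkage equilibrium: per-marker allele frequencies are
  drawn once from a configurable MAF law (default Uniform(0.05, 0.5)) and
  founder alleles are i.i.d. across haplotypes.
* Meiosis is Bernoulli per interval: a crossover occurs independently in
  interval j with probability r_j (no interference); the gamete starts on a
  fair-coin homolog per chromosome.  An optional chi-square (m=2)
  interference mode thins a doubled-intensity Poisson process on the
  genetic scale; it is off by default.
* Map lengths are in Morgan and per-interval rates are used directly as
  switch probabilities (capped at 0.5); no Haldane/Kosambi transform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import GeneticMap, PhysicalMap

MISSING = np.int8(-1)
"""Sentinel for a missing genotype call (distinct from the 0/1/2 codes)."""

_GAMETE_CHUNK = 4096


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation design.

    n_families
        N, the number of paternal half-sib families.
    n_progeny
        n, progeny per family (exact, not expected).
    n_markers
        q, number of SNPs.
    missing_fraction
        Proportion of genotype calls (parents and progeny) masked at random.
    """

    n_families: int
    n_progeny: int
    n_markers: int
    missing_fraction: float = 0.0
    seed: int = 0
    interference: bool = False

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_progeny < 1:
            raise ValueError("need at least one family and one progeny")
        if self.n_markers < 2:
            raise ValueError("need at least two markers")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")


@dataclass
class Founders:
    """Phased founder haplotypes (count x 2 x q) and the MAF they were drawn from."""

    haplotypes: np.ndarray
    freqs: np.ndarray

    @property
    def count(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class SimulatedDataset:
    """A half-sib population with full truth bookkeeping.

    ``genotypes`` holds the true (unmasked) 0/1/2 codes for all rows in
    ``ids`` (sires, then dams, then progeny, matching ``pedigree``).
    ``missing_mask`` flags masked entries; evaluation code must read truth
    from the dedicated truth fields, never from the masked matrix.
    """

    markers: PhysicalMap
    male_map: GeneticMap
    female_map: GeneticMap
    ids: np.ndarray
    pedigree: pd.DataFrame
    genotypes: np.ndarray
    missing_mask: np.ndarray | None
    parent_haplotypes: dict[str, np.ndarray]
    paternal_gametes: np.ndarray
    maternal_gametes: np.ndarray
    paternal_start_origin: np.ndarray
    maternal_start_origin: np.ndarray
    crossovers: pd.DataFrame

    def observed_genotypes(self) -> np.ndarray:
        """Genotypes as an analyst would see them: masked entries set to MISSING."""
        g = self.genotypes.copy()
        if self.missing_mask is not None:
            g[self.missing_mask] = MISSING
        return g

    @property
    def progeny_index(self) -> np.ndarray:
        return np.flatnonzero(self.pedigree["sire"].to_numpy() != "0")

    def true_crossover_counts(self, parent_sex: str = "male") -> pd.Series:
        """Genome-wide true crossover count per progeny for one parental sex."""
        sub = self.crossovers[self.crossovers["parent_sex"] == parent_sex]
        prog = self.ids[self.progeny_index]
        counts = sub.groupby("progeny").size()
        return counts.reindex(prog, fill_value=0)


def make_physical_map(
    q: int,
    length_morgan: float | None = None,
    length_bp: int = 100_000_000,
    chrom: int = 1,
    positions_bp: np.ndarray | None = None,
    cm_per_mbp: float | None = None,
    prefix: str = "snp",
) -> tuple[PhysicalMap, GeneticMap]:
    """Build a single-chromosome physical map and its true genetic map.

    Synthetic mode (default): q markers evenly spaced over ``length_bp``,
    each of the q-1 intervals carrying rate ``length_morgan / (q - 1)``.
    Semi-real mode: supply ``positions_bp`` and ``cm_per_mbp`` (e.g. 1.0 for
    a 1:1 transform of physical into genetic distance); interval rates are
    then proportional to physical gaps.  Rates are capped at 0.5.
    """
    if q < 2:
        raise ValueError("need at least two markers")
    if positions_bp is not None:
        pos = np.asarray(positions_bp, dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        q = pos.size
        if cm_per_mbp is None:
            raise ValueError("semi-real mode requires cm_per_mbp")
        rates = np.diff(pos) * (cm_per_mbp * 1e-8)  # cM/Mbp -> Morgan/bp
    else:
        if length_morgan is None or length_morgan < 0:
            raise ValueError("length_morgan must be non-negative")
        if length_bp < q:
            raise ValueError("length_bp too small for q markers")
        pos = np.unique(np.round(np.linspace(1, length_bp, q)).astype(np.int64))
        if pos.size != q:  # guard against rounding collisions
            pos = np.arange(1, q + 1, dtype=np.int64) * (length_bp // q)
        rates = np.full(q - 1, length_morgan / (q - 1))
    rates = np.minimum(rates, 0.5)
    ids = np.array([f"{prefix}{chrom}_{i + 1}" for i in range(q)], dtype=object)
    pmap = PhysicalMap(ids, np.full(q, chrom), pos)
    gmap = GeneticMap.from_rates(pmap, rates, sex="true")
    return pmap, gmap


def concat_maps(parts: list[tuple[PhysicalMap, GeneticMap]]) -> tuple[PhysicalMap, GeneticMap]:
    """Concatenate per-chromosome maps into one genome-wide map."""
    pmap = PhysicalMap(
        np.concatenate([p.marker_id for p, _ in parts]),
        np.concatenate([p.chrom for p, _ in parts]),
        np.concatenate([p.pos_bp for p, _ in parts]),
    )
    rates = np.zeros(pmap.n_markers - 1)
    off = 0
    for p, g in parts:
        rates[off : off + p.n_markers - 1] = g.rates()
        off += p.n_markers
    return pmap, GeneticMap.from_rates(pmap, rates, sex="true")


def _draw_freqs(maf_law, q: int, rng: np.random.Generator) -> np.ndarray:
    if callable(maf_law):
        f = np.asarray(maf_law(rng, q), dtype=float)
    elif isinstance(maf_law, (int, float)):
        f = np.full(q, float(maf_law))
    else:
        kind, lo, hi = maf_law
        if kind != "uniform":
            raise ValueError(f"unknown maf law {kind!r}")
        f = rng.uniform(lo, hi, size=q)
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("MAF law must yield frequencies in (0, 0.5]")
    return f


def simulate_founders(
    count: int,
    q: int,
    maf_law=("uniform", 0.05, 0.5),
    rng: np.random.Generator | int | None = None,
) -> Founders:
    """Linkage-equilibrium founders: two haplotypes each, alleles i.i.d. Bernoulli(f)."""
    rng = np.random.default_rng(rng)
    freqs = _draw_freqs(maf_law, q, rng)
    haps = (rng.random((count, 2, q)) < freqs).astype(np.int8)
    return Founders(haps, freqs)


def _chrom_blocks(chrom: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) marker index per chromosome, assuming sorted chrom codes."""
    bounds = np.flatnonzero(np.diff(chrom) != 0) + 1
    edges = np.concatenate([[0], bounds, [chrom.size]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _interference_switches(rates: np.ndarray, blocks, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Chi-square (m=2) crossover placement on the genetic scale.

    Events of a Poisson process with doubled intensity are laid on the
    cumulative map; every second event (random phase) is kept as a
    crossover, giving gamma(2)-distributed inter-crossover distances with
    the same expected count as the Bernoulli model.
    """
    switches = np.zeros((n, rates.size), dtype=bool)
    for a, b in blocks:
        r = rates[a : b - 1]
        edges = np.concatenate([[0.0], np.cumsum(r)])
        L = edges[-1]
        if L <= 0:
            continue
        for i in range(n):
            n_ev = rng.poisson(2.0 * L)
            if n_ev == 0:
                continue
            ev = np.sort(rng.uniform(0.0, L, size=n_ev))
            keep = ev[rng.integers(0, 2)::2]
            idx = np.searchsorted(edges, keep, side="right") - 1
            idx = idx[idx < r.size]
            # an odd number of events in one interval is one observable switch
            for j in np.unique(idx):
                if np.count_nonzero(idx == j) % 2 == 1:
                    switches[i, a + j] = True
    return switches


def _simulate_gamete_batch(
    haps: np.ndarray,
    rates: np.ndarray,
    chrom: np.ndarray,
    rng: np.random.Generator,
    interference: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised meiosis for a batch of parents.

    haps: (n, 2, q) parental haplotypes, one meiosis per row.
    Returns (gametes (n, q) int8, switches (n, q-1) bool, start origins
    (n, n_chrom) int8); switches across chromosome joins never occur
    (each chromosome restarts on a random homolog).
    """
    n, _, q = haps.shape
    blocks = _chrom_blocks(chrom)
    if interference:
        switches = _interference_switches(rates, blocks, n, rng)
    else:
        switches = rng.random((n, q - 1)) < rates
    origin = np.empty((n, q), dtype=np.int8)
    starts = np.empty((n, len(blocks)), dtype=np.int8)
    for bi, (a, b) in enumerate(blocks):
        start = rng.integers(0, 2, size=n, dtype=np.int8)
        starts[:, bi] = start
        origin[:, a] = start
        if b - a > 1:
            flips = np.cumsum(switches[:, a : b - 1], axis=1, dtype=np.int32) & 1
            origin[:, a + 1 : b] = (start[:, None] + flips).astype(np.int8) & 1
        if b - 1 < q - 1:  # no switch recorded across the chromosome join
            switches[:, b - 1] = False
    gametes = np.take_along_axis(haps, origin[:, None, :].astype(np.intp), axis=1)[:, 0, :]
    return gametes, switches, starts


def simulate_meiosis(
    parent_haplotypes: np.ndarray,
    rates: np.ndarray,
    rng: np.random.Generator | int | None = None,
    chrom: np.ndarray | None = None,
    interference: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one gamete from a phased parent.

    Returns (gamete (q,), crossover interval indices).  The gamete starts
    on a fair-coin homolog; a switch occurs independently in interval j
    with probability ``rates[j]`` and is recorded as a crossover there.
    """
    haps = np.asarray(parent_haplotypes, dtype=np.int8)
    rates = np.asarray(rates, dtype=float)
    if haps.ndim != 2 or haps.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, q)")
    q = haps.shape[1]
    if rates.shape != (q - 1,):
        raise ValueError("need q - 1 interval rates")
    if np.any((rates < 0) | (rates > 0.5)):
        raise ValueError("rates must lie in [0, 0.5]")
    if chrom is None:
        chrom = np.ones(q, dtype=np.int32)
    rng = np.random.default_rng(rng)
    gam, sw, _ = _simulate_gamete_batch(haps[None], rates, chrom, rng, interference)
    return gam[0], np.flatnonzero(sw[0])


def build_half_sib_population(
    scenario: SimScenario,
    markers: PhysicalMap | None = None,
    male_map: GeneticMap | None = None,
    female_map: GeneticMap | None = None,
    founders: Founders | None = None,
    founder_count: int = 1000,
    maf_law=("uniform", 0.05, 0.5),
    length_morgan: float = 1.0,
    length_bp: int = 100_000_000,
) -> SimulatedDataset:
    """Simulate N paternal half-sib families of exactly n progeny each.

    Sires are drawn without replacement from the founders; dams are drawn
    with replacement from a pool of ``min(ceil(20 N n / 30), founders - N)``
    founders, emulating the few-progeny-per-dam structure of AI cattle
    breeding.  All truth (parent haplotypes, per-meiosis gametes and
    crossover intervals) is recorded before any masking.
    """
    rng = np.random.default_rng(scenario.seed)
    N, n, q = scenario.n_families, scenario.n_progeny, scenario.n_markers
    if markers is None or male_map is None:
        markers, male_map = make_physical_map(q, length_morgan, length_bp)
    if markers.n_markers != q:
        raise ValueError("marker map size does not match scenario q")
    if female_map is None:
        female_map = dataclasses.replace(male_map, sex="female")
    if founders is None:
        founders = simulate_founders(founder_count, q, maf_law, rng)
    if founders.count < N + 1:
        raise ValueError(f"{founders.count} founders cannot supply {N} sires and a dam pool")

    pool_target = int(np.ceil(20 * N * n / 30))
    perm = rng.permutation(founders.count)
    sire_idx = perm[:N]
    dam_pool = perm[N : N + max(1, min(pool_target, founders.count - N))]

    male_rates = np.minimum(male_map.rates(), 0.5)
    female_rates = np.minimum(female_map.rates(), 0.5)
    chrom = markers.chrom

    n_prog = N * n
    dam_choice = dam_pool[rng.integers(0, dam_pool.size, size=n_prog)]

    n_chrom = len(_chrom_blocks(chrom))
    pat_gam = np.empty((n_prog, q), dtype=np.int8)
    mat_gam = np.empty((n_prog, q), dtype=np.int8)
    pat_start = np.empty((n_prog, n_chrom), dtype=np.int8)
    mat_start = np.empty((n_prog, n_chrom), dtype=np.int8)
    xo_rows: list[np.ndarray] = []

    for fam in range(N):
        lo, hi = fam * n, (fam + 1) * n
        sire_haps = np.broadcast_to(founders.haplotypes[sire_idx[fam]], (n, 2, q))
        for start in range(lo, hi, _GAMETE_CHUNK):
            stop = min(start + _GAMETE_CHUNK, hi)
            gam, sw, st = _simulate_gamete_batch(
                sire_haps[: stop - start], male_rates, chrom, rng, scenario.interference
            )
            pat_gam[start:stop] = gam
            pat_start[start:stop] = st
            r, c = np.nonzero(sw)
            xo_rows.append(np.column_stack([r + start, np.zeros_like(r), c]))
    for start in range(0, n_prog, _GAMETE_CHUNK):
        stop = min(start + _GAMETE_CHUNK, n_prog)
        dam_haps = founders.haplotypes[dam_choice[start:stop]]
        gam, sw, st = _simulate_gamete_batch(
            dam_haps, female_rates, chrom, rng, scenario.interference
        )
        mat_gam[start:stop] = gam
        mat_start[start:stop] = st
        r, c = np.nonzero(sw)
        xo_rows.append(np.column_stack([r + start, np.ones_like(r), c]))

    sire_ids = np.array([f"S{i + 1:04d}" for i in range(N)], dtype=object)
    used_dams, dam_inverse = np.unique(dam_choice, return_inverse=True)
    dam_ids = np.array([f"D{i + 1:05d}" for i in range(used_dams.size)], dtype=object)
    prog_ids = np.array(
        [f"P{fam + 1:03d}_{j + 1:04d}" for fam in range(N) for j in range(n)], dtype=object
    )
    ids = np.concatenate([sire_ids, dam_ids, prog_ids])

    geno = np.empty((ids.size, q), dtype=np.int8)
    geno[:N] = founders.haplotypes[sire_idx].sum(axis=1)
    geno[N : N + used_dams.size] = founders.haplotypes[used_dams].sum(axis=1)
    geno[N + used_dams.size :] = pat_gam + mat_gam

    prog_sires = np.repeat(sire_ids, n)
    prog_dams = dam_ids[dam_inverse]
    pedigree = pd.DataFrame(
        {
            "id": ids,
            "sire": np.concatenate([np.repeat("0", N + used_dams.size), prog_sires]),
            "dam": np.concatenate([np.repeat("0", N + used_dams.size), prog_dams]),
            "sex": np.concatenate(
                [
                    np.repeat("M", N),
                    np.repeat("F", used_dams.size),
                    rng.choice(["M", "F"], size=n_prog),
                ]
            ),
        }
    )

    nonempty = [r for r in xo_rows if r.size]
    if nonempty:
        xo = np.concatenate(nonempty, axis=0)
    else:
        xo = np.empty((0, 3), dtype=np.int64)
    order = np.lexsort((xo[:, 2], xo[:, 1], xo[:, 0]))
    xo = xo[order]
    prow, psex, interval = xo[:, 0].astype(int), xo[:, 1].astype(int), xo[:, 2].astype(int)
    crossovers = pd.DataFrame(
        {
            "progeny": prog_ids[prow],
            "parent": np.where(psex == 0, prog_sires[prow], prog_dams[prow]),
            "parent_sex": np.where(psex == 0, "male", "female"),
            "chrom": markers.chrom[interval],
            "interval": interval,
            "left_bp": markers.pos_bp[interval],
            "right_bp": markers.pos_bp[interval + 1],
        }
    )

    parent_haps = {sid: founders.haplotypes[sire_idx[i]] for i, sid in enumerate(sire_ids)}
    parent_haps.update(
        {did: founders.haplotypes[used_dams[i]] for i, did in enumerate(dam_ids)}
    )

    ds = SimulatedDataset(
        markers=markers,
        male_map=dataclasses.replace(male_map, sex="male"),
        female_map=dataclasses.replace(female_map, sex="female"),
        ids=ids,
        pedigree=pedigree,
        genotypes=geno,
        missing_mask=None,
        parent_haplotypes=parent_haps,
        paternal_gametes=pat_gam,
        maternal_gametes=mat_gam,
        paternal_start_origin=pat_start,
        maternal_start_origin=mat_start,
        crossovers=crossovers,
    )
    if scenario.missing_fraction > 0:
        ds = mask_genotypes(ds, scenario.missing_fraction, rng=rng)
    return ds


def mask_genotypes(
    dataset: SimulatedDataset,
    fraction: float = 0.0,
    block_pattern: list[tuple[int, int, float]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Mask genotype calls at random and/or in systematic blocks.

    ``fraction`` masks each (individual, marker) entry independently.
    ``block_pattern`` lists (first_marker, last_marker, sample_fraction)
    triples (inclusive marker indices): the given marker range is masked in
    that fraction of individuals, emulating chip-design missingness.
    Truth fields are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    mask = (
        dataset.missing_mask.copy()
        if dataset.missing_mask is not None
        else np.zeros_like(dataset.genotypes, dtype=bool)
    )
    if fraction > 0:
        mask |= rng.random(dataset.genotypes.shape) < fraction
    for first, last, samp_frac in block_pattern or []:
        hit = rng.random(dataset.genotypes.shape[0]) < samp_frac
        mask[hit, first : last + 1] = True
    return dataclasses.replace(dataset, missing_mask=mask)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write PLINK text, pedigree TSV and the truth bundle to a directory."""
    from . import qc_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "data.ped",
        "map": out / "data.map",
        "pedigree": out / "pedigree.tsv",
        "true_map": out / "true_map.tsv",
        "crossovers": out / "true_crossovers.tsv",
    }
    qc_io.write_plink_text(
        dataset.observed_genotypes(), dataset.ids, dataset.markers,
        paths["ped"], paths["map"], pedigree=dataset.pedigree,
    )
    dataset.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    tm = dataset.markers.to_frame()
    tm["cM_male"] = dataset.male_map.coord * 100
    tm["cM_female"] = dataset.female_map.coord * 100
    tm.to_csv(paths["true_map"], sep="\t", index=False)
    dataset.crossovers.to_csv(paths["crossovers"], sep="\t", index=False)
    return paths
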