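"""Deterministic multipoint estimator for half-sib recombination rates.

Works on progeny genotypes alone: sire heterozygosity is established from
opposing homozygote progeny, sire haplotypes are reconstructed by chaining
strand groups across a sliding window of heterozygous loci (30 by
default), and each progeny receives a grand-parental origin call wherever
its genotype discriminates the two sire strands.  Recombination rates
follow from origin switches between consecutive informative markers: a
switch spanning several marker intervals is attributed fractionally,
proportional to physical interval length, and every spanned interval
counts the meiosis as informative.

Families below the minimum progeny count (30 by default) are skipped:
with fewer progeny the sire haplotypes cannot be established reliably
from progeny alone.
"""

from __future__ import annotations

import numpy as np

from ..maps import PhysicalMap
from .base import (
    Family,
    RateEstimate,
    family_het_markers,
    origin_matrix,
    paternal_allele_matrix,
    phase_het_markers,
)


def phase_sire_deterministic(
    fam: Family, markers: PhysicalMap, window: int = 30, min_progeny: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phase one sire from progeny genotypes only.

    Returns (het_index, haplotype1, haplotype2, origins) where the
    haplotypes are alleles at the het markers (up to a global swap per
    chromosome) and ``origins`` is the per-progeny origin-call matrix at
    those markers (-1 where not discriminating).
    """
    if fam.n_progeny < min_progeny:
        raise ValueError(
            f"family {fam.parent_id} has {fam.n_progeny} progeny; "
            f"deterministic phasing requires >= {min_progeny}"
        )
    het = family_het_markers(fam, use_parent_geno=False)
    if not het.any():
        raise ValueError(f"family {fam.parent_id} has no detectable heterozygous loci")
    het_idx = np.flatnonzero(het)
    A = paternal_allele_matrix(fam, het, use_coparent=False)
    s, phased = phase_het_markers(A, markers.chrom[het_idx], window=window)
    O = origin_matrix(A, s, phased)
    return het_idx, s, (1 - s).astype(np.int8), O


def _accumulate_switches(
    O: np.ndarray,
    het_idx: np.ndarray,
    markers: PhysicalMap,
    cov_diff: np.ndarray,
    dens_diff: np.ndarray,
) -> None:
    """Add one family's origin switches into global diff-array accumulators."""
    chrom = markers.chrom
    pos = markers.pos_bp
    for j in range(O.shape[0]):
        known = O[j] != -1
        g = het_idx[known]
        if g.size < 2:
            continue
        o = O[j][known]
        same = chrom[g[:-1]] == chrom[g[1:]]
        a = g[:-1][same]
        b = g[1:][same]
        sw = (o[:-1] != o[1:])[same]
        np.add.at(cov_diff, a, 1.0)
        np.add.at(cov_diff, b, -1.0)
        if sw.any():
            gap = (pos[b[sw]] - pos[a[sw]]).astype(float)
            np.add.at(dens_diff, a[sw], 1.0 / gap)
            np.add.at(dens_diff, b[sw], -1.0 / gap)


def estimate_rates_deterministic(
    families: list[Family],
    markers: PhysicalMap,
    window: int = 30,
    min_progeny: int = 30,
) -> RateEstimate:
    """Pool deterministic origin switches over families into interval rates."""
    q = markers.n_markers
    cov_diff = np.zeros(q)
    dens_diff = np.zeros(q)
    sexes = {f.parent_sex for f in families}
    used = 0
    for fam in families:
        if fam.n_progeny < min_progeny:
            continue
        try:
            het_idx, _, _, O = phase_sire_deterministic(
                fam, markers, window=window, min_progeny=min_progeny
            )
        except ValueError:
            continue
        _accumulate_switches(O, het_idx, markers, cov_diff, dens_diff)
        used += 1
    if used == 0:
        raise ValueError("no family met the deterministic estimator's requirements")
    cov = np.cumsum(cov_diff)[: q - 1]
    dens = np.cumsum(dens_diff)[: q - 1]
    switches = dens * markers.interval_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(cov > 0, switches / np.maximum(cov, 1e-300), np.nan)
    rates = np.clip(rates, 0.0, 0.5)
    rates[~markers.intra] = np.nan
    cov[~markers.intra] = 0.0
    return RateEstimate(
        markers=markers,
        rates=rates,
        n_informative=cov,
        sex=sexes.pop() if len(sexes) == 1 else "mixed",
        method="deterministic",
    )
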