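"""Pairwise likelihood estimator for half-sib recombination rates.

Works on two markers at a time, using only linkage and linkage
disequilibrium within the family: no multipoint chaining.  For a marker
pair at which the sire is heterozygous, progeny whose transmitted paternal
alleles are identifiable at both markers classify as parental or
recombinant; the sire's two-locus phase is itself inferred from the same
counts (the more frequent diagonal is parental, valid while theta < 0.5),
so the maximum-likelihood estimate reduces to the recombinant fraction
k/n.  The general mixture likelihood, which also uses double-heterozygous
progeny through the maternal allele frequencies, is available as
:func:`two_locus_mle` for arbitrary (also non-adjacent) pairs, e.g. when
screening for misplaced markers.

Adjacent-interval rates for a genetic map are the pairwise estimates of
adjacent marker pairs, pooled over families.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from ..maps import PhysicalMap
from ..popsim import MISSING
from .base import Family, RateEstimate, family_het_markers, paternal_allele_matrix


def _pair_counts(A: np.ndarray, t1: int, t2: int) -> tuple[int, int]:
    """(diagonal, off-diagonal) paternal two-locus counts for columns t1, t2."""
    a, b = A[:, t1], A[:, t2]
    valid = (a != -1) & (b != -1)
    diag = int(np.count_nonzero(valid & (a == b)))
    off = int(np.count_nonzero(valid)) - diag
    return diag, off


def family_recombinant_fraction(fam: Family, i: int, j: int) -> tuple[int, int]:
    """Directly classifiable (recombinant, total) gamete counts for markers i, j.

    The sire must be heterozygous (opposing homozygotes) at both markers;
    phase is taken as the majority pairing.  Returns (k, n); (0, 0) when
    the pair is uninformative in this family.
    """
    het = family_het_markers(fam, use_parent_geno=False)
    if not (het[i] and het[j]):
        return 0, 0
    sub = fam.progeny[:, [i, j]]
    A = np.full(sub.shape, -1, dtype=np.int8)
    A[sub == 0] = 0
    A[sub == 2] = 1
    diag, off = _pair_counts(A, 0, 1)
    return min(diag, off), diag + off


def two_locus_mle(
    fam: Family,
    i: int,
    j: int,
    maternal_freqs: tuple[float, float] | np.ndarray,
) -> float:
    """Two-locus mixture MLE of the recombination fraction for one family.

    Maximises over theta in [0, 0.5] the likelihood of the progeny
    two-locus genotype counts given a heterozygous sire (phase profiled
    out by taking the better of the two pairings) and maternal alleles
    drawn independently with the supplied frequencies (linkage
    equilibrium).  Returns NaN when the sire is not identifiably
    heterozygous at both markers.
    """
    het = family_het_markers(fam, use_parent_geno=False)
    if not (het[i] and het[j]):
        return float("nan")
    fi, fj = float(maternal_freqs[0]), float(maternal_freqs[1])
    gi = fam.progeny[:, i]
    gj = fam.progeny[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi[ok], gj[ok]), 1.0)

    def hap_probs(theta: float, phase: int) -> list[tuple[int, int, float]]:
        # phase 0: haplotypes (0,0)/(1,1) parental; phase 1: (0,1)/(1,0)
        par = [((0, 0), (1, 1)), ((0, 1), (1, 0))][phase]
        rec = [((0, 1), (1, 0)), ((0, 0), (1, 1))][phase]
        out = []
        for h in par:
            out.append((h[0], h[1], (1 - theta) / 2))
        for h in rec:
            out.append((h[0], h[1], theta / 2))
        return out

    def loglik(theta: float, phase: int) -> float:
        pm_i = np.array([1 - fi, fi])
        pm_j = np.array([1 - fj, fj])
        P = np.zeros((3, 3))
        for ai, aj, w in hap_probs(theta, phase):
            for mi in (0, 1):
                for mj in (0, 1):
                    P[ai + mi, aj + mj] += w * pm_i[mi] * pm_j[mj]
        with np.errstate(divide="ignore"):
            L = np.where(counts > 0, counts * np.log(np.maximum(P, 1e-300)), 0.0)
        return float(L.sum())

    best = None
    for phase in (0, 1):
        res = minimize_scalar(
            lambda t: -loglik(t, phase), bounds=(0.0, 0.5), method="bounded",
            options={"xatol": 1e-6},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, float(res.x))
    return best[1]


def _classifiable_probs(fi: np.ndarray, fj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(progeny homozygous at both loci | transmitted config), per pair.

    Maternal alleles (linkage equilibrium, frequencies fi, fj) must match
    the transmitted paternal alleles for the progeny to be homozygous at
    both markers.  Returns (a_eq, a_ne): the probability for equal-allele
    (0,0)/(1,1) and unequal-allele (0,1)/(1,0) paternal configurations.
    """
    a_eq = 0.5 * (fi * fj + (1 - fi) * (1 - fj))
    a_ne = 0.5 * (fi * (1 - fj) + (1 - fi) * fj)
    return a_eq, a_ne


def estimate_rates_pairwise(
    families: list[Family],
    markers: PhysicalMap,
    freqs: np.ndarray | None = None,
    min_progeny: int = 30,
    n_iter: int = 25,
) -> RateEstimate:
    """Two-locus ML rates for adjacent marker pairs, pooled over families.

    For every intra-chromosomal adjacent pair, each family with an
    identifiably heterozygous sire contributes its diagonal/off-diagonal
    paternal two-locus counts among doubly homozygous progeny; the family's
    phase is the majority pairing.  Because a progeny is classifiable only
    when the maternal alleles match the transmitted paternal alleles,
    recombinant and parental gametes are ascertained with different
    probabilities whenever allele frequencies are skewed; the pooled
    maximum-likelihood estimate therefore solves the estimating equation

        sum_f O_f = sum_f N_f * theta b_f / (theta b_f + (1-theta) a_f)

    with (a_f, b_f) the classifiable probabilities of the family's parental
    and recombinant configurations, computed from the supplied population
    allele frequencies (``freqs=None`` assumes 0.5 everywhere, where the
    MLE reduces to the raw recombinant fraction k/n).  Intervals never
    informative in any family are NaN.
    """
    q = markers.n_markers
    if freqs is None:
        freqs = np.full(q, 0.5)
    a_eq, a_ne = _classifiable_probs(freqs[:-1], freqs[1:])
    O_tot = np.zeros(q - 1)
    N_eq = np.zeros(q - 1)   # families whose parental config is equal-allele
    N_ne = np.zeros(q - 1)   # families whose parental config is unequal-allele
    used = 0
    sexes = {f.parent_sex for f in families}
    for fam in families:
        if fam.n_progeny < min_progeny:
            continue
        used += 1
        het = family_het_markers(fam, use_parent_geno=False)
        het_idx = np.flatnonzero(het)
        if het_idx.size < 2:
            continue
        A = paternal_allele_matrix(fam, het, use_coparent=False)
        adj = np.flatnonzero(
            (np.diff(het_idx) == 1) & markers.intra[het_idx[:-1]]
        )
        for t in adj:
            diag, off = _pair_counts(A, t, t + 1)
            if diag + off == 0:
                continue
            j = het_idx[t]
            O_tot[j] += min(diag, off)
            if diag >= off:  # parental phase in coupling (equal alleles)
                N_eq[j] += diag + off
            else:
                N_ne[j] += diag + off
    if used == 0:
        raise ValueError("no family met the likelihood estimator's requirements")
    Ntot = N_eq + N_ne
    defined = Ntot > 0
    theta = np.zeros(q - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta[defined] = O_tot[defined] / Ntot[defined]
        for _ in range(n_iter):
            denom = (
                N_eq * a_ne / (theta * a_ne + (1 - theta) * a_eq)
                + N_ne * a_eq / (theta * a_eq + (1 - theta) * a_ne)
            )
            new = np.where(denom > 0, O_tot / np.maximum(denom, 1e-300), 0.0)
            theta = np.clip(new, 0.0, 0.5)
    rates = np.where(defined, theta, np.nan)
    rates = np.clip(rates, 0.0, 0.5)
    rates[~markers.intra] = np.nan
    Ntot[~markers.intra] = 0.0
    return RateEstimate(
        markers=markers,
        rates=rates,
        n_informative=Ntot,
        sex=sexes.pop() if len(sexes) == 1 else "mixed",
        method="likelihood",
    )
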