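"""Shared building blocks for the three recombination-rate estimators.

Half-sib linkage information enters through one structure: for each parent
(a sire, or a dam when enough of her progeny are genotyped) we collect the
progeny genotypes, the co-parent genotypes aligned per progeny, and the
parent's own genotype.  From progeny alone, a marker where the shared
parent is heterozygous is revealed by opposing homozygote progeny; the
parent's two haplotypes are then reconstructed by chaining strand
assignments across a sliding window of heterozygous loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..maps import PhysicalMap
from ..popsim import MISSING


@dataclass
class RateEstimate:
    """Per-interval recombination rate estimates for one sex.

    ``rates[j]`` is the estimate for the interval between markers j and
    j+1 (NaN when no meiosis was informative there); ``n_informative`` is
    the (possibly fractional) count of meioses contributing.
    """

    markers: PhysicalMap
    rates: np.ndarray
    n_informative: np.ndarray
    sex: str
    method: str

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.n_informative = np.asarray(self.n_informative, dtype=float)
        ok = ~np.isnan(self.rates)
        if np.any((self.rates[ok] < 0) | (self.rates[ok] > 0.5)):
            raise ValueError("rates must lie in [0, 0.5]")

    @property
    def n_undefined(self) -> int:
        return int(np.sum(np.isnan(self.rates) & self.markers.intra))


@dataclass
class Family:
    """One parent's half-sib family, aligned to the marker panel."""

    parent_id: str
    parent_sex: str
    parent_geno: np.ndarray
    progeny: np.ndarray
    coparent: np.ndarray
    progeny_ids: np.ndarray
    progeny_rows: np.ndarray

    @property
    def n_progeny(self) -> int:
        return self.progeny.shape[0]


def split_families(
    genotypes: np.ndarray,
    ids: np.ndarray,
    pedigree: pd.DataFrame,
    parent_col: str = "sire",
    min_progeny: int = 1,
) -> list[Family]:
    """Group genotyped progeny into half-sib families of one parental sex.

    The parent need not be genotyped (its genotype row is then all
    missing); ungenotyped co-parents likewise contribute nothing.
    """
    row = {ind: i for i, ind in enumerate(ids)}
    other = "dam" if parent_col == "sire" else "sire"
    prog = pedigree[pedigree[parent_col] != "0"]
    prog = prog[prog["id"].isin(row)]
    q = genotypes.shape[1]
    out: list[Family] = []
    for parent, members in prog.groupby(parent_col, sort=True):
        kid_rows = np.array([row[i] for i in members["id"]], dtype=np.intp)
        if kid_rows.size < min_progeny:
            continue
        co = np.full((kid_rows.size, q), MISSING, dtype=np.int8)
        for k, oid in enumerate(members[other]):
            if oid in row:
                co[k] = genotypes[row[oid]]
        out.append(
            Family(
                parent_id=str(parent),
                parent_sex="male" if parent_col == "sire" else "female",
                parent_geno=genotypes[row[parent]]
                if parent in row
                else np.full(q, MISSING, dtype=np.int8),
                progeny=genotypes[kid_rows],
                coparent=co,
                progeny_ids=members["id"].to_numpy(dtype=object),
                progeny_rows=kid_rows,
            )
        )
    return out


def opposing_homozygote_het(progeny: np.ndarray) -> np.ndarray:
    """Markers where the shared parent is proven heterozygous by progeny.

    Both homozygote classes observed among progeny at a marker imply the
    parent transmitted both alleles, hence is heterozygous there.
    """
    return np.any(progeny == 0, axis=0) & np.any(progeny == 2, axis=0)


def family_het_markers(fam: Family, use_parent_geno: bool = False) -> np.ndarray:
    """Heterozygous-marker mask for the shared parent.

    With ``use_parent_geno`` the parent's own calls decide where observed
    and opposing homozygotes fill in where the parent call is missing;
    otherwise (progeny-only mode) opposing homozygotes alone are used.
    """
    opp = opposing_homozygote_het(fam.progeny)
    if not use_parent_geno:
        return opp
    het = fam.parent_geno == 1
    het |= opp & (fam.parent_geno == MISSING)
    # a parent call contradicting opposing homozygotes is left to Mendel QC
    return het


def paternal_allele_matrix(
    fam: Family, het: np.ndarray, use_coparent: bool = False
) -> np.ndarray:
    """Transmitted parental allele per progeny at heterozygous markers.

    Returns (n_progeny, H) int8 in {-1, 0, 1}.  A homozygous progeny
    identifies the transmitted allele directly; a heterozygous progeny is
    resolvable only when the co-parent is observed homozygous (used by the
    HMM preparation, not by the progeny-only estimators).
    """
    sub = fam.progeny[:, het]
    A = np.full(sub.shape, -1, dtype=np.int8)
    A[sub == 0] = 0
    A[sub == 2] = 1
    if use_coparent:
        co = fam.coparent[:, het]
        hetp = sub == 1
        A[hetp & (co == 0)] = 1
        A[hetp & (co == 2)] = 0
    return A


def phase_het_markers(
    A: np.ndarray, chrom: np.ndarray, window: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Chain strand assignments across a sliding window of heterozygous loci.

    A is the transmitted-allele matrix at the parent's heterozygous
    markers; ``chrom`` gives each column's chromosome.  Within a
    chromosome, each marker is phased against the last ``window`` phased
    markers by majority agreement of progeny strand assignments; ties or
    absent evidence leave the marker unphased.  Returns (s, phased) where
    ``s[t]`` is the allele carried by homolog 1 at column t (arbitrary
    global swap per chromosome).
    """
    n, H = A.shape
    s = np.zeros(H, dtype=np.int8)
    phased = np.zeros(H, dtype=bool)
    origin = np.full((n, H), -1, dtype=np.int8)  # filled as columns get phased
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        anchored: list[int] = []
        for t in cols:
            a = A[:, t]
            valid = a != -1
            if not valid.any():
                continue
            if not anchored:
                s[t] = 1
                phased[t] = True
                origin[:, t] = np.where(valid, (a != 1).astype(np.int8), -1)
                anchored.append(t)
                continue
            U = anchored[-window:]
            Ou = origin[:, U]
            mu = Ou != -1
            o1 = (a == 0)[:, None]  # origin under the choice s_t = 1
            pairs = mu & valid[:, None]
            agree1 = int(np.count_nonzero((o1 == (Ou == 1)) & pairs))
            total = int(np.count_nonzero(pairs))
            if total == 0 or agree1 * 2 == total:
                continue  # no evidence or tie: leave unphased
            s[t] = 1 if agree1 * 2 > total else 0
            phased[t] = True
            origin[:, t] = np.where(valid, (a != s[t]).astype(np.int8), -1)
            anchored.append(t)
    return s, phased


def origin_matrix(A: np.ndarray, s: np.ndarray, phased: np.ndarray) -> np.ndarray:
    """Grand-parental origin calls (0 = homolog 1) at phased het markers; -1 unknown."""
    O = np.where((A != -1) & phased[None, :], (A != s[None, :]).astype(np.int8), -1)
    return O.astype(np.int8)
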