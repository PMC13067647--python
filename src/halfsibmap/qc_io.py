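"""PLINK-text input/output and pre-inference quality control.

Genotypes travel as an individuals x markers int8 matrix coded 0/1/2 with
-1 for missing, alongside a :class:`~halfsibmap.maps.PhysicalMap` and a
pedigree table (id, sire, dam, sex).  Coordinates are 1-based bp; marker
intervals elsewhere in the package are closed [left_bp, right_bp].

The QC rules mirror standard half-sib workflows: markers are ordered by
the supplied physical map, dropped when their minor allele frequency is at
or below threshold or when they are blacklisted (misplacement candidates),
families and SNPs with excess Mendelian inconsistencies are excluded, and
residually conflicting progeny calls are set to missing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import PhysicalMap
from .popsim import MISSING

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Counts of what each QC step removed; removals are disjointly attributed."""

    markers_maf: int = 0
    markers_blacklist: int = 0
    markers_mendel: int = 0
    families_mendel: int = 0
    genotypes_zeroed: int = 0
    details: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        out = {k: v for k, v in self.__dict__.items() if k != "details"}
        out["details"] = self.details
        Path(path).write_text(json.dumps(out, indent=2, default=str))


@dataclass
class DatasetSummary:
    """Half-sib structure counts as usually tabulated for such data."""

    n_total: int
    n_families: int
    n_sires: int
    n_dams: int
    n_total_reduced: int
    n_families_reduced: int
    q: int
    missing_proportion: float


def summarize_dataset(
    genotypes: np.ndarray, ids: np.ndarray, pedigree: pd.DataFrame, min_family: int = 30
) -> DatasetSummary:
    """Summary counts, including the >=min_family progeny reduction (n*_t, N*)."""
    ped = pedigree.set_index("id")
    prog = ped[ped["sire"] != "0"]
    fam_sizes = prog.groupby("sire").size()
    genotyped = set(ids)
    big = fam_sizes[fam_sizes >= min_family]
    big_members = prog[prog["sire"].isin(big.index)].index
    n_reduced = len(set(big_members) & genotyped) + len(set(big.index) & genotyped)
    return DatasetSummary(
        n_total=ids.size,
        n_families=int(fam_sizes.size),
        n_sires=len(set(prog["sire"]) & genotyped - {"0"}),
        n_dams=len(set(prog["dam"]) & genotyped - {"0"}),
        n_total_reduced=n_reduced,
        n_families_reduced=int(big.size),
        q=genotypes.shape[1],
        missing_proportion=float(np.mean(genotypes == MISSING)),
    )


# ---------------------------------------------------------------------------
# PLINK text round trip
# ---------------------------------------------------------------------------

def write_plink_text(
    genotypes: np.ndarray,
    ids: np.ndarray,
    markers: PhysicalMap,
    ped_path: str | Path,
    map_path: str | Path,
    pedigree: pd.DataFrame | None = None,
    cm: np.ndarray | None = None,
) -> None:
    """Write .ped/.map text files (alleles coded 1/2, missing genotype '0 0')."""
    q = markers.n_markers
    if genotypes.shape != (ids.size, q):
        raise ValueError("genotype matrix shape does not match ids/markers")
    ped = (
        pedigree.set_index("id")
        if pedigree is not None
        else pd.DataFrame(index=pd.Index(ids))
    )
    # genotype code -> two allele columns: 0 -> 1 1, 1 -> 1 2, 2 -> 2 2, missing -> 0 0
    a1 = np.where(genotypes == MISSING, 0, np.where(genotypes == 2, 2, 1))
    a2 = np.where(genotypes == MISSING, 0, np.where(genotypes >= 1, 2, 1))
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(ids):
            sire = ped["sire"].get(ind, "0") if "sire" in ped else "0"
            dam = ped["dam"].get(ind, "0") if "dam" in ped else "0"
            sex = {"M": "1", "F": "2"}.get(ped["sex"].get(ind, ""), "0") if "sex" in ped else "0"
            cols = np.empty(2 * q, dtype=np.int64)
            cols[0::2] = a1[i]
            cols[1::2] = a2[i]
            fh.write(f"FAM {ind} {sire} {dam} {sex} -9 " + " ".join(map(str, cols)) + "\n")
    mp = pd.DataFrame(
        {
            "chrom": markers.chrom,
            "marker": markers.marker_id,
            "cm": cm if cm is not None else np.zeros(q),
            "bp": markers.pos_bp,
        }
    )
    mp.to_csv(map_path, sep="\t", header=False, index=False)


def read_plink_text(
    ped_path: str | Path, map_path: str | Path
) -> tuple[np.ndarray, np.ndarray, PhysicalMap, pd.DataFrame]:
    """Read .ped/.map text files.

    Returns (genotypes, ids, markers, pedigree).  Markers are re-ordered by
    (chromosome, bp) with a warning when the input was unsorted (stable for
    ties); genotype columns follow.  '0 0' becomes the missing sentinel.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"])
    if mp["marker"].duplicated().any():
        raise ValueError("duplicated marker ids in .map")
    order = np.lexsort((mp["bp"].to_numpy(), mp["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(mp))):
        warnings.warn("markers were not ordered by (chromosome, bp); re-ordering")
    mp = mp.iloc[order].reset_index(drop=True)
    markers = PhysicalMap(
        mp["marker"].to_numpy(dtype=object), mp["chrom"].to_numpy(), mp["bp"].to_numpy()
    )

    raw = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    q = len(mp)
    if raw.shape[1] != 6 + 2 * q:
        raise ValueError(".ped column count does not match .map marker count")
    ids = raw.iloc[:, 1].to_numpy(dtype=object)
    sex = raw.iloc[:, 4].map({"1": "M", "2": "F"}).fillna("U")
    pedigree = pd.DataFrame(
        {"id": ids, "sire": raw.iloc[:, 2], "dam": raw.iloc[:, 3], "sex": sex}
    )
    alle = raw.iloc[:, 6:].to_numpy(dtype=object)
    codes = np.empty(alle.shape, dtype=np.int8)
    for token, val in (("0", 0), ("1", 1), ("2", 2)):
        codes[alle == token] = val
    bad = ~np.isin(alle, ["0", "1", "2"])
    if bad.any():
        raise ValueError("allele codes beyond biallelic 1/2 (or missing 0) in .ped")
    a1 = codes[:, 0::2]
    a2 = codes[:, 1::2]
    geno = (a1 == 2).astype(np.int8) + (a2 == 2).astype(np.int8)
    geno[(a1 == 0) | (a2 == 0)] = MISSING
    geno = geno[:, order]
    return geno, ids, markers, pedigree


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id", "sire", "dam", "sex"}
    if not need <= set(ped.columns):
        raise ValueError(f"pedigree must have columns {sorted(need)}")
    return ped


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the '1' allele over non-missing calls (NaN if none)."""
    obs = genotypes != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(obs, genotypes, 0).sum(axis=0) / np.maximum(2 * n, 1)
    return np.where(n > 0, f, np.nan)


def maf_filter(
    genotypes: np.ndarray, markers: PhysicalMap, threshold: float = 0.01,
    report: QCReport | None = None,
) -> tuple[np.ndarray, PhysicalMap, np.ndarray]:
    """Drop markers with minor allele frequency <= threshold (monomorphic included).

    MAF is computed on non-missing calls over all genotyped individuals.
    Returns (genotypes, markers, kept_index).
    """
    f = allele_frequencies(genotypes)
    maf = np.minimum(f, 1 - f)
    keep = maf > threshold
    keep &= ~np.isnan(maf)
    if not keep.any():
        raise ValueError("MAF filter removed every marker")
    if report is not None:
        report.markers_maf += int((~keep).sum())
    return genotypes[:, keep], markers.subset(keep), np.flatnonzero(keep)


def apply_blacklist(
    genotypes: np.ndarray, markers: PhysicalMap, blacklist: list[str] | None,
    report: QCReport | None = None,
) -> tuple[np.ndarray, PhysicalMap, np.ndarray]:
    """Drop listed markers (misplacement candidates); unknown ids warn only."""
    if not blacklist:
        return genotypes, markers, np.arange(markers.n_markers)
    listed = set(blacklist)
    unknown = listed - set(markers.marker_id)
    if unknown:
        warnings.warn(f"{len(unknown)} blacklisted marker ids not in panel; ignored")
    keep = ~np.isin(markers.marker_id, list(listed))
    if report is not None:
        report.markers_blacklist += int((~keep).sum())
    return genotypes[:, keep], markers.subset(keep), np.flatnonzero(keep)


def _opposing_hom(parent: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Mendelian conflict mask for a parent-child duo: opposing homozygotes."""
    return ((parent == 0) & (child == 2)) | ((parent == 2) & (child == 0))


def mendel_check(
    genotypes: np.ndarray,
    ids: np.ndarray,
    pedigree: pd.DataFrame,
    family_max: float = 0.05,
    marker_max: float = 0.10,
    report: QCReport | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Mendelian-inconsistency QC on parent-progeny duos/trios.

    Order of operations: families with a conflict rate above ``family_max``
    are excluded first, then SNPs whose share of informative families with
    a conflict exceeds ``marker_max``, and finally any residual conflicting
    progeny call is set to missing (the progeny side; the parent is kept).
    Returns (genotypes, kept_marker_index, rates table); the genotype matrix
    is modified on a copy, progeny of removed families are retained as
    individuals but no longer checked.
    """
    row = {ind: i for i, ind in enumerate(ids)}
    ped = pedigree[pedigree["id"].isin(row)]
    prog = ped[(ped["sire"] != "0") | (ped["dam"] != "0")]
    geno = genotypes.copy()
    q = geno.shape[1]

    fam_conf: dict[str, int] = {}
    fam_total: dict[str, int] = {}
    snp_conf_fams = np.zeros(q, dtype=np.int64)
    snp_info_fams = np.zeros(q, dtype=np.int64)
    conflicts: dict[str, np.ndarray] = {}

    for sire, members in prog.groupby("sire"):
        if sire == "0" or sire not in row:
            continue
        pg = geno[row[sire]]
        kids = [row[i] for i in members["id"] if i in row]
        if not kids:
            continue
        child = geno[kids]
        conf = _opposing_hom(pg[None, :], child) & (child != MISSING) & (pg != MISSING)[None, :]
        comparable = (child != MISSING) & ((pg != MISSING)[None, :])
        fam_conf[sire] = int(conf.sum())
        fam_total[sire] = int(comparable.sum())
        snp_conf_fams += conf.any(axis=0)
        snp_info_fams += comparable.any(axis=0)
        conflicts[sire] = conf
    # dams as duo parents too (few-progeny families)
    for dam, members in prog.groupby("dam"):
        if dam == "0" or dam not in row:
            continue
        pg = geno[row[dam]]
        kids = [row[i] for i in members["id"] if i in row]
        if not kids:
            continue
        child = geno[kids]
        conf = _opposing_hom(pg[None, :], child) & (child != MISSING) & (pg != MISSING)[None, :]
        comparable = (child != MISSING) & ((pg != MISSING)[None, :])
        fam_conf[dam] = int(conf.sum())
        fam_total[dam] = int(comparable.sum())

    rates = pd.DataFrame(
        {
            "family": list(fam_conf),
            "conflicts": [fam_conf[f] for f in fam_conf],
            "comparable": [fam_total[f] for f in fam_conf],
        }
    )
    rates["rate"] = rates["conflicts"] / rates["comparable"].clip(lower=1)

    bad_fams = set(rates.loc[rates["rate"] > family_max, "family"])
    with np.errstate(invalid="ignore"):
        snp_rate = snp_conf_fams / np.maximum(snp_info_fams, 1)
    keep_snp = snp_rate <= marker_max

    zeroed = 0
    for sire, conf in conflicts.items():
        if sire in bad_fams:
            continue
        kids = [row[i] for i in prog[prog["sire"] == sire]["id"] if i in row]
        sub = conf[:, keep_snp]
        geno_kids = geno[np.ix_(kids, np.flatnonzero(keep_snp))]
        geno_kids[sub] = MISSING
        geno[np.ix_(kids, np.flatnonzero(keep_snp))] = geno_kids
        zeroed += int(sub.sum())

    if report is not None:
        report.families_mendel += len(bad_fams)
        report.markers_mendel += int((~keep_snp).sum())
        report.genotypes_zeroed += zeroed
        report.details["mendel_excluded_families"] = sorted(bad_fams)
    log.info(
        "mendel_check: %d families and %d SNPs excluded, %d genotypes set missing",
        len(bad_fams), int((~keep_snp).sum()), zeroed,
    )
    return geno[:, keep_snp], np.flatnonzero(keep_snp), rates


def run_qc(
    genotypes: np.ndarray,
    ids: np.ndarray,
    markers: PhysicalMap,
    pedigree: pd.DataFrame,
    maf_threshold: float = 0.01,
    family_max: float = 0.05,
    marker_max: float = 0.10,
    blacklist: list[str] | None = None,
) -> tuple[np.ndarray, PhysicalMap, QCReport]:
    """Full QC pipeline: blacklist, MAF, Mendel families/SNPs/zeroing."""
    report = QCReport()
    geno, markers, _ = apply_blacklist(genotypes, markers, blacklist, report)
    geno, markers, _ = maf_filter(geno, markers, maf_threshold, report)
    geno, kept, _ = mendel_check(geno, ids, pedigree, family_max, marker_max, report)
    markers = markers.subset(kept)
    return geno, markers, report
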