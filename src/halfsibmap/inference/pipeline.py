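"""High-level drivers: estimate a sex-specific genetic map from genotypes.

For the HMM estimator a two-run scheme is used, as is common for
HMM-based crossover pipelines on array data: after a first run, markers
whose map-confidence score falls below a threshold (0.986 by default) or
was never defined, and individuals with an implausibly high genome-wide
crossover count (> 58 by default), are removed and the inference is run
once more on the reduced data to obtain the final estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..maps import GeneticMap, PhysicalMap, accumulate_map
from ..qc_io import allele_frequencies
from .base import RateEstimate, split_families
from .crossovers import crossover_counts, first_origins, locate_crossovers
from .deterministic import estimate_rates_deterministic
from .hmm import DecodedPaths, build_meiosis_batch, marker_confidence, rates_from_batch
from .pairwise import estimate_rates_pairwise

MCS_THRESHOLD = 0.986
MAX_CROSSOVERS = 58


@dataclass
class InferenceResult:
    """Final estimates of one estimator run on one parental sex."""

    method: str
    sex: str
    markers: PhysicalMap
    rate_estimate: RateEstimate
    genetic_map: GeneticMap
    crossovers: pd.DataFrame | None = None
    paths: DecodedPaths | None = None
    first_origin: np.ndarray | None = None
    mcs: np.ndarray | None = None
    removed_markers: int = 0
    removed_individuals: int = 0


def _min_progeny_default(method: str) -> int:
    return 30 if method in ("deterministic", "likelihood") else 2


def infer_genetic_map(
    genotypes: np.ndarray,
    ids: np.ndarray,
    pedigree: pd.DataFrame,
    markers: PhysicalMap,
    method: str = "hmm",
    sex: str = "male",
    min_progeny: int | None = None,
    window: int = 30,
    two_run: bool = True,
    mcs_threshold: float = MCS_THRESHOLD,
    max_crossovers: int = MAX_CROSSOVERS,
    em_init: float = 1e-3,
    em_tol: float = 1e-4,
    em_max_iter: int = 20,
) -> InferenceResult:
    """Estimate the recombination map of one parental sex.

    ``method`` selects the estimator family: ``'hmm'`` (transmission HMM
    with EM rate updates and the two-run confidence filter),
    ``'deterministic'`` (multipoint sliding-window strand clustering) or
    ``'likelihood'`` (adjacent-pair two-locus ML).  The deterministic and
    likelihood estimators use progeny genotypes only and require families
    with at least 30 genotyped progeny.
    """
    if min_progeny is None:
        min_progeny = _min_progeny_default(method)
    parent_col = "sire" if sex == "male" else "dam"
    families = split_families(genotypes, ids, pedigree, parent_col, min_progeny)
    if not families:
        raise ValueError(f"no {parent_col} family with >= {min_progeny} genotyped progeny")

    if method == "deterministic":
        est = estimate_rates_deterministic(families, markers, window=window,
                                           min_progeny=min_progeny)
        gmap = accumulate_map(markers, est.rates, sex=sex)
        return InferenceResult(method, sex, markers, est, gmap)
    if method == "likelihood":
        pop_freqs = allele_frequencies(genotypes)
        pop_freqs = np.where(np.isnan(pop_freqs), 0.5, pop_freqs)
        est = estimate_rates_pairwise(families, markers, freqs=pop_freqs,
                                      min_progeny=min_progeny)
        gmap = accumulate_map(markers, est.rates, sex=sex)
        return InferenceResult(method, sex, markers, est, gmap)
    if method != "hmm":
        raise ValueError(f"unknown method {method!r}")

    freqs = allele_frequencies(genotypes)
    freqs = np.where(np.isnan(freqs), 0.5, freqs)
    batch = build_meiosis_batch(families, markers, freqs, window=window)
    est, paths = rates_from_batch(batch, init_rate=em_init, tol=em_tol,
                                  max_iter=em_max_iter)
    mcs = marker_confidence(paths)
    removed_markers = removed_individuals = 0

    if two_run:
        keep_markers = ~(np.isnan(mcs) | (mcs < mcs_threshold))
        records = locate_crossovers(paths)
        counts = crossover_counts(records, paths.progeny_ids)
        drop_ids = set(counts.index[counts > max_crossovers])
        removed_markers = int((~keep_markers).sum())
        removed_individuals = len(drop_ids)
        if removed_markers or removed_individuals:
            keep_rows = ~np.isin(ids, list(drop_ids))
            sub_markers = markers.subset(keep_markers)
            sub_geno = genotypes[np.ix_(keep_rows, np.flatnonzero(keep_markers))]
            sub_ids = ids[keep_rows]
            families = split_families(sub_geno, sub_ids, pedigree, parent_col, min_progeny)
            freqs2 = allele_frequencies(sub_geno)
            freqs2 = np.where(np.isnan(freqs2), 0.5, freqs2)
            batch = build_meiosis_batch(families, sub_markers, freqs2, window=window)
            est, paths = rates_from_batch(batch, init_rate=em_init, tol=em_tol,
                                          max_iter=em_max_iter)
            mcs = marker_confidence(paths)
            markers = sub_markers

    records = locate_crossovers(paths)
    gmap = accumulate_map(markers, est.rates, sex=sex)
    return InferenceResult(
        method="hmm",
        sex=sex,
        markers=markers,
        rate_estimate=est,
        genetic_map=gmap,
        crossovers=records,
        paths=paths,
        first_origin=first_origins(paths),
        mcs=mcs,
        removed_markers=removed_markers,
        removed_individuals=removed_individuals,
    )
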