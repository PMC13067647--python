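import dataclasses

import numpy as np
import pandas as pd
import pytest

from halfsibmap import popsim


@pytest.fixture(scope="session")
def small_dataset():
    """Two half-sib families, 40 progeny each, 120 markers, complete genotypes."""
    scen = popsim.SimScenario(n_families=2, n_progeny=40, n_markers=120, seed=101)
    return popsim.build_half_sib_population(scen, length_morgan=0.8)


@pytest.fixture(scope="session")
def discriminating_dataset():
    """One family whose sire is heterozygous at every marker and whose dam is
    homozygous reference, so each progeny genotype directly reveals the
    transmitted sire allele at every marker."""
    q, n = 200, 60
    pmap, gmap = popsim.make_physical_map(q, 1.5)
    rng = np.random.default_rng(77)
    sire_haps = np.vstack([np.zeros(q, np.int8), np.ones(q, np.int8)])
    pat = np.empty((n, q), np.int8)
    starts = np.empty((n, 1), np.int8)
    rows = []
    for j in range(n):
        gam, xo = popsim.simulate_meiosis(sire_haps, gmap.rates(), rng)
        pat[j] = gam
        starts[j, 0] = gam[0]  # origin equals the transmitted allele here
        for iv in xo:
            rows.append(
                (f"P001_{j + 1:04d}", "S0001", "male", 1, int(iv),
                 int(pmap.pos_bp[iv]), int(pmap.pos_bp[iv + 1]))
            )
    crossovers = pd.DataFrame(
        rows, columns=["progeny", "parent", "parent_sex", "chrom", "interval",
                       "left_bp", "right_bp"],
    )
    ids = np.array(
        ["S0001", "D00001"] + [f"P001_{j + 1:04d}" for j in range(n)], dtype=object
    )
    geno = np.vstack([np.ones(q, np.int8), np.zeros(q, np.int8), pat])
    pedigree = pd.DataFrame(
        {
            "id": ids,
            "sire": ["0", "0"] + ["S0001"] * n,
            "dam": ["0", "0"] + ["D00001"] * n,
            "sex": ["M", "F"] + ["M"] * n,
        }
    )
    return popsim.SimulatedDataset(
        markers=pmap,
        male_map=dataclasses.replace(gmap, sex="male"),
        female_map=dataclasses.replace(gmap, sex="female"),
        ids=ids,
        pedigree=pedigree,
        genotypes=geno,
        missing_mask=None,
        parent_haplotypes={"S0001": sire_haps, "D00001": np.zeros((2, q), np.int8)},
        paternal_gametes=pat,
        maternal_gametes=np.zeros((n, q), np.int8),
        paternal_start_origin=starts,
        maternal_start_origin=np.zeros((n, 1), np.int8),
        crossovers=crossovers,
    )


def subset_true_map(true_map, markers):
    """Restrict a true map to an estimator's final marker set."""
    keep = np.isin(true_map.markers.marker_id, markers.marker_id)
    return true_map.subset(keep)
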