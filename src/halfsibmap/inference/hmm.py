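"""Two-state transmission HMM with EM rate re-estimation.

Each meiosis is a hidden path over the markers whose state says which of
the shared parent's two homologs was transmitted.  Transition probability
between adjacent markers is the current per-interval recombination rate
(independent restart across chromosome joins); the emission at a marker
is the probability of the progeny genotype given the transmitted parental
allele and the co-parent's contribution (its genotype when observed, the
population allele frequency otherwise).  Missing progeny genotypes emit 1
for both states.

Rates are re-estimated from posterior-expected origin switches
(forward-backward) and decoding/estimation is iterated to convergence.
All meioses of one parental sex share the rate vector, so the EM runs
vectorised over the pooled meioses of all families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..maps import PhysicalMap
from ..popsim import MISSING
from .base import (
    Family,
    RateEstimate,
    family_het_markers,
    paternal_allele_matrix,
    phase_het_markers,
)

RATE_FLOOR = 1e-6  # keeps the chain ergodic during EM
_INFORMATIVE_TOL = 1e-9


@dataclass
class MeiosisBatch:
    """Pooled per-meiosis emission data for one parental sex."""

    markers: PhysicalMap
    emissions: np.ndarray  # (M, q, 2): P(progeny genotype | transmitted homolog)
    informative: np.ndarray  # (M, q) bool: emission discriminates the homologs
    parent_ids: np.ndarray
    progeny_ids: np.ndarray
    sex: str

    @property
    def n_meioses(self) -> int:
        return self.emissions.shape[0]

    def marker_major(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (q, M) contiguous views of the two emission layers."""
        if not hasattr(self, "_mm"):
            self._mm = (
                np.ascontiguousarray(self.emissions[:, :, 0].T),
                np.ascontiguousarray(self.emissions[:, :, 1].T),
            )
        return self._mm


@dataclass
class DecodedPaths:
    """Posterior-decoded transmission paths for a batch of meioses."""

    markers: PhysicalMap
    state: np.ndarray  # (M, q) int8 decoded origin (0 = homolog 1)
    posterior: np.ndarray  # (M, q) float32 posterior of the decoded state
    informative: np.ndarray  # (M, q) bool
    parent_ids: np.ndarray
    progeny_ids: np.ndarray
    sex: str
    flagged: np.ndarray  # (M,) bool: zero-likelihood meioses


def parent_haplotype_probs(
    fam: Family,
    markers: PhysicalMap,
    freqs: np.ndarray,
    window: int = 30,
    use_coparent: bool = True,
) -> np.ndarray:
    """P(transmitted allele = 1 | state) per marker, shape (2, q).

    Homozygous parent markers give the same point mass in both states;
    heterozygous phased markers separate the states; unphased het markers
    emit 0.5 in both states and markers with no parent information fall
    back to the population allele frequency.
    """
    q = markers.n_markers
    p = np.tile(freqs.astype(float), (2, 1))
    g = fam.parent_geno
    p[:, g == 0] = 0.0
    p[:, g == 2] = 1.0
    het = family_het_markers(fam, use_parent_geno=True)
    if het.any():
        het_idx = np.flatnonzero(het)
        A = paternal_allele_matrix(fam, het, use_coparent=use_coparent)
        s, phased = phase_het_markers(A, markers.chrom[het_idx], window=window)
        ph = het_idx[phased]
        p[0, ph] = s[phased]
        p[1, ph] = 1 - s[phased]
        unph = het_idx[~phased]
        p[:, unph] = 0.5
    return p


def build_meiosis_batch(
    families: list[Family],
    markers: PhysicalMap,
    freqs: np.ndarray,
    window: int = 30,
    use_coparent: bool = True,
) -> MeiosisBatch:
    """Assemble the emission tensor for all meioses of one parental sex."""
    q = markers.n_markers
    blocks, parents, progeny, infos = [], [], [], []
    for fam in families:
        p_pat = parent_haplotype_probs(fam, markers, freqs, window, use_coparent)
        co = fam.coparent
        qm = np.where(co == MISSING, freqs[None, :], co / 2.0)  # (n, q)
        g = fam.progeny
        E = np.empty((fam.n_progeny, q, 2))
        for state in (0, 1):
            ps = p_pat[state][None, :]
            e = np.where(
                g == 0,
                (1 - ps) * (1 - qm),
                np.where(g == 1, ps * (1 - qm) + (1 - ps) * qm, ps * qm),
            )
            E[:, :, state] = np.where(g == MISSING, 1.0, e)
        blocks.append(E)
        infos.append(np.abs(E[:, :, 0] - E[:, :, 1]) > _INFORMATIVE_TOL)
        parents.append(np.repeat(fam.parent_id, fam.n_progeny))
        progeny.append(fam.progeny_ids)
    if not blocks:
        raise ValueError("no families to decode")
    sexes = {f.parent_sex for f in families}
    return MeiosisBatch(
        markers=markers,
        emissions=np.concatenate(blocks, axis=0),
        informative=np.concatenate(infos, axis=0),
        parent_ids=np.concatenate(parents),
        progeny_ids=np.concatenate(progeny),
        sex=sexes.pop() if len(sexes) == 1 else "mixed",
    )


def _transitions(markers: PhysicalMap, rates: np.ndarray) -> np.ndarray:
    """Per-interval switch probability; 0.5 across chromosome joins."""
    t = np.asarray(rates, dtype=float).copy()
    t[~markers.intra] = 0.5
    return t


def _fb_loops(E0, E1, t, alpha0, alpha1, scale, post, xi, flagged):
    """Forward-backward inner loops on marker-major (q, M) arrays."""
    q, M = E0.shape
    for j in range(M):
        a0 = 0.5 * E0[0, j]
        a1 = 0.5 * E1[0, j]
        s = a0 + a1
        if s <= 0.0:
            flagged[j] = True
            a0 = 0.5
            a1 = 0.5
            s = 1.0
        alpha0[0, j] = a0 / s
        alpha1[0, j] = a1 / s
        scale[0, j] = s
    for m in range(1, q):
        tm = t[m - 1]
        for j in range(M):
            p0 = alpha0[m - 1, j]
            p1 = alpha1[m - 1, j]
            a0 = (p0 * (1.0 - tm) + p1 * tm) * E0[m, j]
            a1 = (p0 * tm + p1 * (1.0 - tm)) * E1[m, j]
            s = a0 + a1
            if s <= 0.0:
                flagged[j] = True
                a0 = 0.5
                a1 = 0.5
                s = 1.0
            alpha0[m, j] = a0 / s
            alpha1[m, j] = a1 / s
            scale[m, j] = s
    loglik = 0.0
    for j in range(M):
        if not flagged[j]:
            for m in range(q):
                loglik += np.log(scale[m, j])
    b0 = np.ones(M)
    b1 = np.ones(M)
    for j in range(M):
        post[q - 1, j] = alpha1[q - 1, j]
    for m in range(q - 1, 0, -1):
        tm = t[m - 1]
        for j in range(M):
            e0 = E0[m, j] * b0[j]
            e1 = E1[m, j] * b1[j]
            ap0 = alpha0[m - 1, j]
            ap1 = alpha1[m - 1, j]
            x_same = ap0 * (1.0 - tm) * e0 + ap1 * (1.0 - tm) * e1
            x_diff = ap0 * tm * e1 + ap1 * tm * e0
            norm = x_same + x_diff
            xi[m - 1, j] = x_diff / norm if norm > 0.0 else 0.0
            nb0 = ((1.0 - tm) * e0 + tm * e1) / scale[m, j]
            nb1 = (tm * e0 + (1.0 - tm) * e1) / scale[m, j]
            b0[j] = nb0
            b1[j] = nb1
            g0 = ap0 * nb0
            g1 = ap1 * nb1
            tot = g0 + g1
            if tot <= 0.0:
                tot = 1.0
            post[m - 1, j] = g1 / tot
    return loglik


try:  # JIT-compile the inner loops when numba is present (pure-python fallback otherwise)
    from numba import njit

    _fb_loops_jit = njit(cache=True)(_fb_loops)
except ImportError:  # pragma: no cover
    _fb_loops_jit = None


def forward_backward(
    batch: MeiosisBatch, rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Vectorised forward-backward over all meioses.

    Returns (posterior_state1 (M, q), expected_switches (M, q-1),
    flagged (M,), total restricted log-likelihood).  Posteriors sum to 1
    over the two states at every marker; the expected switch count per
    interval is the posterior probability of an origin change there.
    """
    M, q, _ = batch.emissions.shape
    # marker-major layout keeps every per-marker slice contiguous
    E0, E1 = batch.marker_major()
    t = _transitions(batch.markers, rates)
    if _fb_loops_jit is not None:
        alpha0 = np.empty((q, M))
        alpha1 = np.empty((q, M))
        scale = np.empty((q, M))
        post = np.empty((q, M))
        xi = np.empty((q - 1, M))
        flagged = np.zeros(M, dtype=np.bool_)
        loglik = _fb_loops_jit(E0, E1, t, alpha0, alpha1, scale, post, xi, flagged)
        return (
            np.ascontiguousarray(post.T),
            np.ascontiguousarray(xi.T),
            flagged,
            float(loglik),
        )
    alpha0 = np.empty((q, M))
    alpha1 = np.empty((q, M))
    scale = np.empty((q, M))
    flagged = np.zeros(M, dtype=bool)

    a0 = 0.5 * E0[0]
    a1 = 0.5 * E1[0]
    s = a0 + a1
    bad = s <= 0
    if bad.any():
        flagged |= bad
        s[bad] = 1.0
        a0[bad] = 0.5
        a1[bad] = 0.5
    alpha0[0] = a0 / s
    alpha1[0] = a1 / s
    scale[0] = s
    for m in range(1, q):
        tm = t[m - 1]
        p0 = alpha0[m - 1]
        p1 = alpha1[m - 1]
        a0 = (p0 * (1 - tm) + p1 * tm) * E0[m]
        a1 = (p0 * tm + p1 * (1 - tm)) * E1[m]
        s = a0 + a1
        bad = s <= 0
        if bad.any():
            flagged |= bad
            s[bad] = 1.0
            a0[bad] = 0.5
            a1[bad] = 0.5
        alpha0[m] = a0 / s
        alpha1[m] = a1 / s
        scale[m] = s

    loglik = float(np.log(scale[:, ~flagged]).sum()) if (~flagged).any() else 0.0

    post = np.empty((q, M))
    xi = np.empty((q - 1, M))
    b0 = np.ones(M)
    b1 = np.ones(M)
    post[q - 1] = alpha1[q - 1]
    for m in range(q - 1, 0, -1):
        tm = t[m - 1]
        e0 = E0[m] * b0
        e1 = E1[m] * b1
        ap0 = alpha0[m - 1]
        ap1 = alpha1[m - 1]
        x_same = ap0 * (1 - tm) * e0 + ap1 * (1 - tm) * e1
        x_diff = ap0 * tm * e1 + ap1 * tm * e0
        norm = x_same + x_diff
        zero = norm <= 0
        if zero.any():
            norm[zero] = 1.0
            x_diff = np.where(zero, 0.0, x_diff)
        xi[m - 1] = x_diff / norm
        b0 = ((1 - tm) * e0 + tm * e1) / scale[m]
        b1 = (tm * e0 + (1 - tm) * e1) / scale[m]
        g0 = ap0 * b0
        g1 = ap1 * b1
        tot = g0 + g1
        tot[tot <= 0] = 1.0
        post[m - 1] = g1 / tot
    return np.ascontiguousarray(post.T), np.ascontiguousarray(xi.T), flagged, loglik


def em_estimate_rates(
    batch: MeiosisBatch,
    init_rate: float = 1e-3,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate decode and re-estimate until the largest rate change < tol.

    The M-step sets each interval's rate to the mean posterior-expected
    switch count over all meioses of the batch, clamped to
    [RATE_FLOOR, 0.5].  Returns (rates, posterior, n_iter).
    """
    q = batch.markers.n_markers
    rates = np.full(q - 1, init_rate)
    post = None
    for it in range(1, max_iter + 1):
        post, xi, flagged, _ = forward_backward(batch, rates)
        ok = ~flagged
        if not ok.any():
            raise ValueError("all meioses have zero likelihood")
        new = np.clip(xi[ok].mean(axis=0), RATE_FLOOR, 0.5)
        new[~batch.markers.intra] = rates[~batch.markers.intra]
        delta = float(np.max(np.abs(new - rates)[batch.markers.intra]))
        rates = new
        if delta < tol:
            break
    return rates, post, it


def decode_paths(batch: MeiosisBatch, rates: np.ndarray) -> DecodedPaths:
    """Posterior decoding; ties at 0.5 inherit the previous state."""
    post, _, flagged, _ = forward_backward(batch, rates)
    M, q = post.shape
    state = np.full((M, q), 0, dtype=np.int8)
    state[post > 0.5] = 1
    ties = np.isclose(post, 0.5, rtol=0.0, atol=1e-12)
    for m in np.flatnonzero(ties.any(axis=0)):
        if m == 0:
            continue
        col = ties[:, m]
        state[col, m] = state[col, m - 1]
    conf = np.where(state == 1, post, 1.0 - post).astype(np.float32)
    return DecodedPaths(
        markers=batch.markers,
        state=state,
        posterior=conf,
        informative=batch.informative,
        parent_ids=batch.parent_ids,
        progeny_ids=batch.progeny_ids,
        sex=batch.sex,
        flagged=flagged,
    )


def decode_transmission(
    parent_haplotypes: np.ndarray,
    progeny_geno: np.ndarray,
    coparent: np.ndarray | float | None,
    rates: np.ndarray,
    markers: PhysicalMap,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a single meiosis against a fully specified phased parent.

    ``parent_haplotypes`` is (2, q) with -1 for unknown alleles;
    ``coparent`` is the other parent's genotype vector, or None to fall
    back to ``freqs``.  Returns (posterior of homolog 2 per marker,
    expected switches per interval).
    """
    q = markers.n_markers
    freqs = np.full(q, 0.5) if freqs is None else np.asarray(freqs, dtype=float)
    haps = np.asarray(parent_haplotypes)
    p_pat = np.where(haps == -1, freqs[None, :], haps).astype(float)
    if coparent is None:
        qm = freqs.copy()
    elif np.isscalar(coparent):
        qm = np.full(q, float(coparent))
    else:
        co = np.asarray(coparent)
        qm = np.where(co == MISSING, freqs, co / 2.0)
    g = np.asarray(progeny_geno)
    E = np.empty((1, q, 2))
    for state in (0, 1):
        ps = p_pat[state]
        e = np.where(
            g == 0,
            (1 - ps) * (1 - qm),
            np.where(g == 1, ps * (1 - qm) + (1 - ps) * qm, ps * qm),
        )
        E[0, :, state] = np.where(g == MISSING, 1.0, e)
    batch = MeiosisBatch(
        markers=markers,
        emissions=E,
        informative=np.abs(E[:, :, 0] - E[:, :, 1]) > _INFORMATIVE_TOL,
        parent_ids=np.array(["parent"], dtype=object),
        progeny_ids=np.array(["progeny"], dtype=object),
        sex="male",
    )
    post, xi, _, _ = forward_backward(batch, np.asarray(rates, dtype=float))
    return post[0], xi[0]


def rates_from_batch(
    batch: MeiosisBatch,
    init_rate: float = 1e-3,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> tuple[RateEstimate, DecodedPaths]:
    """EM-estimated rates plus decoded paths for one parental sex."""
    rates, _, _ = em_estimate_rates(batch, init_rate=init_rate, tol=tol, max_iter=max_iter)
    paths = decode_paths(batch, rates)
    cov = informative_coverage(paths)
    out = rates.copy()
    out[~batch.markers.intra] = np.nan
    out[cov == 0] = np.nan
    est = RateEstimate(
        markers=batch.markers,
        rates=out,
        n_informative=cov,
        sex=batch.sex,
        method="hmm",
    )
    return est, paths


def informative_coverage(paths: DecodedPaths) -> np.ndarray:
    """Number of meioses whose informative span covers each interval."""
    M, q = paths.informative.shape
    diff = np.zeros(q)
    for j in range(M):
        g = np.flatnonzero(paths.informative[j])
        if g.size < 2:
            continue
        chrom = paths.markers.chrom[g]
        starts = g[np.r_[True, chrom[1:] != chrom[:-1]]]
        stops = g[np.r_[chrom[1:] != chrom[:-1], True]]
        for a, b in zip(starts, stops):
            if b > a:
                diff[a] += 1
                diff[b] -= 1
    cov = np.cumsum(diff)[: q - 1]
    cov[~paths.markers.intra] = 0
    return cov


def marker_confidence(paths: DecodedPaths) -> np.ndarray:
    """Map-confidence score per marker in [0, 1].

    The posterior-weighted fraction of meioses whose origin call at the
    marker agrees with the locally smoothed path, taken as the median of
    the three nearest informative calls: a call counts as disagreeing only
    when it differs from both flanking informative calls (an isolated
    flip).  Genuine crossovers are never isolated, so locally consistent
    data score 1, while a misplaced (permuted) marker produces isolated
    flips in many meioses and scores low.  NaN for markers never
    informative.
    """
    M, q = paths.state.shape
    num = np.zeros(q)
    den = np.zeros(q)
    for j in range(M):
        g = np.flatnonzero(paths.informative[j])
        if g.size == 0:
            continue
        chrom = paths.markers.chrom[g]
        cuts = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        for run in np.split(np.arange(g.size), cuts):
            gg = g[run]
            x = paths.state[j, gg]
            agree = np.ones(x.size, dtype=bool)
            if x.size >= 3:
                agree[1:-1] = ~((x[1:-1] != x[:-2]) & (x[1:-1] != x[2:]))
            w = paths.posterior[j, gg].astype(float)
            np.add.at(num, gg, w * agree)
            np.add.at(den, gg, w)
    with np.errstate(invalid="ignore"):
        score = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return score
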