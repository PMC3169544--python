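"""Locus-by-locus AMOVA fixation indices with permutation significance.

The fixation index Φ_ST is obtained from an analysis of molecular
variance (AMOVA): squared inter-sequence distances are partitioned into
among-group and within-group components,

    SSD_total  = (1/N) Σ_{i<j} d²_ij
    SSD_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij
    σ²_w = SSD_within / (N − G)
    σ²_a = (SSD_among/(G−1) − σ²_w) / n',   n' = (N − Σ n_g²/N)/(G−1)
    Φ_ST = σ²_a / (σ²_a + σ²_w)

Significance is the proportion of random permutations of the group
labels whose Φ_ST is at least the observed value, with the plus-one
correction p = (1 + #{perm ≥ obs}) / (1 + n_perm).  Negative variance
components are reported as computed (flagged, never truncated) so that
the permutation distribution stays exchangeable.

Sequence distances used throughout the package count differing
polymorphic sites (an indel site counts one), with pairwise deletion of
missing calls.  Haploid (mtDNA, female Z) and diploid (male Z) sequences
enter the same haplotype-level decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AFLPMatrix, PolymorphismTable

__all__ = [
    "FstResult",
    "pairwise_distances",
    "phi_st",
    "fst_binary",
    "locus_by_locus",
    "pairwise_fst",
]


@dataclass(frozen=True)
class FstResult:
    locus_id: str
    phi_st: float
    p_value: float
    n_permutations: int
    negative_component: bool = False
    error: str | None = None


def pairwise_distances(table: PolymorphismTable) -> pd.DataFrame:
    """Inter-sequence distance matrix: number of differing sites.

    Missing calls are pairwise-deleted; an indel site contributes one
    unit like a SNP site.
    """
    calls = table.calls.to_numpy(dtype=object)
    n = calls.shape[0]
    D = np.zeros((n, n))
    codes = pd.DataFrame(table.calls).copy()
    # factorize each column to integers, -1 for missing
    enc = np.full(calls.shape, -1, dtype=int)
    for j, c in enumerate(table.calls.columns):
        col = table.calls[c]
        codes_j, _ = pd.factorize(col)
        enc[:, j] = codes_j  # NaN -> -1
    for i in range(n):
        both = (enc[i] >= 0) & (enc >= 0)
        diff = (enc[i] != enc) & both
        D[i] = diff.sum(axis=1)
    return pd.DataFrame(D, index=table.calls.index, columns=table.calls.index)


def _amova_phi(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Φ_ST from a squared-distance matrix and integer group codes."""
    N = d2.shape[0]
    G = len(labels)
    ss_total = d2.sum() / (2 * N)
    ss_within = 0.0
    sizes = np.empty(G)
    for k in range(G):
        m = groups == k
        sizes[k] = m.sum()
        ss_within += d2[np.ix_(m, m)].sum() / (2 * sizes[k])
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    sigma_w = ss_within / df_within
    n_prime = (N - (sizes**2).sum() / N) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0, False
    phi = sigma_a / denom
    return float(phi), bool(sigma_a < 0 or sigma_w < 0)


def phi_st(
    distances: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    locus_id: str = "",
    exact: bool = False,
) -> FstResult:
    """AMOVA Φ_ST for one locus with a label-permutation test.

    Parameters
    ----------
    distances
        Symmetric pairwise distance matrix over sequences.
    groups
        One group label per sequence (same order as the matrix).
    n_perm
        Random label permutations for the significance test; the
        plus-one-corrected p-value is bounded below by 1/(n_perm+1).
    exact
        Enumerate every distinct label arrangement instead of sampling;
        p is then #{arrangements with Φ ≥ observed} / #arrangements
        (the identity arrangement is included, so p ≥ 1/#arrangements).
        Only sensible for small n.
    """
    D = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(groups):
        raise ValueError("distance matrix and group labels do not conform")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[counts.argmin()]
        raise ValueError(f"degenerate group {small!r}: fewer than 2 sequences")
    d2 = D**2
    obs, neg = _amova_phi(d2, codes, labels)
    if exact:
        from sympy.utilities.iterables import multiset_permutations

        stats = [
            _amova_phi(d2, np.asarray(perm), labels)[0]
            for perm in multiset_permutations(codes.tolist())
        ]
        hits = sum(s >= obs - 1e-12 for s in stats)
        return FstResult(
            locus_id=locus_id, phi_st=obs, p_value=hits / len(stats),
            n_permutations=len(stats), negative_component=neg,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        stat, _ = _amova_phi(d2, perm, labels)
        if stat >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return FstResult(locus_id=locus_id, phi_st=obs, p_value=p, n_permutations=n_perm, negative_component=neg)


def _binary_phi_from_counts(n1: np.ndarray, ntot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Φ_ST for 0/1 haplotypes from per-group presence counts.

    For binary data the squared distance is the 0/1 mismatch indicator,
    so all AMOVA sums of squares reduce to closed forms in the counts:
    Σ_{i<j∈g} d² = n1_g·n0_g.  ``n1``/``ntot`` have shape (..., G).
    """
    N = ntot.sum(axis=-1)
    G = ntot.shape[-1]
    n1tot = n1.sum(axis=-1)
    ss_total = n1tot * (N - n1tot) / N
    ss_within = (n1 * (ntot - n1) / ntot).sum(axis=-1)
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (N - G)
    n_prime = (N - (ntot**2).sum(axis=-1) / N) / (G - 1)
    sigma_a = (ss_among / (G - 1) - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom == 0, 0.0, sigma_a / denom)
    return phi, sigma_a < 0


def fst_binary(
    column: Sequence[float],
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    locus_id: str = "",
) -> FstResult:
    """Φ_ST for one dominant binary marker (band state as haplotype).

    Each band state is treated as a haplotype of length 1 with 0/1
    mismatch distances, so this is :func:`phi_st` in closed form.
    Missing scores are dropped (with their labels) before testing.
    """
    x = np.asarray(column, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(x)
    x, groups = x[keep], groups[keep]
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError(f"degenerate group {labels[counts.argmin()]!r}: fewer than 2 members")
    if len(np.unique(x)) < 2:
        raise ValueError(f"marker {locus_id!r} is monomorphic")
    G = len(labels)
    onehot = np.eye(G)[codes]  # (N, G)
    ntot = onehot.sum(axis=0)
    n1 = x @ onehot
    obs, neg = _binary_phi_from_counts(n1[None, :], ntot[None, :])
    obs, neg = float(obs[0]), bool(neg[0])
    rng = np.random.default_rng(seed)
    # permute x over individuals: shuffle each row of a (n_perm, N) tile
    tile = np.tile(x, (n_perm, 1))
    tile = rng.permuted(tile, axis=1)
    n1_perm = tile @ onehot  # (n_perm, G)
    phis, _ = _binary_phi_from_counts(n1_perm, np.tile(ntot, (n_perm, 1)))
    hits = int((phis >= obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_perm)
    return FstResult(locus_id=locus_id, phi_st=obs, p_value=p, n_permutations=n_perm, negative_component=neg)


def locus_by_locus(
    data: Mapping[str, pd.DataFrame] | AFLPMatrix,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[FstResult]:
    """Per-locus Φ_ST in stable input order.

    ``data`` is either an :class:`AFLPMatrix` (one binary test per
    marker) or a mapping locus_id → distance matrix.  Per-locus failures
    (monomorphic markers, degenerate groups) are returned as flagged
    rows, not raised.
    """
    rng = np.random.default_rng(seed)
    results: list[FstResult] = []
    if isinstance(data, AFLPMatrix):
        items = [(m, data.bands[m].to_numpy(dtype=float)) for m in data.markers]
        for locus_id, col in items:
            try:
                results.append(fst_binary(col, groups, n_perm=n_perm, seed=rng, locus_id=locus_id))
            except ValueError as exc:
                results.append(FstResult(locus_id, np.nan, np.nan, n_perm, error=str(exc)))
    else:
        for locus_id, D in data.items():
            try:
                results.append(phi_st(D, groups, n_perm=n_perm, seed=rng, locus_id=locus_id))
            except ValueError as exc:
                results.append(FstResult(locus_id, np.nan, np.nan, n_perm, error=str(exc)))
    return results


def pairwise_fst(
    distances: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group × group Φ_ST matrix (zero diagonal, symmetric).

    With ``n_perm`` > 0 a companion permutation p-value matrix could be
    derived per pair via :func:`phi_st`; here the point estimates are
    returned (use :func:`phi_st` directly for a specific pair's test).
    """
    D = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    d2 = D**2
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            m = (groups == a) | (groups == b)
            codes = (groups[m] == b).astype(int)
            phi, _ = _amova_phi(d2[np.ix_(m, m)], codes, np.array([a, b]))
            out.loc[a, b] = out.loc[b, a] = phi
    return out


def results_table(results: Sequence[FstResult]) -> pd.DataFrame:
    """Tidy TSV-ready table of per-locus results."""
    return pd.DataFrame(
        {
            "locus": [r.locus_id for r in results],
            "phi_st": [r.phi_st for r in results],
            "p_value": [r.p_value for r in results],
            "n_perm": [r.n_permutations for r in results],
            "negative_component": [r.negative_component for r in results],
            "error": [r.error or "" for r in results],
        }
    )
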