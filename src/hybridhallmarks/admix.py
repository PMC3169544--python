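"""Bayesian admixture estimation for dominant binary markers.

Model: each individual i has an admixture vector q_i over K source
clusters (Dirichlet(α) prior); each cluster k has a band-presence
frequency p_{k,l} per marker l (Beta(1,1) prior).  Band observations are
treated as haploid binary allele observations — the dominant band state
is modelled as the allele itself, which keeps every full conditional
conjugate.  A dominance-aware genotype likelihood is deliberately out of
scope and this simplification is the package's documented model choice.

The collapsed state is the per-individual-per-marker ancestry origin
z_{i,l} ∈ {1..K}.  One Gibbs sweep:

1. z_{i,l} ~ Categorical ∝ q_{i,k} · p_{k,l}^{x_{i,l}} (1−p_{k,l})^{1−x_{i,l}}
2. p_{k,l} ~ Beta(1 + #presence assigned to k, 1 + #absence assigned to k)
3. q_i     ~ Dirichlet(α + assignment counts of individual i)

Posterior means of q and p are accumulated after burn-in.  Missing bands
are skipped in likelihoods and counts.  Cluster labels are arbitrary
(label switching); use :func:`align_labels` to reconcile runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import AFLPMatrix, PopulationMap

__all__ = ["AdmixtureResult", "estimate_admixture", "admixture_summary", "align_labels"]


@dataclass
class AdmixtureResult:
    K: int
    q: pd.DataFrame  # individuals × K posterior-mean admixture proportions
    p: pd.DataFrame  # K × markers posterior-mean band frequencies
    loglik_trace: np.ndarray
    seed: int | None
    burnin: int
    iterations: int
    excluded: list[str]


def estimate_admixture(
    aflp: AFLPMatrix,
    K: int,
    burnin: int = 5_000,
    iterations: int = 20_000,
    seed: int | None = None,
    dirichlet_alpha: float = 1.0,
) -> AdmixtureResult:
    """Gibbs sampler for admixture proportions on a dominant marker matrix.

    ``iterations`` counts post-burn-in sweeps (the data-collection
    phase); the chain runs ``burnin + iterations`` sweeps in total.
    Individuals with no scored bands are excluded with a warning entry.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    X = aflp.bands.to_numpy(dtype=float)
    individuals = list(aflp.individuals)
    scored = ~np.isnan(X)
    keep = scored.any(axis=1)
    excluded = [ind for ind, k in zip(individuals, keep) if not k]
    X, scored = X[keep], scored[keep]
    individuals = [i for i, k in zip(individuals, keep) if k]
    N, L = X.shape
    if N < 2 * K:
        raise ValueError(f"need at least {2 * K} individuals for K={K}")
    rng = np.random.default_rng(seed)

    Xf = np.nan_to_num(X, nan=0.0)
    q = rng.dirichlet(np.full(K, dirichlet_alpha), size=N)  # (N, K)
    p = rng.uniform(0.2, 0.8, size=(K, L))

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    loglik = np.empty(iterations)
    onehot_eye = np.eye(K)

    total = burnin + iterations
    for it in range(total):
        # 1. ancestry origins
        like = np.where(X[:, :, None] == 1.0, p.T[None, :, :], 1.0 - p.T[None, :, :])  # (N, L, K)
        like = np.where(scored[:, :, None], like, 1.0)
        w = like * q[:, None, :]
        w_sum = w.sum(axis=2, keepdims=True)
        w /= w_sum
        u = rng.random((N, L, 1))
        z = (w.cumsum(axis=2) < u).sum(axis=2)  # (N, L) in 0..K-1
        zoh = onehot_eye[z]  # (N, L, K)
        zoh = np.where(scored[:, :, None], zoh, 0.0)
        # 2. cluster band frequencies
        n1 = np.einsum("nl,nlk->kl", Xf * scored, zoh)
        ntot = zoh.sum(axis=0).T  # (K, L)
        p = rng.beta(1.0 + n1, 1.0 + (ntot - n1))
        # 3. admixture vectors
        counts = zoh.sum(axis=1)  # (N, K)
        g = rng.gamma(dirichlet_alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)
        if it >= burnin:
            q_sum += q
            p_sum += p
            ll = np.log((like * q[:, None, :]).sum(axis=2))
            loglik[it - burnin] = ll[scored.any(axis=1)].sum()

    q_mean = q_sum / iterations
    p_mean = p_sum / iterations
    return AdmixtureResult(
        K=K,
        q=pd.DataFrame(q_mean, index=individuals, columns=[f"cluster{k}" for k in range(K)]),
        p=pd.DataFrame(p_mean, index=[f"cluster{k}" for k in range(K)], columns=aflp.markers),
        loglik_trace=loglik,
        seed=seed,
        burnin=burnin,
        iterations=iterations,
        excluded=excluded,
    )


def admixture_summary(result: AdmixtureResult, pmap: PopulationMap) -> pd.DataFrame:
    """Per-population mean and SD of admixture proportions."""
    pops = pmap.groups_for(result.q.index)
    df = result.q.copy()
    df["population"] = pops
    g = df.groupby("population")
    out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
    return out


def align_labels(results: Sequence[AdmixtureResult]) -> list[AdmixtureResult]:
    """Resolve label switching across runs by greedy q-correlation matching.

    The first run fixes the reference labelling; each later run's
    clusters are greedily matched to reference clusters in decreasing
    order of correlation between q columns (computed over the shared
    individuals).  Returns new results with permuted q/p columns.
    """
    if not results:
        return []
    Ks = {r.K for r in results}
    if len(Ks) != 1:
        raise ValueError(f"runs disagree on K: {sorted(Ks)}")
    K = results[0].K
    ref = results[0]
    aligned = [ref]
    for r in results[1:]:
        shared = ref.q.index.intersection(r.q.index)
        A = ref.q.loc[shared].to_numpy()
        B = r.q.loc[shared].to_numpy()
        corr = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                sa, sb = A[:, i], B[:, j]
                if sa.std() == 0 or sb.std() == 0:
                    corr[i, j] = -np.inf if i != j else 0.0
                else:
                    corr[i, j] = np.corrcoef(sa, sb)[0, 1]
        perm = [-1] * K
        used_i, used_j = set(), set()
        for _ in range(K):
            best = None
            for i in range(K):
                if i in used_i:
                    continue
                for j in range(K):
                    if j in used_j:
                        continue
                    if best is None or corr[i, j] > corr[best]:
                        best = (i, j)
            i, j = best
            perm[i] = j
            used_i.add(i)
            used_j.add(j)
        q = r.q.iloc[:, perm]
        q.columns = ref.q.columns
        p = r.p.iloc[perm]
        p.index = ref.p.index
        aligned.append(
            AdmixtureResult(
                K=K, q=q, p=p, loglik_trace=r.loglik_trace,
                seed=r.seed, burnin=r.burnin, iterations=r.iterations, excluded=r.excluded,
            )
        )
    return aligned
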