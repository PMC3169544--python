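"""Ancestry-informative markers and hybrid genotype classification.

Two classifiers live here:

* the four-way classification of dominant markers in a putative hybrid
  population relative to its two parents (parentA-like / parentB-like /
  intermediate / different), driven by pairwise AMOVA significance;
* the per-individual, per-site genotype classification of sequence
  polymorphisms that are strongly differentiated between the parents,
  producing the A-like / B-like / heterozygote / missing mosaic table
  used to visualise sex-chromosome ancestry.

Category semantics for a marker already known to distinguish the
parents: *parentA_like* — hybrid frequency significantly different from
parentB but not from parentA; *parentB_like* — the mirror image;
*different* — significantly different from both; *intermediate* —
significantly different from neither with the hybrid frequency inside
the closed parental interval.  The residual case (significant vs
neither but frequency outside the parental interval) is flagged
``outside_nonsignificant`` and counted with *intermediate* in headline
four-way totals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import popdiff
from .seqio import AFLPMatrix, AlignedLocus, PolymorphismTable, Sex

__all__ = [
    "MarkerClassification",
    "GenotypeClassTable",
    "select_informative",
    "classify_markers",
    "classify_sequence_genotypes",
]

CATEGORIES = ("parentA_like", "parentB_like", "intermediate", "different")


@dataclass(frozen=True)
class MarkerClassification:
    marker_id: str
    category: str
    outside_nonsignificant: bool
    p_vs_A: float
    p_vs_B: float
    freq_A: float
    freq_B: float
    freq_H: float


def _band_freq(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(x.mean()) if x.size else float("nan")


def select_informative(
    aflp: AFLPMatrix,
    groups: Sequence[str],
    parentA: str,
    parentB: str,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[str]:
    """Markers significantly differentiated between the two parents.

    Runs the binary-marker AMOVA between the parental groups only and
    keeps markers with permutation p ≤ ``alpha``, in stable input order.
    Monomorphic-between-parents markers are silently not selected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups = np.asarray(groups)
    mask = (groups == parentA) | (groups == parentB)
    rng = np.random.default_rng(seed)
    sub = aflp.bands.loc[mask]
    out = []
    for m in aflp.markers:
        col = sub[m].to_numpy(dtype=float)
        try:
            r = popdiff.fst_binary(col, groups[mask], n_perm=n_perm, seed=rng, locus_id=m)
        except ValueError:
            continue
        if r.p_value <= alpha:
            out.append(m)
    return out


def classify_markers(
    aflp: AFLPMatrix,
    groups: Sequence[str],
    hybrid: str,
    parentA: str,
    parentB: str,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[list[MarkerClassification], dict[str, int]]:
    """Four-way classification of (already informative) markers.

    Returns the per-marker classifications plus headline category counts
    (``outside_nonsignificant`` markers counted under *intermediate*,
    with the flagged tally reported separately under its own key).
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    res: list[MarkerClassification] = []
    for m in aflp.markers:
        col = aflp.bands[m].to_numpy(dtype=float)
        fa = _band_freq(col[groups == parentA])
        fb = _band_freq(col[groups == parentB])
        fh = _band_freq(col[groups == hybrid])

        def pair_p(pop: str) -> float:
            sel = (groups == hybrid) | (groups == pop)
            try:
                return popdiff.fst_binary(col[sel], groups[sel], n_perm=n_perm, seed=rng, locus_id=m).p_value
            except ValueError:
                return 1.0  # monomorphic within the pair: indistinguishable

        p_a = pair_p(parentA)
        p_b = pair_p(parentB)
        sig_a, sig_b = p_a <= alpha, p_b <= alpha
        outside = False
        if sig_a and sig_b:
            cat = "different"
        elif sig_b and not sig_a:
            cat = "parentA_like"
        elif sig_a and not sig_b:
            cat = "parentB_like"
        else:
            lo, hi = min(fa, fb), max(fa, fb)
            inside = lo <= fh <= hi
            cat = "intermediate"
            outside = not inside
        res.append(MarkerClassification(m, cat, outside, p_a, p_b, fa, fb, fh))
    counts = Counter(r.category for r in res)
    summary = {c: counts.get(c, 0) for c in CATEGORIES}
    summary["outside_nonsignificant"] = sum(r.outside_nonsignificant for r in res)
    return res, summary


@dataclass
class GenotypeClassTable:
    """Individual × site ancestry codes for strongly differentiated sites.

    Codes: ``A_like``, ``B_like``, ``heterozygote`` (diploid male-Z calls
    with one allele from each parental class), ``missing``.
    """

    codes: pd.DataFrame  # index individual, columns "locus:site"
    site_p_values: pd.Series
    n_unassignable_alleles: int


def classify_sequence_genotypes(
    tables: Mapping[str, PolymorphismTable],
    parentA: str,
    parentB: str,
    hybrid_or_all: Sequence[str] | None = None,
    alpha: float = 0.001,
    n_perm: int = 2_000,
    seed: int | None = None,
) -> GenotypeClassTable:
    """Classify per-individual genotypes at parent-diagnostic sites.

    For every polymorphic site, parental differentiation is tested with
    the single-site AMOVA permutation test on 0/1 allele mismatch
    distances between the two parental groups; sites with p ≤ ``alpha``
    are retained.  At a retained site each allele is assigned to the
    parent in which it is the more frequent; an individual's call is the
    class of its allele(s), ``heterozygote`` when a diploid male carries
    one allele of each class, and ``missing`` when no data (or when the
    allele is seen in neither parent, which also increments the
    unassignable-allele counter).
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, pd.Series] = {}
    site_p: dict[str, float] = {}
    unassignable = 0
    for locus_name, table in tables.items():
        pops = table.populations.loc[table.calls.index]
        par_mask = pops.isin([parentA, parentB]).to_numpy()
        par_groups = pops[par_mask].to_numpy()
        for site in table.sites:
            calls = table.calls[site.site_id]
            par_calls = calls[par_mask]
            ok = par_calls.notna().to_numpy()
            obs = par_calls[ok]
            if obs.nunique() < 2 or len(set(par_groups[ok])) < 2:
                continue  # not variable (or unrepresented) within the parents
            if min(Counter(par_groups[ok]).values()) < 2:
                continue
            # 0/1 mismatch distance == binary "is allele a" indicator per allele pair;
            # use the closed-form binary AMOVA on the factorized major allele
            codes_int, uniques = pd.factorize(obs)
            if len(uniques) == 2:
                r = popdiff.fst_binary(codes_int.astype(float), par_groups[ok], n_perm=n_perm, seed=rng)
            else:
                D = (codes_int[:, None] != codes_int[None, :]).astype(float)
                r = popdiff.phi_st(D, par_groups[ok], n_perm=n_perm, seed=rng)
            if r.p_value > alpha:
                continue
            label = f"{locus_name}:{site.site_id.split(':', 1)[1]}"
            site_p[label] = r.p_value
            # allele -> parental class by majority association
            assign: dict[object, str] = {}
            for allele in obs.unique():
                in_a = ((obs == allele) & (par_groups[ok] == parentA)).sum() / max((par_groups[ok] == parentA).sum(), 1)
                in_b = ((obs == allele) & (par_groups[ok] == parentB)).sum() / max((par_groups[ok] == parentB).sum(), 1)
                if in_a == in_b == 0:
                    continue
                assign[allele] = "A_like" if in_a >= in_b else "B_like"
            per_ind: dict[str, str] = {}
            samples = table.sample_ids.loc[table.calls.index]
            for sample_id in pd.unique(samples):
                seq_ids = samples.index[samples == sample_id]
                classes = []
                for sid in seq_ids:
                    v = calls.loc[sid]
                    if pd.isna(v):
                        continue
                    if v not in assign:
                        unassignable += 1
                        continue
                    classes.append(assign[v])
                if not classes:
                    per_ind[sample_id] = "missing"
                elif len(set(classes)) == 2:
                    per_ind[sample_id] = "heterozygote"
                else:
                    per_ind[sample_id] = classes[0]
            cols[label] = pd.Series(per_ind)
    codes = pd.DataFrame(cols)
    if hybrid_or_all is not None:
        codes = codes.reindex(index=list(hybrid_or_all))
    codes = codes.fillna("missing")
    return GenotypeClassTable(
        codes=codes,
        site_p_values=pd.Series(site_p),
        n_unassignable_alleles=unassignable,
    )
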