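"""Pairwise association (linkage disequilibrium) among polymorphisms.

Recent hybridization elevates LD genome-wide: an F1 carries one full
chromosome set from each parent, and with free recombination the excess
association decays by (1−r)^t per generation.  Comparing the fraction
of significantly associated polymorphism pairs across populations
therefore separates very recent hybrids (lab crosses, nascent swarms)
from an old, isolated hybrid species whose LD has relaxed to the
parental background.

Concrete test: two-sided Fisher's exact test on the 2×2 table of band
(or binarized allele) states, justified because dominant bands and
haploid/phased sequence calls give unambiguous tables.  Missing data are
pairwise-deleted; pairs monomorphic after deletion are excluded from the
denominator.  The headline summary is the percentage of *pairs*
significant at α; per-polymorphism significant fractions are also
emitted and feed the across-population ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import AFLPMatrix, PolymorphismTable

__all__ = ["LDSummary", "pair_exact_test", "ld_summary", "compare_ld", "binary_site_matrix"]


@dataclass
class LDSummary:
    population: str
    n_polymorphisms: int
    n_pairs_tested: int
    n_pairs_significant: int
    percent_significant: float
    alpha: float
    per_polymorphism_fraction: pd.Series
    pair_table: pd.DataFrame  # columns: locus_i, locus_j, p


def pair_exact_test(x, y) -> float:
    """Two-sided Fisher exact p for association between two binary vectors.

    Raises ``ValueError`` if either vector is monomorphic after pairwise
    deletion of missing entries (the pair is then undefined and must be
    excluded from summaries).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("pair monomorphic after pairwise deletion")
    table = np.array(
        [
            [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
            [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
        ]
    )
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binary_site_matrix(table: PolymorphismTable) -> pd.DataFrame:
    """Binarize a polymorphism table: 1 = carries the site's minor allele.

    Multi-allelic sites are reduced to minor-allele presence; missing
    calls stay missing.  Rows are sequences (haploid/phased units).
    """
    out = {}
    for site in table.sites:
        col = table.calls[site.site_id]
        counts = col.value_counts()
        if len(counts) < 2:
            continue
        minor = counts.index[-1]
        vals = np.where(col.isna(), np.nan, (col == minor).astype(float))
        out[site.site_id] = vals
    return pd.DataFrame(out, index=table.calls.index)


def ld_summary(
    data: AFLPMatrix | pd.DataFrame,
    alpha: float = 0.01,
    population: str = "",
) -> LDSummary:
    """Test all unordered polymorphism pairs and summarize significance."""
    df = data.bands if isinstance(data, AFLPMatrix) else data
    cols = [c for c in df.columns if df[c].dropna().nunique() >= 2]
    rows = []
    sig_count: dict[str, int] = {c: 0 for c in cols}
    test_count: dict[str, int] = {c: 0 for c in cols}
    for a, b in combinations(cols, 2):
        try:
            p = pair_exact_test(df[a], df[b])
        except ValueError:
            continue
        rows.append((a, b, p))
        test_count[a] += 1
        test_count[b] += 1
        if p <= alpha:
            sig_count[a] += 1
            sig_count[b] += 1
    pair_table = pd.DataFrame(rows, columns=["locus_i", "locus_j", "p"])
    n_tested = len(rows)
    n_sig = int((pair_table["p"] <= alpha).sum()) if n_tested else 0
    frac = pd.Series(
        {c: (sig_count[c] / test_count[c]) for c in cols if test_count[c] > 0}, dtype=float
    )
    return LDSummary(
        population=population,
        n_polymorphisms=len(cols),
        n_pairs_tested=n_tested,
        n_pairs_significant=n_sig,
        percent_significant=(100.0 * n_sig / n_tested) if n_tested else float("nan"),
        alpha=alpha,
        per_polymorphism_fraction=frac,
        pair_table=pair_table,
    )


def compare_ld(
    datasets: Mapping[str, AFLPMatrix | pd.DataFrame],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, LDSummary]]:
    """Compare LD levels across named populations/datasets.

    Returns ``(summary, pairwise_anova, summaries)``:

    * ``summary`` — one row per population sorted by descending percent
      of significant pairs, with the mean ± SD (across polymorphisms) of
      per-polymorphism significant fractions expressed as percentages;
    * ``pairwise_anova`` — one-way ANOVA p-values for each population
      pair computed on the per-polymorphism fractions, plus the overall
      test across all groups (row label ``<overall>``).
    """
    summaries = {name: ld_summary(d, alpha=alpha, population=name) for name, d in datasets.items()}
    rows = []
    for name, s in summaries.items():
        fr = s.per_polymorphism_fraction * 100
        rows.append(
            {
                "population": name,
                "n_polymorphisms": s.n_polymorphisms,
                "n_pairs_tested": s.n_pairs_tested,
                "percent_pairs_significant": s.percent_significant,
                "mean_percent_per_polymorphism": fr.mean(),
                "sd_percent_per_polymorphism": fr.std(ddof=1),
            }
        )
    summary = (
        pd.DataFrame(rows)
        .sort_values("percent_pairs_significant", ascending=False)
        .reset_index(drop=True)
    )
    names = list(summaries)
    arows = []
    groups = [summaries[n].per_polymorphism_fraction.to_numpy() for n in names]
    if len(names) >= 2 and all(len(g) >= 2 for g in groups):
        F, p = stats.f_oneway(*groups)
        arows.append(("<overall>", "", float(F), float(p)))
        for a, b in combinations(names, 2):
            F, p = stats.f_oneway(summaries[a].per_polymorphism_fraction.to_numpy(),
                                  summaries[b].per_polymorphism_fraction.to_numpy())
            arows.append((a, b, float(F), float(p)))
    pairwise = pd.DataFrame(arows, columns=["group_a", "group_b", "F", "p"])
    return summary, pairwise, summaries
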