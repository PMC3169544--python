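"""Species-specific diversity statistics, ANOVA, and clock calibration."""

import numpy as np
import pandas as pd
import pytest

from hybridhallmarks import divstats, simdata
from hybridhallmarks.seqio import Inheritance, PopulationMap

from conftest import make_locus


def pmap_for(pops_by_sample):
    return PopulationMap.from_pairs({s: (p, "U") for s, p in pops_by_sample.items()})


class TestSpeciesSpecificCounts:
    def test_private_minor_allele_counted_specific(self):
        # species X {AAT, AAT, AGT}, species Y {AAT}: X has 1 polymorphism whose
        # minor allele G is absent from Y -> proportion 1.0
        locus = make_locus(["AAT", "AAT", "AGT", "AAT"],
                           pops=["X", "X", "X", "Y"],
                           samples=["x1", "x2", "x3", "y1"])
        pmap = pmap_for({"x1": "X", "x2": "X", "x3": "X", "y1": "Y"})
        df = divstats.species_specific_counts({"g": locus}, pmap)
        row = df[(df.species == "X")].iloc[0]
        assert row.n_polymorphisms == 1
        assert row.n_species_specific_polymorphisms == 1
        assert row.proportion_specific_polys == 1.0

    def test_shared_alleles_never_specific(self):
        locus = make_locus(["AAT", "AGT", "AAT", "AGT"],
                           pops=["X", "X", "Y", "Y"],
                           samples=["x1", "x2", "y1", "y2"])
        pmap = pmap_for({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"})
        df = divstats.species_specific_counts({"g": locus}, pmap)
        assert (df.n_species_specific_polymorphisms == 0).all()
        assert (df.n_species_specific_haplotypes == 0).all()

    def test_haplotype_counting_with_missing_neutral(self):
        # "ANT" is compatible with both resolved haplotypes, so it joins the
        # first compatible class instead of founding a new one
        locus = make_locus(["AAT", "ANT", "AGT", "CCT", "CCT"],
                           pops=["X", "X", "X", "Y", "Y"],
                           samples=["x1", "x2", "x3", "y1", "y2"])
        pmap = pmap_for({"x1": "X", "x2": "X", "x3": "X", "y1": "Y", "y2": "Y"})
        df = divstats.species_specific_counts({"g": locus}, pmap)
        x = df[df.species == "X"].iloc[0]
        assert x.n_haplotypes == 2
        assert x.n_species_specific_haplotypes == 2

    def test_removing_a_species_cannot_decrease_others_specific_counts(self):
        params = simdata.default_scenario(
            seed=31,
            loci=[simdata.LocusSpec("L1", Inheritance.AUTOSOMAL, 300)],
            sample_sizes={"parentA": 6, "parentB": 6, "hybrid": 6},
        )
        locus = simdata.simulate_sequences(params)[0]
        pmap = PopulationMap.from_pairs(
            {r.sample_id: (r.population, "U") for r in locus.records}
        )
        full = divstats.species_specific_counts({"L1": locus}, pmap)
        # drop the hybrid's sequences and recount
        kept = [r for r in locus.records if r.population != "hybrid"]
        sub = make_locus([r.seq for r in kept],
                         pops=[r.population for r in kept],
                         samples=[r.sample_id for r in kept],
                         inheritance=Inheritance.AUTOSOMAL)
        reduced = divstats.species_specific_counts({"L1": sub}, pmap)
        for sp in ("parentA", "parentB"):
            before = full[full.species == sp].iloc[0].n_species_specific_polymorphisms
            after = reduced[reduced.species == sp].iloc[0].n_species_specific_polymorphisms
            assert after >= before

    def test_specific_never_exceeds_total(self, rng):
        for seed in (101, 102):
            params = simdata.default_scenario(
                seed=seed,
                loci=[simdata.LocusSpec("L", Inheritance.Z_LINKED, 250)],
                sample_sizes={"parentA": 5, "parentB": 5, "hybrid": 5},
            )
            locus = simdata.simulate_sequences(params)[0]
            pmap = PopulationMap.from_pairs(
                {r.sample_id: (r.population, "U") for r in locus.records}
            )
            df = divstats.species_specific_counts({"L": locus}, pmap)
            assert (df.n_species_specific_polymorphisms <= df.n_polymorphisms).all()
            assert (df.n_species_specific_haplotypes <= df.n_haplotypes).all()


class TestProportionSummary:
    def test_constant_proportions_mean_half_sd_zero(self):
        table = pd.DataFrame(
            {
                "gene": list("abc") * 2,
                "species": ["X"] * 3 + ["Y"] * 3,
                "proportion_specific_polys": [0.5] * 6,
                "proportion_specific_haps": [0.5] * 6,
            }
        )
        out = divstats.proportion_summary(table, "polymorphisms")
        assert out.loc["X", "mean"] == 0.5
        assert out.loc["X", "sd"] == 0.0

    def test_unequal_gene_sets_rejected(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "a"],
                "species": ["X", "X", "Y"],
                "proportion_specific_polys": [0.1, 0.2, 0.3],
                "proportion_specific_haps": [0.1, 0.2, 0.3],
            }
        )
        with pytest.raises(ValueError, match="unequal"):
            divstats.proportion_summary(table, "polymorphisms")


def anova_oracle(values, groups):
    """From-scratch sums of squares."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    grand = values.mean()
    ss_between = sum(
        (groups == g).sum() * (values[groups == g].mean() - grand) ** 2 for g in labels
    )
    ss_within = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in labels
    )
    df_b, df_w = len(labels) - 1, len(values) - len(labels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(25):
            g = int(rng.integers(2, 5))
            sizes = rng.integers(3, 8, size=g)
            values = np.concatenate([rng.normal(i * 0.3, 1.0, size=s) for i, s in enumerate(sizes)])
            groups = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
            res = divstats.anova_oneway(values, groups)
            assert res.F == pytest.approx(anova_oracle(values, groups), abs=1e-10)
            assert res.df_between == g - 1
            assert res.df_within == len(values) - g

    def test_all_values_equal_gives_f_zero(self):
        res = divstats.anova_oneway([0.4] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.F == 0.0

    def test_degenerate_separation_reports_floor_p(self):
        res = divstats.anova_oneway([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
        assert res.p <= np.finfo(float).tiny or res.F == np.inf


class TestCalibration:
    def test_unit_case(self):
        assert divstats.calibrate_split_time(2.30, 1.15).split_time_Myr == pytest.approx(1.0)

    def test_linearity(self):
        t1 = divstats.calibrate_split_time(1.7, 1.15).split_time_Myr
        t2 = divstats.calibrate_split_time(3.4, 1.15).split_time_Myr
        assert t2 == pytest.approx(2 * t1)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            divstats.calibrate_split_time(0.0, 1.15)


class TestHybridFraction:
    def test_basic_ratio(self):
        assert divstats.hybrid_fraction(10, 100) == pytest.approx(10.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            divstats.hybrid_fraction(-1, 10)


class TestHybridYoungerThanParents:
    def test_hybrid_has_lower_specific_proportion(self):
        # a recently founded hybrid has had little time to accumulate private
        # variants: its mean species-specific proportion should sit below both
        # parents' (median over replicate simulations)
        wins = 0
        reps = 8
        for seed in range(400, 400 + reps):
            params = simdata.default_scenario(
                seed=seed,
                loci=[simdata.LocusSpec(f"L{i}", Inheritance.Z_LINKED, 300) for i in range(4)],
                sample_sizes={"parentA": 8, "parentB": 8, "hybrid": 8},
            )
            loci = {l.locus_name: l for l in simdata.simulate_sequences(params)}
            pmap = params.population_map()
            df = divstats.species_specific_counts(loci, pmap)
            means = df.groupby("species")["proportion_specific_polys"].mean()
            if means["hybrid"] <= max(means["parentA"], means["parentB"]):
                wins += 1
        assert wins >= reps - 2
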