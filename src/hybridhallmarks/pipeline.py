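"""End-to-end orchestration: simulate → analyze → report.

One :class:`RunConfig` plus a mandatory seed drives the full battery of
diagnostics; outputs are TSV/JSON tables, figures, and a deterministic
``manifest.json`` holding every headline statistic.  The global seed is
expanded into independent named substreams (one per stage) so stages are
individually reproducible; repeated runs with the same config and seed
produce byte-identical manifests.

Stage failures are logged; stages that depend on the failed one are
skipped, and :func:`run_all` reports a non-empty ``failures`` map (the
CLI turns that into a non-zero exit code).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admix, datasets, divstats, ld, markers, phylo, plotting, popdiff, seqio, simdata
from .seqio import Inheritance

log = logging.getLogger("hybridhallmarks")

__all__ = ["RunConfig", "run_all", "stage_rng", "stage_seed"]


def stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def stage_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, name))


@dataclass
class RunConfig:
    """Thresholds follow the conventional gates for each analysis:
    0.05 for the marker screen/classification, 0.001 for the sequence
    genotype mosaic, 0.01 for LD pair significance."""

    seed: int
    out_dir: str = "results"
    scenario: simdata.ScenarioParams | None = None
    input_dir: str | None = None  # pre-made FASTA/TSV inputs instead of simulation
    n_markers: int = 250
    alpha_markers: float = 0.05
    alpha_sequence: float = 0.001
    alpha_ld: float = 0.01
    K_list: tuple[int, ...] = (2, 3, 4)
    bootstrap_reps: int = 2000
    mcmc_burnin: int = 5000
    mcmc_iterations: int = 20000
    n_perm: int = 10_000
    swarm_generations: int = 2
    cross_n: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for a in (self.alpha_markers, self.alpha_sequence, self.alpha_ld):
            if not 0 < a < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen = raw.pop("scenario", None)
        cfg = cls(**{k: (tuple(v) if k == "K_list" else v) for k, v in raw.items()})
        if scen is not None:
            loci = scen.pop("loci", None)
            params = simdata.ScenarioParams(seed=scen.pop("seed", cfg.seed), **scen)
            if loci is not None:
                params.loci = [
                    simdata.LocusSpec(d["name"], Inheritance(d["inheritance"]), int(d["length"]))
                    for d in loci
                ]
            cfg.scenario = params
        return cfg


def _load_inputs(cfg: RunConfig):
    base = Path(cfg.input_dir)
    pmap = seqio.read_population_map(base / "population_map.tsv")
    aflp = seqio.read_aflp_matrix(base / "aflp.tsv")
    loci = []
    manifest = yaml.safe_load((base / "loci.yaml").read_text())
    for entry in manifest:
        loci.append(seqio.read_fasta_alignment(base / entry["path"], entry["inheritance"]))
    return loci, aflp, pmap


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the results bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        log.propagate = False
    manifest: dict = {"seed": config.seed, "stages": {}}
    failures: dict[str, str] = {}
    timings: dict[str, float] = {}
    bundle: dict = {"manifest": manifest, "failures": failures}

    def stage(name: str, fn, *deps: str):
        missing = [d for d in deps if d in failures or d in skipped]
        if missing:
            skipped.add(name)
            log.warning("stage %s skipped (failed/skipped dependencies: %s)", name, missing)
            return None
        t0 = time.perf_counter()
        try:
            res = fn()
            manifest["stages"][name] = "ok"
            return res
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            failures[name] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", name, failures[name])
            return None
        finally:
            timings[name] = round(time.perf_counter() - t0, 3)

    skipped: set[str] = set()

    # --- data ---------------------------------------------------------------
    def data_stage():
        if config.input_dir is not None:
            loci, aflp, pmap = _load_inputs(config)
            manifest["data"] = {"source": "inputs", "n_loci": len(loci), "aflp_shape": list(aflp.shape)}
        else:
            params = config.scenario or simdata.default_scenario(stage_seed(config.seed, "scenario"))
            params = dataclasses.replace(params, seed=stage_seed(config.seed, "simulate"))
            ds = simdata.simulate_dataset(params, n_markers=config.n_markers)
            loci, aflp, pmap = ds.loci, ds.aflp, ds.population_map
            manifest["data"] = {
                "source": "simulated",
                "n_loci": len(loci),
                "aflp_shape": list(aflp.shape),
                "alpha": params.alpha,
            }
            for locus in loci:
                seqio.write_fasta_alignment(locus, out / f"{locus.locus_name}.fasta")
            seqio.write_aflp_matrix(aflp, out / "aflp.tsv")
            seqio.write_population_map(pmap, out / "population_map.tsv")
        return loci, aflp, pmap

    data = stage("data", data_stage)
    if data is None:
        _finish(out, manifest, failures, timings)
        return bundle
    loci, aflp, pmap = data
    pops_aflp = pmap.groups_for(aflp.individuals)
    pop_labels = pmap.populations()
    parentA, parentB, hybrid = (pop_labels + [None, None, None])[:3]

    tables = {l.locus_name: seqio.extract_polymorphisms(l) for l in loci if l.n_sequences >= 2}
    bundle["tables"] = tables

    # --- sequence F_ST ------------------------------------------------------
    def fst_stage():
        rows = []
        pairwise_frames = {}
        for name, table in tables.items():
            D = popdiff.pairwise_distances(table)
            groups = table.populations.loc[table.calls.index].to_numpy()
            r = popdiff.phi_st(
                D, groups, n_perm=config.n_perm, seed=stage_rng(config.seed, f"fst:{name}"), locus_id=name
            )
            rows.append(r)
            pairwise_frames[name] = popdiff.pairwise_fst(D, groups)
        df = popdiff.results_table(rows)
        df.to_csv(out / "sequence_fst.tsv", sep="\t", index=False)
        pw = pd.concat(pairwise_frames, names=["locus", "population"])
        pw.to_csv(out / "sequence_fst_pairwise.tsv", sep="\t")
        manifest["sequence_fst"] = {
            r.locus_id: {"phi_st": round(r.phi_st, 6), "p": round(r.p_value, 6)} for r in rows
        }
        return rows, pairwise_frames

    stage("sequence_fst", fst_stage)

    # --- genotype mosaic ----------------------------------------------------
    def genotype_stage():
        gt = markers.classify_sequence_genotypes(
            tables, parentA, parentB, alpha=config.alpha_sequence,
            n_perm=max(config.n_perm, int(2 / config.alpha_sequence)),
            seed=stage_seed(config.seed, "genotypes"),
        )
        gt.codes.to_csv(out / "genotype_classes.tsv", sep="\t")
        order = [s for p in pop_labels for s in pmap.samples_of(p)]
        if not gt.codes.empty:
            plotting.genotype_heatmap(gt.codes, str(out / "genotype_mosaic.png"), row_order=order)
        manifest["genotype_classes"] = {
            "n_sites": int(gt.codes.shape[1]),
            "n_unassignable_alleles": gt.n_unassignable_alleles,
        }
        return gt

    stage("genotype_classes", genotype_stage)

    # --- marker screen + classification ------------------------------------
    def marker_stage():
        poly = aflp.polymorphic()
        groups = pmap.groups_for(poly.individuals)
        informative = markers.select_informative(
            poly, groups, parentA, parentB, alpha=config.alpha_markers,
            n_perm=config.n_perm, seed=stage_seed(config.seed, "screen"),
        )
        sub = poly.subset(markers=informative)
        cls, counts = markers.classify_markers(
            sub, groups, hybrid, parentA, parentB, alpha=config.alpha_markers,
            n_perm=config.n_perm, seed=stage_seed(config.seed, "classify"),
        )
        pd.DataFrame([dataclasses.asdict(c) for c in cls]).to_csv(
            out / "marker_classification.tsv", sep="\t", index=False
        )
        (out / "marker_counts.json").write_text(json.dumps(counts, indent=2, sort_keys=True))
        manifest["markers"] = {"n_informative": len(informative), **counts}
        return sub, informative

    marker_res = stage("markers", marker_stage)

    # --- admixture ----------------------------------------------------------
    def admix_stage():
        sub, _ = marker_res
        results = {}
        for K in config.K_list:
            r = admix.estimate_admixture(
                sub, K=K, burnin=config.mcmc_burnin, iterations=config.mcmc_iterations,
                seed=stage_seed(config.seed, f"admix:K{K}"),
            )
            r.q.to_csv(out / f"admixture_q_K{K}.tsv", sep="\t")
            plotting.admixture_bars(
                r.q, pd.Series(pmap.groups_for(r.q.index), index=r.q.index),
                str(out / f"admixture_K{K}.png"),
            )
            summary = admix.admixture_summary(r, pmap)
            manifest.setdefault("admixture", {})[f"K{K}"] = {
                pop: [round(v, 4) for v in summary.loc[pop, "mean"].tolist()]
                for pop in summary.index
            }
            results[K] = r
        return results

    stage("admixture", admix_stage, "markers")

    # --- linkage disequilibrium --------------------------------------------
    def ld_stage():
        poly = aflp.polymorphic()
        datasets_by_pop = {
            p: poly.subset(sample_ids=pmap.samples_of(p)) for p in pop_labels
        }
        summary, pairwise, _ = ld.compare_ld(datasets_by_pop, alpha=config.alpha_ld)
        summary.to_csv(out / "ld_summary.tsv", sep="\t", index=False)
        pairwise.to_csv(out / "ld_anova.tsv", sep="\t", index=False)
        manifest["ld"] = {
            row.population: round(row.percent_pairs_significant, 4)
            for row in summary.itertuples()
        }
        return summary

    stage("ld", ld_stage)

    # --- species-specific diversity ----------------------------------------
    def divstats_stage():
        locus_map = {l.locus_name: l for l in loci}
        table = divstats.species_specific_counts(locus_map, pmap, tables=tables)
        table.to_csv(out / "diversity_table.tsv", sep="\t", index=False)
        payload = {}
        for statistic in ("polymorphisms", "haplotypes"):
            summ = divstats.proportion_summary(table, statistic)
            col = "proportion_specific_polys" if statistic == "polymorphisms" else "proportion_specific_haps"
            an = divstats.anova_oneway(table[col], table["species"])
            payload[statistic] = {
                "mean": {sp: round(v, 4) for sp, v in summ["mean"].items()},
                "sd": {sp: round(v, 4) for sp, v in summ["sd"].items()},
                "anova": {"F": round(an.F, 4), "df": [an.df_between, an.df_within], "p": round(an.p, 6)},
            }
        (out / "diversity_summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest["diversity"] = payload
        return table

    stage("diversity", divstats_stage)

    # --- phylogeny ----------------------------------------------------------
    def phylo_stage():
        poly = aflp.polymorphic()
        tree = phylo.bootstrap_support(
            poly, n_reps=config.bootstrap_reps, seed=stage_seed(config.seed, "bootstrap")
        )
        seqio.write_newick(tree, out / "nj_tree.nwk")
        plotting.tree_sketch(tree, str(out / "nj_tree.png"))
        supports = [
            getattr(nd, "support")
            for nd in tree.preorder_node_iter()
            if hasattr(nd, "support")
        ]
        manifest["phylogeny"] = {
            "n_internal_edges": len(supports),
            "median_support": round(float(np.median(supports)), 2) if supports else None,
        }
        return tree

    stage("phylogeny", phylo_stage)

    # --- trait mapping on the species backbone ------------------------------
    def trait_stage():
        import dendropy

        tree = dendropy.Tree.get(data=datasets.backbone_newick(), schema="newick")
        traits = datasets.species_traits().drop(index="appalachiensis")
        recs = phylo.fitch_map(tree, traits, outgroup="garamas")
        rows = [
            {
                "trait": r.trait,
                "n_changes": r.n_changes,
                "n_reconstructions": len(r.reconstructions),
                "change_edges": "; ".join(f"{a}->{b}" for a, b in r.change_edges),
            }
            for r in recs
        ]
        pd.DataFrame(rows).to_csv(out / "trait_reconstruction.tsv", sep="\t", index=False)
        manifest["traits"] = {r.trait: r.n_changes for r in recs}
        return recs

    stage("traits", trait_stage)

    _finish(out, manifest, failures, timings)
    return bundle


def _finish(out: Path, manifest: dict, failures: dict, timings: dict) -> None:
    manifest["failures"] = failures
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True) + "\n")
    for name, dur in timings.items():
        log.info("stage %-16s %8.3fs", name, dur)
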