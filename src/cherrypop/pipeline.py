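"""End-to-end pipeline: data -> tables -> networks -> (optional) ABC.

One TOML config drives the full analysis.  A master seed is fanned out to the
stages through named ``numpy.random.SeedSequence`` children, so any stage can
be rerun in isolation with the seed recorded in the manifest and every output
is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cherrypop import __version__
from cherrypop.errors import InputError
from cherrypop.seqdata import (
    read_dataset,
    recode_indels,
    collapse_haplotypes,
    summarize_alignment,
    write_haplotype_table,
    write_haplotype_fasta,
    write_dataset_fasta,
)
from cherrypop.distances import pairwise_differences, tn93
from cherrypop.popstats import stats_table
from cherrypop.amova import amova, pairwise_fst
from cherrypop.network import median_joining, network_summaries
from cherrypop.simulate import Scenario, make_fixture, summarize
from cherrypop.abc import build_reference, model_choice, estimate_parameters, confusion_errors

log = logging.getLogger("cherrypop.pipeline")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    # input: either a fixture preset or fasta+metadata
    fixture_preset: str | None = None
    fasta: Path | None = None
    metadata: Path | None = None
    locus_name: str = "locus"
    recode_mode: str = "simple_indel_coding"
    include_indel_characters: bool = True
    n_sims: int = 1000
    n_boot: int = 200
    n_perm: int = 1000
    network_epsilon: int = 0
    abc_enabled: bool = False
    abc_scenarios: list[Path] = field(default_factory=list)
    abc_n_per_scenario: int = 2000
    abc_retain: float = 0.01
    abc_n_pods: int = 0
    abc_L: int = 800

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        inp = raw.get("input", {})
        stats = raw.get("stats", {})
        abc_ = raw.get("abc", {})
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            fixture_preset=inp.get("fixture"),
            fasta=Path(inp["fasta"]) if "fasta" in inp else None,
            metadata=Path(inp["metadata"]) if "metadata" in inp else None,
            locus_name=inp.get("locus_name", "locus"),
            recode_mode=raw.get("recode", {}).get("mode", "simple_indel_coding"),
            include_indel_characters=raw.get("recode", {}).get(
                "include_indel_characters", True
            ),
            n_sims=int(stats.get("n_sims", 1000)),
            n_boot=int(stats.get("n_boot", 200)),
            n_perm=int(stats.get("n_perm", 1000)),
            network_epsilon=int(raw.get("network", {}).get("epsilon", 0)),
            abc_enabled=bool(abc_.get("enabled", False)),
            abc_scenarios=[Path(p) for p in abc_.get("scenarios", [])],
            abc_n_per_scenario=int(abc_.get("n_per_scenario", 2000)),
            abc_retain=float(abc_.get("retain", 0.01)),
            abc_n_pods=int(abc_.get("n_pods", 0)),
            abc_L=int(abc_.get("L", 800)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.fixture_preset is None and (self.fasta is None or self.metadata is None):
            raise InputError("config needs either input.fixture or input.fasta+metadata")
        for p in (self.fasta, self.metadata, *self.abc_scenarios):
            if p is not None and not Path(p).exists():
                raise InputError(f"input file does not exist: {p}")


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``cfg.outdir``.

    Returns the manifest dict.  Any stage failure raises with a stage-tagged
    message; outputs of completed stages are left in place.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    seeds = _stage_seeds(
        cfg.seed, ["fixture", "stats", "amova", "fst", "abc_ref", "abc_pods"]
    )
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "outputs": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.2fs", name, timings[name])
            return result

        return deco

    @stage("input")
    def ds():
        if cfg.fixture_preset:
            sd = make_fixture(cfg.fixture_preset, seed=seeds["fixture"])
            write_dataset_fasta(
                sd.dataset, out / "input_alignment.fasta", out / "input_metadata.tsv"
            )
            sd.write_truth(out / "input_truth.json")
            manifest["outputs"] += [
                "input_alignment.fasta", "input_metadata.tsv", "input_truth.json",
            ]
            return sd.dataset
        return read_dataset(cfg.fasta, cfg.metadata, locus_name=cfg.locus_name)

    @stage("recode")
    def ra():
        return recode_indels(ds, mode=cfg.recode_mode)

    @stage("haplotypes")
    def ht():
        table = collapse_haplotypes(ra, relabel_by_frequency=True)
        write_haplotype_table(table, out / "haplotype_counts.tsv")
        write_haplotype_fasta(table, out / "haplotypes.fasta")
        summ = summarize_alignment(ra, cfg.include_indel_characters)
        with open(out / "alignment_summary.json", "w") as fh:
            json.dump(
                {
                    "length_bp": summ.length_bp,
                    "gc_content": round(summ.gc_content, 4),
                    "polymorphic_sites": summ.S,
                    "parsimony_informative_sites": summ.S_pi,
                    "n_haplotypes": summ.n_haplotypes,
                },
                fh,
                indent=2,
            )
        manifest["outputs"] += [
            "haplotype_counts.tsv", "haplotypes.fasta", "alignment_summary.json",
        ]
        return table

    @stage("distances")
    def dms():
        dm_p = pairwise_differences(ht)
        dm_t = tn93(ht)
        dm_p.write_tsv(out / "distances_p.tsv")
        dm_t.write_tsv(out / "distances_tn93.tsv")
        manifest["outputs"] += ["distances_p.tsv", "distances_tn93.tsv"]
        return dm_p, dm_t

    @stage("popstats")
    def stats_df():
        partitions = {"all": list(ht.demes)}
        for grp, demes in ht.groups().items():
            partitions[grp] = demes
        df = stats_table(
            ht, partitions, n_sims=cfg.n_sims, n_boot=cfg.n_boot, seed=seeds["stats"]
        )
        df.to_csv(out / "diversity_neutrality.tsv", sep="\t", index=False)
        manifest["outputs"].append("diversity_neutrality.tsv")
        return df

    @stage("amova")
    def amova_res():
        if len(ht.groups()) < 2:
            log.info("single group: AMOVA skipped")
            return None
        res = amova(ht, dms[1], n_perm=cfg.n_perm, seed=seeds["amova"])
        res.to_dataframe().to_csv(out / "amova.tsv", sep="\t", index=False)
        manifest["outputs"].append("amova.tsv")
        return res

    @stage("fst")
    def fst_res():
        res = pairwise_fst(ht, dms[1], n_perm=cfg.n_perm, seed=seeds["fst"])
        res.write_tsv(out / "pairwise_fst.tsv")
        manifest["outputs"].append("pairwise_fst.tsv")
        return res

    @stage("network")
    def net():
        n = median_joining(ht, epsilon=cfg.network_epsilon)
        n.write_graphml(out / "network.graphml")
        n.write_edgelist(out / "network_edges.tsv")
        network_summaries(n).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        manifest["outputs"] += ["network.graphml", "network_edges.tsv", "network_nodes.tsv"]
        return n

    if cfg.abc_enabled:

        @stage("abc")
        def abc_out():
            scenarios = [Scenario.read(p) for p in cfg.abc_scenarios]
            sizes = {
                d: int(ht.counts[:, j].sum()) for j, d in enumerate(ht.demes)
            }
            rt = build_reference(
                scenarios,
                cfg.abc_n_per_scenario,
                sizes,
                seed=seeds["abc_ref"],
                L=cfg.abc_L,
            )
            rt.save(out / "reference_table.tsv", out / "reference_table.json")
            res = model_choice(rt, summarize(ds), retain=cfg.abc_retain)
            res.parameter_posteriors = estimate_parameters(
                rt, summarize(ds), res.selected_scenario, retain=cfg.abc_retain
            )
            if cfg.abc_n_pods:
                t1, t2 = confusion_errors(
                    scenarios, rt, n_pods=cfg.abc_n_pods,
                    retain=cfg.abc_retain, seed=seeds["abc_pods"],
                )
                res.type1_error, res.type2_error = t1, t2
            with open(out / "abc_result.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=2)
            manifest["outputs"] += [
                "reference_table.tsv", "reference_table.json", "abc_result.json",
            ]
            return res

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "timings.log", "w") as fh:
        for k, v in timings.items():
            fh.write(f"{k}\t{v:.3f}s\n")
    return manifest
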