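"""Haplotype collapsing, alignment summaries, and diversity/neutrality tables.

Reads the datasets written by 01_generate_datasets.py, recodes indels as
binary characters, collapses haplotypes, and writes one diversity table per
dataset (per group and overall): n, k, gene diversity h, nucleotide
diversity pi, Tajima's D and Fu's Fs with coalescent p-values, and the
mismatch-distribution SSD / raggedness with bootstrap p-values.
"""

import argparse
import json
from pathlib import Path

from cherrypop.popstats import stats_table
from cherrypop.seqdata import (
    collapse_haplotypes,
    read_dataset,
    recode_indels,
    summarize_alignment,
    write_haplotype_fasta,
    write_haplotype_table,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/diversity"))
    ap.add_argument("--n-sims", type=int, default=1000)
    ap.add_argument("--n-boot", type=int, default=200)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for preset in ("five_group", "three_group"):
        ds = read_dataset(
            args.datadir / f"{preset}.fasta",
            args.datadir / f"{preset}.meta.tsv",
            locus_name=preset,
        )
        ra = recode_indels(ds)
        ht = collapse_haplotypes(ra, relabel_by_frequency=True)
        summ = summarize_alignment(ra)
        write_haplotype_table(ht, args.outdir / f"{preset}.haplotype_counts.tsv")
        write_haplotype_fasta(ht, args.outdir / f"{preset}.haplotypes.fasta")
        with open(args.outdir / f"{preset}.alignment_summary.json", "w") as fh:
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
        partitions = {"all": list(ht.demes)}
        partitions.update(ht.groups())
        df = stats_table(ht, partitions, n_sims=args.n_sims,
                         n_boot=args.n_boot, seed=args.seed)
        df.to_csv(args.outdir / f"{preset}.diversity_neutrality.tsv",
                  sep="\t", index=False)
        print(f"{preset}: {summ.S} polymorphic sites, {ht.n_haplotypes} haplotypes")
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
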