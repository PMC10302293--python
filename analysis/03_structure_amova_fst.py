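"""Hierarchical AMOVA and pairwise Phi_ST.

On the five-group dataset the AMOVA hierarchy groups the demes into the
three deep lineages (Chinese complex CC+WC+RC, European EC, outgroup MC);
on the three-group dataset every deme is its own group.  Both use Tamura–Nei
distances between haplotypes, squared in the variance decomposition.
"""

import argparse
from pathlib import Path

from cherrypop.amova import amova, pairwise_fst
from cherrypop.distances import tn93
from cherrypop.seqdata import collapse_haplotypes, read_dataset, recode_indels

LINEAGES = {"CC": "Chinese", "WC": "Chinese", "RC": "Chinese",
            "EC": "European", "MC": "Outgroup"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/structure"))
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for preset, hierarchy in (("five_group", LINEAGES), ("three_group", None)):
        ds = read_dataset(args.datadir / f"{preset}.fasta",
                          args.datadir / f"{preset}.meta.tsv", locus_name=preset)
        ht = collapse_haplotypes(recode_indels(ds), relabel_by_frequency=True)
        dm = tn93(ht)
        res = amova(ht, dm, hierarchy=hierarchy, n_perm=args.n_perm,
                    seed=args.seed)
        res.to_dataframe().to_csv(args.outdir / f"{preset}.amova.tsv",
                                  sep="\t", index=False)
        fst = pairwise_fst(ht, dm, n_perm=args.n_perm, seed=args.seed + 1)
        fst.write_tsv(args.outdir / f"{preset}.pairwise_fst.tsv")
        print(f"{preset}: F_CT={res.F_CT:.4f} (p={res.p_CT:.4f}), "
              f"F_SC={res.F_SC:.4f}, F_ST={res.F_ST:.4f} (p={res.p_ST:.4f})")
        print(fst.to_dataframe().round(4).to_string())


if __name__ == "__main__":
    main()
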