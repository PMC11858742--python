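"""Substrate affinity (SRA) of families through time.

Scores each family's carbonate-vs-siliciclastic affinity per sub-period
interval against a binomial null on the combined dataset's background
lithology mix, for every dataset.  Writes results/affinity/.
"""

from _common import SEED, binned_partition, outdir


from paleodark.affinity import affinity_table


def main():
    part, _ = binned_partition(bins="sub_period")
    out = outdir("affinity")

    tab = affinity_table(part, B=5000, seed=SEED, n_min=5)
    tab.to_csv(out / "sra.csv", index=False)

    ok = tab[tab["ok"]]
    print(f"scored {len(ok)} family-interval-dataset combinations "
          f"({len(tab) - len(ok)} withheld for small n or degenerate "
          "background)")
    strong = ok[ok["sra"].abs() > 2].sort_values("sra")
    for row in strong.head(5).itertuples():
        side = "carbonate" if row.sra > 0 else "siliciclastic"
        print(f"  {row.family} / {row.interval} / dataset {row.dataset}: "
              f"SRA {row.sra:+.2f} ({side} affinity)")


if __name__ == "__main__":
    main()
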