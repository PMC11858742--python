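"""Model-based drivers of diversity, per dataset.

Fits GLS-AR(1) regressions of per-bin genus richness on sampling proxies
(collections, Good's u) for every covariate subset, ranks by AICc, and
compares which covariates the best model keeps for each dataset — the
analysis where the choice of dataset can flip the interpretation from
environmental control to sampling control.  Writes results/drivers/.
"""

import pandas as pd

from _common import binned_partition, outdir

from paleodark.diversity import raw_diversity
from paleodark.drivers import dredge, prepare_covariates


def main():
    part, _ = binned_partition()
    out = outdir("drivers")

    raw = raw_diversity(part, taxon_col="genus")
    tables = []
    for label in ("A", "B", "C", "D"):
        sub = raw[raw["dataset"] == label].set_index("bin")
        y = sub["n_taxa"].astype(float)
        cov = pd.DataFrame({"colls": sub["n_collections"].astype(float),
                            "goods_u": sub["goods_u"]})
        cov_t, rep = prepare_covariates(cov)
        keep = cov_t.index.intersection(y.index[y.notna()])
        tab = dredge(y.loc[keep].to_numpy(), cov_t.loc[keep])
        tab.insert(0, "dataset", label)
        tables.append(tab.drop(columns="covariates"))
        best = tab.iloc[0]
        print(f"dataset {label}: best model {best['model']} "
              f"(df={best['df']}, loglik={best['loglik']:.2f}, "
              f"AICc={best['AICc']:.2f}; n={len(keep)} bins, "
              f"{rep['n_dropped_bins']} dropped)")
    pd.concat(tables, ignore_index=True).to_csv(out / "model_selection.csv",
                                                index=False)


if __name__ == "__main__":
    main()
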