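"""Compare metadata composition between datasets.

Tabulates lithology, grain-size, taxonomic-rank and taphonomic-grade
proportions per dataset, tests dark-vs-published differences (chi-squared),
and splits repository contributions into domestic vs foreign research.
Writes results/composition/.
"""

import pandas as pd

from _common import binned_partition, outdir

from paleodark.composition import (chi_squared, composition_counts,
                                   composition_table, domestic_foreign)


def main():
    part, spec = binned_partition()
    out = outdir("composition")

    frames = []
    for var in ("lithology", "grainsize", "rank"):
        t = composition_table(part, var).reset_index()
        t.insert(0, "variable", var)
        frames.append(t)
    taph = composition_table(part, "taph_grade", unit="specimen",
                             specimens=spec).reset_index()
    taph.insert(0, "variable", "taph_grade")
    frames.append(taph)
    comp = pd.concat(frames, ignore_index=True)
    comp.to_csv(out / "proportions.csv", index=False)

    lith = composition_table(part, "lithology")
    print(f"dark data: {100 * lith.loc['A', 'carbonate']:.1f}% carbonate-"
          f"hosted vs {100 * lith.loc['B', 'carbonate']:.1f}% in the "
          "published record")

    tests = []
    for var in ("lithology", "grainsize"):
        res = chi_squared(composition_counts(part, var, datasets=("A", "B")))
        tests.append({"variable": var, "X2": res.statistic, "df": res.df,
                      "p": res.p_value})
        print(f"{var}: X2 = {res.statistic:.2f}, df = {res.df}, "
              f"p = {res.p_value:.3g}")
    pd.DataFrame(tests).to_csv(out / "tests.csv", index=False)

    dom = domestic_foreign(part, top_k=15)
    dom.to_csv(out / "domestic_foreign.csv", index=False)
    d = dom[dom["dataset"] == "D"]
    print("top housing countries (combined): "
          + ", ".join(f"{r.country_housed} {r.pct_total:.0f}%"
                      for r in d.head(3).itertuples()))


if __name__ == "__main__":
    main()
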