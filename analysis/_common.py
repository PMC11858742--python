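"""Shared plumbing for the numbered analysis scripts: load (or generate)
the synthetic study dataset and return the binned four-way partition."""

from pathlib import Path

import paleodark as pdk
from paleodark.occurrence import assign_bins, deduplicate, partition
from paleodark.synthetic import Scenario, write_outputs

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 1


def load_dataset():
    """Occurrences + specimens under the default study conditions
    (generated on first use, cached under results/synthetic)."""
    syn = RESULTS / "synthetic"
    occ_path = syn / "occurrences.csv"
    if not occ_path.exists():
        occ, spec, truth = pdk.simulate(Scenario(), seed=SEED)
        write_outputs(occ, spec, truth, syn)
    import pandas as pd
    occ = pdk.read_occurrences(occ_path)
    spec = pd.read_csv(syn / "specimens.csv")
    return occ, spec


def binned_partition(bins="stage"):
    occ, spec = load_dataset()
    occ = deduplicate(occ)
    table = pdk.palaeozoic_stages() if bins == "stage" \
        else pdk.palaeozoic_subperiods()
    return partition(assign_bins(occ, table)), spec


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
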