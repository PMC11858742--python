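"""Generate the synthetic study dataset.

Draws the default scenario — two sampling channels (museum-only "dark"
and published) over ~120 taxa, sized to yield roughly 1000/1250/590
dark/published/PBDB occurrences — and writes the occurrence, specimen and
ground-truth tables under results/synthetic/.
"""

from _common import RESULTS, SEED

import paleodark as pdk
from paleodark.occurrence import deduplicate, partition
from paleodark.synthetic import Scenario, write_outputs


def main():
    occ, spec, truth = pdk.simulate(Scenario(), seed=SEED)
    paths = write_outputs(occ, spec, truth, RESULTS / "synthetic")
    part = partition(deduplicate(occ))
    print(f"wrote {paths['occurrences']}")
    print(f"occurrences: {len(occ)} raw; after per-collection dedup "
          f"{part.sizes['D']} (dark {part.sizes['A']}, "
          f"published {part.sizes['B']}, PBDB {part.sizes['C']})")
    print(f"specimens: {len(spec)}; taxa: {len(truth)}")


if __name__ == "__main__":
    main()
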