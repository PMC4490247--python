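"""Generate the synthetic CASS study dataset used by the downstream steps.

Writes a mothur-dialect OTU table (3 sites x 10 depth intervals), its
taxonomy, a depth-resolved geochemistry CSV, and the generating ground
truth (zone of every sample, guild fractions) under results/data/.
"""

import json
from pathlib import Path

from cassmicro import io
from cassmicro.synthetic import SyntheticConfig, gen_geochem_profile, gen_otu_table

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    table, truth = gen_otu_table(cfg)
    io.write_shared(table, OUT / "synthetic.shared")
    io.write_constaxonomy(table, OUT / "synthetic.cons.taxonomy")
    io.write_geochem(gen_geochem_profile(cfg), OUT / "synthetic_geochem.csv")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    sizes = table.totals()
    print(f"wrote {table.n_samples} samples x {len(table.otu_ids)} OTUs to {OUT}")
    print(f"library sizes: min {sizes.min()}, mean {sizes.mean():.0f}, max {sizes.max()}")
    zones = sorted(set(truth["zones"].values()))
    for z in zones:
        n = sum(1 for v in truth["zones"].values() if v == z)
        print(f"zone {z}: {n} samples")


if __name__ == "__main__":
    main()
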