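"""Alpha diversity with rarefaction CIs, plus the across-site ANOVA.

Rarefies every sample to 1498 reads (100 independent draws), computes
Good's coverage, Chao1, Shannon, inverse Simpson and evenness with 95%
CIs, and tests whether inverse Simpson differs across the three sites.
Writes results/diversity.tsv and results/anova.tsv.
"""

from pathlib import Path

import pandas as pd

from cassmicro import community, io

SEED = 42
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = io.load_otu_table(
        ROOT / "data" / "synthetic.shared", ROOT / "data" / "synthetic.cons.taxonomy"
    )
    records = community.alpha_with_ci(table, depth=1498, n_iter=100, seed=SEED)
    div = community.diversity_frame(records)
    div.to_csv(ROOT / "diversity.tsv", sep="\t", index=False, float_format="%.10g")

    sites: dict[str, list[float]] = {}
    for r in records:
        sites.setdefault(r.sample_id.split("_")[0], []).append(r.inv_simpson)
    f, p = community.anova_oneway([sites[s] for s in sorted(sites)])
    pd.DataFrame(
        [{"index": "inv_simpson", "grouping": "site", "F": f, "p": p}]
    ).to_csv(ROOT / "anova.tsv", sep="\t", index=False, float_format="%.10g")

    print(f"{len(records)} samples at depth 1498")
    print(
        f"coverage mean {div['goods_coverage'].mean():.3f}; "
        f"inverse Simpson range {div['inv_simpson'].min():.1f}-{div['inv_simpson'].max():.1f}"
    )
    print(f"site means (inv Simpson): "
          + ", ".join(f"{s}={pd.Series(v).mean():.1f}" for s, v in sorted(sites.items())))
    print(f"ANOVA across sites: F={f:.2f}, p={p:.2g}"
          + (" -> diversity differs significantly by site" if p < 0.01 else ""))


if __name__ == "__main__":
    main()
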