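#!/usr/bin/env python
"""Partition HC bivalent regions into three clusters by factor occupancy.

Each bivalent region (+/- 1 kbp) is summarized by the summed RPM of EZH2,
PolII, TAF1 and TCF12; K-means (k=3 on log2, z-scored features) and
semantic relabeling give: cluster 1 = PolII/TAF1-high (transcriptionally
primed), cluster 2 = EZH2-high (PRC2-defined), cluster 3 = intermediate.
Writes factor_features.tsv and bivalent_clusters.tsv.
"""

import argparse

from bivatlas.io import load_config
from bivatlas.pipeline import run_cluster


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="results/study/config.yaml")
    args = ap.parse_args()
    cfg = load_config(args.config)
    features, clusters = run_cluster(cfg)
    n = len(clusters)
    for c in (1, 2, 3):
        frac = (clusters == c).mean()
        means = features.loc[clusters.index[clusters == c]].mean()
        print(f"cluster {c}: {int(frac * n):4d} regions ({100 * frac:4.1f}%)  "
              + "  ".join(f"{f}={v:7.1f}" for f, v in means.items()))


if __name__ == "__main__":
    main()
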