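#!/usr/bin/env python
"""Generate the synthetic study: a small genome with planted bivalent /
H3K4me3-only / H3K27me3-only regions, five-cell-line peak sets, four-factor
signal tracks, an array methylome for eight tumor types and a genes x
tissues expression matrix.

Writes all pipeline inputs (plus machine-readable planted truth) under
results/study/data and the pipeline config to results/study/config.yaml.
"""

import argparse

from bivatlas.pipeline import simulate_study_files


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/study")
    args = ap.parse_args()
    cfg = simulate_study_files(args.outdir, seed=args.seed)
    print(f"synthetic study written under {args.outdir}")
    print(f"config: {args.outdir}/config.yaml")
    print(f"inputs: {len(cfg['inputs']['peaks']['H3K4me3'])} cell lines x 2 marks, "
          f"{len(cfg['inputs']['tracks'])} factor tracks")


if __name__ == "__main__":
    main()
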