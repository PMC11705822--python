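#!/usr/bin/env python
"""Step 3: beta diversity.

Bray-Curtis dissimilarities, a 2-D NMDS embedding, ANOSIM tests of the
season and depth-zone groupings, and Mantel tests of community distance
against each environmental variable's distance.
"""

from common import load, parse_args

from ciliateco.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    tables, cfg = load(args)
    results = run_pipeline(tables, cfg, stages=("beta",))
    out = results["beta"]

    print(f"NMDS stress (2-D): {out['nmds_stress']:.4f}")
    for _, row in out["tests"].iterrows():
        print(f"ANOSIM {row['grouping']}: R = {row['statistic']:.3f}, "
              f"p = {row['p_value']:.4f}")

    mantel = out["mantel"].sort_values("statistic", ascending=False)
    print("\nstrongest Mantel correlations with community distance:")
    for _, row in mantel.head(5).iterrows():
        print(f"  {row['variable']}: r = {row['statistic']:.3f}, "
              f"p = {row['p_value']:.4f}")


if __name__ == "__main__":
    main()
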