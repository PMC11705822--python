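#!/usr/bin/env python
"""Step 4: spatial eigenvectors and variation partitioning.

Builds PCNM axes from station coordinates, forward-selects predictors
within each named set (season / depth / space and the physical / chemical
/ food environment groups), and partitions the Hellinger-transformed
community variance between the temporal-spatial and environmental sets.
"""

from common import load, parse_args

from ciliateco.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    tables, cfg = load(args)
    results = run_pipeline(tables, cfg, stages=("vpa",))
    out = results["vpa"]

    print(f"PCNM axes retained: {out['pcnm'].n_axes} "
          f"(truncation {out['pcnm'].truncation:.1f} km)")
    print("forward-selected predictors per set:")
    for name, X in out["selected"].items():
        print(f"  {name}: {list(X.columns)}")

    print("\nadjusted-R2 fractions (as % of community variance):")
    for _, row in out["fractions"].iterrows():
        print(f"  {row['partition']:>18} {row['fraction']:<28} "
              f"{100 * row['adjusted_r2']:6.2f}%")


if __name__ == "__main__":
    main()
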