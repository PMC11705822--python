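#!/usr/bin/env python
"""Step 2: alpha diversity.

Per-sample species richness and Shannon entropy, Tukey HSD contrasts
between seasons and depth zones, shared/unique species counts, and a
Spearman screen of diversity against every environmental variable.
"""

from common import load, parse_args

from ciliateco.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    tables, cfg = load(args)
    results = run_pipeline(tables, cfg, stages=("alpha",))
    out = results["alpha"]

    rec = out["alpha_records"]
    print(f"richness: mean {rec['richness'].mean():.1f} "
          f"(range {rec['richness'].min()}-{rec['richness'].max()})")
    print(f"shannon:  mean {rec['shannon'].mean():.3f}")

    sig = out["tukey"].query("p_adj < 0.05")
    print(f"\nTukey HSD: {len(sig)} of {len(out['tukey'])} contrasts "
          "significant at 0.05:")
    for _, row in sig.iterrows():
        print(f"  {row['metric']} {row['grouping']}: "
              f"{row['group_a']} vs {row['group_b']} "
              f"(diff {row['mean_difference']:+.3f}, p {row['p_adj']:.4f})")

    shared = out["shared_species"]["zone"]
    print(f"\nspecies shared by all zones: {shared['all_shared']}; "
          f"unique per zone: {shared['unique']}")

    if "alpha_env_correlation" in out:
        corr = out["alpha_env_correlation"].query("significant")
        print(f"significant diversity-environment correlations: {len(corr)}")


if __name__ == "__main__":
    main()
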