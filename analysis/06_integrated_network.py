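#!/usr/bin/env python
"""Step 6: integrated ciliate-phytoplankton-environment network.

Joins the ciliate and phytoplankton tables with the environmental
variables in one correlation network, then classifies edges by endpoint
type and cross-tabulates ciliate-phytoplankton links by feeding habit and
phylum, and ciliate-environment links by trophic type and variable group.
"""

from common import load, parse_args

from ciliateco.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    tables, cfg = load(args)
    results = run_pipeline(tables, cfg, stages=("integrated",))
    out = results["integrated"]

    topo = out["topology"]
    print(f"integrated network: {topo.n_nodes} nodes, {topo.n_edges} edges, "
          f"Q = {out['modularity']:.3f}")
    cls = out["edge_classification"]
    print("\nedge classes:")
    print(cls.counts.to_string(float_format=lambda v: f"{v:.1f}"))
    if not cls.feeding_by_phylum.empty:
        print("\nciliate-phytoplankton edges by feeding habit x phylum:")
        print(cls.feeding_by_phylum.to_string())
    if not cls.trophy_by_env_group.empty:
        print("\nciliate-environment edges by trophic type x variable group:")
        print(cls.trophy_by_env_group.to_string())


if __name__ == "__main__":
    main()
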