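"""Shared argument handling for the numbered analysis steps."""

import argparse
from pathlib import Path

from ciliateco.io import TableSet, read_tables
from ciliateco.pipeline import PipelineConfig


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--data", default="data/synthetic",
                    help="directory produced by 01_simulate.py")
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=None,
                    help="override all stage seeds")
    ap.add_argument("--n-perm", type=int, default=999)
    return ap.parse_args()


def load(args: argparse.Namespace) -> tuple[TableSet, PipelineConfig]:
    d = Path(args.data)
    tables = read_tables(
        d / "community.csv", d / "samples.csv",
        env_path=d / "environment.csv", traits_path=d / "traits.csv",
        phyto_path=d / "phytoplankton.csv",
        phyto_traits_path=d / "phyto_traits.csv")
    cfg = PipelineConfig(output_dir=args.out, n_perm=args.n_perm)
    if args.seed is not None:
        cfg.override_seed(args.seed)
    return tables, cfg
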