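"""Readers and writers for the pipeline's CSV interfaces.

All tables are UTF-8 CSV with a header row; the first column is the sample
id (sample-indexed tables) or the taxon id (trait tables).  Sample order is
normalized to sorted ids, and alignment across tables is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import AbundanceTable, EnvFrame, SampleFrame, TraitFrame


class AlignmentError(ValueError):
    """Tables disagree on their sample sets."""


def _read_indexed(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = index_name
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate {index_name} identifiers: {dups}")
    return df


@dataclass
class TableSet:
    community: AbundanceTable
    frame: SampleFrame
    env: EnvFrame | None = None
    traits: TraitFrame | None = None
    phyto: AbundanceTable | None = None
    phyto_traits: TraitFrame | None = None


def read_tables(
    community_path,
    samples_path,
    env_path=None,
    traits_path=None,
    phyto_path=None,
    phyto_traits_path=None,
    intersect: bool = False,
) -> TableSet:
    """Load and sample-align the pipeline inputs.

    Mismatched sample sets raise :class:`AlignmentError` listing the ids,
    unless ``intersect`` is set, in which case the common subset is kept
    (ids sorted)."""
    community = _read_indexed(community_path, "sample_id")
    samples = _read_indexed(samples_path, "sample_id")
    sample_tables = {"community": community, "samples": samples}
    if env_path is not None:
        sample_tables["environment"] = _read_indexed(env_path, "sample_id")
    if phyto_path is not None:
        sample_tables["phytoplankton"] = _read_indexed(phyto_path, "sample_id")

    ids = [set(t.index) for t in sample_tables.values()]
    common = sorted(set.intersection(*ids))
    union = set.union(*ids)
    if union - set(common):
        report = {
            name: sorted(set(t.index) - set(common))
            for name, t in sample_tables.items()
            if set(t.index) - set(common)
        }
        if not intersect:
            raise AlignmentError(
                f"tables disagree on samples; ids outside the common set: {report}")
    if not common:
        raise AlignmentError("no samples shared across all tables")
    sample_tables = {k: t.loc[common] for k, t in sample_tables.items()}

    traits = (TraitFrame(_read_indexed(traits_path, "taxon"))
              if traits_path is not None else None)
    phyto_traits = (TraitFrame(_read_indexed(phyto_traits_path, "taxon"))
                    if phyto_traits_path is not None else None)
    return TableSet(
        community=AbundanceTable(sample_tables["community"]),
        frame=SampleFrame(sample_tables["samples"]),
        env=(EnvFrame(sample_tables["environment"])
             if "environment" in sample_tables else None),
        traits=traits,
        phyto=(AbundanceTable(sample_tables["phytoplankton"])
               if "phytoplankton" in sample_tables else None),
        phyto_traits=phyto_traits,
    )


def write_csv(df: pd.DataFrame, path, config_hash: str = "", **kwargs) -> Path:
    """Write a CSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, **kwargs)
    return path
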