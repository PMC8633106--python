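"""Bundled reference tables for the Chai-Hu-Shu-Gan-San (CHSGS) case study.

Three small published summaries ship with the package:

* the per-herb component counts for the seven botanical drugs of CHSGS,
  before ADME screening and after (`load_herb_counts`) — the reported
  totals before de-duplication are 1,191 collected / 290 active, and
  1,012 / 249 after de-duplication across herbs;
* the property table of the reported 71-member core group of functional
  components (`load_cgfc_components`), ready for the ADME screen;
* the 13 reported receptor-to-effector cascade chains with their
  maximum-targeting-weight scores (`load_cascade_scores`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import ComponentRecord, read_component_table
from .mtw import CascadePath

__all__ = [
    "load_herb_counts",
    "load_cgfc_components",
    "load_cascade_scores",
    "REPORTED_TOTAL_COMPONENTS",
    "REPORTED_TOTAL_ACTIVE",
    "REPORTED_DEDUP_COMPONENTS",
    "REPORTED_DEDUP_ACTIVE",
]

REPORTED_TOTAL_COMPONENTS = 1191  # summed over herbs, duplicates counted per herb
REPORTED_TOTAL_ACTIVE = 290
REPORTED_DEDUP_COMPONENTS = 1012
REPORTED_DEDUP_ACTIVE = 249


def _data_path(name: str):
    return resources.files("netpharm.data") / name


def load_herb_counts() -> pd.DataFrame:
    """Per-herb collected and ADME-active component counts."""
    with resources.as_file(_data_path("herb_component_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_cgfc_components() -> list[ComponentRecord]:
    """The reported 71 core functional components with their properties."""
    with resources.as_file(_data_path("cgfc_components.tsv")) as p:
        return read_component_table(p)


def load_cascade_scores() -> list[CascadePath]:
    """The 13 reported cascade chains; scores stored as normalized scores."""
    with resources.as_file(_data_path("cascade_scores.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        nodes = tuple(row.chain.split("--"))
        out.append(
            CascadePath(
                nodes=nodes,
                raw=float(row.score) * len(nodes),
                normalized=float(row.score),
            )
        )
    return out
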