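"""Published summary data from the Chilean endemic-genera study.

The full species-level inputs (the deposited phylogeny and the gridded
occurrence matrix) are external downloads, but the study's printed summary
tables travel with the package: the top-20 priority lists for RED and the
four EDGE schemes, the red-list category counts over the 95 evaluated
species, and the tree sizes. These drive the published-results validation
checks (top-20 overlap between RED and every EDGE variant, the dense-rank
tie convention, and the threat-distribution percentages) without any
external data.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "printed_rank_tables",
    "STATUS_COUNTS",
    "N_EVALUATED",
    "BACKBONE_TIPS",
    "FINAL_TIPS",
    "N_IMPUTED",
    "EDGE_METRICS",
]

#: Red-list category counts over the evaluated species.
STATUS_COUNTS = {"CR": 7, "EN": 54, "VU": 23, "NT": 7, "LC": 4}
N_EVALUATED = sum(STATUS_COUNTS.values())  # 95

#: Sequenced backbone tips, final tree tips, and species grafted in.
BACKBONE_TIPS = 147
FINAL_TIPS = 197
N_IMPUTED = FINAL_TIPS - BACKBONE_TIPS

EDGE_METRICS = ("iucn50", "iucn100", "iucn500", "isaac")


def printed_rank_tables() -> dict[str, pd.Series]:
    """Published priority lists as dense-rank Series keyed by metric.

    Keys: ``red`` and the four EDGE schemes (evaluated species only, where
    boundary ties push some lists past 20 species), plus ``ed_all`` (ED over
    all species, 30 species across 20 dense ranks).
    """
    path = files("red_metrics.data").joinpath("chile_printed_ranks.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    return {
        metric: pd.Series(
            sub["rank"].values, index=sub["species"].values, name=metric
        )
        for metric, sub in df.groupby("metric", sort=False)
    }
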