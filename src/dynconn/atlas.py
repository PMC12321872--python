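"""Node bookkeeping: gray/white tissue classes and subnetwork assignments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRAY_NETWORKS = [
    "DefaultMode",
    "Visual",
    "Somatomotor",
    "Limbic",
    "FrontoparietalControl",
    "DorsalAttention",
    "SalienceVentralAttention",
]
WHITE_NETWORKS = [f"WM{i}" for i in range(1, 13)]


@dataclass
class AtlasMap:
    """node_id -> (tissue, subnetwork) assignment.

    Gray nodes belong to one of the 7 cortical networks, white nodes to one
    of the 12 white-matter networks WM1-WM12.
    """

    node_ids: list[str]
    tissue: list[str]
    subnetwork: list[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.node_ids) == len(self.tissue) == len(self.subnetwork)):
            raise ValueError("node_ids, tissue, subnetwork must have equal length")
        for t in self.tissue:
            if t not in ("gray", "white"):
                raise ValueError(f"unknown tissue {t!r}")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node ids")

    def __len__(self) -> int:
        return len(self.node_ids)

    def subnetwork_of(self, node_id: str) -> str:
        if node_id not in self._index:
            raise KeyError(f"unknown node {node_id!r}")
        return self.subnetwork[self._index[node_id]]

    @property
    def subnetworks(self) -> list[str]:
        """All subnetwork block names in canonical order (7 gray then 12 white)."""
        present = set(self.subnetwork)
        return [s for s in GRAY_NETWORKS + WHITE_NETWORKS if s in present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.node_ids, "tissue": self.tissue, "subnetwork": self.subnetwork}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtlasMap":
        return cls(
            node_ids=df["node_id"].astype(str).tolist(),
            tissue=df["tissue"].tolist(),
            subnetwork=df["subnetwork"].tolist(),
        )


def default_atlas(n_gray: int = 200, n_white: int = 128) -> AtlasMap:
    """Contiguous-block assignment of n_gray nodes to the 7 gray networks and
    n_white nodes to WM1-WM12. Node labels are ``g001..`` / ``w001..``.

    Tiny test atlases with fewer nodes than networks fall back to one block
    per node (the full 7 + 12 structure needs n_gray >= 7 and n_white >= 12).
    """
    if n_gray < 1 or n_white < 1:
        raise ValueError("need at least one gray and one white node")
    node_ids = [f"g{i + 1:03d}" for i in range(n_gray)] + [
        f"w{i + 1:03d}" for i in range(n_white)
    ]
    tissue = ["gray"] * n_gray + ["white"] * n_white
    n_gnet = min(n_gray, len(GRAY_NETWORKS))
    n_wnet = min(n_white, len(WHITE_NETWORKS))
    gray_blocks = np.array_split(np.arange(n_gray), n_gnet)
    white_blocks = np.array_split(np.arange(n_white), n_wnet)
    subnetwork = [""] * (n_gray + n_white)
    for name, block in zip(GRAY_NETWORKS, gray_blocks):
        for i in block:
            subnetwork[i] = name
    for name, block in zip(WHITE_NETWORKS, white_blocks):
        for i in block:
            subnetwork[n_gray + i] = name
    return AtlasMap(node_ids=node_ids, tissue=tissue, subnetwork=subnetwork)
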