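"""Loaders for the packaged cluster tables and relatedness panel.

The package ships, as plain TSV, the two curated strain inventories
(15 clusters each), the quinolidomicin reference assembly line
(loading module plus extension modules 1-33), and the pairwise
relatedness panel (digital DDH and gyrB identities) used by the
genomospecies delimitation examples.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Tuple

from .notation import ClusterInventory, GeneCluster, read_cluster_table

__all__ = [
    "load_inventory",
    "load_tp_a0316",
    "load_tp_a0468",
    "load_qnm_reference",
    "load_ddh_panel",
    "fixture_path",
]

_FIXTURES = {
    "tp_a0316": "tp_a0316.tsv",
    "tp_a0468": "tp_a0468.tsv",
    "qnm_ak_an57": "qnm_ak_an57.tsv",
    "ddh_panel": "ddh_panel.tsv",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (``tp_a0316``, ``tp_a0468``,
    ``qnm_ak_an57`` or ``ddh_panel``)."""
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return resources.files("clusterline.data").joinpath(fname)


def load_inventory(name: str) -> ClusterInventory:
    """Load one packaged strain inventory by fixture name."""
    with resources.as_file(fixture_path(name)) as path:
        inventories = read_cluster_table(path)
    if len(inventories) != 1:
        raise ValueError(f"fixture {name!r} holds {len(inventories)} strains")
    return inventories[0]


def load_tp_a0316() -> ClusterInventory:
    """The arisostatin producer's inventory (15 clusters)."""
    return load_inventory("tp_a0316")


def load_tp_a0468() -> ClusterInventory:
    """The kosinostatin producer's inventory (15 clusters)."""
    return load_inventory("tp_a0468")


def load_qnm_reference() -> GeneCluster:
    """The quinolidomicin assembly line (34 module positions)."""
    return load_inventory("qnm_ak_an57").get("qnm")


def load_ddh_panel() -> List[Tuple[str, str, str, float]]:
    """The pairwise relatedness panel (dDDH and gyrB identities)."""
    from .taxonomy import read_panel

    with resources.as_file(fixture_path("ddh_panel")) as path:
        return read_panel(path)
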