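"""Genomospecies delimitation from marker-gene identity and digital DDH.

Two strains are conspecific when their genome relatedness is at or above
70% DNA-DNA hybridization (dDDH); a 98.5% gyrB marker-gene identity is the
established correspondence point for that boundary.  16S rRNA identity is
not sufficient on its own — identical 16S sequences occur between distinct
genomospecies — so a 16S value always yields an inconclusive verdict here.

dDDH values are inputs (computed by external genome-to-genome tools); this
module computes marker-gene identities from sequences, applies the
threshold rules, and partitions strain panels into species groups via the
connected components of the same-species graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import networkx as nx
import pandas as pd
from Bio import Align, SeqIO

from .config import DEFAULT_TAXONOMY, TaxonomyThresholds

__all__ = [
    "TaxonVerdict",
    "pairwise_identity",
    "genomospecies_verdict",
    "ddh_verdict",
    "panel_verdicts",
    "read_panel",
    "read_marker_fasta",
]

_NUCLEOTIDES = set("ACGTN-")


@dataclass(frozen=True)
class TaxonVerdict:
    """A similarity value, the threshold rule applied, and the outcome."""

    metric: str  # identity_16S | identity_gyrB | dDDH
    value: float
    threshold: float
    verdict: str  # same_species | distinct_species | inconclusive
    strain_a: str = ""
    strain_b: str = ""


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two nucleotide sequences after global alignment.

    Identity is matches over aligned columns, excluding terminal gap
    columns (so marker genes trimmed to different lengths are compared over
    their shared span), rounded to one decimal.
    """
    a = str(seq_a).upper().strip()
    b = str(seq_b).upper().strip()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, s in (("seq_a", a), ("seq_b", b)):
        bad = set(s) - _NUCLEOTIDES
        if bad:
            raise ValueError(
                f"{name} contains non-nucleotide symbols: {sorted(bad)}"
            )

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    # free terminal gaps (attribute was renamed across Biopython releases)
    if hasattr(aligner, "open_end_gap_score"):
        aligner.open_end_gap_score = 0
        aligner.extend_end_gap_score = 0
    else:  # pragma: no cover - older Biopython
        aligner.end_open_gap_score = 0
        aligner.end_extend_gap_score = 0
    aln = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
    sa, sb = str(aln[0]), str(aln[1])

    # trim terminal-gap columns
    start = max(len(sa) - len(sa.lstrip("-")), len(sb) - len(sb.lstrip("-")))
    end = len(sa) - max(
        len(sa) - len(sa.rstrip("-")), len(sb) - len(sb.rstrip("-"))
    )
    core_a, core_b = sa[start:end], sb[start:end]
    columns = len(core_a)
    if columns == 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(core_a, core_b) if x == y and x != "-"
    )
    return round(100.0 * matches / columns, 1)


def _check_percent(value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"percent value out of range: {value}")
    return value


def genomospecies_verdict(
    gyrb_identity: float,
    threshold: Optional[float] = None,
    strain_a: str = "",
    strain_b: str = "",
) -> TaxonVerdict:
    """Same/distinct species from gyrB identity (boundary inclusive)."""
    value = _check_percent(gyrb_identity)
    thr = DEFAULT_TAXONOMY.gyrb_identity if threshold is None else threshold
    verdict = "same_species" if value >= thr else "distinct_species"
    return TaxonVerdict("identity_gyrB", value, thr, verdict, strain_a, strain_b)


def ddh_verdict(
    ddh: float,
    threshold: Optional[float] = None,
    strain_a: str = "",
    strain_b: str = "",
) -> TaxonVerdict:
    """Same/distinct species from digital DDH (boundary inclusive at 70%)."""
    value = _check_percent(ddh)
    thr = DEFAULT_TAXONOMY.ddh if threshold is None else threshold
    verdict = "same_species" if value >= thr else "distinct_species"
    return TaxonVerdict("dDDH", value, thr, verdict, strain_a, strain_b)


def panel_verdicts(
    pairs: Iterable[Tuple[str, str, str, float]],
    thresholds: TaxonomyThresholds = DEFAULT_TAXONOMY,
) -> Tuple[List[TaxonVerdict], List[List[str]]]:
    """Verdicts for a panel of pairwise measurements plus species groups.

    ``pairs`` yields ``(strain_a, strain_b, metric, value)`` with metric one
    of ``dDDH``, ``identity_gyrB``, ``identity_16S``.  Species groups are
    the connected components of the graph whose edges are same-species
    verdicts; strains only seen in distinct/inconclusive pairs form
    singleton groups.  The partition is invariant to pair order.
    """
    verdicts: List[TaxonVerdict] = []
    graph = nx.Graph()
    for strain_a, strain_b, metric, value in pairs:
        graph.add_node(strain_a)
        graph.add_node(strain_b)
        if metric == "dDDH":
            v = ddh_verdict(value, thresholds.ddh, strain_a, strain_b)
        elif metric == "identity_gyrB":
            v = genomospecies_verdict(
                value, thresholds.gyrb_identity, strain_a, strain_b
            )
        elif metric == "identity_16S":
            # 16S identity alone cannot delimit species
            v = TaxonVerdict(
                "identity_16S", _check_percent(value), 100.0, "inconclusive",
                strain_a, strain_b,
            )
        else:
            raise ValueError(f"unknown metric {metric!r}")
        verdicts.append(v)
        if v.verdict == "same_species":
            graph.add_edge(strain_a, strain_b)

    groups = [sorted(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda g: (-len(g), g))
    return verdicts, groups


def read_panel(
    source: Union[str, Path],
) -> List[Tuple[str, str, str, float]]:
    """Read a relatedness panel TSV (strain_a, strain_b, metric, value)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    required = ["strain_a", "strain_b", "metric", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel missing column(s): {', '.join(missing)}")
    return [
        (r.strain_a, r.strain_b, r.metric, float(r.value))
        for r in df.itertuples()
    ]


def read_marker_fasta(source: Union[str, Path]) -> Dict[str, str]:
    """Read marker-gene sequences keyed by record id."""
    return {
        record.id: str(record.seq) for record in SeqIO.parse(str(source), "fasta")
    }
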