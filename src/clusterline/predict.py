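"""Cluster typing and co-linearity product-skeleton prediction.

The assembly-line co-linearity rule says the order and number of modules
determine the order and number of units in the product: each NRPS extension
module contributes the residue activated by its adenylation (A) domain, and
each KS-bearing PKS module contributes one ketide unit.  Following the
conventions of the cluster tables this package models, units are written as
3-letter residue codes, ``x`` (A domain present but substrate unknown),
``y`` (condensation/carrier module lacking an A domain), ``pk`` (polyketide
extender unit) and ``st`` (CoA-ligase starter).

Trans-acting domains complicate the rule: when a cluster carries A domains
on standalone proteins (outside any C- or KS-containing module), the
assembly order is no longer encoded in gene order.  Such clusters are
flagged ``colinear=False``; their unit lists are still emitted in gene/ORF
order but carry no order guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .notation import (
    ClusterInventory,
    DomainToken,
    GeneCluster,
    Module,
)

__all__ = [
    "ProductPrediction",
    "classify_cluster",
    "classify_inventory",
    "predict_product",
    "conserved_annotation_check",
    "DomainDifference",
]

_GREEK = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa",
    7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}

#: Unit tokens that stand for one incorporated residue (peptide side).
RESIDUE_UNITS = ("x", "y")


def _length_name(count: int, suffix: str) -> str:
    if count <= 0:
        return ""
    prefix = _GREEK.get(count)
    return f"{prefix}{suffix}" if prefix else f"{count}-{suffix}"


@dataclass
class ProductPrediction:
    """Predicted product skeleton of a gene cluster."""

    cluster_id: str
    category: str  # polyketide | peptide | hybrid | aromatic_polyketide |
    #               type3_polyketide | unpredictable
    units: List[str] = field(default_factory=list)
    length_name: str = ""
    colinear: bool = True
    release: str = "none_detected"  # thioesterase | reductive | none_detected
    annotation: str = ""

    @property
    def unit_string(self) -> str:
        return "-".join(self.units)

    @property
    def residue_units(self) -> List[str]:
        return [u for u in self.units if u not in ("pk", "st")]

    @property
    def ketide_units(self) -> List[str]:
        return [u for u in self.units if u == "pk"]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_cluster(cluster: GeneCluster) -> str:
    """Assign a cluster type from domain content alone.

    Iterative type-II systems are three discrete proteins (KSalpha, KSbeta
    chain-length factor, ACP); type-III synthases are a single standalone
    ketosynthase; modular clusters are typed by which chain-building
    chemistry their modules carry (KS/AT polyketide, C/A peptide, or both).
    """
    standalone_labels = [t.label for t in cluster.standalone_tokens()]
    modules = cluster.modules

    if not modules and set(standalone_labels) <= {"KSalpha", "KSbeta", "ACP"} and {
        "KSalpha",
        "KSbeta",
    } <= set(standalone_labels):
        return "t2pks"
    if (
        not modules
        and len(cluster.orfs) == 1
        and standalone_labels == ["KS"]
    ):
        return "t3pks"

    all_labels = {d.label for orf in cluster.orfs for d in orf.domain_tokens()}
    has_pks = bool({"KS", "AT"} & all_labels)
    has_nrps = bool({"C", "A"} & all_labels)
    if has_pks and has_nrps:
        return "pks_nrps"
    if has_pks:
        return "t1pks"
    if has_nrps:
        return "nrps"
    return "unknown"


def classify_inventory(inventory: ClusterInventory) -> dict:
    """Per-type cluster counts for one strain, with pure-PKS types pooled."""
    counts = {"pks": 0, "nrps": 0, "hybrid": 0, "unknown": 0}
    per_cluster = {}
    for cluster in inventory:
        ctype = classify_cluster(cluster)
        per_cluster[cluster.cluster_id] = ctype
        if ctype in ("t1pks", "t2pks", "t3pks"):
            counts["pks"] += 1
        elif ctype == "nrps":
            counts["nrps"] += 1
        elif ctype == "pks_nrps":
            counts["hybrid"] += 1
        else:
            counts["unknown"] += 1
    return {"counts": counts, "types": per_cluster}


# ---------------------------------------------------------------------------
# Product prediction
# ---------------------------------------------------------------------------


def _module_unit(module: Module) -> Optional[str]:
    """Unit contributed by one assembly-line module, or None."""
    labels = set(module.labels)
    if module.role == "loading":
        # CoA-ligase loading contributes the starter molecule
        return "st" if "CoL" in labels else None
    a_dom = module.find("A")
    if a_dom is not None:
        return a_dom.specificity or "x"
    if "KS" in labels:
        return "pk"
    if "C" in labels or "T" in labels:
        # condensation/carrier module with no A domain: unknown unit
        return "y" if "T" in labels else None
    return None


def _standalone_unit(element) -> Optional[str]:
    """Unit contributed by a trans-acting standalone domain or didomain.

    Standalone A domains activate one residue wherever they act, so each
    contributes a residue unit; lone KS, C, T or carrier domains cannot
    incorporate a unit without a partner and contribute nothing.
    """
    if isinstance(element, Module):
        a_dom = element.find("A")
        if a_dom is not None:
            return a_dom.specificity or "x"
        return None
    if element.label == "A":
        return element.specificity or "x"
    return None


def predict_product(cluster: GeneCluster) -> ProductPrediction:
    """Predict the product skeleton of a parsed cluster by co-linearity.

    Incomplete (truncation-flagged) clusters and clusters with no countable
    modules are unpredictable.  Iterative type-II and type-III systems get
    their category only; their chain length is not module-encoded.
    """
    ctype = classify_cluster(cluster)
    pred = ProductPrediction(
        cluster_id=cluster.cluster_id,
        category="unpredictable",
        annotation=cluster.annotation,
    )

    release = "none_detected"
    all_labels = [d.label for orf in cluster.orfs for d in orf.domain_tokens()]
    if "Te" in all_labels:
        release = "thioesterase"
    elif "TD" in all_labels:
        release = "reductive"
    pred.release = release

    if not cluster.complete:
        pred.colinear = False
        return pred
    if ctype == "t2pks":
        pred.category = "aromatic_polyketide"
        return pred
    if ctype == "t3pks":
        pred.category = "type3_polyketide"
        return pred

    units: List[str] = []
    from_standalone = False
    for orf in cluster.orfs:
        for element in orf.elements:
            if isinstance(element, Module) and element.role in (
                "loading",
                "extension",
            ):
                unit = _module_unit(element)
            else:
                unit = _standalone_unit(element)
                if unit is not None:
                    from_standalone = True
            if unit is not None:
                units.append(unit)

    if not units:
        pred.colinear = False
        return pred

    has_trans = from_standalone or any(
        t.label in ("A", "C", "T") for t in cluster.standalone_tokens()
    ) or any(m.role == "standalone" for m in cluster.modules)
    pred.colinear = not has_trans
    pred.units = units

    n_res = len([u for u in units if u not in ("pk", "st")])
    n_pk = units.count("pk")
    if n_res and n_pk:
        pred.category = "hybrid"
        if n_res >= n_pk:
            pred.length_name = _length_name(n_res, "peptide")
        else:
            pred.length_name = _length_name(n_pk, "ketide")
    elif n_res:
        pred.category = "peptide"
        pred.length_name = _length_name(n_res, "peptide")
    elif n_pk:
        pred.category = "polyketide"
        pred.length_name = _length_name(n_pk, "ketide")
    else:
        # only a starter unit: nothing countable
        pred.category = "unpredictable"
        pred.units = []
    return pred


# ---------------------------------------------------------------------------
# Domain-level difference report against a reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainDifference:
    """One domain present on one side of an aligned module pair only."""

    ref_label: str  # index label of the reference module ("" if gapped)
    query_label: str  # index label of the query module ("" if gapped)
    domain: str
    change: str  # "gained" (in query, not reference) or "lost"


def conserved_annotation_check(
    cluster: GeneCluster,
    reference: GeneCluster,
    thresholds=None,
) -> List[DomainDifference]:
    """Domain-level differences between a cluster and an aligned reference.

    Aligns the module sequences (see :mod:`clusterline.align`) and lists,
    per aligned pair, domains gained by the query and lost from the
    reference.  An identical cluster yields an empty report.
    """
    from .align import align_clusters  # local import to avoid a cycle
    from .config import DEFAULT_ALIGNMENT

    thresholds = thresholds or DEFAULT_ALIGNMENT
    alignment = align_clusters(reference, cluster, thresholds=thresholds)
    ref_mods = {m.index_label: m for m in reference.counted_modules()}
    qry_mods = {m.index_label: m for m in cluster.counted_modules()}

    diffs: List[DomainDifference] = []
    for ref_label, qry_label, _sim in alignment.pairs:
        if ref_label is None or qry_label is None:
            continue
        ref_counts = _label_counts(ref_mods[ref_label])
        qry_counts = _label_counts(qry_mods[qry_label])
        for label in sorted(set(ref_counts) | set(qry_counts)):
            delta = qry_counts.get(label, 0) - ref_counts.get(label, 0)
            for _ in range(delta):
                diffs.append(
                    DomainDifference(ref_label, qry_label, label, "gained")
                )
            for _ in range(-delta):
                diffs.append(
                    DomainDifference(ref_label, qry_label, label, "lost")
                )
    return diffs


def _label_counts(module: Module) -> dict:
    counts: dict = {}
    for d in module.domains:
        counts[d.label] = counts.get(d.label, 0) + 1
    return counts
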