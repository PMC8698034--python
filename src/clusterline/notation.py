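"""Domain-organization notation for modular PKS/NRPS gene clusters.

Assembly lines of type-I polyketide synthases (PKS) and nonribosomal peptide
synthetases (NRPS) are conventionally written as strings of catalytic-domain
codes: domains within a module are joined by ``/`` and successive modules by
``-``, e.g. ``C/A_ser_/T-C/A_pro_/T-Te`` for a two-module NRPS ending in a
thioesterase.  Acyltransferase extender specificity is subscripted
(``AT_m_`` malonyl-CoA, ``AT_mm_`` methylmalonyl-CoA) and adenylation-domain
substrates are subscripted as 3-letter residue codes (``A_thr_``).  An
ellipsis (``…`` or ``...``) at either end of an ORF string marks a cluster
that runs off the edge of a contig.

This module provides the in-memory model (:class:`DomainToken`,
:class:`Module`, :class:`ORFArchitecture`, :class:`GeneCluster`,
:class:`ClusterInventory`), a tolerant parser/serializer for the notation,
and readers/writers for simple TSV/JSON cluster tables.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "DOMAIN_LABELS",
    "DomainToken",
    "Module",
    "ORFArchitecture",
    "GeneCluster",
    "ClusterInventory",
    "NotationError",
    "SchemaError",
    "TableValidationError",
    "parse_orf_architecture",
    "serialize_orf_architecture",
    "read_cluster_table",
    "write_cluster_table",
    "count_modules",
]


class NotationError(ValueError):
    """Raised when a domain-organization string cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a cluster table lacks required columns."""


class TableValidationError(ValueError):
    """Raised when a cluster table violates uniqueness constraints."""


#: Closed enumeration of recognised domain codes.  Unknown codes parse to
#: ``X`` with their raw spelling preserved.
DOMAIN_LABELS = (
    "KS", "AT", "DH", "ER", "KR", "ACP", "CoL", "Te", "TD", "E", "MT",
    "AmT", "C", "A", "T", "KSalpha", "KSbeta", "X",
)

_LABEL_ALIASES = {
    "KSα": "KSalpha",
    "KSβ": "KSbeta",
    "KSa": "KSalpha",
    "KSb": "KSbeta",
    "COL": "CoL",
    "TE": "Te",
}

_AT_SPECIFICITIES = {"m": "malonyl", "mm": "methylmalonyl"}

# Domains that never initiate a module on their own: reductive/tailoring
# chemistry and carriers.
_TAILORING_CARRIER = {"DH", "ER", "KR", "ACP", "T", "Te", "TD", "E", "MT", "AmT"}
_RELEASE = {"Te", "TD"}

_ELLIPSIS_RE = re.compile(r"^(?:…|\.\.\.)|(?:…|\.\.\.)$")


@dataclass(frozen=True)
class DomainToken:
    """One catalytic domain, with optional specificity annotation.

    ``specificity`` is only meaningful for AT (extender unit) and A
    (activated residue) domains; for any other label it must be ``None``.
    ``raw`` preserves the original spelling of codes that did not match the
    enumeration and were mapped to ``X``.
    """

    label: str
    specificity: Optional[str] = None
    truncated: bool = False
    raw: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in DOMAIN_LABELS:
            raise NotationError(f"unknown domain label {self.label!r}")
        if self.specificity is not None and self.label not in ("AT", "A"):
            raise NotationError(
                f"specificity {self.specificity!r} not allowed on {self.label}"
            )

    def notation(self) -> str:
        if self.label == "X" and self.raw:
            return self.raw
        if self.specificity is None:
            return self.label
        if self.label == "AT":
            short = {v: k for k, v in _AT_SPECIFICITIES.items()}.get(
                self.specificity, self.specificity
            )
            return f"AT_{short}_"
        return f"A_{self.specificity}_"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


@dataclass(frozen=True)
class Module:
    """An ordered run of domains acting as one assembly-line unit.

    ``role`` is ``"loading"`` for chain-initiating modules (CoL-led),
    ``"extension"`` for KS- or C-containing elongation modules, and
    ``"standalone"`` for multi-domain units that carry neither KS nor C
    (e.g. a trans-acting ``A/T`` didomain).
    """

    domains: tuple
    role: str
    index_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("loading", "extension", "standalone"):
            raise NotationError(f"bad module role {self.role!r}")
        labels = self.labels
        if self.role == "extension" and not ({"KS", "C"} & set(labels)):
            raise NotationError("extension module must contain KS or C")
        if self.role == "loading" and ({"KS", "C"} & set(labels)) and labels[0] != "CoL":
            raise NotationError("loading module may not contain KS or C")

    @property
    def labels(self) -> tuple:
        return tuple(d.label for d in self.domains)

    def has(self, label: str) -> bool:
        return label in self.labels

    def find(self, label: str) -> Optional[DomainToken]:
        for d in self.domains:
            if d.label == label:
                return d
        return None

    def notation(self) -> str:
        return "/".join(d.notation() for d in self.domains)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


@dataclass
class ORFArchitecture:
    """Parsed domain organization of a single open reading frame.

    ``elements`` preserves the parse order and interleaves :class:`Module`
    objects with lone :class:`DomainToken` standalones, which is what the
    co-linearity predictor walks.  ``modules`` and ``trailing_standalones``
    are filtered views.
    """

    orf_id: str
    elements: List[object] = field(default_factory=list)
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def modules(self) -> List[Module]:
        return [e for e in self.elements if isinstance(e, Module)]

    @property
    def trailing_standalones(self) -> List[DomainToken]:
        return [e for e in self.elements if isinstance(e, DomainToken)]

    @property
    def truncated(self) -> bool:
        return self.left_truncated or self.right_truncated

    def domain_tokens(self) -> Iterator[DomainToken]:
        for e in self.elements:
            if isinstance(e, Module):
                yield from e.domains
            else:
                yield e

    def notation(self) -> str:
        body = "-".join(
            e.notation() for e in self.elements
        )
        left = "…" if self.left_truncated else ""
        right = "…" if self.right_truncated else ""
        return f"{left}{body}{right}"


@dataclass
class GeneCluster:
    """A typed secondary-metabolite gene cluster: ordered ORFs of modules."""

    cluster_id: str
    declared_type: str = "unknown"
    orfs: List[ORFArchitecture] = field(default_factory=list)
    complete: bool = True
    strain_id: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if any(orf.truncated for orf in self.orfs):
            self.complete = False
        relabel_modules(self)

    @property
    def modules(self) -> List[Module]:
        """All loading/extension/standalone modules across ORFs, in order."""
        return [m for orf in self.orfs for m in orf.modules]

    def counted_modules(self) -> List[Module]:
        """Loading + extension modules (the assembly-line positions)."""
        return [m for m in self.modules if m.role in ("loading", "extension")]

    def standalone_tokens(self) -> List[DomainToken]:
        return [t for orf in self.orfs for t in orf.trailing_standalones]


@dataclass
class ClusterInventory:
    """All typed clusters annotated in one strain's genome."""

    strain_id: str
    clusters: List[GeneCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.clusters:
            if c.strain_id and c.strain_id != self.strain_id:
                raise TableValidationError(
                    f"cluster {c.cluster_id} belongs to {c.strain_id}, "
                    f"not {self.strain_id}"
                )
            c.strain_id = self.strain_id
            if c.cluster_id in seen:
                raise TableValidationError(f"duplicate cluster id {c.cluster_id}")
            seen.add(c.cluster_id)

    def __iter__(self) -> Iterator[GeneCluster]:
        return iter(self.clusters)

    def get(self, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def relabel_modules(cluster: GeneCluster) -> None:
    """Assign index labels: ``L`` for loading, 1-based ordinals for
    extension modules, ``s<k>`` for standalone units, across ORFs."""
    n_ext = 0
    n_sa = 0
    for orf in cluster.orfs:
        new_elements = []
        for e in orf.elements:
            if isinstance(e, Module):
                if e.role == "loading":
                    e = replace(e, index_label="L")
                elif e.role == "extension":
                    n_ext += 1
                    e = replace(e, index_label=str(n_ext))
                else:
                    n_sa += 1
                    e = replace(e, index_label=f"s{n_sa}")
            new_elements.append(e)
        orf.elements = new_elements


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_PROTECT = "\x00"


def _parse_token(text: str) -> DomainToken:
    raw = text
    if not text:
        raise NotationError("empty domain token")
    # exact code (including aliases) first, so AmT is not read as A(mT)
    if text in DOMAIN_LABELS:
        return DomainToken(text)
    if text in _LABEL_ALIASES:
        return DomainToken(_LABEL_ALIASES[text])
    # subscripted specificity: AT_m_, AT_m, ATm / A_thr_, A_thr, Athr
    m = re.fullmatch(r"(AT|A)(?:_([A-Za-z0-9-]+)_?|([a-z][a-z0-9-]*))", text)
    if m:
        code, sub = m.group(1), m.group(2) or m.group(3)
        if code == "AT":
            if sub not in _AT_SPECIFICITIES:
                raise NotationError(
                    f"unknown AT extender specificity in token {raw!r}"
                )
            return DomainToken("AT", _AT_SPECIFICITIES[sub])
        return DomainToken("A", sub.lower())
    if "_" in text:
        raise NotationError(f"unbalanced specificity subscript in token {raw!r}")
    # unknown code: preserved verbatim as X, never dropped
    return DomainToken("X", raw=text)


def _split_segments(body: str) -> List[List[str]]:
    """Split module segments on ``-`` and domains on ``/``, protecting
    hyphens inside ``_..._`` subscripts (e.g. ``A_b-ala_``)."""
    protected = re.sub(
        r"_([A-Za-z0-9]+)-([A-Za-z0-9]+)_",
        lambda m: f"_{m.group(1)}{_PROTECT}{m.group(2)}_",
        body,
    )
    segments = []
    for seg in protected.split("-"):
        seg = seg.strip()
        if not seg:
            raise NotationError(f"empty module segment in {body!r}")
        tokens = [t.strip().replace(_PROTECT, "-") for t in seg.split("/")]
        if any(not t for t in tokens):
            raise NotationError(f"empty domain token in segment {seg!r}")
        segments.append(tokens)
    return segments


def _split_at_initiators(tokens: Sequence[DomainToken]) -> List[List[DomainToken]]:
    """A new module starts at each KS or C (and at CoL) after the first
    token; tables normally pre-split these with ``-``."""
    runs: List[List[DomainToken]] = [[]]
    for i, tok in enumerate(tokens):
        if i > 0 and tok.label in ("KS", "C", "CoL"):
            runs.append([])
        runs[-1].append(tok)
    return [r for r in runs if r]


def parse_orf_architecture(text: str, orf_id: str = "") -> ORFArchitecture:
    """Parse a domain-organization string into an :class:`ORFArchitecture`.

    Grammar: modules separated by ``-``, domains within a module by ``/``;
    ``…``/``...`` at either end marks truncation.  A trailing release-only
    segment (``-Te``, ``-TD``) is folded into the preceding module so that
    the spellings ``KS/AT_m_/ACP-Te`` and ``KS/AT_m_/ACP/Te`` normalize
    identically; the same applies to any tailoring/carrier-only segment that
    follows a module within the same ORF.
    """
    if text is None:
        raise NotationError("architecture string is None")
    s = str(text).strip()
    if not s:
        raise NotationError(f"empty architecture string for ORF {orf_id!r}")
    left = bool(re.match(r"^(?:…|\.\.\.)", s))
    right = bool(re.search(r"(?:…|\.\.\.)$", s))
    body = re.sub(r"^(?:…|\.\.\.)", "", s)
    body = re.sub(r"(?:…|\.\.\.)$", "", body).strip(" -")
    if not body:
        raise NotationError(f"no domains in architecture {text!r}")

    orf = ORFArchitecture(orf_id=orf_id, left_truncated=left, right_truncated=right)
    for raw_tokens in _split_segments(body):
        tokens = [_parse_token(t) for t in raw_tokens]
        for run in _split_at_initiators(tokens):
            _append_segment(orf, run)

    if orf.left_truncated and orf.elements:
        _mark_truncated(orf, first=True)
    if orf.right_truncated and orf.elements:
        _mark_truncated(orf, first=False)
    return orf


def _append_segment(orf: ORFArchitecture, tokens: List[DomainToken]) -> None:
    labels = [t.label for t in tokens]
    label_set = set(labels)
    prev = orf.elements[-1] if orf.elements else None

    if labels[0] == "CoL":
        orf.elements.append(Module(tuple(tokens), "loading"))
        return
    if {"KS", "C"} & label_set:
        if len(tokens) == 1:
            # a lone KS or C cannot form an assembly-line module on its own
            orf.elements.append(tokens[0])
        else:
            orf.elements.append(Module(tuple(tokens), "extension"))
        return
    # no chain-initiating domain in this segment
    if label_set <= _TAILORING_CARRIER and isinstance(prev, Module) and (
        prev.role in ("loading", "extension")
    ):
        # merge rule: release/tailoring segment continues the previous module
        orf.elements[-1] = replace(prev, domains=prev.domains + tuple(tokens))
        return
    if len(tokens) == 1:
        orf.elements.append(tokens[0])
    else:
        orf.elements.append(Module(tuple(tokens), "standalone"))


def _mark_truncated(orf: ORFArchitecture, first: bool) -> None:
    idx = 0 if first else -1
    e = orf.elements[idx]
    if isinstance(e, DomainToken):
        orf.elements[idx] = replace(e, truncated=True)
    else:
        doms = list(e.domains)
        j = 0 if first else -1
        doms[j] = replace(doms[j], truncated=True)
        orf.elements[idx] = replace(e, domains=tuple(doms))


def serialize_orf_architecture(orf: ORFArchitecture) -> str:
    """Render an architecture back to normalized notation.

    The output re-parses to an identical structure (round-trip identity).
    """
    return orf.notation()


def count_modules(cluster: GeneCluster) -> int:
    """Number of assembly-line modules (loading + extension) in a cluster.

    Standalone domains and trans-acting standalone units are not counted.
    """
    return len(cluster.counted_modules())


# ---------------------------------------------------------------------------
# Cluster-table I/O
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "strain_id",
    "cluster_id",
    "declared_type",
    "complete_flag",
    "orf_id",
    "architecture",
    "annotation",
]

_CLUSTER_TYPES = ("t1pks", "t2pks", "t3pks", "nrps", "pks_nrps", "unknown")


def _normalize_declared_type(value: str) -> str:
    v = (value or "").strip().lower().replace("/", "_")
    return v if v in _CLUSTER_TYPES else "unknown"


def read_cluster_table(
    source: Union[str, Path, StringIO], dialect: str = "tsv"
) -> List[ClusterInventory]:
    """Read a cluster-architecture table into inventories.

    TSV dialect: UTF-8, tab-separated, header row with the columns
    ``strain_id  cluster_id  declared_type  complete_flag  orf_id
    architecture  annotation``; one row per ORF, rows grouped by strain then
    cluster in file order.  A ``P`` (or ``^P``) in ``complete_flag`` marks a
    cluster that was not completely sequenced.  JSON dialect: an array of
    inventory objects mirroring the same fields.
    """
    if dialect == "json":
        return _read_json(source)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(
        source, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cluster table missing column(s): {', '.join(missing)}")

    dupes = df.duplicated(subset=["strain_id", "cluster_id", "orf_id"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise TableValidationError(
            f"duplicate ORF row: strain {row.strain_id!r} cluster "
            f"{row.cluster_id!r} ORF {row.orf_id!r}"
        )

    inventories: List[ClusterInventory] = []
    by_strain: dict = {}
    by_cluster: dict = {}
    for i, row in df.iterrows():
        try:
            orf = parse_orf_architecture(row.architecture, row.orf_id)
        except NotationError as exc:
            raise NotationError(f"row {i + 2}: {exc}") from exc
        skey = row.strain_id
        if skey not in by_strain:
            inv = ClusterInventory(strain_id=skey)
            by_strain[skey] = inv
            inventories.append(inv)
        ckey = (skey, row.cluster_id)
        if ckey not in by_cluster:
            cluster = GeneCluster(
                cluster_id=row.cluster_id,
                declared_type=_normalize_declared_type(row.declared_type),
                complete="P" not in (row.complete_flag or "").upper(),
                strain_id=skey,
                annotation=row.annotation,
            )
            by_cluster[ckey] = cluster
            by_strain[skey].clusters.append(cluster)
        by_cluster[ckey].orfs.append(orf)

    for cluster in by_cluster.values():
        if any(orf.truncated for orf in cluster.orfs):
            cluster.complete = False
        relabel_modules(cluster)
    return inventories


def _read_json(source: Union[str, Path, StringIO]) -> List[ClusterInventory]:
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        data = json.loads(Path(source).read_text(encoding="utf-8"))
    inventories = []
    for inv in data:
        clusters = []
        for c in inv["clusters"]:
            orfs = [
                parse_orf_architecture(o["architecture"], o["orf_id"])
                for o in c["orfs"]
            ]
            clusters.append(
                GeneCluster(
                    cluster_id=c["cluster_id"],
                    declared_type=_normalize_declared_type(
                        c.get("declared_type", "unknown")
                    ),
                    orfs=orfs,
                    complete=bool(c.get("complete", True)),
                    strain_id=inv["strain_id"],
                    annotation=c.get("annotation", ""),
                )
            )
        inventories.append(
            ClusterInventory(strain_id=inv["strain_id"], clusters=clusters)
        )
    return inventories


def write_cluster_table(
    inventories: Iterable[ClusterInventory],
    path: Union[str, Path, StringIO],
    dialect: str = "tsv",
) -> None:
    """Serialize inventories back to the TSV or JSON table dialect."""
    if dialect == "json":
        data = [
            {
                "strain_id": inv.strain_id,
                "clusters": [
                    {
                        "cluster_id": c.cluster_id,
                        "declared_type": c.declared_type,
                        "complete": c.complete,
                        "annotation": c.annotation,
                        "orfs": [
                            {"orf_id": o.orf_id, "architecture": o.notation()}
                            for o in c.orfs
                        ],
                    }
                    for c in inv.clusters
                ],
            }
            for inv in inventories
        ]
        text = json.dumps(data, indent=1)
        if hasattr(path, "write"):
            path.write(text)
        else:
            Path(path).write_text(text, encoding="utf-8")
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for inv in inventories:
        for c in inv.clusters:
            for o in c.orfs:
                rows.append(
                    {
                        "strain_id": inv.strain_id,
                        "cluster_id": c.cluster_id,
                        "declared_type": c.declared_type,
                        "complete_flag": "" if c.complete else "P",
                        "orf_id": o.orf_id,
                        "architecture": o.notation(),
                        "annotation": c.annotation,
                    }
                )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
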