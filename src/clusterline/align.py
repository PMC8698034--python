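"""Global alignment of module architectures between gene clusters.

Orthologous assembly-line clusters in different strains keep nearly the same
module-by-module domain organization, differing by occasional whole-module
insertions/deletions (which change the predicted product skeleton) and
domain-level gains/losses within modules.  This module aligns two clusters'
module sequences with a Needleman-Wunsch dynamic program whose match score
is a per-module domain-content similarity, calls ortholog verdicts from the
alignment statistics, matches whole inventories one-to-one, and screens
strain panels for orthologs of a reference cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .config import DEFAULT_ALIGNMENT, AlignmentThresholds
from .notation import ClusterInventory, GeneCluster, Module
from .predict import classify_cluster

__all__ = [
    "ModuleAlignment",
    "InventoryComparison",
    "ScreenResult",
    "module_similarity",
    "align_clusters",
    "compare_inventories",
    "screen_for_ortholog",
    "render_alignment",
]


def module_similarity(
    a: Module,
    b: Module,
    specificity_weight: float = DEFAULT_ALIGNMENT.specificity_weight,
) -> float:
    """Domain-content similarity between two modules, in [0, 1].

    Jaccard index over domain labels.  AT and A domains match at the label
    level; when both sides carry a specificity annotation and the
    annotations disagree, that domain's contribution to the intersection is
    multiplied by ``specificity_weight``.  Loading modules are similar only
    to loading modules (cross-role similarity is 0), mirroring how the
    reference comparison pins L to L.
    """
    if (a.role == "loading") != (b.role == "loading"):
        return 0.0
    la, lb = set(a.labels), set(b.labels)
    union = la | lb
    if not union:
        return 0.0
    inter = la & lb
    score = float(len(inter))
    for label in ("AT", "A"):
        if label in inter:
            sa = a.find(label).specificity
            sb = b.find(label).specificity
            if sa is not None and sb is not None and sa != sb:
                score -= 1.0 - specificity_weight
    return score / len(union)


@dataclass
class ModuleAlignment:
    """Result of globally aligning two module sequences.

    ``pairs`` lists aligned positions in order as
    ``(ref_index_label, query_index_label, similarity)``; a gap on either
    side is represented by ``None`` for the missing label and a similarity
    of 0.  ``coverage`` is the fraction of reference modules aligned,
    ``query_coverage`` the symmetric fraction for the query.
    """

    ref_id: str
    query_id: str
    pairs: List[Tuple[Optional[str], Optional[str], float]] = field(
        default_factory=list
    )
    score: float = 0.0
    mean_similarity: float = 0.0
    coverage: float = 0.0
    query_coverage: float = 0.0
    ortholog: bool = False

    @property
    def ref_gaps(self) -> List[str]:
        return [r for r, q, _ in self.pairs if q is None and r is not None]

    @property
    def query_gaps(self) -> List[str]:
        return [q for r, q, _ in self.pairs if r is None and q is not None]

    @property
    def aligned_pairs(self) -> List[Tuple[str, str, float]]:
        return [
            (r, q, s) for r, q, s in self.pairs if r is not None and q is not None
        ]


def _modules(cluster: GeneCluster) -> List[Module]:
    return cluster.counted_modules()


def align_clusters(
    ref: GeneCluster,
    query: GeneCluster,
    gap_penalty: Optional[float] = None,
    s_min: Optional[float] = None,
    c_min: Optional[float] = None,
    thresholds: AlignmentThresholds = DEFAULT_ALIGNMENT,
) -> ModuleAlignment:
    """Optimal global alignment of two clusters' module sequences.

    Needleman-Wunsch over the loading+extension module lists, with
    :func:`module_similarity` as the match score and ``-gap_penalty`` per
    unaligned module.  Traceback ties are broken deterministically:
    diagonal (match) over reference-gap over query-gap.  The ortholog
    verdict requires ``mean_similarity >= s_min`` and both-side coverage
    ``>= c_min``.
    """
    gap = thresholds.gap_penalty if gap_penalty is None else gap_penalty
    s_min = thresholds.s_min if s_min is None else s_min
    c_min = thresholds.c_min if c_min is None else c_min
    if gap <= 0:
        raise ValueError("gap_penalty must be positive")

    A, B = _modules(ref), _modules(query)
    if not A or not B:
        raise ValueError(
            f"cannot align zero-module cluster "
            f"({ref.cluster_id}: {len(A)} modules, "
            f"{query.cluster_id}: {len(B)} modules)"
        )
    n, m = len(A), len(B)
    sim = [
        [module_similarity(a, b, thresholds.specificity_weight) for b in B]
        for a in A
    ]

    NEG = float("-inf")
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    F[0][0] = 0.0
    for i in range(1, n + 1):
        F[i][0] = -gap * i
    for j in range(1, m + 1):
        F[0][j] = -gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i][j] = max(
                F[i - 1][j - 1] + sim[i - 1][j - 1],
                F[i - 1][j] - gap,
                F[i][j - 1] - gap,
            )

    # Deterministic traceback.  Trying the reference-gap move before the
    # diagonal places an indel at the LAST of a run of score-tied
    # positions: when a deleted module sits in a run of identical tandem
    # modules the optimum is degenerate, and reference tables resolve the
    # ambiguity by gene boundaries, which pins the gap to the downstream
    # copy (e.g. the absent module 4 of the quinolidomicin comparison).
    EPS = 1e-9
    pairs: List[Tuple[Optional[str], Optional[str], float]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j >= 0 and abs(F[i][j] - (F[i - 1][j] - gap)) < EPS:
            pairs.append((A[i - 1].index_label, None, 0.0))
            i -= 1
        elif i > 0 and j > 0 and abs(
            F[i][j] - (F[i - 1][j - 1] + sim[i - 1][j - 1])
        ) < EPS:
            pairs.append((A[i - 1].index_label, B[j - 1].index_label,
                          sim[i - 1][j - 1]))
            i, j = i - 1, j - 1
        else:
            pairs.append((None, B[j - 1].index_label, 0.0))
            j -= 1
    pairs.reverse()

    aligned = [(r, q, s) for r, q, s in pairs if r is not None and q is not None]
    mean_sim = sum(s for _, _, s in aligned) / len(aligned) if aligned else 0.0
    cov_ref = len(aligned) / n
    cov_qry = len(aligned) / m
    return ModuleAlignment(
        ref_id=ref.cluster_id,
        query_id=query.cluster_id,
        pairs=pairs,
        score=F[n][m],
        mean_similarity=mean_sim,
        coverage=cov_ref,
        query_coverage=cov_qry,
        ortholog=mean_sim >= s_min and min(cov_ref, cov_qry) >= c_min,
    )


# ---------------------------------------------------------------------------
# Inventory comparison
# ---------------------------------------------------------------------------


@dataclass
class InventoryComparison:
    """One-to-one matching of conserved clusters between two strains."""

    strain_a: str
    strain_b: str
    matched_pairs: List[Tuple[str, str, ModuleAlignment]] = field(
        default_factory=list
    )
    unmatched_a: List[str] = field(default_factory=list)
    unmatched_b: List[str] = field(default_factory=list)


def _comparable(cluster: GeneCluster) -> bool:
    """Whether architecture matching can say anything about this cluster.

    Clusters need at least one assembly-line module, or must be a single
    standalone enzyme (type-III PKS), which is compared by exact identity.
    Multi-protein iterative systems (type-II PKS) always read
    KSalpha/KSbeta/ACP in this notation, so module-architecture matching
    carries no discriminating signal for them and abstains.
    """
    if _modules(cluster):
        return True
    tokens = cluster.standalone_tokens()
    return len(cluster.orfs) == 1 and len(tokens) == 1


def _candidate_alignment(
    a: GeneCluster, b: GeneCluster, thresholds: AlignmentThresholds
) -> Optional[ModuleAlignment]:
    if _modules(a) and _modules(b):
        return align_clusters(a, b, thresholds=thresholds)
    if not _modules(a) and not _modules(b):
        ta = [t.notation() for t in a.standalone_tokens()]
        tb = [t.notation() for t in b.standalone_tokens()]
        identical = ta == tb
        return ModuleAlignment(
            ref_id=a.cluster_id,
            query_id=b.cluster_id,
            pairs=[],
            score=1.0 if identical else 0.0,
            mean_similarity=1.0 if identical else 0.0,
            coverage=1.0 if identical else 0.0,
            query_coverage=1.0 if identical else 0.0,
            ortholog=identical,
        )
    return None


def compare_inventories(
    a: ClusterInventory,
    b: ClusterInventory,
    thresholds: AlignmentThresholds = DEFAULT_ALIGNMENT,
) -> InventoryComparison:
    """Find architecture-conserved cluster pairs between two strains.

    Candidate pairs are restricted to the same computed cluster type
    (hybrids only compare to hybrids), then matched greedily best-first by
    mean similarity among pairs with an ortholog verdict; the matching is
    one-to-one.  Ties are resolved by inventory order.
    """
    types_a = {c.cluster_id: classify_cluster(c) for c in a}
    types_b = {c.cluster_id: classify_cluster(c) for c in b}

    candidates = []
    for ia, ca in enumerate(a):
        if not _comparable(ca):
            continue
        for ib, cb in enumerate(b):
            if not _comparable(cb):
                continue
            if types_a[ca.cluster_id] != types_b[cb.cluster_id]:
                continue
            aln = _candidate_alignment(ca, cb, thresholds)
            if aln is not None and aln.ortholog:
                candidates.append((-aln.mean_similarity, ia, ib, aln))

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    comparison = InventoryComparison(strain_a=a.strain_id, strain_b=b.strain_id)
    for _, ia, ib, aln in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        comparison.matched_pairs.append((aln.ref_id, aln.query_id, aln))
    comparison.unmatched_a = [
        c.cluster_id for i, c in enumerate(a) if i not in used_a
    ]
    comparison.unmatched_b = [
        c.cluster_id for i, c in enumerate(b) if i not in used_b
    ]
    return comparison


# ---------------------------------------------------------------------------
# Reference screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Best match of a reference cluster within one strain's inventory."""

    strain_id: str
    best_cluster_id: Optional[str]
    mean_similarity: float
    coverage: float
    present: bool


def screen_for_ortholog(
    reference: GeneCluster,
    candidates: Sequence[ClusterInventory],
    thresholds: AlignmentThresholds = DEFAULT_ALIGNMENT,
) -> List[ScreenResult]:
    """Presence/absence of an ortholog of ``reference`` per strain.

    Each inventory is scanned for same-type clusters, the best-scoring
    alignment is kept, and presence is its ortholog verdict.
    """
    if not _modules(reference):
        raise ValueError("reference cluster has no modules")
    ref_type = classify_cluster(reference)
    results = []
    for inv in candidates:
        best: Optional[ModuleAlignment] = None
        for cluster in inv:
            if classify_cluster(cluster) != ref_type or not _modules(cluster):
                continue
            aln = align_clusters(reference, cluster, thresholds=thresholds)
            key = (aln.ortholog, aln.mean_similarity * min(
                aln.coverage, aln.query_coverage))
            if best is None or key > (
                best.ortholog,
                best.mean_similarity * min(best.coverage, best.query_coverage),
            ):
                best = aln
        results.append(
            ScreenResult(
                strain_id=inv.strain_id,
                best_cluster_id=best.query_id if best else None,
                mean_similarity=best.mean_similarity if best else 0.0,
                coverage=best.coverage if best else 0.0,
                present=bool(best and best.ortholog),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_alignment(
    ref: GeneCluster, query: GeneCluster, alignment: ModuleAlignment
) -> str:
    """Side-by-side text table of an alignment, '-' marking absent modules."""
    ref_mods = {m.index_label: m for m in ref.counted_modules()}
    qry_mods = {m.index_label: m for m in query.counted_modules()}
    w_label = max([1] + [len(r or "") for r, _, _ in alignment.pairs])
    w_ref = max(
        [len(ref.cluster_id)]
        + [len(ref_mods[r].notation()) for r, _, _ in alignment.pairs if r]
    )
    lines = [
        f"{'M':<{w_label}}  {ref.cluster_id:<{w_ref}}  {query.cluster_id}",
    ]
    for r, q, _ in alignment.pairs:
        left = ref_mods[r].notation() if r else "-"
        right = qry_mods[q].notation() if q else "-"
        lines.append(f"{r or '-':<{w_label}}  {left:<{w_ref}}  {right}")
    lines.append(
        f"# mean similarity {alignment.mean_similarity:.3f}, "
        f"coverage {alignment.coverage:.3f}/{alignment.query_coverage:.3f}, "
        f"ortholog {alignment.ortholog}"
    )
    return "\n".join(lines)
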