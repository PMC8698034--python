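"""Synthetic assembly-line clusters with known ground truth.

Real cluster inventories arrive as curated tables; to test every stage
without external data, this module generates random but realistic modular
clusters over the same domain repertoire the packaged tables use, produces
mutated copies of a reference cluster (whole-module deletions/insertions,
domain swaps, extender/substrate specificity flips) with an exact edit log
for ground-truth evaluation, and simulates diverged marker-gene pairs with
a known realized identity.

All generators are driven by a single seeded NumPy random stream: identical
seed and configuration give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .notation import (
    DomainToken,
    GeneCluster,
    Module,
    ORFArchitecture,
    relabel_modules,
)

__all__ = [
    "GeneratorConfig",
    "generate_cluster",
    "generate_inventory",
    "mutate_cluster",
    "replay_mutations",
    "generate_marker_pair",
]

_SUBSTRATES = (
    "ala", "asn", "cys", "gly", "glu", "ile", "leu", "phe", "pro", "ser",
    "thr", "val",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cluster generator.

    ``n_modules`` is either an exact module count or an inclusive
    ``(low, high)`` range; for PKS-type clusters the count includes the
    CoA-ligase loading module, matching how module totals are reported for
    the packaged tables.  ``domain_repertoire`` weights the optional
    tailoring domains drawn into PKS modules (the reductive loop) and NRPS
    modules.  ``mutation_rates`` is ``(p_module_del, p_module_ins,
    p_domain_swap, p_spec_flip)``, each a per-module (or per-domain, for
    flips) probability.
    """

    seed: int = 0
    n_modules: Union[int, Tuple[int, int]] = (3, 12)
    domain_repertoire: Dict[str, float] = field(
        default_factory=lambda: {"DH": 0.45, "ER": 0.2, "KR": 0.85,
                                 "MT": 0.05, "E": 0.1}
    )
    p_at_mm: float = 0.35
    substrate_alphabet: Sequence[str] = _SUBSTRATES
    p_substrate_annotated: float = 0.7
    mutation_rates: Tuple[float, float, float, float] = (0.05, 0.02, 0.05, 0.05)

    def __post_init__(self) -> None:
        probs = [self.p_at_mm, self.p_substrate_annotated, *self.mutation_rates]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        n = self.n_modules
        lo = n if isinstance(n, int) else n[0]
        if lo < 1:
            raise ValueError("n_modules must be >= 1")

    def draw_n_modules(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_modules, int):
            return self.n_modules
        lo, hi = self.n_modules
        return int(rng.integers(lo, hi + 1))


def _pks_module(config: GeneratorConfig, rng: np.random.Generator) -> Module:
    """One KS/AT/[reductive loop]/ACP extension module."""
    spec = "methylmalonyl" if rng.random() < config.p_at_mm else "malonyl"
    domains = [DomainToken("KS"), DomainToken("AT", spec)]
    rep = config.domain_repertoire
    # reductive domains in catalytic order; DH and ER require KR upstream
    has_kr = rng.random() < rep.get("KR", 0.0)
    if has_kr:
        if rng.random() < rep.get("DH", 0.0):
            domains.append(DomainToken("DH"))
            if rng.random() < rep.get("ER", 0.0):
                domains.append(DomainToken("ER"))
        domains.append(DomainToken("KR"))
    domains.append(DomainToken("ACP"))
    return Module(tuple(domains), "extension")


def _nrps_module(config: GeneratorConfig, rng: np.random.Generator) -> Module:
    """One C/A/T extension module, optionally annotated and tailored."""
    sub = None
    if rng.random() < config.p_substrate_annotated:
        sub = str(rng.choice(np.asarray(config.substrate_alphabet, dtype=object)))
    domains = [DomainToken("C"), DomainToken("A", sub), DomainToken("T")]
    rep = config.domain_repertoire
    if rng.random() < rep.get("MT", 0.0):
        domains.insert(2, DomainToken("MT"))
    if rng.random() < rep.get("E", 0.0):
        domains.append(DomainToken("E"))
    return Module(tuple(domains), "extension")


def generate_cluster(
    config: GeneratorConfig,
    kind: str = "t1pks",
    cluster_id: str = "synthetic-1",
    strain_id: str = "SYN",
) -> GeneCluster:
    """Generate a random, parseable assembly-line cluster.

    ``kind`` is ``t1pks`` (loading module plus KS/AT extension modules),
    ``nrps`` (C/A/T extension modules, thioesterase release) or
    ``pks_nrps`` (a random interleaving of both chemistries).
    """
    if kind not in ("t1pks", "nrps", "pks_nrps"):
        raise ValueError(f"unsupported cluster kind {kind!r}")
    rng = np.random.default_rng(config.seed)
    n = config.draw_n_modules(rng)

    modules: List[Module] = []
    if kind == "t1pks":
        modules.append(
            Module((DomainToken("CoL"), DomainToken("ACP")), "loading")
        )
        n_ext = max(1, n - 1)
        modules.extend(_pks_module(config, rng) for _ in range(n_ext))
    elif kind == "nrps":
        modules.extend(_nrps_module(config, rng) for _ in range(n))
    else:
        for _ in range(n):
            if rng.random() < 0.5:
                modules.append(_pks_module(config, rng))
            else:
                modules.append(_nrps_module(config, rng))

    # append a release domain to the final module
    last = modules[-1]
    modules[-1] = replace(last, domains=last.domains + (DomainToken("Te"),))

    cluster = _cluster_from_modules(
        modules, cluster_id, strain_id, kind, rng
    )
    return cluster


def _cluster_from_modules(
    modules: Sequence[Module],
    cluster_id: str,
    strain_id: str,
    kind: str,
    rng: np.random.Generator,
) -> GeneCluster:
    """Pack modules into ORFs of random size (1-6), like real megasynthases."""
    orfs: List[ORFArchitecture] = []
    i = 0
    orf_no = 0
    while i < len(modules):
        size = int(rng.integers(1, 7))
        orf_no += 1
        chunk = list(modules[i: i + size])
        orfs.append(
            ORFArchitecture(orf_id=f"orf-{orf_no}", elements=chunk)
        )
        i += size
    declared = "pks_nrps" if kind == "pks_nrps" else kind
    return GeneCluster(
        cluster_id=cluster_id,
        declared_type=declared,
        orfs=orfs,
        strain_id=strain_id,
        annotation=f"synthetic {kind} cluster",
    )


def generate_inventory(
    config: GeneratorConfig,
    n_clusters: int = 5,
    strain_id: str = "SYN",
    kinds: Sequence[str] = ("t1pks", "nrps", "pks_nrps"),
):
    """A synthetic strain inventory of ``n_clusters`` random clusters."""
    from .notation import ClusterInventory

    rng = np.random.default_rng(config.seed)
    clusters = []
    for k in range(n_clusters):
        kind = str(rng.choice(np.asarray(kinds, dtype=object)))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        clusters.append(
            generate_cluster(
                replace(config, seed=sub_seed),
                kind=kind,
                cluster_id=f"syn-{k + 1}",
                strain_id=strain_id,
            )
        )
    return ClusterInventory(strain_id=strain_id, clusters=clusters)


# ---------------------------------------------------------------------------
# Mutation with ground-truth log
# ---------------------------------------------------------------------------


def _flat_modules(cluster: GeneCluster) -> List[Module]:
    return cluster.counted_modules()


def mutate_cluster(
    parent: GeneCluster,
    config: GeneratorConfig,
    max_indels: Optional[int] = None,
) -> Tuple[GeneCluster, List[tuple]]:
    """Seeded module indels, domain swaps and specificity flips.

    Returns the mutant and an exact edit log; replaying the log on the
    parent (:func:`replay_mutations`) reproduces the mutant.  Log entries
    (positions are 0-based indices into the parent's loading+extension
    module list):

    - ``("delete_module", pos)``
    - ``("insert_module", pos, notation)`` — insert before ``pos`` a copy
      of an adjacent module, possibly perturbed
    - ``("swap_domain", pos, domain_index, new_label)``
    - ``("flip_specificity", pos, domain_index, new_specificity)``

    A deletion that would leave the cluster without modules is skipped and
    logged as ``("skipped_delete", pos)``.
    """
    if len(_flat_modules(parent)) < 2:
        raise ValueError("parent must have at least 2 modules")
    rng = np.random.default_rng(config.seed)
    p_del, p_ins, p_swap, p_flip = config.mutation_rates
    modules = _flat_modules(parent)
    n = len(modules)
    log: List[tuple] = []
    n_indels = 0

    def indel_budget_left() -> bool:
        return max_indels is None or n_indels < max_indels

    for pos in range(n):
        if rng.random() < p_del and indel_budget_left():
            remaining = n - len(
                [e for e in log if e[0] == "delete_module"]
            )
            if remaining <= 1:
                log.append(("skipped_delete", pos))
                continue
            log.append(("delete_module", pos))
            n_indels += 1
    for pos in range(n + 1):
        if rng.random() < p_ins and indel_budget_left():
            src = modules[min(pos, n - 1)]
            new = src
            if src.find("AT") is not None and rng.random() < 0.5:
                new = _flip_at(src)
            log.append(("insert_module", pos, new.notation()))
            n_indels += 1
    for pos, mod in enumerate(modules):
        if rng.random() < p_swap:
            swappable = [
                i for i, d in enumerate(mod.domains)
                if d.label in ("DH", "ER", "KR", "MT", "E")
            ]
            if swappable:
                i = int(rng.choice(swappable))
                choices = [
                    l for l in ("DH", "ER", "KR", "MT", "E")
                    if l != mod.domains[i].label
                ]
                new_label = str(rng.choice(np.asarray(choices, dtype=object)))
                log.append(("swap_domain", pos, i, new_label))
        for i, dom in enumerate(mod.domains):
            if dom.label in ("AT", "A") and dom.specificity and (
                rng.random() < p_flip
            ):
                if dom.label == "AT":
                    new_spec = (
                        "malonyl"
                        if dom.specificity == "methylmalonyl"
                        else "methylmalonyl"
                    )
                else:
                    others = [
                        s for s in config.substrate_alphabet
                        if s != dom.specificity
                    ]
                    new_spec = str(
                        rng.choice(np.asarray(others, dtype=object))
                    )
                log.append(("flip_specificity", pos, i, new_spec))

    mutant = replay_mutations(parent, log)
    return mutant, log


def _flip_at(module: Module) -> Module:
    domains = list(module.domains)
    for i, d in enumerate(domains):
        if d.label == "AT" and d.specificity:
            flipped = (
                "malonyl" if d.specificity == "methylmalonyl" else "methylmalonyl"
            )
            domains[i] = replace(d, specificity=flipped)
            break
    return replace(module, domains=tuple(domains))


def replay_mutations(parent: GeneCluster, log: Sequence[tuple]) -> GeneCluster:
    """Apply an edit log to a parent cluster, reproducing the mutant."""
    from .notation import parse_orf_architecture

    modules = list(_flat_modules(parent))

    edited: Dict[int, Module] = {i: m for i, m in enumerate(modules)}
    for entry in log:
        op = entry[0]
        if op == "swap_domain":
            _, pos, i, new_label = entry
            doms = list(edited[pos].domains)
            doms[i] = DomainToken(new_label)
            edited[pos] = replace(edited[pos], domains=tuple(doms))
        elif op == "flip_specificity":
            _, pos, i, new_spec = entry
            doms = list(edited[pos].domains)
            doms[i] = replace(doms[i], specificity=new_spec)
            edited[pos] = replace(edited[pos], domains=tuple(doms))

    deleted = {e[1] for e in log if e[0] == "delete_module"}
    inserts: Dict[int, List[Module]] = {}
    for entry in log:
        if entry[0] == "insert_module":
            _, pos, notation = entry
            orf = parse_orf_architecture(notation, "insert")
            inserts.setdefault(pos, []).extend(orf.modules)

    result: List[Module] = []
    for pos in range(len(modules) + 1):
        result.extend(inserts.get(pos, []))
        if pos < len(modules) and pos not in deleted:
            result.append(edited[pos])

    rng = np.random.default_rng(0)  # ORF packing of the mutant is canonical
    mutant = _cluster_from_modules(
        result,
        f"{parent.cluster_id}-mut",
        parent.strain_id,
        parent.declared_type,
        rng,
    )
    return mutant


# ---------------------------------------------------------------------------
# Marker-gene pairs
# ---------------------------------------------------------------------------


def generate_marker_pair(
    length: int, divergence: float, seed: int = 0
) -> Tuple[str, str, float]:
    """A random nucleotide sequence, a diverged copy, and the realized
    percent identity.

    Each position substitutes independently with probability ``divergence``
    (always to a different base), so the substitution count is
    Binomial(length, divergence) and the returned identity is exact.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    mutate = rng.random(length) < divergence
    other = np.array([np.delete(bases, np.where(bases == b)[0]) for b in seq])
    copy = seq.copy()
    if mutate.any():
        picks = rng.integers(0, 3, size=int(mutate.sum()))
        copy[mutate] = other[mutate, picks]
    identity = round(100.0 * (1.0 - mutate.sum() / length), 1)
    return "".join(seq), "".join(copy), float(identity)
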