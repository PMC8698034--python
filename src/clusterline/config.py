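"""Default analysis parameters, collected in one place.

The alignment thresholds are calibrated on the packaged cluster tables: they
must accept the quinolidomicin-reference alignment (near-identical flanks,
one module indel) and the four architecture-conserved cluster pairs between
the two packaged strains, while rejecting same-type clusters that merely
share the generic reduced-polyketide module vocabulary, and rejecting
unrelated random clusters.  The taxonomy thresholds are the standard
genomospecies boundaries: 98.5% gyrB identity (the marker-gene identity
corresponding to 70% DNA-DNA relatedness) and 70% digital DDH; both are
inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AlignmentThresholds:
    """Scoring and ortholog-verdict parameters for module alignment.

    gap_penalty
        Cost per unaligned module in the global alignment (score units of
        one module similarity).
    s_min
        Minimum mean per-position similarity over aligned module pairs for
        an ortholog verdict.
    c_min
        Minimum alignment coverage (fraction of modules aligned, on both
        the reference and the query side) for an ortholog verdict.
    specificity_weight
        Multiplier applied to a matched AT/A domain's contribution when
        both sides carry specificities that disagree (1.0 ignores
        specificity, 0.0 treats a disagreement as a full mismatch).
    """

    gap_penalty: float = 0.4
    s_min: float = 0.9
    c_min: float = 0.85
    specificity_weight: float = 0.0


@dataclass(frozen=True)
class TaxonomyThresholds:
    """Species-boundary thresholds (percent, inclusive)."""

    gyrb_identity: float = 98.5
    ddh: float = 70.0


@dataclass(frozen=True)
class RunConfig:
    """Bundle of all tunables used by the command-line interface."""

    alignment: AlignmentThresholds = field(default_factory=AlignmentThresholds)
    taxonomy: TaxonomyThresholds = field(default_factory=TaxonomyThresholds)
    seed: int = 0


DEFAULT_ALIGNMENT = AlignmentThresholds()
DEFAULT_TAXONOMY = TaxonomyThresholds()
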