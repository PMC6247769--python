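"""Clonal-hematopoiesis detection and false-positive filtering.

Clonally expanded white-blood-cell populations shed DNA into plasma, so
their somatic variants appear in cfDNA and mimic tumor variants unless
matched WBC DNA is profiled. The filter runs in a fixed order, each step
narrowing or relabelling, never adding:

1. discover candidates in WBC DNA against a pooled-healthy-donor
   background (one-sided exact count test);
2. exclude likely germline variants: WBC allele ratio above 25% outside
   known somatic hotspots;
3. validate the surviving candidates in patient-matched cfDNA with the
   same count test;
4. flag confirmed variants in the cfDNA somatic profile as CH false
   positives and remove them from tumor-attributed summaries.

Arm-level copy-number expansions in WBC are reported separately with the
cellularity implied by coverage ratio and SNP allele ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import stats

from .tumor_fraction import ArmEventCellularity, cellularity_from_arm_event
from .types import CHCandidate, CnaSegment, SomaticVariant

__all__ = [
    "GERMLINE_VAF_CUTOFF",
    "detect_wbc_variants",
    "germline_exclusion_filter",
    "validate_in_cfdna",
    "flag_ch_in_profile",
    "detect_wbc_cna",
    "CHFilterResult",
    "WbcCnaEvent",
    "run_ch_filter",
]

GERMLINE_VAF_CUTOFF = 0.25  # WBC allele ratio above which non-hotspots are germline
DEFAULT_BACKGROUND_RATE = 2e-3


def _count_test_p(alt: int, depth: int, rate: float) -> float:
    """One-sided exact p for observing >= alt reads at a background rate."""
    if depth <= 0:
        return 1.0
    return float(stats.binom.sf(alt - 1, depth, rate))


def _site_rate(background, key) -> tuple[float, bool]:
    if background is None:
        return DEFAULT_BACKGROUND_RATE, True
    if isinstance(background, dict):
        if key in background:
            return float(background[key]), False
        return DEFAULT_BACKGROUND_RATE, True
    return float(background), False


def detect_wbc_variants(
    variants: list[SomaticVariant],
    pooled_background=None,
    alpha: float = 0.01,
    min_alt_reads: int = 3,
) -> list[CHCandidate]:
    """Candidate hematopoietic variants from WBC allele counts.

    ``pooled_background`` is a per-site error-rate dict keyed by
    ``(chrom, pos, ref, alt)``, a global scalar rate, or ``None`` (global
    default). A variant becomes a candidate when its WBC alt support
    exceeds the background at significance ``alpha`` with at least
    ``min_alt_reads`` supporting reads.
    """
    candidates = []
    missing_sites = 0
    for v in variants:
        rate, fell_back = _site_rate(pooled_background, v.key)
        missing_sites += int(fell_back and isinstance(pooled_background, dict))
        if v.wbc_alt_depth < min_alt_reads:
            continue
        p = _count_test_p(v.wbc_alt_depth, v.wbc_depth, rate)
        if p < alpha:
            candidates.append(
                CHCandidate(
                    variant=v,
                    wbc_vaf=v.wbc_vaf,
                    cfdna_vaf=v.vaf,
                    hotspot=v.hotspot,
                    background_rate=rate,
                    status="candidate",
                    wbc_p=p,
                )
            )
    if missing_sites:
        warnings.warn(
            f"{missing_sites} sites lacked a pooled-background rate; "
            f"using global default {DEFAULT_BACKGROUND_RATE}"
        )
    return candidates


def germline_exclusion_filter(candidates: list[CHCandidate]) -> list[CHCandidate]:
    """Mark likely-germline candidates: WBC VAF > 25% outside hotspots.

    Hotspot variants are exempt regardless of allele ratio. Idempotent;
    returns the same list with statuses updated in place.
    """
    for c in candidates:
        if c.status in ("candidate", "excluded_germline"):
            if c.wbc_vaf > GERMLINE_VAF_CUTOFF and not c.hotspot:
                c.status = "excluded_germline"
            else:
                c.status = "candidate"
    return candidates


def validate_in_cfdna(
    candidates: list[CHCandidate],
    alpha: float = 0.01,
    min_alt_reads: int = 3,
) -> list[CHCandidate]:
    """Confirm candidates whose cfDNA alt support also exceeds background."""
    for c in candidates:
        if c.status != "candidate":
            continue
        v = c.variant
        if v.cfdna_depth == 0:
            c.status = "unconfirmed"
            c.note = "site not covered in cfDNA"
            continue
        p = _count_test_p(v.cfdna_alt_depth, v.cfdna_depth, c.background_rate)
        c.cfdna_p = p
        if p < alpha and v.cfdna_alt_depth >= min_alt_reads:
            c.status = "confirmed_CH"
        else:
            c.status = "unconfirmed"
    return candidates


@dataclass
class CHFilterResult:
    """Somatic cfDNA profile partitioned into tumor and CH variants."""

    tumor_variants: list = field(default_factory=list)
    flagged_variants: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_variants)


def flag_ch_in_profile(
    somatic_variants: list[SomaticVariant],
    confirmed: list[CHCandidate],
) -> CHFilterResult:
    """Remove confirmed CH variants from the tumor-attributed profile.

    Variants are matched by (chrom, pos, ref, alt). Every confirmed CH
    variant present in the somatic call set is flagged as a CH false
    positive; everything else remains tumor-attributed.
    """
    ch_keys = {c.variant.key for c in confirmed if c.status == "confirmed_CH"}
    result = CHFilterResult()
    for v in somatic_variants:
        if v.key in ch_keys:
            result.flagged_variants.append(v)
        else:
            result.tumor_variants.append(v)
    return result


@dataclass
class WbcCnaEvent:
    """Copy-number event in WBC DNA with its implied cellularity."""

    segment: CnaSegment
    scale: str  # arm | focal
    cellularity: ArmEventCellularity | None


def detect_wbc_cna(
    wbc_segments: list[CnaSegment],
    arm_min_length: float = 30e6,
) -> list[WbcCnaEvent]:
    """Report non-neutral WBC segments with cellularity estimates.

    Segments at least ``arm_min_length`` long are arm-level; shorter
    non-neutral segments (e.g. a focal amplification) are reported as
    focal. Cellularity uses assumed copy number 1 for losses and 3 for
    gains; events whose coverage ratio exceeds the single-extra-copy
    range carry no estimate.
    """
    events = []
    for seg in wbc_segments:
        if not seg.is_aberrant:
            continue
        assumed_cn = 1 if seg.coverage_ratio < 1.0 else 3
        cellularity: ArmEventCellularity | None
        try:
            cellularity = cellularity_from_arm_event(
                seg.coverage_ratio, seg.baf, assumed_cn
            )
        except ValueError:
            cellularity = None
        scale = "arm" if seg.length >= arm_min_length else "focal"
        events.append(WbcCnaEvent(segment=seg, scale=scale, cellularity=cellularity))
    return events


def run_ch_filter(
    variants: list[SomaticVariant],
    somatic_calls: list[SomaticVariant],
    pooled_background=None,
    alpha: float = 0.01,
    min_alt_reads: int = 3,
) -> tuple[list[CHCandidate], CHFilterResult]:
    """Full detect -> germline-exclude -> validate -> flag pipeline."""
    candidates = detect_wbc_variants(variants, pooled_background, alpha, min_alt_reads)
    candidates = germline_exclusion_filter(candidates)
    candidates = validate_in_cfdna(candidates, alpha, min_alt_reads)
    return candidates, flag_ch_in_profile(somatic_calls, candidates)
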