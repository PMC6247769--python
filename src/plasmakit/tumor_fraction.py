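"""ctDNA tumor-fraction estimation from mutations and the CNA profile.

The cfDNA of a cancer patient is a mixture of tumor-derived and normal
DNA. Writing ``tf`` for the tumor fraction, a somatic variant present on
``m`` of ``CN_t`` tumor copies at a locus has expected allele fraction

    VAF = m * tf / (CN_t * tf + 2 * (1 - tf))

and a segment at total tumor copy number ``CN`` has expected
sample/control coverage ratio

    r = (CN * tf + 2 * (1 - tf)) / 2

with mirrored het-SNP B-allele fraction

    BAF = (M * tf + (1 - tf)) / (CN * tf + 2 * (1 - tf))

for major-allele copy number ``M``. These closed forms are inverted per
variant / per segment and combined into a single estimate; the CNA-based
estimate replaces the mutation-based one whenever it is higher.

Detection tiers follow the fixed cutoffs 0.02 (point mutations), 0.10
(LOH) and 0.20 (homozygous deletions): below each cutoff the respective
event class is not reliably detectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    CN_OF_CALL,
    MAJOR_CN_OF_CALL,
    CnaSegment,
    SomaticVariant,
    TumorFractionEstimate,
)

__all__ = [
    "TF_MUTATION_CUTOFF",
    "TF_LOH_CUTOFF",
    "TF_HOMDEL_CUTOFF",
    "TumorFractionError",
    "expected_vaf",
    "tf_from_mutation",
    "tf_from_cna",
    "estimate_tumor_fraction",
    "detection_tier",
    "cellularity_from_arm_event",
    "ArmEventCellularity",
]

TF_MUTATION_CUTOFF = 0.02
TF_LOH_CUTOFF = 0.10
TF_HOMDEL_CUTOFF = 0.20


class TumorFractionError(ValueError):
    """Raised when inputs admit no tumor-fraction estimate."""


def expected_vaf(tf: float, cn_t: float, m: float) -> float:
    """Expected allele fraction of a somatic variant at tumor fraction ``tf``.

    Parameters
    ----------
    tf : tumor fraction in [0, 1].
    cn_t : total tumor copy number at the locus.
    m : number of tumor copies carrying the variant.
    """
    denom = cn_t * tf + 2.0 * (1.0 - tf)
    if denom <= 0:
        raise TumorFractionError("degenerate mixture: no DNA at locus")
    return m * tf / denom


def tf_from_mutation(vaf: float, cn_t: float = 2.0, m: float = 1.0) -> float:
    """Invert the mixture relation: tumor fraction implied by one variant.

    Solves ``VAF = m*tf / (CN_t*tf + 2(1-tf))`` for ``tf``, giving

        tf = 2 * VAF / (m + VAF * (2 - CN_t))

    clipped to [0, 1]. In the diploid single-copy case this is the familiar
    ``tf = 2 * VAF``.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    if m < 1.0:
        raise ValueError("multiplicity m must be >= 1")
    denom = m + vaf * (2.0 - cn_t)
    if denom <= 0:
        raise TumorFractionError(
            f"inconsistent inputs (vaf={vaf}, cn_t={cn_t}, m={m}): denominator <= 0"
        )
    return float(np.clip(2.0 * vaf / denom, 0.0, 1.0))


def _tf_from_ratio(r: float, cn: int) -> float | None:
    """Tumor fraction implied by a coverage ratio at nominal copy number."""
    if cn == 2:
        return None  # neutral coverage carries no purity signal
    return float(np.clip(2.0 * (r - 1.0) / (cn - 2.0), 0.0, 1.0))


def _tf_from_baf(baf: float, cn: int, major: int) -> float | None:
    """Tumor fraction implied by a mirrored BAF at nominal (CN, major CN).

    Closed-form inversions of BAF = (M*tf + (1-tf)) / (CN*tf + 2(1-tf)):
    CN=1 -> tf = 2 - 1/BAF; CN=2 (LOH) -> tf = 2*BAF - 1;
    CN=3 -> tf = (2*BAF-1)/(1-BAF); CN=4 -> tf = (2*BAF-1)/(2*(1-BAF)).
    """
    if cn == 2 * major or cn == 0:  # allelically balanced, or no DNA to genotype
        return None
    denom = major - 1.0 - baf * (cn - 2.0)
    if abs(denom) < 1e-12:
        return None
    tf = (2.0 * baf - 1.0) / denom
    return float(np.clip(tf, 0.0, 1.0))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    return float(values[np.searchsorted(cum, 0.5 * cum[-1])])


def tf_from_cna(
    segments: list[CnaSegment],
    min_snps: int = 10,
    discordance_limit: float = 0.15,
) -> tuple[float, bool, int]:
    """Consensus tumor fraction from aberrant copy-number segments.

    Each aberrant segment contributes the coverage-ratio inversion and,
    when its call implies allelic imbalance, the BAF inversion (the two
    are averaged per segment). The consensus is the n_snps-weighted median
    across segments. Returns ``(tf, discordant, n_segments)``; segments
    whose calls disagree by more than ``discordance_limit`` set the
    discordance flag.
    """
    estimates, weights = [], []
    for seg in segments:
        if not seg.is_aberrant or seg.n_snps < min_snps:
            continue
        cn = CN_OF_CALL[seg.cn_call]
        major = MAJOR_CN_OF_CALL[seg.cn_call]
        parts = []
        tf_r = _tf_from_ratio(seg.coverage_ratio, cn)
        if tf_r is not None:
            parts.append(tf_r)
        tf_b = _tf_from_baf(seg.baf, cn, major)
        if tf_b is not None:
            parts.append(tf_b)
        if parts:
            estimates.append(float(np.mean(parts)))
            weights.append(float(seg.n_snps))
    if not estimates:
        return 0.0, False, 0
    values = np.asarray(estimates)
    tf = _weighted_median(values, np.asarray(weights))
    discordant = bool(values.max() - values.min() > discordance_limit) if len(values) > 1 else False
    return tf, discordant, len(values)


def _refine_multiplicity(variants: list[SomaticVariant], tf0: float) -> np.ndarray:
    """One refinement pass for per-variant multiplicity.

    Default multiplicity is 1; a variant is promoted to m >= 2 only when
    its VAF at the provisional tumor fraction implies it (e.g. a mutation
    on the retained allele of an LOH region, or on an amplified allele).
    """
    ms = np.ones(len(variants))
    if tf0 <= 0:
        return ms
    for i, v in enumerate(variants):
        denom = v.local_total_cn * tf0 + 2.0 * (1.0 - tf0)
        m_implied = v.vaf * denom / tf0
        m_max = max(1.0, round(v.local_total_cn))
        ms[i] = float(np.clip(round(m_implied), 1.0, m_max))
    return ms


def estimate_tumor_fraction(
    variants: list[SomaticVariant],
    segments: list[CnaSegment],
    min_alt_reads: int = 3,
    percentile: float = 90.0,
    min_snps: int = 10,
) -> TumorFractionEstimate:
    """Combined ctDNA fraction estimate for one sample.

    The mutation-based estimate is the ``percentile``-th percentile of
    per-variant ``tf_from_mutation`` values over presumed-clonal variants
    with at least ``min_alt_reads`` supporting reads (an upper robust
    summary approximating the clonal peak while resisting subclonal
    dilution). Where the CNA profile suggests a higher tumor burden, the
    estimate is instead taken from the CNA profile:
    ``tf_final = max(tf_vaf, tf_cna)``.
    """
    usable = [
        v
        for v in variants
        if v.cfdna_alt_depth >= min_alt_reads and v.effect not in ("synonymous", "intronic")
    ]
    tf_vaf = 0.0
    if usable:
        # pass 1: multiplicity 1 everywhere
        first = np.array([tf_from_mutation(v.vaf, v.local_total_cn, 1.0) for v in usable])
        tf0 = float(np.percentile(first, percentile))
        # pass 2: refine multiplicity, drop presumed-subclonal variants
        ms = _refine_multiplicity(usable, tf0)
        refined = np.array(
            [tf_from_mutation(v.vaf, v.local_total_cn, m) for v, m in zip(usable, ms)]
        )
        clonal_mask = np.array([v.vaf >= tf0 / 4.0 for v in usable]) if tf0 > 0 else np.ones(
            len(usable), dtype=bool
        )
        pool = refined[clonal_mask] if clonal_mask.any() else refined
        tf_vaf = float(np.clip(np.percentile(pool, percentile), 0.0, 1.0))

    tf_cna, discordant, n_seg = tf_from_cna(segments, min_snps=min_snps)
    tf_final = max(tf_vaf, tf_cna)
    if tf_final == 0.0:
        method = "none"
    elif tf_cna > tf_vaf:
        method = "cna"
    else:
        method = "vaf"
    return TumorFractionEstimate(
        tf_vaf=tf_vaf,
        tf_cna=tf_cna,
        tf_final=tf_final,
        tier=detection_tier(tf_final),
        method=method,
        cna_discordant=discordant,
        n_variants_used=len(usable),
        n_segments_used=n_seg,
    )


def detection_tier(tf: float) -> frozenset:
    """Detectability flags implied by a tumor fraction (inclusive cutoffs)."""
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf must lie in [0, 1]")
    flags = set()
    if tf >= TF_MUTATION_CUTOFF:
        flags.add("mutation_detectable")
    if tf >= TF_LOH_CUTOFF:
        flags.add("loh_detectable")
    if tf >= TF_HOMDEL_CUTOFF:
        flags.add("homdel_detectable")
    return frozenset(flags)


@dataclass
class ArmEventCellularity:
    """Coverage- and BAF-implied cellularity of an arm-level event."""

    from_ratio: float
    from_baf: float | None
    gap: float | None


def cellularity_from_arm_event(
    r: float, baf: float, assumed_cn: int
) -> ArmEventCellularity:
    """Cellularity of a clonally expanded cell population from one event.

    Used for arm-level copy-number changes in white-blood-cell DNA, where
    the aberrant clone occupies a fraction ``c`` of cells. The coverage
    route gives ``c = 2(r-1)/(CN-2)``; the BAF route inverts the allele
    ratio relation for CN=1 (``c = 2 - 1/BAF``) or CN=3
    (``c = (2*BAF-1)/(1-BAF)``). The agreement gap between the two routes
    indicates whether a single clone explains both signals.
    """
    if r <= 0:
        raise ValueError("coverage ratio must be > 0")
    if not 0.5 <= baf <= 1.0:
        raise ValueError("mirrored baf must lie in [0.5, 1]")
    if assumed_cn == 2:
        raise ValueError("a copy-neutral state carries no cellularity signal")
    if assumed_cn not in (1, 3):
        raise ValueError("assumed_cn must be 1 or 3")
    c_r = float(np.clip(2.0 * (r - 1.0) / (assumed_cn - 2.0), 0.0, 1.0))
    major = 1 if assumed_cn == 1 else 2
    c_b = _tf_from_baf(baf, assumed_cn, major)
    gap = abs(c_r - c_b) if c_b is not None else None
    return ArmEventCellularity(from_ratio=c_r, from_baf=c_b, gap=gap)
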