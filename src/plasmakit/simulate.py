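"""Seeded synthetic-cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes so
every stage is testable without patient data:

* somatic variant read counts are binomial (optionally beta-binomial)
  draws at the expected allele fraction
  ``VAF = m*tf / (CN_t*tf + 2(1-tf))`` given the local copy number;
* copy-number segments carry coverage ratios
  ``r = (CN*tf + 2(1-tf)) / 2`` with multiplicative log-normal noise and
  mirrored het-SNP BAFs consistent with the planted allelic state;
* microsatellite histograms follow a geometric PCR-stutter baseline;
  unstable loci reallocate most of the tumor reads to 1-3 novel repeat
  lengths, so instability is separable at 10% purity;
* clonal-hematopoiesis variants appear in both WBC and cfDNA at matched
  allele fractions, germline-like variants at ~50%, and tumor variants in
  WBC only at the sequencing error rate;
* tumor-suppressor zygosity (wild-type / monoallelic / biallelic) is
  planted per gene together with the generating mechanism (homozygous
  deletion, mutation+LOH, two mutations, or mutation+SV).

Identical seed and configuration reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .types import CnaSegment, MsatProfile, SampleMeta, SomaticVariant, StructuralVariant

__all__ = [
    "GENE_MODELS",
    "CHROM_LENGTHS",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedSample",
    "simulate_sample",
    "simulate_cohort",
    "simulate_normal_profiles",
    "dilute_in_silico",
]

#: approximate GRCh38 gene bodies for the targeted panel
GENE_MODELS = {
    "TP53": ("chr17", 7_668_402, 7_687_550),
    "PTEN": ("chr10", 87_863_113, 87_971_930),
    "RB1": ("chr13", 48_303_748, 48_481_890),
    "BRCA2": ("chr13", 32_315_086, 32_400_268),
    "ATM": ("chr11", 108_222_484, 108_369_102),
    "CHEK2": ("chr22", 28_687_743, 28_742_422),
    "AR": ("chrX", 67_544_021, 67_730_619),
    "SPOP": ("chr17", 49_598_884, 49_678_163),
    "FOXA1": ("chr14", 37_589_552, 37_595_730),
    "DNMT3A": ("chr2", 25_227_855, 25_342_590),
    "SF3B1": ("chr2", 197_388_515, 197_435_079),
    "CTNNB1": ("chr3", 41_194_741, 41_260_096),
    "NRAS": ("chr1", 114_704_469, 114_716_894),
    "BRAF": ("chr7", 140_713_328, 140_924_929),
    "AKT1": ("chr14", 104_769_349, 104_795_751),
    "TMPRSS2": ("chr21", 41_464_300, 41_531_116),
    "ERG": ("chr21", 38_380_027, 38_661_780),
}

#: approximate GRCh38 chromosome lengths
CHROM_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895,
}

#: tumor suppressors with planted zygosity ground truth
TS_GENES = ("TP53", "PTEN", "RB1", "BRCA2", "ATM")
#: genes hosting clonal-hematopoiesis variants
CH_GENES = ("DNMT3A", "TP53", "SF3B1", "NRAS", "BRAF", "AKT1", "CTNNB1")
#: chromosomes free of panel genes, used for background copy-number events
_BACKGROUND_CHROMS = (
    "chr4", "chr5", "chr6", "chr8", "chr9", "chr12",
    "chr15", "chr16", "chr18", "chr19", "chr20",
)

_HIGH_IMPACT_EFFECTS = ("frameshift", "truncating", "splice", "hotspot_missense")
_LINES = ("mHNPC", "mHSPC", "mCRPC1", "mCRPC2", "mCRPC3", "mCRPC4+")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``true_tf`` / ``msi_status`` accept a scalar applied to every sample,
    a per-sample sequence, or ``None`` (tf drawn uniformly from
    ``tf_range``; MSI negative). ``noise`` is the beta-binomial
    overdispersion of read counts (0 = pure binomial).
    """

    seed: int = 0
    n_patients: int = 10
    depth_cfdna: float = 800.0
    depth_wbc: float = 445.0
    true_tf: object = None
    msi_status: object = False
    unstable_locus_fraction: float = 0.10
    n_msat_loci: int = 100
    ch_variants_per_patient: int = 1
    noise: float = 0.0
    # -- secondary knobs (documented in docs/methods.md) -------------------
    tf_range: tuple = (0.05, 0.8)
    depth_sigma: float = 0.25  # per-target log-normal depth spread
    error_rate: float = 5e-4  # per-base background error after dedup
    r_noise_sd: float = 0.02  # log-normal sd of segment coverage ratios
    baf_noise_sd: float = 0.01
    stutter_rate: float = 0.15  # geometric stutter decay per repeat unit
    unstable_shift: float = 0.9  # tumor read mass moved to the novel allele
    n_passenger_mean: float = 5.0
    n_subclonal_mean: float = 2.0
    msi_snv_mean: float = 40.0
    msi_indel_mean: float = 25.0
    n_background_cna_mean: float = 3.0
    ch_vaf_range: tuple = (0.005, 0.5)
    ch_hotspot_fraction: float = 0.4
    germline_variants_per_patient: int = 2
    sv_support_bias: float = 0.5  # SV callers recover ~half the true AF
    gene_state_probs: tuple = (0.5, 0.15, 0.35)  # wild_type, monoallelic, biallelic
    ar_amplification_prob: float = 0.25
    residual_breakpoint_prob: float = 0.3
    min_call_alt_reads: int = 3

    def __post_init__(self) -> None:
        for name in ("depth_cfdna", "depth_wbc"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a finite positive depth")
        for name in (
            "unstable_locus_fraction", "noise", "error_rate",
            "ch_hotspot_fraction", "sv_support_bias", "unstable_shift",
            "residual_breakpoint_prob", "ar_amplification_prob",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        for name in ("n_patients", "n_msat_loci", "ch_variants_per_patient",
                     "germline_variants_per_patient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")
        if self.true_tf is not None and np.isscalar(self.true_tf):
            if not np.isfinite(self.true_tf) or not 0.0 <= self.true_tf <= 1.0:
                raise ValueError("true_tf must be a fraction in [0, 1]")
        if abs(sum(self.gene_state_probs) - 1.0) > 1e-9:
            raise ValueError("gene_state_probs must sum to 1")

    def _key(self) -> tuple:
        return tuple(
            tuple(v) if isinstance(v, (list, tuple)) else v
            for v in (getattr(self, f.name) for f in fields(self))
        )


@dataclass
class GroundTruth:
    """Planted truth for one simulated sample."""

    true_tf: float
    msi_status: bool
    variant_origin: dict = field(default_factory=dict)  # key -> tumor|CH|germline
    variant_clonal: dict = field(default_factory=dict)  # key -> bool (tumor only)
    gene_zygosity: dict = field(default_factory=dict)  # gene -> state
    gene_mechanism: dict = field(default_factory=dict)  # gene -> mechanism
    unstable_loci: frozenset = frozenset()
    residual_breakpoint_genes: frozenset = frozenset()
    cna_burden: float = 0.0


@dataclass
class SimulatedSample:
    """One synthetic plasma sample with its matched-WBC data and truth."""

    meta: SampleMeta
    variants: list  # every variant with cfDNA + WBC depths (incl. germline)
    somatic_calls: list  # the cfDNA somatic call set (tumor + CH reads present)
    segments: list
    svs: list
    msat_profiles: list
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level draws


def _draw_alt(rng: np.random.Generator, depth: int, p: float, rho: float) -> int:
    """Alt-read count at depth: binomial, or beta-binomial when rho > 0."""
    p = float(np.clip(p, 0.0, 1.0))
    if depth <= 0 or p == 0.0:
        return 0
    if rho > 0 and 0.0 < p < 1.0:
        nu = 1.0 / rho - 1.0
        p = rng.beta(p * nu, (1.0 - p) * nu)
    return int(rng.binomial(depth, p))


def _draw_depth(rng: np.random.Generator, mean: float, sigma: float) -> int:
    depth = rng.lognormal(np.log(mean) - 0.5 * sigma**2, sigma)
    return max(1, int(round(depth)))


def _resolve(value, index: int, default):
    if value is None:
        return default
    if np.isscalar(value) or isinstance(value, (bool, np.bool_)):
        return value
    return value[index]


# ---------------------------------------------------------------------------
# copy-number segments


def _segment_observables(
    rng: np.random.Generator, cn: int, major: int, tf: float, cfg: SimulationConfig
) -> tuple[float, float]:
    """Noisy (coverage ratio, mirrored BAF) for a planted segment state."""
    total = cn * tf + 2.0 * (1.0 - tf)
    r = total / 2.0
    if cfg.r_noise_sd > 0:
        r *= rng.lognormal(0.0, cfg.r_noise_sd)
    r = max(r, 1e-3)
    baf = (major * tf + (1.0 - tf)) / total if total > 0 else 0.5
    if cfg.baf_noise_sd > 0:
        baf += rng.normal(0.0, cfg.baf_noise_sd)
    baf = float(np.clip(max(baf, 1.0 - baf), 0.5, 1.0))
    return float(r), baf


_CALL_STATE = {  # cn_call -> (total CN, major CN)
    "homozygous_deletion": (0, 0),
    "deletion_LOH": (1, 1),
    "neutral": (2, 1),
    "neutral_LOH": (2, 2),
    "gain": (3, 2),
    "amplification": (4, 3),
}


def _build_segments(
    rng: np.random.Generator,
    planted: dict[str, list[tuple[int, int, str]]],
    tf: float,
    cfg: SimulationConfig,
) -> list[CnaSegment]:
    """Tile every chromosome with planted events and neutral filler."""
    segments = []
    for chrom, length in CHROM_LENGTHS.items():
        events = sorted(planted.get(chrom, []))
        cursor = 0
        for start, end, call in events:
            start, end = max(0, start), min(length, end)
            if start > cursor:
                segments.append(_make_segment(rng, chrom, cursor, start, "neutral", tf, cfg))
            segments.append(_make_segment(rng, chrom, start, end, call, tf, cfg))
            cursor = end
        if cursor < length:
            segments.append(_make_segment(rng, chrom, cursor, length, "neutral", tf, cfg))
    return segments


def _make_segment(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    end: int,
    call: str,
    tf: float,
    cfg: SimulationConfig,
) -> CnaSegment:
    cn, major = _CALL_STATE[call]
    r, baf = _segment_observables(rng, cn, major, tf, cfg)
    n_snps = max(2, (end - start) // 500_000)  # ~1 informative het SNP / 500 kb
    return CnaSegment(
        chrom=chrom, start=start, end=end,
        coverage_ratio=r, baf=baf, n_snps=n_snps, cn_call=call,
    )


def _local_state(segments: list[CnaSegment], chrom: str, pos: int) -> tuple[int, int]:
    for seg in segments:
        if seg.chrom == chrom and seg.start < pos <= seg.end:
            return _CALL_STATE[seg.cn_call]
    return 2, 1


# ---------------------------------------------------------------------------
# microsatellite histograms


def _stutter_weights(rate: float) -> np.ndarray:
    offsets = np.arange(-2, 3)
    w = rate ** np.abs(offsets)
    return w / w.sum()


def _msat_profiles(
    rng: np.random.Generator,
    tf: float,
    unstable: frozenset,
    cfg: SimulationConfig,
) -> list[MsatProfile]:
    profiles = []
    stable_w = _stutter_weights(cfg.stutter_rate)
    for i in range(cfg.n_msat_loci):
        locus = f"MS{i:03d}"
        modal = 12 + (i % 28)
        depth = _draw_depth(rng, cfg.depth_cfdna, cfg.depth_sigma)
        lengths = modal + np.arange(-2, 3)
        weights = stable_w.copy()
        if locus in unstable and tf > 0:
            # tumor reads: most of the mass moves to a novel expanded allele
            # that stutters like any repeat, so 1-3 novel lengths are
            # supported depending on purity and depth
            offset = int(rng.choice([-7, -6, -5, 5, 6, 7]))
            novel_mass = cfg.unstable_shift
            tumor_lengths = np.concatenate([lengths, modal + offset + np.arange(-2, 3)])
            tumor_w = np.concatenate(
                [(1.0 - novel_mass) * stable_w, novel_mass * stable_w]
            )
            mixed_lengths, mixed_w = _mix_histogram_weights(
                lengths, stable_w, tumor_lengths, tumor_w, tf
            )
            counts = rng.multinomial(depth, mixed_w)
            profiles.append(MsatProfile(locus, mixed_lengths, counts))
        else:
            counts = rng.multinomial(depth, weights)
            profiles.append(MsatProfile(locus, lengths, counts))
    return profiles


def _mix_histogram_weights(lengths_a, w_a, lengths_b, w_b, fraction_b):
    """Union-of-lengths mixture (1-fraction)*A + fraction*B."""
    union = np.union1d(lengths_a, lengths_b)
    mixed = np.zeros(union.shape)
    mixed[np.searchsorted(union, lengths_a)] += (1.0 - fraction_b) * w_a
    mixed[np.searchsorted(union, lengths_b)] += fraction_b * np.asarray(w_b)
    return union, mixed / mixed.sum()


def simulate_normal_profiles(config: SimulationConfig, index: int = 0) -> list[MsatProfile]:
    """Microsatellite histograms of one normal (tumor-free) sample."""
    rng = np.random.default_rng([config.seed, 9_999_000 + index])
    return _msat_profiles(rng, 0.0, frozenset(), config)


def dilute_in_silico(
    tumor: list[MsatProfile],
    normal: list[MsatProfile],
    purity: float,
    seed: int = 0,
) -> list[MsatProfile]:
    """Read-level mixture of a tumor and a normal microsatellite profile.

    Per locus, each of the tumor profile's ``depth`` reads is drawn from
    the tumor histogram with probability ``purity`` and from the normal
    histogram otherwise, preserving total depth within sampling.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    tumor_by_id = {p.locus_id: p for p in tumor}
    normal_by_id = {p.locus_id: p for p in normal}
    missing = sorted(set(tumor_by_id) ^ set(normal_by_id))
    if missing:
        raise ValueError(f"locus sets disagree; unmatched loci: {missing}")
    rng = np.random.default_rng(seed)
    mixed = []
    for locus_id in sorted(tumor_by_id):
        t, n = tumor_by_id[locus_id], normal_by_id[locus_id]
        depth = t.depth
        k = int(rng.binomial(depth, purity))
        union = np.union1d(t.repeat_lengths, n.repeat_lengths)
        counts = np.zeros(union.shape, dtype=int)
        if k > 0 and t.depth > 0:
            draw = rng.multinomial(k, t.read_counts / t.depth)
            counts[np.searchsorted(union, t.repeat_lengths)] += draw
        if depth - k > 0 and n.depth > 0:
            draw = rng.multinomial(depth - k, n.read_counts / n.depth)
            counts[np.searchsorted(union, n.repeat_lengths)] += draw
        mixed.append(MsatProfile(locus_id, union, counts))
    return mixed


# ---------------------------------------------------------------------------
# variants and structural variants


_BASES = ("A", "C", "G", "T")


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _place_variant(
    rng: np.random.Generator,
    gene: str,
    effect: str,
    ccf: float,
    tf: float,
    segments: list[CnaSegment],
    cfg: SimulationConfig,
    used: set,
    indel: bool = False,
) -> SomaticVariant:
    chrom, g_start, g_end = GENE_MODELS[gene]
    pos = int(rng.integers(g_start, g_end))
    while (chrom, pos) in used:
        pos = int(rng.integers(g_start, g_end))
    used.add((chrom, pos))
    cn, major = _local_state(segments, chrom, pos)
    m = 1.0
    cell_tf = ccf * tf
    denom = cn * tf + 2.0 * (1.0 - tf)
    vaf = m * cell_tf / denom if denom > 0 else 0.0
    depth_cf = _draw_depth(rng, cfg.depth_cfdna, cfg.depth_sigma)
    depth_wbc = _draw_depth(rng, cfg.depth_wbc, cfg.depth_sigma)
    alt_cf = _draw_alt(rng, depth_cf, vaf, cfg.noise)
    alt_wbc = _draw_alt(rng, depth_wbc, cfg.error_rate, cfg.noise)
    if indel:
        ref, alt = "CA", "C"
    else:
        ref, alt = _random_snv_alleles(rng)
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, effect=effect,
        cfdna_ref_depth=depth_cf - alt_cf, cfdna_alt_depth=alt_cf,
        wbc_ref_depth=depth_wbc - alt_wbc, wbc_alt_depth=alt_wbc,
        hotspot=(effect == "hotspot_missense"),
        local_total_cn=float(cn), multiplicity=m,
    )


def _gene_sv(
    rng: np.random.Generator,
    gene: str,
    region: str,
    tf: float,
    cfg: SimulationConfig,
) -> StructuralVariant:
    chrom, g_start, g_end = GENE_MODELS[gene]
    p1 = int(rng.integers(g_start, g_end))
    p2 = int(rng.integers(g_start, g_end))
    if p1 > p2:
        p1, p2 = p2, p1
    sv_type = ("deletion", "inversion", "duplication")[rng.integers(3)]
    true_af = tf / 2.0  # heterozygous event in the tumor
    depth = _draw_depth(rng, cfg.depth_cfdna, cfg.depth_sigma)
    support = _draw_alt(rng, depth, true_af * cfg.sv_support_bias, cfg.noise)
    return StructuralVariant(
        chrom1=chrom, pos1=p1, chrom2=chrom, pos2=max(p2, p1 + 1),
        sv_type=sv_type,
        genes_disrupted=[(gene, region)],
        supporting_fraction=support / depth,
    )


# ---------------------------------------------------------------------------
# the sample-level generator


def simulate_sample(config: SimulationConfig, sample_index: int) -> SimulatedSample:
    """Generate one synthetic plasma sample plus matched WBC data and truth."""
    if sample_index >= config.n_patients:
        raise ValueError("sample_index must be < n_patients")
    rng = np.random.default_rng([config.seed, sample_index])
    tf = float(_resolve(config.true_tf, sample_index,
                        rng.uniform(*config.tf_range)))
    msi_spec = _resolve(config.msi_status, sample_index, False)
    if isinstance(msi_spec, (bool, np.bool_)):
        msi = bool(msi_spec)
    else:  # probability
        msi = bool(rng.random() < float(msi_spec))

    truth = GroundTruth(true_tf=tf, msi_status=msi)
    used_positions: set = set()
    planted_cna: dict[str, list] = {}
    svs: list[StructuralVariant] = []
    residual_genes = set()

    # ---- plant tumor-suppressor zygosity states -------------------------
    mechanisms = {}
    for gene in TS_GENES:
        state = ("wild_type", "monoallelic", "biallelic")[
            rng.choice(3, p=config.gene_state_probs)
        ]
        truth.gene_zygosity[gene] = state
        if state == "biallelic":
            mechanisms[gene] = ("homdel", "mut_loh", "two_mut", "mut_sv")[
                rng.integers(4)
            ]
        elif state == "monoallelic":
            mechanisms[gene] = "mut_only" if rng.random() < 0.7 else "sv_only"
    truth.gene_mechanism = dict(mechanisms)

    for gene, mech in mechanisms.items():
        chrom, g_start, g_end = GENE_MODELS[gene]
        margin = int(rng.integers(200_000, 2_000_000))
        if mech == "homdel":
            planted_cna.setdefault(chrom, []).append(
                (g_start - margin, g_end + margin, "homozygous_deletion")
            )
            if rng.random() < config.residual_breakpoint_prob:
                svs.append(_gene_sv(rng, gene, "exonic_span", tf, config))
                residual_genes.add(gene)
        elif mech == "mut_loh":
            planted_cna.setdefault(chrom, []).append(
                (g_start - margin, g_end + margin, "deletion_LOH")
            )
    truth.residual_breakpoint_genes = frozenset(residual_genes)

    # ---- AR amplification ------------------------------------------------
    ar_amplified = rng.random() < config.ar_amplification_prob
    if ar_amplified:
        chrom, g_start, g_end = GENE_MODELS["AR"]
        planted_cna.setdefault(chrom, []).append(
            (g_start - 500_000, g_end + 500_000, "amplification")
        )
        if rng.random() < 0.4:  # intra-AR SV rides along with amplification
            svs.append(_gene_sv(rng, "AR", "exonic_span", tf, config))
    truth.gene_zygosity["AR"] = "amplified" if ar_amplified else "wild_type"

    # ---- background arm-level events on gene-free chromosomes ----------
    n_background = rng.poisson(config.n_background_cna_mean)
    bg_chroms = rng.permutation(np.array(_BACKGROUND_CHROMS))
    for j in range(min(n_background, len(bg_chroms))):
        chrom = str(bg_chroms[j])
        length = CHROM_LENGTHS[chrom]
        size = int(rng.integers(30_000_000, min(90_000_000, length - 1)))
        start = int(rng.integers(0, length - size))
        call = ("deletion_LOH", "gain")[rng.integers(2)]
        planted_cna.setdefault(chrom, []).append((start, start + size, call))

    segments = _build_segments(rng, planted_cna, tf, config)
    genome = sum(CHROM_LENGTHS.values())
    truth.cna_burden = (
        sum(s.length for s in segments if s.is_aberrant) / genome
    )

    # ---- driver mutations implementing the planted states ---------------
    variants: list[SomaticVariant] = []

    def add_tumor_variant(gene, effect, ccf, indel=False):
        v = _place_variant(rng, gene, effect, ccf, tf, segments, config,
                           used_positions, indel)
        variants.append(v)
        truth.variant_origin[v.key] = "tumor"
        truth.variant_clonal[v.key] = ccf >= 0.5
        return v

    for gene, mech in mechanisms.items():
        effect = _HIGH_IMPACT_EFFECTS[rng.integers(4)]
        if mech in ("mut_loh", "mut_only"):
            add_tumor_variant(gene, effect, 1.0, indel=effect == "frameshift")
        elif mech == "two_mut":
            add_tumor_variant(gene, effect, 1.0)
            add_tumor_variant(gene, _HIGH_IMPACT_EFFECTS[rng.integers(4)], 1.0)
        elif mech == "mut_sv":
            add_tumor_variant(gene, effect, 1.0)
            svs.append(_gene_sv(rng, gene, "exonic_span", tf, config))
        elif mech == "sv_only":
            svs.append(_gene_sv(rng, gene, "exonic_span", tf, config))

    # ---- clonal passengers ----------------------------------------------
    homdel_genes = {g for g, m in mechanisms.items() if m == "homdel"}
    passenger_pool = [g for g in GENE_MODELS if g not in homdel_genes]
    n_clonal = max(4, rng.poisson(config.n_passenger_mean))
    for _ in range(n_clonal):
        gene = passenger_pool[rng.integers(len(passenger_pool))]
        effect = ("missense_nonhotspot", "synonymous", "intronic")[
            rng.choice(3, p=(0.5, 0.25, 0.25))
        ]
        add_tumor_variant(gene, effect, 1.0)

    # ---- subclonal passengers -------------------------------------------
    for _ in range(rng.poisson(config.n_subclonal_mean)):
        gene = passenger_pool[rng.integers(len(passenger_pool))]
        effect = ("missense_nonhotspot", "synonymous", "intronic")[rng.integers(3)]
        add_tumor_variant(gene, effect, float(rng.uniform(0.1, 0.4)))

    # ---- MSI hypermutation ----------------------------------------------
    if msi:
        for _ in range(rng.poisson(config.msi_snv_mean)):
            gene = passenger_pool[rng.integers(len(passenger_pool))]
            effect = ("missense_nonhotspot", "synonymous", "intronic")[rng.integers(3)]
            add_tumor_variant(gene, effect, 1.0)
        for _ in range(rng.poisson(config.msi_indel_mean)):
            gene = passenger_pool[rng.integers(len(passenger_pool))]
            effect = ("frameshift", "intronic")[rng.integers(2)]
            add_tumor_variant(gene, effect, 1.0, indel=True)

    # ---- clonal hematopoiesis and germline variants ---------------------
    lo, hi = config.ch_vaf_range
    for _ in range(config.ch_variants_per_patient):
        gene = CH_GENES[rng.integers(len(CH_GENES))]
        ch_vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        hotspot = rng.random() < config.ch_hotspot_fraction
        chrom, g_start, g_end = GENE_MODELS[gene]
        pos = int(rng.integers(g_start, g_end))
        while (chrom, pos) in used_positions:
            pos = int(rng.integers(g_start, g_end))
        used_positions.add((chrom, pos))
        depth_cf = _draw_depth(rng, config.depth_cfdna, config.depth_sigma)
        depth_wbc = _draw_depth(rng, config.depth_wbc, config.depth_sigma)
        alt_cf = _draw_alt(rng, depth_cf, ch_vaf, config.noise)
        alt_wbc = _draw_alt(rng, depth_wbc, ch_vaf, config.noise)
        ref, alt = _random_snv_alleles(rng)
        v = SomaticVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            effect="hotspot_missense" if hotspot else "missense_nonhotspot",
            cfdna_ref_depth=depth_cf - alt_cf, cfdna_alt_depth=alt_cf,
            wbc_ref_depth=depth_wbc - alt_wbc, wbc_alt_depth=alt_wbc,
            hotspot=hotspot,
        )
        variants.append(v)
        truth.variant_origin[v.key] = "CH"

    for _ in range(config.germline_variants_per_patient):
        gene = passenger_pool[rng.integers(len(passenger_pool))]
        chrom, g_start, g_end = GENE_MODELS[gene]
        pos = int(rng.integers(g_start, g_end))
        while (chrom, pos) in used_positions:
            pos = int(rng.integers(g_start, g_end))
        used_positions.add((chrom, pos))
        depth_cf = _draw_depth(rng, config.depth_cfdna, config.depth_sigma)
        depth_wbc = _draw_depth(rng, config.depth_wbc, config.depth_sigma)
        alt_cf = _draw_alt(rng, depth_cf, 0.5, config.noise)
        alt_wbc = _draw_alt(rng, depth_wbc, 0.5, config.noise)
        ref, alt = _random_snv_alleles(rng)
        v = SomaticVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            effect="missense_nonhotspot",
            cfdna_ref_depth=depth_cf - alt_cf, cfdna_alt_depth=alt_cf,
            wbc_ref_depth=depth_wbc - alt_wbc, wbc_alt_depth=alt_wbc,
            hotspot=False,
        )
        variants.append(v)
        truth.variant_origin[v.key] = "germline"

    # ---- TMPRSS2-ERG fusion ---------------------------------------------
    if rng.random() < 0.3 and tf > 0:
        c1, s1, e1 = GENE_MODELS["TMPRSS2"]
        c2, s2, e2 = GENE_MODELS["ERG"]
        depth = _draw_depth(rng, config.depth_cfdna, config.depth_sigma)
        support = _draw_alt(rng, depth, tf / 2.0 * config.sv_support_bias, config.noise)
        svs.append(
            StructuralVariant(
                chrom1=c1, pos1=int(rng.integers(s1, e1)),
                chrom2=c2, pos2=int(rng.integers(s2, e2)),
                sv_type="translocation",
                genes_disrupted=[("TMPRSS2", "exonic_span"), ("ERG", "exonic_span")],
                supporting_fraction=support / depth,
            )
        )
    # occasional intronic VUS structural variant
    if rng.random() < 0.1 and tf > 0:
        gene = passenger_pool[rng.integers(len(passenger_pool))]
        svs.append(_gene_sv(rng, gene, "single_intron", tf, config))

    # ---- microsatellites -------------------------------------------------
    if msi:
        n_unstable = int(round(config.unstable_locus_fraction * config.n_msat_loci))
        unstable = frozenset(
            f"MS{i:03d}"
            for i in rng.choice(config.n_msat_loci, size=n_unstable, replace=False)
        )
    else:
        unstable = frozenset()
    truth.unstable_loci = unstable
    msat_profiles = _msat_profiles(rng, tf, unstable, config)

    # ---- cfDNA somatic call set: cfDNA-supported variants surviving the
    # matched-WBC germline subtraction (high WBC allele ratio outside
    # hotspots looks germline and never enters a somatic profile)
    somatic_calls = [
        v
        for v in variants
        if truth.variant_origin[v.key] in ("tumor", "CH")
        and v.cfdna_alt_depth >= config.min_call_alt_reads
        and not (v.wbc_vaf > 0.25 and not v.hotspot)
    ]

    # ---- metadata: CTC count and cfDNA concentration track tumor burden --
    ctc = max(0, int(round(rng.lognormal(np.log(200.0 * tf + 1.0), 0.8))) - 1)
    concentration = float(rng.lognormal(np.log(10.0 + 60.0 * tf), 0.4))
    meta = SampleMeta(
        patient_id=f"P{sample_index:04d}",
        sample_id=f"S{sample_index:04d}",
        timepoint="baseline",
        stage_line=_LINES[rng.integers(len(_LINES))],
        ctc_count=ctc,
        cfdna_concentration=concentration,
    )

    return SimulatedSample(
        meta=meta,
        variants=variants,
        somatic_calls=somatic_calls,
        segments=segments,
        svs=svs,
        msat_profiles=msat_profiles,
        ground_truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> list[SimulatedSample]:
    """All ``n_patients`` samples of a synthetic cohort."""
    return [simulate_sample(config, i) for i in range(config.n_patients)]
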