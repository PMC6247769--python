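"""Microsatellite-instability calling from cfDNA microsatellite histograms.

Baseline-referenced scoring in the style of mSINGS: for every targeted
microsatellite locus, the number of supported repeat-length alleles
(lengths with read support of at least ``peak_fraction`` of the modal
length's support) is compared against a baseline of normal samples. A
locus is unstable when its allele count exceeds ``mu + k * sigma`` of the
baseline; a sample's MSI score is the fraction of evaluable loci that are
unstable. Samples with a ctDNA fraction below 0.1 are not evaluable, and
a sample whose score clears the 0.10 cutoff without an accompanying
increase in mutation count is downgraded to MSS when it shows a high
copy-number burden (a chromosomal-instability phenotype mimicking locus
instability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MsatProfile, SomaticVariant

__all__ = [
    "MSI_SCORE_CUTOFF",
    "MSI_TF_ELIGIBILITY",
    "MsatBaseline",
    "MsiResult",
    "MsiCaller",
    "allele_count",
    "build_baseline",
    "score_locus",
    "msi_score",
    "count_mutations",
    "call_msi",
    "dilution_benchmark",
]

MSI_SCORE_CUTOFF = 0.10  # fraction of unstable loci at/above which MSI is called
MSI_TF_ELIGIBILITY = 0.10  # minimum ctDNA fraction for an evaluable call


@dataclass
class MsatBaseline:
    """Per-locus allele-count baseline across normal samples.

    ``stats`` maps locus_id -> (mu, sd, n_normals); sd is the population
    standard deviation (divisor n).
    """

    stats: dict

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.stats

    def __getitem__(self, locus_id: str) -> tuple:
        return self.stats[locus_id]

    def __len__(self) -> int:
        return len(self.stats)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus_id": k, "mu": mu, "sd": sd, "n": n}
            for k, (mu, sd, n) in sorted(self.stats.items())
        ]
        return pd.DataFrame(rows, columns=["locus_id", "mu", "sd", "n"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MsatBaseline":
        return cls(
            {
                str(r.locus_id): (float(r.mu), float(r.sd), int(r.n))
                for r in frame.itertuples()
            }
        )


@dataclass
class MsiResult:
    """Outcome of MSI evaluation for one sample."""

    fraction_unstable: float
    n_loci_evaluated: int
    n_unstable: int
    snv_count: int
    indel_count: int
    call: str  # MSI | MSS | not_evaluable
    cna_burden: float = 0.0
    cin_exception: bool = False
    low_confidence: bool = False


def allele_count(profile: MsatProfile, peak_fraction: float = 0.05) -> int:
    """Number of supported repeat-length alleles in one histogram.

    A length qualifies when its read support is at least ``peak_fraction``
    of the modal length's support (and non-zero).
    """
    counts = profile.read_counts
    if counts.sum() == 0:
        return 0
    modal = counts.max()
    threshold = peak_fraction * modal
    return int(((counts >= threshold) & (counts > 0)).sum())


def build_baseline(
    normals: list[list[MsatProfile]],
    min_depth: int = 30,
    peak_fraction: float = 0.05,
) -> MsatBaseline:
    """Allele-count baseline from a panel of normal samples.

    Each element of ``normals`` is one normal sample's locus profiles.
    Loci with depth >= ``min_depth`` in fewer than two normals are
    excluded. The per-locus spread is the population SD (divisor n).
    """
    if not normals:
        raise ValueError("at least one normal sample is required")
    per_locus: dict[str, list[int]] = {}
    for sample in normals:
        for profile in sample:
            if profile.depth >= min_depth:
                per_locus.setdefault(profile.locus_id, []).append(
                    allele_count(profile, peak_fraction)
                )
    stats = {
        locus: (float(np.mean(v)), float(np.std(v)), len(v))
        for locus, v in per_locus.items()
        if len(v) >= 2
    }
    if not stats:
        raise ValueError("no locus was covered in at least two normals")
    return MsatBaseline(stats)


def score_locus(
    profile: MsatProfile,
    baseline_locus: tuple,
    peak_fraction: float = 0.05,
    k: float = 2.0,
    min_depth: int = 30,
) -> bool | None:
    """Per-locus instability call; ``None`` when the locus is not evaluable."""
    if profile.depth < min_depth:
        return None
    mu, sd = baseline_locus[0], baseline_locus[1]
    return allele_count(profile, peak_fraction) > mu + k * sd


def msi_score(
    profiles: list[MsatProfile],
    baseline: MsatBaseline,
    peak_fraction: float = 0.05,
    k: float = 2.0,
    min_depth: int = 30,
) -> tuple[float, int, int]:
    """Fraction of unstable loci: ``(fraction, n_evaluated, n_unstable)``."""
    n_eval = n_unstable = 0
    for profile in profiles:
        if profile.locus_id not in baseline:
            continue
        verdict = score_locus(
            profile, baseline[profile.locus_id], peak_fraction, k, min_depth
        )
        if verdict is None:
            continue
        n_eval += 1
        n_unstable += int(verdict)
    fraction = n_unstable / n_eval if n_eval else 0.0
    return fraction, n_eval, n_unstable


def count_mutations(variants: list[SomaticVariant]) -> tuple[int, int]:
    """(SNV, indel) counts for one sample, including intronic and synonymous."""
    snv = sum(1 for v in variants if not v.is_indel)
    indel = sum(1 for v in variants if v.is_indel)
    return snv, indel


def call_msi(
    score: float,
    counts: tuple[int, int],
    tf: float,
    cna_burden: float = 0.0,
    score_cutoff: float = MSI_SCORE_CUTOFF,
    tf_eligibility: float = MSI_TF_ELIGIBILITY,
    mutation_count_reference: float | None = None,
    elevation_factor: float = 3.0,
    cna_burden_cutoff: float = 0.30,
    n_loci_evaluated: int = 0,
    min_loci: int = 30,
) -> MsiResult:
    """MSI / MSS / not_evaluable call for one sample.

    ``mutation_count_reference`` is the cohort median total mutation count
    at comparable tumor fraction; mutation counts are "elevated" above
    ``elevation_factor`` times that reference. A score above the cutoff
    without elevated counts is downgraded to MSS only when the copy-number
    burden (fraction of the genome in non-neutral segments) exceeds
    ``cna_burden_cutoff`` — a chromosomal-instability phenotype; without
    that evidence the sample is called MSI with a low-confidence flag.
    """
    snv, indel = counts
    if tf < tf_eligibility or (n_loci_evaluated and n_loci_evaluated < min_loci):
        return MsiResult(score, n_loci_evaluated, 0, snv, indel, "not_evaluable", cna_burden)
    if score < score_cutoff:
        return MsiResult(score, n_loci_evaluated, 0, snv, indel, "MSS", cna_burden)
    elevated = (
        True
        if mutation_count_reference is None
        else (snv + indel) > elevation_factor * mutation_count_reference
    )
    if elevated:
        return MsiResult(score, n_loci_evaluated, 0, snv, indel, "MSI", cna_burden)
    if cna_burden > cna_burden_cutoff:
        return MsiResult(
            score, n_loci_evaluated, 0, snv, indel, "MSS", cna_burden, cin_exception=True
        )
    return MsiResult(
        score, n_loci_evaluated, 0, snv, indel, "MSI", cna_burden, low_confidence=True
    )


class MsiCaller:
    """Baseline-referenced MSI caller with a scikit-learn-style interface.

    ``fit`` builds the per-locus allele-count baseline from normal
    samples; ``score_samples`` returns each sample's fraction of unstable
    loci and ``predict`` thresholds that fraction at ``score_threshold``
    (mutation-count and tumor-fraction gating are applied separately via
    :func:`call_msi`, which needs per-sample metadata).

    Parameters
    ----------
    peak_fraction : minimum read support for an allele, as a fraction of
        the modal length's support.
    k : number of baseline SDs above the mean allele count at which a
        locus is unstable.
    min_depth : minimum locus depth for evaluation.
    min_loci : minimum evaluable loci for a sample-level score.
    score_threshold : fraction-unstable cutoff for the MSI label
        (inclusive).
    """

    def __init__(
        self,
        peak_fraction: float = 0.05,
        k: float = 2.0,
        min_depth: int = 30,
        min_loci: int = 30,
        score_threshold: float = MSI_SCORE_CUTOFF,
    ):
        self.peak_fraction = peak_fraction
        self.k = k
        self.min_depth = min_depth
        self.min_loci = min_loci
        self.score_threshold = score_threshold

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "peak_fraction": self.peak_fraction,
            "k": self.k,
            "min_depth": self.min_depth,
            "min_loci": self.min_loci,
            "score_threshold": self.score_threshold,
        }

    def set_params(self, **params) -> "MsiCaller":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- estimator API -----------------------------------------------------
    def fit(self, normals: list[list[MsatProfile]], y=None) -> "MsiCaller":
        self.baseline_ = build_baseline(normals, self.min_depth, self.peak_fraction)
        self.n_loci_ = len(self.baseline_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("MsiCaller must be fit on normal samples first")

    def score_samples(self, samples: list[list[MsatProfile]]) -> np.ndarray:
        """Fraction of unstable loci per sample (NaN if too few loci)."""
        self._check_fitted()
        out = np.empty(len(samples))
        for i, profiles in enumerate(samples):
            fraction, n_eval, _ = msi_score(
                profiles, self.baseline_, self.peak_fraction, self.k, self.min_depth
            )
            out[i] = fraction if n_eval >= self.min_loci else np.nan
        return out

    def predict(self, samples: list[list[MsatProfile]]) -> np.ndarray:
        """Boolean MSI label per sample by the score-threshold rule alone."""
        scores = self.score_samples(samples)
        return (scores >= self.score_threshold) & ~np.isnan(scores)


def dilution_benchmark(
    msi_samples: list[list[MsatProfile]],
    mss_samples: list[list[MsatProfile]],
    normals: list[list[MsatProfile]],
    purity_grid: list[float],
    n_reps: int = 1,
    seed: int = 0,
    caller: MsiCaller | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of the MSI caller under in-silico dilution.

    Each MSI sample is diluted to every purity on the grid by read-level
    mixing against a paired normal (cycled from ``normals``), then scored
    against a baseline built from ``normals``. MSS samples are scored
    undiluted, so specificity is purity-invariant and is repeated on every
    row for convenience. Only the score-threshold rule is exercised; the
    mutation-count cross-check needs variant calls and is bypassed here.
    """
    if not purity_grid:
        raise ValueError("purity grid must be non-empty")
    for p in purity_grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"purity {p} outside [0, 1]")
    from .simulate import dilute_in_silico  # local import to avoid a cycle

    caller = caller or MsiCaller()
    caller.fit(normals)
    mss_called = caller.predict(mss_samples)
    specificity = 1.0 - float(np.mean(mss_called)) if len(mss_called) else float("nan")

    rows = []
    rng = np.random.default_rng(seed)
    for purity in purity_grid:
        called = []
        for _ in range(n_reps):
            for i, tumor in enumerate(msi_samples):
                normal = normals[i % len(normals)]
                mixed = dilute_in_silico(
                    tumor, normal, purity, seed=int(rng.integers(2**31))
                )
                called.append(bool(caller.predict([mixed])[0]))
        rows.append(
            {
                "purity": purity,
                "sensitivity": float(np.mean(called)),
                "specificity": specificity,
                "n_msi": len(msi_samples) * n_reps,
                "n_mss": len(mss_samples),
            }
        )
    return pd.DataFrame(rows)
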