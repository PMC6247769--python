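"""Cohort-level report assembly.

Renders the per-line-of-therapy tumor-burden table (baseline vs
follow-up), the MSI summary, per-gene alteration fractions and the
clonal-hematopoiesis false-positive counts into plain DataFrames with
deterministic ordering, ready to be written as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interpret import gene_alteration_summary
from .tumor_fraction import TF_MUTATION_CUTOFF

__all__ = ["CohortReport", "cohort_report"]

_LINE_ORDER = ["mHNPC", "mHSPC", "mCRPC1", "mCRPC2", "mCRPC3", "mCRPC4+"]


@dataclass
class CohortReport:
    """Bundle of cohort summary tables."""

    tumor_burden: pd.DataFrame
    msi_summary: pd.DataFrame
    gene_alterations: dict = field(default_factory=dict)
    ch_summary: pd.DataFrame | None = None
    key_mismatches: list = field(default_factory=list)


def _line_sort_key(line: str) -> int:
    return _LINE_ORDER.index(line) if line in _LINE_ORDER else len(_LINE_ORDER)


def cohort_report(
    metas: list,
    estimates: dict,
    gene_statuses: dict | None = None,
    msi_results: dict | None = None,
    ch_results: dict | None = None,
    genes: list | None = None,
) -> CohortReport:
    """Assemble the cohort report.

    All per-sample inputs are keyed by ``sample_id``; metadata rows whose
    key is missing from a table are listed under ``key_mismatches`` and
    skipped for that table.
    """
    gene_statuses = gene_statuses or {}
    msi_results = msi_results or {}
    ch_results = ch_results or {}
    mismatches = sorted(
        {m.sample_id for m in metas} - set(estimates)
    )

    # -- tumor burden by line of therapy and timepoint ---------------------
    rows = []
    groups: dict = {}
    for meta in metas:
        if meta.sample_id not in estimates:
            continue
        groups.setdefault((meta.stage_line, meta.timepoint), []).append(
            estimates[meta.sample_id].tf_final
        )
    for (line, timepoint) in sorted(groups, key=lambda k: (_line_sort_key(k[0]), k[1])):
        tfs = np.asarray(groups[(line, timepoint)])
        rows.append(
            {
                "stage_line": line,
                "timepoint": timepoint,
                "n_samples": tfs.size,
                "median_tf": float(np.median(tfs)),
                "frac_ctdna_detected": float(np.mean(tfs >= TF_MUTATION_CUTOFF)),
            }
        )
    burden = pd.DataFrame(
        rows,
        columns=["stage_line", "timepoint", "n_samples", "median_tf", "frac_ctdna_detected"],
    )

    # -- MSI summary -------------------------------------------------------
    calls = [msi_results[m.sample_id].call for m in metas if m.sample_id in msi_results]
    n_eval = sum(1 for c in calls if c != "not_evaluable")
    msi_summary = pd.DataFrame(
        [
            {
                "n_samples": len(calls),
                "n_evaluable": n_eval,
                "n_msi": sum(1 for c in calls if c == "MSI"),
                "frac_msi_of_evaluable": (
                    sum(1 for c in calls if c == "MSI") / n_eval if n_eval else float("nan")
                ),
            }
        ]
    )

    # -- gene alteration fractions ----------------------------------------
    pairs = [
        (m, gene_statuses[m.sample_id]) for m in metas if m.sample_id in gene_statuses
    ]
    gene_tables = {}
    for gene in genes or []:
        gene_tables[gene] = gene_alteration_summary(pairs, gene)

    # -- clonal hematopoiesis ----------------------------------------------
    ch_summary = None
    if ch_results:
        n_flagged = sum(r.n_flagged for r in ch_results.values())
        patients = {
            m.patient_id
            for m in metas
            if m.sample_id in ch_results and ch_results[m.sample_id].n_flagged > 0
        }
        all_patients = {m.patient_id for m in metas if m.sample_id in ch_results}
        ch_summary = pd.DataFrame(
            [
                {
                    "n_flagged_variants": n_flagged,
                    "n_patients_with_ch": len(patients),
                    "frac_patients_with_ch": (
                        len(patients) / len(all_patients) if all_patients else float("nan")
                    ),
                }
            ]
        )

    return CohortReport(
        tumor_burden=burden,
        msi_summary=msi_summary,
        gene_alterations=gene_tables,
        ch_summary=ch_summary,
        key_mismatches=mismatches,
    )
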