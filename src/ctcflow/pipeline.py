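"""End-to-end orchestration: cohort in, consolidated report out.

``run_pipeline`` ties the stages together: derive the HER2 positivity
cutoff from the control Gaussians, resolve the cohort (packaged fixture,
external CSV, or simulation), stratify into groups A/A'/B/C, and compute the
cohort statistics.  Survival analysis runs whenever progression-free
survival columns are present; the mutation-landscape summary always runs on
a simulated matrix (real per-sample calls are not distributed) and is
flagged ``synthetic`` in the report.

The report is plain JSON; every number in it is produced by an operation in
the library, and provenance (config hash, seed, package version) is echoed
so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ctcflow import __version__
from ctcflow.cohort import (
    assign_groups,
    concordance,
    group_emt_summary,
    holm_adjust,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    pairwise_rank_test,
    spearman_rho,
)
from ctcflow.errors import ValidationError
from ctcflow.her2 import ThresholdModel, classify_her2
from ctcflow.io import AnalysisConfig, load_cohort_csv, load_table2_fixture
from ctcflow.landscape import (
    annotate_emt_genes,
    gene_group_presence,
    group_median_counts,
    venn_partition,
)
from ctcflow.cohort import tissue_her2_status
from ctcflow.synthetic import (
    default_cohort_spec,
    default_mutation_model,
    simulate_cohort,
    simulate_mutation_matrix,
)

__all__ = ["ReportBundle", "prepare_cohort", "run_pipeline"]


@dataclass
class ReportBundle:
    """Consolidated analysis report with provenance."""

    payload: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary_text(self) -> str:
        p = self.payload
        sizes = p["group_sizes"]
        a_prime = sizes["A'"]
        lines = [
            f"HER2 positivity cutoff: > {p['cutoff']} "
            f"(raw crossover {p['t_raw']:.4f})",
            f"Patients: {p['n_patients']}  groups "
            f"A={sizes['A']} (A'={a_prime}) "
            f"B={sizes['B']} C={sizes['C']}",
            f"Tissue/CTC concordance: {p['concordance']['n_concordant']}/"
            f"{p['concordance']['n_total']} "
            f"({p['concordance']['percent']}%)",
            f"Spearman rho (HER2 intensity ~ EMT-index): "
            f"{p['spearman_rho']:.3f}",
            f"Median CTC count: {p['median_ctc_count']:g}   "
            f"median EMT-index: {p['median_emt_index']:g}",
        ]
        for row in p["group_emt"]:
            lines.append(
                f"  EMT-index {row['stratum']}: median {row['median']:.3f} "
                f"({row['min']:.2f}-{row['max']:.2f}), n={row['n']}"
            )
        if "survival" in p:
            for g, med in p["survival"]["km_median_months"].items():
                label = "not reached" if med is None else f"{med:.1f}"
                lines.append(f"  median PFS {g}: {label} months")
            lines.append(
                f"  log-rank p = {p['survival']['logrank_p']:.4g}"
            )
        return "\n".join(lines)


def _cohort_from_csv(path: str, cutoff: int) -> pd.DataFrame:
    raw = load_cohort_csv(path)
    records = raw.copy()
    records["tissue_her2"] = [
        tissue_her2_status(ihc, fish)
        for ihc, fish in zip(raw["ihc_score"], raw["fish_ratio"])
    ]
    status = []
    for x in raw["ctc_her2_intensity"]:
        status.append(
            None if pd.isna(x) else classify_her2(float(x), cutoff)
        )
    records["ctc_her2_status"] = status
    return assign_groups(records)


def prepare_cohort(config: AnalysisConfig, cutoff: int) -> pd.DataFrame:
    """Resolve the cohort table named by the configuration."""
    if config.cohort_source == "fixture":
        return load_table2_fixture()
    if config.cohort_source == "csv":
        if config.cohort_csv is None:
            raise ValidationError("cohort_source 'csv' needs cohort_csv")
        return _cohort_from_csv(config.cohort_csv, cutoff)
    spec = default_cohort_spec(config.cohort_sim.n_patients)
    spec = type(spec)(
        **{
            **spec.__dict__,
            "coupling": config.cohort_sim.coupling,
            "censoring_fraction": config.cohort_sim.censoring_fraction,
            "cutoff": cutoff,
        }
    )
    return simulate_cohort(spec, seed=config.seed)


def run_pipeline(config: AnalysisConfig | None = None) -> ReportBundle:
    config = config or AnalysisConfig()
    model = ThresholdModel(
        mu_neg=config.threshold.mu_neg,
        sigma_neg=config.threshold.sigma_neg,
        mu_pos=config.threshold.mu_pos,
        sigma_pos=config.threshold.sigma_pos,
    )
    records = prepare_cohort(config, model.cutoff)

    conc = concordance(records)
    measured = records.dropna(subset=["ctc_her2_intensity", "emt_index"])
    rho = spearman_rho(
        measured["ctc_her2_intensity"], measured["emt_index"]
    )
    emt_summary = group_emt_summary(records)

    strata = {
        row["stratum"]: records_for_stratum(records, row["stratum"])
        for _, row in emt_summary.iterrows()
    }
    kw_h, kw_p = kruskal_wallis(
        *[s["emt_index"].to_numpy() for s in strata.values()]
    )
    labels = list(strata)
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    pair_p = [
        pairwise_rank_test(
            strata[a]["emt_index"].to_numpy(),
            strata[b]["emt_index"].to_numpy(),
        )
        for a, b in pairs
    ]
    if config.multiplicity == "holm":
        pair_p = holm_adjust(pair_p)

    group_sizes = {
        "A": int((records["group"] == "A").sum()),
        "A'": int(records["a_prime"].sum()),
        "B": int((records["group"] == "B").sum()),
        "C": int((records["group"] == "C").sum()),
    }

    payload: dict = {
        "cutoff": model.cutoff,
        "t_raw": model.t_raw,
        "n_patients": len(records),
        "group_sizes": group_sizes,
        "concordance": {
            "n_concordant": conc.n_concordant,
            "n_total": conc.n_total,
            "percent": conc.percent,
        },
        "spearman_rho": round(rho, 6),
        "median_ctc_count": float(records["ctc_count"].median()),
        "median_emt_index": float(records["emt_index"].median()),
        "group_emt": emt_summary.to_dict(orient="records"),
        "kruskal_wallis": {"H": kw_h, "p": kw_p},
        "pairwise_p": {
            f"{a} vs {b}": p for (a, b), p in zip(pairs, pair_p)
        },
        "provenance": {
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "version": __version__,
            "cohort_source": config.cohort_source,
        },
    }

    if "pfs_months" in records.columns and records["pfs_months"].notna().any():
        surv = records.dropna(subset=["pfs_months"])
        medians, groups_te = {}, {}
        for g in ("A", "B", "C"):
            sub = surv[surv["group"] == g]
            if len(sub) == 0:
                continue
            curve = km_estimate(
                sub["pfs_months"], sub["pfs_event"].astype(bool)
            )
            medians[g] = curve.median
            groups_te[g] = (
                sub["pfs_months"].to_numpy(),
                sub["pfs_event"].astype(bool).to_numpy(),
            )
        chi2, p = logrank_test(groups_te)
        payload["survival"] = {
            "km_median_months": medians,
            "logrank_chi2": chi2,
            "logrank_p": p,
            "synthetic": config.cohort_source == "simulate",
        }

    payload["mutation_landscape"] = _mutation_summary(config.seed)
    return ReportBundle(payload=payload)


def records_for_stratum(records: pd.DataFrame, stratum: str) -> pd.DataFrame:
    rec = records.dropna(subset=["emt_index"])
    if stratum == "A'":
        return rec[(rec["group"] == "A") & rec["a_prime"]]
    return rec[rec["group"] == stratum]


def _mutation_summary(seed: int) -> dict:
    """Mutation-landscape summary on a simulated matrix.

    Sample sheet mirrors the assayed cohort: 15 CTC samples (6 A', 5 B,
    4 C) and 6 tissue samples from patients that also have a CTC sample.
    """
    ctc_groups = ["A"] * 6 + ["B"] * 5 + ["C"] * 4
    sheet = pd.DataFrame(
        {
            "sample": [f"CTC{i + 1:02d}" for i in range(15)],
            "patient_id": [f"P{i + 1:02d}" for i in range(15)],
            "group": ctc_groups,
            "source": "CTC",
        }
    )
    tissue = pd.DataFrame(
        {
            "sample": [f"TIS{i + 1:02d}" for i in range(6)],
            "patient_id": [f"P{i + 1:02d}" for i in range(6)],
            "group": ctc_groups[:6],
            "source": "tissue",
        }
    )
    sheet = pd.concat([sheet, tissue], ignore_index=True)
    matrix = simulate_mutation_matrix(
        default_mutation_model(), sheet, seed=seed
    )
    medians = group_median_counts(matrix, by="group")
    presence = gene_group_presence(matrix)
    regions = venn_partition(presence)
    return {
        "synthetic": True,
        "group_median_counts": medians.to_dict(orient="records"),
        "venn_region_sizes": {k: len(v) for k, v in regions.items()},
        "shared_all_groups": sorted(regions["A&B&C"]),
        "emt_genes_shared": sorted(
            annotate_emt_genes(regions["A&B&C"])
        ),
    }
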