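"""Set algebra over binary gene x sample mutation matrices.

A :class:`MutationMatrix` holds post-variant-calling binary calls (gene rows,
sample columns) with per-sample metadata: patient, group (A/B/C) and source
(CTC or tumor tissue).  The analyses are counting and set comparisons: per-
sample mutated-gene counts, per-stratum medians, three-group Venn partitions
of the mutated gene sets, CTC-versus-tissue comparisons, and flagging of
EMT-related genes.

A gene is attributed to a group when it is mutated in at least one sample of
that group (no frequency cutoff); variant class annotations, when present,
ride along but never affect the set algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ctcflow.errors import ValidationError

__all__ = [
    "DEFAULT_EMT_GENES",
    "MutationMatrix",
    "annotate_emt_genes",
    "gene_group_presence",
    "group_median_counts",
    "mutation_counts",
    "source_comparison",
    "venn_partition",
]

#: Genes with a documented role in epithelial-mesenchymal transition.
DEFAULT_EMT_GENES = frozenset(
    {"PIK3CA", "ARID1A", "CDH1", "MET", "RB1", "TP53", "CCND1"}
)

GROUPS = ("A", "B", "C")
SOURCES = ("CTC", "tissue")


@dataclass
class MutationMatrix:
    """Binary gene x sample calls plus sample metadata.

    ``calls``: DataFrame, genes as index, samples as columns, entries 0/1.
    ``meta``: DataFrame indexed by sample with columns ``patient_id``,
    ``group``, ``source``.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("calls must be binary (0/1)")
        self.calls = self.calls.astype(int)
        missing = set(self.calls.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)}"
            )
        for col in ("patient_id", "group", "source"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata lacks column {col!r}")
        bad_group = set(self.meta["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown groups: {sorted(bad_group)}")
        bad_src = set(self.meta["source"]) - set(SOURCES)
        if bad_src:
            raise ValidationError(f"unknown sources: {sorted(bad_src)}")
        pairs = self.meta[["patient_id", "source"]]
        if pairs.duplicated().any():
            raise ValidationError(
                "(patient_id, source) pairs must be unique"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def subset(self, samples: Iterable[str]) -> "MutationMatrix":
        samples = list(samples)
        return MutationMatrix(
            calls=self.calls[samples], meta=self.meta.loc[samples]
        )

    def to_csv(self, calls_path, meta_path) -> None:
        self.calls.to_csv(calls_path, index_label="gene")
        self.meta.to_csv(meta_path, index_label="sample")

    @classmethod
    def from_csv(cls, calls_path, meta_path) -> "MutationMatrix":
        calls = pd.read_csv(calls_path, index_col="gene")
        meta = pd.read_csv(meta_path, index_col="sample")
        calls.index.name = None
        meta.index.name = None
        return cls(calls=calls, meta=meta)


def mutation_counts(matrix: MutationMatrix) -> pd.Series:
    """Mutated-gene count per sample (column sums)."""
    return matrix.calls.sum(axis=0)


def group_median_counts(
    matrix: MutationMatrix, by: str = "group"
) -> pd.DataFrame:
    """Median and (min, max) of per-sample counts per stratum.

    ``by`` is ``"group"`` (A/B/C) or ``"source"`` (CTC/tissue).
    """
    if by not in ("group", "source"):
        raise ValidationError("by must be 'group' or 'source'")
    counts = mutation_counts(matrix)
    strata = matrix.meta[by]
    rows = []
    for level in sorted(strata.unique()):
        vals = counts[strata[strata == level].index].to_numpy()
        if len(vals) == 0:
            raise ValidationError(f"empty stratum {level!r}")
        rows.append(
            {
                by: level,
                "n": len(vals),
                "median": float(np.median(vals)),
                "min": int(vals.min()),
                "max": int(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def gene_group_presence(matrix: MutationMatrix) -> dict[str, set[str]]:
    """Per-group mutated gene sets (a gene counts if mutated in >= 1 sample
    of the group)."""
    out: dict[str, set[str]] = {}
    for group in GROUPS:
        cols = matrix.meta.index[matrix.meta["group"] == group]
        cols = [c for c in cols if c in matrix.calls.columns]
        if cols:
            hit = matrix.calls[cols].sum(axis=1) > 0
            out[group] = set(matrix.calls.index[hit])
        else:
            out[group] = set()
    return out


def venn_partition(sets: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Decompose three sets into the 7 disjoint Venn regions.

    Keys of the result are the sorted member names joined by ``&``
    (e.g. ``"A"``, ``"A&B"``, ``"A&B&C"``).  Regions are pairwise disjoint
    and their union is the union of the inputs.
    """
    if len(sets) != 3:
        raise ValidationError(f"need exactly 3 sets, got {len(sets)}")
    names = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[str, set[str]] = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        key = "&".join(members)
        ins = [sets[m] for m in members]
        outs = [sets[n] for n in names if n not in members]
        region = set.intersection(*ins) if ins else set(universe)
        for o in outs:
            region -= o
        regions[key] = region
    return regions


def source_comparison(matrix: MutationMatrix) -> dict:
    """CTC-versus-tissue comparison.

    Returns the 2-set partition of mutated genes (shared / CTC-only /
    tissue-only) and, for patients with both a CTC and a tissue sample, the
    per-patient paired difference in mutated-gene counts (CTC - tissue).
    """
    by_source: dict[str, set[str]] = {}
    for source in SOURCES:
        cols = matrix.meta.index[matrix.meta["source"] == source]
        cols = [c for c in cols if c in matrix.calls.columns]
        if not cols:
            raise ValidationError(f"no samples with source {source!r}")
        hit = matrix.calls[cols].sum(axis=1) > 0
        by_source[source] = set(matrix.calls.index[hit])
    shared = by_source["CTC"] & by_source["tissue"]
    ctc_only = by_source["CTC"] - by_source["tissue"]
    tissue_only = by_source["tissue"] - by_source["CTC"]

    counts = mutation_counts(matrix)
    meta = matrix.meta
    paired = {}
    patients_ctc = set(meta.loc[meta["source"] == "CTC", "patient_id"])
    patients_tis = set(meta.loc[meta["source"] == "tissue", "patient_id"])
    for pid in sorted(patients_ctc & patients_tis):
        sample_of = {
            row_source: sample
            for sample, row_source in meta.loc[
                meta["patient_id"] == pid, "source"
            ].items()
        }
        paired[pid] = int(
            counts[sample_of["CTC"]] - counts[sample_of["tissue"]]
        )
    if not paired:
        warnings.warn(
            "no patients with both CTC and tissue samples; paired "
            "differences empty",
            stacklevel=2,
        )
    return {
        "shared": shared,
        "ctc_only": ctc_only,
        "tissue_only": tissue_only,
        "paired_count_diff": paired,
    }


def annotate_emt_genes(
    gene_set: Iterable[str],
    emt_list: Iterable[str] = DEFAULT_EMT_GENES,
) -> set[str]:
    """The EMT-related subset of a gene set (intersection with the
    configured EMT gene list)."""
    return set(gene_set) & set(emt_list)
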