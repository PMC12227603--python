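#!/usr/bin/env python
"""Mutation-landscape set comparisons on a simulated call matrix.

Per-sample mutation calls are not published, so a binary matrix is drawn
from the group/source Bernoulli model whose gene compartments echo the
observed three-group Venn structure (6 genes shared by all groups, 5 shared
by A and B, 9 private to A, 5 private to B).  Computes per-group mutated-
gene medians, the three-group Venn partition with EMT-gene flags, and the
CTC-versus-tissue comparison with per-patient paired differences.  Writes
results/landscape_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from ctcflow.landscape import (
    annotate_emt_genes,
    gene_group_presence,
    group_median_counts,
    source_comparison,
    venn_partition,
)
from ctcflow.synthetic import default_mutation_model, simulate_mutation_matrix

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def sample_sheet() -> pd.DataFrame:
    """15 CTC samples (6 A / 5 B / 4 C) + 6 matched tissue samples."""
    ctc = pd.DataFrame(
        {
            "sample": [f"CTC{i + 1:02d}" for i in range(15)],
            "patient_id": [f"P{i + 1:02d}" for i in range(15)],
            "group": ["A"] * 6 + ["B"] * 5 + ["C"] * 4,
            "source": "CTC",
        }
    )
    tissue = pd.DataFrame(
        {
            "sample": [f"TIS{i + 1:02d}" for i in range(6)],
            "patient_id": [f"P{i + 1:02d}" for i in range(6)],
            "group": ["A"] * 6,
            "source": "tissue",
        }
    )
    return pd.concat([ctc, tissue], ignore_index=True)


def main() -> None:
    matrix = simulate_mutation_matrix(
        default_mutation_model(), sample_sheet(), seed=SEED
    )
    medians = group_median_counts(matrix)
    print("mutated-gene counts per group:")
    for row in medians.itertuples(index=False):
        print(
            f"  {row.group}: median {row.median:.1f} "
            f"({row.min}-{row.max}), n={row.n}"
        )
    regions = venn_partition(gene_group_presence(matrix))
    print("three-group Venn region sizes:")
    for key in ("A", "B", "C", "A&B", "A&C", "B&C", "A&B&C"):
        emt = sorted(annotate_emt_genes(regions[key]))
        extra = f"  EMT: {', '.join(emt)}" if emt else ""
        print(f"  {key:6s}: {len(regions[key]):2d}{extra}")
    src = source_comparison(matrix)
    print(
        f"CTC vs tissue genes: shared {len(src['shared'])}, "
        f"CTC-only {len(src['ctc_only'])}, tissue-only "
        f"{len(src['tissue_only'])}"
    )
    print(f"paired CTC-tissue count differences: {src['paired_count_diff']}")

    OUT.mkdir(exist_ok=True)
    (OUT / "landscape_summary.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "group_median_counts": medians.to_dict(orient="records"),
                "venn_regions": {k: sorted(v) for k, v in regions.items()},
                "source_comparison": {
                    "shared": sorted(src["shared"]),
                    "ctc_only": sorted(src["ctc_only"]),
                    "tissue_only": sorted(src["tissue_only"]),
                    "paired_count_diff": src["paired_count_diff"],
                },
            },
            indent=2,
        )
        + "\n"
    )
    print(f"wrote {OUT / 'landscape_summary.json'}")


if __name__ == "__main__":
    main()
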