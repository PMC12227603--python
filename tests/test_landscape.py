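"""Mutation-matrix set algebra against hand enumeration and a bit-mask oracle."""

import numpy as np
import pandas as pd
import pytest

from ctcflow.errors import ValidationError
from ctcflow.landscape import (
    DEFAULT_EMT_GENES,
    MutationMatrix,
    annotate_emt_genes,
    gene_group_presence,
    group_median_counts,
    mutation_counts,
    source_comparison,
    venn_partition,
)


def toy_matrix() -> MutationMatrix:
    """6 genes x 5 samples, hand-enumerable.

    samples: a1, a2 (group A CTC), b1 (B CTC), c1 (C CTC), t1 (A tissue of
    the same patient as a1).
    """
    calls = pd.DataFrame(
        {
            "a1": [1, 1, 0, 0, 1, 0],
            "a2": [1, 0, 1, 0, 0, 0],
            "b1": [1, 0, 0, 1, 0, 0],
            "c1": [1, 0, 0, 0, 0, 0],
            "t1": [1, 1, 0, 0, 0, 1],
        },
        index=["TP53", "PIK3CA", "MET", "CCND1", "ATM", "ERBB2"],
    )
    meta = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4", "p1"],
            "group": ["A", "A", "B", "C", "A"],
            "source": ["CTC", "CTC", "CTC", "CTC", "tissue"],
        },
        index=calls.columns,
    )
    return MutationMatrix(calls=calls, meta=meta)


class TestMutationMatrix:
    def test_nonbinary_rejected(self):
        m = toy_matrix()
        calls = m.calls.copy()
        calls.iloc[0, 0] = 2
        with pytest.raises(ValidationError):
            MutationMatrix(calls=calls, meta=m.meta)

    def test_duplicate_patient_source_rejected(self):
        m = toy_matrix()
        meta = m.meta.copy()
        meta.loc["a2", "patient_id"] = "p1"  # second (p1, CTC) pair
        with pytest.raises(ValidationError):
            MutationMatrix(calls=m.calls, meta=meta)

    def test_csv_round_trip(self, tmp_path):
        m = toy_matrix()
        m.to_csv(tmp_path / "calls.csv", tmp_path / "meta.csv")
        back = MutationMatrix.from_csv(
            tmp_path / "calls.csv", tmp_path / "meta.csv"
        )
        pd.testing.assert_frame_equal(back.calls, m.calls)
        pd.testing.assert_frame_equal(back.meta, m.meta)


class TestCounts:
    def test_all_zero(self):
        m = toy_matrix()
        zero = MutationMatrix(calls=m.calls * 0, meta=m.meta)
        assert (mutation_counts(zero) == 0).all()

    def test_hand_summation(self):
        counts = mutation_counts(toy_matrix())
        assert counts.to_dict() == {"a1": 3, "a2": 2, "b1": 2, "c1": 1, "t1": 3}

    def test_invariant_under_gene_reordering(self):
        m = toy_matrix()
        reordered = MutationMatrix(
            calls=m.calls.iloc[::-1], meta=m.meta
        )
        assert mutation_counts(reordered).to_dict() == mutation_counts(
            m
        ).to_dict()

    def test_group_medians_hand_checked(self):
        res = group_median_counts(toy_matrix()).set_index("group")
        # group A counts {3, 2, 3} -> median 3; B {2}; C {1}
        assert res.loc["A", "median"] == 3.0
        assert (res.loc["A", "min"], res.loc["A", "max"]) == (2, 3)
        assert res.loc["B", "median"] == 2.0
        assert res.loc["C", "median"] == 1.0

    def test_medians_by_source(self):
        res = group_median_counts(toy_matrix(), by="source").set_index(
            "source"
        )
        assert res.loc["CTC", "median"] == 2.0  # {3,2,2,1}
        assert res.loc["tissue", "median"] == 3.0

    def test_planted_rate_ordering_recovered(self):
        """Bernoulli rates 0.5/0.3/0.1 over 50 genes order the group medians
        correctly in >= 95% of replicates."""
        from ctcflow.synthetic import MutationModel, simulate_mutation_matrix

        genes = tuple(f"G{i}" for i in range(50))
        model = MutationModel(
            genes=genes,
            group_gene_probs={
                "A": {g: 0.5 for g in genes},
                "B": {g: 0.3 for g in genes},
                "C": {g: 0.1 for g in genes},
            },
        )
        sheet = pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(15)],
                "patient_id": [f"P{i}" for i in range(15)],
                "group": ["A"] * 5 + ["B"] * 5 + ["C"] * 5,
                "source": "CTC",
            }
        )
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            m = simulate_mutation_matrix(model, sheet, seed=1000 + rep)
            res = group_median_counts(m).set_index("group")["median"]
            hits += res["A"] > res["B"] > res["C"]
        assert hits / n_rep >= 0.95


class TestPresenceAndVenn:
    def test_presence_hand_enumeration(self):
        sets = gene_group_presence(toy_matrix())
        assert sets["A"] == {"TP53", "PIK3CA", "MET", "ATM", "ERBB2"}
        assert sets["B"] == {"TP53", "CCND1"}
        assert sets["C"] == {"TP53"}

    def test_group_exclusive_gene(self):
        sets = gene_group_presence(toy_matrix())
        assert "CCND1" in sets["B"]
        assert "CCND1" not in sets["A"] and "CCND1" not in sets["C"]

    def test_identical_sets_only_center(self):
        s = {"X": {"a", "b"}, "Y": {"a", "b"}, "Z": {"a", "b"}}
        regions = venn_partition(s)
        assert regions["X&Y&Z"] == {"a", "b"}
        assert all(
            not v for k, v in regions.items() if k != "X&Y&Z"
        )

    def test_disjoint_sets_only_exclusive_regions(self):
        s = {"X": {"a"}, "Y": {"b"}, "Z": {"c"}}
        regions = venn_partition(s)
        assert regions["X"] == {"a"}
        assert regions["Y"] == {"b"}
        assert regions["Z"] == {"c"}
        assert all(
            not v for k, v in regions.items() if "&" in k
        )

    def test_random_sets_match_bitmask_oracle(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(10):
            sets = {
                name: {g for g in universe if rng.random() < 0.4}
                for name in ("A", "B", "C")
            }
            regions = venn_partition(sets)
            # oracle: classify each gene by its 3-bit membership pattern
            for gene in universe:
                pattern = [name for name in ("A", "B", "C") if gene in sets[name]]
                if not pattern:
                    continue
                key = "&".join(pattern)
                assert gene in regions[key]
            # disjoint, and unions reconstruct the inputs
            all_regions = list(regions.values())
            for i in range(len(all_regions)):
                for j in range(i + 1, len(all_regions)):
                    assert not (all_regions[i] & all_regions[j])
            for name in ("A", "B", "C"):
                rebuilt = set().union(
                    *(v for k, v in regions.items() if name in k.split("&"))
                )
                assert rebuilt == sets[name]


class TestSourceComparison:
    def test_hand_enumerated_partition(self):
        res = source_comparison(toy_matrix())
        # CTC genes: TP53, PIK3CA, MET, CCND1, ATM; tissue: TP53, PIK3CA, ERBB2
        assert res["shared"] == {"TP53", "PIK3CA"}
        assert res["ctc_only"] == {"MET", "CCND1", "ATM"}
        assert res["tissue_only"] == {"ERBB2"}

    def test_partition_sizes_sum_to_genes_mutated_anywhere(self):
        res = source_comparison(toy_matrix())
        total = len(res["shared"]) + len(res["ctc_only"]) + len(
            res["tissue_only"]
        )
        anywhere = (toy_matrix().calls.sum(axis=1) > 0).sum()
        assert total == anywhere

    def test_paired_difference(self):
        res = source_comparison(toy_matrix())
        assert res["paired_count_diff"] == {"p1": 0}  # 3 - 3

    def test_identical_columns_give_zero_difference(self):
        m = toy_matrix()
        calls = m.calls.copy()
        calls["t1"] = calls["a1"]
        res = source_comparison(MutationMatrix(calls=calls, meta=m.meta))
        assert res["paired_count_diff"]["p1"] == 0

    def test_no_paired_patients_warns(self):
        m = toy_matrix()
        meta = m.meta.copy()
        meta.loc["t1", "patient_id"] = "p9"
        with pytest.warns(UserWarning, match="paired"):
            res = source_comparison(MutationMatrix(calls=m.calls, meta=meta))
        assert res["paired_count_diff"] == {}


class TestEmtAnnotation:
    def test_empty_set(self):
        assert annotate_emt_genes(set()) == set()

    def test_default_list_flags_tp53_not_atm(self):
        assert annotate_emt_genes({"TP53", "ATM"}) == {"TP53"}

    def test_idempotent(self):
        flagged = annotate_emt_genes(DEFAULT_EMT_GENES | {"KRAS"})
        assert annotate_emt_genes(flagged) == flagged
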