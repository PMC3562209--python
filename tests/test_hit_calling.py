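"""Dual-filter hit calling, antisense subtraction, matrix, common binders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpscreen.errors import EmptyInputError, PairingError, ParameterError
from rbpscreen.hit_calling import (
    HitTable,
    build_matrix,
    call_hits,
    cluster_matrix,
    common_binders,
    sense_specific,
)


def stats_frame(rows):
    """rows: {protein_id: (min_ratio, mean_ratio, zscore)}"""
    df = pd.DataFrame(
        [(pid, mean, mn, z) for pid, (mn, mean, z) in rows.items()],
        columns=["protein_id", "mean_ratio", "min_ratio", "zscore"],
    ).set_index("protein_id")
    return df


def table(hit_ids, rna="TP53", strand="sense", z_min=3.0, fold_min=2.5):
    df = stats_frame({pid: (5.0, 5.0, 10.0) for pid in hit_ids})
    return HitTable(rna_id=rna, strand=strand, stats=df,
                    z_min=z_min, fold_min=fold_min)


class TestCallHits:
    def test_validated_interaction_passes_filter(self):
        # duplicate ratios 3.0 / 3.38 (mean 3.19), Z = 4.24: a bona fide hit
        df = stats_frame({"STAU1": (3.0, 3.19, 4.24)})
        assert call_hits(df).hits == {"STAU1"}

    def test_one_weak_duplicate_vetoes(self):
        # ratios (2.4, 9.0): min below 2.5 despite huge mean and Z
        df = stats_frame({"X": (2.4, 5.7, 10.0)})
        assert call_hits(df).hits == frozenset()

    def test_low_zscore_vetoes(self):
        df = stats_frame({"X": (5.0, 5.0, 2.9)})
        assert call_hits(df).hits == frozenset()

    def test_thresholds_inclusive(self):
        df = stats_frame({"EDGE": (2.5, 2.5, 3.0)})
        assert call_hits(df).hits == {"EDGE"}

    @pytest.mark.parametrize("kwargs", [{"z_min": 0}, {"fold_min": -1}])
    def test_nonpositive_thresholds_rejected(self, kwargs):
        df = stats_frame({"A": (3.0, 3.0, 5.0)})
        with pytest.raises(ParameterError):
            call_hits(df, **kwargs)

    def test_unset_zscores_rejected(self):
        df = stats_frame({"A": (3.0, 3.0, 5.0)})
        df.loc["A", "zscore"] = np.nan
        with pytest.raises(ValueError):
            call_hits(df)

    @given(
        st.dictionaries(
            st.text(st.characters(min_codepoint=65, max_codepoint=90),
                    min_size=1, max_size=4),
            st.tuples(st.floats(0, 10), st.floats(0, 5), st.floats(-3, 8)),
            max_size=30,
        ),
        st.floats(0.5, 6.0), st.floats(0.5, 6.0),
        st.floats(0.0, 3.0), st.floats(0.0, 3.0),
    )
    @settings(max_examples=60)
    def test_raising_thresholds_never_adds_hits(self, rows, z0, f0, dz, df_):
        frame = stats_frame(
            {pid: (mn, mn + extra, z) for pid, (mn, extra, z) in rows.items()}
        )
        loose = call_hits(frame, z_min=z0, fold_min=f0)
        tight = call_hits(frame, z_min=z0 + dz, fold_min=f0 + df_)
        assert tight.hits <= loose.hits


class TestSenseSpecific:
    def test_subtraction(self):
        out = sense_specific(table({"A", "B", "C"}),
                             table({"B"}, strand="antisense"))
        assert out.hits == {"A", "C"}
        assert out.strand == "sense"

    def test_empty_antisense_changes_nothing(self):
        out = sense_specific(table({"A", "B"}), table(set(), strand="antisense"))
        assert out.hits == {"A", "B"}

    def test_sense_subset_of_antisense_empties_table(self):
        out = sense_specific(table({"A"}), table({"A", "B"}, strand="antisense"))
        assert out.hits == frozenset()

    def test_self_subtraction_is_empty(self):
        assert sense_specific(table({"A", "B"}),
                              table({"A", "B"}, strand="antisense")).hits == frozenset()

    def test_locus_mismatch_rejected(self):
        with pytest.raises(PairingError):
            sense_specific(table({"A"}, rna="TP53"),
                           table({"A"}, rna="HRAS", strand="antisense"))

    def test_threshold_mismatch_rejected(self):
        with pytest.raises(PairingError):
            sense_specific(table({"A"}),
                           table({"A"}, strand="antisense", z_min=4.0))


class TestBuildMatrix:
    def test_two_tables(self):
        m = build_matrix([table({"A", "B"}, rna="TP53"),
                          table({"B", "C"}, rna="HRAS")])
        assert m.proteins == ["A", "B", "C"]
        assert m.rnas == ["TP53", "HRAS"]
        assert m.n_interactions == 4
        assert m.values.loc["B"].tolist() == [1, 1]
        assert m.values.loc["A"].tolist() == [1, 0]

    def test_single_empty_table(self):
        m = build_matrix([table(set(), rna="TP53")])
        assert m.values.shape == (0, 1)

    def test_duplicate_rna_rejected(self):
        with pytest.raises(ValueError, match="TP53"):
            build_matrix([table({"A"}, rna="TP53"), table({"B"}, rna="TP53")])

    def test_column_sums_equal_per_rna_hit_counts(self):
        tables = [table({"A", "B"}, rna="TP53"), table({"B", "C", "D"}, rna="HRAS")]
        m = build_matrix(tables)
        assert m.values.sum(axis=0).tolist() == [2, 3]


class TestCommonBinders:
    def _tables(self, counts, n=20):
        # counts: {protein: number of tables it appears in}
        rnas = [f"R{i}" for i in range(n)]
        return [
            table({p for p, c in counts.items() if c > i}, rna=rnas[i])
            for i in range(n)
        ]

    def test_75_percent_boundary_retained(self):
        df = common_binders(self._tables({"A": 15}))
        assert df.loc["A", "percent"] == 75.0

    def test_below_threshold_excluded(self):
        df = common_binders(self._tables({"A": 14}))
        assert "A" not in df.index

    def test_full_house_ranks_first(self):
        df = common_binders(self._tables({"PCBP2": 20, "B": 16, "A": 18}))
        assert df.index[0] == "PCBP2"
        assert df.loc["PCBP2", "percent"] == 100.0
        assert list(df.index) == ["PCBP2", "A", "B"]

    def test_ties_break_lexicographically(self):
        df = common_binders(self._tables({"Z": 16, "A": 16}))
        assert list(df.index) == ["A", "Z"]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            common_binders([])


class TestClusterMatrix:
    def test_identical_rows_adjacent(self):
        m = build_matrix([table({"A", "C"}, rna="R1"),
                          table({"A", "C"}, rna="R2"),
                          table({"B"}, rna="R3")])
        c = cluster_matrix(m)
        order = [m.proteins[i] for i in c.row_order]
        ia, ic = order.index("A"), order.index("C")
        assert abs(ia - ic) == 1

    def test_single_row_identity_order(self):
        m = build_matrix([table({"A"}, rna="R1")])
        c = cluster_matrix(m)
        assert c.row_order == [0]
        assert c.col_order == [0]

    def test_deterministic(self):
        m = build_matrix([table({"A", "B"}, rna="R1"), table({"B", "C"}, rna="R2"),
                          table({"C", "D"}, rna="R3")])
        c1, c2 = cluster_matrix(m), cluster_matrix(m)
        assert c1.row_order == c2.row_order
        assert c1.col_order == c2.col_order

    def test_permuted_input_same_grouping(self):
        t1 = [table({"A", "B"}, rna="R1"), table({"B", "C"}, rna="R2"),
              table({"D"}, rna="R3")]
        m1 = cluster_matrix(build_matrix(t1))
        m2 = cluster_matrix(build_matrix(t1[::-1]))
        # row partition order may flip but the clustered row sets agree
        rows1 = [m1.proteins[i] for i in m1.row_order]
        rows2 = [m2.proteins[i] for i in m2.row_order]
        assert set(rows1) == set(rows2)
        assert m1.ordered().loc[rows1].shape == m2.ordered().loc[rows2].shape

    def test_orthogonal_rows_positive_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist
        m = build_matrix([table({"A"}, rna="R1"), table({"B"}, rna="R2"),
                          table({"C"}, rna="R3")])
        heights = linkage(pdist(m.values.to_numpy().astype(bool), "jaccard"),
                          "average")[:, 2]
        assert (heights > 0).all()
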