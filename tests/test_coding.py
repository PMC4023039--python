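"""Discretization, matrix building/transposition, polarization, abundance coding."""

import numpy as np
import pandas as pd
import pytest

from retrodict.coding import (
    ANCESTOR_LABEL,
    CharacterMatrix,
    CodingError,
    attach_ancestor,
    build_matrix,
    code_abundance,
    discretize,
    to_nexus,
)


def stats_table(n_mol=3, regions=("acceptor", "d_arm", "anticodon_arm", "variable_loop", "t_arm")):
    rows = []
    rng = np.random.default_rng(5)
    for i in range(n_mol):
        for r in regions:
            for st in ("Q", "P", "S"):
                rows.append(
                    {"name": f"m{i}", "region": r, "stat": st, "value": rng.random()}
                )
    return pd.DataFrame(rows)


class TestDiscretize:
    def test_equal_width_binning(self):
        states, flag = discretize([0.0, 0.5, 1.0], k=3)
        assert states.tolist() == [0, 1, 2] and not flag

    def test_constant_column_flagged(self):
        states, flag = discretize([2.0, 2.0, 2.0], k=5)
        assert states.tolist() == [0, 0, 0] and flag

    def test_nan_rejected(self):
        with pytest.raises(CodingError):
            discretize([0.0, float("nan")], k=3)

    def test_boundary_ties_go_to_lower_state(self):
        # 1/3 is exactly the 0/1 bin boundary of [0,1] with k=3
        states, _ = discretize([0.0, 1 / 3, 1.0], k=3)
        assert states.tolist() == [0, 0, 2]

    def test_monotone_in_values(self, rng):
        for _ in range(50):
            v = rng.normal(size=12)
            states, _ = discretize(v, k=int(rng.integers(2, 24)))
            order = np.argsort(v)
            assert np.all(np.diff(states[order]) >= 0)


class TestBuildMatrix:
    def test_tom_shape(self):
        m = build_matrix(stats_table(), mode="ToM", k=8)
        assert len(m.taxa) == 3 and len(m.characters) == 15

    def test_tos_shape_single_stat(self):
        m = build_matrix(stats_table(), mode="ToS", k=8, stat="Q")
        assert len(m.taxa) == 5 and len(m.characters) == 3

    def test_transpose_is_involution(self):
        m = build_matrix(stats_table(), mode="ToM", k=8)
        t2 = m.transpose().transpose()
        assert t2.taxa == m.taxa and t2.characters == m.characters
        assert np.array_equal(t2.states, m.states)

    def test_missing_cells_listed(self):
        df = stats_table().iloc[:-1]
        with pytest.raises(CodingError, match="missing cells"):
            build_matrix(df, mode="ToM", k=8)


class TestAncestor:
    def test_polarity_convention(self):
        m = build_matrix(stats_table(), mode="ToM", k=24)
        a = attach_ancestor(m)
        anc = a.row(ANCESTOR_LABEL)
        for ch, st in zip(a.characters, anc):
            stat = ch.split(":")[1]
            assert st == (23 if stat == "Q" else 0)

    def test_non_anc_rows_unchanged(self):
        m = build_matrix(stats_table(), mode="ToM", k=24)
        a = attach_ancestor(m)
        assert np.array_equal(a.states[:-1], m.states)

    def test_name_collision_rejected(self):
        m = build_matrix(stats_table(), mode="ToM", k=24)
        with pytest.raises(CodingError, match="already contains"):
            attach_ancestor(attach_ancestor(m))

    def test_undefined_polarity_is_config_error(self):
        m = CharacterMatrix(
            taxa=("a", "b"), characters=("x",), states=np.array([[0], [1]]), k=4
        )
        with pytest.raises(CodingError, match="polarity"):
            attach_ancestor(m)


class TestAbundanceCoding:
    def test_log_coding_formula(self):
        census = pd.DataFrame({"p1": [0, 9, 99]}, index=["d1", "d2", "d3"])
        m = code_abundance(census, k=24)
        # ln(10)/ln(100) = 0.5 -> 23 * 0.5 = 11.5 rounds half-up to 12
        assert m.states[:, 0].tolist() == [0, 12, 23]

    def test_all_zero_column_flagged(self):
        census = pd.DataFrame({"p1": [0, 0]}, index=["d1", "d2"])
        m = code_abundance(census, k=24)
        assert m.states[:, 0].tolist() == [0, 0]
        assert m.uninformative[0]

    def test_negative_counts_rejected(self):
        census = pd.DataFrame({"p1": [1, -2]}, index=["d1", "d2"])
        with pytest.raises(CodingError):
            code_abundance(census)

    def test_scale_monotone(self, rng):
        counts = rng.integers(0, 500, (10, 4))
        base = code_abundance(
            pd.DataFrame(counts, index=[f"d{i}" for i in range(10)]), k=24
        )
        scaled = code_abundance(
            pd.DataFrame(counts * 7, index=[f"d{i}" for i in range(10)]), k=24
        )
        for c in range(4):
            a, b = base.states[:, c], scaled.states[:, c]
            for i in range(10):
                for j in range(10):
                    if a[i] < a[j]:
                        assert b[i] <= b[j]

    def test_default_polarity_is_max_abundance_ancestral(self):
        census = pd.DataFrame({"p1": [0, 9, 99]}, index=["d1", "d2", "d3"])
        a = attach_ancestor(code_abundance(census, k=24))
        assert a.row(ANCESTOR_LABEL).tolist() == [23]


class TestNexus:
    def test_round_trip_via_dendropy(self):
        import dendropy

        m = attach_ancestor(build_matrix(stats_table(), mode="ToM", k=24))
        text = to_nexus(m)
        cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
        assert len(cm) == len(m.taxa)
        row = cm[[t for t in cm if t.label == m.taxa[0]][0]]
        symbols = "0123456789ABCDEFGHIJKLMN"
        assert [symbols.index(str(c)) for c in row] == m.states[0].tolist()
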