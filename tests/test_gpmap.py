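"""GP-map analysis: neutral sets, components, transition matrices, generators."""

import numpy as np
import pytest

from gprobust import bounds, gpmap
from gprobust.hamming import GenotypeSpace, cross_edge_count, induced_edge_count
from gprobust.sumdigits import sums_of_digits


@pytest.fixture()
def packed_53(cube3):
    """Bricklayer-packed map on the 3-cube: blocks of 5 and 3 vertices."""
    return gpmap.generate_bricklayer_packed(cube3, [5, 3], labels=["A", "B"])


class TestReadWrite:
    def test_roundtrip(self, packed_53, tmp_path):
        path = tmp_path / "map.tsv"
        gpmap.write_gpmap(packed_53, path)
        back = gpmap.read_gpmap(path)
        assert back.labels == packed_53.labels
        assert np.array_equal(back.codes, packed_53.codes)

    def test_two_phenotype_file(self, tmp_path):
        path = tmp_path / "m.tsv"
        rows = [f"{i:03b}\t{'X' if i < 4 else 'Y'}" for i in range(8)]
        path.write_text("# comment\ngenotype\tphenotype\n" + "\n".join(rows) + "\n")
        m = gpmap.read_gpmap(path)
        assert set(m.labels) == {"X", "Y"}
        assert m.space.k == 2 and m.space.length == 3

    def test_missing_genotype_errors_without_default(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\n".join(f"{i:03b}\tX" for i in range(7)) + "\n")
        with pytest.raises(gpmap.GPMapError, match="not total"):
            gpmap.read_gpmap(path)
        m = gpmap.read_gpmap(path, default_phenotype=".")
        assert set(m.labels) == {"X", "."}

    def test_duplicate_consistent_accepted_with_notice(self, tmp_path):
        path = tmp_path / "m.tsv"
        rows = [f"{i:02b}\tX" for i in range(4)] + ["00\tX"]
        path.write_text("\n".join(rows) + "\n")
        with pytest.warns(UserWarning, match="duplicate"):
            m = gpmap.read_gpmap(path)
        assert m.labels == ("X",)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        rows = [f"{i:02b}\tX" for i in range(4)] + ["00\tY"]
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(gpmap.GPMapError, match="assigned to both"):
            gpmap.read_gpmap(path)

    def test_ragged_lengths_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("00\tX\n000\tX\n")
        with pytest.raises(gpmap.GPMapError, match="ragged"):
            gpmap.read_gpmap(path)


class TestPhenotypeStats:
    def test_bricklayer_block_attains_max(self, packed_53, cube3):
        stats = {s.label: s for s in gpmap.phenotype_stats(packed_53)}
        a = stats["A"]
        assert a.n == 5
        assert a.edge_count == sums_of_digits(5, 2) == 5
        assert a.rho == pytest.approx(2 / 3)
        assert len(a.components) == 1
        assert a.components[0].attains_max

    def test_antipodal_singletons(self, square):
        # hand-built: phenotype S on {0, 3}, T on {1, 2}
        per_vertex = np.array(["S", "T", "T", "S"], dtype=object)
        m = gpmap.GPMap.from_vertex_labels(square, per_vertex)
        stats = {s.label: s for s in gpmap.phenotype_stats(m)}
        assert stats["S"].rho == 0.0
        assert [c.size for c in stats["S"].components] == [1, 1]

    def test_single_phenotype_has_unit_robustness(self, cube3):
        m = gpmap.generate_bricklayer_packed(cube3, [8])
        (st,) = gpmap.phenotype_stats(m)
        assert st.rho == pytest.approx(1.0)

    def test_component_bounds_respected_on_random_maps(self, cube4):
        """rho_min(single component) <= rho_component <= rho_max(size)."""
        for seed in range(5):
            m = gpmap.generate_random_null(cube4, [6, 5, 5], seed=seed)
            for st in gpmap.phenotype_stats(m):
                assert st.rho <= bounds.rho_max(st.n, cube4) + 1e-12
                for c in st.components:
                    assert c.rho >= bounds.rho_min(c.size, cube4) - 1e-12
                    assert c.rho <= bounds.rho_max(c.size, cube4) + 1e-12

    def test_sizes_and_edges_are_consistent(self, cube4):
        m = gpmap.generate_random_null(cube4, [9, 4, 3], seed=11)
        for st in gpmap.phenotype_stats(m):
            assert sum(c.size for c in st.components) == st.n
            assert sum(c.edge_count for c in st.components) == st.edge_count


class TestTransitionMatrix:
    def test_half_split_square(self, square):
        m = gpmap.generate_bricklayer_packed(square, [2, 2], labels=["L", "R"])
        tm = gpmap.transition_matrix(m)
        assert np.allclose(tm.phi, 0.5)

    def test_single_phenotype(self, cube3):
        tm = gpmap.transition_matrix(gpmap.generate_bricklayer_packed(cube3, [8]))
        assert tm.phi.shape == (1, 1)
        assert tm.phi[0, 0] == pytest.approx(1.0)

    def test_column_stochastic_and_detailed_balance(self, cube4):
        m = gpmap.generate_random_null(cube4, [7, 5, 4], seed=2)
        tm = gpmap.transition_matrix(m)
        assert np.allclose(tm.phi.sum(axis=0), 1.0, atol=1e-12)
        flux = tm.phi * tm.f[np.newaxis, :]
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_offdiagonal_matches_cross_edge_oracle(self, cube3):
        m = gpmap.generate_random_null(cube3, [5, 3], seed=9)
        tm = gpmap.transition_matrix(m)
        va = m.vertices_of(tm.labels[0])
        vb = m.vertices_of(tm.labels[1])
        cross = cross_edge_count(set(va.tolist()), set(vb.tolist()), cube3)
        assert tm.phi[1, 0] == pytest.approx(cross / (cube3.degree * len(va)))
        assert tm.phi[0, 0] == pytest.approx(
            2 * induced_edge_count(set(va.tolist()), cube3) / (cube3.degree * len(va))
        )

    def test_edge_mass_identity(self, cube4):
        """sum_s rho_s f_s + 2 sum_{r>s} phi_rs f_s = 2|E(H)| / (l(k-1)k^l)."""
        m = gpmap.generate_random_null(cube4, [6, 6, 4], seed=5)
        tm = gpmap.transition_matrix(m)
        diag = float(np.sum(tm.rho * tm.f))
        cross = float(sum(
            2 * tm.phi[r, s] * tm.f[s]
            for s in range(3) for r in range(s + 1, 3)
        ))
        assert diag + cross == pytest.approx(1.0)  # the whole graph's edge mass

    def test_csv_roundtrip(self, cube3, tmp_path):
        tm = gpmap.transition_matrix(gpmap.generate_random_null(cube3, [5, 3], seed=1))
        path = tmp_path / "phi.csv"
        tm.to_csv(path)
        back = gpmap.TransitionMatrix.from_csv(path, frequencies=tm.f)
        assert back.labels == tm.labels
        assert np.allclose(back.phi, tm.phi)


class TestGenerators:
    def test_random_null_is_reproducible(self, cube3):
        a = gpmap.generate_random_null(cube3, [4, 4], seed=7)
        b = gpmap.generate_random_null(cube3, [4, 4], seed=7)
        c = gpmap.generate_random_null(cube3, [4, 4], seed=8)
        assert np.array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)

    def test_random_null_mean_robustness_tracks_frequency(self):
        """Monte-Carlo mean of rho is the hypergeometric (n-1)/(N-1) ~ f."""
        space = GenotypeSpace(k=2, length=5)
        N = space.n_vertices
        rhos = []
        for seed in range(60):
            m = gpmap.generate_random_null(space, [16, 16], seed=seed)
            rhos.append(gpmap.phenotype_stats(m)[0].rho)
        mean = float(np.mean(rhos))
        se = float(np.std(rhos, ddof=1) / np.sqrt(len(rhos)))
        assert abs(mean - (16 - 1) / (N - 1)) < 3 * se

    def test_size_mismatch_rejected(self, cube3):
        with pytest.raises(ValueError, match="sum"):
            gpmap.generate_random_null(cube3, [4, 3], seed=0)

    def test_bricklayer_packed_blocks(self, cube3):
        m = gpmap.generate_bricklayer_packed(cube3, [5, 3], labels=["A", "B"])
        assert np.array_equal(m.vertices_of("A"), np.arange(5))
        later = {s.label: s for s in gpmap.phenotype_stats(m)}["B"]
        assert later.rho <= bounds.rho_max(3, cube3) + 1e-12

    def test_transition_probabilities_scale_like_frequency(self):
        """Random-null off-diagonals concentrate near phi_ts ~ f_t."""
        space = GenotypeSpace(k=2, length=5)
        phis = []
        for seed in range(60):
            m = gpmap.generate_random_null(space, [16, 16], seed=seed)
            tm = gpmap.transition_matrix(m)
            phis.append(tm.phi[1, 0])
        mean = float(np.mean(phis))
        # E[phi_ts] = f_t * N/(N-1) exactly; ~f_t up to O(1/N)
        assert mean == pytest.approx(0.5, abs=0.03)


class TestDeviationTable:
    def test_single_bricklayer_phenotype(self, cube3):
        m = gpmap.generate_bricklayer_packed(cube3, [5, 3])
        df = gpmap.deviation_table(m).set_index("phenotype")
        assert df.loc["P1", "lhs"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["P1", "rhs"] == pytest.approx(0.0, abs=1e-12)

    def test_two_singleton_components(self, square):
        per_vertex = np.array(["S", "T", "T", "S"], dtype=object)
        m = gpmap.GPMap.from_vertex_labels(square, per_vertex)
        df = gpmap.deviation_table(m).set_index("phenotype")
        # S occupies opposite corners: lhs = rho_max(2) - 0 = 1/2 = rhs = 1/l
        assert df.loc["S", "lhs"] == pytest.approx(0.5)
        assert df.loc["S", "rhs"] == pytest.approx(0.5)
        assert df.loc["S", "m"] == 2 and bool(df.loc["S", "proven"])

    def test_proven_rows_satisfy_bound_on_random_maps(self, cube4):
        for seed in range(10):
            m = gpmap.generate_random_null(cube4, [8, 4, 4], seed=seed)
            df = gpmap.deviation_table(m)
            proven = df[df["proven"]]
            assert np.all(proven["lhs"].to_numpy() >= proven["rhs"].to_numpy() - 1e-12)
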