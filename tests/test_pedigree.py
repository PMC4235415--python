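import io

import numpy as np
import pytest

from svdlmm import (
    Individual,
    Pedigree,
    PedigreeError,
    ScenarioSpec,
    additive_matrix,
    family_offsets,
    kinship,
    make_pedigree,
    read_pedigree,
)
from svdlmm.pedigree import gene_drop_kinship

from conftest import NUCLEAR_FAM


class TestReadPedigree:
    def test_nuclear_family_parses(self, nuclear_ped):
        assert len(nuclear_ped) == 4
        founders = [r for r in nuclear_ped if r.is_founder]
        assert {r.iid for r in founders} == {"dad", "mom"}
        kid = nuclear_ped.records[nuclear_ped.index_of("kid1")]
        assert (kid.father, kid.mother) == ("dad", "mom")

    def test_one_parent_only_names_offender(self):
        bad = "F1 a 0 0 1 -9\nF1 b a 0 1 -9\n"
        with pytest.raises(PedigreeError, match="'b'"):
            read_pedigree(io.StringIO(bad))

    def test_duplicate_id_rejected(self):
        bad = NUCLEAR_FAM + "F2 kid1 0 0 1 -9\n"
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(io.StringIO(bad))

    def test_cyclic_ancestry_rejected(self):
        bad = "F1 a b c 1 -9\nF1 b a c 1 -9\nF1 c 0 0 2 -9\n"
        with pytest.raises(PedigreeError, match="cyclic"):
            read_pedigree(io.StringIO(bad))

    def test_parent_in_other_family_rejected(self):
        bad = "F1 a 0 0 1 -9\nF1 b 0 0 2 -9\nF2 c a b 1 -9\n"
        with pytest.raises(PedigreeError, match="different family"):
            read_pedigree(io.StringIO(bad))

    def test_interleaved_families_reordered_contiguously(self):
        rows = [
            "F1 a 0 0 1 -9",
            "F2 x 0 0 1 -9",
            "F1 b 0 0 2 -9",
            "F2 y 0 0 2 -9",
            "F1 c a b 1 -9",
        ]
        ped = read_pedigree(io.StringIO("\n".join(rows)))
        assert [r.family for r in ped] == ["F1", "F1", "F1", "F2", "F2"]
        assert ped.is_family_contiguous() and ped.is_topologically_sorted()
        assert {r.iid for r in ped} == {"a", "b", "c", "x", "y"}

    def test_header_ped_dialect(self):
        txt = "fid iid father mother sex\nF1 a 0 0 1\nF1 b 0 0 2\nF1 c a b 1\n"
        ped = read_pedigree(io.StringIO(txt), dialect="ped")
        assert len(ped) == 3


class TestKinship:
    def test_standard_coefficients(self, nuclear_ped):
        K = kinship(nuclear_ped)
        k = K.to_frame()
        assert k.loc["dad", "kid1"] == 0.25  # parent-offspring
        assert k.loc["kid1", "kid2"] == 0.25  # full sibs
        assert k.loc["dad", "mom"] == 0.0
        assert np.allclose(np.diag(K.values), 0.5)

    def test_first_cousins(self, two_trios_ped):
        K = kinship(two_trios_ped).to_frame()
        assert K.loc["F1_a1", "F1_b1"] == 0.0625

    def test_inbred_full_sib_mating(self):
        recs = [
            Individual("gp1", sex=1), Individual("gp2", sex=2),
            Individual("s1", "gp1", "gp2", 1),
            Individual("s2", "gp1", "gp2", 2),
            Individual("kid", "s1", "s2", 1),
        ]
        K = kinship(Pedigree(recs)).to_frame()
        # phi_self = (1 + f)/2 with f = phi(parents) = 0.25
        assert K.loc["kid", "kid"] == 0.625

    def test_unsorted_pedigree_rejected(self):
        recs = [
            Individual("kid", "dad", "mom", 1),
            Individual("dad", sex=1),
            Individual("mom", sex=2),
        ]
        with pytest.raises(PedigreeError, match="parents before children"):
            kinship(Pedigree(recs))

    def test_matches_gene_dropping_oracle(self, two_trios_ped):
        K = kinship(two_trios_ped)
        est, se = gene_drop_kinship(two_trios_ped, n_drops=200_000, seed=1)
        assert np.all(np.abs(est.values - K.values) <= 3 * np.maximum(se, 1e-12))

    def test_phantom_restriction_is_projection(self, two_trios_ped):
        """Dropping phantoms after the recursion equals the submatrix of the
        full kinship matrix."""
        full = Pedigree([
            Individual(r.iid, r.father, r.mother, r.sex, r.family, sampled=True)
            for r in two_trios_ped.records
        ])
        K_full = kinship(full).to_frame()
        K_sub = kinship(two_trios_ped).to_frame()
        ids = list(K_sub.index)
        assert np.allclose(K_full.loc[ids, ids].values, K_sub.values)

    @pytest.mark.parametrize("scenario", ["nuclear", "two_trios", "asymmetric", "combination"])
    def test_A_is_psd_and_block_diagonal(self, scenario):
        ped = make_pedigree(ScenarioSpec(scenario, n_fam=3))
        A = additive_matrix(kinship(ped))
        assert np.allclose(A.values, A.values.T)
        assert np.linalg.eigvalsh(A.values).min() >= -1e-8
        off = family_offsets(ped)
        mask = np.ones_like(A.values, dtype=bool)
        for sl in off.slices():
            mask[sl, sl] = False
        assert np.all(A.values[mask] == 0.0)

    def test_additive_is_twice_kinship(self, nuclear_ped):
        K = kinship(nuclear_ped)
        A = additive_matrix(K)
        assert np.allclose(A.values, 2 * K.values)
        assert A.values[0, 0] == 1.0  # non-inbred diagonal
        a = A.to_frame()
        assert a.loc["kid1", "kid2"] == 0.5  # full sibs


class TestFamilyOffsets:
    def test_sizes_seven_and_eight(self):
        recs = [Individual(f"a{i}", family="F1") for i in range(7)]
        recs += [Individual(f"b{i}", family="F2") for i in range(8)]
        off = family_offsets(Pedigree(recs))
        assert off.offsets.tolist() == [1, 8, 16]
        assert off.sizes().tolist() == [7, 8]

    def test_single_family(self):
        recs = [Individual(f"a{i}", family="F1") for i in range(5)]
        off = family_offsets(Pedigree(recs))
        assert off.offsets.tolist() == [1, 6]

    def test_many_uniform_families(self):
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=100))
        off = family_offsets(ped)
        assert np.all(np.diff(off.offsets) == 4)
        assert off.offsets[-1] == 401

    def test_non_contiguous_rejected(self):
        recs = [
            Individual("a", family="F1"),
            Individual("b", family="F2"),
            Individual("c", family="F1"),
        ]
        ped = Pedigree.__new__(Pedigree)  # bypass sorting to hit the guard
        ped.records = recs
        ped._index = {r.iid: i for i, r in enumerate(recs)}
        with pytest.raises(PedigreeError, match="not contiguous"):
            family_offsets(ped)

    def test_slices_cover_everything_once(self, two_trios_ped):
        off = family_offsets(two_trios_ped)
        covered = np.concatenate([np.arange(sl.start, sl.stop) for sl in off.slices()])
        assert covered.tolist() == list(range(off.n))
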