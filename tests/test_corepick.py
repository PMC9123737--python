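"""Tests of the eight core-definition strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apygblup import corepick, relmat
from apygblup.synthpop import GenotypeMatrix



@pytest.fixture(scope="module")
def study_bits(medium_study):
    ped = medium_study.pedigree
    gids = medium_study.genotypes.ids
    G = relmat.build_G(medium_study.genotypes)
    A22 = relmat.build_A(ped, subset=gids)
    Gb = relmat.blend_G(G, A22)
    return ped, gids, medium_study.genotypes, Gb


def assert_valid_partition(part, gids):
    assert len(np.intersect1d(part.core, part.noncore)) == 0
    assert set(part.core) | set(part.noncore) == set(gids)
    assert part.achieved_size == len(part.core)
    assert part.shortfall == max(0, part.target_size - part.achieved_size)


class TestMPA:
    def test_single_prolific_sire_selected(self):
        rows = [(1, 0, 0, "M"), (2, 0, 0, "F"), (3, 0, 0, "M")]
        rows += [(i, 1, 2, "F") for i in range(4, 14)]   # sire 1: 10 progeny
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex"])
        ped["cohort"] = 0
        ped["litter"] = ped["animal"]
        ped["pen"] = 1
        ped["genotyped"] = True
        ped["phenotyped"] = True
        # make animal 4 eligible (parents known + record); founders are not
        part = corepick.select_mpa(ped, None, target=1)
        # eligible animals are 4..13 (parents known); all have 0 progeny
        # except none; ranking falls back to the smallest id
        assert part.core.tolist() == [4]

    def test_ranked_by_progeny_count(self):
        # two eligible parents with differing progeny counts
        rows = [(1, 0, 0, "M"), (2, 0, 0, "F")]
        rows += [(3, 1, 2, "M"), (4, 1, 2, "F")]
        rows += [(i, 3, 4, "M") for i in range(5, 11)]      # 3,4: 6 progeny
        rows += [(i, 5, 6, "F") for i in range(11, 13)]     # 5: 2 progeny
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex"])
        ped["cohort"] = 0
        ped["litter"] = ped["animal"]
        ped["pen"] = 1
        ped["genotyped"] = True
        ped["phenotyped"] = True
        part = corepick.select_mpa(ped, None, target=2)
        assert part.core.tolist() == [3, 4]

    def test_target_all_eligible(self, study_bits):
        ped = study_bits[0]
        recorded = set(ped.loc[ped["phenotyped"], "animal"])
        elig = ped[(ped["genotyped"]) & (ped["sire"] != 0)
                   & (ped["dam"] != 0) & ped["animal"].isin(recorded)]
        part = corepick.select_mpa(ped, None, target=len(elig))
        assert set(part.core) == set(elig["animal"])

    def test_matches_bruteforce_sort_filter_oracle(self, study_bits):
        ped = study_bits[0]
        target = 40
        part = corepick.select_mpa(ped, None, target=target)
        # independent re-implementation
        prog = {}
        for _, r in ped.iterrows():
            for p in (r["sire"], r["dam"]):
                if p:
                    prog[p] = prog.get(p, 0) + 1
        recorded = set(ped.loc[ped["phenotyped"], "animal"])
        pool = [r["animal"] for _, r in ped.iterrows()
                if r["genotyped"] and r["sire"] and r["dam"]
                and r["animal"] in recorded]
        ranked = sorted(pool, key=lambda a: (-prog.get(a, 0), a))
        assert sorted(ranked[:target]) == part.core.tolist()

    def test_empty_pool_rejected(self):
        ped = pd.DataFrame({
            "animal": [1, 2], "sire": [0, 0], "dam": [0, 0],
            "sex": ["M", "F"], "cohort": 0, "litter": [1, 2], "pen": 1,
            "genotyped": True, "phenotyped": True})
        with pytest.raises(ValueError, match="pool empty"):
            corepick.select_mpa(ped, None, target=1)


class TestRandom:
    def test_target_n_returns_all(self):
        part = corepick.select_random(np.arange(1, 11), 10, seed=1)
        assert part.core.tolist() == list(range(1, 11))
        assert len(part.noncore) == 0

    def test_deterministic_under_seed(self):
        a = corepick.select_random(np.arange(1, 101), 20, seed=5)
        b = corepick.select_random(np.arange(1, 101), 20, seed=5)
        np.testing.assert_array_equal(a.core, b.core)

    def test_inclusion_frequency_uniform(self):
        ids = np.arange(1, 26)
        target, reps = 5, 2000
        counts = np.zeros(25)
        for s in range(reps):
            part = corepick.select_random(ids, target, seed=s)
            counts[part.core - 1] += 1
        f = target / 25
        se = np.sqrt(f * (1 - f) / reps)
        assert np.all(np.abs(counts / reps - f) < 3 * se + 1e-12)

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            corepick.select_random(np.arange(5), 6)


class TestPedSpread:
    def test_target_n_returns_all(self):
        part = corepick.select_ped_spread(None, np.arange(1, 8), 7)
        assert part.core.tolist() == list(range(1, 8))

    def test_stated_index_rule_n10_target2(self):
        part = corepick.select_ped_spread(None, np.arange(1, 11), 2)
        assert part.core.tolist() == [3, 8]    # 1-based ranks 3 and 8

    def test_core_counts_proportional_to_cohorts(self, study_bits):
        ped, gids = study_bits[0], study_bits[1]
        target = 60
        part = corepick.select_ped_spread(ped, gids, target)
        cohorts = ped.set_index("animal").loc[gids, "cohort"]
        n = len(gids)
        for c, size in cohorts.value_counts().items():
            expected = target * size / n
            got = (cohorts.loc[part.core] == c).sum()
            assert abs(got - expected) <= 1 + 1e-9


class TestFamily:
    def test_no_two_core_members_share_both_parents(self, study_bits):
        ped, gids = study_bits[0], study_bits[1]
        fams = ped.set_index("animal")
        n_families = len({(s, d) if s and d else ("solo", a)
                          for a, s, d in zip(ped["animal"], ped["sire"],
                                             ped["dam"])
                          if a in set(gids)})
        target = min(40, n_families)
        part = corepick.select_family(ped, gids, target, seed=2)
        pairs = [(fams.loc[a, "sire"], fams.loc[a, "dam"])
                 for a in part.core]
        pairs = [p for p in pairs if p[0] and p[1]]
        assert len(pairs) == len(set(pairs))

    def test_top_up_when_fewer_families_than_target(self):
        ped = pd.DataFrame({
            "animal": [1, 2, 3, 4, 5], "sire": [0, 0, 1, 1, 1],
            "dam": [0, 0, 2, 2, 2], "sex": ["M", "F", "M", "M", "F"],
            "cohort": [0, 0, 1, 1, 1], "litter": [1, 2, 3, 3, 3],
            "pen": 1, "genotyped": True, "phenotyped": False})
        part = corepick.select_family(ped, np.arange(1, 6), 4, seed=0)
        assert part.achieved_size == 4
        assert part.shortfall == 0

    def test_within_family_choice_uniform(self):
        ped = pd.DataFrame({
            "animal": [1, 2, 3, 4, 5], "sire": [0, 0, 1, 1, 1],
            "dam": [0, 0, 2, 2, 2], "sex": ["M", "F", "M", "M", "F"],
            "cohort": [0, 0, 1, 1, 1], "litter": [1, 2, 3, 3, 3],
            "pen": 1, "genotyped": [False, False, True, True, True],
            "phenotyped": False})
        counts = {3: 0, 4: 0, 5: 0}
        reps = 2000
        for s in range(reps):
            part = corepick.select_family(ped, np.array([3, 4, 5]), 1,
                                          seed=s)
            counts[part.core[0]] += 1
        f = 1 / 3
        se = np.sqrt(f * (1 - f) / reps)
        for c in counts.values():
            assert abs(c / reps - f) < 3 * se


class TestUnrelated:
    def test_threshold_above_max_keeps_everyone(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(12, 30))
        G = relmat.RelationshipMatrix(np.arange(1, 13),
                                      0.5 * (Z @ Z.T + (Z @ Z.T).T) / 30)
        tmax = G.values[~np.eye(12, dtype=bool)].max()
        part = corepick.select_unrelated(G, target=12, seed=0,
                                         threshold=tmax + 1)
        assert part.achieved_size == 12

    def test_duplicate_animal_only_one_kept(self):
        vals = np.array([[1.0, 1.0, 0.0],
                         [1.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0]])
        G = relmat.RelationshipMatrix([1, 2, 3], vals)
        part = corepick.select_unrelated(G, target=3, seed=0, threshold=0.5)
        assert len({1, 2} & set(part.core)) == 1
        assert 3 in part.core

    @pytest.mark.parametrize("seed", [0, 1])
    def test_kept_set_pairwise_below_threshold(self, study_bits, seed):
        Gb = study_bits[3]
        part = corepick.select_unrelated(Gb, target=60, seed=seed)
        thr = part.meta["threshold"]
        sub = Gb.submatrix(part.core)
        off = sub[~np.eye(len(sub), dtype=bool)]
        assert off.max() <= thr + 1e-12
        assert part.achieved_size == 60


class TestLeastPopular:
    def make_ped(self):
        rows = [(1, 0, 0, "M", True, False),
                (2, 0, 0, "F", True, False),
                (3, 1, 2, "M", True, False),   # has progeny -> excluded
                (4, 1, 2, "M", True, False),   # eligible
                (5, 1, 2, "M", True, True),    # has record -> excluded
                (6, 3, 2, "F", True, False)]   # eligible female
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex",
                                          "genotyped", "phenotyped"])
        ped["cohort"] = 0
        ped["litter"] = ped["animal"]
        ped["pen"] = 1
        return ped

    def test_progeny_and_records_excluded(self):
        ped = self.make_ped()
        part = corepick.select_least_popular(ped, None, "M", target=5,
                                             seed=0)
        assert part.core.tolist() == [4]
        assert part.shortfall == 4

    def test_pool_membership_matches_bruteforce(self, study_bits):
        ped = study_bits[0]
        part = corepick.select_least_popular(ped, None, "F", target=10 ** 6,
                                             seed=0)
        prog = pd.concat([ped["sire"], ped["dam"]]).value_counts()
        pool = [r["animal"] for _, r in ped.iterrows()
                if r["genotyped"] and r["sex"] == "F" and r["sire"]
                and r["dam"] and not r["phenotyped"]
                and prog.get(r["animal"], 0) == 0]
        assert part.core.tolist() == sorted(pool)

    def test_empty_pool_rejected(self):
        ped = self.make_ped()
        ped["phenotyped"] = True
        with pytest.raises(ValueError, match="pool empty"):
            corepick.select_least_popular(ped, None, "M", 1)


class TestQR:
    def test_orthogonal_columns_largest_norms_picked(self):
        # animals = columns of Z' with norms 3 > 2 > 1, orthogonal
        Z = np.diag([3.0, 2.0, 1.0])
        dosage = np.zeros((3, 3), dtype=np.int8)
        gm = GenotypeMatrix.from_dosage([1, 2, 3], dosage)
        gm.p = np.full(3, 0.5)

        class FakeGM(GenotypeMatrix):
            def centered(self):
                return Z

        gm.__class__ = FakeGM
        part = corepick.select_qr(gm, target=2)
        assert set(part.core) == {1, 2}

    def test_duplicate_animal_columns_not_both_core(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        dosage[1] = dosage[0]              # animal 2 duplicates animal 1
        dosage[:, 0] = [0, 0, 1, 2, 1, 0]  # keep SNPs polymorphic
        gm = GenotypeMatrix.from_dosage(np.arange(1, 7), dosage)
        part = corepick.select_qr(gm, target=5)
        assert not {1, 2} <= set(part.core)

    def test_pivot_rdiag_nonincreasing(self, study_bits):
        gm = study_bits[2]
        part = corepick.select_qr(gm, target=50)
        rdiag = part.meta["rdiag"]
        assert np.all(np.diff(rdiag) <= 1e-9)

    def test_rdiag_matches_reference_factorization(self, study_bits):
        """|diag(R)| from the pivoted QR agrees with numpy's QR applied to
        the pivoted column order (independent route)."""
        import scipy.linalg
        gm = study_bits[2]
        Z = gm.centered().T
        R, piv = scipy.linalg.qr(Z, mode="r", pivoting=True)
        R2 = np.linalg.qr(Z[:, piv], mode="r")
        np.testing.assert_allclose(np.abs(np.diag(R)),
                                   np.abs(np.diag(R2)), rtol=1e-8)


class TestFullCore:
    def test_single_animal(self):
        part = corepick.make_full_core([1])
        assert part.core.tolist() == [1]
        assert len(part.noncore) == 0

    def test_noncore_always_empty(self, study_bits):
        part = corepick.make_full_core(study_bits[1])
        assert len(part.noncore) == 0
        assert part.achieved_size == len(study_bits[1])


@pytest.mark.parametrize("definition", corepick.DEFINITIONS + ("FULL",))
@pytest.mark.parametrize("seed", [0, 1])
def test_every_strategy_returns_valid_partition(study_bits, definition,
                                                seed):
    ped, gids, gm, Gb = study_bits
    spec = corepick.CoreSpec(definition, target_size=30, seed=seed)
    part = corepick.select_core(spec, ped=ped, genotypes=gm, G=Gb,
                                genotyped_ids=gids)
    assert_valid_partition(part, gids)
    # determinism under identical inputs and seed
    part2 = corepick.select_core(spec, ped=ped, genotypes=gm, G=Gb,
                                 genotyped_ids=gids)
    np.testing.assert_array_equal(part.core, part2.core)


@given(st.integers(min_value=1, max_value=50),
       st.integers(min_value=0, max_value=1000))
@settings(max_examples=30, deadline=None)
def test_ped_spread_indices_are_unique_and_in_range(target, offset):
    n = 50
    ids = np.arange(offset + 1, offset + n + 1)
    part = corepick.select_ped_spread(None, ids, target)
    assert part.achieved_size == target
    assert len(np.unique(part.core)) == target
    assert set(part.core) <= set(ids)
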