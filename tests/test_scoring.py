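"""Genome scoring: redundant vs unique counts, totals, association sums,
and the Redundancy Multiplication Score."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cazhotspot.scoring import (
    GenomeProfile,
    association_sum,
    rms,
    round_half_up,
    score_genome,
    total_capacity,
)
from cazhotspot.substrate import SUBSTRATES, SubstrateMap, SubstrateMapEntry, substrates_for

from conftest import inst


def brute_force_profile(instances, smap):
    """Independent oracle: dict/set accumulation straight from the score
    definitions."""
    redundant = {s: 0.0 for s in SUBSTRATES}
    unique = {s: 0.0 for s in SUBSTRATES}
    for i in instances:
        for s, w in substrates_for(i.key, smap).items():
            redundant[s] += w
    for k in {i.key for i in instances}:
        for s, w in substrates_for(k, smap).items():
            unique[s] += w
    return redundant, unique


class TestScoreGenome:
    def test_three_copies_of_one_key(self, tiny_map):
        instances = [inst("g", f"p{i}", "3.2.1.4", "GH5") for i in range(3)]
        p = score_genome(instances, tiny_map)
        assert p.redundant["cellulose"] == 3.0
        assert p.unique["cellulose"] == 1.0

    def test_half_count_key_splits_one_unit(self, tiny_map):
        p = score_genome([inst("g", "p1", "3.1.1.73", "CE1")], tiny_map)
        assert p.redundant["pectin"] == 0.5
        assert p.redundant["xylan"] == 0.5
        assert p.total_redundant == pytest.approx(1.0)

    def test_empty_instance_list_gives_all_zero_profile(self, tiny_map):
        p = score_genome([], tiny_map)
        assert all(v == 0.0 for v in p.redundant.values())
        assert all(v == 0.0 for v in p.unique.values())

    def test_unmapped_instances_contribute_nothing(self, tiny_map):
        p = score_genome([inst("g", "p1", "1.1.1.1", "GH5")], tiny_map)
        assert p.total_redundant == 0.0 and p.total_unique == 0.0

    def test_mixed_genomes_rejected(self, tiny_map):
        with pytest.raises(ValueError, match="multiple genomes"):
            score_genome(
                [inst("gA", "p1", "3.2.1.4", "GH5"), inst("gB", "p1", "3.2.1.4", "GH5")],
                tiny_map,
            )

    def test_hand_enumerated_fixture_matches_brute_force(self, tiny_map):
        # 10 proteins over 4 distinct keys.
        instances = (
            [inst("g", f"p{i}", "3.2.1.4", "GH5") for i in range(4)]
            + [inst("g", f"q{i}", "3.2.1.8", "GH11") for i in range(3)]
            + [inst("g", f"r{i}", "3.1.1.73", "CE1") for i in range(2)]
            + [inst("g", "s0", "1.10.3.2", "AA1")]
        )
        p = score_genome(instances, tiny_map)
        assert p.redundant == {
            "cellulose": 4.0,
            "pectin": 1.0,
            "xylan": 4.0,
            "lignin": 1.0,
        }
        assert p.unique == {
            "cellulose": 1.0,
            "pectin": 0.5,
            "xylan": 1.5,
            "lignin": 1.0,
        }
        red, uniq = brute_force_profile(instances, tiny_map)
        assert p.redundant == red and p.unique == uniq


class TestTotalsAndAssociations:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ({"cellulose": 248, "pectin": 85, "xylan": 208, "lignin": 0}, 541),
            ({"cellulose": 91, "pectin": 204, "xylan": 50, "lignin": 149}, 494),
            ({s: 0 for s in SUBSTRATES}, 0),
        ],
    )
    def test_total_is_sum_of_four_substrates(self, scores, expected):
        p = GenomeProfile("g", redundant=dict(scores))
        assert total_capacity(p) == expected

    @pytest.mark.parametrize(
        "scores, combo, expected",
        [
            ({"cellulose": 91, "pectin": 204, "xylan": 50, "lignin": 149},
             {"pectin", "lignin"}, 353),
            ({"cellulose": 139, "pectin": 176, "xylan": 74, "lignin": 95},
             {"pectin", "lignin"}, 271),
        ],
    )
    def test_association_sum(self, scores, combo, expected):
        p = GenomeProfile("g", redundant=dict(scores))
        assert association_sum(p, combo, "redundant") == expected

    def test_all_four_combo_equals_total(self):
        p = GenomeProfile(
            "g", redundant={"cellulose": 1.5, "pectin": 2, "xylan": 3, "lignin": 0.5}
        )
        assert association_sum(p, SUBSTRATES) == total_capacity(p)

    def test_unknown_substrate_token_fatal(self):
        with pytest.raises(ValueError, match="granite"):
            association_sum(GenomeProfile("g"), {"granite"})


class TestRMS:
    @pytest.mark.parametrize(
        "redundant, unique, rounded, flag",
        [
            (208, 16, 13.0, "high"),
            (204, 24, 8.5, "high"),
            (108, 22, 4.9, "none"),
            (149, 18, 8.3, "high"),
            (5, 5, 1.0, "low"),
        ],
    )
    def test_reported_values_and_flags(self, redundant, unique, rounded, flag):
        v = rms(redundant, unique)
        assert v.rounded == rounded
        assert v.flag == flag

    def test_rounding_is_half_up(self):
        assert rms(85, 20).rounded == 4.3  # 4.25 rounds up, not to even
        assert round_half_up(4.25) == 4.3

    def test_flags_use_unrounded_ratio(self):
        # 7.96 rounds to 8.0 but is not > 8, so no high flag.
        assert rms(796, 100).flag == "none"
        # 8.04 rounds to 8.0 but is > 8.
        assert rms(804, 100).flag == "high"

    def test_undefined_when_unique_zero(self):
        for redundant in (0, 7):
            v = rms(redundant, 0)
            assert v.ratio is None and v.flag == "undefined" and str(v) == "NA"

    def test_flag_characters(self):
        assert rms(208, 16).flag_char == "*"
        assert rms(10, 10).flag_char == "¤"
        assert rms(108, 22).flag_char == ""


def random_fixture(rng):
    ecs = ["3.2.1.4", "3.2.1.8", "3.2.1.15", "1.10.3.2", "3.1.1.73", "5.5.5.5"]
    entries = []
    for ec in ecs[:-1]:
        k = rng.choice([1, 2, 3])
        entries.append(
            SubstrateMapEntry(ec, "*", frozenset(rng.sample(SUBSTRATES, k)))
        )
    smap = SubstrateMap(entries)
    instances = []
    for i in range(rng.randint(0, 40)):
        instances.append(
            inst("g", f"p{i}", rng.choice(ecs), rng.choice(["GH5", "GH7", "PL1"]))
        )
    return instances, smap


@pytest.mark.parametrize("seed", range(200))
def test_invariants_on_random_fixtures(seed):
    """On 200 random fixtures: the profile matches a brute-force oracle,
    U_s <= R_s everywhere, and T_R equals the number of substrate-mapped
    instances (each mapped instance contributes total weight exactly one)."""
    rng = random.Random(seed)
    instances, smap = random_fixture(rng)
    p = score_genome(instances, smap)
    red, uniq = brute_force_profile(instances, smap)
    for s in SUBSTRATES:
        assert p.redundant[s] == pytest.approx(red[s], abs=1e-9)
        assert p.unique[s] == pytest.approx(uniq[s], abs=1e-9)
        assert p.unique[s] <= p.redundant[s] + 1e-12
    n_mapped = sum(1 for i in instances if substrates_for(i.key, smap))
    assert p.total_redundant == pytest.approx(n_mapped, abs=1e-9)


@given(st.integers(1, 50), st.integers(1, 6))
def test_duplicating_instances_doubles_redundant_not_unique(n, k):
    """Scaling law: duplicating every instance doubles each R_s, leaves U_s
    unchanged, and doubles every defined RMS ratio."""
    rng = random.Random(n * 1000 + k)
    instances, smap = random_fixture(rng)
    if not instances:
        return
    doubled = instances + [
        inst(i.genome_id, i.protein_id + "_dup", str(i.key.ec), i.key.family)
        for i in instances
    ]
    p1 = score_genome(instances, smap)
    p2 = score_genome(doubled, smap)
    for s in SUBSTRATES:
        assert p2.redundant[s] == pytest.approx(2 * p1.redundant[s])
        assert p2.unique[s] == pytest.approx(p1.unique[s])
        v1, v2 = rms(p1.redundant[s], p1.unique[s]), rms(p2.redundant[s], p2.unique[s])
        if v1.ratio is not None:
            assert v2.ratio == pytest.approx(2 * v1.ratio)


@given(st.integers(0, 500), st.integers(0, 500))
def test_rms_at_least_one_for_genome_scores(r_extra, u):
    """RMS >= 1 whenever the unique score is positive and the pair comes from
    a genome (instances >= distinct keys)."""
    if u == 0:
        assert rms(r_extra, 0).ratio is None
    else:
        v = rms(u + r_extra, u)
        assert v.ratio >= 1.0
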