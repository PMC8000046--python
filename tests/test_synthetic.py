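"""Ground-truth recovery from the synthetic cohort generator."""

import pytest

from cazhotspot.observation import extract_observations
from cazhotspot.ranking import phylum_distribution, rank_genomes
from cazhotspot.scoring import rms, score_genome
from cazhotspot.substrate import SUBSTRATES, SubstrateMap
from cazhotspot.synthetic import CohortBundle, GenomeSpec, generate_cohort, generate_genome


def score_generated(records, entries):
    instances = extract_observations(records)
    return score_genome(instances, SubstrateMap(entries))


class TestGenerateGenome:
    def test_multiplier_one_gives_rms_one(self):
        spec = GenomeSpec("g", u={"cellulose": 5, "xylan": 3}, seed=7)
        records, entries, truth = generate_genome(spec)
        p = score_generated(records, entries)
        assert p.unique["cellulose"] == 5 and p.redundant["cellulose"] == 5
        assert p.unique["xylan"] == 3 and p.redundant["xylan"] == 3
        assert rms(p.total_redundant, p.total_unique).ratio == 1.0
        assert p.redundant == truth.redundant and p.unique == truth.unique

    def test_rms_near_multiplier_for_large_repertoires(self):
        spec = GenomeSpec("g", u={"cellulose": 2000}, m={"cellulose": 4.0}, seed=3)
        records, entries, _ = generate_genome(spec)
        p = score_generated(records, entries)
        ratio = rms(p.redundant["cellulose"], p.unique["cellulose"]).ratio
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_same_seed_reproduces_identical_tables(self):
        spec = GenomeSpec("g", u={"cellulose": 30, "pectin": 10},
                          m={"cellulose": 2.5}, dual_fraction=0.3, seed=42)
        a = generate_genome(spec)
        b = generate_genome(spec)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].redundant == b[2].redundant

    def test_pool_exhaustion_fatal(self):
        spec = GenomeSpec("g", u={"cellulose": 10}, seed=1)
        with pytest.raises(ValueError, match="pool"):
            generate_genome(spec, pool_size=5)

    def test_missing_seed_fatal(self):
        with pytest.raises(ValueError, match="seed"):
            generate_genome(GenomeSpec("g", u={"cellulose": 1}))

    @pytest.mark.parametrize("dual", [0.0, 0.25, 0.6, 1.0])
    def test_unique_scores_exactly_match_spec_for_any_dual_fraction(self, dual):
        u = {"cellulose": 40, "pectin": 24, "xylan": 16, "lignin": 8}
        spec = GenomeSpec("g", u=u, dual_fraction=dual, seed=9)
        records, entries, truth = generate_genome(spec)
        p = score_generated(records, entries)
        for s in SUBSTRATES:
            assert p.unique[s] == u[s]
            assert truth.unique[s] == u[s]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="m\\["):
            GenomeSpec("g", u={"cellulose": 1}, m={"cellulose": 0.5}, seed=1)
        with pytest.raises(ValueError, match="dual_fraction"):
            GenomeSpec("g", u={"cellulose": 1}, dual_fraction=1.5, seed=1)
        with pytest.raises(ValueError, match="substrate"):
            GenomeSpec("g", u={"granite": 1}, seed=1)


class TestGenerateCohort:
    def test_duplicate_genome_ids_fatal(self):
        specs = [GenomeSpec("g", u={"cellulose": 1}), GenomeSpec("g", u={"xylan": 1})]
        with pytest.raises(ValueError, match="duplicate"):
            generate_cohort(specs, seed=1)

    def test_constructed_capacity_order_recovered_exactly(self):
        specs = [
            GenomeSpec(f"g{i}", u={"cellulose": 10 * (i + 1)}) for i in range(5)
        ]
        bundle = generate_cohort(specs, seed=2)
        profiles = _score_bundle(bundle)
        ranking = rank_genomes(profiles, bundle.metadata, "total")
        assert [e.genome_id for e in ranking] == ["g4", "g3", "g2", "g1", "g0"]
        assert [e.rank for e in ranking] == [1, 2, 3, 4, 5]

    def test_cohort_of_one(self):
        bundle = generate_cohort([GenomeSpec("solo", u={"pectin": 3})], seed=5)
        profiles = _score_bundle(bundle)
        ranking = rank_genomes(profiles, bundle.metadata, "total")
        assert len(ranking) == 1 and ranking[0].rank == 1

    def test_two_phylum_cohort_census_matches_spec_counts(self):
        specs = [
            GenomeSpec(f"a{i}", u={"cellulose": 5 + i}, phylum="Ascomycota")
            for i in range(3)
        ] + [
            GenomeSpec(f"b{i}", u={"cellulose": 1 + i}, phylum="Basidiomycota")
            for i in range(2)
        ]
        bundle = generate_cohort(specs, seed=8)
        profiles = _score_bundle(bundle)
        ranking = rank_genomes(profiles, bundle.metadata, "total")
        (win,) = phylum_distribution(ranking, [(1, 5)])
        assert win.phylum_counts == {"Ascomycota": 3, "Basidiomycota": 2}

    def test_intended_representative_wins_selection(self):
        from cazhotspot.assembly import select_representative

        bundle = generate_cohort(
            [GenomeSpec("g0", u={"cellulose": 2}), GenomeSpec("g1", u={"xylan": 2})],
            seed=3,
        )
        selection, _ = select_representative(bundle.assemblies)
        assert selection == bundle.expected_representatives


def _score_bundle(bundle: CohortBundle):
    instances = extract_observations(bundle.records)
    by_genome = {gid: [] for gid in bundle.metadata}
    for i in instances:
        by_genome[i.genome_id].append(i)
    profiles = []
    for gid in sorted(by_genome):
        p = score_genome(by_genome[gid], bundle.substrate_map)
        if not p.genome_id:
            p.genome_id = gid
        profiles.append(p)
    return profiles


def test_mean_rms_recovers_multiplier_across_seeds():
    """Parameter recovery: the mean scored per-substrate RMS over 20 seeds is
    within 5% of the spec multiplier for repertoires of 200 keys."""
    m = {"cellulose": 1.0, "pectin": 2.0, "xylan": 4.0, "lignin": 8.0}
    u = {s: 200 for s in SUBSTRATES}
    ratios = {s: [] for s in SUBSTRATES}
    for seed in range(20):
        records, entries, _ = generate_genome(GenomeSpec("g", u=u, m=m, seed=seed))
        p = score_generated(records, entries)
        for s in SUBSTRATES:
            assert p.unique[s] == u[s]
            ratios[s].append(p.redundant[s] / p.unique[s])
    for s in SUBSTRATES:
        mean = sum(ratios[s]) / len(ratios[s])
        assert mean == pytest.approx(m[s], rel=0.05)
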