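"""Synthetic-data generator: JC69 divergence, crosses, reads, gene trees."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridcensus import (
    GeneTreeForestSpec,
    SimulationConfig,
    jc69_expected_p,
    make_hybrid,
    simulate_gene_trees,
    simulate_parent_genomes,
    simulate_reads,
)
from hybridcensus.simdata import decode_seq, encode_seq, revcomp
from hybridcensus.treecensus import sister_census


def _concat(chroms):
    return np.concatenate(chroms)


class TestJC69:
    def test_zero_branch_is_identity(self):
        cfg = SimulationConfig(
            seed=1, species=[("anc_copy", 0.0), ("other", 0.1)], dam="anc_copy", sire="other"
        )
        gs = simulate_parent_genomes(cfg)
        assert all(
            np.array_equal(a, c)
            for a, c in zip(gs.ancestor, gs["anc_copy"].chromosomes)
        )
        assert np.array_equal(gs.mito_ancestor, gs["anc_copy"].mito)

    def test_saturation_limit(self):
        cfg = SimulationConfig(
            seed=2, species=[("sat", 10.0), ("other", 0.1)], dam="sat", sire="other"
        )
        gs = simulate_parent_genomes(cfg)
        diff = (_concat(gs.ancestor) != _concat(gs["sat"].chromosomes)).mean()
        se = math.sqrt(0.75 * 0.25 / cfg.genome_length)
        assert abs(diff - 0.75) < 4 * se

    def test_divergence_matches_formula_at_1mb(self):
        d = 0.10
        cfg = SimulationConfig(
            seed=3,
            genome_length=1_000_000,
            n_chromosomes=1,
            species=[("x", d), ("y", d)],
            dam="x",
            sire="y",
        )
        gs = simulate_parent_genomes(cfg)
        p = jc69_expected_p(d)
        assert abs(p - 0.0935) < 5e-4  # closed form itself
        diff = (_concat(gs.ancestor) != _concat(gs["x"].chromosomes)).mean()
        se = math.sqrt(p * (1 - p) / cfg.genome_length)
        assert abs(diff - p) < 3 * se

    def test_pairwise_divergence_is_additive(self):
        d1, d2 = 0.05, 0.08
        cfg = SimulationConfig(
            seed=4,
            genome_length=1_000_000,
            n_chromosomes=1,
            species=[("x", d1), ("y", d2)],
            dam="x",
            sire="y",
        )
        gs = simulate_parent_genomes(cfg)
        p = jc69_expected_p(d1 + d2)
        diff = (
            _concat(gs["x"].chromosomes) != _concat(gs["y"].chromosomes)
        ).mean()
        se = math.sqrt(p * (1 - p) / cfg.genome_length)
        assert abs(diff - p) < 3 * se

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(species=[("a", -0.1), ("b", 0.1)], dam="a", sire="b")
        with pytest.raises(ValueError):
            SimulationConfig(error_rate=1.0)


class TestHybrid:
    def test_f1_origin_is_half_half_exactly(self, small_genomes):
        cfg, gs = small_genomes
        h = make_hybrid(gs, cfg)
        assert h.ancestry_fraction("numida") == 0.5
        assert h.ancestry_fraction("gallus") == 0.5
        # haplotype 0 entirely dam, haplotype 1 entirely sire
        assert all((o == 0).all() for o in h.origins[0])
        assert all((o == 1).all() for o in h.origins[1])

    def test_f1_mito_identical_to_dam(self, small_genomes):
        cfg, gs = small_genomes
        h = make_hybrid(gs, cfg)
        assert np.array_equal(h.mito, gs[cfg.dam].mito)

    def test_bc1_mean_ancestry_converges_to_075(self):
        fracs = []
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed,
                genome_length=10_000,
                n_chromosomes=4,
                hybrid_cross="BC1",
                backcross_parent="numida",
            )
            gs = simulate_parent_genomes(cfg)
            fracs.append(make_hybrid(gs, cfg).ancestry_fraction("numida"))
        # SD of one replicate ~= 0.144/sqrt(4 chromosomes) = 0.072
        assert abs(np.mean(fracs) - 0.75) < 3 * 0.072 / math.sqrt(200)

    def test_balanced_crossovers_give_exact_075(self):
        cfg = SimulationConfig(
            seed=5,
            hybrid_cross="BC1",
            backcross_parent="numida",
            balanced_crossovers=True,
        )
        gs = simulate_parent_genomes(cfg)
        assert make_hybrid(gs, cfg).ancestry_fraction("numida") == 0.75

    def test_origin_track_partitions_every_position(self, small_genomes):
        cfg, gs = small_genomes
        cfg2 = SimulationConfig(
            **{
                **{f.name: getattr(cfg, f.name) for f in cfg.__dataclass_fields__.values()},
                "hybrid_cross": "BC1",
                "backcross_parent": "gallus",
            }
        )
        h = make_hybrid(gs, cfg2)
        for hap_seq, hap_org in zip(h.haplotypes, h.origins):
            for seq, org in zip(hap_seq, hap_org):
                assert seq.size == org.size
                assert set(np.unique(org)) <= {0, 1}

    def test_bc1_requires_backcross_parent(self):
        with pytest.raises(ValueError):
            SimulationConfig(hybrid_cross="BC1")
        with pytest.raises(ValueError):
            SimulationConfig(hybrid_cross="BC1", backcross_parent="phasianus")


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self, small_genomes):
        cfg, gs = small_genomes
        cfg = SimulationConfig(
            seed=9,
            genome_length=10_000,
            n_chromosomes=4,
            mito_length=4_000,
            species=[("numida", 0.05), ("gallus", 0.05), ("phasianus", 0.2)],
            n_reads=200,
            error_rate=0.0,
            mito_read_fraction=0.0,
        )
        h = make_hybrid(gs, cfg)
        reads = simulate_reads(h, cfg)
        for r in reads:
            info = dict(p.split("=") for p in r.id.split("|")[1:])
            hap, chrom = info["loc"].split("/")
            src = h.haplotypes[int(hap[3])][int(chrom[3])]
            start = int(info["start"])
            expect = src[start : start + cfg.read_length]
            got = encode_seq(r.seq)
            if info["strand"] == "-":
                got = revcomp(got)
            assert np.array_equal(got, expect)

    def test_error_rate_recovered(self, small_genomes):
        cfg0, gs = small_genomes
        cfg = SimulationConfig(
            seed=10,
            genome_length=10_000,
            n_chromosomes=4,
            mito_length=4_000,
            species=cfg0.species,
            n_reads=10_000,
            error_rate=0.01,
            mito_read_fraction=0.0,
        )
        h = make_hybrid(gs, cfg)
        reads = simulate_reads(h, cfg)
        mism = total = 0
        for r in reads:
            info = dict(p.split("=") for p in r.id.split("|")[1:])
            hap, chrom = info["loc"].split("/")
            src = h.haplotypes[int(hap[3])][int(chrom[3])]
            start = int(info["start"])
            expect = src[start : start + cfg.read_length]
            got = encode_seq(r.seq)
            if info["strand"] == "-":
                got = revcomp(got)
            mism += int((got != expect).sum())
            total += cfg.read_length
        se = math.sqrt(0.01 * 0.99 / total)
        assert abs(mism / total - 0.01) < 3 * se

    def test_mito_fraction_binomial(self, small_genomes):
        cfg0, gs = small_genomes
        cfg = SimulationConfig(
            seed=11,
            genome_length=10_000,
            n_chromosomes=4,
            mito_length=4_000,
            species=cfg0.species,
            n_reads=10_000,
            mito_read_fraction=0.1,
        )
        h = make_hybrid(gs, cfg)
        reads = simulate_reads(h, cfg)
        n_mito = sum(1 for r in reads if r.origin.startswith("mito:"))
        se = math.sqrt(0.1 * 0.9 * cfg.n_reads)
        assert abs(n_mito - 1000) < 4 * se

    def test_seeded_determinism(self, small_genomes):
        cfg, gs = small_genomes
        h = make_hybrid(gs, cfg)
        r1 = simulate_reads(h, cfg)
        r2 = simulate_reads(h, cfg)
        assert [(a.id, a.seq, a.qual) for a in r1] == [
            (a.id, a.seq, a.qual) for a in r2
        ]

    def test_rejects_nonpositive_read_count(self, small_genomes):
        cfg, gs = small_genomes
        with pytest.raises(ValueError):
            simulate_reads(make_hybrid(gs, cfg), SimulationConfig(n_reads=0))


class TestGeneTrees:
    TAXA = ["H", "O", "A", "B", "C", "D"]

    def test_pure_mixture_every_sister_is_a(self):
        spec = GeneTreeForestSpec(
            n_trees=50, taxa=self.TAXA, focal="H", outgroup="O",
            sister_mixture={"A": 1.0}, seed=1,
        )
        cen = sister_census(simulate_gene_trees(spec), "H", "O")
        assert cen.counts["A"] == 50 and cen.n_singleton == 50

    def test_quota_counts_exact(self):
        quota = {"A": 30, "B": 12, "C": 3, "__multi__": 5}
        spec = GeneTreeForestSpec(
            n_trees=50, taxa=self.TAXA, focal="H", outgroup="O",
            sister_mixture={"A": 0.6, "B": 0.24, "C": 0.06},
            non_singleton_fraction=0.1, quota_counts=quota, seed=2,
        )
        cen = sister_census(simulate_gene_trees(spec), "H", "O")
        assert cen.counts["A"] == 30 and cen.counts["B"] == 12 and cen.counts["C"] == 3
        assert cen.n_multi_sister == 5

    def test_bernoulli_mixture_recovered_within_3se(self):
        mix = {"A": 0.45, "B": 0.34, "C": 0.21}
        spec = GeneTreeForestSpec(
            n_trees=8063, taxa=self.TAXA, focal="H", outgroup="O",
            sister_mixture=mix, seed=3,
        )
        cen = sister_census(simulate_gene_trees(spec), "H", "O")
        assert cen.n_singleton == 8063
        for sp, p in mix.items():
            se = math.sqrt(p * (1 - p) / 8063)
            assert abs(cen.proportions[sp] - p) < 3 * se

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GeneTreeForestSpec(
                n_trees=5, taxa=self.TAXA, focal="H", outgroup="O",
                sister_mixture={"A": 0.5}, non_singleton_fraction=0.2,
            )

    def test_forest_determinism(self):
        spec = GeneTreeForestSpec(
            n_trees=20, taxa=self.TAXA, focal="H", outgroup="O",
            sister_mixture={"A": 0.5, "B": 0.5}, seed=9,
        )
        assert simulate_gene_trees(spec) == simulate_gene_trees(spec)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=80))
def test_encode_decode_roundtrip(s):
    assert decode_seq(encode_seq(s)) == s


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
def test_revcomp_is_involution(s):
    a = encode_seq(s)
    assert np.array_equal(revcomp(revcomp(a)), a)
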