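"""Simulator: construction guarantees, determinism, and truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from alemut.effects import translate, wild_type_cds
from alemut.models import DiploidGenotype, GenotypeTable, SiteRecord
from alemut.simulate import (
    CNVEvent,
    SimulationConfig,
    evolve_lineage,
    generate_cohort,
    make_parent,
    make_reference,
    simulate_depth,
)

SMALL = SimulationConfig(
    n_contigs=2, contig_length=30_000, n_cds_per_contig=10,
    n_loh_tracts=3, tract_length_mean=4_000, n_de_novo=6.0,
    n_lineages=2, group_sizes=(1, 1),
)


class TestMakeReference:
    def test_gc_zero_yields_at_only_outside_cds(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=5_000, gc_fraction=0.0,
                               n_cds_per_contig=0, n_lineages=1, group_sizes=(1,),
                               group_names=("A",))
        ref, _ = make_reference(cfg, seed=3)
        assert set(next(iter(ref.contigs.values()))) <= {"A", "T"}

    def test_every_cds_is_a_clean_orf(self):
        ref, feats = make_reference(SMALL, seed=5)
        for f in feats:
            seq = wild_type_cds(f, ref)
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            protein, stop, incomplete = translate(seq)
            # stop is the final codon and nowhere earlier
            assert stop == len(seq) // 3
            assert not incomplete
            assert "*" not in protein

    def test_same_seed_same_genome(self):
        a, fa = make_reference(SMALL, seed=9)
        b, fb = make_reference(SMALL, seed=9)
        assert a.contigs == b.contigs
        assert fa == fb

    def test_infeasible_cds_request_rejected(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=2_000,
                               n_cds_per_contig=50, n_lineages=1,
                               group_sizes=(1,), group_names=("A",))
        with pytest.raises(ValueError, match="could not place"):
            make_reference(cfg, seed=1)


class TestMakeParent:
    def test_zero_density_empty(self):
        ref, _ = make_reference(SMALL, seed=5)
        assert len(make_parent(ref, 0.0, seed=1)) == 0

    def test_site_count_matches_binomial_oracle(self):
        """300 kb at density 1/300: count within 3 SD of the binomial mean
        (905-1095); the pinned seed gives exactly 983."""
        ref, _ = make_reference(SimulationConfig(), seed=11)
        parent = make_parent(ref, 1 / 300, seed=42)
        L, p = ref.total_length, 1 / 300
        mean, sd = L * p, (L * p * (1 - p)) ** 0.5
        assert mean - 3 * sd <= len(parent) <= mean + 3 * sd
        assert len(parent) == 983

    def test_all_sites_heterozygous_ref_alt(self):
        ref, _ = make_reference(SMALL, seed=5)
        parent = make_parent(ref, 1 / 200, seed=7)
        assert len(parent) > 0
        for rec in parent:
            assert rec.genotype.is_het
            assert rec.ref in rec.genotype
            assert ref.base(rec.contig, rec.pos) == rec.ref


class TestEvolveLineage:
    def _setup(self, **overrides):
        cfg = SimulationConfig(**{**SMALL.__dict__, **overrides})
        ref, _ = make_reference(cfg, seed=5)
        parent = make_parent(ref, cfg.het_density, seed=7)
        return cfg, ref, parent

    def test_no_events_means_identical_table(self):
        cfg, ref, parent = self._setup(n_loh_tracts=0, n_de_novo=0.0,
                                       n_cnv_events_mean=0.0)
        evolved, truth = evolve_lineage(parent, ref, cfg, seed=1)
        assert [(r.pos, r.genotype) for r in evolved] == [
            (r.pos, r.genotype) for r in parent
        ]
        assert truth.labels == [] and truth.de_novo == []

    def test_reference_retaining_tract_drops_all_covered_sites(self):
        cfg, ref, parent = self._setup(n_loh_tracts=1, n_de_novo=0.0,
                                       p_retain_reference=1.0,
                                       n_cnv_events_mean=0.0)
        evolved, truth = evolve_lineage(parent, ref, cfg, seed=3)
        (tract,) = truth.tracts
        covered = [r for r in parent
                   if r.contig == tract["contig"]
                   and tract["start"] <= r.pos <= tract["end"]]
        assert tract["n_het_sites"] == len(covered)
        assert all(l.is_reversion for l in truth.labels)
        assert len(truth.labels) == len(covered)
        evolved_keys = {r.key for r in evolved}
        assert all(r.key not in evolved_keys for r in covered)

    def test_truth_covers_exactly_the_differing_sites(self):
        """Under hom-ref imputation the differing sites are exactly the truth
        labels; reversions are the parent sites silently missing from the
        evolved table (hence invisible without a parent-aware comparison)."""
        cfg, ref, parent = self._setup()
        evolved, truth = evolve_lineage(parent, ref, cfg, seed=11)
        psites, esites = parent.sites(), evolved.sites()
        differing = set()
        for key in set(psites) | set(esites):
            p, e = psites.get(key), esites.get(key)
            if p is None or e is None or p.genotype != e.genotype:
                differing.add(key)
        labelled = {(l.contig, l.pos) for l in truth.labels}
        assert differing == labelled
        reversion = {(l.contig, l.pos) for l in truth.labels
                     if l.category == "loh" and l.is_reversion}
        visible_in_evolved = {
            (l.contig, l.pos) for l in truth.labels
            if not (l.category == "loh" and l.is_reversion)
        }
        assert all(k in psites and k not in esites for k in reversion)
        assert all(k in esites for k in visible_in_evolved)

    @pytest.mark.parametrize("p_retain", [0.0, 1.0])
    def test_retention_probability_endpoints(self, p_retain):
        cfg, ref, parent = self._setup(n_loh_tracts=2, n_de_novo=0.0,
                                       n_cnv_events_mean=0.0,
                                       p_retain_reference=p_retain)
        _, truth = evolve_lineage(parent, ref, cfg, seed=13)
        assert all(t["retained_reference"] == bool(p_retain) for t in truth.tracts)

    def test_reversion_fraction_unbiased_over_many_tracts(self):
        """Retained-reference fraction over 240 independent tracts shows no
        gross bias away from p_retain_reference = 0.5 (3.3-sigma guard)."""
        cfg, ref, parent = self._setup(n_loh_tracts=2, n_de_novo=0.0,
                                       n_cnv_events_mean=0.0)
        n_ref = n_total = 0
        for seed in range(120):  # 240 tracts
            _, truth = evolve_lineage(parent, ref, cfg, seed=seed)
            for t in truth.tracts:
                n_total += 1
                n_ref += t["retained_reference"]
        assert n_total >= 200
        half_width = 3.3 * (0.25 / n_total) ** 0.5
        assert abs(n_ref / n_total - 0.5) <= half_width

    def test_cnv_events_change_profile_not_genotypes(self):
        cfg, ref, parent = self._setup(n_loh_tracts=0, n_de_novo=0.0)
        events = [CNVEvent("chrI", +1, (1001, 7000)), CNVEvent("chrII", -1, None)]
        evolved, truth = evolve_lineage(parent, ref, cfg, seed=2, cnv_events=events)
        assert [(r.pos, r.genotype) for r in evolved] == [
            (r.pos, r.genotype) for r in parent
        ]
        assert set(truth.copy_profile["chrI"][1000:7000]) == {3}
        assert set(truth.copy_profile["chrI"][:1000]) == {2}
        assert set(truth.copy_profile["chrII"]) == {1}


class TestSimulateDepth:
    def test_mean_depth_matches_poisson_oracle(self):
        profile = {"chrA": np.full(50_000, 2, dtype=int)}
        track = simulate_depth(profile, mean_depth=50.0, seed=4)
        mean = track.depths["chrA"].mean()
        sd_of_mean = (50.0 / 50_000) ** 0.5
        assert abs(mean - 50.0) <= 3 * sd_of_mean

    def test_copy_zero_gives_zero_depth(self):
        profile = {"chrA": np.array([2] * 10 + [0] * 10)}
        track = simulate_depth(profile, mean_depth=50.0, seed=4)
        assert np.all(track.depths["chrA"][10:] == 0)

    def test_deterministic_per_seed(self):
        profile = {"chrA": np.full(1_000, 2, dtype=int)}
        a = simulate_depth(profile, 30.0, seed=8)
        b = simulate_depth(profile, 30.0, seed=8)
        np.testing.assert_array_equal(a.depths["chrA"], b.depths["chrA"])

    def test_negative_copy_rejected(self):
        with pytest.raises(ValueError):
            simulate_depth({"chrA": np.array([-1, 2])}, 50.0, seed=1)


class TestGenerateCohort:
    def test_file_tree_and_refusal(self, tmp_path):
        out = tmp_path / "c"
        generate_cohort(SMALL, out, seed=5)
        assert (out / "parent.vcf").exists()
        assert len(list(out.glob("EV*.vcf"))) == SMALL.n_lineages
        assert len(list((out / "truth").glob("*.json"))) == SMALL.n_lineages
        groups = (out / "groups.tsv").read_text().splitlines()
        assert len(groups) == SMALL.n_lineages
        with pytest.raises(FileExistsError):
            generate_cohort(SMALL, out, seed=5)

    def test_same_seed_same_checksums(self, tmp_path):
        m1 = generate_cohort(SMALL, tmp_path / "a", seed=5)
        m2 = generate_cohort(SMALL, tmp_path / "b", seed=5)
        assert m1["files"] == m2["files"]

    def test_config_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        import yaml

        p.write_text(yaml.safe_dump(SMALL.to_dict()))
        assert SimulationConfig.from_yaml(p) == SMALL

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            SimulationConfig.from_dict({"n_contigs": 2, "typo_key": 1})
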