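"""The synthetic-study generator: determinism, calibration, file round trips."""
from __future__ import annotations

import math

import numpy as np
import pytest

from herbmark.preprocess import revcomp
from herbmark.simulate import (
    PANEL_DOSAGE_FORMS,
    PANEL_SPECIES_COUNTS,
    GroundTruth,
    Scenario,
    default_scenario,
    emit_fastq,
    fungal_species_pool,
    plant_species_pool,
    read_fastq_pairs,
    simulate_formulation,
    simulate_reads,
    simulate_reference_db,
    simulate_study,
    write_study,
)


def _binomial_ci(p: float, n: int, z: float = 4.0) -> tuple[float, float]:
    half = z * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestReferenceDb:
    def test_structure_and_divergence(self):
        rng = np.random.default_rng(11)
        records = simulate_reference_db(rng, n_families=3, genera_per_family=2,
                                        species_per_genus=2, n_fungi=2)
        plants = [r for r in records if r.lineage.kingdom == "Plantae"]
        fungi = [r for r in records if r.lineage.kingdom == "Fungi"]
        assert len(plants) == 3 * 2 * 2 * 2  # families x genera x species x loci
        assert len(fungi) == 2 * 2
        assert len({r.record_id for r in records}) == len(records)
        assert all(400 <= len(r.sequence) <= 480 for r in records)
        assert len(plant_species_pool(records)) == 12
        assert fungal_species_pool(records) == [
            "Fungaus contaminans", "Fungbus contaminans"
        ]
        # congeneric species must sit below the 99% species-acceptance band
        from herbmark.alignment import global_identity

        a = next(r for r in plants if r.record_id == "ITS2_Agenusa_aensis")
        b = next(r for r in plants if r.record_id == "ITS2_Agenusa_bensis")
        assert global_identity(a.sequence, b.sequence) < 0.99

    def test_deterministic(self):
        r1 = simulate_reference_db(np.random.default_rng(5), n_families=2)
        r2 = simulate_reference_db(np.random.default_rng(5), n_families=2)
        assert r1 == r2


class TestFormulation:
    def _pool(self):
        rng = np.random.default_rng(17)
        records = simulate_reference_db(rng, n_families=10)
        return plant_species_pool(records), fungal_species_pool(records)

    def test_truth_invariants(self):
        pool, fungi = self._pool()
        rng = np.random.default_rng(23)
        for _ in range(50):
            label, truth = simulate_formulation(
                8, pool, rng, contaminant_pool=fungi
            )
            assert len(label.declared_species) == 8
            assert set(truth.present_declared) <= set(label.declared_species)
            assert set(truth.dropped_declared) <= set(label.declared_species)
            assert not set(truth.admixture_taxa) & set(label.declared_species)
            assert set(truth.contaminant_taxa) <= set(fungi)
            if truth.abundances:
                assert sum(truth.abundances.values()) == pytest.approx(1.0)

    def test_dropout_rate_calibrated(self):
        pool, _ = self._pool()
        rng = np.random.default_rng(29)
        n_rep, n_species = 2000, 10
        dropped = sum(
            len(simulate_formulation(n_species, pool, rng, dropout_rate=0.2)[1].dropped_declared)
            for _ in range(n_rep)
        )
        lo, hi = _binomial_ci(0.2, n_rep * n_species)
        assert lo <= dropped / (n_rep * n_species) <= hi

    def test_contaminant_probability_calibrated(self):
        pool, fungi = self._pool()
        rng = np.random.default_rng(31)
        n_rep = 2000
        hits = sum(
            bool(simulate_formulation(5, pool, rng, contaminant_pool=fungi,
                                      contaminant_prob=0.3)[1].contaminant_taxa)
            for _ in range(n_rep)
        )
        lo, hi = _binomial_ci(0.3, n_rep)
        assert lo <= hits / n_rep <= hi

    def test_uniform_alpha_none(self):
        pool, _ = self._pool()
        _, truth = simulate_formulation(
            6, pool, np.random.default_rng(37), dropout_rate=0.0,
            admixture_rate=0.0, alpha=None,
        )
        assert all(w == pytest.approx(1 / 6) for w in truth.abundances.values())

    def test_validation(self):
        pool, _ = self._pool()
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match=r"\[1, 55\]"):
            simulate_formulation(0, pool, rng)
        with pytest.raises(ValueError, match="pool size"):
            simulate_formulation(55, pool[:10], rng)


class TestReads:
    def _setup(self):
        rng = np.random.default_rng(41)
        records = simulate_reference_db(rng, n_families=2, n_fungi=0)
        its2 = [r for r in records if r.locus == "ITS2"]
        species = sorted({r.lineage.species for r in its2})[:2]
        truth = GroundTruth(
            sample_id="S1",
            abundances={species[0]: 0.7, species[1]: 0.3},
            present_declared=tuple(species),
            dropped_declared=(),
            admixture_taxa=(),
            contaminant_taxa=(),
        )
        return truth, its2

    def test_shapes_qualities_and_sources(self):
        truth, its2 = self._setup()
        pairs = simulate_reads(truth, its2, depth=50,
                               rng=np.random.default_rng(43))
        assert len(pairs) == 50
        valid_ids = {r.record_id for r in its2}
        for p in pairs:
            assert len(p.fwd_seq) == len(p.fwd_qual) == 300
            assert len(p.rev_seq) == len(p.rev_qual) == 300
            assert p.true_source in valid_ids or p.true_source.startswith("CHIMERA:")
        # the quality ramp encodes the true error profile (Q40 down to ~Q23)
        q = [ord(c) - 33 for c in pairs[0].fwd_qual]
        assert q[0] == 33  # -10*log10(5e-4) = 33.0
        assert q[-1] == 23  # -10*log10(5e-3) = 23.0
        assert all(a >= b for a, b in zip(q, q[1:]))

    def test_zero_error_reads_match_templates(self):
        truth, its2 = self._setup()
        by_id = {r.record_id: r.sequence for r in its2}
        pairs = simulate_reads(truth, its2, depth=30, rng=np.random.default_rng(47),
                               err0=0.0, err1=0.0, chimera_fraction=0.0)
        for p in pairs:
            template = by_id[p.true_source]
            assert p.fwd_seq == template[:300]
            assert revcomp(p.rev_seq) == template[-300:]

    def test_source_fractions_calibrated(self):
        truth, its2 = self._setup()
        pairs = simulate_reads(truth, its2, depth=4000,
                               rng=np.random.default_rng(53), chimera_fraction=0.0)
        id_to_species = {r.record_id: r.lineage.species for r in its2}
        first = sorted(truth.abundances)[0]
        frac = sum(id_to_species[p.true_source] == first for p in pairs) / len(pairs)
        lo, hi = _binomial_ci(truth.abundances[first], len(pairs))
        assert lo <= frac <= hi

    def test_chimera_fraction_calibrated(self):
        truth, its2 = self._setup()
        pairs = simulate_reads(truth, its2, depth=6000,
                               rng=np.random.default_rng(59), chimera_fraction=0.05)
        frac = sum(p.true_source.startswith("CHIMERA:") for p in pairs) / len(pairs)
        lo, hi = _binomial_ci(0.05, len(pairs))
        assert lo <= frac <= hi

    def test_oversized_amplicon_skipped(self, caplog):
        truth, its2 = self._setup()
        # with 150-nt reads every 400+ nt amplicon leaves too little overlap
        with pytest.raises(ValueError, match="no usable amplicon"):
            simulate_reads(truth, its2, depth=5, rng=np.random.default_rng(1),
                           read_len=150)


class TestPanel:
    def test_roster_shape(self):
        assert len(PANEL_SPECIES_COUNTS) == 39
        assert len(PANEL_DOSAGE_FORMS) == 39
        assert min(PANEL_SPECIES_COUNTS) == 1 and max(PANEL_SPECIES_COUNTS) == 55
        assert PANEL_DOSAGE_FORMS.count("POWDER") == 25
        assert PANEL_DOSAGE_FORMS.count("CAPSULE") == 9
        assert PANEL_DOSAGE_FORMS.count("TABLET") == 5

    def test_default_scenario(self):
        sc = default_scenario(depth_per_species=40, min_depth=200)
        assert len(sc.products) == 39
        assert sum(p.source_type == "IN_HOUSE" for p in sc.products) == 24
        assert all(p.depth >= 200 for p in sc.products)
        one = next(p for p in sc.products if p.n_species == 55)
        assert one.depth == 2200


class TestStudy:
    def _tiny_scenario(self, **overrides):
        base = default_scenario()
        products = base.products[30:34]  # small labels (5, 1, 1, 4 species)
        kwargs = dict(
            products=products, loci=("ITS2",), n_families=4,
            genera_per_family=2, species_per_genus=2, n_fungi=2,
        )
        kwargs.update(overrides)
        return Scenario(**kwargs)

    def test_study_deterministic_and_written(self, tmp_path):
        sc = self._tiny_scenario()
        b1 = simulate_study(sc, seed=123)
        b2 = simulate_study(sc, seed=123)
        assert b1.reads.keys() == b2.reads.keys()
        for key in b1.reads:
            assert b1.reads[key] == b2.reads[key]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(b1, d1)
        write_study(b2, d2)
        for rel in ("refdb.fasta", "taxonomy.tsv", "labels.tsv", "ground_truth.tsv"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        sid = sc.products[0].sample_id
        assert (d1 / "fastq" / f"{sid}_ITS2_R1.fastq").read_bytes() == (
            d2 / "fastq" / f"{sid}_ITS2_R1.fastq"
        ).read_bytes()

    def test_different_seeds_differ(self):
        sc = self._tiny_scenario()
        b1 = simulate_study(sc, seed=1)
        b2 = simulate_study(sc, seed=2)
        assert any(b1.reads[k] != b2.reads[k] for k in b1.reads)

    def test_zero_depth_sample_has_no_reads(self):
        import dataclasses

        sc = self._tiny_scenario()
        sc = dataclasses.replace(sc, zero_depth_samples=(sc.products[0].sample_id,))
        bundle = simulate_study(sc, seed=3)
        assert bundle.reads[(sc.products[0].sample_id, "ITS2")] == []

    def test_fastq_roundtrip(self, tmp_path):
        truth, its2 = TestReads()._setup()
        pairs = simulate_reads(truth, its2, depth=20, rng=np.random.default_rng(61))
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        emit_fastq(pairs, r1, r2, truth_path=tmp_path / "truth.tsv")
        back = read_fastq_pairs(r1, r2)
        assert len(back) == 20
        for orig, rec in zip(pairs, back):
            assert (rec.read_id, rec.fwd_seq, rec.fwd_qual) == (
                orig.read_id, orig.fwd_seq, orig.fwd_qual
            )
            assert (rec.rev_seq, rec.rev_qual) == (orig.rev_seq, orig.rev_qual)
        truth_lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert truth_lines[0] == "read_id\ttrue_source"
        assert len(truth_lines) == 21
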