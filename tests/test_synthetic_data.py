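"""Generator behaviour: divergence targets, planted classes, genome
round-trips, AED/GO statistical structure, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duoproteome import (ConfigError, LineageParams, SimulationConfig,
                         TruthLedger, simulate, simulate_ancestral_proteome)
from duoproteome.synthetic_data import (SPECIES_A, SPECIES_B,
                                        assign_aed_and_go, emit_genomes,
                                        evolve_proteome, lineage_params_for,
                                        mutate_to_identity,
                                        random_protein, _identity_between)

from conftest import small_sim_config


def _translate(dna: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(dna).translate())


def _revcomp(dna: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(dna).reverse_complement())


class TestAncestralProteome:
    def test_length_clamp_boundary(self):
        cfg = SimulationConfig(n_ancestral=1, mean_len=100, sd_len=400)
        recs = simulate_ancestral_proteome(cfg, np.random.default_rng(0))
        assert len(recs) == 1 and len(recs[0].seq) >= 30

    def test_mean_length_matches_lognormal_target(self):
        cfg = SimulationConfig(n_ancestral=500, mean_len=300, sd_len=120)
        recs = simulate_ancestral_proteome(cfg, np.random.default_rng(3))
        lengths = np.array([len(r.seq) for r in recs])
        se = cfg.sd_len / math.sqrt(len(recs))
        assert abs(lengths.mean() - cfg.mean_len) < 3 * se

    def test_invalid_length_parameters_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig.from_dict({"mean_len": -5})

    def test_alphabet(self):
        cfg = SimulationConfig(n_ancestral=20, mean_len=80, sd_len=10)
        recs = simulate_ancestral_proteome(cfg, np.random.default_rng(1))
        assert all(set(r.seq) <= set("ACDEFGHIKLMNPQRSTVWY") for r in recs)


class TestEvolveProteome:
    def test_identity_case_no_change(self):
        rng = np.random.default_rng(0)
        anc = simulate_ancestral_proteome(
            SimulationConfig(n_ancestral=10, mean_len=100, sd_len=20), rng)
        params = LineageParams("A", identity_mean=100, identity_sd=0,
                               p_loss=0, p_dup=0)
        recs, events = evolve_proteome(anc, params, 5)
        assert [r.seq for r in recs] == [a.seq for a in anc]
        assert (events["event"] == "descend").all()

    def test_total_loss_empties_lineage(self):
        rng = np.random.default_rng(0)
        anc = simulate_ancestral_proteome(
            SimulationConfig(n_ancestral=15, mean_len=80, sd_len=10), rng)
        params = LineageParams("B", identity_mean=80, identity_sd=5,
                               p_loss=1.0, p_dup=0)
        recs, events = evolve_proteome(anc, params, 5)
        assert recs == []
        assert (events["event"] == "loss").all()
        assert len(events) == len(anc)

    def test_realized_identity_quantile_matches_target(self):
        """5th percentile of realized ancestor-descendant identities is at
        the Gaussian quantile of the configured target distribution."""
        rng = np.random.default_rng(12)
        anc = simulate_ancestral_proteome(
            SimulationConfig(n_ancestral=400, mean_len=300, sd_len=100), rng)
        params = LineageParams("A", identity_mean=80, identity_sd=8,
                               p_loss=0, p_dup=0)
        _, events = evolve_proteome(anc, params, 21)
        realized = events["realized_identity"].to_numpy()
        expected_q5 = 80 + 8 * stats.norm.ppf(0.05)
        assert abs(np.percentile(realized, 5) - expected_q5) < 3.0

    def test_zero_identity_target_rejected(self):
        anc = [random_protein(50, np.random.default_rng(0))]
        from duoproteome import ProteinRecord
        anc = [ProteinRecord("ANC00001", "ANC", anc[0])]
        with pytest.raises(ConfigError):
            evolve_proteome(anc, LineageParams("A", identity_mean=0,
                                               identity_sd=1, p_loss=0,
                                               p_dup=0), 1)


class TestMutateToIdentity:
    @pytest.mark.parametrize("target", [100.0, 95.0, 80.0, 50.0])
    def test_exact_identity(self, target):
        rng = np.random.default_rng(4)
        seq = random_protein(200, rng)
        mut = mutate_to_identity(seq, target, rng)
        assert abs(_identity_between(seq, mut) - target) <= 100.0 / len(seq)


class TestPlantSpecificAndHidden:
    def test_specific_counts_and_ledger(self, small_sim):
        truth = small_sim.truth.frame
        spec_a = truth[(truth.species == SPECIES_A)
                       & (truth.category == "specific")]
        assert len(spec_a) == small_sim.config.n_specific_A
        assert (spec_a["ancestral_id"] == "").all()

    def test_hidden_interval_identity(self, small_sim):
        """Re-translating each planted hidden interval recovers a >=90%
        identical copy of its source protein."""
        intervals = small_sim.gene_intervals
        hidden = intervals[intervals.hidden]
        assert len(hidden) == (small_sim.config.n_hidden_A
                               + small_sim.config.n_hidden_B)
        proteins = {r.gene_id: r.seq
                    for sp in (SPECIES_A, SPECIES_B)
                    for r in small_sim.proteomes[sp]}
        for row in hidden.itertuples(index=False):
            _, genome = small_sim.genomes[row.genome_species]
            cds = genome[row.start - 1:row.end]
            if row.strand == "-":
                cds = _revcomp(cds)
            peptide = _translate(cds).rstrip("*")
            source = proteins[row.gene_id]
            assert len(peptide) == len(source)
            assert _identity_between(peptide, source) >= 90.0

    def test_no_planting_leaves_only_lineage_rows(self):
        cfg = SimulationConfig(n_ancestral=30, mean_len=100, sd_len=30,
                               n_specific_A=0, n_specific_B=0,
                               n_hidden_A=0, n_hidden_B=0, seed=2)
        res = simulate(cfg)
        cats = set(res.truth.frame["category"])
        assert cats <= {"shared_ortholog", "inparalog", "lost_in_other"}


class TestEmitGenomes:
    def test_genome_length_arithmetic(self):
        rng = np.random.default_rng(0)
        from duoproteome import ProteinRecord
        prot = ProteinRecord("A_x", "A", random_protein(100, rng))
        cfg = SimulationConfig(intergenic_len=50)
        genomes, intervals = emit_genomes(
            {SPECIES_A: [prot], SPECIES_B: []}, {}, cfg, rng)
        _, seq = genomes[SPECIES_A]
        assert len(seq) == 3 * 100 + 3 + 2 * 50
        row = intervals.iloc[0]
        assert (row.start, row.end) == (51, 51 + 302)

    def test_every_cds_translates_back(self, small_sim):
        proteins = {r.gene_id: r.seq
                    for sp in (SPECIES_A, SPECIES_B)
                    for r in small_sim.proteomes[sp]}
        annotated = small_sim.gene_intervals[~small_sim.gene_intervals.hidden]
        assert len(annotated) > 0
        for row in annotated.itertuples(index=False):
            _, genome = small_sim.genomes[row.genome_species]
            cds = genome[row.start - 1:row.end]
            if row.strand == "-":
                cds = _revcomp(cds)
            assert _translate(cds).rstrip("*") == proteins[row.gene_id]

    def test_strand_assignment_balanced(self):
        rng = np.random.default_rng(9)
        from duoproteome import ProteinRecord
        prots = [ProteinRecord(f"A_{i}", "A", random_protein(60, rng))
                 for i in range(200)]
        cfg = SimulationConfig(intergenic_len=20)
        _, intervals = emit_genomes({SPECIES_A: prots, SPECIES_B: []},
                                    {}, cfg, rng)
        n_plus = int((intervals["strand"] == "+").sum())
        # 3.5 sigma binomial band around 100/200
        assert abs(n_plus - 100) < 3.5 * math.sqrt(200 * 0.25)


def _category_frame(n_conserved, n_specific):
    rows = [(f"C{i:05d}", "A", "shared_ortholog", f"ANC{i:05d}", f"TOG{i}")
            for i in range(n_conserved)]
    rows += [(f"S{i:05d}", "A", "specific", "", f"TOGS{i}")
             for i in range(n_specific)]
    return TruthLedger(pd.DataFrame(rows, columns=list(TruthLedger.COLUMNS)))


class TestAedAndGo:
    def test_aed_group_means_hit_targets(self):
        truth = _category_frame(2000, 2000)
        cfg = SimulationConfig()
        aed, _ = assign_aed_and_go(truth, cfg, np.random.default_rng(5))
        merged = aed.merge(truth.frame[["gene_id", "category"]], on="gene_id")
        cons = merged[merged.category == "shared_ortholog"]["aed"]
        spec = merged[merged.category == "specific"]["aed"]
        assert abs(cons.mean() - 0.35) < 0.03
        assert abs(spec.mean() - 0.73) < 0.03

    def test_null_enrichment_balanced(self):
        truth = _category_frame(900, 100)
        cfg = SimulationConfig(enrichment_odds=1.0, base_term_prob=0.2)
        _, go = assign_aed_and_go(truth, cfg, np.random.default_rng(6))
        carriers = set(go[go.go_term == cfg.enriched_term]["gene_id"])
        spec = {g for g in truth.frame.gene_id if g.startswith("S")}
        f_in = len(carriers & spec) / 100
        f_out = len(carriers - spec) / 900
        # both binomial around 0.2; 4-sigma band on the difference
        se = math.sqrt(0.2 * 0.8 * (1 / 100 + 1 / 900))
        assert abs(f_in - f_out) < 4 * se

    def test_planted_odds_ratio_recovered(self):
        truth = _category_frame(900, 100)
        cfg = SimulationConfig(enrichment_odds=8.0, base_term_prob=0.2)
        _, go = assign_aed_and_go(truth, cfg, np.random.default_rng(7))
        carriers = set(go[go.go_term == cfg.enriched_term]["gene_id"])
        spec = {g for g in truth.frame.gene_id if g.startswith("S")}
        a = len(carriers & spec)
        c = len(carriers - spec)
        odds = (a / (100 - a)) / (c / (900 - c))
        assert 4.0 < odds < 12.0  # within +-50% of the planted 8


class TestWholeSimulation:
    def test_byte_determinism(self, tmp_path):
        cfg = small_sim_config()
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        simulate(cfg).write(d1)
        simulate(cfg).write(d2)
        for name in ("proteome_A.faa", "proteome_B.faa", "proteome_out.faa",
                     "genome_A.fna", "genome_B.fna", "aed.tsv", "go.tsv",
                     "truth.tsv", "intervals.tsv", "config.yaml"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_ledger_partitions_each_proteome(self, small_sim):
        truth = small_sim.truth
        for sp in (SPECIES_A, SPECIES_B):
            annotated = {r.gene_id for r in small_sim.proteomes[sp]}
            assert truth.genes(sp) == annotated
            per_cat = sum(len(truth.genes(sp, [c]))
                          for c in ("shared_ortholog", "inparalog",
                                    "lost_in_other", "specific",
                                    "hidden_in_other_genome"))
            assert per_cat == len(annotated)

    def test_pair_identity_mean_matches_config(self, small_sim):
        """Identity of ortholog pairs (via their common ancestor-mutated
        sites) is centred on the configured pair target."""
        ev = small_sim.events
        merged = ev[ev.event == "descend"].merge(
            ev[ev.event == "descend"], on="ancestral_id")
        pairs = merged[(merged.species_x == SPECIES_A)
                       & (merged.species_y == SPECIES_B)]
        # product approximation: identity(A,B) ~ iA * iB / 100
        approx = (pairs.realized_identity_x * pairs.realized_identity_y / 100)
        assert abs(approx.mean() - small_sim.config.identity_mean) < 2.0

    def test_lineage_derivation_formulas(self):
        cfg = SimulationConfig(identity_mean=80, identity_sd=8)
        p = lineage_params_for(cfg, SPECIES_A)
        assert p.identity_mean == pytest.approx(100 * math.sqrt(0.8))
        assert p.identity_sd == pytest.approx(
            p.identity_mean * 0.1 / math.sqrt(2))
        out = lineage_params_for(cfg, "OUT")
        assert out.identity_mean * p.identity_mean / 100 == pytest.approx(60.0)
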