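"""Simulator: determinism, layout, ground-truth consistency, composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srtail import classify as cl
from srtail import simulate as sim
from srtail.seq import revcomp, to_dna


def se3(p, n):
    """Three binomial standard errors."""
    return 3 * np.sqrt(p * (1 - p) / n)


class TestToyGenome:
    def test_fixed_seed_runs_are_byte_identical(self, tmp_path):
        out = []
        for _ in range(2):
            genome, db = sim.build_toy_genome(sim.SimGenomeSpec(seed=42))
            gff = tmp_path / "a.gff3"
            db.to_gff3(gff)
            out.append((genome, gff.read_text()))
        assert out[0] == out[1]

    def test_centromeric_copies_are_identical(self, toy):
        genome, db = toy
        copies = [genome[f.chrom][f.start : f.end] for f in db.by_type("centromeric_repeat")]
        assert len(copies) == 4
        assert len(set(copies)) == 1

    def test_infeasible_layout_raises(self):
        spec = sim.SimGenomeSpec(
            chromosome_lengths=(10_000,), n_centromeric_copies=4,
            centromeric_copy_length=3_000,
        )
        with pytest.raises(sim.LayoutError):
            sim.build_toy_genome(spec)

    def test_short_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            sim.SimGenomeSpec(chromosome_lengths=(5_000, 50_000))

    def test_annotation_round_trips_through_gff3(self, toy, tmp_path):
        _, db = toy
        path = tmp_path / "ann.gff3"
        db.to_gff3(path)
        db2 = cl.load_annotation(path)
        key = lambda d: sorted(
            (f.feature_id, f.chrom, f.start, f.end, f.strand, f.ftype)
            for f in d.features
        )
        assert key(db) == key(db2)

    def test_features_fit_and_do_not_overlap(self, toy):
        genome, db = toy
        by_chrom = {}
        for f in db.features:
            if f.ftype in ("exon", "intron"):
                continue
            assert 0 <= f.start < f.end <= len(genome[f.chrom])
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestReadModelPresets:
    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError):
            sim.preset_model("cid99")

    def test_wt_ago_is_adenine_dominant(self):
        m = sim.preset_model("wt", "ago_bound")
        assert m.tail_identity_dist["A"] > m.tail_identity_dist["U"]
        assert m.tail_identity_dist["A"] > 0.7

    def test_cid16_loses_uridylation(self):
        m = sim.preset_model("cid16", "ago_bound")
        assert m.tail_identity_dist["U"] == 0.0
        assert m.tail_identity_dist["A"] > 0.9

    def test_double_mutant_tail_probability_near_zero(self):
        m = sim.preset_model("cid14cid16", "ago_bound")
        assert all(p < 0.01 for p in m.tail_prob_by_class.values())

    def test_total_fraction_reduces_noncentromeric_tailing(self):
        ago = sim.preset_model("wt", "ago_bound")
        tot = sim.preset_model("wt", "total")
        assert tot.tail_prob_by_class["mRNA_sense"] < ago.tail_prob_by_class["mRNA_sense"]
        assert tot.tail_prob_by_class["centromeric"] == ago.tail_prob_by_class["centromeric"]
        assert tot.class_mixture["centromeric"] == pytest.approx(0.25)

    def test_preset_suffix_forms_accepted(self):
        assert sim.preset_model("wt_ago").fraction == "ago_bound"
        assert sim.preset_model("wt_total").fraction == "total"

    def test_invalid_models_rejected(self):
        base = sim.preset_model("wt")
        bad_mix = {**base.class_mixture, "centromeric": 0.9}
        with pytest.raises(ValueError):
            sim.ReadModel(**{**base.__dict__, "class_mixture": bad_mix}).validate()
        with pytest.raises(ValueError):
            sim.ReadModel(**{**base.__dict__, "modal_length": 25}).validate()


class TestSimulateSample:
    def test_fixed_seed_is_deterministic(self, toy):
        genome, db = toy
        model = sim.preset_model("wt", n_reads=500, seed=3)
        r1, t1 = sim.simulate_sample(genome, db, model)
        r2, t2 = sim.simulate_sample(genome, db, model)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_read_count_lengths_and_truth_rows(self, wt_sample):
        reads, truth = wt_sample
        assert len(reads) == len(truth) == 8_000
        assert all(20 <= len(s) <= 30 for _, s in reads)
        assert (truth["true_length"] == [len(s) for _, s in reads]).all()

    def test_class_mixture_recovered_within_3se(self, wt_sample):
        _, truth = wt_sample
        emp = truth["true_class"].value_counts(normalize=True)
        model = sim.preset_model("wt", "ago_bound")
        for c, p in model.class_mixture.items():
            assert abs(emp.get(c, 0.0) - p) < se3(p, len(truth)), c

    def test_all_5prime_u_when_forced(self, toy):
        genome, db = toy
        base = sim.preset_model("wt", n_reads=300, seed=9)
        model = sim.ReadModel(**{**base.__dict__, "p_5prime_U": 1.0})
        reads, truth = sim.simulate_sample(genome, db, model)
        untailed = set(truth.loc[truth["true_tail"] == "", "read_id"])
        assert all(s[0] == "T" for rid, s in reads if rid in untailed)

    def test_errorfree_untailed_reads_are_exact_substrings(self, toy):
        genome, db = toy
        base = sim.preset_model("wt", n_reads=200, seed=13)
        model = sim.ReadModel(
            **{
                **base.__dict__,
                "seq_error_rate": 0.0,
                "tail_prob_by_class": {c: 0.0 for c in base.tail_prob_by_class},
            }
        )
        reads, _ = sim.simulate_sample(genome, db, model)
        haystacks = [s for s in genome.values()] + [revcomp(s) for s in genome.values()]
        for _, s in reads:
            assert any(s in h for h in haystacks)

    def test_truth_locates_every_errorfree_read(self, toy, errorfree_sample):
        genome, _ = toy
        reads, truth = errorfree_sample
        seqs = dict(reads)
        for row in truth.itertuples():
            read = seqs[row.read_id]
            tail = to_dna(row.true_tail)
            glen = row.true_length - len(tail)
            core = genome[row.chrom][row.start0 : row.start0 + glen]
            if row.strand == "-":
                core = revcomp(core)
            assert read == core + tail

    def test_tail_bases_differ_from_template(self, toy, errorfree_sample):
        genome, _ = toy
        _, truth = errorfree_sample
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for row in truth[truth["true_tail"] != ""].itertuples():
            tail = to_dna(row.true_tail)
            glen = row.true_length - len(tail)
            for j, b in enumerate(tail):
                if row.strand == "+":
                    templ = genome[row.chrom][row.start0 + glen + j]
                else:
                    templ = comp[genome[row.chrom][row.start0 - 1 - j]]
                assert b != templ

    def test_weighted_class_without_features_raises(self, toy):
        genome, db = toy
        base = sim.preset_model("wt")
        model = sim.ReadModel(
            **{
                **base.__dict__,
                "n_reads": 10,
                "class_mixture": {"intronic": 1.0},
            }
        )
        genome2, db2 = sim.build_toy_genome(sim.SimGenomeSpec(seed=1, n_mrna=0))
        with pytest.raises(ValueError, match="intronic"):
            sim.simulate_sample(genome2, db2, model)


class TestCompositionRecovery:
    """Chi-square goodness of fit of the emitted distributions (alpha=0.001)."""

    @pytest.fixture(scope="class")
    def big_truth(self, toy):
        genome, db = toy
        model = sim.preset_model("wt", "ago_bound", n_reads=100_000, seed=41)
        _, truth = sim.simulate_sample(genome, db, model)
        return truth, sim.preset_model("wt", "ago_bound")

    def test_class_mixture_not_rejected(self, big_truth):
        truth, model = big_truth
        obs = truth["true_class"].value_counts()
        classes = sorted(model.class_mixture)
        f_obs = [obs.get(c, 0) for c in classes]
        f_exp = [model.class_mixture[c] * len(truth) for c in classes]
        assert sps.chisquare(f_obs, f_exp).pvalue > 0.001

    def test_length_distribution_not_rejected(self, big_truth):
        truth, model = big_truth
        obs = truth["true_length"].value_counts()
        lengths = sorted(model.length_dist)
        f_obs = [obs.get(n, 0) for n in lengths]
        f_exp = [model.length_dist[n] * len(truth) for n in lengths]
        assert sps.chisquare(f_obs, f_exp).pvalue > 0.001

    def test_tail_length_and_identity_not_rejected(self, big_truth):
        truth, model = big_truth
        tails = truth.loc[truth["true_tail"] != "", "true_tail"]
        obs_len = tails.str.len().value_counts()
        f_obs = [obs_len.get(t, 0) for t in sorted(model.tail_length_dist)]
        f_exp = [model.tail_length_dist[t] * len(tails) for t in sorted(model.tail_length_dist)]
        assert sps.chisquare(f_obs, f_exp).pvalue > 0.001

        nt = "".join(tails)
        obs_id = pd.Series(list(nt)).value_counts()
        bases = [b for b, p in model.tail_identity_dist.items() if p > 0]
        f_obs = [obs_id.get(b, 0) for b in bases]
        f_exp = [model.tail_identity_dist[b] * len(nt) for b in bases]
        assert sps.chisquare(f_obs, f_exp).pvalue > 0.001


class TestExpressionSimulator:
    def test_shape_and_determinism(self):
        a1, b1 = sim.simulate_expression_counts(n_genes=50, n_reps=3, seed=5)
        a2, b2 = sim.simulate_expression_counts(n_genes=50, n_reps=3, seed=5)
        assert a1.shape == b1.shape == (50, 3)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_mean_and_overdispersion(self):
        a, _ = sim.simulate_expression_counts(
            n_genes=2_000, mean=200, dispersion=0.1, n_reps=3, seed=8
        )
        vals = a.to_numpy().ravel()
        assert vals.mean() == pytest.approx(200, rel=0.05)
        # var = mu + 0.1 mu^2 = 4200 >> Poisson
        assert vals.var() == pytest.approx(4_200, rel=0.15)
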