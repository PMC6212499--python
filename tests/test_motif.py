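import numpy as np
import pytest
from scipy import stats

import arginylome as ag
from arginylome.motif import raw_motif_score
from arginylome.peptides import AMINO_ACIDS, PeptideError


def pset(*seqs, label=ag.Label.POSITIVE):
    return ag.PeptideSet([ag.Peptide(s, label) for s in seqs], allow_duplicates=True)


UNIFORM = np.full(20, 1 / 20)


class TestFitMotif:
    def test_single_positive_uniform_background_no_pseudocount(self):
        model = ag.fit_motif(pset("DIAALVHSSGMC"), UNIFORM, pseudocount=0.0)
        i = AMINO_ACIDS.index("I")
        assert model.log_odds[0, i] == pytest.approx(np.log(20))
        assert raw_motif_score(model, "DIAALVHSSGMC") == pytest.approx(11 * np.log(20))

    def test_counts_proportional_to_background_give_zero_log_odds(self):
        # every residue equally often at every offset, uniform background
        seqs = ["D" + aa * 11 for aa in AMINO_ACIDS]
        model = ag.fit_motif(pset(*seqs), UNIFORM, pseudocount=0.0)
        assert np.allclose(model.log_odds, 0.0, atol=1e-12)
        assert raw_motif_score(model, "DAAAAAAAAAAA") == pytest.approx(0.0)

    def test_huge_pseudocount_shrinks_log_odds_to_zero(self):
        model = ag.fit_motif(pset("DIAALVHSSGMC"), UNIFORM, pseudocount=1e9)
        assert np.allclose(model.log_odds, 0.0, atol=1e-6)

    def test_empty_positive_set_rejected(self):
        with pytest.raises(PeptideError):
            ag.fit_motif(ag.PeptideSet([]), UNIFORM)


class TestScoreMotif:
    def test_consensus_sequence_achieves_maximum_score(self, default_dataset):
        peptides, _ = default_dataset
        positives = peptides.filter(label=ag.Label.POSITIVE)
        model = ag.fit_motif(positives, UNIFORM)
        best = ag.score_motif(model, model.consensus())
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "D" + "".join(rng.choice(list(AMINO_ACIDS), 11))
            assert ag.score_motif(model, seq) <= best + 1e-12

    def test_position_one_does_not_affect_score(self):
        model = ag.fit_motif(pset("DIAALVHSSGMC", "EIAALVHSSGMC"), UNIFORM)
        assert ag.score_motif(model, "DIAALVHSSGMC") == pytest.approx(
            ag.score_motif(model, "EIAALVHSSGMC")
        )

    def test_zero_log_odds_with_unit_calibration_scores_half(self):
        model = ag.MotifModel(np.zeros((11, 20)), UNIFORM, 1.0, (0.0, 1.0))
        assert ag.score_motif(model, "DIAALVHSSGMC") == pytest.approx(0.5)

    def test_score_strictly_increasing_in_scored_residue_log_odds(self):
        lo = np.zeros((11, 20))
        model_flat = ag.MotifModel(lo, UNIFORM, 1.0, (0.0, 1.0))
        lo2 = lo.copy()
        lo2[0, AMINO_ACIDS.index("H")] = 1.0
        model_up = ag.MotifModel(lo2, UNIFORM, 1.0, (0.0, 1.0))
        assert ag.score_motif(model_up, "DHAAAAAAAAAA") > ag.score_motif(
            model_flat, "DHAAAAAAAAAA"
        )

    def test_scores_live_in_open_unit_interval(self, default_dataset):
        peptides, _ = default_dataset
        model = ag.fit_motif(peptides.filter(label=ag.Label.POSITIVE), UNIFORM)
        scores = ag.score_motif_many(model, list(peptides)[:100])
        assert np.all((scores > 0) & (scores < 1))


class TestTwoSampleLogo:
    def test_fisher_tail_matches_hypergeometric_enumeration(self):
        positives = pset(*["DH" + "A" * 10] * 10)
        negatives = pset(
            "DH" + "A" * 10, *["DG" + "A" * 10] * 9, label=ag.Label.UNLABELED
        )
        table = ag.two_sample_logo(positives, negatives, alpha=0.05)
        row = table[(table.offset == 1) & (table.residue == "H")].iloc[0]
        expected = stats.fisher_exact([[10, 0], [1, 9]], alternative="greater")[1]
        assert row.p == pytest.approx(expected)
        assert row.direction == "enriched"
        assert bool(row.significant)

    def test_identical_sets_flag_nothing(self):
        same = pset("DIAALVHSSGMC", "DHYYAAAMAAAA")
        table = ag.two_sample_logo(same, same, alpha=0.05)
        assert not table.significant.any()
        assert (table.p == 1.0).all()

    def test_alpha_zero_flags_nothing(self):
        positives = pset(*["DH" + "A" * 10] * 10)
        negatives = pset(*["DG" + "A" * 10] * 10, label=ag.Label.UNLABELED)
        table = ag.two_sample_logo(positives, negatives, alpha=0.0)
        assert not table.significant.any()

    def test_planted_cells_flagged_on_synthetic_data(self):
        peptides, _ = ag.generate_dataset(500, 500, seed=11)
        table = ag.two_sample_logo(
            peptides.filter(label=ag.Label.POSITIVE),
            peptides.filter(label=ag.Label.UNLABELED),
            alpha=0.05,
        )
        flagged = set(
            map(tuple, table.loc[table.significant, ["offset", "residue"]].values)
        )
        assert flagged & {(1, "H"), (1, "C")}
        assert flagged & {(2, "H"), (2, "C")}
        assert {(3, "Y"), (4, "Y"), (7, "M")} <= flagged

    def test_empty_set_rejected(self):
        with pytest.raises(PeptideError):
            ag.two_sample_logo(ag.PeptideSet([]), pset("DIAALVHSSGMC"))
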