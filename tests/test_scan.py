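import numpy as np
import pandas as pd
import pytest

import arginylome as ag
from arginylome.peptides import PeptideError


class TestExtractSiteWindows:
    def test_conservative_mode_takes_md_start(self):
        rec = ag.ProteinRecord("p", "MDAAAAAAAAAAAA")
        wins = ag.extract_site_windows(rec, "nterm_conservative")
        assert len(wins) == 1
        assert wins[0].position == 2
        assert wins[0].window == "DAAAAAAAAAAA"

    def test_internal_site_only_in_all_de_mode(self):
        rec = ag.ProteinRecord("p", "MAAADAAAAAAAAA")
        assert ag.extract_site_windows(rec, "nterm_conservative") == []
        wins = ag.extract_site_windows(rec, "all_DE")
        assert len(wins) == 1
        assert wins[0].position == 5

    def test_c_terminal_site_is_pad_extended(self):
        rec = ag.ProteinRecord("p", "AAAAAAAAAAD")
        wins = ag.extract_site_windows(rec, "all_DE")
        assert wins[0].window == "D" + "-" * 11

    def test_conservative_subset_of_all_de(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list(ag.AMINO_ACIDS), 40))
            rec = ag.ProteinRecord("p", seq)
            n_cons = len(ag.extract_site_windows(rec, "nterm_conservative"))
            n_all = len(ag.extract_site_windows(rec, "all_DE"))
            assert n_cons <= n_all

    def test_no_acidic_nterm_gives_empty_conservative_scan(self):
        rec = ag.ProteinRecord("p", "MKLVAAAAAAADAA")
        assert ag.extract_site_windows(rec, "nterm_conservative") == []


@pytest.fixture(scope="module")
def scan_setup():
    peptides, _ = ag.generate_dataset(300, 600, seed=7)
    data = ag.to_training_set(peptides)
    model = ag.train_ensemble(data, n_members=30, seed=7)
    pos_scores = ag.predict_scores(model, data.X[data.y == 1])
    return model, pos_scores


class TestScanProteome:
    def test_fraction_recovers_planted_rate(self, scan_setup):
        model, pos_scores = scan_setup
        proteome, truth = ag.generate_proteome(2000, signal_fraction=0.03, seed=3)
        from arginylome.features import extract_features
        from arginylome.scan import extract_site_windows

        windows = [w for rec in proteome for w in extract_site_windows(rec, "nterm_conservative")]
        X = np.vstack([extract_features(ag.Peptide(w.window)).values for w in windows])
        prior = ag.estimate_alpha(pos_scores, ag.predict_scores(model, X))
        res = ag.scan_proteome(proteome, model, prior, "nterm_conservative")
        assert 0.02 <= res.fraction <= 0.04
        assert res.n_sites == len(proteome)

    def test_alpha_zero_prior_gives_zero_fraction(self, scan_setup):
        model, pos_scores = scan_setup
        proteome, _ = ag.generate_proteome(100, signal_fraction=0.05, seed=1)
        prior = ag.estimate_alpha(pos_scores, np.linspace(0.01, 0.99, 200))
        prior.alpha = 0.0
        res = ag.scan_proteome(proteome, model, prior, "nterm_conservative")
        assert res.fraction == 0.0

    def test_fraction_invariant_to_protein_order(self, scan_setup):
        model, pos_scores = scan_setup
        proteome, _ = ag.generate_proteome(150, signal_fraction=0.1, seed=2)
        prior = ag.estimate_alpha(pos_scores, np.linspace(0.01, 0.99, 200))
        a = ag.scan_proteome(proteome, model, prior, "nterm_conservative")
        b = ag.scan_proteome(proteome[::-1], model, prior, "nterm_conservative")
        assert a.fraction == pytest.approx(b.fraction)

    def test_zero_windows_rejected(self, scan_setup):
        model, pos_scores = scan_setup
        prior = ag.estimate_alpha(pos_scores, np.linspace(0.01, 0.99, 200))
        no_sites = [ag.ProteinRecord("p", "MKLVAAAA")]
        with pytest.raises(PeptideError):
            ag.scan_proteome(no_sites, model, prior, "nterm_conservative")


class TestConservationFilter:
    def _table(self):
        return pd.DataFrame(
            {
                "id": ["g1", "g2", "g3", "g4", "g5"],
                "branch_length": [0.5, 0.5, 0.3, 0.5, 0.5],
                "phylocsf": [10.0, 5.0, 8.0, -2.0, 3.0],
                "residue_conserved": [True, True, True, True, False],
                "consensus_score": [0.9, 0.8, 0.9, 0.9, 0.9],
            }
        )

    def test_exactly_matching_rows_kept(self):
        kept = ag.conservation_filter(self._table(), branch_min=0.4, score_min=0.0)
        assert sorted(kept["id"]) == ["g1", "g2"]

    def test_score_threshold_above_range_empties_table(self):
        kept = ag.conservation_filter(self._table(), score_min=1.01)
        assert kept.empty

    def test_duplicate_gene_keeps_highest_consensus(self):
        df = pd.DataFrame(
            {
                "id": ["g1", "g1"],
                "branch_length": [0.5, 0.5],
                "phylocsf": [1.0, 1.0],
                "residue_conserved": [True, True],
                "consensus_score": [0.8, 0.9],
            }
        )
        kept = ag.conservation_filter(df)
        assert len(kept) == 1
        assert kept["consensus_score"].iloc[0] == 0.9

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="phylocsf"):
            ag.conservation_filter(self._table().drop(columns=["phylocsf"]))
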