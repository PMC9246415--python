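"""Synthetic ligandome generator: hierarchy, motifs, decoys, labels."""

import numpy as np
import pandas as pd
import pytest

from epiconv.simdata import (
    CORE_LEN,
    ImmunogenicityRule,
    SyntheticCorpus,
    build_corpus,
    label_immunogenicity,
    motif_score,
    random_proteome,
    sample_decoys,
    sample_ligands,
    simulate_hierarchy,
    threshold_for_ratio,
)


class TestHierarchy:
    def test_delta_zero_siblings_share_anchor_columns(self):
        m = simulate_hierarchy(2, 3, delta=0.0, seed=4)
        a, b = m["DRB1*01:01"], m["DRB1*01:03"]
        for pos in a.anchors:
            np.testing.assert_array_equal(a.pwm[pos], b.pwm[pos])

    def test_delta_one_sibling_anchors_independent(self):
        # across many seeds the preferred anchor residues of siblings agree
        # no more often than chance (1/20 per column)
        agree, total = 0, 0
        for seed in range(120):
            m = simulate_hierarchy(1, 2, delta=1.0, seed=seed, genes=("DRB1",))
            a, b = m["DRB1*01:01"], m["DRB1*01:02"]
            for pos in a.anchors:
                agree += a.pwm[pos].argmax() == b.pwm[pos].argmax()
                total += 1
        rate = agree / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate < 0.05 + 4 * se

    def test_partial_delta_shares_more_than_independent(self):
        shared_small, shared_big = 0, 0
        for seed in range(40):
            for delta, bucket in ((0.15, "small"), (1.0, "big")):
                m = simulate_hierarchy(1, 2, delta=delta, seed=seed,
                                       genes=("DRB1",))
                a, b = m["DRB1*01:01"], m["DRB1*01:02"]
                n = sum(np.allclose(a.pwm[p], b.pwm[p]) for p in a.anchors)
                if bucket == "small":
                    shared_small += n
                else:
                    shared_big += n
        assert shared_small > shared_big

    def test_deterministic_given_seed(self):
        m1 = simulate_hierarchy(2, 2, 0.3, seed=9)
        m2 = simulate_hierarchy(2, 2, 0.3, seed=9)
        for k in m1:
            np.testing.assert_array_equal(m1[k].pwm, m2[k].pwm)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            simulate_hierarchy(1, 1, delta=1.5)

    def test_rows_are_probability_distributions(self):
        m = simulate_hierarchy(2, 2, 0.5, seed=0)
        for model in m.values():
            np.testing.assert_allclose(model.pwm.sum(axis=1), 1.0)


class TestLigands:
    def test_core_frequencies_match_motif_within_3_se(self):
        m = simulate_hierarchy(1, 1, 0.0, seed=2, genes=("DRB1",))
        motif = m["DRB1*01:01"]
        n = 1500
        peps, offs = sample_ligands(
            motif, n, length_range=(9, 9), seed=3, return_offsets=True
        )
        # length 9 forces offset 0, so core positions are known
        counts = np.zeros((CORE_LEN, 20))
        aa_index = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        for p in peps:
            for pos, ch in enumerate(p):
                counts[pos, aa_index[ch]] += 1
        freqs = counts / n
        for pos in range(CORE_LEN):
            se = np.sqrt(motif.pwm[pos] * (1 - motif.pwm[pos]) / n)
            assert np.all(np.abs(freqs[pos] - motif.pwm[pos]) <= 3 * se + 1e-9)

    def test_lengths_span_only_requested_range(self):
        m = simulate_hierarchy(1, 1, 0.0, seed=2, genes=("DRB1",))
        peps = sample_ligands(m["DRB1*01:01"], 300, seed=1)
        lengths = {len(p) for p in peps}
        assert lengths <= set(range(9, 26))

    def test_zero_count_rejected(self):
        m = simulate_hierarchy(1, 1, 0.0, seed=2, genes=("DRB1",))
        with pytest.raises(ValueError):
            sample_ligands(m["DRB1*01:01"], 0)

    def test_seeded_reproducibility(self):
        m = simulate_hierarchy(1, 1, 0.0, seed=2, genes=("DRB1",))
        a = sample_ligands(m["DRB1*01:01"], 20, seed=5)
        b = sample_ligands(m["DRB1*01:01"], 20, seed=5)
        assert a == b


class TestDecoys:
    @pytest.fixture()
    def setup(self):
        m = simulate_hierarchy(1, 1, 0.0, seed=6, genes=("DRB1",))
        motif = m["DRB1*01:01"]
        proteome = random_proteome(20, 300, seed=6)
        return motif, proteome

    def test_decoys_score_below_ligands(self, setup):
        motif, proteome = setup
        lig = sample_ligands(motif, 150, seed=7)
        dec = sample_decoys(proteome, motif, 150, seed=7)
        lig_mean = np.mean([motif_score(p, motif) for p in lig])
        dec_mean = np.mean([motif_score(p, motif) for p in dec])
        assert dec_mean < lig_mean

    def test_rejection_truncates_overlap_of_weak_motifs(self):
        # a weakly concentrated motif makes protein windows and ligands
        # overlap in score, so the rejection threshold is actually binding
        m = simulate_hierarchy(1, 1, 0.0, seed=6, genes=("DRB1",),
                               anchor_concentration=0.25)
        motif = m["DRB1*01:01"]
        proteome = random_proteome(20, 300, seed=6)
        lig_scores = [motif_score(p, motif)
                      for p in sample_ligands(motif, 300, seed=8)]
        cut = np.percentile(lig_scores, 10)
        raw = sample_decoys(proteome, motif, 300, seed=8, reject=False)
        raw_scores = [motif_score(p, motif) for p in raw]
        assert max(raw_scores) > cut  # unrejected windows straddle the range
        kept = sample_decoys(proteome, motif, 100, seed=8, reject=True,
                             reference_ligands=300)
        kept_scores = [motif_score(p, motif) for p in kept]
        assert max(kept_scores) <= cut + 2.0  # threshold from its own draw

    def test_reproducible(self, setup):
        motif, proteome = setup
        assert sample_decoys(proteome, motif, 25, seed=3) == \
            sample_decoys(proteome, motif, 25, seed=3)


class TestImmunogenicityRule:
    def test_noiseless_extreme_scores_deterministic(self):
        rule = ImmunogenicityRule(threshold=0.0, eta=0.0)
        high = "A" * 2 + "W" + "A" * 1 + "K" + "AA" + "R" + "A"  # contacts W,K,R
        low = "A" * 2 + "D" + "A" * 1 + "E" + "AA" + "D" + "A"
        assert label_immunogenicity(high, rule, core_offset=0) == 1
        assert label_immunogenicity(low, rule, core_offset=0) == 0

    def test_non_contact_flip_never_changes_noiseless_label(self):
        rule = ImmunogenicityRule(threshold=0.0, eta=0.0)
        base = "AAWAKAARA"
        lab = label_immunogenicity(base, rule, core_offset=0)
        for pos in (0, 1, 3, 5, 6, 8):
            for sub in "GLY":
                mut = base[:pos] + sub + base[pos + 1:]
                assert label_immunogenicity(mut, rule, core_offset=0) == lab

    def test_threshold_tunes_prevalence_to_162(self):
        rng = np.random.default_rng(0)
        rule = ImmunogenicityRule(eta=0.0)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peps = ["".join(rng.choice(aas, 9)) for _ in range(4000)]
        scores = np.array([rule.raw_score(p, 0) for p in peps])
        rule.threshold = threshold_for_ratio(scores, 1.62)
        labels = [label_immunogenicity(p, rule, 0) for p in peps]
        ratio = sum(labels) / (len(labels) - sum(labels))
        assert ratio == pytest.approx(1.62, rel=0.08)


class TestCorpus:
    def test_manifest_regenerates_bitwise(self):
        c1 = build_corpus(seed=11, ligands_per_subtype=20,
                          decoys_per_subtype=20, n_proteins=10,
                          protein_length=200)
        c2 = SyntheticCorpus.from_manifest(c1.manifest)
        pd.testing.assert_frame_equal(c1.presentation, c2.presentation)
        pd.testing.assert_frame_equal(c1.immunogenicity, c2.immunogenicity)
        assert c1.proteins == c2.proteins

    def test_sibling_motif_scores_heldout_ligands_better_than_unrelated(self):
        # the structural premise of hierarchical encoding, in expectation
        # over seeds: a sibling's motif transfers, an unrelated one doesn't
        sib_margin = []
        for seed in range(8):
            m = simulate_hierarchy(1, 2, delta=0.15, seed=seed,
                                   genes=("DRB1", "DPB1"))
            held = m["DRB1*01:02"]
            lig = sample_ligands(held, 40, seed=seed + 100)
            sib = np.mean([motif_score(p, m["DRB1*01:01"]) for p in lig])
            unrel = np.mean([motif_score(p, m["DPB1*01:01"]) for p in lig])
            sib_margin.append(sib - unrel)
        assert np.mean(sib_margin) > 0

    def test_cross_negatives_come_from_other_gene_ligands(self):
        c = build_corpus(seed=13, ligands_per_subtype=30, decoys_per_subtype=30,
                         frac_cross_negatives=0.5, n_proteins=10,
                         protein_length=200)
        df = c.presentation
        lig_by_gene = {
            g: set(df[(df["label"] == 1)
                      & (df["allele"].str.startswith(g))]["peptide"])
            for g in ("DRB1", "DPB1")
        }
        negs_drb1 = set(df[(df["label"] == 0)
                           & (df["allele"].str.startswith("DRB1"))]["peptide"])
        assert negs_drb1 & lig_by_gene["DPB1"]

    def test_bayes_optimal_motif_beats_permuted_labels(self):
        c = build_corpus(seed=17, ligands_per_subtype=40, decoys_per_subtype=40,
                         genes=("DRB1",), n_f1_per_gene=1, n_f2_per_f1=1,
                         n_proteins=10, protein_length=200)
        from sklearn.metrics import roc_auc_score

        df = c.presentation
        motif = c.motifs["DRB1*01:01"]
        scores = [motif_score(p, motif) for p in df["peptide"]]
        auc = roc_auc_score(df["label"], scores)
        rng = np.random.default_rng(0)
        perm_aucs = [
            roc_auc_score(rng.permutation(df["label"].to_numpy()), scores)
            for _ in range(20)
        ]
        assert auc > max(perm_aucs)
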