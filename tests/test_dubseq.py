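"""Fragment scoring, NNLS gene deconvolution, hit gates and shuffle FDR."""

import numpy as np
import pandas as pd
import pytest

from phagescreen import dubseq, synthetic as syn


def make_fmap(frags):
    """frags: dict up_barcode -> tuple of covered genes."""
    return pd.DataFrame(
        {
            "up_barcode": list(frags),
            "dn_barcode": [f"D{i}" for i in range(len(frags))],
            "scaffold": "chr",
            "start": 1,
            "end": 100,
            "covered_genes": [tuple(v) for v in frags.values()],
        }
    )


def make_scores(scores, reads=100):
    return pd.DataFrame(
        {
            "score": pd.Series(scores, dtype=float),
            "reads_treatment": reads,
            "reads_t0_total": reads,
        }
    ).rename_axis("barcode")


class TestValidBarcodes:
    def test_below_ten_in_every_t0_is_invalid(self, count_table_factory):
        ct = count_table_factory(
            {"t0a": {"BC1": 9, "BC2": 12}, "t0b": {"BC1": 9, "BC2": 0},
             "t0c": {"BC1": 9, "BC2": 0}, "end": {"BC1": 50, "BC2": 50}},
            {"t0a": "start", "t0b": "start", "t0c": "start", "end": "end"},
        )
        valid = dubseq.select_valid_barcodes(ct, "set1")
        assert list(valid) == ["BC2"]  # (9,9,9) fails, (12,0,0) passes

    def test_single_qualifying_t0_sample_suffices(self, count_table_factory):
        ct = count_table_factory(
            {"t0a": {"BC1": 0}, "t0b": {"BC1": 10}, "end": {"BC1": 1}},
            {"t0a": "start", "t0b": "start", "end": "end"},
        )
        assert list(dubseq.select_valid_barcodes(ct, "set1")) == ["BC1"]

    def test_all_abundant_barcodes_valid(self, count_table_factory):
        ct = count_table_factory(
            {"t0": {"BC1": 10, "BC2": 100}, "end": {"BC1": 0, "BC2": 0}},
            {"t0": "start", "end": "end"},
        )
        assert set(dubseq.select_valid_barcodes(ct, "set1")) == {"BC1", "BC2"}

    def test_no_t0_samples_raises(self, count_table_factory):
        ct = count_table_factory({"t0": {"BC1": 10}}, {"t0": "start"})
        with pytest.raises(ValueError, match="set9"):
            dubseq.select_valid_barcodes(ct, "set9")


class TestFragmentScores:
    def test_treatment_equal_to_t0_profile_scores_zero(self, count_table_factory):
        profile = {f"BC{i}": 50 + i for i in range(20)}
        ct = count_table_factory(
            {"t0": profile, "end": profile}, {"t0": "start", "end": "end"}
        )
        fs = dubseq.fragment_scores(ct, "end", pseudocount=0.0)
        assert np.allclose(fs["score"], 0.0)

    def test_1024_fold_enrichment_scores_ten(self, count_table_factory):
        t0 = {f"BC{i}": 100 for i in range(101)}
        end = dict(t0)
        end["BC0"] = 102_400
        ct = count_table_factory({"t0": t0, "end": end}, {"t0": "start", "end": "end"})
        fs = dubseq.fragment_scores(ct, "end", pseudocount=0.0)
        # the enriched fragment is 1024x the others; the median fragment is unchanged
        assert fs.loc["BC0", "score"] == pytest.approx(10.0)
        assert fs["score"].median() == pytest.approx(0.0)

    def test_depth_scaling_makes_scores_invariant(self, count_table_factory):
        rng = np.random.default_rng(1)
        t0 = {f"BC{i}": int(c) for i, c in enumerate(rng.integers(10, 200, 50))}
        end = {f"BC{i}": int(c) for i, c in enumerate(rng.integers(10, 200, 50))}
        ct1 = count_table_factory({"t0": t0, "end": end}, {"t0": "start", "end": "end"})
        ct2 = count_table_factory(
            {"t0": t0, "end": {k: 2 * v for k, v in end.items()}},
            {"t0": "start", "end": "end"},
        )
        a = dubseq.fragment_scores(ct1, "end", pseudocount=0.0)
        b = dubseq.fragment_scores(ct2, "end", pseudocount=0.0)
        assert np.allclose(a["score"], b["score"])


class TestGeneScoresNnls:
    def test_consistent_system_attributes_shared_fragment_to_causal_gene(self):
        fmap = make_fmap({"F1": ("g1",), "F2": ("g1", "g2"), "F3": ("g2",)})
        fs = make_scores({"F1": 8.0, "F2": 8.0, "F3": 0.0})
        gs = dubseq.gene_scores_nnls(fs, fmap).set_index("gene_id")
        assert gs.loc["g1", "score_nnls"] == pytest.approx(8.0, abs=1e-10)
        assert gs.loc["g2", "score_nnls"] == pytest.approx(0.0, abs=1e-10)

    def test_two_fragments_one_gene_gives_least_squares_mean(self):
        fmap = make_fmap({"F1": ("g1",), "F2": ("g1",)})
        fs = make_scores({"F1": 2.0, "F2": 4.0})
        gs = dubseq.gene_scores_nnls(fs, fmap)
        assert gs["score_nnls"].item() == pytest.approx(3.0)
        assert gs["score_mean"].item() == pytest.approx(3.0)
        assert gs["n_fragments"].item() == 2

    def test_negative_score_clipped_by_nonnegativity(self):
        fmap = make_fmap({"F1": ("g1",)})
        fs = make_scores({"F1": -3.0})
        gs = dubseq.gene_scores_nnls(fs, fmap)
        assert gs["score_nnls"].item() == 0.0
        assert gs["score_mean"].item() == pytest.approx(-3.0)

    def test_uncovered_genes_absent_from_output(self):
        fmap = make_fmap({"F1": ("g1",), "F2": tuple()})
        fs = make_scores({"F1": 1.0, "F2": 5.0})
        gs = dubseq.gene_scores_nnls(fs, fmap)
        assert list(gs["gene_id"]) == ["g1"]

    def test_objective_beats_zero_and_clipped_mean_vectors(self, nnls_oracle):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_frag, n_gene = rng.integers(2, 7), rng.integers(1, 4)
            design = (rng.random((n_frag, n_gene)) < 0.5).astype(float)
            design[design.sum(axis=1) == 0, 0] = 1.0
            target = rng.normal(0, 3, n_frag)
            frags = {f"F{i}": tuple(f"g{j}" for j in range(n_gene) if design[i, j])
                     for i in range(n_frag)}
            gs = dubseq.gene_scores_nnls(make_scores(dict(zip(frags, target))), make_fmap(frags))
            x = gs.set_index("gene_id")["score_nnls"]
            x = x.reindex([f"g{j}" for j in range(n_gene)], fill_value=0.0).to_numpy()
            obj = np.sum((target - design @ x) ** 2)
            assert obj <= np.sum(target**2) + 1e-9
            clipped = np.clip(
                [target[design[:, j] > 0].mean() if design[:, j].any() else 0.0
                 for j in range(n_gene)],
                0, None,
            )
            assert obj <= np.sum((target - design @ clipped) ** 2) + 1e-9

    def test_matches_brute_force_oracle_on_small_instances(self, nnls_oracle):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_frag, n_gene = int(rng.integers(1, 7)), int(rng.integers(1, 4))
            design = (rng.random((n_frag, n_gene)) < 0.6).astype(float)
            design[design.sum(axis=1) == 0, 0] = 1.0
            target = rng.normal(0, 3, n_frag)
            frags = {f"F{i}": tuple(f"g{j}" for j in range(n_gene) if design[i, j])
                     for i in range(n_frag)}
            gs = dubseq.gene_scores_nnls(make_scores(dict(zip(frags, target))), make_fmap(frags))
            x = gs.set_index("gene_id")["score_nnls"]
            x = x.reindex([f"g{j}" for j in range(n_gene)], fill_value=0.0).to_numpy()
            obj = float(np.sum((target - design @ x) ** 2))
            assert obj == pytest.approx(nnls_oracle(design, target), abs=1e-4)

    def test_barcode_relabeling_leaves_gene_scores_unchanged(self):
        fmap = make_fmap({"F1": ("g1",), "F2": ("g1", "g2"), "F3": ("g2",)})
        fs = make_scores({"F1": 5.0, "F2": 3.0, "F3": 1.0})
        relabel = {"F1": "X1", "F2": "X2", "F3": "X3"}
        fmap2 = fmap.assign(up_barcode=fmap["up_barcode"].map(relabel))
        fs2 = fs.rename(index=relabel)
        a = dubseq.gene_scores_nnls(fs, fmap).set_index("gene_id")
        b = dubseq.gene_scores_nnls(fs2, fmap2).set_index("gene_id")
        pd.testing.assert_frame_equal(a, b)

    def test_removing_fragment_only_affects_its_component(self):
        fmap = make_fmap(
            {"F1": ("g1",), "F2": ("g1", "g2"), "F3": ("g2",), "F4": ("g3",), "F5": ("g3",)}
        )
        fs = make_scores({"F1": 5.0, "F2": 3.0, "F3": 1.0, "F4": 2.0, "F5": 4.0})
        full = dubseq.gene_scores_nnls(fs, fmap).set_index("gene_id")
        reduced = dubseq.gene_scores_nnls(fs.drop("F1"), fmap[fmap["up_barcode"] != "F1"])
        reduced = reduced.set_index("gene_id")
        assert reduced.loc["g3", "score_nnls"] == pytest.approx(full.loc["g3", "score_nnls"])


class TestCallGeneHits:
    def make_gene_row(self, **kw):
        row = {"gene_id": "g1", "score_nnls": 5.0, "score_mean": 5.0, "n_fragments": 3,
               "consistency_p": 0.001, "reads_support": 100}
        row.update(kw)
        return pd.DataFrame([row])

    def test_score_boundary_is_inclusive(self):
        assert len(dubseq.call_gene_hits(self.make_gene_row(score_nnls=4.0))) == 1
        assert len(dubseq.call_gene_hits(self.make_gene_row(score_nnls=3.999))) == 0

    def test_single_fragment_gene_needs_doubled_read_support(self):
        row = self.make_gene_row(n_fragments=1, consistency_p=np.nan, reads_support=20)
        assert len(dubseq.call_gene_hits(row, reads_min=10)) == 1
        row = self.make_gene_row(n_fragments=1, consistency_p=np.nan, reads_support=19)
        assert len(dubseq.call_gene_hits(row, reads_min=10)) == 0

    def test_all_zero_scores_give_no_hits(self):
        row = self.make_gene_row(score_nnls=0.0, score_mean=0.0)
        assert len(dubseq.call_gene_hits(row)) == 0

    def test_inconsistent_fragments_rejected(self):
        row = self.make_gene_row(consistency_p=0.5)
        assert len(dubseq.call_gene_hits(row)) == 0


class TestShuffleFdr:
    def test_ratio_definition(self):
        rep = dubseq.ShuffleFdrReport(thresholds={}, observed_hits=4, shuffled_hits=[2, 2])
        assert rep.fdr == pytest.approx(0.5)

    def test_zero_observed_and_zero_shuffled_is_zero(self):
        rep = dubseq.ShuffleFdrReport(thresholds={}, observed_hits=0, shuffled_hits=[0, 0])
        assert rep.fdr == 0.0

    def test_strong_single_gene_selection_gives_low_fdr(self):
        # library with realistic ~20x fragment coverage per gene, so that
        # no gene rests on a single fragment
        genome = syn.GenomeModel.regular(200, 1000, 100)
        fmap = syn.make_fragment_map(genome, 2000, seed=2)
        covered = [g for genes in fmap["covered_genes"] for g in genes]
        causal = pd.Series(covered).mode()[0]
        scen = syn.SelectionScenario(
            "N4", 1.0, resistance_map={causal: "overexpression_suppressor"},
            kill_prob_sensitive=0.999, doublings_resistant=4.0,
            read_depth=200_000, seed=13,
        )
        ct = syn.simulate_selection(fmap, scen, n_start_samples=2)
        fs, _ = dubseq.score_experiment(ct, fmap, ct.end_samples()[0])
        rep = dubseq.shuffle_fdr(fs, fmap, n_shuffles=5, seed=1)
        assert rep.observed_hits >= 1
        assert rep.fdr < 0.3
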