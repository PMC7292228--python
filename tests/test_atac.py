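import numpy as np
import pandas as pd
import pytest

from plscreen import (
    annotate_peaks,
    concordance_cdf,
    consensus_peaks,
    differential_peaks,
    md_differential,
    md_score,
    simulate_atac,
)
from plscreen.atac import merge_intervals


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def coverage_oracle(sets):
    """Quadratic oracle: per-bp intersection of all sets, as intervals."""
    hi = max(int(s["end"].max()) for s in sets)
    chroms = set().union(*(set(s["chrom"]) for s in sets))
    out = []
    for chrom in sorted(chroms):
        covered = np.ones(hi, bool)
        for s in sets:
            mask = np.zeros(hi, bool)
            for _, r in s[s["chrom"] == chrom].iterrows():
                mask[r["start"]:r["end"]] = True
            covered &= mask
        # runs of True -> intervals
        edges = np.flatnonzero(np.diff(np.concatenate([[0], covered, [0]])))
        for s0, e0 in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s0), int(e0)))
    return bed(out)


def md_oracle(peaks, hits, r_small=150, r_large=1500):
    """All-pairs nearest-center distances per motif."""
    pk = peaks.copy()
    centers = {}
    for chrom, sub in pk.groupby("chrom"):
        centers[chrom] = ((sub["start"] + sub["end"]) // 2).to_numpy()
    rows = {}
    for motif, sub in hits.groupby("motif_id"):
        n_s = n_l = 0
        for _, r in sub.iterrows():
            c = (r["start"] + r["end"]) // 2
            pc = centers.get(r["chrom"])
            if pc is None or len(pc) == 0:
                continue
            d = np.abs(pc - c).min()
            n_s += d <= r_small
            n_l += d <= r_large
        rows[motif] = n_s / n_l if n_l else np.nan
    return rows


class TestConsensus:
    def test_identical_sets_are_a_fixed_point(self):
        a = bed([("chr1", 0, 100), ("chr1", 200, 300)])
        out = consensus_peaks([a, a.copy(), a.copy()])
        pd.testing.assert_frame_equal(out, a)

    def test_partial_overlap_keeps_intersection_span(self):
        out = consensus_peaks([bed([("chr1", 0, 100)]), bed([("chr1", 50, 150)])])
        pd.testing.assert_frame_equal(out, bed([("chr1", 50, 100)]))

    def test_disjoint_sets_give_empty_consensus(self):
        out = consensus_peaks([bed([("chr1", 0, 10)]), bed([("chr1", 20, 30)])])
        assert out.empty

    def test_matches_quadratic_coverage_oracle(self, rng):
        sets = []
        for _ in range(4):
            starts = np.sort(rng.choice(5000, 120, replace=False))
            sets.append(merge_intervals(bed(
                [("chr1", int(s), int(s) + int(w) + 1)
                 for s, w in zip(starts, rng.integers(5, 80, 120))])))
        out = consensus_peaks(sets[:2], sets[2:])
        pd.testing.assert_frame_equal(out, coverage_oracle(sets))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([])


class TestDifferentialPeaks:
    def test_identical_conditions_change_nothing(self):
        a = bed([("chr1", 0, 100), ("chr2", 5, 50)])
        gained, lost = differential_peaks(a, a.copy())
        assert gained.empty and lost.empty

    def test_added_peak_is_gained(self):
        control = bed([("chr1", 0, 100)])
        condition = bed([("chr1", 0, 100), ("chr1", 500, 600)])
        gained, lost = differential_peaks(condition, control)
        pd.testing.assert_frame_equal(gained.reset_index(drop=True),
                                      bed([("chr1", 500, 600)]))
        assert lost.empty

    def test_planted_gain_loss_counts_recovered(self):
        sim = simulate_atac(n_peaks=300, n_motifs=2, n_gained=200, n_lost=150,
                            seed=4)
        cond = consensus_peaks(sim["condition"], sim["condition_pseudoreplicates"])
        ctrl = consensus_peaks(sim["control"], sim["control_pseudoreplicates"])
        gained, lost = differential_peaks(cond, ctrl)
        assert len(gained) == 200 and len(lost) == 150

    def test_gained_has_zero_control_overlap(self, rng):
        cond = merge_intervals(bed(
            [("chr1", int(s), int(s) + 20)
             for s in np.sort(rng.choice(4000, 80, replace=False))]))
        ctrl = merge_intervals(bed(
            [("chr1", int(s), int(s) + 20)
             for s in np.sort(rng.choice(4000, 80, replace=False))]))
        gained, _ = differential_peaks(cond, ctrl)
        for _, g in gained.iterrows():
            ov = ctrl[(ctrl["start"] < g["end"]) & (ctrl["end"] > g["start"])]
            assert ov.empty


class TestAnnotate:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame({
            "gene_id": ["GA", "GB"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [10_000, 50_000],
            "exon_starts": ["10000,14000", "46000,49500"],
            "exon_ends": ["10500,15000", "46800,50000"],
        })

    def test_center_near_tss_is_promoter(self, genes):
        peaks = bed([("chr1", 9_400, 9_600)])  # center 500 bp upstream
        table, _ = annotate_peaks(peaks, genes, promoter_radius=2000)
        assert table.loc[0, "region"] == "promoter"
        assert table.loc[0, "nearest_gene"] == "GA"

    def test_priority_exon_then_intron_then_intergenic(self, genes):
        peaks = bed([("chr1", 14_100, 14_300),   # inside exon, outside promoter
                     ("chr1", 13_000, 13_200),   # gene body, no exon
                     ("chr1", 30_000, 30_200)])  # between genes
        table, _ = annotate_peaks(peaks, genes, promoter_radius=2000)
        assert list(table["region"]) == ["exon", "intron", "intergenic"]

    def test_empty_annotation_classes_all_intergenic(self):
        peaks = bed([("chr1", 0, 100), ("chr2", 5, 60)])
        with pytest.warns(UserWarning):
            table, proportions = annotate_peaks(
                peaks, pd.DataFrame(columns=["gene_id", "chrom", "strand",
                                             "tss", "exon_starts", "exon_ends"]))
        assert (table["region"] == "intergenic").all()
        assert proportions["intergenic"] == 1.0

    def test_proportions_sum_to_one(self, genes, rng):
        starts = rng.integers(0, 60_000, 50)
        peaks = bed([("chr1", int(s), int(s) + 200) for s in starts])
        _, proportions = annotate_peaks(peaks, genes)
        assert proportions.sum() == pytest.approx(1.0)

    def test_summit_beats_midpoint_for_centering(self, genes):
        peaks = bed([("chr1", 5_000, 13_000)]).assign(summit=9_900)
        table, _ = annotate_peaks(peaks, genes, promoter_radius=2000)
        assert table.loc[0, "region"] == "promoter"


class TestMDScore:
    def test_half_of_large_radius_hits_are_close(self):
        peaks = bed([("chr1", 950, 1050), ("chr1", 99_500, 100_500),
                     ("chr1", 199_000, 201_000)])
        # offsets 10, 200, 1600 from the three peak centers
        hits = pd.DataFrame({
            "motif_id": "M1",
            "chrom": "chr1",
            "start": [1000 + 10, 100_000 + 200, 200_000 + 1600],
        })
        hits["end"] = hits["start"] + 1
        res = md_score(peaks, hits)
        assert res.loc["M1", "md"] == pytest.approx(0.5)
        assert res.loc["M1", "n_large"] == 2

    def test_all_hits_at_centers_give_one(self):
        peaks = bed([("chr1", 0, 100), ("chr1", 5000, 5100)])
        hits = pd.DataFrame({"motif_id": "M1", "chrom": "chr1",
                             "start": [50, 5050]})
        hits["end"] = hits["start"] + 1
        assert md_score(peaks, hits).loc["M1", "md"] == 1.0

    def test_no_hits_in_large_radius_flagged_undefined(self):
        peaks = bed([("chr1", 0, 100)])
        hits = pd.DataFrame({"motif_id": ["M1"], "chrom": ["chr1"],
                             "start": [1_000_000], "end": [1_000_001]})
        assert np.isnan(md_score(peaks, hits).loc["M1", "md"])

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        starts = np.sort(rng.choice(2_000_000, 500, replace=False))
        peaks = bed([("chr1", int(s), int(s) + 300) for s in starts])
        hits = pd.DataFrame({
            "motif_id": rng.choice(["M1", "M2", "M3"], 500),
            "chrom": "chr1",
            "start": rng.integers(0, 2_000_000, 500),
        })
        hits["end"] = hits["start"] + 10
        fast = md_score(peaks, hits)
        slow = md_oracle(peaks, hits)
        for motif, expected in slow.items():
            got = fast.loc[motif, "md"]
            assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)

    def test_translation_invariance(self, rng):
        starts = np.sort(rng.choice(100_000, 50, replace=False))
        peaks = bed([("chr1", int(s), int(s) + 100) for s in starts])
        hits = pd.DataFrame({"motif_id": "M1", "chrom": "chr1",
                             "start": rng.integers(0, 100_000, 200)})
        hits["end"] = hits["start"] + 1
        base = md_score(peaks, hits).loc["M1", "md"]
        shift = 7_777
        shifted = md_score(peaks.assign(start=peaks["start"] + shift,
                                        end=peaks["end"] + shift),
                           hits.assign(start=hits["start"] + shift,
                                       end=hits["end"] + shift)).loc["M1", "md"]
        assert shifted == pytest.approx(base)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            md_score(bed([("chr1", 0, 1)]), pd.DataFrame(
                {"motif_id": [], "chrom": [], "start": [], "end": []}),
                r_small=1500, r_large=150)


class TestMDDifferential:
    def test_identical_conditions_give_zero_delta(self, rng):
        starts = np.sort(rng.choice(500_000, 100, replace=False))
        peaks = bed([("chr1", int(s), int(s) + 200) for s in starts])
        hits = pd.DataFrame({"motif_id": rng.choice(["M1", "M2"], 300),
                             "chrom": "chr1",
                             "start": rng.integers(0, 500_000, 300)})
        hits["end"] = hits["start"] + 1
        diff = md_differential(peaks, peaks.copy(), hits)
        assert np.allclose(diff["delta"].dropna(), 0.0)

    def test_antisymmetric_under_condition_swap(self, rng):
        a = bed([("chr1", int(s), int(s) + 200)
                 for s in np.sort(rng.choice(500_000, 80, replace=False))])
        b = bed([("chr1", int(s), int(s) + 200)
                 for s in np.sort(rng.choice(500_000, 80, replace=False))])
        hits = pd.DataFrame({"motif_id": "M1", "chrom": "chr1",
                             "start": rng.integers(0, 500_000, 400)})
        hits["end"] = hits["start"] + 1
        d1 = md_differential(a, b, hits)["delta"]
        d2 = md_differential(b, a, hits)["delta"]
        assert np.allclose(d1.dropna(), -d2.dropna())

    def test_planted_motif_ranks_first(self):
        sim = simulate_atac(n_peaks=400, n_motifs=10,
                            planted={"MOTIF001": 0.8}, n_gained=200,
                            n_lost=150, seed=2)
        cond = consensus_peaks(sim["condition"], sim["condition_pseudoreplicates"])
        ctrl = consensus_peaks(sim["control"], sim["control_pseudoreplicates"])
        diff = md_differential(cond, ctrl, sim["motif_hits"])
        assert diff["delta"].idxmax() == "MOTIF001"
        assert diff.loc["MOTIF001", "delta"] > 0.3
        assert diff["delta"].abs().idxmax() == "MOTIF001"


class TestConcordanceCDF:
    def make_inputs(self, rng, shift=0.0):
        genes = [f"g{i}" for i in range(200)]
        lfc = pd.Series(rng.normal(0, 1, 200), index=genes)
        hit_genes = genes[:40]
        lfc.loc[hit_genes] += shift
        peak_table = pd.DataFrame({
            "gene": hit_genes,
            "fold_change": rng.uniform(2.5, 9, 40) * rng.choice([1, -1], 40),
            "p": rng.uniform(0, 0.009, 40),
        })
        return peak_table, lfc

    def test_selection_of_everything_gives_zero_ks(self, rng):
        _, lfc = self.make_inputs(rng)
        peak_table = pd.DataFrame({"gene": lfc.index, "fold_change": 10.0,
                                   "p": 0.001})
        out = concordance_cdf(peak_table, lfc, fc_cuts=(2,))
        assert out[2]["ks"] == pytest.approx(0.0)

    def test_ks_matches_direct_two_sample_computation(self, rng):
        def ks_brute(x, y):
            # max ECDF gap evaluated at every observed value
            pts = np.concatenate([x, y])
            return max(abs((x <= t).mean() - (y <= t).mean()) for t in pts)

        peak_table, lfc = self.make_inputs(rng, shift=1.0)
        out = concordance_cdf(peak_table, lfc, fc_cuts=(2, 5))
        for cut in (2, 5):
            sel = lfc.loc[out[cut]["genes"]].to_numpy()
            assert out[cut]["ks"] == pytest.approx(ks_brute(sel, lfc.to_numpy()))
        assert out[2]["ks"] > 0.2  # planted positive shift is visible

    def test_raising_cut_never_enlarges_selection(self, rng):
        peak_table, lfc = self.make_inputs(rng, shift=1.0)
        out = concordance_cdf(peak_table, lfc, fc_cuts=(2, 5, 8))
        assert set(out[8]["genes"]) <= set(out[5]["genes"]) <= set(out[2]["genes"])

    def test_empty_selection_flagged(self, rng):
        peak_table, lfc = self.make_inputs(rng)
        out = concordance_cdf(peak_table, lfc, fc_cuts=(100,))
        assert not out[100]["defined"]
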