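"""Benchmark construction rules: windows, negatives, labels, normalization, splits."""

import numpy as np
import pandas as pd
import pytest

import plantlm as plm
from plantlm.io import GenomicInterval, gc_content, revcomp
from plantlm.pgb import (assign_gene_families, audit_splits, extract_apa_positives,
                         extract_promoter_window, label_chromatin_windows,
                         make_apa_negatives, make_splits, match_lncrna_negatives,
                         normalize_expression, size_factors)


@pytest.fixture(scope="module")
def chrom_10kb():
    rng = np.random.default_rng(0)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=10_000))}


class TestApaWindows:
    def test_plus_strand_geometry(self, chrom_10kb):
        # site at 1-based 1000 -> window covers 1-based [700, 1099]
        sites = [GenomicInterval("chr1", 999, 1000, "+")]
        out, report = extract_apa_positives(chrom_10kb, sites)
        assert len(out) == 1
        win = out[0].sequence
        assert len(win) == 400
        assert win == chrom_10kb["chr1"][699:1099]
        assert win[300] == chrom_10kb["chr1"][999]  # site at 1-based position 301

    def test_minus_strand_reverse_complemented(self, chrom_10kb):
        sites = [GenomicInterval("chr1", 999, 1000, "-")]
        out, _ = extract_apa_positives(chrom_10kb, sites)
        win = out[0].sequence
        assert len(win) == 400
        # genomic 1-based [901, 1300]: 99 left of the site, the site, 300 right
        assert win == revcomp(chrom_10kb["chr1"][900:1300])
        assert win[300] == revcomp(chrom_10kb["chr1"][999])

    def test_boundary_sites_skipped_and_counted(self, chrom_10kb):
        sites = [GenomicInterval("chr1", 199, 200, "+"),  # 200 bp from start
                 GenomicInterval("chr1", 999, 1000, "+")]
        out, report = extract_apa_positives(chrom_10kb, sites)
        assert len(out) == 1
        assert report["n_skipped_boundary"] == 1

    def test_negatives_never_put_site_at_301_and_ratio_holds(self, chrom_10kb):
        rng = np.random.default_rng(3)
        sites = [GenomicInterval("chr1", int(p), int(p) + 1, "+")
                 for p in rng.integers(500, 9_400, size=100)]
        positives, _ = extract_apa_positives(chrom_10kb, sites)
        negatives = make_apa_negatives(positives, chrom_10kb, seed=5)
        assert len(negatives) == 2 * len(positives)
        for neg in negatives:
            shift = neg.provenance["shift"]
            assert 1 <= abs(shift) <= 50
            # true site lands at window position 301 - shift, never 301
            true_pos_in_window = 301 - shift
            site = neg.provenance["site_pos"]
            assert neg.sequence[true_pos_in_window - 1] == chrom_10kb["chr1"][site - 1]
            assert true_pos_in_window != 301

    def test_shift_sign_convention(self, chrom_10kb):
        # shift +50 puts the true site at window position 251; -1 puts it at 302
        positives, _ = extract_apa_positives(
            chrom_10kb, [GenomicInterval("chr1", 4999, 5000, "+")])
        seq = chrom_10kb["chr1"]
        for shift, expected in [(50, 251), (-1, 302)]:
            shifted = 5000 + shift
            window = seq[shifted - 301:shifted + 99]
            assert window[expected - 1] == seq[4999]


class TestLncRnaMatching:
    def _mk(self, length, gc, seed=0):
        n_gc = int(round(length * gc / 100))
        rng = np.random.default_rng(seed)
        seq = ["G" if i < n_gc else "A" for i in range(length)]
        rng.shuffle(seq)
        return "".join(seq)

    def test_tolerance_eligibility(self):
        lnc = {"l1": self._mk(500, 40.0)}
        assert match_lncrna_negatives(lnc, {"m": self._mk(580, 40.8)})[0] == [("l1", "m")]
        assert match_lncrna_negatives(lnc, {"m": self._mk(650, 40.0)})[0] == []
        assert match_lncrna_negatives(lnc, {"m": self._mk(500, 41.6)})[0] == []

    def test_overlong_sequences_removed_first(self):
        lnc = {"l1": self._mk(500, 40.0)}
        mrna = {"m_long": self._mk(6500, 40.0), "m_ok": self._mk(520, 40.0)}
        pairs, unmatched = match_lncrna_negatives(lnc, mrna)
        assert pairs == [("l1", "m_ok")]

    def test_matched_pairs_satisfy_tolerances_post_hoc(self):
        rng = np.random.default_rng(4)
        lnc = {f"l{i}": self._mk(int(rng.integers(200, 3000)),
                                 float(rng.uniform(30, 60)), i) for i in range(40)}
        mrna = {f"m{i}": self._mk(int(rng.integers(200, 3000)),
                                  float(rng.uniform(30, 60)), 100 + i) for i in range(80)}
        pairs, unmatched = match_lncrna_negatives(lnc, mrna, seed=1)
        assert len(pairs) + len(unmatched) == 40
        used = [m for _, m in pairs]
        assert len(set(used)) == len(used)  # no mRNA reuse
        for lid, mid in pairs:
            assert abs(len(mrna[mid]) - len(lnc[lid])) <= 100
            assert abs(gc_content(mrna[mid]) - gc_content(lnc[lid])) <= 1.0


class TestChromatinLabeling:
    @pytest.mark.parametrize("ocr,expected", [
        ((450, 560), 1),   # overlap 110 > 100
        ((450, 540), 0),   # overlap 90
        ((400, 500), 0),   # overlap exactly 100: strict inequality
    ])
    def test_center_overlap_rule(self, ocr, expected):
        windows = [GenomicInterval("c", 0, 1000)]
        out = label_chromatin_windows(windows, [GenomicInterval("c", *ocr)])
        assert out[0].targets == expected

    def test_multi_track_gives_label_vector(self):
        windows = [GenomicInterval("c", 0, 1000)]
        tracks = {"leaf": [GenomicInterval("c", 400, 600)],
                  "root": [GenomicInterval("c", 0, 100)]}
        out = label_chromatin_windows(windows, tracks)
        np.testing.assert_array_equal(out[0].targets, [1, 0])

    def test_wrong_window_size_rejected(self):
        with pytest.raises(ValueError):
            label_chromatin_windows([GenomicInterval("c", 0, 999)], [])

    def test_matches_per_base_overlap_oracle(self):
        """Union-coverage labeling vs brute-force per-base counting on 1,000
        random window/OCR configurations."""
        rng = np.random.default_rng(9)
        for _ in range(1000):
            w_start = int(rng.integers(0, 5000))
            window = GenomicInterval("c", w_start, w_start + 1000)
            ocrs = []
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(max(0, w_start - 500), w_start + 1500))
                ocrs.append(GenomicInterval("c", s, s + int(rng.integers(20, 400))))
            got = label_chromatin_windows([window], ocrs)[0].targets
            center = range(w_start + 400, w_start + 600)
            covered = sum(1 for b in center if any(o.start <= b < o.end for o in ocrs))
            assert got == int(covered > 100)


class TestPromoterWindows:
    def test_plus_strand_span(self, chrom_10kb):
        genes = [("g1", "chr1", 7001, "+")]
        out, _ = extract_promoter_window(chrom_10kb, genes, upstream=5000,
                                         downstream=1000)
        assert len(out) == 1
        assert out[0].provenance["genomic_span"] == (2001, 8000)
        assert len(out[0].sequence) == 6000
        assert out[0].sequence == chrom_10kb["chr1"][2000:8000]

    def test_minus_strand_reverse_complemented(self, chrom_10kb):
        genes = [("g1", "chr1", 4000, "-")]
        out, _ = extract_promoter_window(chrom_10kb, genes, upstream=2000,
                                         downstream=1000)
        assert out[0].provenance["genomic_span"] == (3001, 6000)
        assert out[0].sequence == revcomp(chrom_10kb["chr1"][3000:6000])

    def test_boundary_clipped_genes_skipped_with_count(self, chrom_10kb):
        genes = [("g1", "chr1", 100, "+"), ("g2", "chr1", 7001, "+")]
        out, report = extract_promoter_window(chrom_10kb, genes)
        assert report["n_skipped_boundary"] == 1
        assert len(out) == 1

    def test_missing_chromosome_named(self, chrom_10kb):
        with pytest.raises(KeyError, match="chr9"):
            extract_promoter_window(chrom_10kb, [("g1", "chr9", 7001, "+")])

    def test_gff3_parsing_path(self, chrom_10kb, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tgene\t7001\t7800\t.\t+\t.\tID=geneA\n")
        out, _ = extract_promoter_window(chrom_10kb, str(gff))
        assert out[0].id == "geneA"
        assert len(out[0].sequence) == 6000


class TestNormalization:
    def test_hand_computed_size_factors(self):
        counts = pd.DataFrame([[2, 4], [6, 12], [10, 20]],
                              columns=["s1", "s2"],
                              index=["g1", "g2", "g3"])
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))
        norm = normalize_expression(counts, {"s1": "t1", "s2": "t2"})
        np.testing.assert_allclose(norm["t1"], norm["t2"])

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 8, 2], "s2": [5, 8, 2]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_recovers_known_column_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 500, size=(200, 1))
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame((base * scales).astype(int),
                              columns=list("abcd"))
        f = size_factors(counts)
        ratio = f / f.iloc[1]
        np.testing.assert_allclose(ratio, scales / scales[1], rtol=1e-6)

    def test_zero_count_gets_pseudocount_log(self):
        counts = pd.DataFrame({"s1": [0, 10, 20], "s2": [4, 10, 20]})
        norm = normalize_expression(counts, {"s1": "t1", "s2": "t2"})
        assert norm.loc[0, "t1"] == pytest.approx(np.log2(0 / size_factors(counts)["s1"] + 1))

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]})
        with pytest.raises(ValueError):
            normalize_expression(counts, {"s1": "t1", "s2": "t2"})

    def test_replicates_averaged_per_tissue(self):
        counts = pd.DataFrame({"r1": [4, 4], "r2": [8, 8], "x": [6, 6]})
        norm = normalize_expression(counts, {"r1": "t", "r2": "t", "x": "u"})
        assert set(norm.columns) == {"t", "u"}


class TestGeneFamilies:
    def test_connected_components(self):
        fam = assign_gene_families([("A", "B", 1.0), ("B", "C", 0.9)], 0.5,
                                   genes=["A", "B", "C", "D"])
        assert fam.gene_to_family["A"] == fam.gene_to_family["C"]
        assert fam.gene_to_family["D"] != fam.gene_to_family["A"]

    def test_empty_edges_all_singletons(self):
        fam = assign_gene_families([], 0.5, genes=["A", "B"])
        assert len(fam.families) == 2

    def test_threshold_above_all_scores_gives_singletons(self):
        fam = assign_gene_families([("A", "B", 0.3)], 0.9, genes=["A", "B"])
        assert fam.gene_to_family["A"] != fam.gene_to_family["B"]

    def test_contradictory_duplicate_edges_keep_max(self):
        fam = assign_gene_families([("A", "B", 0.1), ("B", "A", 0.9)], 0.5)
        assert fam.gene_to_family["A"] == fam.gene_to_family["B"]


class TestSplits:
    def _examples(self, ids, chroms=None):
        return [plm.PgbExample(id=i, sequence="ACGT", targets=0,
                               provenance={"chromosome": (chroms or {}).get(i, "chr1")})
                for i in ids]

    def test_family_allocation_close_to_target(self):
        fam = assign_gene_families([("A", "B", 1), ("B", "C", 1)], 0.5,
                                   genes=list("ABCDE"))
        examples = self._examples(list("ABCDE"))
        manifest = make_splits(examples, "gene_family", families=fam,
                               test_fraction=0.2, seed=0)
        test_ids = set(manifest[manifest.split == "test"]["id"])
        assert len(test_ids) == 1  # exactly one singleton family in test

    def test_no_family_straddles_splits(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        edges = [(genes[i], genes[i + 1], 1.0) for i in range(0, 58, 3)]
        fam = assign_gene_families(edges, 0.5, genes=genes)
        manifest = make_splits(self._examples(genes), "gene_family",
                               families=fam, test_fraction=0.25, seed=4)
        split_of = dict(zip(manifest["id"], manifest["split"]))
        for members in fam.families.values():
            assert len({split_of[g] for g in members}) == 1

    def test_chromosome_holdout(self):
        chroms = {"a": "chr5", "b": "chr1", "c": "chr5"}
        manifest = make_splits(self._examples(list("abc"), chroms),
                               "chromosome_holdout", holdout_chromosomes=["chr5"])
        assert set(manifest[manifest.split == "test"]["id"]) == {"a", "c"}

    def test_audit_rejects_duplicate_ids_across_splits(self):
        manifest = pd.DataFrame({"id": ["a", "a"], "split": ["train", "test"]})
        with pytest.raises(ValueError):
            audit_splits(manifest, [])
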