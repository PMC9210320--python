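"""Tn-seq stage: junction detection, mapping, collapsing, classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import barhem
from barhem import tnseq

from oracles import collapse_oracle, collapse_two_stage_oracle, junction_oracle

ARM = "ACGCTGATCGTAGCTAGCTTGACCATGGTA"  # final 22 used for detection
ARM22 = ARM[-22:]


def _mutate(seq, positions, base="N"):
    s = list(seq)
    for p in positions:
        s[p] = "G" if s[p] != "G" else "T"
    return "".join(s)


class TestDetectJunction:
    layout = tnseq.JunctionLayout(barcode_length=20, barcode_gap=0,
                                  min_fragment_length=10)

    def _read(self, barcode, fragment):
        return "TTAAGG" + barcode + ARM22 + fragment

    def test_exact_arm_split(self):
        bc, frag = "A" * 20, "CGTA" * 5
        obs, reason = tnseq.detect_junction(self._read(bc, frag), ARM,
                                            layout=self.layout)
        assert reason == "ok"
        assert obs.barcode == bc and obs.genomic_fragment == frag

    def test_two_mismatches_tolerated_three_rejected(self):
        bc, frag = "C" * 20, "ACGT" * 5
        read2 = "TTAAGG" + bc + _mutate(ARM22, [3, 10]) + frag
        obs, reason = tnseq.detect_junction(read2, ARM, layout=self.layout)
        assert reason == "ok" and obs.barcode == bc
        read3 = "TTAAGG" + bc + _mutate(ARM22, [3, 10, 17]) + frag
        obs, reason = tnseq.detect_junction(read3, ARM, layout=self.layout)
        assert obs is None and reason == "no_arm"

    def test_truncated_barcode_or_fragment_rejected(self):
        # barcode would run off the left end
        obs, reason = tnseq.detect_junction("AAAA" + ARM22 + "T" * 30, ARM,
                                            layout=self.layout)
        assert reason == "truncated"
        # fragment too short
        obs, reason = tnseq.detect_junction("T" * 26 + ARM22 + "ACGT", ARM,
                                            layout=self.layout)
        assert reason == "truncated"

    def test_leftmost_hit_wins(self):
        bc = "G" * 20
        read = "TTAAGG" + bc + ARM22 + "CCCC" + ARM22 + "A" * 12
        obs, reason = tnseq.detect_junction(read, ARM, layout=self.layout)
        assert reason == "ok"
        assert obs.genomic_fragment == "CCCC" + ARM22 + "A" * 12

    def test_matches_sliding_window_oracle_on_simulated_reads(self, small_screen):
        cfg = dataclasses.replace(small_screen["config"], base_error_rate=0.05)
        reads = barhem.simulate_tnseq_reads(small_screen["truth"],
                                            small_screen["genome"], cfg)
        layout = tnseq.JunctionLayout(barcode_length=cfg.barcode_length,
                                      barcode_gap=cfg.junction_gap,
                                      min_fragment_length=30)
        for _, seq in reads[:2000]:
            obs, reason = tnseq.detect_junction(seq, cfg.transposon_arm,
                                                layout=layout)
            expect = junction_oracle(seq, cfg.transposon_arm, 2,
                                     cfg.barcode_length, cfg.junction_gap, 30)
            if expect is None:
                assert obs is None
            else:
                assert obs is not None
                assert (obs.barcode, obs.genomic_fragment) == expect


class TestCollapse:
    def test_dominated_satellite_eliminated(self):
        a = "A" * 20
        b = "C" + a[1:]
        kept, elim = tnseq.collapse_error_barcodes({a: 1000, b: 5}, 1, 10)
        assert set(kept) == {a} and set(elim) == {b}

    def test_genuine_neighbours_both_retained(self):
        a = "A" * 20
        c = "C" + a[1:]
        kept, elim = tnseq.collapse_error_barcodes({a: 1000, c: 800}, 1, 10)
        assert set(kept) == {a, c} and not elim

    def test_distance_two_stage(self):
        a = "A" * 20
        d2 = "CC" + a[2:]
        kept1, _ = tnseq.collapse_error_barcodes({a: 1000, d2: 5}, 1, 10)
        assert set(kept1) == {a, d2}  # distance 2 survives the d=1 pass
        kept2, elim2 = tnseq.collapse_error_barcodes(kept1, 2, 10)
        assert set(kept2) == {a} and set(elim2) == {d2}

    def test_empty_input(self):
        assert tnseq.collapse_error_barcodes({}, 1, 10) == ({}, {})

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        parents = ["".join(rng.choice(bases, 12)) for _ in range(120)]
        counts = {}
        for p in set(parents):
            counts[p] = int(rng.integers(200, 2000))
        # inject distance-1 and distance-2 satellites at varied abundances
        for p in list(counts)[:60]:
            pos = int(rng.integers(12))
            sat = p[:pos] + ("A" if p[pos] != "A" else "C") + p[pos + 1:]
            counts.setdefault(sat, int(rng.integers(1, 400)))
            pos2 = (pos + 5) % 12
            sat2 = sat[:pos2] + ("G" if sat[pos2] != "G" else "T") + sat[pos2 + 1:]
            counts.setdefault(sat2, int(rng.integers(1, 40)))
        kept, elim1, elim2 = tnseq.collapse_all(counts, 10.0)
        assert set(kept) == collapse_two_stage_oracle(counts, 10.0)
        for d, elim in ((1, elim1), (2, elim2)):
            src = counts if d == 1 else {**kept, **elim2}
            oracle_kept, oracle_elim = collapse_oracle(src, d, 10.0)
            assert set(elim) == set(oracle_elim)


class TestMapFragment:
    def test_unique_exact_location(self, small_screen):
        genome = small_screen["genome"]
        index = tnseq.GenomeIndex(genome, k=15)
        frag = genome["chr1_cer"][100:150]
        hits = tnseq.map_fragment(frag, index)
        assert hits == [("chr1_cer", 101, "+", 50)]

    def test_duplicated_span_two_equal_hits(self, small_screen):
        genome = dict(small_screen["genome"])
        frag = genome["chr1_cer"][200:250]
        genome["dup"] = "TTTT" + frag + "GGGG"
        index = tnseq.GenomeIndex(genome, k=15)
        hits = tnseq.map_fragment(frag, index)
        assert len(hits) == 2 and {h[0] for h in hits} == {"chr1_cer", "dup"}
        assert hits[0][3] == hits[1][3] == 50

    def test_reverse_strand_position_convention(self, small_screen):
        genome = small_screen["genome"]
        index = tnseq.GenomeIndex(genome, k=15)
        frag = tnseq.revcomp(genome["chr1_par"][300:350])
        hits = tnseq.map_fragment(frag, index)
        assert hits == [("chr1_par", 350, "-", 50)]

    def test_random_fragment_unmapped(self, small_screen):
        index = tnseq.GenomeIndex(small_screen["genome"], k=15)
        rng = np.random.default_rng(5)
        frag = "".join(rng.choice(list("ACGT"), 50))
        assert tnseq.map_fragment(frag, index) == []

    def test_short_fragment_rejected(self, small_screen):
        index = tnseq.GenomeIndex(small_screen["genome"], k=15)
        with pytest.raises(ValueError, match="shorter"):
            tnseq.map_fragment("ACGTACGT", index)

    def test_two_mismatches_still_found(self, small_screen):
        genome = small_screen["genome"]
        index = tnseq.GenomeIndex(genome, k=15)
        frag = _mutate(genome["chr1_cer"][100:150], [5, 40])
        hits = tnseq.map_fragment(frag, index)
        assert hits[0][:3] == ("chr1_cer", 101, "+") and hits[0][3] == 46


class TestClassifyMapping:
    def test_single_strong_location_unique(self):
        assert tnseq.classify_mapping([(("c", 1, "+"), 50, 40)], 50) == "unique"

    def test_two_strong_locations_multilocus(self):
        obs = [(("c", 1, "+"), 50, 20), (("c", 900, "+"), 48, 15)]
        assert tnseq.classify_mapping(obs, 50) == "multilocus"

    def test_weak_majority_ambiguous(self):
        obs = [(("c", 1, "+"), 50, 10), (("c", 900, "+"), 30, 15),
               (("d", 5, "-"), 28, 10)]
        assert tnseq.classify_mapping(obs, 50) == "ambiguous"

    def test_weak_minority_still_unique(self):
        obs = [(("c", 1, "+"), 50, 30), (("c", 900, "+"), 30, 10)]
        assert tnseq.classify_mapping(obs, 50) == "unique"

    def test_empty_unmapped(self):
        assert tnseq.classify_mapping([], 50) == "unmapped"


class TestAnnotate:
    def test_genic_intergenic_plasmid(self, small_screen):
        features = small_screen["features"]
        gene = next(f for f in features if f.type == "gene"
                    and f.attributes["allele_species"] == "cer")
        records = pd.DataFrame([
            {"chrom": gene.seqid, "position": gene.start + 5, "strand": "+",
             "barcode": "b1", "n_reads": 3, "mapping_class": "unique"},
            {"chrom": gene.seqid, "position": gene.end + 1, "strand": "+",
             "barcode": "b2", "n_reads": 3, "mapping_class": "unique"},
            {"chrom": "plasmid", "position": 10, "strand": "+",
             "barcode": "b3", "n_reads": 3, "mapping_class": "unique"},
        ])
        out = tnseq.annotate_records(records, features)
        assert list(out["gene_id"]) == [gene.attributes["gene_id"],
                                        "intergenic", "plasmid"]
        assert list(out["allele_species"]) == ["cer", "cer", "na"]

    def test_position_outside_contigs_is_error(self, small_screen):
        records = pd.DataFrame([{"chrom": "chr1_cer", "position": 10 ** 7,
                                 "strand": "+", "barcode": "b", "n_reads": 1,
                                 "mapping_class": "unique"}])
        with pytest.raises(ValueError, match="outside"):
            tnseq.annotate_records(records, small_screen["features"])


class TestBuildCatalog:
    def _catalog(self, screen, cfg):
        reads = barhem.simulate_tnseq_reads(screen["truth"], screen["genome"], cfg)
        layout = tnseq.JunctionLayout(barcode_length=cfg.barcode_length,
                                      barcode_gap=cfg.junction_gap)
        return reads, barhem.build_catalog(reads, screen["genome"],
                                           screen["features"],
                                           cfg.transposon_arm, layout)

    def test_errorfree_catalog_recovers_truth_exactly(self, small_screen,
                                                      errorfree_config):
        reads, catalog = self._catalog(small_screen, errorfree_config)
        truth = small_screen["truth"].insertions
        rec = catalog.records
        assert len(rec) == len(truth)
        merged = truth.merge(rec, on="barcode", suffixes=("_true", ""))
        assert (merged["position_true"] == merged["position"]).all()
        assert (merged["chrom_true"] == merged["chrom"]).all()
        assert (merged["gene_id_true"] == merged["gene_id"]).all()
        assert (merged["allele_species_true"] == merged["allele_species"]).all()

    def test_read_accounting_reconciles(self, small_screen):
        cfg = dataclasses.replace(small_screen["config"], base_error_rate=0.03)
        reads, catalog = self._catalog(small_screen, cfg)
        qc = catalog.qc
        assert qc["input_reads"] == len(reads)
        assert qc["reads_with_junction"] + qc["reads_rejected_no_arm"] + \
            qc["reads_rejected_truncated"] == qc["input_reads"]
        assert qc["barcodes_observed"] == qc["barcodes_off_by_one"] + \
            qc["barcodes_off_by_two"] + qc["barcodes_multilocus"] + \
            qc["barcodes_ambiguous"] + qc["barcodes_unmapped"] + \
            qc["barcodes_retained"]

    def test_species_relabel_symmetry(self, small_screen, errorfree_config):
        """Swapping cer/par chromosome labels only relabels allele_species."""
        screen = small_screen
        reads, catalog = self._catalog(screen, errorfree_config)
        swap = {"cer": "par", "par": "cer"}
        features2 = []
        for f in screen["features"]:
            f2 = dataclasses.replace(f, attributes=dict(f.attributes))
            if "allele_species" in f2.attributes:
                f2.attributes["allele_species"] = swap[f2.attributes["allele_species"]]
            features2.append(f2)
        layout = tnseq.JunctionLayout(barcode_length=errorfree_config.barcode_length,
                                      barcode_gap=errorfree_config.junction_gap)
        catalog2 = barhem.build_catalog(reads, screen["genome"], features2,
                                        errorfree_config.transposon_arm, layout)
        a, b = catalog.records, catalog2.records
        pd.testing.assert_frame_equal(a.drop(columns="allele_species"),
                                      b.drop(columns="allele_species"))
        mapped = a["allele_species"].map(lambda s: swap.get(s, s))
        assert (mapped.to_numpy() == b["allele_species"].to_numpy()).all()
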