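import numpy as np
import pandas as pd
import pytest

from splicelab.diffuse import Thresholds
from splicelab.genome import Genome
from splicelab.junctions import Junction
from splicelab.siteclass import (ClassedSiteSets, SiteRecord, classify_splice_sites,
                                 combine_lfc, donjuan_classify, emit_class_fasta)


@pytest.fixture()
def toy():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    genome = Genome({"c": seq})
    junctions = {}
    for i in range(8):
        j = Junction("c", 500 + i * 300, 700 + i * 300, "+" if i % 2 == 0 else "-")
        junctions[j.id] = j
    return genome, junctions


def results_for(junctions, rows):
    jids = list(junctions)
    return pd.DataFrame(
        [{"feature_id": jids[i], "gene_id": f"g{i}", "logFC": lfc, "p": p,
          "fdr": fdr} for i, (lfc, p, fdr) in enumerate(rows)])


class TestClassifySpliceSites:
    def class_of(self, sets, junctions, i):
        jid = list(junctions)[i]
        for name, records in sets.classes.items():
            if any(r.junction_id == jid for r in records):
                return name
        return "unassigned" if jid in sets.unassigned else None

    @pytest.mark.parametrize("lfc,fdr,expected", [
        (0.8, 0.001, "enhanced"),     # significant, strong positive effect
        (0.8, 0.2, "unassigned"),     # between significance and control cut-offs
        (0.0, 0.9, "control"),        # clearly unregulated
        (-0.9, 0.01, "repressed"),
        (0.3, 0.01, "unassigned"),    # significant but effect below cut-off
        (2.5, 0.9, "control"),        # control class is not logFC-restricted
    ])
    def test_rules(self, toy, lfc, fdr, expected):
        genome, junctions = toy
        res = results_for(junctions, [(lfc, fdr / 2, fdr)])
        sets = classify_splice_sites(res, junctions, genome)
        assert self.class_of(sets, junctions, 0) == expected

    def test_disjoint_classes(self, toy):
        genome, junctions = toy
        rng = np.random.default_rng(3)
        rows = [(float(rng.normal(0, 1)), 0.0, float(rng.random()))
                for _ in junctions]
        sets = classify_splice_sites(results_for(junctions, rows),
                                     junctions, genome)
        ids = [r.junction_id for recs in sets.classes.values() for r in recs]
        assert len(ids) == len(set(ids))

    def test_threshold_monotonicity(self, toy):
        genome, junctions = toy
        rows = [(lfc, 0.001, 0.001) for lfc in
                (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)]
        res = results_for(junctions, rows)
        sizes = []
        for cut in (0.3, 0.7, 1.1):
            t = Thresholds(site_enh_lfc=cut)
            sets = classify_splice_sites(res, junctions, genome, t)
            sizes.append(len(sets.classes["enhanced"]))
        assert sizes == sorted(sizes, reverse=True)

    def test_window_sequences_are_strand_oriented(self, toy):
        genome, junctions = toy
        res = results_for(junctions, [(1.0, 0.001, 0.001)] * len(junctions))
        sets = classify_splice_sites(res, junctions, genome, flank=10)
        from splicelab.genome import fetch_sequence
        for r in sets.classes["enhanced"]:
            assert r.sequence == fetch_sequence(genome, r.chrom, r.start,
                                                r.end, r.strand)
            assert len(r.sequence) == 21

    def test_clipped_window_dropped_and_counted(self, toy):
        genome, junctions = toy
        j = Junction("c", 20, 200, "+")  # donor at 20 < flank
        junctions = {j.id: j}
        res = pd.DataFrame([{"feature_id": j.id, "gene_id": "g", "logFC": 1.0,
                             "p": 0.001, "fdr": 0.001}])
        sets = classify_splice_sites(res, junctions, genome, flank=80)
        assert sets.classes["enhanced"] == [] and sets.n_clipped == 1


class TestDonjuan:
    @pytest.mark.parametrize("jlfc,jfdr,alfc,expected", [
        (1.4, 0.01, 1.0, "included"),    # combined (1.4+1.0)/2 = 1.2 > 1
        (-1.6, 0.001, -1.2, "skipped"),  # combined -1.4 < -1
        (2.0, 0.7, 5.0, "control"),      # fdr > 0.5 -> control regardless
        (0.8, 0.01, 0.6, "unassigned"),  # combined 0.7 below inclusion cut
    ])
    def test_rules(self, toy, jlfc, jfdr, alfc, expected):
        genome, junctions = toy
        jid = list(junctions)[0]
        jres = pd.DataFrame([{"feature_id": jid, "gene_id": "g", "logFC": jlfc,
                              "p": jfdr / 2, "fdr": jfdr}])
        ares = pd.DataFrame([{"feature_id": f"anchor:{jid}", "gene_id": "g",
                              "logFC": alfc, "p": 0.5, "fdr": 0.5}])
        sets = donjuan_classify(jres, ares, junctions, genome)
        if expected == "unassigned":
            assert jid in sets.unassigned
        else:
            assert any(r.junction_id == jid for r in sets.classes[expected])

    def test_missing_anchor_falls_back_to_junction(self, toy):
        genome, junctions = toy
        jid = list(junctions)[0]
        jres = pd.DataFrame([{"feature_id": jid, "gene_id": "g", "logFC": 1.5,
                              "p": 0.001, "fdr": 0.001}])
        ares = pd.DataFrame(columns=["feature_id", "gene_id", "logFC", "p", "fdr"])
        sets = donjuan_classify(jres, ares, junctions, genome)
        rec = sets.classes["included"][0]
        assert rec.combined_lfc == pytest.approx(1.5)

    @pytest.mark.parametrize("strategy,expected", [
        ("mean", 1.0), ("min", 0.5), ("anchor_only", 1.5)])
    def test_combine_strategies(self, strategy, expected):
        assert combine_lfc(0.5, 1.5, strategy) == pytest.approx(expected)

    def test_combine_min_is_magnitude_based(self):
        assert combine_lfc(-2.0, -0.5, "min") == pytest.approx(-0.5)

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            combine_lfc(1.0, 1.0, "median")


class TestEmitFasta:
    def sets(self):
        recs = [SiteRecord("c:200-400:+", "c", 120, 281, "+", "ACGT" * 40 + "A",
                           1.2, 0.01),
                SiteRecord("c:900-1100:+", "c", 820, 981, "+", "TTTT" * 40 + "T",
                           1.5, 0.02)]
        return ClassedSiteSets("donjuan", {"included": recs, "skipped": [],
                                           "control": []},
                              Thresholds(), 80)

    def test_round_trip(self, tmp_path):
        sets = self.sets()
        paths = emit_class_fasta(sets, tmp_path)
        text = paths["included"].read_text()
        entries = text.strip().split("\n")
        assert entries[0] == ">c:200-400:+|included|c:120-281:+"
        assert entries[1] == "ACGT" * 40 + "A"
        # headers parse back to coordinates
        jid, cls, span = entries[2][1:].split("|")
        assert jid == "c:900-1100:+" and cls == "included"
        assert span == "c:820-981:+"

    def test_empty_class_writes_empty_file(self, tmp_path):
        paths = emit_class_fasta(self.sets(), tmp_path)
        assert paths["skipped"].read_text() == ""

    def test_sequence_interval_mismatch_rejected(self):
        rec = SiteRecord("j", "c", 0, 10, "+", "ACGT", 0.0, 1.0)
        with pytest.raises(ValueError, match="length"):
            ClassedSiteSets("donjuan", {"included": [rec]}, Thresholds(), 80)

    def test_duplicate_across_classes_rejected(self):
        rec = SiteRecord("j", "c", 0, 4, "+", "ACGT", 0.0, 1.0)
        with pytest.raises(ValueError, match="both"):
            ClassedSiteSets("donjuan", {"included": [rec], "skipped": [rec]},
                            Thresholds(), 80)
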