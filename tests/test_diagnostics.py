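"""Probe scanning, genome statistics and trait-table keys."""

import numpy as np
import pytest

from anitax.align import revcomp
from anitax.diagnostics import (ITS_DIAGNOSTIC_PROBE, PNECC_16S_PROBE,
                                SignatureProbe, diagnostic_key, genome_stats,
                                load_trait_table, packaged_table, scan_probe)
from anitax.seqio import GenomeRecord, IUPAC_CODES
from anitax.synthetic import generate_genome


def naive_scan(seq, probe_seq, max_mm=0):
    """Brute-force oracle: test every window against the IUPAC expansion."""
    hits = []
    k = len(probe_seq)
    for i in range(len(seq) - k + 1):
        mm = sum(
            1 for a, b in zip(probe_seq, seq[i : i + k])
            if not (IUPAC_CODES[a] & IUPAC_CODES.get(b, frozenset()))
        )
        if mm <= max_mm:
            hits.append(i)
    return hits


class TestScanProbe:
    def test_embedded_16s_signature_found_at_444(self):
        rng = np.random.default_rng(51)
        flank = "".join(rng.choice(list("ACGT"), 600))
        seq = flank[:444] + PNECC_16S_PROBE.sequence + flank[444:]
        hits = scan_probe(seq, PNECC_16S_PROBE)
        assert any(h.position == 444 and h.strand == "+" and h.mismatches == 0
                   for h in hits)

    def test_absent_probe_no_hits(self):
        assert scan_probe("ACGT" * 50, ITS_DIAGNOSTIC_PROBE) == []

    def test_reverse_strand_hit_matches_naive_oracle(self):
        rng = np.random.default_rng(53)
        flank = "".join(rng.choice(list("ACGT"), 300))
        seq = flank[:100] + revcomp(ITS_DIAGNOSTIC_PROBE.sequence) + flank[100:]
        hits = scan_probe(seq, ITS_DIAGNOSTIC_PROBE)
        assert [h.position for h in hits if h.strand == "-"] == naive_scan(
            seq, revcomp(ITS_DIAGNOSTIC_PROBE.sequence))
        assert not scan_probe(seq, ITS_DIAGNOSTIC_PROBE, search_revcomp=False)

    def test_iupac_probe_matches_expansion_set(self):
        probe = SignatureProbe("amb", "ARYN")
        assert [h.position for h in scan_probe("AATC", probe, search_revcomp=False)] == [0]
        assert [h.position for h in scan_probe("AGCG", probe, search_revcomp=False)] == [0]
        assert scan_probe("ACCG", probe, search_revcomp=False) == []

    def test_mismatch_budget_agrees_with_oracle(self):
        rng = np.random.default_rng(59)
        seq = "".join(rng.choice(list("ACGT"), 500))
        probe = SignatureProbe("p", seq[200:218])
        for max_mm in (0, 1, 2, 3):
            got = [h.position for h in scan_probe(seq, probe, search_revcomp=False,
                                                  max_mismatches=max_mm)]
            assert got == naive_scan(seq, probe.sequence, max_mm)

    def test_invalid_probe_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            SignatureProbe("bad", "ACGU")


class TestGenomeStats:
    def test_all_gc_sequence(self):
        g = GenomeRecord("g", ["GGCC"])
        assert genome_stats(g)["gc_molpct"] == 100.0

    def test_generated_genome_near_target_gc(self):
        g = generate_genome(100_000, gc=0.448, seed=61)
        s = genome_stats(g)
        assert s["gc_molpct"] == pytest.approx(44.8, abs=0.5)
        assert s["size_mbp"] == 0.10

    def test_gc_invariant_under_reverse_complement(self):
        g = generate_genome(5_000, gc=0.6, seed=67)
        rc = GenomeRecord("rc", [revcomp(g.contigs[0])])
        assert genome_stats(g)["gc_molpct"] == genome_stats(rc)["gc_molpct"]

    def test_ambiguity_codes_excluded(self):
        g = GenomeRecord("g", ["GGCCNNNNRY"])
        assert genome_stats(g)["gc_molpct"] == 100.0

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="unambiguous"):
            genome_stats(GenomeRecord("g", ["NNNN"]))


class TestDiagnosticKey:
    def test_assimilation_table_unique_traits(self):
        table = load_trait_table(packaged_table("assimilation_traits.tsv")).normalize()
        key = diagnostic_key(table)
        assert ("L-Aspartate", "positive") in key["unique_traits"]["QLW-P1DMWA-1"]
        assert ("Propionic acid", "negative") in key["unique_traits"]["MWH-MoK4"]
        assert key["indistinguishable_pairs"] == []

    def test_fatty_acid_table_binarized_uniques(self):
        table = load_trait_table(packaged_table("fatty_acids.tsv")).normalize()
        key = diagnostic_key(table)
        assert ("C20:0", "positive") in key["unique_traits"]["QLW-P1DMWA-1"]
        assert ("C16:0 2-OH", "positive") in key["unique_traits"]["MWH-MoK4"]

    def test_identical_rows_reported_indistinguishable(self):
        import pandas as pd

        from anitax.diagnostics import TraitTable

        df = pd.DataFrame({"t1": ["+", "+"], "t2": ["-", "+"]},
                          index=["a", "b"]).T.T
        df = pd.DataFrame([["+", "-"], ["+", "-"], ["-", "-"]],
                          index=["a", "b", "c"], columns=["t1", "t2"])
        key = diagnostic_key(TraitTable(df))
        assert ("a", "b") in key["indistinguishable_pairs"]
        assert key["pair_differences"][("a", "c")] == ["t1"]

    def test_key_invariant_to_row_and_column_permutation(self):
        table = load_trait_table(packaged_table("assimilation_traits.tsv")).normalize()
        from anitax.diagnostics import TraitTable

        df = table.df
        rng = np.random.default_rng(71)
        shuffled = TraitTable(
            df.iloc[rng.permutation(len(df.index)), rng.permutation(len(df.columns))]
        )
        k1 = diagnostic_key(table)
        k2 = diagnostic_key(shuffled)
        assert {t: set(v) for t, v in k1["unique_traits"].items()} == \
               {t: set(v) for t, v in k2["unique_traits"].items()}

    def test_gene_content_table_loads_rectangular(self):
        table = load_trait_table(packaged_table("gene_content.tsv"))
        assert len(table.taxa) == 4
        assert table.value("QLW-P1DMWA-1", "Catalase") == "2 genes"
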