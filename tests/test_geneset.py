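import numpy as np
import pytest

from seqbug.correction import CorrectionDecision
from seqbug.geneset import (
    TranscriptModel,
    load_gtf,
    project_corrections,
    summarize_gene_effects,
    write_cds_fasta,
)

# independent codon table for the brute-force oracle
_ORACLE_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_RC = str.maketrans("ACGT", "TGCA")


def _oracle_cds(scaffold, segments, strand):
    seq = "".join(scaffold[s - 1 : e] for s, e in sorted(segments))
    return seq.translate(_RC)[::-1] if strand == "-" else seq


def _oracle_effects(scaffold, segments, strand, corrections):
    """Brute force: apply corrections to the scaffold, rebuild and translate
    both CDS versions, then diff per codon."""
    fixed = list(scaffold)
    for pos, base in corrections:
        fixed[pos - 1] = base
    before = _oracle_cds(scaffold, segments, strand)
    after = _oracle_cds("".join(fixed), segments, strand)
    out = {}
    for ci in range(len(before) // 3):
        c0, c1 = before[ci * 3 : ci * 3 + 3], after[ci * 3 : ci * 3 + 3]
        if c0 == c1:
            continue
        a0, a1 = _ORACLE_CODE[c0], _ORACLE_CODE[c1]
        if ci == 0 and c0 == "ATG" and a1 != "M":
            effect = "start_loss"
        elif a0 != "*" and a1 == "*":
            effect = "stop_gain"
        elif a0 == "*" and a1 != "*":
            effect = "stop_loss"
        elif a0 == a1:
            effect = "synonymous"
        else:
            effect = "nonsynonymous"
        out[ci + 1] = (c0, c1, effect)
    return out


def _dec(seq_id, pos, ref, alt):
    return CorrectionDecision(seq_id, pos, ref, alt, 1, 50, "corrected")


GTF_TEMPLATE = (
    '{seq}\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t{frame}\t'
    'gene_id "{gene}"; transcript_id "{tx}";'
)


class TestLoadGtf:
    def test_two_exon_plus_strand(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text(
            "#!genome-build test\n"
            + GTF_TEMPLATE.format(seq="s", start=1, end=6, strand="+", frame=0, gene="g1", tx="t1")
            + "\n"
            + GTF_TEMPLATE.format(seq="s", start=10, end=12, strand="+", frame=0, gene="g1", tx="t1")
            + "\n"
        )
        (model,) = load_gtf(gtf)
        assert model.cds_length == 9
        assert model.segments == [(1, 6, 0), (10, 12, 0)]
        assert not model.partial

    def test_minus_strand_reverses_order_and_complements(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text(
            GTF_TEMPLATE.format(seq="s", start=10, end=12, strand="-", frame=0, gene="g1", tx="t1")
            + "\n"
            + GTF_TEMPLATE.format(seq="s", start=1, end=6, strand="-", frame=0, gene="g1", tx="t1")
            + "\n"
        )
        (model,) = load_gtf(gtf)
        assert model.segments == [(10, 12, 0), (1, 6, 0)]
        scaffold = "ACGTACGTAACG"
        expected = _oracle_cds(scaffold, [(1, 6), (10, 12)], "-")
        assert model.cds_sequence(scaffold) == expected

    def test_missing_transcript_id_skipped_with_warning(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text('s\ttest\tCDS\t1\t6\t.\t+\t0\tgene_id "g1";\n')
        with pytest.warns(UserWarning, match="transcript_id"):
            assert load_gtf(gtf) == []

    def test_inconsistent_frames_flag_partial(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text(
            GTF_TEMPLATE.format(seq="s", start=1, end=6, strand="+", frame=0, gene="g1", tx="t1")
            + "\n"
            + GTF_TEMPLATE.format(seq="s", start=10, end=12, strand="+", frame=2, gene="g1", tx="t1")
            + "\n"
        )
        (model,) = load_gtf(gtf)
        assert model.partial

    def test_non_multiple_of_three_flag_partial(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text(GTF_TEMPLATE.format(seq="s", start=1, end=7, strand="+", frame=0, gene="g1", tx="t1") + "\n")
        (model,) = load_gtf(gtf)
        assert model.partial


class TestProjectCorrections:
    def test_nonsynonymous_third_base(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        ccs, cds, _ = project_corrections([model], [_dec("s", 3, "G", "A")], {"s": "ATGAAA"})
        (cc,) = ccs
        assert (cc.ref_codon, cc.corrected_codon) == ("ATG", "ATA")
        assert (cc.ref_aa, cc.corrected_aa) == ("M", "I")
        assert cc.effect == "start_loss"  # ATG at codon 1 is the start
        assert cds["t1"] == "ATA"

    def test_nonsynonymous_not_at_start(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 6, 0)])
        (cc,), _, _ = project_corrections([model], [_dec("s", 6, "G", "A")], {"s": "AAAATG"})
        assert cc.codon_index == 2
        assert cc.effect == "nonsynonymous"

    def test_synonymous(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        (cc,), _, _ = project_corrections([model], [_dec("s", 3, "A", "G")], {"s": "GGA"})
        assert cc.effect == "synonymous"

    def test_stop_gain(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        (cc,), _, _ = project_corrections([model], [_dec("s", 3, "C", "A")], {"s": "TAC"})
        assert cc.effect == "stop_gain"

    def test_minus_strand_complemented(self):
        # genomic TAC on minus strand reads GTA; correct genomic pos1 T->C => GTG (V, synonymous GTA->GTG)
        model = TranscriptModel("g1", "t1", "s", "-", [(1, 3, 0)])
        (cc,), _, _ = project_corrections([model], [_dec("s", 1, "T", "C")], {"s": "TAC"})
        assert cc.ref_codon == "GTA"
        assert cc.corrected_codon == "GTG"
        assert cc.effect == "synonymous"

    def test_two_sites_one_codon_merged(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        ccs, _, _ = project_corrections(
            [model], [_dec("s", 1, "A", "T"), _dec("s", 3, "G", "A")], {"s": "ATG"}
        )
        (cc,) = ccs
        assert sorted(cc.genomic_sites) == [1, 3]
        oracle = _oracle_effects("ATG", [(1, 3)], "+", [(1, "T"), (3, "A")])
        assert cc.corrected_codon == oracle[1][1]
        assert cc.effect == oracle[1][2]

    def test_partial_transcript_sites_unprojectable(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 4, 0)], partial=True)
        ccs, cds, unproj = project_corrections([model], [_dec("s", 2, "T", "C")], {"s": "ATGA"})
        assert ccs == []
        assert unproj == [("t1", 2)]
        assert "t1" not in cds

    def test_site_outside_cds_ignored(self):
        model = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        ccs, _, unproj = project_corrections([model], [_dec("s", 5, "A", "G")], {"s": "ATGAA"})
        assert ccs == [] and unproj == []

    def test_overlapping_transcripts_get_one_record_each(self):
        m1 = TranscriptModel("g1", "t1", "s", "+", [(1, 6, 0)])
        m2 = TranscriptModel("g1", "t2", "s", "+", [(4, 6, 0)])
        ccs, _, _ = project_corrections([m1, m2], [_dec("s", 6, "G", "T")], {"s": "ATGATG"})
        assert sorted(c.transcript_id for c in ccs) == ["t1", "t2"]

    def test_every_transcript_in_corrected_cds(self):
        m1 = TranscriptModel("g1", "t1", "s", "+", [(1, 3, 0)])
        m2 = TranscriptModel("g2", "t2", "s", "+", [(4, 6, 0)])
        _, cds, _ = project_corrections([m1, m2], [], {"s": "ATGATG"})
        assert set(cds) == {"t1", "t2"}


def _random_transcript_case(rng):
    """Random scaffold + transcript + corrections, for the oracle sweep."""
    n_exons = int(rng.integers(1, 4))
    exon_lens = [int(rng.integers(2, 20)) * 3 for _ in range(n_exons)]
    # pad so total is a multiple of 3 regardless of split across exons
    total = sum(exon_lens)
    offset = total % 3
    if offset:
        exon_lens[-1] += 3 - offset
    cursor = int(rng.integers(1, 5))
    segments = []
    for el in exon_lens:
        segments.append((cursor, cursor + el - 1))
        cursor += el + int(rng.integers(2, 10))
    scaffold_len = cursor + int(rng.integers(0, 5))
    scaffold = "".join("ACGT"[i] for i in rng.integers(0, 4, size=scaffold_len))
    strand = "+" if rng.random() < 0.5 else "-"
    cds_positions = [p for s, e in segments for p in range(s, e + 1)]
    k = int(rng.integers(0, min(4, len(cds_positions)) + 1))
    picked = sorted(rng.choice(cds_positions, size=k, replace=False).tolist()) if k else []
    corrections = []
    for pos in picked:
        ref = scaffold[pos - 1]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        corrections.append((pos, alt))
    oriented = segments if strand == "+" else list(reversed(segments))
    model = TranscriptModel("g", "t", "s", strand, [(s, e, 0) for s, e in oriented])
    return scaffold, model, segments, strand, corrections


def _check_against_oracle(scaffold, model, segments, strand, corrections):
    decisions = [_dec("s", pos, scaffold[pos - 1], alt) for pos, alt in corrections]
    # corrections on the minus strand arrive in genomic coordinates; the
    # oracle substitutes genomic bases then re-extracts the CDS
    oracle = _oracle_effects(scaffold, segments, strand, corrections)
    ccs, cds, _ = project_corrections([model], decisions, {"s": scaffold})
    got = {cc.codon_index: (cc.ref_codon, cc.corrected_codon, cc.effect) for cc in ccs}
    assert got == oracle
    # translation oracle: corrected CDS translation equals codon-level patching
    fixed = list(scaffold)
    for pos, alt in corrections:
        fixed[pos - 1] = alt
    assert cds["t"] == _oracle_cds("".join(fixed), segments, strand)


def test_translation_oracle_sweep():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        _check_against_oracle(*_random_transcript_case(rng))


def test_strand_symmetry():
    """Reverse-complementing the scaffold and flipping strand yields the same
    effect classes."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        scaffold, model, segments, strand, corrections = _random_transcript_case(rng)
        decisions = [_dec("s", pos, scaffold[pos - 1], alt) for pos, alt in corrections]
        ccs, _, _ = project_corrections([model], decisions, {"s": scaffold})

        L = len(scaffold)
        rc = scaffold.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        flip = {"+": "-", "-": "+"}[strand]
        rc_segments = sorted((L - e + 1, L - s + 1) for s, e in segments)
        rc_oriented = rc_segments if flip == "+" else list(reversed(rc_segments))
        rc_model = TranscriptModel("g", "t", "s", flip, [(s, e, 0) for s, e in rc_oriented])
        comp = str.maketrans("ACGT", "TGCA")
        rc_decisions = [
            _dec("s", L - pos + 1, scaffold[pos - 1].translate(comp), alt.translate(comp))
            for pos, alt in corrections
        ]
        rc_ccs, _, _ = project_corrections([rc_model], rc_decisions, {"s": rc})
        assert {(c.codon_index, c.ref_codon, c.corrected_codon, c.effect) for c in ccs} == {
            (c.codon_index, c.ref_codon, c.corrected_codon, c.effect) for c in rc_ccs
        }


class TestSummarizeGeneEffects:
    def _cc(self, gene, tx, ci, effect, ref="ATG", alt="ATA"):
        from seqbug.geneset import CodonCorrection

        return CodonCorrection(gene, tx, ci, ref, alt, "M", "I", effect, (1,))

    def test_gene_in_both_classes(self):
        df = summarize_gene_effects(
            [self._cc("g1", "t1", 1, "synonymous"), self._cc("g1", "t1", 2, "nonsynonymous")]
        )
        row = df.iloc[0]
        assert bool(row.has_synonymous) and bool(row.has_nonsynonymous)
        assert row.n_codons_corrected == 2

    def test_stop_gain_counts_as_nonsynonymous(self):
        df = summarize_gene_effects([self._cc("g1", "t1", 1, "stop_gain")])
        assert bool(df.iloc[0].has_nonsynonymous)

    def test_empty(self):
        df = summarize_gene_effects([])
        assert df.empty

    def test_conservation(self, sim, decisions, gtf_file):
        _, _, truth = sim
        models = load_gtf(gtf_file)
        ccs, _, _ = project_corrections(models, decisions, truth.corrupted_genome)
        df = summarize_gene_effects(ccs)
        assert df.n_codons_corrected.sum() == len({(c.transcript_id, c.codon_index) for c in ccs})


def test_simulator_effect_classes_match_ground_truth(sim, decisions, gtf_file):
    _, _, truth = sim
    models = load_gtf(gtf_file)
    ccs, _, _ = project_corrections(models, decisions, truth.corrupted_genome)
    got = {(c.transcript_id, c.codon_index): c.effect for c in ccs}
    assert got == truth.coding_effects


def test_write_cds_fasta_wraps(tmp_path):
    path = tmp_path / "c.fa"
    write_cds_fasta({"t1": "A" * 130}, path)
    lines = path.read_text().splitlines()
    assert lines[0] == ">t1"
    assert [len(l) for l in lines[1:]] == [60, 60, 10]
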