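"""Data model, I/O round trips, and k-mer opportunity counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from uvscape import genome_model as gm
from uvscape.genome_model import (ConsistencyError, IntervalSet, MutationRecord,
                                  NumericTrack, ParseError, canonical_kmer,
                                  count_opportunities, encode, extract_context,
                                  mask_records, merge_adjacent_snvs, revcomp)


# ---------------------------------------------------------------------------
# intervals and tracks
# ---------------------------------------------------------------------------

def test_interval_set_normalizes_and_contains():
    iv = IntervalSet.from_pairs({"chr1": [(50, 100), (90, 150), (200, 210)]})
    assert iv.pairs("chr1").tolist() == [[50, 150], [200, 210]]
    hits = iv.contains("chr1", [49, 50, 149, 150, 205, 300])
    assert hits.tolist() == [False, True, True, False, True, False]
    assert iv.total_length() == 110


def test_interval_set_ops():
    a = IntervalSet.from_pairs({"chr1": [(0, 100)]})
    b = IntervalSet.from_pairs({"chr1": [(50, 150)]})
    assert a.intersect(b).pairs("chr1").tolist() == [[50, 100]]
    assert a.union(b).pairs("chr1").tolist() == [[0, 150]]
    assert a.complement({"chr1": 200}).pairs("chr1").tolist() == [[100, 200]]


def test_bedgraph_overlap_last_writer_wins(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\nchr1\t300\t400\t3.0\n")
    tr = NumericTrack.from_bedgraph(str(p))
    assert tr.value_at("chr1", [10, 60, 120, 350]).tolist() == [1.0, 2.0, 2.0, 3.0]
    assert np.isnan(tr.value_at("chr1", [200])[0])  # uncovered -> missing, not 0
    with pytest.raises(ParseError):
        NumericTrack.from_bedgraph(str(p), strict=True)


def test_wig_reader_fixed_and_variable(tmp_path):
    p = tmp_path / "t.wig"
    p.write_text("fixedStep chrom=chr1 start=1 step=10 span=10\n5\n7\n"
                 "variableStep chrom=chr2 span=5\n101\t2.5\n")
    tr = NumericTrack.from_wig(str(p))
    assert tr.value_at("chr1", [0, 10])[0] == 5 and tr.value_at("chr1", [10])[0] == 7
    assert tr.value_at("chr2", [100])[0] == 2.5


def test_window_means_coverage_weighted():
    tr = NumericTrack.from_arrays("chr1", [0, 500], [500, 1000], [2.0, 4.0])
    means = tr.window_means("chr1", 2000, 1000)
    assert means[0] == pytest.approx(3.0)
    assert np.isnan(means[1])


# ---------------------------------------------------------------------------
# reference + VCF I/O
# ---------------------------------------------------------------------------

def test_read_reference_and_consistency(tmp_path, tiny_bundle):
    fa = tmp_path / "ref.fa"
    tiny_bundle.write_fasta(str(fa))
    genes = tmp_path / "genes.tsv"
    tiny_bundle.genes.to_table(str(genes))
    bundle = gm.read_reference(str(fa), str(genes))
    assert dict(bundle.contigs) == dict(tiny_bundle.contigs)
    assert len(bundle.genes) == 2
    # annotation naming an absent contig -> consistency error
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene_id\tcontig\tstrand\tstart\tend\texpression\n"
                   "gX\tchrZ\t+\t0\t10\t1.0\n")
    with pytest.raises(ConsistencyError):
        gm.read_reference(str(fa), str(bad))


def test_vcf_round_trip(tmp_path, tiny_bundle):
    recs = [
        MutationRecord("s1", "chr1", 15, "C", "T", 0.3, 10, 2, 1,
                       {"CONTQ": 50.0, "POPAF": 6.0}),
        MutationRecord("s1", "chr1", 25, "CC", "TT", 0.4, 20, 4, 4, {"TLOD": 12.0}),
        MutationRecord("s1", "chr2", 5, "C", "A", 0.1, 30, 2, 1, {}),
    ]
    path = tmp_path / "t.vcf"
    gm.write_vcf(recs, str(path), tiny_bundle.contigs)
    back = gm.read_mutations(str(path))
    assert [(r.contig, r.pos, r.ref, r.alt) for r in back] == \
        [("chr1", 15, "C", "T"), ("chr1", 25, "CC", "TT"), ("chr2", 5, "C", "A")]
    assert back[0].info["CONTQ"] == pytest.approx(50.0)
    assert back[0].info["POPAF"] == pytest.approx(6.0)
    assert back[0].vaf == pytest.approx(0.3, abs=1e-6)
    assert back[0].adf == 2 and back[0].adr == 1


def test_read_mutations_vaf_and_multiallelic(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=1000>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:7,3\n"
        "chr1\t200\t.\tA\tC,T\t.\tPASS\t.\tGT:AD\t0/1:5,3,2\n"
        "chr1\t300\t.\tG\t<DEL>\t.\tPASS\t.\tGT:AD\t0/1:5,5\n")
    recs = gm.read_mutations(str(vcf))
    assert recs[0].vaf == pytest.approx(0.3) and recs[0].dp == 10
    assert len(recs) == 4  # multi-allelic split into two records
    assert {r.alt for r in recs[1:3]} == {"C", "T"}
    assert recs[3].vclass == "other"


def test_variant_classes_and_ref_check(tiny_bundle):
    assert MutationRecord("s", "chr1", 1, "A", "T").vclass == "SBS"
    assert MutationRecord("s", "chr1", 1, "CC", "TT").vclass == "DBS"
    assert MutationRecord("s", "chr1", 1, "C", "<DEL>").vclass == "other"
    assert MutationRecord("s", "chr1", 1, "CAT", "C").vclass == "other"
    ref_base = tiny_bundle.sequence("chr1", 4, 5)
    good = MutationRecord("s", "chr1", 5, ref_base, "T" if ref_base != "T" else "G")
    good.validate(tiny_bundle)
    bad_base = "A" if ref_base != "A" else "G"
    with pytest.raises(ConsistencyError):
        MutationRecord("s", "chr1", 5, bad_base, "T").validate(tiny_bundle)


# ---------------------------------------------------------------------------
# DBS merging
# ---------------------------------------------------------------------------

def _snv(sample, contig, pos, ref="C", alt="T"):
    return MutationRecord(sample, contig, pos, ref, alt)


def test_merge_adjacent_snvs_rules():
    recs = [_snv("s1", "chr1", 100), _snv("s1", "chr1", 101),       # adjacent -> DBS
            _snv("s1", "chr1", 200), _snv("s1", "chr1", 202),       # gap -> unchanged
            _snv("s1", "chr1", 300), _snv("s2", "chr1", 301)]       # other sample
    out = merge_adjacent_snvs(recs)
    dbs = [r for r in out if r.vclass == "DBS"]
    assert len(dbs) == 1 and dbs[0].pos == 100 and dbs[0].ref == "CC" and dbs[0].alt == "TT"
    sbs = [r for r in out if r.vclass == "SBS"]
    assert len(sbs) == len(recs) - 2  # count conservation


def test_merge_triplet_greedy_left_to_right():
    recs = [_snv("s", "chr1", p) for p in (10, 11, 12)]
    out = merge_adjacent_snvs(recs)
    assert [r.vclass for r in out] == ["DBS", "SBS"]
    assert out[0].pos == 10 and out[1].pos == 12


@given(st.lists(st.integers(1, 60), min_size=0, max_size=25, unique=True))
def test_merge_adjacent_is_idempotent(positions):
    recs = [_snv("s", "chr1", p) for p in sorted(positions)]
    once = merge_adjacent_snvs(recs)
    twice = merge_adjacent_snvs(once)
    assert [(r.pos, r.ref, r.alt) for r in once] == [(r.pos, r.ref, r.alt) for r in twice]


# ---------------------------------------------------------------------------
# context extraction, masks
# ---------------------------------------------------------------------------

def test_extract_context(tiny_bundle):
    seq = tiny_bundle.sequence("chr1", 0, 7)
    assert extract_context(tiny_bundle, "chr1", 3, 1) == seq[2:5]
    assert extract_context(tiny_bundle, "chr1", 0, 1) is None  # contig edge
    assert extract_context(tiny_bundle, "chr1", 2, 2) == seq[0:5]


def test_extract_context_skips_n():
    b = gm.ReferenceBundle({"c": encode("ACNGT")})
    assert extract_context(b, "c", 2, 1) is None
    assert extract_context(b, "c", 1, 1) is None


def test_mask_records_partition(tiny_bundle):
    rng = np.random.default_rng(0)
    recs = [_snv("s", "chr1", int(p)) for p in rng.integers(1, 200, 100)]
    mask = IntervalSet.from_pairs({"chr1": [(50, 120)]})
    kept = mask_records(recs, mask, "keep_inside")
    dropped = mask_records(recs, mask, "remove_inside")
    assert len(kept) + len(dropped) == 100
    assert all(50 <= r.pos0 < 120 for r in kept)
    # 1-based position 150 has pos0 149 inside [100, 200)
    one = [_snv("s", "chr1", 150)]
    m2 = IntervalSet.from_pairs({"chr1": [(100, 200)]})
    assert mask_records(one, m2, "keep_inside") == one
    assert mask_records(one, m2, "remove_inside") == []


# ---------------------------------------------------------------------------
# opportunity counting vs brute force
# ---------------------------------------------------------------------------

def brute_count(seq: str, lo: int, hi: int, k: int, collapse: bool) -> dict:
    """Literal O(L) scan counting k-mers with center inside [lo, hi)."""
    off = (k - 1) // 2
    out: dict[str, int] = {}
    for start in range(len(seq) - k + 1):
        center = start + off
        if not (lo <= center < hi):
            continue
        kmer = seq[start:start + k]
        if "N" in kmer:
            continue
        key = canonical_kmer(kmer) if collapse else kmer
        out[key] = out.get(key, 0) + 1
    return out


@pytest.mark.parametrize("k", [3, 4])
@pytest.mark.parametrize("collapse", [True, False])
def test_count_opportunities_matches_brute_force(k, collapse):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=3000))
    bundle = gm.ReferenceBundle({"c": encode(seq)})
    iv = IntervalSet.from_pairs({"c": [(100, 900), (1500, 2500)]})
    got = count_opportunities(bundle, iv, k=k, collapse_strands=collapse)
    expected: dict[str, int] = {}
    for lo, hi in [(100, 900), (1500, 2500)]:
        for key, n in brute_count(seq, lo, hi, k, collapse).items():
            expected[key] = expected.get(key, 0) + n
    assert got == expected


def test_count_opportunities_examples():
    bundle = gm.ReferenceBundle({"c": encode("ACCA")})
    assert count_opportunities(bundle, k=4, collapse_strands=False) == {"ACCA": 1}
    # conservation: total 3-mer windows = L - 2 when no Ns
    b2 = gm.ReferenceBundle({"c": encode("ACGTACGTACGT")})
    assert sum(count_opportunities(b2, k=3).values()) == 10
    empty = IntervalSet()
    assert count_opportunities(b2, empty, k=3) == {}


@given(st.text(alphabet="ACGT", min_size=3, max_size=60))
def test_canonical_kmer_involution(seq):
    for k in (3, 4):
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            assert canonical_kmer(kmer) == canonical_kmer(revcomp(kmer))


def test_coordinate_duality():
    rec = MutationRecord("s", "chr1", 150, "C", "T")
    assert rec.pos0 + 1 == rec.pos
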