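"""Shared genomic data model and I/O.

Coordinates are 0-based half-open everywhere inside the package; the VCF
boundary (1-based positions) converts on read/write.  Sequences are held as
numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4) so that context extraction
and opportunity counting are vectorized scans rather than per-base Python
loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

BASES = "ACGTN"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (N for anything non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ParseError(ValueError):
    """Malformed input file; message names file and offending line."""


class ConsistencyError(ValueError):
    """Inputs disagree with each other (e.g. contig named but absent)."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

class IntervalSet:
    """Per-contig sorted, non-overlapping half-open intervals [start, end)."""

    def __init__(self, intervals: dict[str, np.ndarray] | None = None):
        self._iv: dict[str, np.ndarray] = {}
        if intervals:
            for contig, arr in intervals.items():
                self._iv[contig] = self._normalize(np.asarray(arr, dtype=np.int64))

    @staticmethod
    def _normalize(arr: np.ndarray) -> np.ndarray:
        if arr.size == 0:
            return arr.reshape(0, 2)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    @classmethod
    def from_pairs(cls, mapping: dict[str, list[tuple[int, int]]]) -> "IntervalSet":
        return cls({c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in mapping.items()})

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
                try:
                    out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        return cls.from_pairs(out)

    def contigs(self) -> list[str]:
        return list(self._iv)

    def pairs(self, contig: str) -> np.ndarray:
        return self._iv.get(contig, np.empty((0, 2), dtype=np.int64))

    def contains(self, contig: str, positions) -> np.ndarray:
        """Vectorized point-in-interval test for 0-based positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        iv = self.pairs(contig)
        if iv.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < iv[idx[ok], 1]
        return ok

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._iv.values()))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for c in set(self._iv) | set(other._iv):
            out[c] = np.vstack([self.pairs(c), other.pairs(c)])
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for c in set(self._iv) & set(other._iv):
            a, b = self.pairs(c), other.pairs(c)
            res, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[c] = res
        return IntervalSet.from_pairs(out)

    def complement(self, contig_lengths: dict[str, int]) -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for c, length in contig_lengths.items():
            res, prev = [], 0
            for s, e in self.pairs(c):
                if s > prev:
                    res.append((prev, int(s)))
                prev = max(prev, int(e))
            if prev < length:
                res.append((prev, length))
            out[c] = res
        return IntervalSet.from_pairs(out)


# ---------------------------------------------------------------------------
# Numeric tracks
# ---------------------------------------------------------------------------

class NumericTrack:
    """Piecewise-constant genomic track.

    Per contig: sorted disjoint intervals with a float value.  Queries on
    uncovered positions return NaN, never a silent zero.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.data = data  # contig -> (starts, ends, values), sorted, disjoint

    @classmethod
    def from_arrays(cls, contig: str, starts, ends, values) -> "NumericTrack":
        order = np.argsort(np.asarray(starts))
        return cls({contig: (np.asarray(starts, dtype=np.int64)[order],
                             np.asarray(ends, dtype=np.int64)[order],
                             np.asarray(values, dtype=float)[order])})

    @classmethod
    def from_bedgraph(cls, path: str, strict: bool = False) -> "NumericTrack":
        """Read a bedGraph file.

        Overlapping intervals are resolved last-writer-wins with a warning,
        or raise in strict mode.
        """
        rows: dict[str, list[list]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ParseError(f"{path}:{ln}: expected 4 bedGraph columns")
                try:
                    rows.setdefault(parts[0], []).append([int(parts[1]), int(parts[2]), float(parts[3])])
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        data = {}
        for contig, rr in rows.items():
            res: list[list] = []
            for s, e, v in rr:  # file order; later lines win on overlap
                clipped = []
                for ps, pe, pv in res:
                    if pe <= s or ps >= e:
                        clipped.append([ps, pe, pv])
                        continue
                    if strict:
                        raise ParseError(f"{path}: overlapping intervals on {contig} at {s}")
                    log.warning("%s: overlapping bedGraph intervals on %s at %d; last writer wins", path, contig, s)
                    if ps < s:
                        clipped.append([ps, s, pv])
                    if pe > e:
                        clipped.append([e, pe, pv])
                clipped.append([s, e, v])
                res = sorted(clipped)
            arr = np.asarray(res, dtype=float)
            data[contig] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(data)

    @classmethod
    def from_wig(cls, path: str) -> "NumericTrack":
        """Minimal fixedStep/variableStep wiggle reader."""
        rows: dict[str, list[list]] = {}
        mode = contig = None
        start = step = span = 1
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith(("fixedStep", "variableStep")):
                    kv = dict(p.split("=") for p in line.split()[1:])
                    mode = line.split()[0]
                    contig = kv["chrom"]
                    span = int(kv.get("span", 1))
                    step = int(kv.get("step", 1))
                    start = int(kv.get("start", 1)) - 1  # wig is 1-based
                    continue
                if mode is None:
                    raise ParseError(f"{path}:{ln}: data before step declaration")
                parts = line.split()
                if mode == "fixedStep":
                    rows.setdefault(contig, []).append([start, start + span, float(parts[0])])
                    start += step
                else:
                    p = int(parts[0]) - 1
                    rows.setdefault(contig, []).append([p, p + span, float(parts[1])])
        data = {}
        for c, rr in rows.items():
            arr = np.asarray(sorted(rr), dtype=float)
            data[c] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(data)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for contig, (s, e, v) in self.data.items():
                for i in range(len(s)):
                    fh.write(f"{contig}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")

    def value_at(self, contig: str, positions) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        out = np.full(pos.shape, np.nan)
        if contig not in self.data:
            return out
        starts, ends, values = self.data[contig]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        out[ok] = values[idx[ok]]
        return out

    def window_means(self, contig: str, contig_length: int, window: int) -> np.ndarray:
        """Coverage-weighted mean per fixed window; NaN where uncovered."""
        n_win = -(-contig_length // window)
        sums = np.zeros(n_win)
        cov = np.zeros(n_win)
        if contig in self.data:
            starts, ends, values = self.data[contig]
            for s, e, v in zip(starts, ends, values):
                w0, w1 = s // window, (e - 1) // window
                for w in range(w0, w1 + 1):
                    lo, hi = max(s, w * window), min(e, (w + 1) * window, contig_length)
                    if hi > lo:
                        sums[w] += v * (hi - lo)
                        cov[w] += hi - lo
        with np.errstate(invalid="ignore"):
            return np.where(cov > 0, sums / np.maximum(cov, 1), np.nan)

    def covered_intervals(self) -> IntervalSet:
        return IntervalSet({c: np.column_stack([s, e]) for c, (s, e, _v) in self.data.items()})


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int  # 0-based body start (inclusive)
    end: int    # body end (exclusive)
    expression: float = 0.0
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start boundary (body start for '+', body end for '-')."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end boundary (first position past the body for '+')."""
        return self.end if self.strand == "+" else self.start

    @property
    def template_strand(self) -> str:
        return "-" if self.strand == "+" else "+"


class GeneSet:
    def __init__(self, genes: list[Gene]):
        for g in genes:
            if g.strand not in "+-":
                raise ConsistencyError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            if g.start >= g.end:
                raise ConsistencyError(f"gene {g.gene_id}: empty body")
            ex = sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if e1 > s2:
                    raise ConsistencyError(f"gene {g.gene_id}: overlapping exons")
        self.genes = list(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "contig": [g.contig for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "expression": [g.expression for g in self.genes],
            }
        )

    def body_intervals(self, strand: str | None = None) -> IntervalSet:
        out: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            if strand is None or g.strand == strand:
                out.setdefault(g.contig, []).append((g.start, g.end))
        return IntervalSet.from_pairs(out)

    @classmethod
    def from_table(cls, path: str) -> "GeneSet":
        """TSV with columns gene_id, contig, strand, start, end, expression
        and optional `exons` as semicolon-separated start-end pairs."""
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "contig", "strand", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        genes = []
        for _, row in df.iterrows():
            exons = []
            if "exons" in df.columns and isinstance(row.get("exons"), str) and row["exons"]:
                exons = [tuple(map(int, p.split("-"))) for p in row["exons"].split(";")]
            genes.append(
                Gene(str(row["gene_id"]), str(row["contig"]), str(row["strand"]),
                     int(row["start"]), int(row["end"]),
                     float(row.get("expression", 0.0)), exons)
            )
        return cls(genes)

    def to_table(self, path: str) -> None:
        df = self.df.copy()
        df["exons"] = [";".join(f"{s}-{e}" for s, e in g.exons) for g in self.genes]
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation records
# ---------------------------------------------------------------------------

ANNOTATION_KEYS = ("CONTQ", "SEQQ", "STRANDQ", "TLOD", "POPAF")


@dataclass
class MutationRecord:
    """One somatic variant (1-based VCF position convention)."""

    sample: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float = float("nan")
    dp: int = 0
    adf: int = 0  # alt-supporting forward reads
    adr: int = 0  # alt-supporting reverse reads
    info: dict = field(default_factory=dict)
    filter: str = "PASS"

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def vclass(self) -> str:
        a = set(self.ref) | set(self.alt)
        if not a <= set("ACGT"):
            return "other"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SBS"
        if len(self.ref) == 2 and len(self.alt) == 2:
            return "DBS"
        return "other"

    def validate(self, bundle: "ReferenceBundle | None" = None) -> None:
        if self.ref == self.alt:
            raise ConsistencyError(f"{self.contig}:{self.pos}: ref equals alt")
        if bundle is not None and self.vclass in ("SBS", "DBS"):
            ref_seq = bundle.sequence(self.contig, self.pos0, self.pos0 + len(self.ref))
            if ref_seq != self.ref:
                raise ConsistencyError(
                    f"{self.contig}:{self.pos}: ref {self.ref} != reference {ref_seq}")


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------

class ReferenceBundle:
    """Genome sequence + gene set + numeric tracks + interval masks."""

    def __init__(self, sequences: dict[str, np.ndarray], genes: GeneSet | None = None,
                 tracks: dict[str, NumericTrack] | None = None,
                 masks: dict[str, IntervalSet] | None = None):
        self._seq = sequences
        self.genes = genes if genes is not None else GeneSet([])
        self.tracks = tracks or {}
        self.masks = masks or {}
        lengths = self.contig_lengths
        for g in self.genes:
            if g.contig not in lengths:
                raise ConsistencyError(f"gene {g.gene_id}: contig {g.contig!r} absent from FASTA")
            if not (0 <= g.start < g.end <= lengths[g.contig]):
                raise ConsistencyError(f"gene {g.gene_id}: outside contig bounds")

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, len(codes)) for name, codes in self._seq.items()]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(codes) for name, codes in self._seq.items()}

    def codes(self, contig: str) -> np.ndarray:
        return self._seq[contig]

    def sequence(self, contig: str, start: int, end: int) -> str:
        if contig not in self._seq:
            raise ConsistencyError(f"unknown contig {contig!r}")
        return decode(self._seq[contig][start:end])

    def genome_intervals(self) -> IntervalSet:
        return IntervalSet.from_pairs({c: [(0, n)] for c, n in self.contigs})

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, codes in self._seq.items():
                fh.write(f">{name}\n")
                s = decode(codes)
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")


def read_reference(fasta_path: str, annotation_path: str | None = None,
                   track_paths: dict[str, str] | None = None,
                   mask_paths: dict[str, str] | None = None,
                   strict_tracks: bool = False) -> ReferenceBundle:
    """Load FASTA + gene table + bedGraph/wig tracks + BED masks."""
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    sequences = {name: encode(str(fa[name][:])) for name in fa.keys()}
    genes = GeneSet.from_table(annotation_path) if annotation_path else GeneSet([])
    tracks = {}
    for name, path in (track_paths or {}).items():
        if path.endswith(".wig"):
            tracks[name] = NumericTrack.from_wig(path)
        else:
            tracks[name] = NumericTrack.from_bedgraph(path, strict=strict_tracks)
        for contig in tracks[name].data:
            if contig not in sequences:
                raise ConsistencyError(f"track {name}: contig {contig!r} absent from FASTA")
    masks = {name: IntervalSet.from_bed(path) for name, path in (mask_paths or {}).items()}
    return ReferenceBundle(sequences, genes, tracks, masks)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_mutations(vcf_path: str, sample: str | None = None) -> list[MutationRecord]:
    """Parse a VCF into MutationRecords, one per ALT allele.

    Multi-allelic records are split; symbolic alleles become class "other";
    missing annotations stay missing (not imputed).
    """
    records: list[MutationRecord] = []
    vf = pysam.VariantFile(vcf_path)
    sample_names = list(vf.header.samples)
    use_sample = sample or (sample_names[0] if sample_names else "sample")
    for var in vf:
        for alt in var.alts or ():
            info = {}
            for key in ANNOTATION_KEYS:
                if key in var.info:
                    val = var.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            vaf, dp, adf, adr = float("nan"), 0, 0, 0
            if sample_names:
                fmt = var.samples[use_sample]
                if "DP" in fmt and fmt["DP"] is not None:
                    dp = int(fmt["DP"])
                ad = fmt.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    alt_idx = (var.alts.index(alt) + 1) if alt in var.alts else 1
                    alt_reads = int(ad[alt_idx]) if ad[alt_idx] is not None else 0
                    total = int(sum(x for x in ad if x is not None))
                    dp = dp or total
                    if total > 0:
                        vaf = alt_reads / total
                af = fmt.get("AF")
                if af is not None and np.isnan(vaf):
                    vaf = float(af[0] if isinstance(af, tuple) else af)
                for key, fkey in (("adf", "ADF"), ("adr", "ADR")):
                    v = fmt.get(fkey)
                    if v is not None:
                        val = v[1] if isinstance(v, tuple) and len(v) > 1 else v
                        if key == "adf":
                            adf = int(val if not isinstance(val, tuple) else val[0])
                        else:
                            adr = int(val if not isinstance(val, tuple) else val[0])
            filt = ";".join(var.filter.keys()) if list(var.filter.keys()) else "PASS"
            records.append(MutationRecord(use_sample, var.contig, var.pos, var.ref, alt,
                                          vaf, dp, adf, adr, info, filt))
    return records


def write_vcf(records: list[MutationRecord], path: str,
              contigs: list[tuple[str, int]], sample: str | None = None) -> None:
    """Write records for one sample to an uncompressed VCF."""
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    for key in ANNOTATION_KEYS:
        header.info.add(key, 1, "Float", f"{key} caller annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("ADF", "R", "Integer", "Forward-strand allelic depths")
    header.formats.add("ADR", "R", "Integer", "Reverse-strand allelic depths")
    header.formats.add("AF", "A", "Float", "Allele fraction")
    header.filters.add("artifact", None, None, "Flagged by a filter stage")
    sample_name = sample or (records[0].sample if records else "sample")
    header.add_sample(sample_name)
    vf = pysam.VariantFile(path, "w", header=header)
    for rec in sorted(records, key=lambda r: (r.contig, r.pos)):
        alt_reads = rec.adf + rec.adr
        ref_reads = max(rec.dp - alt_reads, 0)
        var = vf.new_record(
            contig=rec.contig, start=rec.pos0, stop=rec.pos0 + len(rec.ref),
            alleles=(rec.ref, rec.alt),
            filter="PASS" if rec.filter == "PASS" else "artifact")
        for key, val in rec.info.items():
            if key in ANNOTATION_KEYS and val is not None and not np.isnan(val):
                var.info[key] = float(val)
        var.samples[sample_name]["GT"] = (0, 1)
        var.samples[sample_name]["DP"] = int(rec.dp)
        var.samples[sample_name]["AD"] = (ref_reads, alt_reads)
        var.samples[sample_name]["ADF"] = (0, rec.adf)
        var.samples[sample_name]["ADR"] = (0, rec.adr)
        if not np.isnan(rec.vaf):
            var.samples[sample_name]["AF"] = (float(rec.vaf),)
        vf.write(var)
    vf.close()


def merge_adjacent_snvs(records: list[MutationRecord]) -> list[MutationRecord]:
    """Merge same-sample SBS pairs at adjacent positions into one DBS.

    Runs of >=3 adjacent SNVs merge greedily left-to-right with a warning.
    Idempotent: DBS records are never merged further.
    """
    ordered = sorted(records, key=lambda r: (r.sample, r.contig, r.pos))
    out: list[MutationRecord] = []
    i = 0
    while i < len(ordered):
        a = ordered[i]
        if (a.vclass == "SBS" and i + 1 < len(ordered)):
            b = ordered[i + 1]
            if (b.vclass == "SBS" and b.sample == a.sample and b.contig == a.contig
                    and b.pos == a.pos + 1):
                if (i + 2 < len(ordered) and ordered[i + 2].vclass == "SBS"
                        and ordered[i + 2].sample == a.sample
                        and ordered[i + 2].contig == a.contig
                        and ordered[i + 2].pos == a.pos + 2):
                    log.warning("run of >=3 adjacent SNVs at %s:%d; merging first pair",
                                a.contig, a.pos)
                vafs = [v for v in (a.vaf, b.vaf) if not np.isnan(v)]
                merged = replace(a, ref=a.ref + b.ref, alt=a.alt + b.alt,
                                 dp=min(a.dp, b.dp) if a.dp and b.dp else max(a.dp, b.dp),
                                 vaf=float(np.mean(vafs)) if vafs else float("nan"))
                out.append(merged)
                i += 2
                continue
        out.append(a)
        i += 1
    return out


def mask_records(records: list[MutationRecord], mask: IntervalSet,
                 mode: str = "keep_inside") -> list[MutationRecord]:
    """Partition records by point-in-interval test on the ref-allele start."""
    if mode not in ("keep_inside", "remove_inside"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for rec in records:
        inside = bool(mask.contains(rec.contig, rec.pos0)[0])
        if inside == (mode == "keep_inside"):
            out.append(rec)
    return out


def extract_context(bundle: ReferenceBundle, contig: str, pos0: int,
                    flank: int = 1) -> str | None:
    """(2*flank+1)-mer centered on pos0; None if out of bounds or containing N."""
    length = bundle.contig_lengths[contig]
    if pos0 - flank < 0 or pos0 + flank + 1 > length:
        return None
    ctx = bundle.sequence(contig, pos0 - flank, pos0 + flank + 1)
    if "N" in ctx:
        return None
    return ctx


# ---------------------------------------------------------------------------
# K-mer opportunity counting
# ---------------------------------------------------------------------------

def _kmer_string(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def canonical_kmer(kmer: str) -> str:
    """Pyrimidine-centric representative for odd k; for even k, keep the
    orientation whose central dinucleotide is a pyrimidine pair, falling
    back to the lexicographic minimum for mixed centers."""
    rc = revcomp(kmer)
    k = len(kmer)
    if k % 2 == 1:
        return kmer if kmer[k // 2] in PYRIMIDINES else rc
    c1, c2 = kmer[k // 2 - 1], kmer[k // 2]
    if c1 in PYRIMIDINES and c2 in PYRIMIDINES:
        return kmer
    if c1 in PURINES and c2 in PURINES:
        return rc
    return min(kmer, rc)


def kmer_positions(bundle: ReferenceBundle, contig: str, k: int):
    """Plus-strand k-mer ids for every start position of the contig.

    Returns (start_positions, kmer_ids, valid_mask); invalid = contains N.
    k-mer id is the base-4 big-endian encoding of the plus-strand k-mer.
    """
    codes = bundle.codes(contig)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, bool)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        valid &= c != 4
        ids = ids * 4 + np.where(c == 4, 0, c).astype(np.int64)
    return np.arange(n, dtype=np.int64), ids, valid


def count_opportunities(bundle: ReferenceBundle, intervals: IntervalSet | None = None,
                        k: int = 3, collapse_strands: bool = True) -> dict[str, int]:
    """Count k-mers whose center (odd k) or central dinucleotide (even k)
    lies inside `intervals` (whole genome when None).

    With collapse_strands, each k-mer pools with its reverse complement
    under the canonical representative from :func:`canonical_kmer`.
    """
    if intervals is None:
        intervals = bundle.genome_intervals()
    counts = np.zeros(4 ** k, dtype=np.int64)
    off = (k - 1) // 2  # center offset from k-mer start
    for contig, _length in bundle.contigs:
        starts, ids, valid = kmer_positions(bundle, contig, k)
        if starts.size == 0:
            continue
        centers = starts + off
        sel = valid & intervals.contains(contig, centers)
        counts += np.bincount(ids[sel], minlength=4 ** k)
    out: dict[str, int] = {}
    for idx in np.nonzero(counts)[0]:
        kmer = _kmer_string(int(idx), k)
        key = canonical_kmer(kmer) if collapse_strands else kmer
        out[key] = out.get(key, 0) + int(counts[idx])
    return out
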