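"""Protein-level consequence annotation and damaging/silent summaries.

One canonical transcript per gene (the longest CDS); exonic substitutions
are classified by codon rewrite into silent / missense / nonsense, with
2-bp splice windows at intron edges counted as damaging.  Doublets are
applied codon-aware (both bases substituted before translation; when the
doublet spans two codons, both are evaluated and the worst consequence
wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .classify import assign_gene, records_frame
from .genome_model import MutationRecord, ReferenceBundle, revcomp

log = logging.getLogger(__name__)

DAMAGING = ("missense", "nonsense", "splice_site")
SPLICE_WINDOW = 2  # bp at each intron edge


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 0-based half-open
    canonical: bool = True

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def splice_windows(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, e1 + SPLICE_WINDOW))
            out.append((s2 - SPLICE_WINDOW, s2))
        return out


class TranscriptModel:
    def __init__(self, transcripts: list[Transcript]):
        for t in transcripts:
            if t.cds_length % 3:
                raise ValueError(f"{t.transcript_id}: CDS length not divisible by 3")
            ex = sorted(t.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if e1 > s2:
                    raise ValueError(f"{t.transcript_id}: overlapping exons")
        self.transcripts = list(transcripts)

    @classmethod
    def from_bundle(cls, bundle: ReferenceBundle) -> "TranscriptModel":
        """Canonical transcript per gene from the bundle's exon structures
        (longest CDS wins when a gene carries alternatives)."""
        ts = [Transcript(f"{g.gene_id}.t1", g.gene_id, g.contig, g.strand, list(g.exons))
              for g in bundle.genes if g.exons]
        return cls(ts)



def cds_sequence(t: Transcript, bundle: ReferenceBundle,
                 edits: dict[int, str] | None = None) -> str:
    """Spliced CDS in reading orientation, optionally with genomic point
    edits {pos0: base} applied first."""
    parts = []
    for s, e in t.exons:
        seq = bundle.sequence(t.contig, s, e)
        if edits:
            seq = list(seq)
            for p, b in edits.items():
                if s <= p < e:
                    seq[p - s] = b
            seq = "".join(seq)
        parts.append(seq)
    cds = "".join(parts)
    return cds if t.strand == "+" else revcomp(cds)


def _worst(calls: list[str]) -> str:
    for c in ("nonsense", "missense", "silent"):
        if c in calls:
            return c
    return "silent"


def annotate_consequence(rec: MutationRecord, model: TranscriptModel,
                         bundle: ReferenceBundle) -> str:
    """Consequence of one SBS/DBS against the canonical transcript:
    silent, missense, nonsense, splice_site or noncoding."""
    if rec.vclass not in ("SBS", "DBS"):
        return "noncoding"
    positions = range(rec.pos0, rec.pos0 + len(rec.ref))
    hits = []
    for t in model.transcripts:
        if t.contig != rec.contig:
            continue
        for s, e in t.splice_windows():
            if any(s <= p < e for p in positions):
                return "splice_site"
        if any(s <= p < e for s, e in t.exons for p in positions):
            hits.append(t)
    if not hits:
        return "noncoding"
    if len(hits) > 1:  # overlapping canonical transcripts: longest CDS wins
        hits.sort(key=lambda t: -t.cds_length)
        log.debug("record %s:%d overlaps %d transcripts; using %s",
                  rec.contig, rec.pos, len(hits), hits[0].transcript_id)
    t = hits[0]
    edits = {rec.pos0 + i: b for i, b in enumerate(rec.alt)}
    ref_cds = cds_sequence(t, bundle)
    alt_cds = cds_sequence(t, bundle, edits)
    if len(ref_cds) != len(alt_cds):
        return "noncoding"
    calls = []
    for i in range(0, len(ref_cds) - 2, 3):
        c_ref, c_alt = ref_cds[i:i + 3], alt_cds[i:i + 3]
        if c_ref == c_alt:
            continue
        aa_ref = str(Seq(c_ref).translate())
        aa_alt = str(Seq(c_alt).translate())
        if aa_alt == aa_ref:
            calls.append("silent")
        elif aa_alt == "*":
            calls.append("nonsense")
        else:
            calls.append("missense")
    if not calls:  # alleles differ but CDS untouched (partially exonic DBS edge)
        return "noncoding"
    return _worst(calls)


def annotate_frame(records, model: TranscriptModel, bundle: ReferenceBundle) -> pd.DataFrame:
    """records_frame plus a `consequence` column (one call per record)."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    if "strand_class" not in df.columns:
        df = assign_gene(df, bundle)
    recs = [MutationRecord(r.sample, r.contig, r.pos0 + 1, r.ref, r.alt)
            for r in df.itertuples()]
    df = df.copy()
    df["consequence"] = [annotate_consequence(r, model, bundle) for r in recs]
    return df


MUTATION_CLASSES = ("C>T SBS", "CC>TT DBS", "other SBS")


def _class_of(row) -> str | None:
    if row.vclass == "SBS" and row.label is not None:
        return "C>T SBS" if "C>T" in row.label else "other SBS"
    if row.vclass == "DBS" and row.label is not None:
        return "CC>TT DBS"
    return None


def impact_summaries(annotated: pd.DataFrame) -> pd.DataFrame:
    """Damaging/silent ratios per sample, mutation class and lesion strand.

    Expects the output of :func:`annotate_frame`.  Ratios with zero silent
    count are +inf; the exonic fraction counts exonic (silent or damaging)
    records over all records per sample.
    """
    df = annotated.copy()
    df["mclass"] = [(_class_of(r)) for r in df.itertuples()]
    rows = []
    for sample, sub in df.groupby("sample"):
        exonic = sub["consequence"].isin(DAMAGING[:2] + ("silent",)) | (
            sub["consequence"] == "splice_site")
        base = {"sample": sample, "exonic_fraction": float(exonic.mean())}
        for mclass in MUTATION_CLASSES:
            for strand in (None, "transcribed", "untranscribed"):
                s = sub[(sub["mclass"] == mclass)]
                if strand is not None:
                    s = s[s["strand_class"] == strand]
                dam = int(s["consequence"].isin(DAMAGING).sum())
                sil = int((s["consequence"] == "silent").sum())
                key = mclass if strand is None else f"{mclass}|{strand}"
                rows.append({**base, "class": key, "damaging": dam, "silent": sil,
                             "ratio": dam / sil if sil else (np.inf if dam else np.nan)})
    return pd.DataFrame(rows)


def exhaustive_code_ratio(model: TranscriptModel, bundle: ReferenceBundle,
                          mclass: str = "C>T SBS") -> dict:
    """Brute-force damaging/silent ratio: enumerate every possible
    substitution of the class at every eligible exonic position.

    C>T SBS enumerates plus-strand C>T and G>A; CC>TT DBS enumerates
    doublets at plus-strand CC and GG sites inside exons; other SBS
    enumerates all remaining single-base changes.
    """
    counts = {"damaging": 0, "silent": 0, "noncoding": 0}
    for t in model.transcripts:
        for s, e in t.exons:
            seq = bundle.sequence(t.contig, s, e)
            for i, base in enumerate(seq):
                pos0 = s + i
                if mclass == "C>T SBS":
                    subs = [("C", "T")] if base == "C" else ([("G", "A")] if base == "G" else [])
                elif mclass == "other SBS":
                    subs = [(base, a) for a in "ACGT"
                            if a != base and not (base == "C" and a == "T")
                            and not (base == "G" and a == "A")]
                elif mclass == "CC>TT DBS":
                    if i + 1 < len(seq) and seq[i:i + 2] == "CC":
                        subs = [("CC", "TT")]
                    elif i + 1 < len(seq) and seq[i:i + 2] == "GG":
                        subs = [("GG", "AA")]
                    else:
                        subs = []
                else:
                    raise ValueError(f"unknown class {mclass!r}")
                for ref, alt in subs:
                    rec = MutationRecord("enum", t.contig, pos0 + 1, ref, alt)
                    call = annotate_consequence(rec, model, bundle)
                    if call in DAMAGING:
                        counts["damaging"] += 1
                    elif call == "silent":
                        counts["silent"] += 1
                    else:
                        counts["noncoding"] += 1
    ratio = (counts["damaging"] / counts["silent"] if counts["silent"]
             else (np.inf if counts["damaging"] else np.nan))
    return {**counts, "ratio": ratio}
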