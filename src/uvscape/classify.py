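"""Pyrimidine-centric mutation classification shared by all analyses.

The 96 single-base-substitution classes follow the standard trinucleotide
catalog: six substitution types from a pyrimidine reference (C>A, C>G, C>T,
T>A, T>C, T>G), each in 16 5'/3' flank combinations, labelled ``X[R>A]Z``.
Purine-reference mutations are mapped to the reverse-complement class; the
strand that carried the pyrimidine is retained as the lesion strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_model import (MutationRecord, PYRIMIDINES, ReferenceBundle,
                           extract_context, revcomp)

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = "ACGT"

SBS96_LABELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUB_TYPES for five in FLANKS for three in FLANKS
)

#: C>T classes with at least one flanking pyrimidine (YC>YT or CY>TY) —
#: the canonical UV photoproduct contexts (12 classes).
UV12_LABELS = tuple(
    lab for lab in SBS96_LABELS
    if lab[2:5] == "C>T" and (lab[0] in PYRIMIDINES or lab[6] in PYRIMIDINES)
)

DBS_TETRA_LABELS = tuple(
    f"{five}[CC>TT]{three}" for five in FLANKS for three in FLANKS
)

_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def label_context(label: str) -> str:
    """Trinucleotide context string of an SBS-96 label (``T[C>T]A`` -> ``TCA``)."""
    return label[0] + label[2] + label[6]


def sbs96_label(ref: str, alt: str, context: str) -> str | None:
    """Classify one SBS given its plus-strand trinucleotide context.

    Returns None for invalid contexts (N or mismatched center).
    """
    if context is None or len(context) != 3 or "N" in context:
        return None
    if context[1] != ref:
        return None
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def dbs_tetra_label(ref: str, alt: str, context4: str) -> str | None:
    """Classify a CC>TT-type doublet into its W[CC>TT]Z tetranucleotide class.

    `context4` is the plus-strand 4-mer around the doublet.  GG>AA events
    map through the reverse complement.  Returns None for other doublets.
    """
    if context4 is None or len(context4) != 4 or "N" in context4:
        return None
    if ref == "GG" and alt == "AA":
        context4 = revcomp(context4)
        ref, alt = "CC", "TT"
    if ref != "CC" or alt != "TT" or context4[1:3] != "CC":
        return None
    return f"{context4[0]}[CC>TT]{context4[3]}"


def records_frame(records: list[MutationRecord], bundle: ReferenceBundle | None = None) -> pd.DataFrame:
    """Tabulate records with derived classification columns.

    Columns: sample, contig, pos0, ref, alt, vclass, context (plus-strand,
    length 3 for SBS / 4 for DBS, None if invalid), label (SBS-96 or DBS
    tetra class), pyr_strand (strand carrying the pyrimidine of the
    canonical class; None if unclassifiable).
    """
    rows = []
    for rec in records:
        vclass = rec.vclass
        context = label = pyr_strand = None
        if bundle is not None and vclass == "SBS":
            context = extract_context(bundle, rec.contig, rec.pos0, 1)
            label = sbs96_label(rec.ref, rec.alt, context)
            if label is not None:
                pyr_strand = "+" if rec.ref in PYRIMIDINES else "-"
        elif bundle is not None and vclass == "DBS":
            length = bundle.contig_lengths[rec.contig]
            if rec.pos0 - 1 >= 0 and rec.pos0 + 3 <= length:
                context = bundle.sequence(rec.contig, rec.pos0 - 1, rec.pos0 + 3)
                if "N" in context:
                    context = None
            label = dbs_tetra_label(rec.ref, rec.alt, context)
            if label is not None:
                pyr_strand = "+" if rec.ref == "CC" else "-"
        rows.append((rec.sample, rec.contig, rec.pos0, rec.ref, rec.alt,
                     vclass, context, label, pyr_strand, rec.vaf))
    return pd.DataFrame(rows, columns=["sample", "contig", "pos0", "ref", "alt",
                                       "vclass", "context", "label", "pyr_strand", "vaf"])


def assign_gene(df: pd.DataFrame, bundle: ReferenceBundle) -> pd.DataFrame:
    """Attach gene_id / gene_strand / expression for records inside single
    gene bodies; records in territory covered by genes on both strands get
    gene_id None and both_strands=True (excluded from stranded analyses)."""
    out = df.reset_index(drop=True).copy()
    df = out
    gene_id = np.full(len(df), None, dtype=object)
    gene_strand = np.full(len(df), None, dtype=object)
    expression = np.full(len(df), np.nan)
    both = np.zeros(len(df), dtype=bool)
    plus = bundle.genes.body_intervals("+")
    minus = bundle.genes.body_intervals("-")
    for contig, sub in df.groupby("contig"):
        pos = sub["pos0"].to_numpy()
        in_plus = plus.contains(contig, pos)
        in_minus = minus.contains(contig, pos)
        both_here = in_plus & in_minus
        both[sub.index] = both_here
        for g in bundle.genes:
            if g.contig != contig:
                continue
            hit = (pos >= g.start) & (pos < g.end) & ~both_here
            idx = sub.index[hit]
            gene_id[idx] = g.gene_id
            gene_strand[idx] = g.strand
            expression[idx] = g.expression
    out["gene_id"] = gene_id
    out["gene_strand"] = gene_strand
    out["expression"] = expression
    out["both_strands"] = both
    # lesion on the template strand of its gene => "transcribed"
    tmpl = np.where(pd.Series(gene_strand) == "+", "-",
                    np.where(pd.Series(gene_strand) == "-", "+", None))
    ls = out["pyr_strand"].to_numpy(dtype=object)
    strand_class = np.full(len(df), None, dtype=object)
    genic = pd.notna(pd.Series(gene_strand)) & pd.notna(out["pyr_strand"])
    strand_class[genic] = np.where(ls[genic.to_numpy()] == tmpl[genic.to_numpy()],
                                   "transcribed", "untranscribed")
    out["strand_class"] = strand_class
    return out
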