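"""Dimer translesion bias: 3' versus 5' mutation allocation inside
unambiguous pyrimidine dimers.

In a 4-mer like ACCA the central CC is the only possible pyrimidine dimer
on that strand (purine flanks rule out alternative registers), so a C>T at
either central position can be attributed to the 5' or 3' base of one
dimer.  Error-prone backup bypass of dimers (absent polymerase eta) puts
almost all errors on the 3' base; the statistics here quantify that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import records_frame
from .genome_model import (PURINES, PYRIMIDINES, ReferenceBundle,
                           count_opportunities, revcomp)


@dataclass
class DimerBiasResult:
    per_sample: pd.DataFrame  # n_5prime, n_3prime, fraction_3prime, CI, ratio_5_3
    dimer_context: str
    pooled_n5: int
    pooled_n3: int

    @property
    def fraction_3prime(self) -> float:
        tot = self.pooled_n3 + self.pooled_n5
        return self.pooled_n3 / tot if tot else np.nan

    def pooled_ci(self, conf: float = 0.95) -> tuple[float, float]:
        tot = self.pooled_n3 + self.pooled_n5
        if tot == 0:
            return (np.nan, np.nan)
        ci = stats.binomtest(self.pooled_n3, tot).proportion_ci(conf, method="exact")
        return (float(ci.low), float(ci.high))

    @property
    def ratio_5_3(self) -> float:
        return self.pooled_n5 / self.pooled_n3 if self.pooled_n3 else np.inf


def _validate_dimer_context(ctx: str) -> None:
    if len(ctx) != 4:
        raise ValueError("dimer context must be a 4-mer")
    if not (ctx[1] in PYRIMIDINES and ctx[2] in PYRIMIDINES
            and ctx[0] in PURINES and ctx[3] in PURINES):
        raise ValueError(
            f"{ctx}: central dinucleotide must be a pyrimidine pair flanked by purines")


def dimer_positions(records, bundle: ReferenceBundle,
                    dimer_context: str = "ACCA",
                    alt_bases: tuple[str, ...] | None = None) -> DimerBiasResult:
    """Allocate qualifying SBS to the 5' or 3' base of the central dimer.

    A mutation qualifies when its plus-strand 4-mer context matches
    `dimer_context` (or its reverse complement, handled by canonical
    mapping) at the second or third position.  For C-dimers the default
    counts C>T; for T-dimers (e.g. ATTA) T>A and T>C, matching the
    mutation types attributable to error-prone dimer bypass.  `alt_bases`
    restricts the counted ALT alleles (on the lesion strand).
    """
    _validate_dimer_context(dimer_context)
    if alt_bases is None:
        alt_bases = ("T",) if dimer_context[1] == "C" else ("A", "C")
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    sbs = df[(df["vclass"] == "SBS") & df["pyr_strand"].notna()]
    rc = revcomp(dimer_context)
    comp = str.maketrans("ACGT", "TGCA")
    rows = []
    for rec in sbs.itertuples():
        length = bundle.contig_lengths[rec.contig]
        pyr_plus = rec.pyr_strand == "+"
        ref = rec.ref if pyr_plus else rec.ref.translate(comp)
        alt = rec.alt if pyr_plus else rec.alt.translate(comp)
        if ref != dimer_context[1] or alt not in alt_bases:
            continue
        # try the mutation as the 5' base then as the 3' base of the dimer
        for which, lo in (("5", rec.pos0 - 1), ("3", rec.pos0 - 2)):
            if lo < 0 or lo + 4 > length:
                continue
            quad = bundle.sequence(rec.contig, lo, lo + 4)
            target = dimer_context if pyr_plus else rc
            if quad == target:
                pos_in = ("5" if pyr_plus else "3") if which == "5" else ("3" if pyr_plus else "5")
                # on the minus strand the 4-mer reads reverse-complemented,
                # so the genomic-left central base is the lesion-strand 3' base
                rows.append((rec.sample, pos_in))
    tab = pd.DataFrame(rows, columns=["sample", "position"])
    per_sample = []
    for sample, sub in tab.groupby("sample"):
        n5 = int((sub["position"] == "5").sum())
        n3 = int((sub["position"] == "3").sum())
        tot = n5 + n3
        if tot:
            ci = stats.binomtest(n3, tot).proportion_ci(0.95, method="exact")
            lo_ci, hi_ci = float(ci.low), float(ci.high)
        else:
            lo_ci = hi_ci = np.nan
        per_sample.append({"sample": sample, "n_5prime": n5, "n_3prime": n3,
                           "fraction_3prime": n3 / tot if tot else np.nan,
                           "ci_low": lo_ci, "ci_high": hi_ci,
                           "ratio_5_3": n5 / n3 if n3 else np.inf})
    ps = pd.DataFrame(per_sample).set_index("sample") if per_sample else pd.DataFrame(
        columns=["n_5prime", "n_3prime", "fraction_3prime", "ci_low", "ci_high", "ratio_5_3"])
    return DimerBiasResult(ps, dimer_context,
                           int(ps["n_5prime"].sum()) if len(ps) else 0,
                           int(ps["n_3prime"].sum()) if len(ps) else 0)


def _count_quad_mutations(df: pd.DataFrame, bundle: ReferenceBundle,
                          quad: str, mut_pos: int, alt: str) -> pd.Series:
    """Per-sample counts of SBS at position `mut_pos` of plus-strand 4-mer
    `quad` (or the mirrored position of its reverse complement)."""
    rc = revcomp(quad)
    comp = str.maketrans("ACGT", "TGCA")
    ref = quad[mut_pos]
    counts: dict[str, int] = {}
    sbs = df[df["vclass"] == "SBS"]
    for rec in sbs.itertuples():
        length = bundle.contig_lengths[rec.contig]
        lo = rec.pos0 - mut_pos
        if lo >= 0 and lo + 4 <= length and rec.ref == ref and rec.alt == alt:
            if bundle.sequence(rec.contig, lo, lo + 4) == quad:
                counts[rec.sample] = counts.get(rec.sample, 0) + 1
                continue
        # reverse-complement orientation: position mirrors to 3 - mut_pos
        lo = rec.pos0 - (3 - mut_pos)
        if (lo >= 0 and lo + 4 <= length and rec.ref == ref.translate(comp)
                and rec.alt == alt.translate(comp)):
            if bundle.sequence(rec.contig, lo, lo + 4) == rc:
                counts[rec.sample] = counts.get(rec.sample, 0) + 1
    return pd.Series(counts, dtype=float)


def ct_tc_normalized_ratio(records, bundle: ReferenceBundle) -> pd.DataFrame:
    """Opportunity-normalized ratio of ATCA>ATTA to ACTA>ATTA mutations.

    ratio = [N(ATCA>ATTA)/O(ATCA)] / [N(ACTA>ATTA)/O(ACTA)]; the numerator
    mutates the 3' C of a TC dimer, the denominator the 5' C of a CT dimer,
    so the ratio reads out the 3' error preference after correcting for the
    different genomic frequencies of the two 4-mers.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    opp = count_opportunities(bundle, k=4, collapse_strands=True)
    o_atca = opp.get("ATCA", 0)
    o_acta = opp.get("ACTA", 0)
    n_atca = _count_quad_mutations(df, bundle, "ATCA", 2, "T")
    n_acta = _count_quad_mutations(df, bundle, "ACTA", 1, "T")
    samples = sorted(df["sample"].unique())
    out = pd.DataFrame(index=samples)
    out["n_atca_to_atta"] = n_atca.reindex(samples).fillna(0)
    out["n_acta_to_atta"] = n_acta.reindex(samples).fillna(0)
    out["o_atca"] = o_atca
    out["o_acta"] = o_acta
    num = out["n_atca_to_atta"] / o_atca if o_atca else np.nan
    den = out["n_acta_to_atta"] / o_acta if o_acta else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = ratio.where((out["n_atca_to_atta"] + out["n_acta_to_atta"]) > 0)
    out["normalized_ratio"] = ratio.replace([np.inf, -np.inf], np.inf)
    return out


def context_correlations(class_counts: pd.DataFrame,
                         class_pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson correlation of per-sample mutation counts between classes.

    `class_counts`: samples x class columns.  Zero-variance vectors give a
    missing correlation.
    """
    if len(class_counts) < 4:
        raise ValueError("need at least four samples for context correlations")
    rows = []
    for a, b in class_pairs:
        x = class_counts[a].to_numpy(dtype=float)
        y = class_counts[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"class_a": a, "class_b": b, "r": np.nan, "p": np.nan})
        else:
            r, p = stats.pearsonr(x, y)
            rows.append({"class_a": a, "class_b": b, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
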