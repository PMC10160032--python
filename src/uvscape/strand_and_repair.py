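"""Transcriptional strand bias and repair-activity statistics.

TRB (transcriptional bias) is the ratio of lesion-strand mutation counts,
untranscribed over transcribed, computed on UV-context C>T mutations by
default: active transcription-coupled repair depresses the transcribed
(template) strand, pushing the ratio above 1.  The module also builds
TSS/TES-anchored stranded meta-profiles (the "extended TC-NER" readout),
aggregates excision-repair (XR-seq-like) tracks, and estimates relative
GG-NER efficiency between groups from their TRBs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import UV12_LABELS, assign_gene, label_context, records_frame
from .genome_model import (Gene, NumericTrack, ReferenceBundle,
                           canonical_kmer, kmer_positions)
from .topography import _CANON3_INDEX, _canonical_maps

log = logging.getLogger(__name__)

PURINE_CT_LABELS = tuple(l for l in (  # C>A classes: lesions on the purine strand
    f"{x}[C>A]{z}" for x in "ACGT" for z in "ACGT"))


@dataclass
class TRBResult:
    per_sample: pd.DataFrame  # untranscribed, transcribed, trb
    pooled_untranscribed: int
    pooled_transcribed: int
    pooled_trb: float
    ci: tuple[float, float]
    lesion_base: str

    def __repr__(self):
        return (f"TRBResult(pooled={self.pooled_trb:.3f}, "
                f"ci=({self.ci[0]:.3f}, {self.ci[1]:.3f}), n={len(self.per_sample)})")


def _lesion_strand_counts(df: pd.DataFrame, lesion_base: str) -> pd.DataFrame:
    counts = df.groupby(["sample", "strand_class"]).size().unstack(fill_value=0)
    for col in ("transcribed", "untranscribed"):
        if col not in counts:
            counts[col] = 0
    if lesion_base == "purine":
        # the damaged base sits on the purine strand: strand labels flip
        counts = counts.rename(columns={"transcribed": "untranscribed",
                                        "untranscribed": "transcribed"})
    return counts[["untranscribed", "transcribed"]]


def transcriptional_bias(records, bundle: ReferenceBundle,
                         lesion_base: str = "pyrimidine",
                         class_filter=UV12_LABELS,
                         n_boot: int = 1000, seed: int = 0) -> TRBResult:
    """TRB = N(lesion on untranscribed strand) / N(lesion on transcribed).

    Counts are restricted to `class_filter` mutations inside single-strand
    gene bodies; the bootstrap CI resamples mutations (seeded).
    """
    if lesion_base not in ("pyrimidine", "purine"):
        raise ValueError("lesion_base must be 'pyrimidine' or 'purine'")
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    if "strand_class" not in df.columns:
        df = assign_gene(df, bundle)
    sel = df[df["label"].isin(class_filter) & df["strand_class"].notna()]
    counts = _lesion_strand_counts(sel, lesion_base)
    counts["trb"] = np.where(counts["transcribed"] > 0,
                             counts["untranscribed"] / counts["transcribed"].replace(0, np.nan),
                             np.inf)
    u, t = int(counts["untranscribed"].sum()), int(counts["transcribed"].sum())
    pooled = u / t if t > 0 else np.inf
    rng = np.random.default_rng(seed)
    if u + t > 0 and n_boot > 0:
        draws = rng.binomial(u + t, u / (u + t), size=n_boot)
        ratios = draws / np.maximum((u + t) - draws, 1)
        ci = (float(np.quantile(ratios, 0.025)), float(np.quantile(ratios, 0.975)))
    else:
        ci = (np.nan, np.nan)
    return TRBResult(counts, u, t, pooled, ci, lesion_base)


def trb_by_expression(records, bundle: ReferenceBundle, n_bins: int = 6,
                      class_filter=UV12_LABELS) -> pd.DataFrame:
    """TRB within equal-count gene bins of expression (lowest bin first).

    Ties at bin edges break by gene id order.
    """
    genes = bundle.genes
    if len(genes) < n_bins:
        raise ValueError(f"fewer genes than bins ({len(genes)} < {n_bins})")
    gdf = genes.df.sort_values(["expression", "gene_id"], kind="stable").reset_index(drop=True)
    gdf["expr_bin"] = (np.arange(len(gdf)) * n_bins) // len(gdf) + 1
    bin_of = dict(zip(gdf["gene_id"], gdf["expr_bin"]))

    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    if "strand_class" not in df.columns:
        df = assign_gene(df, bundle)
    sel = df[df["label"].isin(class_filter) & df["strand_class"].notna()].copy()
    sel["expr_bin"] = sel["gene_id"].map(bin_of)
    rows = []
    for b in range(1, n_bins + 1):
        sub = sel[sel["expr_bin"] == b]
        u = int((sub["strand_class"] == "untranscribed").sum())
        t = int((sub["strand_class"] == "transcribed").sum())
        rows.append({"expr_bin": b, "untranscribed": u, "transcribed": t,
                     "trb": u / t if t else np.inf,
                     "mean_expression": gdf.loc[gdf["expr_bin"] == b, "expression"].mean()})
    return pd.DataFrame(rows).set_index("expr_bin")


# ---------------------------------------------------------------------------
# Anchored meta-profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """TSS/TES-anchored stranded profile: +/-50 kb in ten 10-kb bins.

    `table` rows are bins (offsets -5..-1 upstream, 1..5 downstream of the
    anchor, in transcription direction); columns are MultiIndex
    (strand in {transcribed, untranscribed}, quantity in
    {mutations, opportunity, rate, fraction}) for records, or mean intensity
    for tracks.
    """
    table: pd.DataFrame
    anchor: str
    n_genes_used: int
    n_genes_excluded: int


_BIN_OFFSETS = tuple(range(-5, 0)) + tuple(range(1, 6))


def _anchor_coord(g: Gene, anchor: str) -> int:
    if anchor == "TES":
        return g.end if g.strand == "+" else g.start - 1
    if anchor == "TSS":
        return g.start if g.strand == "+" else g.end - 1
    raise ValueError(f"anchor must be TSS or TES, got {anchor!r}")


def _signed_offset(pos: np.ndarray, a: int, strand: str) -> np.ndarray:
    return pos - a if strand == "+" else a - pos


def anchored_metaprofile(records, bundle: ReferenceBundle, anchor: str = "TES",
                         half_width: int = 50_000, bin_size: int = 10_000,
                         class_filter=UV12_LABELS) -> MetaProfile:
    """Stranded, trinucleotide-adjusted mutation profile around gene anchors.

    1-kb intervals overlapping any other gene body are removed; genes whose
    window leaves the contig are excluded and counted.  Strand labels follow
    the anchoring gene: a pyrimidine on its template strand is "transcribed".
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    n_side = half_width // bin_size
    offsets = tuple(range(-n_side, 0)) + tuple(range(1, n_side + 1))
    bin_index = {off: i for i, off in enumerate(offsets)}
    canon, pyr_plus = _canonical_maps(3)
    ctxs = sorted({canonical_kmer(label_context(l)) for l in class_filter})
    ctx_pos = {c: j for j, c in enumerate(ctxs)}
    pos_of = np.full(32, -1, dtype=np.int64)  # canonical id -> column in ctxs
    for c, j in ctx_pos.items():
        pos_of[_CANON3_INDEX[c]] = j

    caches = {}
    for contig, _n in bundle.contigs:
        starts, ids, valid = kmer_positions(bundle, contig, 3)
        centers = (starts + 1)[valid]
        caches[contig] = (centers, canon[ids[valid]], pyr_plus[ids[valid]])

    lengths = bundle.contig_lengths
    other_bodies = {g.gene_id: None for g in bundle.genes}
    all_bodies = bundle.genes.body_intervals()

    m = np.zeros((2, len(offsets), len(ctxs)))      # strand x bin x context mutations
    o = np.zeros((2, len(offsets), len(ctxs)))      # strand x bin x context opportunities
    used = excluded = 0
    muts = df[df["label"].isin(class_filter) & df["pyr_strand"].notna()]

    for g in bundle.genes:
        a = _anchor_coord(g, anchor)
        if a - half_width < 0 or a + half_width >= lengths[g.contig]:
            excluded += 1
            continue
        used += 1
        lo, hi = a - half_width, a + half_width + 1
        centers, cids, pyr = caches[g.contig]
        i0, i1 = np.searchsorted(centers, [lo, hi])
        cen = centers[i0:i1]
        # drop 1-kb intervals overlapping any *other* gene body
        kb = cen // 1000
        in_other = all_bodies.contains(g.contig, cen) & ~((cen >= g.start) & (cen < g.end))
        bad_kb = np.unique(kb[in_other])
        ok = ~np.isin(kb, bad_kb)
        cen, cid, py = cen[ok], cids[i0:i1][ok], pyr[i0:i1][ok]
        off = _signed_offset(cen, a, g.strand)
        off_bin = np.where(off >= 0, off // bin_size + 1, -((-off - 1) // bin_size + 1))
        cols = pos_of[cid]
        pyr_on_template = py == (g.template_strand == "+")
        for s_idx, strand_is_tr in enumerate((True, False)):
            sel = (pyr_on_template if strand_is_tr else ~pyr_on_template)
            sel = sel & (cols >= 0) & np.isin(off_bin, offsets)
            if sel.any():
                rows = np.asarray([bin_index[b] for b in off_bin[sel]])
                flat = np.bincount(rows * len(ctxs) + cols[sel],
                                   minlength=len(offsets) * len(ctxs))
                o[s_idx] += flat.reshape(len(offsets), len(ctxs))
        here = muts[(muts["contig"] == g.contig) & (muts["pos0"] >= lo) & (muts["pos0"] < hi)]
        if len(here):
            pos = here["pos0"].to_numpy()
            ok = ~np.isin(pos // 1000, bad_kb)
            here, pos = here[ok], pos[ok]
            off = _signed_offset(pos, a, g.strand)
            off_bin = np.where(off >= 0, off // bin_size + 1, -((-off - 1) // bin_size + 1))
            tr = here["pyr_strand"].to_numpy() == g.template_strand
            mcols = np.asarray([ctx_pos[canonical_kmer(label_context(l))]
                                for l in here["label"]])
            for s_idx, strand_is_tr in enumerate((True, False)):
                sel = (tr if strand_is_tr else ~tr) & np.isin(off_bin, offsets)
                for b, c in zip(off_bin[sel], mcols[sel]):
                    m[s_idx, bin_index[b], c] += 1

    w = o.sum(axis=(0, 1))
    w = w / w.sum() if w.sum() else w
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(o > 0, m / np.maximum(o, 1), 0.0)
    bad = (o == 0) & (m > 0)
    if bad.any():
        raise ValueError("mutations observed in a bin/context with zero opportunity")
    rate = (rate * w[None, None, :]).sum(axis=2)
    frac = rate / rate.sum() if rate.sum() else rate
    m_tot = m.sum(axis=2)
    cols_ix = pd.MultiIndex.from_product([("transcribed", "untranscribed"),
                                          ("mutations", "rate", "fraction")])
    table = pd.DataFrame(index=offsets, columns=cols_ix, dtype=float)
    for s_idx, strand in enumerate(("transcribed", "untranscribed")):
        table[(strand, "mutations")] = m_tot[s_idx]
        table[(strand, "rate")] = rate[s_idx]
        table[(strand, "fraction")] = frac[s_idx]
    return MetaProfile(table, anchor, used, excluded)


def track_metaprofile(tracks: dict[str, NumericTrack], bundle: ReferenceBundle,
                      anchor: str = "TES", half_width: int = 50_000,
                      bin_size: int = 10_000) -> MetaProfile:
    """Mean per-strand track intensity (e.g. XR-seq) in anchored bins;
    strand labels follow the anchoring gene's template strand."""
    n_side = half_width // bin_size
    offsets = tuple(range(-n_side, 0)) + tuple(range(1, n_side + 1))
    sums = {s: np.zeros(len(offsets)) for s in ("transcribed", "untranscribed")}
    ns = {s: np.zeros(len(offsets)) for s in ("transcribed", "untranscribed")}
    lengths = bundle.contig_lengths
    used = excluded = 0
    for g in bundle.genes:
        a = _anchor_coord(g, anchor)
        if a - half_width < 0 or a + half_width >= lengths[g.contig]:
            excluded += 1
            continue
        used += 1
        for i, off in enumerate(offsets):
            if off > 0:
                lo_off, hi_off = (off - 1) * bin_size, off * bin_size
            else:
                lo_off, hi_off = off * bin_size, (off + 1) * bin_size
            if g.strand == "+":
                lo, hi = a + lo_off, a + hi_off
            else:
                lo, hi = a - hi_off + 1, a - lo_off + 1
            mid = np.arange(lo, hi, 1000) + 500
            for phys_strand, track in tracks.items():
                strand = ("transcribed" if phys_strand == g.template_strand
                          else "untranscribed")
                v = track.value_at(g.contig, mid)
                sums[strand][i] += np.nansum(v)
                ns[strand][i] += np.sum(~np.isnan(v))
    cols = pd.MultiIndex.from_product([("transcribed", "untranscribed"), ("mean",)])
    table = pd.DataFrame(index=offsets, columns=cols, dtype=float)
    for s in ("transcribed", "untranscribed"):
        table[(s, "mean")] = np.where(ns[s] > 0, sums[s] / np.maximum(ns[s], 1), np.nan)
    return MetaProfile(table, anchor, used, excluded)


def post_tes_bias_extent(profile: MetaProfile, q: float = 0.05,
                         bin_size: int = 10_000) -> dict:
    """Extent of the post-TES strand bias: per downstream bin, a binomial
    test of untranscribed vs transcribed mutation counts against 0.5,
    Benjamini-Hochberg corrected across bins; the extent is the length of
    the leading run of significant bins."""
    down = profile.table.loc[[o for o in profile.table.index if o > 0]]
    pvals = []
    for _off, row in down.iterrows():
        u = int(row[("untranscribed", "mutations")])
        t = int(row[("transcribed", "mutations")])
        if u + t == 0:
            pvals.append(1.0)
        else:
            pvals.append(stats.binomtest(u, u + t, 0.5, alternative="greater").pvalue)
    reject, qvals, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    run = 0
    for r in reject:
        if not r:
            break
        run += 1
    return {"extent_bp": run * bin_size, "n_significant_leading": run,
            "pvalues": list(pvals), "qvalues": list(qvals)}


# ---------------------------------------------------------------------------
# XR-seq style summaries
# ---------------------------------------------------------------------------

def dipyrimidine_window_counts(bundle: ReferenceBundle, window: int = 1000
                               ) -> dict[str, dict[str, np.ndarray]]:
    """Per-strand dipyrimidine (TT+TC+CT+CC) site counts per window."""
    out = {"+": {}, "-": {}}
    for contig, n in bundle.contigs:
        codes = bundle.codes(contig)
        d1, d2 = codes[:-1], codes[1:]
        pyr1, pyr2 = np.isin(d1, (1, 3)), np.isin(d2, (1, 3))
        pur1, pur2 = np.isin(d1, (0, 2)), np.isin(d2, (0, 2))
        n_win = -(-n // window)
        pos = np.arange(len(d1))
        for strand, mask in (("+", pyr1 & pyr2), ("-", pur1 & pur2)):
            out[strand][contig] = np.bincount(pos[mask] // window, minlength=n_win)
    return out


def xrseq_summaries(tracks: dict[str, NumericTrack], bundle: ReferenceBundle,
                    rt_window_bins: dict[str, np.ndarray] | None = None,
                    n_rt_bins: int = 5, window: int = 1000) -> pd.DataFrame:
    """Dipyrimidine-normalized mean XR-seq intensity by RT bin and stratum.

    Strata: intergenic, genic transcribed / untranscribed strand (relative
    to each window's covering gene).  A track given without strand split
    (single key) is treated strand-agnostically with a warning.
    """
    if set(tracks) != {"+", "-"}:
        log.warning("XR track missing per-strand split; strand-agnostic mode")
        tracks = {"+": next(iter(tracks.values())), "-": next(iter(tracks.values()))}
    if rt_window_bins is None:
        from .topography import quantile_window_bins
        rt_window_bins = quantile_window_bins(bundle, "rt", n_rt_bins, window)
    dipyr = dipyrimidine_window_counts(bundle, window)
    plus_iv = bundle.genes.body_intervals("+")
    minus_iv = bundle.genes.body_intervals("-")
    rows = []
    for contig, n in bundle.contigs:
        n_win = -(-n // window)
        mids = np.arange(n_win) * window + window // 2
        bins = rt_window_bins.get(contig)
        in_plus = plus_iv.contains(contig, mids)
        in_minus = minus_iv.contains(contig, mids)
        for strand, track in tracks.items():
            v = track.value_at(contig, mids)
            opp = dipyr[strand][contig][:n_win]
            norm = np.where(opp > 0, v / np.maximum(opp, 1), np.nan)
            # template of '+' genes is '-'
            stratum = np.where(~in_plus & ~in_minus, "intergenic",
                               np.where(in_plus & in_minus, "overlap",
                                        np.where((in_plus & (strand == "-")) |
                                                 (in_minus & (strand == "+")),
                                                 "genic_transcribed", "genic_untranscribed")))
            for i in range(n_win):
                if bins is None or i >= len(bins) or bins[i] < 0 or np.isnan(norm[i]):
                    continue
                if stratum[i] == "overlap":
                    continue
                rows.append((int(bins[i]) + 1, stratum[i], norm[i]))
    df = pd.DataFrame(rows, columns=["rt_bin", "stratum", "norm_intensity"])
    return df.groupby(["rt_bin", "stratum"])["norm_intensity"].agg(["mean", "sem", "count"]).reset_index()


def xr_expression_correlation(tracks: dict[str, NumericTrack], bundle: ReferenceBundle,
                              region: str = "downstream", width: int = 50_000) -> dict:
    """Pearson correlation between per-gene XR intensity (template strand,
    gene body or downstream-of-TES region) and gene expression."""
    xs, ys = [], []
    lengths = bundle.contig_lengths
    for g in bundle.genes:
        track = tracks[g.template_strand]
        if region == "body":
            lo, hi = g.start, g.end
        else:
            a = _anchor_coord(g, "TES")
            lo, hi = (a, a + width) if g.strand == "+" else (a - width + 1, a + 1)
        lo, hi = max(lo, 0), min(hi, lengths[g.contig])
        mid = np.arange(lo, hi, 1000) + 500
        v = track.value_at(g.contig, mid)
        if np.isnan(v).all():
            continue
        xs.append(np.nanmean(v))
        ys.append(g.expression)
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n_genes": len(xs)}


def intergenic_bias_vs_xrseq(records, tracks: dict[str, NumericTrack],
                             bundle: ReferenceBundle, n_bins: int = 4,
                             window: int = 1000,
                             class_filter=UV12_LABELS) -> pd.DataFrame:
    """Intergenic strand bias and relative mutation rate by XR-seq bin.

    1-kb intergenic windows are binned by total dipyrimidine-normalized XR
    intensity; per bin the ratio of lesions on the less-repaired vs the
    more-repaired strand and the adjusted relative mutation rate (per
    dipyrimidine site, normalized to bin 1) are reported.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    sel = df[df["label"].isin(class_filter) & df["pyr_strand"].notna()]
    dipyr = dipyrimidine_window_counts(bundle, window)
    genic = bundle.genes.body_intervals()
    per_win = []
    for contig, n in bundle.contigs:
        n_win = -(-n // window)
        mids = np.arange(n_win) * window + window // 2
        inter = ~genic.contains(contig, mids)
        vp = np.nan_to_num(tracks["+"].value_at(contig, mids))
        vm = np.nan_to_num(tracks["-"].value_at(contig, mids))
        op = dipyr["+"][contig][:n_win].astype(float)
        om = dipyr["-"][contig][:n_win].astype(float)
        xr = np.where(op + om > 0, (vp + vm) / np.maximum(op + om, 1), np.nan)
        repaired_plus = vp / np.maximum(op, 1) >= vm / np.maximum(om, 1)
        here = sel[sel["contig"] == contig]
        wp = np.bincount(here.loc[here["pyr_strand"] == "+", "pos0"] // window, minlength=n_win)
        wm = np.bincount(here.loc[here["pyr_strand"] == "-", "pos0"] // window, minlength=n_win)
        for i in np.flatnonzero(inter & ~np.isnan(xr)):
            per_win.append((xr[i], bool(repaired_plus[i]), int(wp[i]), int(wm[i]),
                            op[i] + om[i]))
    pw = pd.DataFrame(per_win, columns=["xr", "rep_plus", "m_plus", "m_minus", "opp"])
    edges = np.quantile(pw["xr"], np.linspace(0, 1, n_bins + 1)[1:-1])
    pw["bin"] = np.searchsorted(edges, pw["xr"], side="right") + 1
    rows = []
    for b, sub in pw.groupby("bin"):
        unrep = np.where(sub["rep_plus"], sub["m_minus"], sub["m_plus"]).sum()
        rep = np.where(sub["rep_plus"], sub["m_plus"], sub["m_minus"]).sum()
        rate = (sub["m_plus"] + sub["m_minus"]).sum() / max(sub["opp"].sum(), 1)
        rows.append({"xr_bin": b, "strand_ratio": unrep / rep if rep else np.inf,
                     "rate": rate, "n_windows": len(sub)})
    out = pd.DataFrame(rows).set_index("xr_bin")
    out["relative_rate"] = out["rate"] / out["rate"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# Relative GG-NER efficiency
# ---------------------------------------------------------------------------

GGNER_MODEL_STATEMENT = (
    "Linear lesion-survival model: untranscribed-strand mutation counts are "
    "proportional to lesions left unrepaired by GG-NER, while the transcribed "
    "strand is a shared TC-NER-controlled baseline; then the GG-NER removal "
    "fraction of group g is e_g = 1 - TRB_g / TRB_null, with TRB_null from a "
    "group with GG-NER absent but TC-NER active."
)


def relative_ggner_efficiency(trb_target: float, trb_reference: float,
                              trb_null: float) -> dict:
    """Relative GG-NER removal efficiency of target vs reference group."""
    if min(trb_target, trb_reference, trb_null) <= 0:
        raise ValueError("all TRBs must be positive")
    def removal(trb):
        e = 1.0 - trb / trb_null
        if e < 0:
            log.warning("TRB %.3f exceeds null %.3f; efficiency clamped at 0 (noise regime)",
                        trb, trb_null)
            return 0.0
        return e
    e_t, e_r = removal(trb_target), removal(trb_reference)
    return {
        "e_target": e_t,
        "e_reference": e_r,
        "relative_efficiency": e_t / e_r if e_r > 0 else np.nan,
        "model": GGNER_MODEL_STATEMENT,
    }
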