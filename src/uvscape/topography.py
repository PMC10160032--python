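"""Mutation topography: trinucleotide-adjusted load along genomic covariates.

All profiles share one engine: the genome is cut into fixed windows
(default 1 kb), every window gets a bin id from some covariate (replication
timing quantile, TAD-boundary side, normalized mark intensity, ...), and the
per-sample mutation fraction per bin is computed with
``rate_b = sum_c (m_bc / o_bc) * w_c`` where ``o`` are k-mer opportunity
counts per bin and ``w_c`` the genome-wide context weights; fractions are
``rate_b / sum_b rate_b``.  Bin 1 is the latest-replicating bin by
convention, so UV repair gradients appear as negative log-slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .classify import UV12_LABELS, assign_gene, label_context, records_frame
from .genome_model import (NumericTrack, ReferenceBundle, canonical_kmer,
                           kmer_positions)

log = logging.getLogger(__name__)

#: canonical (pyrimidine-centric) trinucleotide contexts, fixed order
CANON3 = tuple(f"{x}{y}{z}" for y in "CT" for x in "ACGT" for z in "ACGT")
_CANON3_INDEX = {c: i for i, c in enumerate(CANON3)}

STRATA = ("all", "intergenic", "genic_transcribed", "genic_untranscribed")


def _canonical_maps(k: int = 3):
    """kmer id -> canonical context index (-1 if N-ish), and whether the
    plus-strand k-mer has a pyrimidine center."""
    n = 4 ** k
    canon = np.full(n, -1, dtype=np.int64)
    pyr_plus = np.zeros(n, dtype=bool)
    for idx in range(n):
        digits = []
        v = idx
        for _ in range(k):
            digits.append("ACGT"[v % 4])
            v //= 4
        kmer = "".join(reversed(digits))
        c = canonical_kmer(kmer)
        canon[idx] = _CANON3_INDEX[c]
        pyr_plus[idx] = kmer[k // 2] in "CT"
    return canon, pyr_plus


def stratum_window_context_counts(bundle: ReferenceBundle, window: int = 1000,
                                  ) -> dict[str, dict[str, np.ndarray]]:
    """Per-stratum, per-contig (n_windows x 32) canonical trinucleotide
    opportunity counts.

    Strand-resolved genic strata count a context toward "transcribed" when
    the pyrimidine of the canonical k-mer lies on the template strand of the
    covering gene; territory covered by genes on both strands is excluded
    from every stratum except "all".
    """
    canon, pyr_plus = _canonical_maps(3)
    out: dict[str, dict[str, np.ndarray]] = {s: {} for s in STRATA}
    plus_iv = bundle.genes.body_intervals("+")
    minus_iv = bundle.genes.body_intervals("-")
    for contig, length in bundle.contigs:
        n_win = -(-length // window)
        starts, ids, valid = kmer_positions(bundle, contig, 3)
        centers = starts + 1
        sel = valid
        cen = centers[sel]
        cid = canon[ids[sel]]
        pyr = pyr_plus[ids[sel]]
        win = cen // window
        in_plus = plus_iv.contains(contig, cen)
        in_minus = minus_iv.contains(contig, cen)
        both = in_plus & in_minus
        genic = (in_plus | in_minus) & ~both
        # lesion strand is where the pyrimidine sits; template of '+' genes is '-'
        transcribed = genic & ((in_plus & ~pyr) | (in_minus & pyr))
        untranscribed = genic & ~transcribed
        def acc(mask):
            flat = np.bincount(win[mask] * 32 + cid[mask], minlength=n_win * 32)
            return flat.reshape(n_win, 32)
        out["all"][contig] = acc(np.ones(cen.shape, dtype=bool))
        out["intergenic"][contig] = acc(~in_plus & ~in_minus)
        out["genic_transcribed"][contig] = acc(transcribed)
        out["genic_untranscribed"][contig] = acc(untranscribed)
    return out


def _mutation_stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=df.index)
    if stratum == "intergenic":
        return df["gene_id"].isna() & ~df["both_strands"]
    if stratum == "genic_transcribed":
        return df["strand_class"] == "transcribed"
    if stratum == "genic_untranscribed":
        return df["strand_class"] == "untranscribed"
    raise ValueError(f"unknown stratum {stratum!r}")


@dataclass
class BinnedFractionProfile:
    """Per-sample adjusted mutation fractions over ordered bins."""
    fractions: pd.DataFrame      # samples x bins, rows sum to 1
    rates: pd.DataFrame          # unnormalized adjusted rates
    opportunities: pd.DataFrame  # bins x contexts
    stratum: str

    def group_mean_sem(self, groups: pd.Series | None = None) -> pd.DataFrame:
        f = self.fractions
        if groups is None:
            return pd.DataFrame({"mean": f.mean(axis=0), "sem": f.sem(axis=0)})
        df = f.join(groups.rename("group"))
        return df.groupby("group").agg(["mean", "sem"])


def adjusted_fractions(records, bundle: ReferenceBundle,
                       window_bins: dict[str, np.ndarray], n_bins: int,
                       stratum: str = "all", subset=UV12_LABELS,
                       window: int = 1000,
                       opportunity_counts: dict | None = None) -> BinnedFractionProfile:
    """Trinucleotide-adjusted mutation fractions per bin per sample.

    `window_bins`: per contig, the bin index (0-based; -1 = excluded) of each
    fixed window.  `subset` restricts mutations to the given SBS-96 labels
    (UV C>T contexts by default); opportunities use the matching
    trinucleotide contexts.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    if "strand_class" not in df.columns:
        df = assign_gene(df, bundle)
    if opportunity_counts is None:
        opportunity_counts = stratum_window_context_counts(bundle, window)
    ctxs = sorted({canonical_kmer(label_context(l)) for l in subset})
    ctx_idx = np.asarray([_CANON3_INDEX[c] for c in ctxs])

    # opportunities per bin for this stratum
    o = np.zeros((n_bins, len(ctxs)))
    for contig, counts in opportunity_counts[stratum].items():
        bins = window_bins.get(contig)
        if bins is None:
            continue
        m = min(len(bins), counts.shape[0])
        for b in range(n_bins):
            sel = bins[:m] == b
            if sel.any():
                o[b] += counts[:m][sel][:, ctx_idx].sum(axis=0)
    w = o.sum(axis=0)
    if w.sum() == 0:
        raise ValueError(f"no opportunity territory for stratum {stratum!r}")
    w = w / w.sum()

    # mutations per sample / bin / context
    sel = df["label"].isin(subset) & _mutation_stratum_mask(df, stratum)
    sub = df[sel].copy()
    ctx = sub["label"].map(lambda l: canonical_kmer(label_context(l)))
    sub = sub.assign(ctx=ctx)
    bin_of = np.full(len(sub), -1, dtype=np.int64)
    for contig, grp in sub.groupby("contig"):
        bins = window_bins.get(contig)
        if bins is None:
            continue
        wi = grp["pos0"].to_numpy() // window
        ok = wi < len(bins)
        vals = np.full(len(grp), -1, dtype=np.int64)
        vals[ok] = bins[wi[ok]]
        bin_of[sub.index.get_indexer(grp.index)] = vals
    sub = sub.assign(bin=bin_of)
    sub = sub[sub["bin"] >= 0]

    samples = sorted(df["sample"].unique())
    rates = pd.DataFrame(0.0, index=samples, columns=range(1, n_bins + 1))
    cpos = {c: j for j, c in enumerate(ctxs)}
    for (sample, b, c), cnt in sub.groupby(["sample", "bin", "ctx"]).size().items():
        j = cpos[c]
        if o[b, j] == 0:
            raise ValueError(
                f"mutations observed in context {c} bin {b + 1} with zero opportunity")
        rates.loc[sample, b + 1] += (cnt / o[b, j]) * w[j]
    totals = rates.sum(axis=1)
    fractions = rates.div(totals.where(totals > 0), axis=0)
    opp = pd.DataFrame(o, index=range(1, n_bins + 1), columns=ctxs)
    return BinnedFractionProfile(fractions, rates, opp, stratum)


# ---------------------------------------------------------------------------
# Bin schemes
# ---------------------------------------------------------------------------

def quantile_window_bins(bundle: ReferenceBundle, track: str | NumericTrack,
                         n_bins: int = 8, window: int = 1000,
                         bin1_latest: bool = True) -> dict[str, np.ndarray]:
    """Equal-territory bins of track value over covered windows.

    Windows all have equal size, so equal covered territory per bin equals
    equal window counts; bin 1 holds the lowest values (latest replication)
    unless bin1_latest=False.
    """
    tr = bundle.tracks[track] if isinstance(track, str) else track
    means = {c: tr.window_means(c, n, window) for c, n in bundle.contigs}
    pooled = np.concatenate([v[~np.isnan(v)] for v in means.values()])
    if pooled.size == 0:
        raise ValueError("track covers no windows")
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
    out = {}
    for contig, v in means.items():
        bins = np.full(v.shape, -1, dtype=np.int64)
        ok = ~np.isnan(v)
        b = np.searchsorted(edges, v[ok], side="right")
        if not bin1_latest:
            b = n_bins - 1 - b
        bins[ok] = b
        out[contig] = bins
    return out


def build_consensus_rt(tracks: list[NumericTrack], bundle: ReferenceBundle,
                       sd_cutoff: float = 15.0, window: int = 1000,
                       weights: np.ndarray | None = None
                       ) -> tuple[NumericTrack, pd.DataFrame]:
    """Consensus replication timing across cell-line tracks.

    Per window: weighted mean across tracks (equal weights by default) and
    SD across tracks; windows with SD > cutoff or covered by fewer than two
    tracks are dropped with a reason.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two replication-timing tracks")
    w = np.ones(len(tracks)) if weights is None else np.asarray(weights, dtype=float)
    data = {}
    dropped = []
    for contig, n in bundle.contigs:
        mats = np.vstack([t.window_means(contig, n, window) for t in tracks])
        cov = (~np.isnan(mats)).sum(axis=0)
        wsum = np.nansum(np.where(np.isnan(mats), 0, w[:, None] * np.ones_like(mats)), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            wm = np.nansum(mats * w[:, None], axis=0) / np.where(wsum > 0, wsum, np.nan)
            sq = np.where(np.isnan(mats), 0.0, (mats - wm) ** 2)
            sd = np.sqrt(sq.sum(axis=0) / np.maximum(cov - 1, 1))
        keep = (cov >= 2) & (sd <= sd_cutoff)
        n_win = mats.shape[1]
        starts = np.arange(n_win, dtype=np.int64) * window
        ends = np.minimum(starts + window, n)
        data[contig] = (starts[keep], ends[keep], wm[keep])
        for i in np.flatnonzero(~keep):
            reason = "insufficient coverage" if cov[i] < 2 else "sd_above_cutoff"
            dropped.append((contig, int(starts[i]), reason))
    return NumericTrack(data), pd.DataFrame(dropped, columns=["contig", "start", "reason"])


# ---------------------------------------------------------------------------
# Slope fitting
# ---------------------------------------------------------------------------

@dataclass
class SlopeResult:
    slope: float
    se: float
    fold: float  # fraction(bin 1, latest) / fraction(bin n, earliest)

    @property
    def z(self) -> float:
        return self.slope / self.se if self.se > 0 else np.inf


def fit_log_slope(fractions: pd.Series, pseudo: bool = False) -> SlopeResult:
    """OLS of ln(fraction) on bin index 1..n.

    Zero fractions raise unless `pseudo` adds 0.5/total-scale pseudo-fraction.
    """
    f = fractions.to_numpy(dtype=float)
    if (f <= 0).any():
        if not pseudo:
            raise ValueError("zero fraction in profile; use pseudo=True to add a pseudo-fraction")
        f = f + 0.5 / max(len(f), 1) / 100.0
    x = sm.add_constant(np.arange(1, len(f) + 1, dtype=float))
    fit = sm.OLS(np.log(f), x).fit()
    return SlopeResult(float(fit.params[1]), float(fit.bse[1]), float(f[0] / f[-1]))


def slopes_per_sample(profile: BinnedFractionProfile, pseudo: bool = False) -> pd.DataFrame:
    rows = {}
    for sample, row in profile.fractions.iterrows():
        r = fit_log_slope(row, pseudo=pseudo)
        rows[sample] = {"slope": r.slope, "se": r.se, "fold": r.fold}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# TAD boundaries
# ---------------------------------------------------------------------------

def boundaries_from_state_track(bundle: ReferenceBundle, track: str = "tad_state",
                                window: int = 1000) -> pd.DataFrame:
    """Boundary positions where a binary active/inactive track switches.

    Returns contig, pos, active_side in {left, right}.
    """
    tr = bundle.tracks[track]
    rows = []
    for contig, n in bundle.contigs:
        v = tr.window_means(contig, n, window)
        state = v > 0.5
        flips = np.flatnonzero(state[1:] != state[:-1]) + 1
        for f in flips:
            rows.append((contig, int(f * window), "left" if state[f - 1] else "right"))
    return pd.DataFrame(rows, columns=["contig", "pos", "active_side"])


def tad_boundary_bins(bundle: ReferenceBundle, boundaries: pd.DataFrame,
                      half_width: int = 500_000, window: int = 1000
                      ) -> tuple[dict[str, np.ndarray], int]:
    """4-bin window assignment around active/inactive TAD boundaries.

    Bins: 1 = active-far, 2 = active-near, 3 = inactive-near, 4 =
    inactive-far (each half_width/2 wide).  Boundaries closer than
    half_width to a contig edge are dropped and counted.
    """
    lengths = bundle.contig_lengths
    bins = {c: np.full(-(-n // window), -1, dtype=np.int64) for c, n in bundle.contigs}
    dropped = 0
    half = half_width // 2
    for row in boundaries.itertuples():
        n = lengths[row.contig]
        if row.pos < half_width or row.pos + half_width > n:
            dropped += 1
            continue
        w = bins[row.contig]
        segs = [(row.pos - half_width, row.pos - half), (row.pos - half, row.pos),
                (row.pos, row.pos + half), (row.pos + half, row.pos + half_width)]
        order = [0, 1, 2, 3] if row.active_side == "left" else [3, 2, 1, 0]
        for b, (s, e) in zip(order, segs):
            w[s // window:-(-e // window)] = b
    return bins, dropped


def tad_boundary_profile(records, bundle: ReferenceBundle,
                         boundaries: pd.DataFrame | None = None,
                         stratum: str = "all", window: int = 1000,
                         half_width: int = 500_000) -> BinnedFractionProfile:
    if boundaries is None:
        boundaries = boundaries_from_state_track(bundle, window=window)
    bins, dropped = tad_boundary_bins(bundle, boundaries, half_width, window)
    if dropped:
        log.info("%d boundaries dropped near contig edges", dropped)
    return adjusted_fractions(records, bundle, bins, 4, stratum=stratum, window=window)


# ---------------------------------------------------------------------------
# Epigenetic-mark quantile profiles
# ---------------------------------------------------------------------------

def covariate_quantile_profile(records, bundle: ReferenceBundle,
                               track: str | NumericTrack, n_bins: int = 5,
                               normalize_1_100: bool = True,
                               alignability_min: float = 0.9,
                               mappability_track: str = "mappability",
                               policy: str = "value_interval",
                               stratum: str = "all",
                               window: int = 1000) -> BinnedFractionProfile:
    """Adjusted fractions across mark-intensity bins.

    Window means are min-max normalized to [1, 100]; windows split into
    n_bins by equal value intervals (or by quantiles with policy
    "quantile").  Windows with mappability coverage below `alignability_min`
    are excluded.
    """
    tr = bundle.tracks[track] if isinstance(track, str) else track
    mp = bundle.tracks.get(mappability_track)
    means, keep = {}, {}
    for contig, n in bundle.contigs:
        v = tr.window_means(contig, n, window)
        ok = ~np.isnan(v)
        if mp is not None:
            mv = mp.window_means(contig, n, window)
            ok &= ~np.isnan(mv) & (mv >= alignability_min)
        means[contig], keep[contig] = v, ok
    pooled = np.concatenate([v[k] for v, k in zip(means.values(), keep.values())])
    if pooled.size == 0:
        raise ValueError("no eligible windows")
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        raise ValueError("constant track: single degenerate bin; use quantile policy on "
                         "a non-constant covariate")
    bins_out = {}
    if normalize_1_100:
        norm = lambda v: 1 + 99 * (v - lo) / (hi - lo)
        pooled_n = norm(pooled)
    else:
        norm = lambda v: v
        pooled_n = pooled
    if policy == "value_interval":
        edges = np.linspace(pooled_n.min(), pooled_n.max(), n_bins + 1)[1:-1]
    elif policy == "quantile":
        edges = np.quantile(pooled_n, np.linspace(0, 1, n_bins + 1)[1:-1])
    else:
        raise ValueError(f"unknown policy {policy!r}")
    for contig, v in means.items():
        b = np.full(v.shape, -1, dtype=np.int64)
        ok = keep[contig]
        b[ok] = np.searchsorted(edges, norm(v[ok]), side="right")
        bins_out[contig] = b
    return adjusted_fractions(records, bundle, bins_out, n_bins, stratum=stratum, window=window)


# ---------------------------------------------------------------------------
# Megabase-scale density PCA
# ---------------------------------------------------------------------------

def megabase_density_pca(records, bundle: ReferenceBundle,
                         window_size: int = 1_000_000,
                         mappable_fraction: float = 0.8,
                         min_mutations: int = 50_000,
                         n_components: int = 2) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample normalized C>T density per fixed window, then PCA.

    Windows need >= `mappable_fraction` of bases at mappability score 1;
    samples below `min_mutations` classifiable C>T mutations are excluded
    and listed.  Returns (coordinates, excluded_samples).
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records, bundle)
    ct = df[df["label"].notna() & df["label"].str.contains("C>T", regex=False, na=False)]
    mp = bundle.tracks.get("mappability")
    windows = []
    for contig, n in bundle.contigs:
        for s in range(0, n, window_size):
            e = min(s + window_size, n)
            if mp is not None:
                # mappability is piecewise-constant on the 1-kb grid, so the
                # mean over 1-kb sample points is the exact base fraction
                frac = float(np.nan_to_num(mp.value_at(contig, np.arange(s, e, 1000))).mean())
                if not frac >= mappable_fraction:
                    continue
            windows.append((contig, s, e))
    counts = {}
    for sample, sub in ct.groupby("sample"):
        if len(sub) < min_mutations:
            continue
        vec = np.zeros(len(windows))
        for i, (contig, s, e) in enumerate(windows):
            here = sub[sub["contig"] == contig]
            vec[i] = ((here["pos0"] >= s) & (here["pos0"] < e)).sum() / (e - s)
        total = vec.sum()
        counts[sample] = vec / total if total > 0 else vec
    excluded = sorted(set(ct["sample"].unique()) - set(counts))
    if len(counts) < 2:
        raise ValueError("fewer than two eligible samples for density PCA")
    mat = pd.DataFrame(counts).T
    pca = PCA(n_components=min(n_components, len(mat) - 1), svd_solver="full")
    coords = pca.fit_transform(mat.to_numpy())
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    out = pd.DataFrame(coords, index=mat.index,
                       columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out, excluded
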