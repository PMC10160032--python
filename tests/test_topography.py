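"""Topography: consensus RT, adjusted fractions, slopes, TAD/mark profiles,
megabase density PCA."""

import numpy as np
import pandas as pd
import pytest

from uvscape import synthetic_cohort as sc, topography as topo
from uvscape.classify import UV12_LABELS, assign_gene, records_frame
from uvscape.genome_model import MutationRecord, NumericTrack, ReferenceBundle, encode


# ---------------------------------------------------------------------------
# consensus RT
# ---------------------------------------------------------------------------

def _const_track(contig, n, window, values):
    starts = np.arange(len(values), dtype=np.int64) * window
    ends = np.minimum(starts + window, n)
    return NumericTrack({contig: (starts, ends, np.asarray(values, float))})


def test_consensus_rt_mean_and_sd_rule(tiny_bundle):
    n = 200
    t1 = _const_track("chr1", n, 100, [50, 10])
    t2 = _const_track("chr1", n, 100, [50, 60])
    t3 = _const_track("chr1", n, 100, [50, 60])
    cons, dropped = topo.build_consensus_rt([t1, t2, t3], tiny_bundle, window=100)
    assert cons.value_at("chr1", [0])[0] == pytest.approx(50.0)
    # window 2: values (10, 60, 60) -> SD 28.9 > 15 -> dropped
    assert np.isnan(cons.value_at("chr1", [150])[0])
    assert "sd_above_cutoff" in dropped["reason"].tolist()


def test_consensus_rt_two_tracks_sd_formula(tiny_bundle):
    t1 = _const_track("chr1", 100, 100, [10.0])
    t2 = _const_track("chr1", 100, 100, [60.0])
    cons, dropped = topo.build_consensus_rt([t1, t2], tiny_bundle, window=100)
    # SD of (10, 60) = 35.36 > 15
    assert np.isnan(cons.value_at("chr1", [50])[0])
    with pytest.raises(ValueError):
        topo.build_consensus_rt([t1], tiny_bundle)


def test_consensus_identical_tracks_is_identity(tiny_bundle):
    t = _const_track("chr1", 200, 100, [30.0, 40.0])
    cons, _ = topo.build_consensus_rt([t, t, t], tiny_bundle, window=100)
    assert cons.value_at("chr1", [0, 150]).tolist() == [30.0, 40.0]


# ---------------------------------------------------------------------------
# adjusted fractions
# ---------------------------------------------------------------------------

def test_adjusted_fractions_hand_example():
    """Single context, 2 bins, m=(10,10), o=(100,50) -> fractions (1/3, 2/3)."""
    seq = "TCA" * 200  # every window of 3 bp holds exactly one TCA center
    bundle = ReferenceBundle({"c": encode(seq)})
    window = 3
    bins = {"c": np.array([0] * 100 + [1] * 50 + [-1] * 50)}
    c_positions = [3 * i + 1 for i in range(200)]
    bin0 = c_positions[:10]                # inside windows 0..99
    bin1 = [p for p in c_positions if 300 <= p < 450][:10]
    recs = [MutationRecord("s", "c", p + 1, "C", "T") for p in bin0 + bin1]
    prof = topo.adjusted_fractions(recs, bundle, bins, 2, stratum="all",
                                   subset=("T[C>T]A",), window=window)
    o = prof.opportunities["TCA"]
    assert o.loc[1] == 100 and o.loc[2] == 50
    f = prof.fractions.loc["s"]
    assert f[1] == pytest.approx(1 / 3) and f[2] == pytest.approx(2 / 3)


def test_uniform_rates_give_flat_fractions(small_bundle):
    """Mutations drawn uniformly over eligible sites -> fractions ~ 1/n."""
    rng = np.random.default_rng(0)
    recs = []
    for contig, n in small_bundle.contigs:
        seq = small_bundle.sequence(contig, 0, n)
        cs = [i for i in range(1, n - 1) if seq[i] == "C" and seq[i - 1] in "CT"]
        for p in rng.choice(cs, 1200, replace=False):
            recs.append(MutationRecord("s", contig, int(p) + 1, "C", "T"))
    bins = topo.quantile_window_bins(small_bundle, "rt", 4)
    prof = topo.adjusted_fractions(records_frame(recs, small_bundle), small_bundle,
                                   bins, 4, stratum="all")
    assert np.allclose(prof.fractions.loc["s"], 0.25, atol=0.05)


def test_adjusted_fractions_zero_opportunity_with_mutations_errors():
    """A mutation landing in a bin whose opportunity table lacks its context
    flags inconsistent inputs instead of dividing silently."""
    seq = "TCA" * 50
    bundle = ReferenceBundle({"c": encode(seq)})
    recs = [MutationRecord("s", "c", 2, "C", "T")]  # window 0 -> bin 1
    bins = {"c": np.array([0] * 25 + [1] * 25)}
    from uvscape.topography import _CANON3_INDEX
    counts = {"all": {"c": np.zeros((50, 32), dtype=np.int64)}}
    counts["all"]["c"][25:, _CANON3_INDEX["TCA"]] = 1  # TCA territory only in bin 2
    with pytest.raises(ValueError, match="zero opportunity"):
        topo.adjusted_fractions(recs, bundle, bins, 2, stratum="all",
                                subset=("T[C>T]A",), window=3,
                                opportunity_counts=counts)


def test_brute_force_equivalence_small_genome(small_cohort, small_bundle):
    """Engine result equals a dict-based per-context recomputation."""
    df = assign_gene(records_frame(small_cohort.all_records, small_bundle), small_bundle)
    window, n_bins = 1000, 4
    bins = topo.quantile_window_bins(small_bundle, "rt", n_bins, window)
    prof = topo.adjusted_fractions(df, small_bundle, bins, n_bins, stratum="all",
                                   window=window)
    # brute force: scan every trinucleotide center, accumulate o[bin][ctx]
    from uvscape.genome_model import canonical_kmer
    ctxs = sorted({canonical_kmer(l[0] + l[2] + l[6]) for l in UV12_LABELS})
    o = {b: {c: 0 for c in ctxs} for b in range(n_bins)}
    for contig, n in small_bundle.contigs:
        seq = small_bundle.sequence(contig, 0, n)
        wb = bins[contig]
        for i in range(1, n - 1):
            tri = seq[i - 1:i + 2]
            if "N" in tri:
                continue
            b = wb[i // window]
            c = canonical_kmer(tri)
            if b >= 0 and c in o[b]:
                o[b][c] += 1
    m = {b: {c: 0 for c in ctxs} for b in range(n_bins)}
    for row in df[df["label"].isin(UV12_LABELS)].itertuples():
        b = bins[row.contig][row.pos0 // window]
        if b >= 0:
            m[b][canonical_kmer(row.label[0] + row.label[2] + row.label[6])] += 1
    tot_o = {c: sum(o[b][c] for b in o) for c in ctxs}
    wsum = sum(tot_o.values())
    rates = []
    for b in range(n_bins):
        r = sum((m[b][c] / o[b][c]) * (tot_o[c] / wsum)
                for c in ctxs if o[b][c] > 0)
        rates.append(r)
    fracs = np.asarray(rates) / sum(rates)
    pooled = prof.rates.sum(axis=0)
    pooled_frac = (pooled / pooled.sum()).to_numpy()
    assert np.allclose(pooled_frac, fracs, atol=1e-12)


# ---------------------------------------------------------------------------
# slopes
# ---------------------------------------------------------------------------

def test_fit_log_slope_exact_exponential():
    fracs = pd.Series(np.exp(-0.2 * np.arange(1, 9)))
    fracs = fracs / fracs.sum()
    res = topo.fit_log_slope(fracs)
    assert res.slope == pytest.approx(-0.2, abs=1e-12)
    assert res.fold == pytest.approx(np.exp(0.2 * 7), rel=1e-9)


def test_fit_log_slope_flat_and_zero_handling():
    flat = pd.Series([0.25] * 4)
    res = topo.fit_log_slope(flat)
    assert res.slope == pytest.approx(0.0, abs=1e-12) and res.fold == 1.0
    with pytest.raises(ValueError, match="pseudo"):
        topo.fit_log_slope(pd.Series([0.5, 0.5, 0.0]))
    topo.fit_log_slope(pd.Series([0.5, 0.5, 0.0]), pseudo=True)  # no raise


def test_slope_recovers_generating_coefficient_with_noise():
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(20):
        f = np.exp(-0.3 * np.arange(1, 9)) * np.exp(rng.normal(0, 0.05, 8))
        res = topo.fit_log_slope(pd.Series(f / f.sum()))
        if abs(res.slope - (-0.3)) < 2 * res.se:
            hits += 1
    assert hits >= 17  # ~95% nominal coverage


def test_fold_and_slope_agree_in_sign(frames, toy_bundle):
    bins = topo.quantile_window_bins(toy_bundle, "rt", 8)
    for name in ("sporadic", "xpc"):
        prof = topo.adjusted_fractions(frames[name], toy_bundle, bins, 8,
                                       stratum="intergenic")
        res = topo.fit_log_slope(prof.fractions.mean(axis=0))
        assert np.sign(res.slope) == -np.sign(np.log(res.fold))


# ---------------------------------------------------------------------------
# TAD boundaries and marks
# ---------------------------------------------------------------------------

def test_boundaries_found_at_state_flips(toy_bundle):
    bounds = topo.boundaries_from_state_track(toy_bundle)
    block = sc.preset("sporadic").tracks.tad_block
    assert len(bounds) > 0
    assert all(p % block == 0 for p in bounds["pos"])


def test_tad_contrast_present_with_repair_absent_without(frames, toy_bundle):
    spor = topo.tad_boundary_profile(frames["sporadic"], toy_bundle, stratum="intergenic")
    xpa = topo.tad_boundary_profile(frames["xpa"], toy_bundle, stratum="intergenic")
    f_s = spor.fractions.mean(axis=0)
    f_a = xpa.fractions.mean(axis=0)
    contrast_s = (f_s[3] + f_s[4]) / (f_s[1] + f_s[2])   # inactive / active
    contrast_a = (f_a[3] + f_a[4]) / (f_a[1] + f_a[2])
    assert contrast_s > 1.3
    assert contrast_a == pytest.approx(1.0, abs=0.1)
    assert contrast_s > contrast_a


def test_covariate_profile_sign_follows_coupling(frames, toy_bundle):
    """Repair rises with the open-chromatin mark, so mutation fractions fall
    with it in sporadic tumors; the closed mark shows the opposite sign."""
    up = topo.covariate_quantile_profile(frames["sporadic"], toy_bundle,
                                         "mark_open", stratum="intergenic")
    down = topo.covariate_quantile_profile(frames["sporadic"], toy_bundle,
                                           "mark_closed", stratum="intergenic")
    mu, md = up.fractions.mean(axis=0), down.fractions.mean(axis=0)
    assert mu.iloc[0] > mu.iloc[-1]
    assert md.iloc[0] < md.iloc[-1]


def test_covariate_profile_constant_track_errors(toy_bundle, frames):
    flat = NumericTrack({c: (np.array([0]), np.array([n]), np.array([5.0]))
                         for c, n in toy_bundle.contigs})
    with pytest.raises(ValueError, match="constant track"):
        topo.covariate_quantile_profile(frames["sporadic"], toy_bundle, flat)


def test_alignability_filter_excludes_low_windows(frames):
    cfg = sc.preset("sporadic")
    cfg.tracks.mappability_holes = ((0, 0, 50_000),)
    b = sc.build_toy_reference(cfg, 7)
    df = frames["sporadic"]
    prof = topo.covariate_quantile_profile(df, b, "mark_open", stratum="all")
    hole = topo.covariate_quantile_profile(df, b, "mark_open", stratum="all",
                                           alignability_min=0.0)
    assert prof.opportunities.to_numpy().sum() < hole.opportunities.to_numpy().sum()


# ---------------------------------------------------------------------------
# megabase density PCA
# ---------------------------------------------------------------------------

def test_density_pca_separates_flat_from_gradient(frames, toy_bundle):
    df = pd.concat([frames["sporadic"], frames["xpa"]], ignore_index=True)
    coords, excluded = topo.megabase_density_pca(df, toy_bundle,
                                                 window_size=50_000,
                                                 min_mutations=100)
    assert excluded == []
    groups = coords.index.str.startswith("sporadic")
    a = coords.loc[groups, "PC1"]
    b = coords.loc[~groups, "PC1"]
    assert (a.min() > b.max()) or (b.min() > a.max())  # PC1 separates groups


def test_density_pca_duplicate_sample_coincides(frames, toy_bundle):
    df = frames["sporadic"]
    dup = df.copy()
    dup["sample"] = dup["sample"] + "_copy"
    coords, _ = topo.megabase_density_pca(pd.concat([df, dup], ignore_index=True),
                                          toy_bundle, window_size=50_000,
                                          min_mutations=100)
    for s in df["sample"].unique():
        d = np.linalg.norm(coords.loc[s] - coords.loc[s + "_copy"])
        assert d < 1e-12


def test_density_pca_excludes_low_burden_samples(frames, toy_bundle):
    with pytest.raises(ValueError, match="fewer than two eligible"):
        topo.megabase_density_pca(frames["sporadic"], toy_bundle,
                                  window_size=50_000, min_mutations=10**9)


def test_density_pca_window_order_invariance(frames, toy_bundle):
    """Relabeling contigs (hence permuting window order) leaves the
    embedding unchanged up to the deterministic sign convention."""
    df = frames["sporadic"]
    coords, _ = topo.megabase_density_pca(df, toy_bundle, window_size=50_000,
                                          min_mutations=100)
    relabeled = df.copy()
    relabeled["contig"] = relabeled["contig"].map({"chr1": "chr2", "chr2": "chr1"})
    seqs = {("chr2" if c == "chr1" else "chr1"): toy_bundle.codes(c)
            for c, _ in toy_bundle.contigs}
    tracks = {}
    for name, tr in toy_bundle.tracks.items():
        tracks[name] = type(tr)({("chr2" if c == "chr1" else "chr1"): v
                                 for c, v in tr.data.items()})
    from uvscape.genome_model import ReferenceBundle
    b2 = ReferenceBundle(seqs, tracks=tracks)
    coords2, _ = topo.megabase_density_pca(relabeled, b2, window_size=50_000,
                                           min_mutations=100)
    assert np.allclose(np.abs(coords.to_numpy()),
                       np.abs(coords2.reindex(coords.index).to_numpy()), atol=1e-9)
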