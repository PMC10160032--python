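"""Mutation matrices, distances, embeddings, clustering, signature refits."""

import numpy as np
import pandas as pd
import pytest

from uvscape import mutation_profiles as mp
from uvscape.classify import (SBS96_LABELS, UV12_LABELS, dbs_tetra_label,
                              records_frame, sbs96_label)
from uvscape.genome_model import MutationRecord, ReferenceBundle, encode, revcomp


def test_catalog_combinatorics():
    assert len(SBS96_LABELS) == 96
    assert len(set(SBS96_LABELS)) == 96
    assert len(UV12_LABELS) == 12


def test_sbs96_label_examples():
    assert sbs96_label("C", "T", "TCA") == "T[C>T]A"
    # purine reference maps through the reverse complement: TGC with G>A
    assert sbs96_label("G", "A", "TGC") == "G[C>T]A"
    assert sbs96_label("C", "T", "TNA") is None
    assert sbs96_label("C", "T", "TAA") is None  # center mismatch


def test_sbs96_label_strand_collapse_invariance():
    rng = np.random.default_rng(0)
    for _ in range(200):
        ctx = "".join(rng.choice(list("ACGT"), 3))
        ref = ctx[1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        assert sbs96_label(ref, alt, ctx) == \
            sbs96_label(revcomp(ref), revcomp(alt), revcomp(ctx))


def test_dbs_tetra_label():
    assert dbs_tetra_label("CC", "TT", "ACCA") == "A[CC>TT]A"
    assert dbs_tetra_label("GG", "AA", "TGGT") == "A[CC>TT]A"
    assert dbs_tetra_label("TG", "CA", "ATGA") is None


def _mini_bundle():
    # chr1: TCACCGTGCA -> contexts around each position are exact
    return ReferenceBundle({"chr1": encode("TCACCGTGCA")})


def test_build_sbs96_counts_and_brute_force():
    bundle = _mini_bundle()
    recs = [
        MutationRecord("s1", "chr1", 2, "C", "T"),   # TCA -> T[C>T]A
        MutationRecord("s1", "chr1", 8, "G", "A"),   # TGC revcomp -> G[C>T]A
        MutationRecord("s1", "chr1", 1, "T", "G"),   # contig edge -> skipped
        MutationRecord("s2", "chr1", 4, "C", "A"),   # ACC -> A[C>A]C
    ]
    mat = mp.build_sbs96(recs, bundle)
    assert mat.loc["s1", "T[C>T]A"] == 1
    assert mat.loc["s1", "G[C>T]A"] == 1
    assert mat.loc["s2", "A[C>A]C"] == 1
    assert mat.attrs["skipped"] == 1
    assert mat.loc["s1"].sum() == 2 and mat.loc["s2"].sum() == 1


def test_build_sbs96_equals_brute_force_on_cohort(small_cohort, small_bundle):
    recs = [r for r in small_cohort.all_records if r.vclass == "SBS"]
    mat = mp.build_sbs96(recs, small_bundle)
    brute: dict[tuple, int] = {}
    comp = str.maketrans("ACGT", "TGCA")
    for r in recs:
        ctx = small_bundle.sequence(r.contig, r.pos0 - 1, r.pos0 + 2)
        if len(ctx) != 3 or "N" in ctx:
            continue
        ref, alt = r.ref, r.alt
        if ref in "AG":
            ctx = ctx.translate(comp)[::-1]
            ref, alt = ref.translate(comp), alt.translate(comp)
        label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
        brute[(r.sample, label)] = brute.get((r.sample, label), 0) + 1
    for (sample, label), n in brute.items():
        assert mat.loc[sample, label] == n
    assert mat.to_numpy().sum() == sum(brute.values())


def test_stranded_matrix_truth_table(tiny_bundle):
    # gA: '+' gene on chr1 [20,120); template is '-'
    recs = []
    seq = tiny_bundle.sequence("chr1", 0, 200)
    pos_c = next(i for i in range(30, 110) if seq[i] == "C" and "N" not in seq[i-1:i+2])
    pos_g = next(i for i in range(30, 110) if seq[i] == "G" and "N" not in seq[i-1:i+2])
    recs.append(MutationRecord("s", "chr1", pos_c + 1, "C", "T"))  # pyr on '+': untranscribed
    recs.append(MutationRecord("s", "chr1", pos_g + 1, "G", "A"))  # pyr on '-': transcribed
    recs.append(MutationRecord("s", "chr1", 5, "A", "T"))          # intergenic: excluded
    mat = mp.build_stranded(recs, tiny_bundle)
    assert mat.filter(like="U:").to_numpy().sum() == 1
    assert mat.filter(like="T:").to_numpy().sum() == 1
    assert mat.to_numpy().sum() == 2


def test_stranded_sums_match_genic_sbs96(small_cohort, small_bundle):
    df = records_frame(small_cohort.all_records, small_bundle)
    stranded = mp.build_stranded(df, small_bundle)
    for lab in SBS96_LABELS:
        pair = stranded[f"T:{lab}"] + stranded[f"U:{lab}"]
        assert (pair >= 0).all()
    assert stranded.to_numpy().sum() > 0


def test_uv_subset_selects_12_flanking_pyrimidine_classes():
    mat = pd.DataFrame(1, index=["s"], columns=list(SBS96_LABELS))
    sub = mp.uv_subset(mat)
    assert sub.shape[1] == 12
    assert "T[C>T]A" in sub.columns      # 5' pyrimidine
    assert "A[C>T]G" not in sub.columns  # both flanks purine
    assert sub.loc["s"].sum() <= mat.loc["s"].sum()


def test_cosine_matrix_matches_formula():
    rng = np.random.default_rng(3)
    profiles = pd.DataFrame(rng.random((3, 96)), columns=list(SBS96_LABELS))
    S = mp.cosine_matrix(profiles)
    X = profiles.to_numpy()
    for i in range(3):
        for j in range(3):
            expect = X[i] @ X[j] / (np.linalg.norm(X[i]) * np.linalg.norm(X[j]))
            assert S.iloc[i, j] == pytest.approx(expect, abs=1e-12)
    assert np.allclose(np.diag(S), 1.0)
    disjoint = pd.DataFrame([[1, 0, 0], [0, 1, 0]], columns=["a", "b", "c"], dtype=float)
    assert mp.cosine_matrix(disjoint).iloc[0, 1] == pytest.approx(0.0)


def test_cosine_matrix_zero_norm_raises():
    profiles = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["ok", "empty"])
    with pytest.raises(ValueError, match="empty"):
        mp.cosine_matrix(profiles)


def test_classical_mds_reconstructs_euclidean_distances():
    rng = np.random.default_rng(4)
    pts = rng.random((5, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    sim = pd.DataFrame(1 - D)  # mds converts back to D = 1 - sim
    emb = mp.mds_embedding(sim, n_components=2)
    got = np.sqrt(((emb.to_numpy()[:, None] - emb.to_numpy()[None]) ** 2).sum(-1))
    assert np.allclose(got, D, atol=1e-9)


def test_mds_identical_samples_coincide_and_modes():
    sim = pd.DataFrame(np.ones((3, 3)))
    emb = mp.mds_embedding(sim)
    assert np.allclose(emb.to_numpy(), emb.to_numpy()[0], atol=1e-9)
    with pytest.raises(ValueError):
        mp.mds_embedding(pd.DataFrame([[1.0, 0.2], [0.5, 1.0]]))
    with pytest.raises(ValueError):
        mp.mds_embedding(sim, mode="bogus")
    emb2 = mp.mds_embedding(pd.DataFrame(np.eye(3)), mode="pca_on_distance")
    assert emb2.shape == (3, 2)


def test_hierarchical_clustering_merge_count_and_heights(frames, toy_bundle):
    sim = pd.DataFrame(np.ones((4, 4)))
    Z = mp.hierarchical_clustering(sim)
    assert Z.shape == (3, 4)  # n - 1 merges
    assert np.allclose(Z[:, 2], 0.0)  # identical samples merge at height 0


def test_refit_exact_mixture_and_orthogonal():
    rng = np.random.default_rng(5)
    S = pd.DataFrame(rng.dirichlet(np.ones(96), 2).T,
                     index=list(SBS96_LABELS), columns=["A", "B"])
    profile = pd.Series(S.to_numpy() @ np.array([0.6, 0.4]) * 1000, index=S.index)
    res = mp.refit_signatures(profile, S)
    assert res["cosine_dissimilarity"] < 1e-10
    expos = res["exposures"] / res["exposures"].sum()
    assert expos["A"] == pytest.approx(0.6, abs=1e-8)
    # profile orthogonal to the signatures -> zero exposures, dissimilarity 1
    S2 = pd.DataFrame(0.0, index=list(SBS96_LABELS), columns=["A"])
    S2.iloc[0, 0] = 1.0
    prof2 = pd.Series(0.0, index=list(SBS96_LABELS))
    prof2.iloc[1] = 5.0
    res2 = mp.refit_signatures(prof2, S2)
    assert res2["exposures"]["A"] == pytest.approx(0.0, abs=1e-12)
    assert res2["cosine_dissimilarity"] == pytest.approx(1.0)


def test_refit_matches_grid_search_oracle():
    """NNLS solution beats / matches an exhaustive 2-signature grid search."""
    rng = np.random.default_rng(6)
    S = pd.DataFrame(rng.dirichlet(np.ones(96), 2).T,
                     index=list(SBS96_LABELS), columns=["A", "B"])
    true = np.array([3.0, 7.0])
    y = S.to_numpy() @ true + rng.dirichlet(np.ones(96)) * 0.5
    profile = pd.Series(y, index=S.index)
    res = mp.refit_signatures(profile, S)
    Sm = S.to_numpy()
    best, best_e = np.inf, None
    for a in np.arange(0, 10.01, 0.1):
        for b in np.arange(0, 10.01, 0.1):
            r = np.linalg.norm(y - Sm @ np.array([a, b]))
            if r < best:
                best, best_e = r, (a, b)
    nnls_resid = np.linalg.norm(y - Sm @ res["exposures"].to_numpy())
    assert nnls_resid <= best + 1e-9
    assert res["exposures"]["A"] == pytest.approx(best_e[0], abs=0.1)
    assert res["exposures"]["B"] == pytest.approx(best_e[1], abs=0.1)


def test_refit_residual_never_increases_with_extra_signature():
    rng = np.random.default_rng(7)
    S = pd.DataFrame(rng.dirichlet(np.ones(96), 3).T,
                     index=list(SBS96_LABELS), columns=["A", "B", "C"])
    profile = pd.Series(rng.random(96), index=S.index)
    r2 = mp.refit_signatures(profile, S[["A", "B"]])
    r3 = mp.refit_signatures(profile, S)
    def resid(res):
        return np.linalg.norm(profile.to_numpy() - res["reconstruction"].to_numpy())
    assert resid(r3) <= resid(r2) + 1e-9


def test_refit_uv12_mode_restricts_and_renormalizes():
    rng = np.random.default_rng(8)
    S = pd.DataFrame(rng.dirichlet(np.ones(96), 2).T,
                     index=list(SBS96_LABELS), columns=["A", "B"])
    prof = pd.Series(rng.random(96), index=S.index)
    res = mp.refit_signatures(prof, S, mode="uv12")
    assert len(res["reconstruction"]) == 12
    with pytest.raises(ValueError):
        mp.refit_signatures(prof * 0, S)


def test_profile_summaries_arithmetic(tiny_bundle):
    seq = tiny_bundle.sequence("chr1", 0, 200)
    # craft: 2 CC>TT doublets + C>T mutations in pyrimidine context
    recs = []
    n_uv = 0
    for i in range(1, 150):
        if seq[i] == "C" and seq[i - 1] in "CT" and n_uv < 10:
            recs.append(MutationRecord("s", "chr1", i + 1, "C", "T"))
            n_uv += 1
    cc = [i for i in range(1, 150) if seq[i:i + 2] == "CC"][:2]
    for i in cc:
        recs.append(MutationRecord("s", "chr1", i + 1, "CC", "TT"))
    summ = mp.profile_summaries(recs, tiny_bundle)
    assert summ.loc["s", "n_dbs_cctt"] == 2
    assert summ.loc["s", "dbs_ratio"] == pytest.approx(2 / 10)
    assert summ.loc["s", "tmb_per_mb"] == pytest.approx((10 + 2) / (360 / 1e6))


def test_profile_summaries_no_dbs_gives_zero_ratio(tiny_bundle):
    recs = [MutationRecord("s", "chr1", 14, "C", "T")]
    summ = mp.profile_summaries(recs, tiny_bundle)
    assert summ.loc["s", "dbs_ratio"] in (0.0,) or np.isnan(summ.loc["s", "dbs_ratio"])
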