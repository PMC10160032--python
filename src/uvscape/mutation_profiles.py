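"""Mutation-matrix construction, profile distances, embeddings, clustering,
and refitting against fixed UV signatures.

Matrices are pandas DataFrames: samples as rows, context classes as columns
in the fixed catalog order of :mod:`uvscape.classify`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .classify import (DBS_TETRA_LABELS, SBS96_LABELS, UV12_LABELS,
                       assign_gene, records_frame)
from .genome_model import ReferenceBundle


def _as_frame(records, bundle):
    if isinstance(records, pd.DataFrame):
        return records
    return records_frame(records, bundle)


def build_sbs96(records, bundle: ReferenceBundle) -> pd.DataFrame:
    """Samples x 96 count matrix of single-base substitutions.

    Purine-reference mutations map to the reverse-complement pyrimidine
    class; records with invalid (N or edge) contexts are skipped and the
    number of skips is stored in ``result.attrs['skipped']``.
    """
    df = _as_frame(records, bundle)
    sbs = df[df["vclass"] == "SBS"]
    classified = sbs[sbs["label"].notna()]
    mat = (classified.groupby(["sample", "label"]).size().unstack(fill_value=0)
           .reindex(columns=SBS96_LABELS, fill_value=0))
    mat = mat.reindex(sorted(mat.index))
    mat.attrs["skipped"] = int(len(sbs) - len(classified))
    return mat


def build_stranded(records, bundle: ReferenceBundle) -> pd.DataFrame:
    """Samples x 192 matrix: the 96 classes split by lesion strand.

    Only mutations inside single-strand gene bodies count; the lesion strand
    is the strand carrying the pyrimidine of the canonical class, and a
    lesion on the template strand of its gene is "transcribed" (T:), else
    "untranscribed" (U:).  Mutations in territory covered by genes on both
    strands are excluded; their number lands in ``attrs['excluded_overlap']``.
    """
    df = assign_gene(_as_frame(records, bundle), bundle)
    genic = df[(df["vclass"] == "SBS") & df["label"].notna()]
    overlap = int(genic["both_strands"].sum())
    genic = genic[genic["strand_class"].notna()]
    genic = genic.assign(slabel=genic["strand_class"].str[0].str.upper() + ":" + genic["label"])
    columns = [f"{s}:{lab}" for s in "TU" for lab in SBS96_LABELS]
    mat = (genic.groupby(["sample", "slabel"]).size().unstack(fill_value=0)
           .reindex(columns=columns, fill_value=0))
    mat = mat.reindex(sorted(mat.index))
    mat.attrs["excluded_overlap"] = overlap
    return mat


def build_dbs_tetra(records, bundle: ReferenceBundle) -> pd.DataFrame:
    """Samples x 16 matrix of CC>TT doublets in tetranucleotide context."""
    df = _as_frame(records, bundle)
    dbs = df[(df["vclass"] == "DBS") & df["label"].notna()]
    mat = (dbs.groupby(["sample", "label"]).size().unstack(fill_value=0)
           .reindex(columns=DBS_TETRA_LABELS, fill_value=0))
    return mat.reindex(sorted(mat.index))


def uv_subset(matrix: pd.DataFrame) -> pd.DataFrame:
    """Restrict an SBS-96 matrix to the 12 UV contexts (YC>YT / CY>TY)."""
    return matrix[list(UV12_LABELS)]


def cosine_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between sample profiles (rows)."""
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm profile for sample(s) {list(profiles.index[zero])}")
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=profiles.index, columns=profiles.index)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # deterministic sign: largest-magnitude loading positive per axis
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return coords


def mds_embedding(similarity: pd.DataFrame, mode: str = "classical_mds",
                  n_components: int = 2) -> pd.DataFrame:
    """Embed samples from a cosine-similarity matrix.

    classical_mds: double-centered eigendecomposition of -D^2/2 with
    D = 1 - similarity; pca_on_distance: principal components of the
    distance-matrix rows (mirrors running PCA directly on the distances).
    Both are deterministic up to sign, fixed by making the largest-magnitude
    loading positive.
    """
    S = similarity.to_numpy(dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    D = 1.0 - S
    n = D.shape[0]
    if mode == "classical_mds":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        w, v = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:n_components]
        coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    elif mode == "pca_on_distance":
        centered = D - D.mean(axis=0, keepdims=True)
        _u, s, vt = np.linalg.svd(centered, full_matrices=False)
        coords = centered @ vt[:n_components].T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    coords = _fix_signs(coords)
    return pd.DataFrame(coords, index=similarity.index,
                        columns=[f"dim{i + 1}" for i in range(coords.shape[1])])


def hierarchical_clustering(similarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration on cosine distance; returns the scipy
    linkage matrix (deterministic merge order)."""
    D = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def top_split_labels(Z: np.ndarray, n: int) -> np.ndarray:
    """Two-cluster membership from the final merge of a linkage matrix."""
    from scipy.cluster.hierarchy import fcluster
    return fcluster(Z, t=2, criterion="maxclust")


def refit_signatures(profile: pd.Series, signatures: pd.DataFrame,
                     mode: str = "all96") -> dict:
    """Non-negative least-squares refit of a profile onto fixed signatures.

    exposures solve min ||profile - S e||_2 with e >= 0 (active-set NNLS);
    dissimilarity = 1 - cosine(observed, reconstructed).  In uv12 mode both
    profile and signatures are restricted to the 12 UV contexts and the
    signature columns renormalized on that subspace.
    """
    if mode not in ("all96", "uv12"):
        raise ValueError(f"unknown mode {mode!r}")
    sigs = signatures.copy()
    prof = profile.astype(float)
    if mode == "uv12":
        labels = [l for l in UV12_LABELS if l in sigs.index]
        sigs = sigs.loc[labels]
        sigs = sigs / sigs.sum(axis=0)
        prof = prof.loc[labels]
    else:
        prof = prof.reindex(sigs.index, fill_value=0.0)
    if prof.sum() == 0:
        raise ValueError("all-zero profile cannot be refit")
    S = sigs.to_numpy(dtype=float)
    y = prof.to_numpy(dtype=float)
    exposures, _res = nnls(S, y)
    recon = S @ exposures
    denom = np.linalg.norm(y) * np.linalg.norm(recon)
    cos = float(y @ recon / denom) if denom > 0 else 0.0
    return {
        "exposures": pd.Series(exposures, index=sigs.columns),
        "reconstruction": pd.Series(recon, index=sigs.index),
        "cosine_dissimilarity": 1.0 - cos,
        "mode": mode,
    }


def load_signatures(path: str) -> pd.DataFrame:
    """Read a 96-row signature TSV (contexts x signatures), columns
    normalized to sum to 1 (validated to 1e-6)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        df = df / sums
    return df


def profile_summaries(records, bundle: ReferenceBundle,
                      analyzable_mb: float | None = None) -> pd.DataFrame:
    """Per-sample burden and class-composition summary.

    Columns: n_sbs, n_dbs_cctt, tmb_per_mb (over analyzable territory, the
    masked genome when `analyzable_mb` is given, else the full genome),
    dbs_ratio = CC>TT / (C>T with flanking pyrimidine), pct_c_to_a,
    pct_t_in_tt (T>A/C/G with 5' T and 3' pyrimidine partner counted over
    the TT-context classes).
    """
    df = _as_frame(records, bundle)
    if analyzable_mb is None:
        analyzable_mb = sum(n for _c, n in bundle.contigs) / 1e6
    rows = []
    for sample, sub in df.groupby("sample"):
        sbs = sub[(sub["vclass"] == "SBS") & sub["label"].notna()]
        n_sbs = len(sbs)
        n_dbs = int(((sub["vclass"] == "DBS") & sub["label"].notna()).sum())
        uv_ct = int(sbs["label"].isin(UV12_LABELS).sum())
        c_to_a = int(sbs["label"].str.contains("C>A", regex=False).sum())
        t_in_tt = int((sbs["label"].str.startswith("T[T")).sum())
        rows.append({
            "sample": sample,
            "n_sbs": n_sbs,
            "n_dbs_cctt": n_dbs,
            "tmb_per_mb": (n_sbs + n_dbs) / analyzable_mb,
            "dbs_ratio": n_dbs / uv_ct if uv_ct else (0.0 if n_dbs == 0 else np.nan),
            "pct_c_to_a": 100.0 * c_to_a / n_sbs if n_sbs else np.nan,
            "pct_t_in_tt": 100.0 * t_in_tt / n_sbs if n_sbs else np.nan,
        })
    return pd.DataFrame(rows).set_index("sample")


def group_mean_sem(summaries: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group mean +/- SEM (SD/sqrt(n)) of every numeric summary column."""
    df = summaries.join(groups.rename("group"))
    agg = df.groupby("group").agg(["mean", "sem", "count"])
    return agg
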