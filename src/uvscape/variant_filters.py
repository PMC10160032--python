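"""Somatic-variant filtration stack.

Hard caller-quality thresholds, mappability/blacklist region masks, the
per-sample SVM classifier that separates genuine UV doublets (CC:GG>TT:AA)
from formalin-fixation artifacts (TG:CA>CA:TG), and the cell-line clonality
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .genome_model import IntervalSet, MutationRecord, NumericTrack

log = logging.getLogger(__name__)

DEFAULT_COST_GRID = (0.001, 0.01, 0.1, 1, 5, 10, 100)
DEFAULT_FEATURES = ("CONTQ", "SEQQ", "STRANDQ", "TLOD")


@dataclass
class HardFilterConfig:
    min_total_reads: int = 3
    min_reads_per_strand: int = 1
    min_vaf: float = 0.05
    min_popaf: float = 5.0  # -log10 population allele frequency
    require_pass: bool = True

    def __post_init__(self):
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf outside [0, 1]")
        if min(self.min_total_reads, self.min_reads_per_strand) < 0 or self.min_popaf < 0:
            raise ValueError("thresholds must be non-negative")


def apply_hard_filters(records: list[MutationRecord], config: HardFilterConfig | None = None,
                       lenient_missing: bool = False
                       ) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Keep records passing all caller-quality thresholds.

    A record is kept iff PASS (when required), alt support >= 3 total with
    >= 1 read on each strand, VAF > 0.05 and POPAF > 5.  Each dropped record
    is tagged with the first failing rule; kept + dropped partition the input.
    """
    config = config or HardFilterConfig()
    kept, dropped = [], []
    for rec in records:
        alt_reads = rec.adf + rec.adr
        reason = None
        if config.require_pass and rec.filter != "PASS":
            reason = "not_pass"
        elif alt_reads < config.min_total_reads:
            reason = "low_support"
        elif min(rec.adf, rec.adr) < config.min_reads_per_strand:
            reason = "strand_support"
        elif not (rec.vaf > config.min_vaf):
            reason = "low_vaf"
        else:
            popaf = rec.info.get("POPAF")
            if popaf is None or np.isnan(popaf):
                if not lenient_missing:
                    reason = "missing_annotation"
            elif not (popaf > config.min_popaf):
                reason = "low_popaf"
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return kept, dropped


def apply_region_masks(records: list[MutationRecord], mappability: NumericTrack | None = None,
                       blacklist: IntervalSet | None = None,
                       min_score: float = 1.0) -> list[MutationRecord]:
    """Remove records in low-alignability territory (score < 1, or uncovered
    by the mappability track) and records inside blacklist intervals."""
    kept = []
    n_uncovered = 0
    for rec in records:
        if blacklist is not None and bool(blacklist.contains(rec.contig, rec.pos0)[0]):
            continue
        if mappability is not None:
            score = float(mappability.value_at(rec.contig, rec.pos0)[0])
            if np.isnan(score):
                n_uncovered += 1
                continue
            if score < min_score:
                continue
        kept.append(rec)
    if n_uncovered:
        log.warning("%d records outside mappability coverage treated as score < 1", n_uncovered)
    return kept


# ---------------------------------------------------------------------------
# FFPE artifact SVM
# ---------------------------------------------------------------------------

def ffpe_label(rec: MutationRecord) -> str:
    """true_like for CC:GG>TT:AA doublets, artifact_like for TG:CA>CA:TG."""
    key = (rec.ref, rec.alt)
    if key in (("CC", "TT"), ("GG", "AA")):
        return "true_like"
    if key in (("TG", "CA"), ("CA", "TG")):
        return "artifact_like"
    return "unlabeled"


def build_feature_matrix(records: list[MutationRecord],
                         pileup: pd.DataFrame | None = None,
                         features: tuple[str, ...] = DEFAULT_FEATURES) -> pd.DataFrame:
    """Flat numeric feature table per record, with labels.

    `pileup` optionally supplies BAM-derived alt-allele statistics as a
    table keyed by (sample, contig, pos, alt); its numeric columns are
    appended to the caller annotations.
    """
    rows = []
    for rec in records:
        row = {f: rec.info.get(f, np.nan) for f in features}
        row["label"] = ffpe_label(rec)
        rows.append(row)
    df = pd.DataFrame(rows)
    if pileup is not None:
        key = pd.DataFrame({"sample": [r.sample for r in records],
                            "contig": [r.contig for r in records],
                            "pos": [r.pos for r in records],
                            "alt": [r.alt for r in records]})
        merged = key.merge(pileup, on=["sample", "contig", "pos", "alt"], how="left")
        extra = merged.drop(columns=["sample", "contig", "pos", "alt"])
        df = pd.concat([df.drop(columns="label"), extra, df[["label"]]], axis=1)
    return df


@dataclass
class FFPEModel:
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    chosen_cost: float
    cost_grid: tuple[float, ...]
    threshold: float
    heldout_accuracy: float
    medians: pd.Series = field(repr=False, default=None)

    def prob_true(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: model expects {self.feature_names}, got {tuple(X.columns)}")
        Xf = X.fillna(self.medians)
        classes = list(self.pipeline.classes_)
        return self.pipeline.predict_proba(Xf.to_numpy())[:, classes.index("true_like")]


def train_ffpe_classifier(features: pd.DataFrame, seed: int = 0,
                          cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
                          min_per_class: int = 50, threshold: float = 0.95,
                          calibration: str = "isotonic") -> FFPEModel:
    """Per-sample training procedure.

    Labeled doublets are split (seeded) into disjoint 25% tuning / 50%
    training / 25% held-out subsets.  The soft-margin cost is tuned on the
    tuning subset by cross-validated accuracy over the fixed grid, then an
    RBF SVM (bandwidth 1/n_features after standardization) with probability
    calibration is fit on the training subset.

    Calibration defaults to isotonic regression on cross-validated decision
    values: when the two labeled classes are strongly separated the
    empirical posterior is step-like and the parametric (Platt sigmoid)
    alternative caps high-confidence probabilities below the retention
    threshold; "sigmoid" is available for the classic behavior.
    """
    labeled = features[features["label"].isin(["true_like", "artifact_like"])]
    counts = labeled["label"].value_counts()
    if counts.get("true_like", 0) < min_per_class or counts.get("artifact_like", 0) < min_per_class:
        raise ValueError("insufficient labeled variants; FFPE filtering skipped for sample")
    feat_cols = tuple(c for c in features.columns if c != "label")
    X = labeled[list(feat_cols)]
    medians = X.median()
    X = X.fillna(medians).to_numpy()
    y = labeled["label"].to_numpy()

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labeled))
    n = len(idx)
    tune_idx = idx[: n // 4]
    train_idx = idx[n // 4: n // 4 + n // 2]
    hold_idx = idx[n // 4 + n // 2:]

    # tuning uses the plain decision machine; the final model adds Platt
    # calibration (cross-validated sigmoid) for the probability output
    def make_svc(cost):
        return Pipeline([("scale", StandardScaler()),
                         ("svm", SVC(C=cost, kernel="rbf", gamma="auto",
                                     random_state=seed))])

    if len(cost_grid) > 1:
        _, tune_counts = np.unique(y[tune_idx], return_counts=True)
        cv = int(max(2, min(10, tune_counts.min())))
        search = GridSearchCV(make_svc(1.0), {"svm__C": list(cost_grid)}, cv=cv,
                              scoring="accuracy", n_jobs=1)
        search.fit(X[tune_idx], y[tune_idx])
        scores = search.cv_results_["mean_test_score"]
        best = scores.max()
        # on separable samples whole stretches of the grid tie at perfect
        # accuracy; break ties toward the default cost 1 (extreme small C
        # underfits the decision function and coarsens the calibration)
        tied = [c for c, s in zip(cost_grid, scores) if s >= best - 1e-12]
        chosen = float(min(tied, key=lambda c: abs(np.log10(c))))
    else:
        chosen = float(cost_grid[0])

    _, train_counts = np.unique(y[train_idx], return_counts=True)
    cal_cv = int(max(2, min(10, train_counts.min())))
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", CalibratedClassifierCV(SVC(C=chosen, kernel="rbf", gamma="auto",
                                           random_state=seed),
                                       method=calibration, cv=cal_cv, ensemble=False)),
    ])
    pipe.fit(X[train_idx], y[train_idx])
    heldout = float((pipe.predict(X[hold_idx]) == y[hold_idx]).mean()) if len(hold_idx) else float("nan")
    model = FFPEModel(pipe, feat_cols, chosen, tuple(cost_grid), threshold, heldout, medians)
    # sanity: the model must at least recognise its own true-like examples
    p_self = model.prob_true(labeled[labeled["label"] == "true_like"][list(feat_cols)])
    if p_self.mean() <= 0.5:
        log.warning("FFPE model assigns mean P(true)=%.2f to its own true-like set", p_self.mean())
    return model


def score_and_filter_ffpe(model: FFPEModel, records: list[MutationRecord],
                          features: pd.DataFrame, threshold: float | None = None
                          ) -> tuple[list[MutationRecord], np.ndarray]:
    """Keep records with calibrated P(true_like) > threshold.

    Labeled training variants are scored like any other record.
    """
    threshold = model.threshold if threshold is None else threshold
    feat_cols = [c for c in features.columns if c != "label"]
    probs = model.prob_true(features[feat_cols])
    kept = [rec for rec, p in zip(records, probs) if p > threshold]
    return kept, probs


# ---------------------------------------------------------------------------
# Cell-line clonality filter
# ---------------------------------------------------------------------------

def clonal_filter_cellline(per_clone: dict[str, list[MutationRecord]],
                           min_vaf: float = 0.3,
                           min_total_reads: int = 3,
                           min_reads_per_strand: int = 1) -> dict[str, list[MutationRecord]]:
    """Keep clone-unique, strictly clonal variants.

    Variants shared between any two clones are removed from all of them;
    then the read-support rule and VAF > min_vaf apply.
    """
    if len(per_clone) < 2:
        log.warning("single clone supplied; shared-variant removal skipped")
        shared: set = set()
    else:
        seen: dict[tuple, int] = {}
        for recs in per_clone.values():
            for rec in recs:
                key = (rec.contig, rec.pos, rec.ref, rec.alt)
                seen[key] = seen.get(key, 0) + 1
        shared = {k for k, c in seen.items() if c > 1}
    out = {}
    for clone, recs in per_clone.items():
        kept = []
        for rec in recs:
            if (rec.contig, rec.pos, rec.ref, rec.alt) in shared:
                continue
            alt_reads = rec.adf + rec.adr
            if alt_reads < min_total_reads or min(rec.adf, rec.adr) < min_reads_per_strand:
                continue
            if not rec.vaf > min_vaf:
                continue
            kept.append(rec)
        out[clone] = kept
    return out
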