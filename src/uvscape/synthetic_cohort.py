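"""Synthetic UV-mutagenesis cohort simulator.

Generates toy reference bundles and tumor cohorts whose mutation sets carry
the lesion/repair/bypass structure of the repair-deficiency groups
(sporadic, XP-A/C/D/E/V, POLH-knockout):

* **Lesions** — independent Bernoulli draws per eligible dinucleotide site
  per strand: pyrimidine dimers (CPD, 6-4PP) at YY sites, rare photoproducts
  at TA/TG dinucleotides.
* **Repair** — global-genome NER removes a lesion with probability
  ``gg_scale * g0 * (1 - gamma_rt * rtRank)`` where ``rtRank`` is the
  within-contig replication-timing quantile (0 = earliest, most accessible).
  On the transcribed (template) strand of annotated genes in TC-proficient
  cells, transcription-coupled NER takes over exclusively: the stalled
  transcription machinery shields the lesion from global-genome sensing, and
  the lesion is removed with probability ``t0 * h(expr)``, where
  ``h(e) = e/(e + h_k)`` saturates with expression.  The coupling continues
  past the transcription end site with the shielding/removal probability
  decaying as ``exp(-d / l_ext)``.
* **Translesion synthesis** — with polymerase eta present, surviving dimers
  mutate with probability ``mu_eta`` and a C>T-dominated spectrum; without
  it (XP-V / POLH-KO) backup inserters err with probability ``mu_backup``,
  at the 3' base of the dimer with probability ``beta_3prime``, and with a
  broader spectrum that also mutates thymines.  Rare TA/TG photoproducts are
  bypassed near-error-free by polymerase eta but become strongly mutagenic
  without it, yielding TA>TT / TG>TT-type changes (T>A and C>A classes).

Every emitted variant is traceable to a ground-truth lesion row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (Gene, GeneSet, MutationRecord, NumericTrack,
                           ReferenceBundle, encode, revcomp, write_vcf)

log = logging.getLogger(__name__)

_PYR = (1, 3)   # C, T codes
_PUR = (0, 2)   # A, G codes
_BASE = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    n_contigs: int = 2
    contig_length: int = 1_500_000
    gc: float = 0.42


@dataclass
class GeneSpec:
    n_genes: int = 24
    length_min: int = 6_000
    length_max: int = 14_000
    expression_mu: float = 2.8   # lognormal log-mean (median RPKM ~ 16)
    expression_sigma: float = 1.2
    coding: bool = True
    edge_margin: int = 55_000    # clean flank kept free of other genes


@dataclass
class TrackSpec:
    window: int = 1_000
    tad_block: int = 500_000
    rt_active: tuple[float, float] = (60.0, 95.0)
    rt_inactive: tuple[float, float] = (5.0, 40.0)
    rt_replicates: int = 3
    rt_replicate_sd: float = 3.0
    mark_noise_sd: float = 5.0
    mappability_holes: tuple[tuple[int, int, int], ...] = ()  # (contig_idx, start, end)


@dataclass
class LesionRates:
    """Expected lesions per eligible dinucleotide site per strand.

    `exposure_sigma` is the log-SD of a per-tumor lognormal exposure factor
    scaling all three rates together, emulating dose variation between
    tumors (it is what couples the per-tumor burdens of the different
    photoproduct classes)."""
    cpd: float = 0.035
    pp64: float = 0.010
    rare: float = 0.012
    exposure_sigma: float = 0.4


@dataclass
class RepairParams:
    g0: float = 0.8          # baseline GG-NER removal probability
    gamma_rt: float = 0.9    # coupling of GG-NER to replication timing
    t0: float = 0.9          # TC-NER removal probability at saturating expression
    h_k: float = 2.0         # expression half-saturation (RPKM)
    l_ext: float = 13_000.0  # post-TES exponential decay length (bp)
    ext_cutoff: float = 80_000.0
    gg_scale: float = 1.0
    tc_scale: float = 1.0


@dataclass
class TLSParams:
    pol_eta: bool = True
    mu_eta: float = 0.25       # error probability per bypassed dimer (pol eta)
    mu_backup: float = 0.55    # error probability per dimer without pol eta
    beta_3prime: float = 0.55  # fraction of dimer errors at the 3' base
    t_accept_eta: float = 0.05     # error acceptance at T bases, pol eta
    t_accept_backup: float = 0.35  # error acceptance at T bases, backup TLS
    dbs_prob: float = 0.20     # CC dimer error -> CC>TT doublet probability
    mu_rare_eta: float = 0.02      # rare TA/TG photoproduct mutation prob, pol eta
    mu_rare_backup: float = 0.90   # without pol eta
    spectrum_eta: dict = field(default_factory=lambda: {
        "C": {"T": 0.94, "A": 0.03, "G": 0.03},
        "T": {"A": 0.50, "C": 0.40, "G": 0.10},
    })
    spectrum_backup: dict = field(default_factory=lambda: {
        "C": {"T": 0.75, "A": 0.20, "G": 0.05},
        "T": {"A": 0.60, "C": 0.35, "G": 0.05},
    })
    spectrum_rare: dict = field(default_factory=lambda: {
        "A": {"T": 0.85, "C": 0.10, "G": 0.05},
        "G": {"T": 0.90, "A": 0.05, "C": 0.05},
    })


@dataclass
class FFPESpec:
    enabled: bool = False
    n_artifacts: int = 800       # injected TG:CA>CA:TG doublets per tumor
    separation_sd: float = 4.0   # per-feature mean shift, in pooled SDs
    feature_means: dict = field(default_factory=lambda: {
        "CONTQ": 60.0, "SEQQ": 60.0, "STRANDQ": 50.0, "TLOD": 40.0})
    feature_sds: dict = field(default_factory=lambda: {
        "CONTQ": 10.0, "SEQQ": 10.0, "STRANDQ": 12.0, "TLOD": 10.0})


@dataclass
class SimulationConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    tracks: TrackSpec = field(default_factory=TrackSpec)
    lesions: LesionRates = field(default_factory=LesionRates)
    repair: RepairParams = field(default_factory=RepairParams)
    tls: TLSParams = field(default_factory=TLSParams)
    ffpe: FFPESpec = field(default_factory=FFPESpec)
    group: str = "sporadic"

    def validate(self) -> None:
        r, t, l = self.repair, self.tls, self.lesions
        for name, p in [("g0", r.g0), ("gamma_rt", r.gamma_rt), ("t0", r.t0),
                        ("gg_scale", r.gg_scale), ("tc_scale", r.tc_scale),
                        ("mu_eta", t.mu_eta), ("mu_backup", t.mu_backup),
                        ("beta_3prime", t.beta_3prime), ("dbs_prob", t.dbs_prob)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if min(l.cpd, l.pp64, l.rare) < 0:
            raise ValueError("lesion rates must be non-negative")
        if r.l_ext <= 0:
            raise ValueError("l_ext must be positive")
        for spec in (t.spectrum_eta, t.spectrum_backup, t.spectrum_rare):
            for base, probs in spec.items():
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"substitution spectrum for {base} does not sum to 1")


def _apply_overrides(obj, overrides: dict):
    for key, val in overrides.items():
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply_overrides(cur, val)
        elif isinstance(cur, dict) and isinstance(val, dict):
            cur.update(val)
        else:
            setattr(obj, key, tuple(val) if isinstance(cur, tuple) else val)


def preset(name: str, **section_overrides) -> SimulationConfig:
    """Load a packaged group preset (sporadic, xpa, xpc, xpd, xpe, xpv, polh_ko)."""
    path = resources.files("uvscape").joinpath("presets", f"{name}.json")
    if not path.is_file():
        raise ValueError(f"unknown preset {name!r}")
    overrides = json.loads(path.read_text())
    overrides.pop("description", None)
    cfg = SimulationConfig(group=name)
    _apply_overrides(cfg, overrides)
    _apply_overrides(cfg, section_overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Toy reference construction
# ---------------------------------------------------------------------------

def _random_orf(length: int, rng: np.random.Generator) -> str:
    """Random open reading frame of `length` bases (multiple of 3)."""
    n_codons = length // 3
    codons = ["ATG"]
    sense = [c for c in ("".join(p) for p in itertools.product(_BASE, repeat=3))
             if c not in STOP_CODONS]
    codons += [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def build_toy_reference(config: SimulationConfig, seed: int) -> ReferenceBundle:
    """Deterministic toy genome with genes, RT/chromatin/mappability tracks."""
    rng = np.random.default_rng(seed)
    gspec, gene_spec, tspec = config.genome, config.genes, config.tracks
    gc = gspec.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences = {}
    for i in range(gspec.n_contigs):
        sequences[f"chr{i + 1}"] = rng.choice(4, size=gspec.contig_length,
                                              p=probs).astype(np.uint8)

    # Slot-based gene placement keeps flanks clean for anchored profiles.
    genes: list[Gene] = []
    if gene_spec.n_genes:
        per_contig = [gene_spec.n_genes // gspec.n_contigs] * gspec.n_contigs
        for i in range(gene_spec.n_genes % gspec.n_contigs):
            per_contig[i] += 1
        gid = 0
        for ci, n_here in enumerate(per_contig):
            contig = f"chr{ci + 1}"
            if n_here == 0:
                continue
            slot = gspec.contig_length // n_here
            for j in range(n_here):
                length = int(rng.integers(gene_spec.length_min, gene_spec.length_max + 1))
                lo = j * slot + gene_spec.edge_margin
                hi = (j + 1) * slot - gene_spec.edge_margin - length
                if hi <= lo:
                    raise ValueError(
                        "genes cannot be placed without overlap; lower the gene "
                        "count or edge margin")
                start = int(rng.integers(lo, hi))
                strand = "+" if rng.random() < 0.5 else "-"
                expr = float(rng.lognormal(gene_spec.expression_mu,
                                           gene_spec.expression_sigma))
                exons: list[tuple[int, int]] = []
                if gene_spec.coding:
                    n_ex = int(rng.integers(2, 5))
                    cds_len = 3 * int(rng.integers(60, 160))
                    cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), n_ex - 1,
                                              replace=False)) * 3
                    ex_lens = np.diff(np.concatenate([[0], cuts, [cds_len]]))
                    intron = max((length - cds_len) // max(n_ex - 1, 1), 60)
                    pos = start + 30
                    for el in ex_lens:
                        exons.append((pos, pos + int(el)))
                        pos += int(el) + intron
                    if exons[-1][1] > start + length:
                        exons = [(start + 30, start + 30 + cds_len)]
                    orf = _random_orf(cds_len, rng)
                    # genomic concatenation of exons spells the CDS ('+')
                    # or its reverse complement ('-')
                    cds = encode(orf if strand == "+" else revcomp(orf))
                    cursor = 0
                    seq = sequences[contig]
                    for s, e in exons:
                        seq[s:e] = cds[cursor:cursor + (e - s)]
                        cursor += e - s
                genes.append(Gene(f"g{gid:03d}", contig, strand, start,
                                  start + length, expr, exons))
                gid += 1

    # Tracks on a fixed window grid.
    window = tspec.window
    tracks: dict[str, NumericTrack] = {}
    rt_data, tad_data, map_data = {}, {}, {}
    mark_open, mark_closed = {}, {}
    rt_reps: list[dict] = [dict() for _ in range(tspec.rt_replicates)]
    for ci, (contig, codes) in enumerate(sequences.items()):
        n_win = -(-len(codes) // window)
        starts = np.arange(n_win, dtype=np.int64) * window
        ends = np.minimum(starts + window, len(codes))
        block = starts // tspec.tad_block
        active = block % 2 == 0
        lo = np.where(active, tspec.rt_active[0], tspec.rt_inactive[0])
        hi = np.where(active, tspec.rt_active[1], tspec.rt_inactive[1])
        rt = lo + rng.random(n_win) * (hi - lo)
        rt_data[contig] = (starts, ends, rt)
        tad_data[contig] = (starts, ends, active.astype(float))
        mark_open[contig] = (starts, ends, rt + rng.normal(0, tspec.mark_noise_sd, n_win))
        mark_closed[contig] = (starts, ends, 100 - rt + rng.normal(0, tspec.mark_noise_sd, n_win))
        for rep in rt_reps:
            rep[contig] = (starts, ends, rt + rng.normal(0, tspec.rt_replicate_sd, n_win))
        mp = np.ones(n_win)
        for hc, hs, he in tspec.mappability_holes:
            if hc == ci:
                mp[(starts >= hs) & (starts < he)] = 0.0
        map_data[contig] = (starts, ends, mp)
    tracks["rt"] = NumericTrack(rt_data)
    tracks["tad_state"] = NumericTrack(tad_data)
    tracks["mark_open"] = NumericTrack(mark_open)
    tracks["mark_closed"] = NumericTrack(mark_closed)
    tracks["mappability"] = NumericTrack(map_data)
    for i, rep in enumerate(rt_reps, 1):
        tracks[f"rt_rep{i}"] = NumericTrack(rep)
    return ReferenceBundle(sequences, GeneSet(genes), tracks, {})


# ---------------------------------------------------------------------------
# Lesion formation
# ---------------------------------------------------------------------------

def simulate_lesions(bundle: ReferenceBundle, config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw photoproduct lesions per eligible site per strand.

    Returns one row per lesion: contig, start0 (plus-strand coordinate of the
    dinucleotide's left base), strand, ltype in {CPD, 64PP, TA, TG},
    five_base/three_base read on the lesion strand.
    """
    rates = config.lesions
    rows = []
    for contig, codes in ((c, bundle.codes(c)) for c, _ in bundle.contigs):
        d1, d2 = codes[:-1], codes[1:]
        pyr1 = (d1 == 1) | (d1 == 3)
        pyr2 = (d2 == 1) | (d2 == 3)
        pur1 = (d1 == 0) | (d1 == 2)
        pur2 = (d2 == 0) | (d2 == 2)
        eligible = {
            ("dimer", "+"): np.flatnonzero(pyr1 & pyr2),
            ("dimer", "-"): np.flatnonzero(pur1 & pur2),
            ("TA", "+"): np.flatnonzero((d1 == 3) & (d2 == 0)),
            ("TA", "-"): np.flatnonzero((d1 == 3) & (d2 == 0)),
            ("TG", "+"): np.flatnonzero((d1 == 3) & (d2 == 2)),
            ("TG", "-"): np.flatnonzero((d1 == 1) & (d2 == 0)),  # plus CA
        }
        draws = [("CPD", "dimer", rates.cpd), ("64PP", "dimer", rates.pp64),
                 ("TA", "TA", rates.rare), ("TG", "TG", rates.rare)]
        for ltype, key, lam in draws:
            if lam <= 0:
                continue
            for strand in "+-":
                sites = eligible[(key, strand)]
                if sites.size == 0:
                    continue
                hit = sites[rng.random(sites.size) < lam]
                if hit.size == 0:
                    continue
                if strand == "+":
                    fb, tb = d1[hit], d2[hit]
                else:
                    fb, tb = 3 - d2[hit].astype(np.int16), 3 - d1[hit].astype(np.int16)
                for pos, f, t in zip(hit, fb, tb):
                    rows.append((contig, int(pos), strand, ltype, _BASE[f], _BASE[t]))
    df = pd.DataFrame(rows, columns=["contig", "start0", "strand", "ltype",
                                     "five_base", "three_base"])
    return df.sort_values(["contig", "start0", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Repair
# ---------------------------------------------------------------------------

def rt_rank_arrays(bundle: ReferenceBundle, track_name: str = "rt") -> dict[str, np.ndarray]:
    """Per-contig array of RT quantile ranks per track window (0 = earliest,
    i.e. the highest RT value).  NaN where the track is missing."""
    track = bundle.tracks[track_name]
    out = {}
    for contig, (starts, _ends, values) in track.data.items():
        order = np.argsort(np.argsort(-values, kind="stable"), kind="stable")
        n = len(values)
        out[contig] = (order + 0.5) / n
    return out


def _tc_engagement(lesions: pd.DataFrame, bundle: ReferenceBundle,
                   rp: RepairParams) -> tuple[np.ndarray, np.ndarray]:
    """Shielding probability and TC removal probability per lesion.

    A lesion on the template strand within a gene body is shielded with
    probability tc_scale; past the TES both shielding and removal decay as
    exp(-d/l_ext).
    """
    n = len(lesions)
    shield = np.zeros(n)
    remove = np.zeros(n)
    if rp.tc_scale <= 0 or len(bundle.genes) == 0:
        return shield, remove
    pos = lesions["start0"].to_numpy()
    strand = lesions["strand"].to_numpy()
    contig = lesions["contig"].to_numpy()
    for g in bundle.genes:
        h = g.expression / (g.expression + rp.h_k)
        on = (contig == g.contig) & (strand == g.template_strand)
        if not on.any():
            continue
        p = pos[on]
        if g.strand == "+":
            in_body = (p >= g.start) & (p < g.end)
            d = p - g.end + 1.0
        else:
            in_body = (p >= g.start) & (p < g.end)
            d = (g.start - 1.0) - p
        downstream = (~in_body) & (d > 0) & (d <= rp.ext_cutoff)
        decay = np.zeros(p.shape)
        decay[in_body] = 1.0
        decay[downstream] = np.exp(-d[downstream] / rp.l_ext)
        sh = rp.tc_scale * decay
        idx = np.flatnonzero(on)
        better = sh > shield[idx]
        shield[idx[better]] = sh[better]
        remove[idx[better]] = rp.t0 * h
    return shield, remove


def apply_repair(lesions: pd.DataFrame, bundle: ReferenceBundle,
                 config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each lesion a repair outcome; returns the table with
    ``repaired`` (bool), ``pathway`` ('GG'/'TC'/None), and ``rt_rank``."""
    rp = config.repair
    lesions = lesions.copy()
    n = len(lesions)
    if n == 0:
        lesions["rt_rank"] = np.empty(0)
        lesions["repaired"] = np.empty(0, dtype=bool)
        lesions["pathway"] = np.empty(0, dtype=object)
        return lesions
    ranks = rt_rank_arrays(bundle)
    window = config.tracks.window
    rt_rank = np.full(n, 0.5)
    missing = 0
    for contig, sub in lesions.groupby("contig"):
        arr = ranks.get(contig)
        w = (sub["start0"].to_numpy() // window)
        if arr is None:
            missing += len(sub)
            continue
        ok = w < len(arr)
        rt_rank[sub.index[ok]] = arr[w[ok]]
        missing += int((~ok).sum())
    if missing:
        log.warning("%d lesions outside RT coverage; using median rank", missing)
    p_gg = rp.gg_scale * rp.g0 * (1.0 - rp.gamma_rt * rt_rank)
    shield, p_tc = _tc_engagement(lesions, bundle, rp)
    shielded = rng.random(n) < shield
    u = rng.random(n)
    repaired = np.where(shielded, u < p_tc, u < p_gg)
    pathway = np.full(n, None, dtype=object)
    pathway[repaired & shielded] = "TC"
    pathway[repaired & ~shielded] = "GG"
    lesions["rt_rank"] = rt_rank
    lesions["shielded"] = shielded
    lesions["repaired"] = repaired
    lesions["pathway"] = pathway
    return lesions


# ---------------------------------------------------------------------------
# Translesion synthesis
# ---------------------------------------------------------------------------

def _draw_from_spectrum(bases: np.ndarray, spectrum: dict, rng: np.random.Generator) -> np.ndarray:
    """Vectorized substitution draw; `bases` is an array of ref base chars."""
    out = np.empty(bases.shape, dtype=object)
    for base, probs in spectrum.items():
        sel = bases == base
        if not sel.any():
            continue
        alts = list(probs)
        p = np.asarray([probs[a] for a in alts])
        out[sel] = np.asarray(alts, dtype=object)[rng.choice(len(alts), sel.sum(), p=p / p.sum())]
    return out


def apply_tls(lesions: pd.DataFrame, config: SimulationConfig,
              rng: np.random.Generator, sample: str = "tumor") -> tuple[list[MutationRecord], pd.DataFrame]:
    """Replicate across surviving lesions; emit mutations and the truth table.

    Truth columns extend the lesion table with mutated, at_3prime, ref/alt
    (plus-strand), pos (1-based), is_dbs.
    """
    tls = config.tls
    truth = lesions.copy()
    n = len(truth)
    mutated = np.zeros(n, dtype=bool)
    at_3prime = np.zeros(n, dtype=bool)
    ref = np.full(n, None, dtype=object)
    alt = np.full(n, None, dtype=object)
    pos1 = np.zeros(n, dtype=np.int64)
    is_dbs = np.zeros(n, dtype=bool)

    surv = ~truth["repaired"].to_numpy() if "repaired" in truth else np.ones(n, dtype=bool)
    dimer = truth["ltype"].isin(["CPD", "64PP"]).to_numpy()
    rare = ~dimer

    # --- pyrimidine dimers ---
    mu = tls.mu_eta if tls.pol_eta else tls.mu_backup
    t_accept = tls.t_accept_eta if tls.pol_eta else tls.t_accept_backup
    spectrum = tls.spectrum_eta if tls.pol_eta else tls.spectrum_backup
    cand = np.flatnonzero(surv & dimer)
    if cand.size and mu > 0:
        err = cand[rng.random(cand.size) < mu]
        three = rng.random(err.size) < tls.beta_3prime
        bases = np.where(three, truth["three_base"].to_numpy()[err],
                         truth["five_base"].to_numpy()[err]).astype(object)
        accept = np.where(bases == "T", rng.random(err.size) < t_accept, True)
        err, three, bases = err[accept], three[accept], bases[accept]
        if err.size:
            subs = _draw_from_spectrum(bases.astype(str), spectrum, rng)
            cc = ((truth["five_base"].to_numpy()[err] == "C")
                  & (truth["three_base"].to_numpy()[err] == "C")
                  & (rng.random(err.size) < tls.dbs_prob))
            strands = truth["strand"].to_numpy()[err]
            starts = truth["start0"].to_numpy()[err]
            mutated[err] = True
            at_3prime[err] = three
            is_dbs[err] = cc
            # doublets: CC>TT on the lesion strand
            dd = np.flatnonzero(cc)
            for i in dd:
                j = err[i]
                if strands[i] == "+":
                    ref[j], alt[j], pos1[j] = "CC", "TT", starts[i] + 1
                else:
                    ref[j], alt[j], pos1[j] = "GG", "AA", starts[i] + 1
            ss = np.flatnonzero(~cc)
            for i in ss:
                j = err[i]
                b, s = str(bases[i]), str(subs[i])
                if strands[i] == "+":
                    p0 = starts[i] + (1 if three[i] else 0)
                    ref[j], alt[j], pos1[j] = b, s, p0 + 1
                else:
                    p0 = starts[i] + (0 if three[i] else 1)
                    ref[j], alt[j], pos1[j] = _COMP[b], _COMP[s], p0 + 1

    # --- rare TA/TG photoproducts: error at the 3' purine ---
    mu_r = tls.mu_rare_eta if tls.pol_eta else tls.mu_rare_backup
    cand = np.flatnonzero(surv & rare)
    if cand.size and mu_r > 0:
        err = cand[rng.random(cand.size) < mu_r]
        if err.size:
            bases = truth["three_base"].to_numpy()[err].astype(str)
            subs = _draw_from_spectrum(bases, tls.spectrum_rare, rng)
            strands = truth["strand"].to_numpy()[err]
            starts = truth["start0"].to_numpy()[err]
            mutated[err] = True
            at_3prime[err] = True
            for i, j in enumerate(err):
                b, s = str(bases[i]), str(subs[i])
                if strands[i] == "+":
                    ref[j], alt[j], pos1[j] = b, s, starts[i] + 2
                else:
                    ref[j], alt[j], pos1[j] = _COMP[b], _COMP[s], starts[i] + 1

    truth["mutated"] = mutated
    truth["at_3prime"] = at_3prime
    truth["ref"] = ref
    truth["alt"] = alt
    truth["pos"] = pos1
    truth["is_dbs"] = is_dbs

    records = []
    seen = set()
    for row in truth[truth["mutated"]].itertuples():
        key = (row.contig, row.pos)
        if key in seen:  # two lesions resolving at the same site: keep first
            continue
        seen.add(key)
        records.append(MutationRecord(sample, row.contig, int(row.pos),
                                      str(row.ref), str(row.alt)))
    return records, truth


# ---------------------------------------------------------------------------
# Quality annotations + FFPE artifact injection
# ---------------------------------------------------------------------------

def _attach_qualities(records: list[MutationRecord], ffpe: FFPESpec,
                      rng: np.random.Generator, artifact: bool) -> None:
    shift = ffpe.separation_sd if artifact else 0.0
    for rec in records:
        info = {}
        for key, mean in ffpe.feature_means.items():
            sd = ffpe.feature_sds[key]
            info[key] = float(rng.normal(mean - shift * sd, sd))
        info["POPAF"] = float(np.clip(rng.normal(7.0, 1.0), 0, 12))
        rec.info = info
        vaf = float(np.clip(rng.beta(8, 12) if not artifact else rng.beta(3, 14), 0.02, 0.98))
        dp = max(int(rng.poisson(60)), 8)
        altn = max(int(round(vaf * dp)), 1)
        adf = int(rng.binomial(altn, 0.5))
        rec.vaf, rec.dp, rec.adf, rec.adr = altn / dp, dp, adf, altn - adf


def inject_ffpe_artifacts(bundle: ReferenceBundle, ffpe: FFPESpec,
                          rng: np.random.Generator, sample: str) -> list[MutationRecord]:
    """Inject TG:CA>CA:TG doublet artifacts at random TG/CA sites."""
    recs = []
    contigs = bundle.contigs
    lens = np.asarray([n for _c, n in contigs], dtype=float)
    p = lens / lens.sum()
    made = 0
    while made < ffpe.n_artifacts:
        ci = rng.choice(len(contigs), p=p)
        contig, n = contigs[ci]
        pos0 = int(rng.integers(0, n - 1))
        dinuc = bundle.sequence(contig, pos0, pos0 + 2)
        if dinuc == "TG":
            recs.append(MutationRecord(sample, contig, pos0 + 1, "TG", "CA"))
            made += 1
        elif dinuc == "CA":
            recs.append(MutationRecord(sample, contig, pos0 + 1, "CA", "TG"))
            made += 1
    return recs


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------

@dataclass
class TumorResult:
    sample: str
    group: str
    records: list[MutationRecord]
    truth: pd.DataFrame | None
    summary: dict


@dataclass
class CohortResult:
    bundle: ReferenceBundle
    config: SimulationConfig
    tumors: list[TumorResult]

    @property
    def all_records(self) -> list[MutationRecord]:
        return [r for t in self.tumors for r in t.records]

    def write(self, outdir: str) -> dict:
        """Write per-tumor VCFs, truth TSVs, bundle files and a manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bundle.write_fasta(str(out / "reference.fa"))
        self.bundle.genes.to_table(str(out / "genes.tsv"))
        for name, track in self.bundle.tracks.items():
            track.to_bedgraph(str(out / f"track_{name}.bedgraph"))
        manifest = {"group": self.config.group, "tumors": []}
        for t in self.tumors:
            vcf = out / f"{t.sample}.vcf"
            write_vcf(t.records, str(vcf), self.bundle.contigs, t.sample)
            entry = {"sample": t.sample, "vcf": vcf.name,
                     "sha256": hashlib.sha256(vcf.read_bytes()).hexdigest(),
                     **{k: v for k, v in t.summary.items()}}
            if t.truth is not None:
                tp = out / f"{t.sample}.truth.tsv"
                t.truth.to_csv(tp, sep="\t", index=False)
                entry["truth"] = tp.name
            manifest["tumors"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def simulate_tumor(bundle: ReferenceBundle, config: SimulationConfig,
                   rng: np.random.Generator, sample: str,
                   keep_truth: bool = True) -> TumorResult:
    if config.lesions.exposure_sigma > 0:
        factor = float(rng.lognormal(0.0, config.lesions.exposure_sigma))
        config = dataclasses.replace(
            config, lesions=dataclasses.replace(
                config.lesions, cpd=config.lesions.cpd * factor,
                pp64=config.lesions.pp64 * factor,
                rare=config.lesions.rare * factor))
    lesions = simulate_lesions(bundle, config, rng)
    lesions = apply_repair(lesions, bundle, config, rng)
    records, truth = apply_tls(lesions, config, rng, sample=sample)
    _attach_qualities(records, config.ffpe, rng, artifact=False)
    n_true = len(records)
    if config.ffpe.enabled:
        artifacts = inject_ffpe_artifacts(bundle, config.ffpe, rng, sample)
        _attach_qualities(artifacts, config.ffpe, rng, artifact=True)
        records = records + artifacts
    summary = {
        "group": config.group,
        "n_lesions": int(len(truth)),
        "n_repaired": int(truth["repaired"].sum()),
        "n_mutations": n_true,
        "n_artifacts": len(records) - n_true,
        "n_dbs": int(truth["is_dbs"].sum()),
    }
    return TumorResult(sample, config.group, records,
                       truth if keep_truth else None, summary)


def simulate_cohort(config: SimulationConfig, n_tumors: int, seed: int,
                    bundle: ReferenceBundle | None = None,
                    keep_truth: bool = True) -> CohortResult:
    """Simulate `n_tumors` genomes under one group preset.

    One master seed spawns independent per-tumor streams, so results are
    reproducible and order-independent.  The reference bundle is built from
    the master seed unless one is shared in.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    bundle_seed, *tumor_seeds = ss.spawn(n_tumors + 1)
    if bundle is None:
        bundle = build_toy_reference(config, seed)
    tumors = []
    for i, child in enumerate(tumor_seeds):
        rng = np.random.default_rng(child)
        tumors.append(simulate_tumor(bundle, config, rng,
                                     f"{config.group}_t{i:02d}", keep_truth))
    return CohortResult(bundle, config, tumors)


# ---------------------------------------------------------------------------
# Analytic helpers (closed forms used by tests and the acceptance script)
# ---------------------------------------------------------------------------

def implied_rt_fold(config: SimulationConfig, n_bins: int = 8) -> float:
    """Latest/earliest mutation-fraction fold implied by the GG-NER RT
    coupling, at the mean rank of the extreme quantile bins."""
    rp = config.repair
    r_late = 1.0 - 0.5 / n_bins
    r_early = 0.5 / n_bins
    s = lambda r: 1.0 - rp.gg_scale * rp.g0 * (1.0 - rp.gamma_rt * r)
    return s(r_late) / s(r_early)


def xr_track_from_truth(truth: pd.DataFrame, bundle: ReferenceBundle,
                        window: int = 1000, pathway: str | None = None) -> dict[str, NumericTrack]:
    """Repair-event density tracks (per strand) — the simulator's XR-seq.

    Counts repaired lesions per window; `pathway` restricts to 'TC' or 'GG'.
    """
    rep = truth[truth["repaired"]]
    if pathway is not None:
        rep = rep[rep["pathway"] == pathway]
    out = {}
    for strand in "+-":
        data = {}
        sub = rep[rep["strand"] == strand]
        for contig, n in bundle.contig_lengths.items():
            n_win = -(-n // window)
            starts = np.arange(n_win, dtype=np.int64) * window
            ends = np.minimum(starts + window, n)
            counts = np.zeros(n_win)
            here = sub[sub["contig"] == contig]
            if len(here):
                np.add.at(counts, here["start0"].to_numpy() // window, 1.0)
            data[contig] = (starts, ends, counts)
        out[strand] = NumericTrack(data)
    return out
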