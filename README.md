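# uvscape

Analysis toolkit for UV-induced somatic mutagenesis in skin cancers with
defects of nucleotide excision repair (NER) or translesion synthesis (TLS),
together with a synthetic-cohort simulator of those deficiency groups.

Skin tumors accumulate C>T mutations at pyrimidine dimers (CPD and 6-4PP
photoproducts).  How many of those lesions become mutations depends on two
repair routes — global-genome NER (GG-NER), which scans the whole genome
and works best in early-replicating open chromatin, and
transcription-coupled NER (TC-NER), which clears the transcribed strand of
expressed genes — and on how the replication fork bypasses what is left:
polymerase η copies dimers near-error-free, while its backup polymerases
err almost exclusively at the 3′ base of the dimer.  Patients of the
xeroderma pigmentosum (XP) complementation groups knock these components
out one at a time (XP-C: GG-NER; XP-A/XP-D: all NER; XP-E: partial GG-NER;
XP-V: polymerase η), so their tumor genomes are natural experiments in
lesion processing.  `uvscape` implements the statistics that read this
biology out of somatic variant calls, for bioinformaticians analyzing such
cohorts:

* **Filtration** — caller-quality hard thresholds, mappability/blacklist
  masks, a per-sample SVM that separates genuine UV doublets (CC:GG>TT:AA)
  from formalin-fixation artifacts (TG:CA>CA:TG) with calibrated
  probabilities, and a clonality filter for cell-line clones.
* **Mutation profiles** — SBS-96 and transcription-strand-split matrices,
  CC>TT tetranucleotide doublet profiles, cosine distances, classical MDS,
  average-linkage clustering, and non-negative least-squares refitting
  against fixed UV signatures (exposures `e ≥ 0` minimizing
  `‖m − S e‖₂`, with the 12-context UV subset NCY>NTY / YCN>YTN available).
* **Topography** — trinucleotide-adjusted mutation fractions
  `f_b ∝ Σ_c (m_bc/o_bc)·w_c` across replication-timing bins (log-linear
  slopes and latest/earliest folds), TAD-boundary bins, chromatin-mark
  quantiles, and megabase-scale density PCA.
* **Strand bias and repair** — transcriptional bias
  TRB = N(untranscribed)/N(transcribed) per sample and per expression bin,
  TSS/TES-anchored stranded meta-profiles (±50 kb, 10-kb bins) that expose
  TC-NER activity continuing past transcription end sites, XR-seq track
  aggregation normalized by dipyrimidine opportunity, and a relative GG-NER
  efficiency estimator `e_g = 1 − TRB_g/TRB_null`.
* **Dimer translesion bias** — 3′ vs 5′ mutation allocation inside
  unambiguous dimers (ACCA, ATTA) with exact binomial intervals, and the
  4-mer-normalized ATCA>ATTA / ACTA>ATTA ratio.
* **Coding impact** — codon-aware consequence calls (doublets included) and
  damaging/silent ratios, with an exhaustive enumeration oracle.
* **Simulation** — `uvscape.synthetic_cohort` generates toy genomes, gene
  sets, replication-timing/chromatin tracks and tumor cohorts under group
  presets (`sporadic`, `xpa`, `xpc`, `xpd`, `xpe`, `xpv`, `polh_ko`),
  emitting VCFs plus a per-lesion ground-truth table, so the entire
  pipeline can be exercised and validated without any external data.

## Worked example

Simulate two polymerase-η-deficient (XP-V-like) tumors and analyze them:

```bash
$ uvscape simulate --preset xpv --tumors 2 --seed 42 --out sim
simulated 2 xpv tumors into sim

$ uvscape dimerbias --vcf sim/xpv_t00.vcf --vcf sim/xpv_t01.vcf \
    --fasta sim/reference.fa --out dimer.tsv
ACCA: pooled 3' fraction 0.961 (5'/3' ratio 0.040) -> dimer.tsv

$ uvscape strandbias --vcf sim/xpv_t00.vcf --fasta sim/reference.fa \
    --genes sim/genes.tsv --out meta.tsv
pooled TRB 2.671 [2.254, 3.210]; meta-profile -> meta.tsv

$ uvscape topography --vcf sim/xpv_t00.vcf --fasta sim/reference.fa \
    --genes sim/genes.tsv --rt-track sim/track_rt.bedgraph \
    --bins 8 --stratum intergenic --out topo.tsv
            slope        se     fold
xpv_t00 -0.173361  0.013122  3.55477
```

The dimer statistic shows 96% of C>T events in the ACCA context arising
from the 3′ cytosine — the fingerprint of error-prone backup bypass (the
preset generates errors at the 3′ base with probability 0.97).  The TRB of
2.7 with a bootstrap CI excluding 1 reflects intact TC-NER depleting
mutations from transcribed strands.  The negative replication-timing slope
(fraction falling ~16% per bin from latest- to earliest-replicating
territory, a 3.6-fold total gradient) reflects GG-NER tracking chromatin
accessibility.  The same functions are importable from Python
(`uvscape.translesion_bias.dimer_positions`,
`uvscape.strand_and_repair.transcriptional_bias`,
`uvscape.topography.adjusted_fractions`, ...), operating on record lists or
classified DataFrames.

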