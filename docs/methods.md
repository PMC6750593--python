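# Methods

## Model

`ribostall` simulates gene expression of a stall-containing mRNA as a
rule-defined continuous-time Markov chain over agent-like molecules.
A DNA template produces capped mRNAs (rate `k_transcription`, default
0.001 s⁻¹ — arbitrary; it sets the steady-state pool at 1–2
translatable mRNAs).  Each mRNA carries:

* a **cap** (present/absent) — required for initiation, must be absent
  for 5'→3' exonucleolysis to enter;
* a **start region** (clear/blocked) — a compact encoding of start-codon
  occlusion: initiation blocks it, elongation off codon 9 (one
  footprint less one) clears it;
* **backbone sites** `r_1..r_Lm` (intact / endocleaved / exocleaved),
  one per codon (`L_m` = 650, matching a ~650-codon reporter CDS);
* a **poly(A) tail** of `L_p` = 60 removable residues;
* bound **ribosomes**, each an A-site position plus two collision bonds
  (`hit_back`: a trailing ribosome collided into it; `hit_front`: it
  collided into a leading ribosome).

Translation is initiation (`k_init`, the swept control variable;
default 0.1 s⁻¹) → elongation (10 s⁻¹ per codon; destination codon and
the codon one footprint ahead must be free) → termination (1 s⁻¹,
slower than elongation to mimic elevated stop-codon density; its exact
value is immaterial while it exceeds per-mRNA throughput).  Ribosomes
occupy 10 codons; two ribosomes at exactly footprint distance collide
at the trailing ribosome's elongation rate, forming an explicit bond
that dissolves when either partner moves or leaves.

A stall is `n_stall` consecutive slow codons starting at codon 401;
each slow codon elongates at `n_stall × net_stall_rate` so the summed
expected dwell across the stall is `1/net_stall_rate` (default net
0.1 s⁻¹) regardless of how the stall is subdivided — this isolates the
effect of the *number* of kinetic partitions.

Canonical decay is sequential: 3'→5' deadenylation (0.03 s⁻¹ per
residue), decapping after complete deadenylation (0.01 s⁻¹), then
5'→3' exonucleolysis (1 s⁻¹ per backbone site) blocked at A-site
codons.  These rates calibrate the mean lifetime to
60/0.03 + 1/0.01 + 1 = 2101 s ≈ 35 min, the measured lifetime of a
stable yeast mRNA.  3'→5' exonucleolysis is modeled but its rate
defaults to 0 (it is much slower in vivo and contributes no full
protein or translatable mRNA).  An mRNA's lifetime is the interval
from transcription to its **first** 5'→3' exonucleolysis event; mRNAs
alive at simulation end are censored and excluded from lifetime means.

### Quality control at the stall

Two event families, each split into four collision channels
(`no_hit`, `back_hit`, `front_hit`, `both_hit`):

* **Abortive termination** removes the ribosome and scores an aborted
  protein, dissolving its bonds.  If the aborting ribosome still
  covers the start region (A site < footprint) the start region is
  vacated — without this, a ribosome aborting at codons 1–9 would
  leave the start blocked forever and silence the mRNA, an artifact
  that inverts the CAT model's phase behavior.
* **Endonucleolytic cleavage** marks backbone site `a_site − L_c`
  endocleaved (`L_c` = 10, placing the cut at the collided interface)
  and removes the cap, so a given mRNA cleaves at most once and stops
  initiating.  Ribosomes that later translocate onto the endocleaved
  site abort at a uniform 1 s⁻¹ (`k_abort_truncated`) regardless of
  collision state — efficient recycling at a truncated 3' end.
  Ribosomes already 3' of the cut finish normally.

**Stall scoping.**  Quality control acts at the stall, not on every
traffic fluctuation: the `no_hit` and `back_hit` channels (and all
cleavage channels) require the acting ribosome's own A site on a slow
codon; the `front_hit` abort channel requires the ribosome's front
partner to be stalled (it "ran into" the stall); `both_hit` abort
accepts either.  Consequences that motivated this choice: stacked
ribosomes deep in a queue are not substrates (so SAT's nonzero
back-hit rate does not bleed the queue), stop-codon mini-queues never
trigger cleavage (keeping SEC's output monotone in initiation rate),
and the CSEC cleavage hazard does not grow with queue length (so SEC
and CSEC saturate at the same cleavage-limited output).

**Presets.**  TJ: all abort channels 0.  SAT: `no = back = k_a`
(collisions neither stimulate nor protect).  CAT: `front = both =
k_a`.  CSAT: `back = both = k_a`.  SEC: cleave `no = back =
k_cleave`.  CSEC: cleave `back = both = k_cleave`.  Defaults `k_a` =
0.5 s⁻¹ and `k_cleave` = 0.001 s⁻¹.  `k_a` is chosen comparable to
the 0.6 s⁻¹ per-slow-codon elongation rate: an aborted stalled leader
is replaced by its trailer within ~1 s, so abort rates well below the
per-codon stall rate leave throughput untouched and the CSAT
high-initiation decrease only emerges for `k_a` ≳ 0.3 s⁻¹ (we mapped
0.1–0.5).  Both are exposed as parameters; in vivo values are
unknown.

### Known deviations and limitations

* Initiation is pseudo-first-order (`k_init` per eligible mRNA): free
  ribosomes, nucleases and decay factors are not depleted.
* The start region clears when a ribosome elongates off codon 9, so an
  initiation in the short window while the leader sits at codon 10
  creates a sub-footprint gap (probability `k_init/(k_init+10)` per
  initiation).  Such pairs cannot overlap or pass (destination-codon
  check) and never collide (collision requires exactly footprint
  distance); the artifact is inherited from the rule encoding and left
  as is.
* Deadenylated-but-capped mRNAs initiate at full efficiency until
  decapped.
* Exonucleolysis is blocked only at A-site codons, not across the full
  footprint; the exonuclease can therefore trail one codon behind a
  translocating ribosome but never removes backbone under an A site.
* Ribosomal ubiquitination kinetics, tRNA pools, codon-specific
  elongation beyond the stall profile, and 40S/60S subunit resolution
  are out of scope.
* Under stall-scoped cleavage with `k_cleave` = 0.001 s⁻¹ the CSEC
  protein-output curve saturates with only a shallow (~8%) decline
  past its peak: the collision tail below the critical initiation rate
  (Poisson arrivals collide even at stall utilization < 1) erodes the
  peak.  A strong output decrease under cleavage alone requires either
  a larger cleavage rate or a cleavage hazard that grows with queue
  length; the latter is incompatible with SEC/CSEC saturating at the
  same value, so we keep the scoped model and document the shallow
  decline.

## Simulation engines

`engine.run` samples the chain exactly with the direct method.  The
production path is a numba kernel over a compressed state (poly(A)
suffix counter, exocleavage prefix counter, one endocleavage index,
sorted ribosome arrays with bond flags); per-mRNA propensity totals
are cached and only the modified mRNA is rescanned after an event, so
cost per event is O(ribosomes on one mRNA).  A pure-Python reference
engine runs directly over the explicit rule set, supports full event
logging and 3'→5' exonucleolysis, and is the oracle the kernel is
validated against (statistical agreement of all counters; enumeration
equality against an independently coded brute-force rule checker;
propensity-normalized inter-event gaps distributed Exp(1)).

Reproducibility: a `(params, duration, seed, engine)` tuple yields an
identical trajectory.  Replicate seeds derive from one base seed via
`numpy.random.SeedSequence`; sweep cells additionally mix in the cell
index.  An event-count cap (default 5×10⁸ fast / 5×10⁶ reference)
guards runaway configurations and is reported on the trajectory, never
silent.

Observables: protein synthesis rate = full proteins / simulated time
(per simulated system; with transcription on this is the per-cell
convention, not per-mRNA), and mean lifetime over uncensored mRNAs.
Sweeps over `k_init` run abort presets in single-mRNA mode
(transcription and decay off, one tracked mRNA) and cleavage presets
with turnover on.

**Problem sizes.**  The package's test suite runs sweeps at 2–10×10⁴ s
of biological time with 4 replicates per grid point and states every
tolerance in replicate standard errors, so the checks scale with the
duration chosen; production-quality curves (standard errors smaller
than plot markers) need ~10⁶ s per point, which the same functions
handle unchanged.

## Sequence and profiling analyses

* **Stall scanning** translates each CDS with the standard code and
  slides a 10-codon window at stride 1 (any coarser stride can miss
  qualifying windows); a window qualifies with ≥ 6 K/R codons or ≥ 6 P
  codons (acidic control: ≥ 6 E/D).  Ambiguous codons (N) never
  match.  Overlapping/abutting windows collapse into maximal regions
  reported by their first window's start codon; a gene's stall
  location is its first region's start.  Genes flagged "Dubious" are
  excluded; CDS lengths not divisible by 3 are rejected per gene.
* **P-site coverage** assigns each footprint read to its 13th
  nucleotide (5' position + 12); out-of-bounds assignments are dropped
  and counted.
* **Metagene density**: per stall window, a 150-nt span (default 60 nt
  upstream flank) is normalized by its own mean coverage, then
  averaged position-wise across windows; the offset axis puts the
  window's first nucleotide at +1.  Zero-coverage windows are
  excluded.
* **TE**: Ribo-seq rpkm / RNA-seq rpkm for genes ≥ 5 rpkm in both
  samples; group difference Δlog₂TE is a difference of group means
  (medians optional) with a two-sided Wilcoxon rank-sum p-value.  The
  upstream-restricted variant sums coverage over CDS nucleotides
  1..3(boundary−1) — boundary = first stall region for stall genes,
  the stall group's median stall location for controls — and requires
  ≥ 100 reads per gene in both assays.
* **Barcode quantification**: exact-match counting of 8-nt barcodes at
  a fixed read offset (no error correction — identification, not
  correction, and exact matching makes collisions the dominant risk at
  depth); barcodes < 100 counts in either the cDNA or gDNA library are
  discarded; reporter level = mean log₂(cDNA/gDNA) over retained
  barcodes ± SE, median-normalized within each 5' UTR variant group.
  Reporters with no retained barcode are reported missing, not zero.

## Synthetic data

The fixture generators produce ground-truth inputs with the
statistical structure of the real assays, deterministically under
(seed, parameters):

* CDS sets draw background codons from residues outside {K,R,P,E,D},
  so qualifying windows exist exactly where implanted; implants place
  their 6 matching residues at window offsets {1–5, 10} so no shifted
  window also qualifies and the recovered region start equals the
  implant coordinate.
* TE tables draw RNA rpkm log-normally and per-gene log₂TE normally
  with a group mean offset (default 0.23 log₂ units, the effect size
  the TE comparison is designed to detect) and dispersion 0.5.
* Coverage tracks are Poisson around a Gaussian ribosome-density bump
  (default center +24 nt into the window, sd 3 nt — a sharp
  P-site-assigned stall peak).
* Barcode read sets draw gDNA counts multinomially uniform and cDNA
  counts proportional to ratio × gDNA share, assembling 50-nt reads
  with the barcode at a fixed offset.

What passing on these fixtures does *not* show: real libraries have
position-dependent coverage bias, multimapping, codon-usage structure
correlated with the scanned residues, and overdispersed counts; the
fixtures validate the arithmetic and thresholds, not robustness to
those artifacts.

## Numerical choices

Propensity selection walks a fixed event order with a cached per-mRNA
total; float roundoff that lets the selection walk fall off the end of
an mRNA's event list (≲1 in 10⁹ events) re-targets the midpoint of a
freshly computed total.  Zero-propensity states terminate the run
early and are recorded (`absorbed_at`).  mRNAs that become inert (no
ribosomes, no enabled events — a bare undegradable 3' fragment) are
retired from the live state; their birth/death records are kept.
Lifetime SE uses the between-replicate spread, not the within-run SD,
wherever replicates exist.
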