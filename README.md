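# ribostall

Stochastic modeling of ribosome collisions and quality control on
stall-containing mRNAs, with companion analyses for ribosome-profiling
and pooled-reporter sequencing data.

## The problem

Polybasic tracts (runs of lysine/arginine codons) and polyproline runs
stall elongating ribosomes.  When initiation is fast enough, trailing
ribosomes collide with the stalled one, and eukaryotic cells respond
with ribosome-associated quality control: abortive termination of the
nascent chain and no-go endonucleolytic cleavage of the mRNA.  The
counterintuitive consequence is that *more* initiation can mean *less*
protein and *less* mRNA from a stall-containing gene.  `ribostall`
implements a rule-based continuous-time Markov chain that couples

* canonical translation — initiation (`k_init`), codon-wise elongation
  with hard-core exclusion (footprint 10 codons), termination;
* collision-stimulated quality control — abortive termination and/or
  endonucleolytic cleavage, with rates conditioned on each ribosome's
  collision state (`no hit`, `hit from back`, `hit from front`, `both`);
* canonical mRNA decay — sequential 3'→5' deadenylation of an `L_p`-
  residue poly(A) tail, decapping, 5'→3' exonucleolysis,

and simulates it exactly with Gillespie's direct method (a numba
kernel for production runs, a transparent pure-Python rule engine for
validation).  Model presets select who responds to a collision:

| preset | quality-control event | who acts |
|--------|----------------------|----------|
| TJ     | none (traffic jam)   | — |
| SAT    | abortive termination | stalled ribosome, collisions irrelevant |
| CAT    | abortive termination | trailing ribosome that hit a stalled one |
| CSAT   | abortive termination | stalled (leading) ribosome when hit from behind |
| SEC    | mRNA cleavage        | stalled ribosome, collisions irrelevant |
| CSEC   | mRNA cleavage        | stalled ribosome only when hit from behind |

The toolkit also implements the downstream sequence analyses: scanning
coding sequences for 10-codon windows with ≥ 6 K/R (or ≥ 6 P) codons,
P-site-assigned metagene density around such windows, translation
efficiency (TE = Ribo-seq rpkm / RNA-seq rpkm, thresholded at 5 rpkm)
compared between stall-containing and stall-free genes, and the
barcode arithmetic of pooled cDNA/gDNA reporter assays (100-count
threshold, log2 ratio, median normalization within 5' UTR variant
sets).

## Worked example

Protein synthesis rate (PSR, full proteins per second) of a single
650-codon mRNA carrying a 6-codon stall (net rate 0.1 s⁻¹ across the
stall, i.e. 0.6 s⁻¹ per slow codon) after 400 codons, under the
collision-stimulated abort model:

```python
from ribostall import sweep

df = sweep("csat", "none", [0.005, 0.02, 0.1, 0.4],
           k_a=0.5, duration=3e4, n_reps=4, base_seed=11)
print(df[["k_init", "psr_mean", "psr_se"]].to_string(index=False))
```

```
 k_init  psr_mean   psr_se
  0.005  0.004870 0.000210
  0.020  0.016790 0.000240
  0.100  0.042880 0.000140
  0.400  0.028090 0.000310
```

Output rises with initiation rate while collisions are rare, peaks
near the stall's net elongation rate, then *falls* at high initiation:
every ribosome that must finish transits the six slow codons under
collision pressure, and each codon is a kinetic partition between
elongation (0.6 s⁻¹) and collision-stimulated abort (`k_a`).  Under
the same conditions the TJ control rises monotonically to ~0.093 s⁻¹
and CAT (trailing ribosome aborts) stays monotone — the decrease is
specific to the *leading* ribosome aborting, and (see
`tests/test_acceptance.py`) disappears when the stall is a single slow
codon instead of several.

The same package reproduces canonical mRNA turnover: with translation
off, deadenylation at 0.03 s⁻¹ over 60 poly(A) residues, decapping at
0.01 s⁻¹ and exonuclease entry at 1 s⁻¹ give a mean mRNA lifetime of
60/0.03 + 1/0.01 + 1/1 = 2101 s = 35 min.

A CLI mirrors the library: `ribostall simulate`, `ribostall sweep`,
`ribostall scan-stalls`, `ribostall metagene`, `ribostall te`,
`ribostall barcode-quant`, `ribostall make-fixtures` (see `--help`).

## Layout

```
src/ribostall/
  params.py         rate constants, presets, YAML config
  kinetic_model.py  state types + the full reaction-rule set
  _kernel.py        numba direct-method SSA kernel
  engine.py         fast/reference engines, trajectories, replicates
  observables.py    PSR, mRNA lifetime, initiation-rate sweeps
  stall_scan.py     10-codon stall/control window scanning
  ribo_te.py        P-site coverage, metagene, TE comparisons
  barcode_quant.py  pooled-reporter barcode quantification
  fixtures.py       deterministic synthetic ground-truth generators
  cli.py            command-line interface
docs/methods.md     model description, assumptions, numerical choices
```
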