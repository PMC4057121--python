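# refstab

Reference-gene stability analysis and efficiency-corrected relative
quantification for qPCR experiments, built around a validated pan-avian
primer panel.

## The problem

Quantitative real-time PCR measures a gene's expression as the cycle
threshold Ct at which amplification becomes detectable. To compare
expression between samples, a target gene is normalized against reference
("housekeeping") genes assumed to be stably expressed — but no gene is
stable in every tissue and condition, so candidate references must be
screened and ranked for each new experimental design. `refstab` implements
that complete workflow for panels like the 14-gene avian set (18S, ABL,
GAPDH, GUSB, HMBS, HPRT, PGK1, RPL13, RPL19, RPS7, SDHA, TFRC, VIM,
YWHAZ) validated across nine bird species:

* **Triplicate QC** — wells are run in technical triplicate; if one Ct
  deviates from the other two by more than 0.5 cycles it is dropped, and a
  well set with no concordant pair fails.
* **Efficiency screening** — each assay's amplification factor per cycle is
  fitted from a ten-fold dilution series as E = 10^(−1/slope) of the
  Ct-vs-log10(dilution) regression; assays are established when percent
  efficiency (E − 1) × 100 lies in 90–110%.
* **Three independent stability rankings** over efficiency-corrected
  relative quantities Q = E^(Ctmin − Ct):
  * *geNorm*: a gene's M value is its mean pairwise log-ratio SD with all
    other candidates; stepwise exclusion of the highest-M gene yields the
    two most stable genes, and the pairwise variation V_n/n+1 < 0.15 rule
    recommends how many references to use;
  * *NormFinder-style model*: decomposes each gene's (sample-centred, log2)
    signal into an inter-group shift and intra-group variance, combining
    both into a stability value; the best *pair* is the one whose averaged
    signal is most stable, letting opposite group biases cancel;
  * *BestKeeper*: ranks genes by raw-Ct SD, CV, and Pearson correlation
    with the per-sample geometric-mean index, combined by mean-of-ranks
    with a spread-based tie-break.
* **Validation by normalization** — targets are divided by the geometric
  mean of the chosen reference pair's quantities and groups compared with
  the exact two-sided Mann–Whitney U test (p < 0.05 \*, p < 0.01 \*\*).

Because raw Ct tables for the original singing-vs-silent zebra finch
experiment are not public, the package includes a synthetic-data module
that generates raw triplicate tables from that study design (5 singing vs
7 silent Area X microbiopsies, 9 stable reference candidates, EGR1/CFOS
induced 8-fold, FOXP2 flat) so the entire pipeline is testable end to end.

## Worked example

```bash
refstab simulate --preset song --seed 3 --out sim.csv   # raw triplicates
refstab qc --in sim.csv --out clean.csv                  # 0.5-cycle rule
refstab stability genorm --in clean.csv
refstab compare --in clean.csv --target EGR1 --refs PGK1,YWHAZ \
    --treatment song --control silent
```

The QC step reports `wrote 12 samples x 12 genes`. The geNorm report for
this seed selects `["RPS7", "SDHA"]` as the final pair with V2/3 = 0.042 —
below the 0.15 cutoff, so `recommended_n` is 2: two reference genes
suffice for this data set. The comparison prints

```
EGR1 vs PGK1/YWHAZ: fold=7.89 (mean-based 8.36) U=0 p=0.002525 [**]
```

i.e. the simulated 8-fold singing induction of EGR1 is recovered above
7-fold and is highly significant (U = 0 means complete group separation;
p = 2/792 is the smallest two-sided value attainable at n = 5 vs 7).

The same stages are available as a library (`refstab.genorm`,
`refstab.normfinder`, `refstab.bestkeeper`, `refstab.quantify`, ...), and
`refstab run --config run.yaml` executes everything in one call, emitting
a side-by-side three-algorithm ranking table with the top four genes per
algorithm highlighted.

The packaged primer panel can be checked against its own design rules
(length 15–25 nt, GC 40–70%, amplicon < 250 bp) with
`refstab panel validate`; note the published panel itself contains three
boundary violations (GAPDH amplicon length, RPL19/SDHA reverse-primer GC),
which the tool reports rather than hides.

## Layout

```
src/refstab/        library modules (panel, ct_data, efficiency, genorm,
                    normfinder, bestkeeper, quantify, synthetic, pipeline, cli)
src/refstab/data/   primer panel and nine-species screening fixtures (CSV)
tests/              pytest suite with independent brute-force oracles
docs/methods.md     models, estimators, parameter choices, limitations
```
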