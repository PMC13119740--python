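# minmark

Minimal SNP marker sets for genebank accession fingerprinting.

Genebanks conserve millions of seed accessions whose identity must survive
decades of regeneration cycles, during which mislabelling and seed mix-ups
are unavoidable. Full genome sequencing or saturated arrays can fingerprint
an accession but are far too expensive for routine quality control, while
morphological comparison can detect errors but rarely correct them. A
*minimal marker set* (MMS) sits in between: the fewest biallelic SNP markers
(typically 20–25 KASP assays) whose joint genotype calls give every
accession in a collection a unique multilocus fingerprint. `minmark`
implements the full in-silico side of that workflow for inbred cereal-style
collections:

- **QC filtering** of genotype matrices (marker call rate and minor allele
  frequency, accession call rate and heterozygosity, monomorphic markers),
- **greedy panel selection** minimising the number of markers needed to
  discriminate all accession pairs, with forced inclusion and exclusion
  lists and panel augmentation for new populations,
- **fingerprinting**: duplicate-group detection, discrimination rates,
  per-group summaries, and QC/QA matching of regenerated stocks against a
  fingerprint registry,
- **robustness simulation** of random marker (assay) failure,
- **marker statistics** (MAF, expected/observed heterozygosity, PIC,
  pairwise LD as r²), and
- a **synthetic-data generator** producing genebank-like panels (diverged
  subpopulations of inbred lines, planted duplicates, pedigree families,
  wild populations) with known ground truth.

## The core algorithm and statistics

Selection is greedy set cover over accession pairs. For a candidate marker
the *incremental discrimination* is the number of accession pairs not
distinguished by any previously selected marker but distinguished by the
candidate — under the default STRICT policy two calls distinguish a pair only
when they are opposite homozygotes; a missing call never distinguishes. The
first pick is the marker with the highest minor allele frequency (the most
even population split); each later pick maximises incremental
discrimination, with ties broken by input order; the loop stops when all
pairs are resolved, no marker adds value, or a size cap is reached. Markers
in complete LD with a selected marker have zero incremental value and are
never chosen.

Per-marker informativeness for a biallelic marker with allele frequencies
*p* and *q* = 1 − *p*:

- He = 1 − (p² + q²)
- PIC = 1 − (p² + q²) − 2p²q²  (maximal 0.375 at p = 0.5)
- MAF = min(p, q); Ho = fraction of heterozygous calls.

The *discrimination rate* of a panel over a population is the percentage of
accessions whose fingerprint is unique (100 × unique/total, two decimals).
Robustness is quantified by removing k random panel markers (k = 1 … n − 1),
200 replicates per level, and recording the mean ± sd of the residual
discrimination rate.

## Worked example

```python
import minmark as mk

cfg = mk.SimConfig(n_markers=2000, n_accessions=500, n_duplicate_pairs=4,
                   pedigree_groups=((6, 40),), seed=7)
gm, truth = mk.simulate_panel(cfg)
gm, _ = mk.filter_markers(gm)        # call rate > 95%, MAF > 5%
gm, _ = mk.drop_monomorphic(gm)
print(f"after QC: {gm.n_accessions} accessions x {gm.n_markers} markers")

panel = mk.select_minimal_markers(gm)
print(f"selected {len(panel)} markers; resolved fraction {panel.resolved_fraction:.4f}")
print("first picks:", panel.markers[:4], "newly resolved:", panel.newly_resolved[:4])

ft = mk.fingerprint_table(gm, panel)
print(f"discrimination rate: {mk.discrimination_rate(ft)}%")
print("duplicate groups found:", [g for g in ft.groups if len(g) > 1])

rob = mk.marker_failure_simulation(gm, panel, reps=200, seed=7)
print(mk.robustness_plot_table(rob).head(6).to_string(index=False))
```

prints

```
after QC: 500 accessions x 1867 markers
selected 14 markers; resolved fraction 1.0000
first picks: ['M00228', 'M00149', 'M00615', 'M00198'] newly resolved: [62250, 31363, 15626, 7799]
discrimination rate: 98.4%
duplicate groups found: [['ACC00000', 'DUP000'], ['ACC00001', 'DUP001'], ['ACC00002', 'DUP002'], ['ACC00003', 'DUP003']]
 k  mean_discrimination       sd  reps
 0               98.400 0.000000   200
 1               94.792 0.929222   200
 2               87.899 1.500820   200
 3               76.574 2.281259   200
 4               58.060 2.891957   200
 5               34.820 2.062540   200
```

Fourteen markers resolve every resolvable pair of the 500 simulated
accessions; the first marker alone splits 62,250 of the 124,750 pairs. The
only accessions without a unique fingerprint are the four planted exact
duplicates (492/500 = 98.4%), which the duplicate report recovers exactly.
The robustness table shows the k = 0 baseline equals the exact panel rate
with zero variance and how discrimination degrades as assays fail — a
minimal panel has no spare redundancy by construction, which is why panels
destined for the wet lab are usually augmented a few markers beyond the
in-silico minimum.

The same workflow is scriptable from a shell: `minmark simulate`, `minmark
filter`, `minmark select`, `minmark fingerprint`, `minmark discriminate`,
`minmark match`, `minmark robustness`, or end-to-end with `minmark run
--config run.yaml` (see `minmark --help`).

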