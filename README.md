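# osmoomics

Tools for analysing how a bacterium responds to hyperosmotic stress when it
largely lacks the classical compatible-solute machinery — the situation in
*Caulobacter crescentus*, which is missing most of the potassium-uptake,
glycine-betaine and trehalose genes that *E. coli* deploys against salt or
sucrose shock. The package implements, as one pipeline, the five
computational procedures such a study needs:

1. **Ortholog screen** (`ortholog_screen`) — a reciprocal best-hit (RBH)
   search of an osmolyte seed panel (kup, trkAHG, kdpABCDEF, glnA, gltBD,
   gdhA, betABCI, betS, proP, proVWZ, proABC, ostAB) against target
   proteomes. Pairs are aligned with local Smith–Waterman under affine gaps
   (BLOSUM62, gap open 11 / extend 1 by default); a hit must reach score
   ≥ 100 and cover ≥ 75% of the hit's length, candidates are ranked by
   percent identity, and a gene is *present* only if the forward best hit
   finds the seed again on the back-search. Output: a seed × organism
   presence/identity matrix (TSV + blue-shaded SVG heatmap, white = absent).
2. **Transcriptome DE caller** (`transcriptome_de`) — probe-level two-color
   log2 ratios (9–11 probes per gene tiled over −300..+200 around the
   translational start) are positionally filtered (only probes at offset
   ≥ +1 count), averaged per gene and replicate, and a gene is called
   up/down only when |mean log2 ratio| > 1 **in all three biological
   replicates**. The same rule on the direct sucrose-vs-NaCl ratios drives
   the G1–G4 stress-comparison grouping and per-category summaries.
3. **Proteome spot statistics** (`proteome_spots`) — 2D-gel spot volumes
   normalized to 100% of each gel's detected quantity, a 0.02% low-abundance
   floor (a spot must fall below it on *every* image to be dropped),
   per-spot standardization, one-way ANOVA over control/NaCl/sucrose at
   α = 0.1, strict two-fold substantial-change calls, RSD reproducibility
   QC, and the MS identification rule (≥ 2 Mowse scores ≥ 50 and coverage
   ≥ 30% → accepted; scores pass but coverage fails → needs MS/MS).
4. **Metabolome quantification** (`metabolome_quant`) — GC-MS analyte peak
   areas divided by the ribitol internal-standard area, condition means over
   three replicates, and two-sided pooled-variance Student's t-tests of each
   stress against the control (p < 0.05).
5. **Treemap rendering** (`treemap_viz`) — a genome-ordered hierarchical
   treemap (TIGR main role → sub-role → operon → gene) where protein log2
   ratios color the cells, mRNA log2 ratios color a circle in each cell and
   the connectors between operon members, on a blue–grey–orange ramp
   saturating at |log2| = 2; genes without data are dark grey.

A synthetic-data module (`synthetic_data`) generates every input kind —
proteome pairs with orthologs planted at controlled identity, probe tables
with planted DE genes, compositional spot tables with planted fold changes,
and peak tables targeting published condition means — so the entire pipeline
is testable without any download. (Real microarray data for this system is
deposited in GEO as GSE49654; no downloader is included.)

## Worked example

```
osmoomics simulate --out sim --seed 1
osmoomics metab --peaks sim/peaks.tsv --out metab
```

prints the publication-style metabolite summary computed from the simulated
peak areas (three replicates per condition, 10% CV):

```
                 control  NaCl  sucrose   p_NaCl  sig_NaCl  p_sucrose  sig_sucrose
analyte
Glucose             10.9  50.4     57.7 9.54e-05      True   8.98e-05         True
L-glutamate         16.9  79.2     55.2  5.4e-05      True   0.000227         True
L-isoleucine       0.203 0.209    0.545    0.782     False   0.000302         True
L-leucine          0.396 0.595    0.914  0.00115      True   9.64e-05         True
L-phenylalanine   0.0612 0.129     0.15 0.000397      True   0.000606         True
L-proline          0.185 0.345    0.444  6.41e-05     True    0.00215         True
```

Each row is one metabolite's mean relative quantity (analyte area /
ribitol area) per condition and the Student's t-test p value of each stress
against the control; note L-isoleucine responds to sucrose but not NaCl, the
pattern the generator plants. The remaining stages run from the same
simulated inputs:

```
osmoomics screen  --source sim/proteome_source.faa --target sim/proteome_target.faa \
                  --seeds SRC_0000,SRC_0005,SRC_0010 --out screen
osmoomics de      --probes sim/probes.tsv --annotation sim/annotation.tsv --out de
osmoomics spots   --table sim/spots.tsv --out spots
osmoomics treemap --annotation sim/annotation.tsv --out treemap.svg
```

printing, for the same seed:

```
3 seeds x 1 organisms, 3 present
NaCl: 20 up, 15 down
sucrose: 20 up, 15 down
200 spots, 53 significant at alpha=0.1, 20 substantial (> 2.0-fold)
200 cells -> treemap.svg
```

— the screen recovers all three planted orthologs, the DE caller recovers
exactly the 20 up / 15 down genes planted per stress, and the spot stage
flags exactly the 20 planted 3-fold spots as substantial.

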