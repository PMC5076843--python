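# quadloop

Toolkit for finding and analysing RNA G-quadruplexes (G4) with an oversized
loop 1 or loop 3 (8–40 nt) in the untranslated regions of mRNAs, and for the
downstream assays used to validate them:

* **g4_scanner** — locates potential G4 motifs (`Gx N1–40 Gx N1–7 Gx N1–7 Gx`
  and its loop-3 mirror, x = 3) with a lazy, non-overlapping parse that
  reports the full track/loop decomposition, restricts hits to UTRs
  (majority rule, signed 1-based UTR coordinates), and collapses
  isoform-redundant hits.
* **cgcc_scoring** — consecutive-G over consecutive-C (cG/cC) fold-propensity
  score on a hit plus 25-nt transcript flanks; ≥ 3.05 likely folded,
  ≤ 2.05 unlikely, in between ambiguous.
* **probing_analysis** — per-nucleotide K+/Li+ band-intensity ratio profiles
  from in-line probing lanes, with a folded/unfolded call (threshold 2 on
  loop nucleotides, G/A mutant as negative control).
* **reporter_stats** — dual-luciferase WT/mutant fold change with an unpaired
  Student's t test on day-level ratios, plus the qPCR CT-ratio mRNA control.
* **synthetic_data** — seeded generators for transcriptomes with planted
  motifs (exact truth tables), probing experiments and reporter plates.
* **oracle** — an independent exhaustive-tiling reference parser used as
  ground truth in the property tests.

## CLI

```sh
# generate a seeded synthetic transcriptome with planted motifs
quadloop simulate transcriptome --n-transcripts 10 \
    --plant "3,3,3,3:38,1,4:utr3" --seed 7 --outdir sim/

# scan transcripts (FASTA + CDS annotation TSV) for long-loop G4 hits
quadloop scan sim/synthetic.fasta sim/synthetic.annotation.tsv \
    --pattern PLL1 --pattern PLL3 --out hits.tsv

# cG/cC score raw sequences (whole record = scoring window)
quadloop score candidates.fasta --out scores.tsv

# in-line probing ratio analysis with a folding verdict
quadloop probe lanes.csv --loops 3-6,10 --ratio-out ratios.tsv \
    --verdict-out verdict.json

# dual-luciferase fold change and qPCR control
quadloop reporter wells.csv --qpcr-csv qpcr.csv --out result.json
```

The annotation TSV has the header `accession  gene  cds_start  cds_end`
(0-based half-open CDS bounds on the spliced transcript). Probing lanes use
long-format CSV columns `position,nucleotide,construct,cation,replicate,intensity`;
luciferase wells use `construct,day,tech_rep,rluc,fluc`.

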