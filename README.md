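# igconvert

Detection, donor annotation and summarisation of **somatic gene conversion
(SGC) events** in immunoglobulin V-region repertoire sequences that
diversify a single functional germline V allele using a library of
pseudogene donors (as in the chicken IgH/IgL loci).

## What it does

For each repertoire sequence:

1. **Event detection** (`event_detection`) — global alignment against the
   functional allele; maximal mismatch stretches are merged under a loose
   (6 nt) and a strict (3 nt) inter-stretch window into candidate
   conversion events; events spanning < 3 nt are dropped, so isolated
   point mutations (SHM-like noise) never become events.
2. **Donor nomination** (`donor_search`) — an in-package seeded local
   aligner (exact 6-mers, step 1, gapped extension, minimum-score filter)
   searches three alignment sets: loose-event queries, the full-length
   observed sequence, and strict-event queries. The best-identity donor is
   nominated with the event-specific Levenshtein distance; events whose
   best match needs more than `0.5 × width` edits (width > 10) are marked
   suboptimal and re-annotated via their strict sub-events; events with no
   adequate donor are reported as unmatched.
3. **Refinement** (`refine_annotate`) — adjacent same-donor events
   separated by functional==donor sequence are merged; every event gets a
   *min* (mismatch-bounded) and a *max* (extended over 100% functional/donor
   identity) interval, 10-nt flanks, the 5′ distance to the nearest AID
   hotspot trinucleotide (AGC, AGT, GGC, GGT, TGC, AAC, TAC), and a flag
   for conversions that introduce a new hotspot.
4. **Summaries** (`repertoire_summary`) — positional event coverage maps,
   per-position pseudogene diversity profiles (Hill number of order 1,
   scores in [1, 4]), donor usage with the > 2% "preferred" rule, usage vs
   germline distance (Spearman, exact small-n p-value), AID-distance
   histograms with a per-position baseline, and a false-discovery control
   mode that swaps the donor library for same-family alleles.
5. **Simulation** (`simulate`) — synthetic repertoires with implanted
   donor tracts, SHM noise and optional template-jumping chimeras, plus a
   recovery scorer; this makes every stage testable without external data.

All exported coordinates are 1-based inclusive on the ungapped functional
allele. IMGT-gapped reference FASTA (dot gaps) is accepted and degapped on
load.

## CLI

```bash
# annotate a repertoire
igconvert annotate --functional functional.fa --pseudogenes pseudogenes.fa \
    --repertoire repertoire.fa --out events.tsv

# repertoire-level tables
igconvert summarize --events events.tsv --functional functional.fa \
    --pseudogenes pseudogenes.fa --distances distances.tsv --outdir summary/

# synthetic data with ground truth
igconvert simulate --synthetic-reference --n-sequences 200 --shm-rate 0.005 \
    --seed 1 --out-fasta sim.fa --out-truth truth.tsv

# score predictions against simulation truth
igconvert score --truth truth.tsv --events events.tsv
```

All thresholds (merge windows, minimum event span, seed settings,
suboptimal ratio, flank length, AID motif list, alignment scores, …) live
in a YAML config passed via `--config`; defaults follow the published
method where stated and are recorded in `igconvert.Params`.

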