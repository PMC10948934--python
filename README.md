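# vap-triage

Candidate identification for VAP-interactome studies: rank pull-down
proteins by FFAT-dependent enrichment, scan protein sequences for
FFAT / Phospho-FFAT motifs, and tabulate a downstream genetic modifier
screen into trigger-specific vs effector suppressors.

## The problem

VAP-A and VAP-B are ER membrane proteins whose MSP domain binds short
linear "FFAT" motifs (two phenylalanines in an acidic tract) in client
proteins, anchoring them at membrane contact sites. A common screen
design pulls down cell extracts with the wild-type MSP domain and with
a binding-dead (KD/MD) mutant, quantifies each protein by its
peptide-spectrum matches (PSMs) in both samples, and treats WT-enriched
proteins as candidate FFAT-dependent interactors. Candidates are then
scored for motifs, mapped to fly orthologs, and fed into an in vivo
RNAi suppressor screen in a retinal-degeneration background. This
package implements that computational arm as a tested, reusable
pipeline, plus seeded synthetic-data generators so every stage is
verifiable without any external download.

## The scoring model

A motif is 19 contiguous residues: six upstream flank positions
(U1–U6), a seven-residue core (C1–C7), six downstream flank positions
(D1–D6). A penalty matrix assigns a non-negative cost to each (position,
residue) pair; a window's score is the sum of its 19 per-position
penalties, and an ideal sequence scores exactly 0. Scores in the closed
band [0, 2.5] are called significant. The conventional-FFAT matrix is
derived from the Phospho-FFAT matrix by a single edit at the core
acid/phospho-acceptor position C4: penalty 4 for S and T, penalty 0 for
D and E. The matrices bundled here are a synthetic reconstruction
around the FFAT consensus (see `docs/methods.md`); any matrix in the
same TSV dialect can be substituted.

Enrichment is ranked by the pseudocounted PSM ratio
`(psm_wt + 1) / (psm_mut + 1)`; selection requires ratio ≥ 2 and ≥ 2
peptides (configurable). Screen tabulation requires two independent
RNAi lines with a positive suppression grade (`+` or `++`); suppressors
that also rescue an independent degeneration mutant (*norpA*) are
classed as effectors, the remainder as trigger-specific.

## Worked example

```sh
vap-triage simulate proteome --seed 7 -o sim/
# wrote 100 proteins, 36 planted motifs -> sim
vap-triage scan --fasta sim/proteome.fasta -o sim/hits.tsv
# scanned 100 proteins; 36 significant (score <= 2.5); wrote sim/hits.tsv
```

The generator planted 36 degraded motifs (budget 2.5 penalty units
each) into 100 random-background proteins, and the scanner recovers
exactly those 36 proteins as significant; `sim/proteome_truth.json`
records every planted position and expected score for independent
checking. On the packaged transcription of the suppressor screen:

```sh
vap-triage classify --screen src/vap_triage/data/table1_screen.tsv -o report/
```

prints, among other counts, `suppressors_tabulated ... 52`,
`effectors ... 13`, `trigger_specific ... 39` and `erg_flagged ... 6`:
52 tabulated suppressors, of which 13 also suppress *norpA*
(effectors), 39 are specific to the *rdgB* trigger, and 6 show a
consistent electroretinogram abnormality when depleted in a wild-type
background.

The full pipeline (`vap-triage run`) chains ranking, scanning,
annotation, ortholog joining and screen triage, writing TSVs and a JSON
manifest that hashes all inputs and outputs; a rerun on identical
inputs is byte-identical.

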