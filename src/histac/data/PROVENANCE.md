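# Bundled histone reconstruction — provenance

These files exist so paper-scale runs need no downloads. They are a
**reconstruction**, not a database export; the `.reconstruction.` infix in
the filenames marks that.

- `human_histones.reconstruction.fasta` — mature (initiator-Met-removed)
  human core-histone sequences. H3.1, H4 and H2A follow the canonical
  sequences; H2B is minimally edited so that every spatial-catalog site
  (H2BK40/K43/K105/K113/K117/K122) exists as a lysine under mature
  numbering, making it partially synthetic.
- `arabidopsis_histones.reconstruction.fasta` — synthetic reconstructions
  constrained by the published facts about these proteins: H3 differs from
  human at exactly positions 31/87/90 (with 14 lysines in H3.2/H3.3), H4
  differs at exactly 60/72, H2B.10/6/7 carry 29/32/32 lysines with
  lysine-rich N-terminal tails, and the six H2A variants carry
  13/12/12/22/16/21 lysines including K5 and K144. Residues not pinned
  down by those constraints are synthetic filler and do not reproduce the
  true Arabidopsis sequences.
- `*.sites.tsv` — per-lysine acetylation labels (P = reported acetylable,
  N = not observed, absent = unknown), transcribed from the experimental
  histone-acetylation literature at the scale of sites per variant
  (7 per Arabidopsis H3 variant, 5 in H4, 6/6/7 in H2B.6/7/10, K5 and
  K144 in H2A); the specific human N-terminal sites are the classical
  acetylation marks.

Any analysis quoting biological conclusions should treat results on these
files as method demonstrations, not as statements about the real proteins.
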