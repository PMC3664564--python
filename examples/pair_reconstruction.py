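"""Reproduce the published 11-pair result from encoded directions.

The original oral-lichen-planus screen reported 11 miRNA-mRNA candidate
pairs, each a significantly up-regulated miRNA predicted to target a
significantly down-regulated transcript.  This example feeds the encoded
directions and prediction memberships (plus distractor rows that must be
filtered out) through the pairing stage and prints the assembled pairs.
"""

from mirpair import assemble_pairs
from mirpair.studydata import reconstruction_tables

de_mrna, de_mirna, predictions = reconstruction_tables(extra_distractors=True)
pairs = assemble_pairs(de_mrna, de_mirna, predictions, alpha=0.05)

print(f"{len(pairs)} opposite-direction candidate pairs "
      f"({pairs.attrs['n_skipped']} prediction row(s) skipped):\n")
for row in pairs.itertuples():
    print(f"  {row.mrna_id:8s} (FC {row.mrna_fc_signed:+.1f})  <-  "
          f"{row.mirna_id} (FC {row.mirna_fc_signed:+.1f})")
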