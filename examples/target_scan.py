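"""Seed-match target scanning: canonical site types on a toy 3'UTR.

let-7a's seed (positions 2-8: GAGGUAG) reads CTACCTC as a reverse complement
in a DNA UTR; with the target adenosine opposite position 1 it becomes the
8mer CTACCTCA.  The scanner reports each site's type, 0-based offset and
pairing score (8mer=4, 7mer-m8=3, 7mer-A1=2, 6mer=1, +1 for a 3'
supplementary match).
"""

from mirpair import predict_table, seed_sites

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"
UTR = ("GGACGTTTGG" "CTACCTCA"        # 8mer at offset 10
       "TTTTTTTTTT" "CTACCTC" "G"     # 7mer-m8 at offset 28
       "AAAA")

for site in seed_sites(LET7A, UTR, "let-7a", "demo-UTR"):
    print(f"{site.site_type:8s} at {site.utr_start:3d}  "
          f"score {site.pairing_score}")

table = predict_table({"let-7a": LET7A}, {"demo-UTR": UTR},
                      min_site_type="7mer-m8")
print("\nprediction table (best site per miRNA-transcript pair):")
print(table.to_string(index=False))
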