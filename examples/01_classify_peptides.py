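"""Classify peptides as B cell epitopes by database similarity.

Builds a tiny epitope database, then classifies three query peptides:
an exact database copy, a copy with two terminal substitutions, and an
unrelated random peptide.  A peptide is called an epitope iff it has at
least one ungapped hit of length >= 8 and identity >= 80% to the
database.
"""

import bepiscan as bp

db = bp.EpitopeDataset(
    [
        bp.EpitopeRecord("epi1", "WLPKKYIVDENSA", source="antigen A"),
        bp.EpitopeRecord("epi2", "MKTAYIAKQRQISF", source="antigen B",
                         neutralizing=True),
        bp.EpitopeRecord("epi3", "GDEVRQIAPGQTGK", source="antigen C"),
    ]
)

queries = {
    "exact copy of epi1": "WLPKKYIVDENSA",
    "epi2 with substituted ends": "AKTAYIAKQRQISW",
    "unrelated peptide": "HHHCCNNNWWYYQQ",
}

for name, pep in queries.items():
    pred = bp.classify_peptide(pep, db)
    line = f"{name:28s} -> {pred.verdict}"
    if pred.hits:
        h = pred.hits[0]
        line += (f"  (hit to {h.subject_id}: length {h.length}, "
                 f"identity {h.identity_pct:.1f}%, bit score "
                 f"{h.bit_score:.1f})")
    print(line)

print()
print("The verdict is positive whenever one qualifying hit exists; the")
print("bit score is the BLOSUM62 raw score rescaled to bits and ranks")
print("how strong the matching database epitope is.")
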