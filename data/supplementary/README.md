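# Reference epitope collections

The reference-dataset reproduction tests in `tests/test_acceptance.py`
evaluate the classifier on the published linear B cell epitope
collections and their negative counterparts:

| file            | content                                              |
|-----------------|------------------------------------------------------|
| `BEPIBD.fasta`  | 62,730 curated linear B cell epitopes (IEDB-derived) |
| `RANDPEP.fasta` | 62,730 background-composition random peptides        |
| `IEDBNB.fasta`  | 62,730 peptides with negative B cell assays          |
| `BECIP.fasta`   | 503 independent epitopes (BCIPEP-derived)            |
| `IRPEP.fasta`   | 503 independent random peptides                      |
| `INB.fasta`     | 503 independent assay-negative peptides              |

These are journal supplementary downloads and are not redistributed
here. Place them in this directory as plain multi-FASTA files (one
record per peptide) to enable the reproduction tests; an optional
sibling `<stem>.meta.tsv` with columns `id`, `source`, `neutralizing`
carries record metadata.
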