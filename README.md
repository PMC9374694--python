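# bepiscan

Sequence-similarity prediction of **linear B cell epitopes** — the
contiguous peptide stretches of an antigen that antibodies can recognize
outside the folded protein context. Identifying them matters because a
predicted linear epitope can be synthesized as a peptide and used in place
of the whole antigen for antibody production and detection.

Instead of training a model on epitope *features*, bepiscan exploits the
sheer volume of experimentally verified epitope sequences directly: a query
is called an epitope when it is sufficiently similar to a *known* epitope.
The package provides the classifier, a protein-scanning mode, the dataset
curation and statistics machinery, synthetic benchmark generators, and a
cross-validation/holdout evaluation harness, with a thin `bepiscan` CLI
over the library. Intended users are immunoinformatics practitioners who
want a transparent, alignment-based baseline (or production predictor)
with a fully reproducible evaluation.

## Method

**Peptide classification.** Given a database *D* of known linear B cell
epitope peptides (curated to 8–25 residues, mutual identity < 90%), a
query peptide is predicted to be a B cell epitope iff it produces at least
one **ungapped** hit to *D* with

  length ≥ 8 and identity ≥ 80%,

where identity is the fraction of identical positions over the hit length.
The search engine enumerates every maximal qualifying window on every
query/subject diagonal (an exact, deterministic equivalent of an ungapped
word-seeded search). Hits are scored with BLOSUM62 and reported as
Karlin–Altschul bit scores, *S'* = (λ·*S* − ln *K*)/ln 2, with the
standard ungapped constants λ = 0.3176, *K* = 0.134.

**Protein scanning.** For a protein query, all qualifying hits are
collected and the number of hits covering each residue is tallied (*B*;
residues in no hit have *B* = 0). The tally is z-scored over the whole
protein,

  *Z*<sub>B</sub> = (*B* − µ<sub>B</sub>) / ∂<sub>B</sub>,

and non-overlapping **epitope cores** are extracted: segments of ≥ 8
covered residues whose *Z*<sub>B</sub> values are ≥ those of the flanking
residues. Cores carry the best supporting bit score, a
neutralizing-epitope support flag, and (when per-residue tracks are
supplied) mean accessibility/flexibility.

**Evaluation.** Sensitivity, specificity, accuracy and the Matthews
correlation coefficient are computed from TP/FP/TN/FN; tenfold
cross-validation builds each round's database from 90% of the positives
and classifies the held-out positives plus one tenth of the negatives
against it (negatives never enter the database).

## Worked example

`examples/03_cross_validation.py` generates a synthetic benchmark (25
parent epitopes, 400 near-duplicate positives at 5% substitutions, 400
composition- and length-matched random negatives) and cross-validates the
classifier:

```
benchmark: 25 parent epitopes, 400 positives, 400 negatives

% SE    % SP    % ACC   MCC
100.00 ± 0.00   100.00 ± 0.00   100.00 ± 0.00   1.00 ± 0.00
```

Every held-out positive is recovered through its near-twins in the
training database (SE), and random peptides essentially never share an
8-residue 80%-identity window with the database (SP); values are mean ±
population std over the 10 folds. `examples/02_scan_protein.py` shows the
protein mode — two epitopes planted in random flanking sequence come back
as exactly two cores at their planted coordinates:

```
start  end  peptide              bit   access  neutralizing
   26   39  FKLLYSNYEENAAL        35.4  0.50    False
   60   77  KVPLLFAEQEIASEGTLT    42.3  0.50    False
```

The same pipelines are available from the shell, e.g.

```bash
bepiscan simulate --n-pos 400 --n-neg 400 --seed 1 --out bench/
bepiscan evaluate --positives bench/positives.fasta \
                  --negatives bench/negatives.fasta --seed 1 --out eval/
bepiscan scan --db bench/db.fasta --query protein.fasta --out scan/
```

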