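# prokannot

Homology-driven annotation of prokaryotic genomes. `prokannot` predicts open
reading frames in all six frames with a single-pass finite-state machine,
transfers function from a protein reference database by local alignment,
refines start sites against the best-matching subject, resolves overlapping
calls with a length-prioritized cleaning strategy, applies three pre-curation
filters, and writes a curated EMBL feature table. It can annotate a genome
FASTA from scratch or improve an existing EMBL/GenBank annotation while
keeping its coordinates.

It is a headless library plus CLI aimed at people building or curating
bacterial/archaeal annotations who want every automatic decision to be
inspectable: every ORF keeps its full candidate hit list, and every removal
is logged with its reason.

## The metrics

Two quantities drive every decision.

**Accuracy** scores how well a database entry and an ORF fit together,
combining alignment identity with mutual coverage:

```
ACC = ID · (ML / SL) · (ML / OL)
```

where `ID` is the identity fraction of the local alignment, `ML` the aligned
(match) length, `SL` the subject (database protein) length and `OL` the ORF
length — all length terms in amino acids. When the match covers both
sequences entirely (`ML = SL = OL`), `ACC = ID`.

**Similarity** of two equal-length peptide strings uses the Levenshtein edit
distance `D`:

```
S = (L − D) / L
```

It gates start-site extensions: when an ORF is extended upstream to meet a
longer subject, the extension is accepted only if its translation scores
`S ≥ 0.90` against the corresponding subject region and contains no in-frame
stop — a deliberate stand-in for re-running the similarity search.

The annotation engine processes candidate ORFs longest-first. Each is
searched, its entries are scored with their eventual resized lengths, the
best entry is chosen by ordered criteria (accuracy within a 2% tolerance
band, gene acronym, named product, accuracy, shorter match, input order),
and the ORF is resized. Confirmed characterized ORFs with accuracy ≥ 0.90
then clean their overlap neighbourhood: never-searched overlappers are
truncated to a start codon clearing the overlap or removed, and
already-searched overlappers below 0.80 accuracy are dropped.

## Worked example

The built-in generator plants known genes in a synthetic genome, which makes
a self-contained demonstration:

```python
from prokannot.synth import synth_protein_db, synth_genome
from prokannot.seqio import write_fasta, write_protein_db

db = synth_protein_db(20, seed=4)          # 20 reference proteins
truth = synth_genome(db, 12, seed=4)       # 12 of them planted in a contig
write_fasta(truth.genome, "genome.fa")
write_protein_db(db, "proteins.fa")
```

```
$ prokannot annotate genome.fa --db proteins.fa -o project
CDS:            12
tRNA:           0
rRNA:           0
gene acronyms:  10
hypothetical:   0
mean accuracy:  100.00%
```

All 12 planted genes are recovered (10 of them carry gene acronyms in the
database, none is a hypothetical protein), each at its exact planted
coordinates, so every hit has `ID = 1` and full mutual coverage — mean
accuracy 100.00%. `project/annotation.embl` holds the feature table
(`FT   CDS             121..603` …), `project/hits/` one JSON per ORF with
its full candidate list, and `project/log.json` the removal log for the
spurious ORFs (reverse-strand shadows and short junk) that the engine
searched and discarded.

Re-annotation starts from an existing flat file instead:

```
$ prokannot reannotate project/annotation.embl --db proteins.fa -o project2
```

and `prokannot filter <project> --low-acc 0.8 --overlaps --intergenic`
re-applies any subset of the pre-curation passes; `prokannot report
<project>` reprints the summary.

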