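# constellation

Most genome analyses quietly assume the textbook picture of a gene: a
solitary transcription unit with its own promoter, comfortably separated
from its neighbours. In compact genomes such as *Drosophila
melanogaster*'s, that picture is the exception. This package classifies
every gene of an annotated genome by its *constellation* — its spatial
relationship with neighbouring genes — and quantifies what those
constellations correlate with functionally and evolutionarily. It is aimed
at molecular-evolution and population-genetics researchers who want to
test, or control for, gene constellation as a covariate in their own
datasets.

## The classification scheme

Each gene (represented by its maximum-length transcript, with a 1 kb
non-coding 5' region upstream of the transcription start site) is assigned
to exactly one group by a priority rule over pairwise relations:

| Group | Relation |
|-------|----------|
| `5PP` | 5' regions of the two genes overlap (head-to-head promoters) |
| `EE` | exons overlap exons — the cis-NAT (natural antisense) geometry |
| `5PI_EI` | a 5' region or exon lies in the partner's intron, without exon contact |
| `COS` | spans within the transcriptional-territory distance (20 kb default), opposite strands |
| `CSS` | as COS, on the same strand |
| `SG` | solitary: none of the above |

Priority: `5PP > EE > 5PI_EI > COS > CSS > SG`. Pairs in which one gene's
exons overlap both the 5' region and the exons of the partner on the
opposite strand are contradictory under the scheme and are excluded as
`CONFLICT`.

Around the classifier, the package implements the correlate analyses:
GO semantic similarity (Resnik, Lin, Jiang–Conrath and Relevance measures
with best-match/max/avg aggregation over gene term sets), hypergeometric GO
enrichment, the codon adaptation index (CAI), the neutral-theory
polymorphism summaries θ_W, θ_π and Tajima's D, Hudson's F_ST, expression
Q_ST from ANOVA variance components, Pearson co-expression calling,
rank-product differential expression with permutation pfp, cross-species
conservation of constellation over an ortholog map, and stepwise
standardized multiple regression for ranking the relative statistical
effects of constellation, recombination rate, chromosomal linkage and gene
function. Seeded synthetic-data generators (constellation geometries, toy
ontologies, Kingman-coalescent haplotypes, expression matrices, regression
tables) provide ground truth for every stage.

## Worked example

Simulate a genome with 260 genes placed in known constellations, classify
it, and enumerate the groups:

```python
from constellation.synthetic_data import simulate_genome
from constellation.classify import classify_genome
from constellation.report import enumeration_report

sim = simulate_genome(
    {"SG": 50, "5PP": 60, "EE": 20, "5PI_EI": 20, "COS": 80, "CSS": 30}, seed=1
)
calls = classify_genome(sim.genes, sim.config, sim.chrom_lengths)
recovered = sum(c.group == sim.truth[c.gene_id] for c in calls)
print(f"{recovered}/{len(calls)} genes recovered in their planted constellation")
print(enumeration_report(calls).to_string(index=False))
```

```
260/260 genes recovered in their planted constellation
        group  count  percent
           SG     50     19.2
          5PP     60     23.1
           EE     20      7.7
       5PI_EI     20      7.7
          COS     80     30.8
          CSS     30     11.5
  overlapping    100     38.5
co-clustering    110     42.3
        total    260    100.0
```

Every gene lands in the group it was generated in; the report counts each
group and its percentage of classified genes, plus the aggregate
"overlapping" (5PP+EE+5PI_EI) and "co-clustering" (COS+CSS) classes. On
the published *D. melanogaster* counts the same report yields the familiar
headline numbers: solitary genes are only 7.5% of the genome, overlapping
genes 50.1% and co-clustering genes 42.4%.

The same operations are available from the shell:

```bash
constellation simulate genome --seed 1 --out sim/
constellation classify --gff sim/genome.gff3 --chrom-sizes sim/chrom.sizes --out calls.tsv
constellation report --calls calls.tsv --out report.tsv
constellation sweep --gff sim/genome.gff3 --distances 2000,20000,100000,200000 --out sweep.tsv
```

See `constellation --help` for the remaining subcommands (`gosim`,
`enrich`, `evostats`, `biastest`, `regress`, `conserve`, `pipeline`).

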