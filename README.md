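# cogtrait

Prediction of microbial phenotypic traits from genome gene content.

Metagenomic assembly and binning now routinely produce near-complete genomes
of uncultivated microbes, but almost nothing is known about their phenotypes.
`cogtrait` predicts binary organism-level traits — motility, spore formation,
thermophily, obligate intracellular lifestyle, ... — directly from a genome's
*genotype profile*: the set of clusters of orthologous groups (COGs/NOGs)
that its protein-coding genes belong to. It is aimed at microbial ecologists
and comparative genomicists who have COG-annotated genomes (or
metagenome-assembled bins) and curated trait labels for a training set.

## Model

Each genome *i* is a binary vector **x**ᵢ ∈ {0,1}ᵖ over a COG vocabulary
fixed at training time (1 = COG present; no scaling, so weights stay
interpretable). A soft-margin support vector machine with a linear kernel and
cost C = 5 is trained on labelled genomes; a new genome is called
trait-positive iff its decision value

&nbsp;&nbsp;&nbsp;&nbsp;*f*(**x**) = **w**·**x** + *b* &gt; 0.

Because the model is linear, its features can be ranked by |wⱼ|: a positive
weight means the COG's **presence** predicts the trait, a negative weight
means its **absence** does. Absence-predictive ("negative predictor")
features matter biologically: traits characterized by genome reduction, such
as an obligate intracellular lifestyle, are predicted mainly by genes that
are *missing*.

Prediction quality is reported as **balanced accuracy**,

&nbsp;&nbsp;&nbsp;&nbsp;BA = ½ · ( TP/(TP+FN) + TN/(TN+FP) ),

estimated by 5-fold cross-validation with 10 replicates; true/false
prediction counts are pooled per replicate before one BA per replicate is
computed, and mean ± sd are taken over replicates. A constant classifier
scores exactly 0.5, so 0.5 is the informative floor.

Two protocols target metagenomic practice:

* **Completeness filter** — a genome is deemed complete if it carries at
  least 39 of 40 universal single-copy prokaryotic marker COGs (the marker
  list is a user-supplied input file).
* **Incompleteness robustness** — models are trained on intact genomes while
  held-out test genomes are degraded by random removal of a fraction of
  their COGs, yielding a BA-vs-completeness response curve.

A built-in generator creates *virtual species* (random COG subsets of a
large universe, up to 5,000 genomes × ~200,000 features) with *planted*
traits of known architecture (single marker, k-of-m presence, or
absence-driven) so the whole system is testable without any external
database.

## Worked example

Generate a 60-genome population with a planted single-marker trait, train a
model, cross-validate, and rank features:

```sh
cogtrait synth demo --n-genomes 60 --universe-size 2000 --mean-size 15 \
    --seed 7 --architecture single_marker --trait-name planted
cogtrait train demo.genotype.tsv demo.phenotype.tsv planted demo.model.txt
cogtrait crossvalidate demo.genotype.tsv demo.phenotype.tsv planted demo --seed 5
cogtrait rank demo.model.txt demo.rank.tsv --top 3
```

The log reports

```
trained 'planted' on 37 positive / 23 negative genomes (730 features) -> demo.model.txt
'planted': mean balanced accuracy 1.0000 +/- 0.0000 (5-fold, 10 replicates, seed 5)
```

i.e. the planted trait is recovered perfectly in replicated cross-validation,
and `demo.rank.tsv` puts the planted marker at rank 1 as a presence
predictor, far above the random background:

```
rank  cog        weight               direction
1     TRAIT0000  0.9973364716663239   presence_predicts_positive
2     COG000863  -0.15911860070624984 absence_predicts_positive
3     COG000140  -0.11866354135342885 absence_predicts_positive
```

Models are versioned, human-inspectable text files (`[meta]`, `[bias]`,
`[features]` sections); `cogtrait predict` applies them to new genotype
files, silently ignoring COGs unseen in training (a count is logged), so
metagenomic inputs with novel COGs are handled gracefully.

File formats are plain TSV: genotype (`genome_id TAB cog TAB cog ...`),
phenotype (header row naming traits, body rows of YES/NO/NA), marker list
(one COG id per line). See `cogtrait --help` for all subcommands:
`synth`, `train`, `predict`, `crossvalidate`, `completeness`, `rank`.

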