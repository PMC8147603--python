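# beemito

Mitochondrial mitotyping of honey bees (*Apis mellifera*) from the
COI-COII intergenic region, as a tested, reusable pipeline.

The region between the tRNA-leu and COII genes carries a variable
cassette of non-coding tandem elements — P-type (long variant P₀, short
variant P) and Q — whose composition identifies the major maternal
lineages: a lone **Q** marks the Southeast-European **C**-lineage,
**P₀** followed by 1–3 Q copies the African **A**-lineage, and **P**
followed by 1–3 Q copies the West/North-European **M**-lineage.
`beemito` detects those elements by semi-global consensus alignment,
calls structure strings (e.g. `P0QQ`) and lineages, removes putative
same-colony duplicates with a Queller–Goodnight relatedness filter
(r̂ from 13 microsatellite loci; pairs < 5 km apart sharing a mitotype
whose bootstrap lower bound on r exceeds 0 are collapsed), builds a
statistical-parsimony haplotype network with a 95% connection limit and
simple indel coding, and estimates lineage frequencies with exact
(Clopper–Pearson) binomial intervals

&nbsp;&nbsp;&nbsp;&nbsp;CI(k, n) = [ B⁻¹(α/2; k, n−k+1), B⁻¹(1−α/2; k+1, n−k) ]

plus logistic clines, logit P(lineage) = β₀ + β_lat·latitude +
β_tr·1[west of 20° E], with Wald tests, model χ² and McFadden's
pseudo-R². A seeded synthetic-data generator emulates the whole study —
sequences, haplodiploid pedigrees with planted super-sister pairs
(expected r = 0.75), and clined transect sampling — so every stage is
testable against known ground truth. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Simulate a survey at the default study conditions (444 bees along two
~900 km meridional transects, 17 planted kin duplicates), deduplicate,
type, and estimate frequencies:

```bash
beemito simulate --out sim --seed 1
beemito type  --input sim/seqs.fasta --out typing.tsv
beemito dedup --input sim/seqs.fasta --meta sim/meta.tsv \
              --genotypes sim/genotypes.tsv --seed 1 --out kept.tsv
# keep typing rows for retained samples, then:
beemito freq  --typing typing_kept.tsv --out freq.tsv
```

The dedup step prints `kept 427 of 444` — the 17 planted super-sister
duplicates, and only those, are detected and removed. The frequency
table that follows is computed from the 427 kept bees:

```
label   k   n  p_hat  ci_low  ci_high  percent  percent_low  percent_high
    Q 376 427  0.881   0.846    0.910    88.06        84.60         90.98
all C 376 427  0.881   0.846    0.910    88.06        84.60         90.98
  P0Q   2 427  0.005   0.001    0.017     0.47         0.06          1.68
 P0QQ   5 427  0.012   0.004    0.027     1.17         0.38          2.71
all A   7 427  0.016   0.007    0.033     1.64         0.66          3.35
   PQ   1 427  0.002   0.000    0.013     0.23         0.01          1.30
  PQQ  36 427  0.084   0.060    0.115     8.43         5.97         11.48
 PQQQ   7 427  0.016   0.007    0.033     1.64         0.66          3.35
all M  44 427  0.103   0.076    0.136    10.30         7.59         13.59
```

Read: 7 of 427 bees (1.64%) carry African-lineage mitotypes, with an
exact 95% interval of 0.66–3.35%; the C-lineage dominates at 88.06%
(84.60–90.98%) and the M-lineage sits at 10.30% (7.59–13.59%).

The latitudinal cline of the M-lineage on the same run:

```bash
beemito cline --typing typing_kept.tsv --meta sim/meta.tsv --lineage M --out cline.json
```

reports a latitude coefficient of 0.648 (SE 0.106, p < 0.001, so within
two standard errors of the generating value 0.535), a west-transect
contrast of −0.697 (SE 0.355) relative to the eastern reference, and
model χ²(2) = 58.8 — the M-lineage becomes more frequent northwards,
as simulated.

A parsimony network of aligned unique mitotypes:

```bash
beemito network --input aligned.fasta --conf 0.95 --out net
```

writes `net.edges.tsv` / `net.nodes.tsv` (and GraphML with
`--format graphml`); node tables carry observed counts and flag
inferred median nodes.

## Layout

```
src/beemito/
  io_formats.py     FASTA / genotype / metadata / network readers-writers
  repeat_typing.py  element detection, structure & lineage calls, DraI digest
  haplonet.py       indel coding, distances, connection limit, network build
  relatedness.py    Queller-Goodnight r, locus bootstrap, kin dedup filter
  freq_geo_stats.py exact binomial CIs, frequency tables, logistic clines
  synthetic_data.py seeded generator for sequences, pedigrees, geography
  cli.py            beemito simulate|type|dedup|network|freq|cline
  data/elements.fasta  default (synthetic) element consensi, overridable
```
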