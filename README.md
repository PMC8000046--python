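# cazhotspot

Ranking genomes as biomass-degrading enzyme hotspots from integrated
"Function;Family" CAZyme observations.

## The problem

Genome sequencing far outpaces enzyme characterization: thousands of fungal
genomes encode carbohydrate-active enzymes (CAZymes) that have never been
expressed or assayed. For enzyme discovery and for understanding how fungi
interact with plant biomass, one wants to compare genomes *quantitatively*:
which species carry the richest repertoires of cellulose-, xylan-, pectin-
and lignin-active enzymes, and whether that richness comes from many distinct
enzyme specificities or from many gene copies of a few.

Neither a CAZy family label (e.g. GH5 — a fold/sequence family hosting many
activities) nor an EC number (e.g. 3.2.1.4, cellulase — an activity found in
many families) is specific enough on its own. `cazhotspot` therefore counts
integrated **Function;Family observations**: a predicted EC function paired
with the CAZy family of the protein carrying it, written `3.2.1.4;GH5`. The
same EC in two families (`3.2.1.4;GH5` vs `3.2.1.4;GH7`) is two different
observations. Partial EC predictions keep their first three fields with `*`
in the fourth (`3.2.1.*`). Glycosyl transferases (GT families, biosynthetic)
and LPMOs (AA9–AA17, function not reliably predictable) are excluded.

## Scores

For each genome and substrate *s* ∈ {cellulose, pectin, xylan, lignin}:

* **Redundant score** R_s — every protein-level occurrence of an observation
  counts (degradation *capacity*; gene-copy redundancy raises it).
* **Unique score** U_s — every distinct observation key counts once
  (function *specificity diversity*).
* **Total** T = Σ_s R_s (or Σ_s U_s in unique mode).
* **Half-count rule** — an observation associated with two substrates counts
  ½ for each (generalised to 1/k for k substrates), so every mapped
  observation contributes total weight exactly 1 and the Total equals the sum
  of the substrate scores.
* **Association sums** — scores summed over substrate combinations
  (cellulose+xylan, cellulose+xylan+lignin, lignin+pectin) rank genomes for
  co-occurring capacities.
* **Redundancy Multiplication Score** RMS = R/U ≥ 1, reported half-up to one
  decimal; RMS > 8 is flagged `*` (capacity boosted by gene multiplication),
  RMS < 3 is flagged `¤` (capacity carried by distinct specificities).

Genomes are ranked by any of these scores with competition ("1224") ranking;
tied genomes share the minimum rank and carry a tie flag. Helper analyses
summarise the phylum composition of rank windows and the rank spread within
each genus. When several assemblies exist per species, the representative is
the one maximizing sequencing coverage × contig N50.

Which substrate(s) an observation targets comes from a declarative map
(TSV: `ec_pattern`, `family_pattern`, `substrates`), resolved most-specific
first (exact EC+family → exact EC → exact family). The bundled map
(`src/cazhotspot/data/substrate_map.tsv`) is illustrative; supply a curated
map with `--substrate-map` for real analyses.

## Worked example

Simulate a three-genome cohort with known ground truth, then run the full
report:

```sh
cazhotspot simulate --spec cohort.yaml --out-dir inputs
cazhotspot report --annotations inputs/annotations.tsv \
    --metadata inputs/metadata.tsv \
    --substrate-map inputs/substrate_map.tsv \
    --assemblies inputs/assemblies.tsv --out-dir reports
```

where `cohort.yaml` gives each genome its per-substrate unique repertoire
`u` and redundancy multiplier `m` (mean gene copies per observation), e.g. a
rumen-fungus-like genome with few specificities but heavy duplication:

```yaml
seed: 11
genomes:
  - genome_id: rumen_fungus
    u: {cellulose: 16, xylan: 12}
    m: {cellulose: 8.0, xylan: 6.0}
    genus: Pecorasim
    phylum: Chytridiomycota
    class_: Neocallimastigomycetes
  # ... leaf_pathogen (pectin/lignin-rich), soil_saprotroph (low copy number)
```

`reports/profiles.tsv` then holds the scored profiles:

```
genome_id        R_cellulose  R_pectin  R_xylan  R_lignin  T_R  U_cellulose  U_pectin  U_xylan  U_lignin  T_U
leaf_pathogen    10           99        0        50        159  10           24        0        18        52
rumen_fungus     125          0         82       0         207  16           0         12       0         28
soil_saprotroph  12           6         8        0         26   12           6         8        0         26
```

The rumen fungus tops the capacity ranking
(`reports/ranking_redundant_total.tsv`) with T_R = 207 from only 28 distinct
observations — 125 cellulose-active gene copies over 16 cellulose
specificities — while the leaf pathogen ranks second on raw capacity but
first on diversity (T_U = 52). `reports/rms.tsv` makes the mechanism
explicit, e.g. for the leaf pathogen:

```
genome_id      grouping   redundant  unique  rms  flag
leaf_pathogen  total      159        52      3.1
leaf_pathogen  cellulose  10         10      1.0  ¤
leaf_pathogen  pectin     99         24      4.1
leaf_pathogen  lignin     50         18      2.8  ¤
```

a low-RMS genome whose capacity comes from distinct specificities, against
the rumen fungus's RMS ≈ 7–8 driven by duplication. The report directory
also contains unique-mode and per-substrate rankings, the association
rankings, the phylum census per rank window, the genus rank-spread table,
and `assembly_selection.tsv` with the coverage × N50 audit (the intended
representative, constructed with dominant coverage and contig N50, wins for
every species).

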