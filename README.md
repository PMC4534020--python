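# wgpmap

Construction of chromosome-scale BAC physical maps from whole-genome-profiling
(WGP) fingerprints, with radiation-hybrid (RH) anchoring and comparative
gene-order analysis.

## The problem

Very large plant chromosomes — a single wheat chromosome can approach a
gigabase — were physically mapped before whole-genome assembly was feasible by
(1) flow-sorting the chromosome arms, (2) cloning them into ~130 kb BAC
libraries, (3) fingerprinting every clone with short sequence tags at
restriction sites (WGP), (4) assembling overlapping clones into contigs, and
(5) anchoring those contigs onto a radiation-hybrid map built from
irradiation-induced chromosome breaks.  `wgpmap` implements that entire
analysis chain as a reusable, tested Python library, together with a
ground-truthed simulator so every stage can be validated without any external
data.

## Methods at the core

**Sulston-score contig assembly.**  Two fingerprints with `n_L <= n_H` tags
sharing `m` of them are scored by the probability of that overlap arising by
chance on a "gel" of `G` distinct possible tags:

```
q = 1 - (1 - 1/G)^n_H        S = P(X >= m),  X ~ Binomial(n_L, q)
```

computed in log10 space (two identical 20-tag fingerprints on a gel of
120,913 tags score below 1e-75).  Clones are clustered by single linkage at a
stringent initial cut-off (1e-75), then merged stepwise — only end-to-end or
single-to-end joins, 5 orders of magnitude per round — with contigs
containing >10% Questionable clones re-assembled at a more stringent cut-off
each round.  Contig sizes are reported in consensus-band (CB) units (~5 kb of
genome per tag interval), and a greedy furthest-reach interval cover selects
the minimal tiling path (MTP).

**Contamination screen.**  Flow-sorted fractions are only 85–92% pure.  Each
tag votes for a chromosome group of origin; a clone is foreign when the best
other group outnumbers the target group by more than 4 tags, and a contig is
eliminated when foreign clones exceed 66% of its members.  Small contigs
whose tags are contained in a larger contig are removed as redundant shadows.

**RH mapping.**  Markers scored present/absent across an irradiated panel are
modelled by the equal-retention haploid RH model (breakage probability
`theta` between adjacent loci, single retention probability `r`).  Two-point
estimates come from the closed-form marginal `r` and a 1-D likelihood
optimisation for `theta`; linkage groups require LOD >= 4.0 and <= 100 cR;
locus order is found by greedy chaining, maximum-likelihood insertion, 2-opt
and windowed ripple over a Markov-chain multipoint likelihood; distances are
`d = -100 ln(1 - theta)` centirays.  Obligate breaks (adjacent 1/0
transitions per line) measure map resolution, and terminal-deletion lines
partition the map into deletion bins.

**Integration and comparative analysis.**  Anchored markers place each contig
at the median locus of its hits; marker clusters more than 50 cR apart flag a
chimeric contig, which is split at the largest CB gap.  Co-located contigs
are ordered by the reference-chromosome positions of their syntenic genes,
and ordered ortholog links are segmented into monotone runs to call
inversions and translocations against a homologous reference chromosome.

## Worked example

```python
from wgpmap.config import RunConfig
from wgpmap.pipeline import run
from wgpmap.assembly import assembly_stats
from wgpmap.rhmap import map_summaries

cfg = RunConfig(seed=1, simulate=dict(
    length=20_000_000, arm_boundary=9_000_000, n_genes=200,
    coverage=8.0, n_markers=80, n_rh_lines=200))
r = run(cfg, upto="compare")

stats = assembly_stats(r.contigs, arm_size=r.dataset.model.length)
print(len(r.contigs), "contigs,", r.rh_map.n_loci, "loci,",
      r.rh_map.obligate_breaks_total, "obligate breaks")
mapped = [c.estimated_size for c in r.contigs]
res = map_summaries(r.rh_map, mapped)
print(round(res["cR_per_locus"], 1), "cR/locus,",
      round(res["mb_per_break"] or 0, 2), "Mb/break")
```

prints

```
19 contigs, 64 loci, 537 obligate breaks
14.1 cR/locus, 0.04 Mb/break
```

i.e. on this 20 Mb toy chromosome the screen-surviving assembly collapses to
19 contigs, the RH panel resolves 64 loci spaced ~14 cR apart, and with 537
observed breaks over ~21 Mb of mapped contigs the map resolves structure at
roughly 40 kb per break (a 20 Mb chromosome with 8 breaks per line is, per
megabase, far more fragmented than a ~900 Mb one).

The same stages are exposed as a CLI:
`wgpmap simulate|assemble|screen|rhmap|integrate|compare|report --config cfg.yaml --seed 1 --out outdir`,
each writing its outputs (fingerprint TSV, contig tables, RH map TSV, AGP/BED
exports, summary CSVs) plus a manifest with input hashes and versions.

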