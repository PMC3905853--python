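# Methods

## The model

A DRE that regulates a gene does so by chromatin looping. That physical
contact has two observable consequences, and the method requires both:

* **Contact evidence.** Hi-C reads whose two ends fall in the DRE and in
  the gene should be enriched over random collisions. Reads are mapped to
  the *intragenic DHS* of a gene rather than to its promoter, because
  promoters are depleted of Hi-C reads (the loop at the promoter appears
  transient) while intragenic DHS are enriched. For each (DRE, gene,
  dataset) the count is the maximum over the gene's intragenic DHS of the
  per-DHS supporting reads; a sum would grow with gene length simply
  because long genes carry more DHS.
* **Evolutionary evidence.** If the loop constrains both partners, lineages
  that lose the DRE should preferentially also lose the target. Presence is
  measured with phylogenetic profiles over a fixed ordered panel of S
  non-human species (default 45): bins are the atoms induced by all
  alignment-block endpoints, each bin carrying a 0/1 coverage vector, and a
  region's profile is the bin-length-weighted average of bin vectors. Pair
  evidence is the Pearson correlation of the two profiles.

Both channels are gated: profile correlation must exceed `pcc_cutoff`
(default 0.8, strict), and within a cell line some replicate must exceed
`read_cutoff` reads (default 2, strict, i.e. ≥ 3) — or, as a rescue, every
replicate of that cell line must contribute ≥ 1 read. The final set is the
union over cell lines. Only distal pairs (inter-chromosomal or minimum
DRE-to-gene-body gap > 500 kb) are eligible; below that distance profile
correlation is dominated by regional context and would not be evidence of
a specific relationship.

## Parameter conventions

| parameter | default | meaning |
|---|---|---|
| `tss_flank` | 2000 bp | DHS farther than this from every TSS (and outside all gene bodies) is a DRE |
| `upstream` | 1000 bp | gene profile region runs from TSS − 1000 (strand-aware) to gene end |
| `dhs_flank` | 1000 bp | gene-side Hi-C capture window: intragenic DHS center ± flank |
| `far`, `near` | 500 kb, 50 kb | distance classes; only > `far` or inter-chromosomal pairs are predicted |
| `pcc_cutoff` | 0.8 | strict lower bound on profile correlation |
| `read_cutoff` | 2 | strict lower bound on the best replicate's read count |
| `cluster_gap` | 5 kb | single-linkage chaining threshold for DRE clusters |

Geometry choices the sources of these thresholds leave open, fixed here:
TSS distance is the minimum absolute distance from any base of the DHS to
the TSS point; "inside a gene" is any overlap with the gene body; a DHS
overlapping several gene bodies is intragenic for each host; the DRE-gene
distance anchor is the minimum gap between the DRE interval and the gene
body (conservative for the 500 kb exclusion); a BEDPE end's mapped position
is the floor midpoint of its interval.

Profile conventions: the weighted-average denominator is the full region
length, so unaligned human sequence counts as absence in every species —
a 0 means "no homolog", and this keeps profiles comparable across regions
(`denominator="aligned"` is available); multiple blocks of one species over
a bin still give indicator 1; correlation is computed on the real-valued
averaged profiles, not re-binarized; a zero-variance profile makes the
correlation undefined and the pair is excluded rather than scored 0,
because no correlation evidence exists either way.

Repeatability uses the replicate with fewer total contacts as reference
(inclusive cutoffs, count ≥ read_cutoff and r ≥ pcc_cutoff, matching the
grid labels "1, 2, 3 and more"), and reports NA — never 0 or 1 — for empty
cells. The prediction rules are strict (>) per the chosen operating point
"PCC > 0.8, reads > 2"; both cutoffs are configurable because inclusive
readings exist.

For marker enrichment the *ratio* uses marginals over the unique DREs and
unique genes of the analyzed pair set (configurable in principle to
genome-wide marginals), while *significance* comes from the pair-level 2×2
contingency table of DRE-side × gene-side marker presence (1 df chi-square,
no continuity correction). A goodness-of-fit of "pairs with both" against
n·p̂·q̂ with marginals estimated from the same pairs was rejected during
design: its null variance is overstated, deflating type-I error to ≈ 0.8%
where the contingency form is correctly calibrated (≈ 5%). Fisher's test
for knockout-DE enrichment is two-sided. Resnik similarity uses
biological-process terms only, `is_a` edges only, IC(t) = −ln p(t) with
p(t) the fraction of annotated genes at or below t, terms with < 3
annotated genes dropped, and IEA-evidence annotations excluded upstream.
Cluster mean scores average each unordered target-gene pair once, skipping
undefined pairs; control sets are drawn uniformly without replacement from
the genes for which the metric is defined; the permutation p-value compares
the mean proportion-above-cutoff across the grid between observed clusters
and the control replicates.

## What the synthetic data emulates

The generator plants the statistical structure the method exploits, with
defaults chosen as the reference study conditions:

* each gene/DRE has a latent presence vector across S = 45 species
  (presence probability 0.5); a true DRE copies its target's entries with
  probability `rho_true` (default 0.9) and redraws otherwise, giving pair
  correlation ≈ rho_true; alignment blocks are emitted only where the
  element is present, with ≤ 100 bp boundary jitter;
* per dataset (2 cell lines × 2 replicates), each true pair receives
  Poisson(`lambda_signal` = 5) contacts between the DRE and one fixed
  "loop anchor" intragenic DHS of the target (fixed per pair, so max-rule
  counts are exactly Poisson distributed); background contacts are
  independent Poisson(`lambda_noise` = 0.05) per random (DRE, gene) pair,
  uniform over the gene's DHS, ignoring genomic-distance decay — adequate
  because predictions are restricted to > 500 kb where contact frequency is
  nearly flat (a power-law `distance_decay` option exists, off by default);
* DREs are laid out in spatial groups with ~2 kb internal gaps (under the
  5 kb clustering threshold); each group's true targets come from one gene
  module; module genes share two leaf GO terms under a module parent in a
  3-level DAG and a latent 79-tissue expression profile (noise SD 0.5), so
  predicted clusters have functionally related, co-expressed targets;
* every true pair is distal by construction; 60% of DREs carry a true
  target by default (`fraction_true_pairs`), raised to 1.0 with 4 DREs per
  group for the functional-analysis scenario so clusters reach the ≥ 3
  target genes that analysis requires.

Problem sizes are deliberately desk-scale — 4 chromosomes × 2 Mb, 80
genes, 380 DHS by default, a few thousand contacts — enough for every
statistical pattern to be resolvable while the whole pipeline runs in
seconds. What passing on this data does *not* show: robustness to mapping
artifacts, copy-number and restriction-fragment biases of real Hi-C,
phylogenetic tree structure (species are exchangeable here, with no shared
descent among losses), alignment quality differences across the species
panel, or the distance-decay confounding that motivates the 500 kb filter
in the first place. Those require the original genome-scale inputs.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open everywhere. Ties in the max rule go to
the intragenic DHS earliest in genomic order. Correlations are clamped to
[−1, 1] against floating-point drift. Undefined quantities are explicit:
`None` correlation (zero variance), NA repeatability (empty selection),
`None` precision (no predictions), and clusters whose every gene pair has
an undefined metric are excluded and counted in the log. The density
profile requires at least one target with nonzero background and errors
otherwise. The GO DAG is checked acyclic at load. Output tables are sorted
(locus, then gene id) so fixed-seed runs are byte-identical.

## Known limitations

* Profile correlation is computed between a DRE's peak region (hundreds of
  bp) and a gene region (tens of kb); on real alignments the two live at
  different coverage scales, which the synthetic data does not emulate.
* The per-pair Poisson background has no overdispersion; real Hi-C noise
  is overdispersed, so real repeatability at reads = 1 would be lower.
* The rescue rule is evaluated per cell line with exactly the configured
  replicate roster; datasets with ≥ 3 replicates generalize the rule as
  "every replicate ≥ 1 read", which is untested against any reference.
* Resnik similarity ignores `part_of` and other non-`is_a` relations.
* The mode-of-distribution summaries used to describe correlation
  distributions at different distance classes are out of scope; the
  package reports raw correlations and grids instead.
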