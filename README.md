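# mseqevo

Multi-region tumour evolution analysis for hypermutated (mismatch-repair
deficient / MSI-like) cancers, plus a ground-truthed branched-tumour
simulator for validating every step.

Multi-region exome sequencing (MSeq) profiles several spatially separated
samples of one tumour and reconstructs its clonal evolution. This package
implements the full downstream analysis as a tested, reusable library:

- **Mutation filtering and categorisation** — per-region depth and germline
  filters, a cross-germline panel-of-normals filter (reject when a variant is
  present at VAF ≥ 2% in ≥ 20% of normals), and two-tier multi-region calling:
  a mutation is kept if any region reaches VAF ≥ 5%, and is called present
  per region at VAF > 2.5%. Retained mutations are *ubiquitous* (all
  regions), *shared* (some), or *private* (one).
- **Copy-number metrics** — ploidy as the segment-length-weighted mean of the
  unrounded total copy number,
  `ploidy = Σ(CN_abs × length) / Σ(length)`; the weighted genome integrity
  index (wGII), the per-autosome fraction of covered length whose rounded CN
  differs from rounded ploidy, averaged over autosomes (wGII > 0.2 flags
  chromosomal instability); LOH calls (minor allele = 0).
- **Cancer-cell fractions** — mutation copy number
  `MUT_CN = VAF · (1/p) · (p·CN_t + 2(1−p))` for purity `p` and locus total
  copy number `CN_t`; multiplicity `m = clamp(round(MUT_CN), 1, CN_major)`;
  `CCF = MUT_CN / m` capped at 1; clonal iff CCF ≥ 0.7. Copy-number gains are
  timed early/late from the fraction of ubiquitous mutations at full
  multiplicity inside the gained segment.
- **Clone trees** — mutations are clustered by regional presence pattern and
  CCF centroid, then assembled into a rooted lineage tree (root = germline)
  under the sum rule (per region, a parent clone's CCF ≥ the sum of its
  children's, within slack ε); trees are ranked by a sum-rule error score.
  Presence-matrix conflicts are explained by regional copy losses where the
  locus CN drops; parallel evolution of driver genes across branches is
  reported.
- **Mutational signatures** — 96 trinucleotide-context spectra
  (pyrimidine frame) refit against a signature catalog by nonnegative least
  squares; signatures below 5% in every group are masked from reports.
- **Selection (dN/dS)** — trinucleotide-context-adjusted dN/dS per tree
  compartment (ubiquitous / shared / private): per-context mutation rates are
  profiled out of a Poisson model `s_c ~ Pois(λ_c L_S,c)`,
  `n_c ~ Pois(ω λ_c L_N,c)`, with a likelihood-ratio 95% CI on ω.
- **Single- vs multi-region comparison** — per-region total, clonal and
  ubiquitous mutation loads, subclonal fractions, and the "illusion of
  clonality": heterogeneous mutations that look clonal (CCF ≥ 0.7) within a
  single region.
- **Simulator** — branched clone trees with truncal/branch signature
  mixtures, 20–34% indel fraction, per-region purity, ~200× depth, early/late
  allele-specific gains, allele losses that delete acquired mutations, and a
  panel of normals carrying recurrent artifacts — with full ground truth for
  every quantity above.

## Worked example

```python
from mseqevo import run_pipeline, SimulationConfig

result = run_pipeline(SimulationConfig(seed=3), out_dir="demo_out")
print(result.manifest["category_summary"])
print(result.tree.newick())
print(result.dnds_table)
```

This simulates a seven-region tumour under the default study conditions
(700 truncal + 1194 branch mutations on a six-clone tree, 27% indels,
purity 0.2–0.9, 200× depth, an early chromosome-8 gain, a late
chromosome-20 gain, truncal 17-LOH and a subclonal chromosome-18 loss) and
runs every stage. It prints:

```
{'non_silent_total': 1065.0, 'ubiquitous': 431.0, 'heterogeneous': 634.0,
 'pct_ubiquitous': 40.5, 'pct_heterogeneous': 59.5}
(((((C7:42)C5:278)C3:13,(C6:213,C8:197)C4:306)C2:297)C1:379)germline:0;
  compartment  n_syn  n_nonsyn  ratio  ci_low  ci_high
0  ubiquitous    117       280   1.10    0.89     1.37
1      shared    104       238   1.03    0.82     1.30
2     private     95       177   0.81    0.63     1.05
```

40.5% of retained non-silent mutations are ubiquitous across all seven
regions — the long truncal trunk typical of this tumour type — and the rest
are heterogeneous. The Newick tree gives branch lengths in mutation counts
(C1 is the 379-mutation trunk cluster after filtering). The dN/dS table
shows ratios near 1 with 95% CIs: the simulated mutations are selectively
neutral, and the context-adjusted estimator correctly reports this even
though the signature-driven mutation spectrum is strongly context-biased.
The gain-timing report labels the chromosome-8 gain *early* (0% of
ubiquitous mutations at full multiplicity) and the chromosome-20 gain
*late* (50%), and the per-region wGII stays below the 0.2 CIN cutoff for
this near-diploid genome.

The same stages are available from the shell:

```bash
mseq-evo simulate --seed 5 --out sim/       # variants, segments, truth, FASTA
mseq-evo filter --variants sim/variants.tsv --panel sim/normal_panel.tsv --out flt/
mseq-evo ccf --variants flt/variants_filtered.tsv --segments sim/segments/R1.seg.tsv ... --out ccf/
mseq-evo tree --ccf-matrix ccf/ccf_matrix.tsv --out tree/
mseq-evo run --seed 3 --out full/           # everything, plus a run manifest
```

All outputs are plain TSV / JSON / Newick / FASTA; `manifest.json` records
the seed, config hash and per-file SHA-256 digests, and is byte-identical
across reruns with the same seed.

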