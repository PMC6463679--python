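# cagesel

Comparison of transcript 5′ ends between a polysome-associated RNA
population (the **translatome**) and total RNA (the **transcriptome**) from
CAGE data, at single-nucleotide resolution.

In CAGE (Cap Analysis of Gene Expression), 27-nt tags are sequenced from
the capped 5′ ends of mRNAs; each mapped tag 5′ end marks a transcription
start site (TSS), and a cluster of overlapping tags marks a core promoter.
Because polysome association is a prerequisite for translation, comparing
the 5′-end landscape of polysome-bound RNA against total RNA reveals which
TSSs, core promoters and genes the translation machinery preferentially
engages — a selection layer downstream of transcription. `cagesel`
implements that comparison as a tested, reusable pipeline for anyone
analysing paired CAGE libraries, together with a synthetic-data generator
that emits a complete two-condition dataset with a known answer key.

## What the pipeline computes

Starting from per-sample CTSS tables (`chrom  pos  strand  count`, 1-based
5′-end positions) and a GTF/GFF annotation:

1. **Tag clustering.** Same-strand tags whose 27-nt bodies overlap are
   merged (single linkage); a set of ≥ 4 tags is a tag cluster (TC). The
   threshold is justified by a Poisson background model: if *T* mapped tags
   fell uniformly on a genome of length *N*, the count in a tag-set window
   of (*n*−1)·27 nt would be Poisson with λ = (*n*−1)·27·*T*/*N*, and
   P(X ≥ 4) ≪ 0.001 at genome scale.
2. **Promoter annotation.** Each TC is reduced to its representative TSS
   (the most frequently used position) and assigned to a genomic feature by
   priority 5′UTR (incl. 100 nt upstream) > 3′UTR > CDS > intron, else
   intergenic. 5′UTR lengths, first-nucleotide frequencies and
   expressed-gene flags follow.
3. **Shape classes.** TCs with ≥ 100 tags are classified as SP (single
   dominant peak), DP (broad, one dominant peak), MP (separated multi-peak)
   or BP (generally broad) by ordered interquantile/peak criteria.
4. **TSS disparity.** Matched translatome/transcriptome TC pairs (≥ 100
   tags each) are tested for 5′-end distribution change with a two-sample
   Kolmogorov–Smirnov test (changed at p < 0.001; BH-adjusted q reported).
5. **Differential promoter usage.** Per TC pair, fold change
   FC = RPM_translatome / RPM_transcriptome with an exact two-library
   binomial test; significant at |log₂ FC| ≥ 1 and p < 0.05. Per gene with
   promoter abundances *pᵢ* (translatome) and *tᵢ* (transcriptome):

   E_p = Σᵢ pᵢ,  E_t = Σᵢ tᵢ,  S_fc = E_p / E_t,
   S_du = ½ Σᵢ | pᵢ/E_p − tᵢ/E_t |

   S_fc measures polysome preference for the gene; S_du ∈ [0, 1] measures
   how differently its promoters are used (0 = same proportions,
   1 = disjoint promoter support).
6. **Sequence context.** GC content, AUG (start codon) counts and TATA-box
   enrichment in the 100 nt around representative TSSs of top-enriched,
   top-depleted and FC-matched control promoters.

## Worked example

```python
import os, tempfile
from cagesel import synthetic_data as sd, pipeline

d = tempfile.mkdtemp()
bundle = sd.simulate(sd.scaled_config(seed=1, n_genes=500,
                                      library_size=100_000), d)
cfg = pipeline.RunConfig(
    ctss_translatome=bundle.ctss_translatome,
    ctss_transcriptome=bundle.ctss_transcriptome,
    gtf=bundle.gtf, fasta=bundle.fasta,
    out_dir=os.path.join(d, "out"), group_k=50)
tables = pipeline.run_all(cfg)

disp = tables["disparity"]
print(f"matched core promoters tested for disparity: {len(disp)}")
print(f"changed 5'-end distributions (p<0.001): {disp['changed'].sum()} "
      f"({disp['changed'].mean():.1%})")
td = tables["tc_diff"]
sig = td["status"].isin(["enriched", "depleted"]).sum()
print(f"TC pairs with |log2FC|>=1 and p<0.05: {sig} ({sig/len(td):.1%})")
sdu = tables["gene_sdu"]
print(f"multi-promoter genes scored: {len(sdu)}; S_du>0.5: {(sdu['S_du']>0.5).sum()}")
```

prints

```
matched core promoters tested for disparity: 158
changed 5'-end distributions (p<0.001): 37 (23.4%)
TC pairs with |log2FC|>=1 and p<0.05: 304 (30.9%)
multi-promoter genes scored: 340; S_du>0.5: 29
```

158 promoter pairs had ≥ 100 tags in both conditions; 23% of them changed
their 5′-end distribution (the generator shifted 30% of promoters, not all
of which clear the depth filter), 31% of promoter pairs changed abundance
significantly, and 29 genes redistributed more than half of their promoter
usage between conditions. The same pipeline is available from the shell
(`cagesel simulate`, `cagesel run-all --config run.yaml`, or per-stage
subcommands); stage outputs are TSVs with `#` provenance headers.

The numbered scripts under `analysis/` walk through the full study on a
mid-sized simulation — clustering and annotation, disparity testing,
differential usage, sequence features, and recovery against the
generator's truth key — writing summary tables to `results/analysis/`.

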