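# cidscope

Analysis toolkit for an amplified, polymorphic two-gene operon (`cidA`-`cidB`)
whose variant repertoire governs crossing types between insect lines. The
package implements the full analysis chain as reusable, tested components,
plus a first-class synthetic data generator so every stage can be exercised
end-to-end without any external downloads:

- **`cidscope.synthetic_data`** — seeded generators for reference/sample
  genomes (one vs. *k* operon copies, 14 single-copy marker genes, a
  single-copy `wsp` locus, a duplicated cidB 3' tail), uniform read sampling,
  clone sampling from variant copies, qPCR Cq tables, and line panels whose
  crossing type follows a variant-signature rule with configurable
  discordance.
- **`cidscope.coverage_cn`** — amplification detection as the ratio of
  normalized operon read depth to single-copy marker depth, with the three
  standard adjustments (genome-mean normalization, polymorphic-region
  exclusion, duplicated-tail exclusion), and qPCR relative copy number from
  replicate-mean delta-Cq.
- **`cidscope.repertoire`** — typing of cloned amplicon sequences into named
  variants (`cidA_IV(δ/1)` style) via two fixed polymorphic regions per gene,
  per-line repertoires with clone support, incompatibility-signature flags,
  and direct-trace consistency checks.
- **`cidscope.rflp`** — in-silico PCR (mismatch-tolerant primers) and
  multi-enzyme restriction digestion with IUPAC-degenerate recognitions
  (ApoI, Hpy188I, BanI, TaqI ship as config), fragment-pattern calling with
  gel-style tolerance, non-discriminating bands, and a mixed-template mode.
- **`cidscope.blocks`** — polymorphic-column/block detection, block-allele
  assignment, four-gamete recombination testing, cross-group block-sharing
  reports, and uncorrected P-distance matrices (PHYLIP/NEXUS export for
  split-network tools).
- **`cidscope.association`** — crossing-type classification from cross
  tables, the signature-by-crossing-type 2×2, the two-proportion chi-square
  test with Yates continuity correction, and the discordance breakdown.
- **`cidscope.pipeline` / `cidscope.cli`** — end-to-end orchestration with a
  checksummed, seed-stamped run manifest.

## CLI

```bash
cidscope run --seed 1 --out-dir demo_run            # full synthetic pipeline
cidscope simulate --seed 1 --k-operon 3 --out-dir sim
cidscope coverage --reference sim/reference.fa --reads sim/reads.fa \
    --regions sim/regions.bed --out coverage.json
cidscope qpcr --table sim/qpcr.tsv --target cidA --ref-locus wsp
cidscope type --clones sim/clones_cidA.fa --gene cidA --min-support 2
cidscope rflp --template line.fa --test cidA_upstream
cidscope blocks --alignment variants.fa --max-gap 3
cidscope associate --flags sim/panel.tsv --positive-rule any_variant
```

All file formats are plain text: FASTA, BED (0-based half-open), TSV, JSON,
and minimal SAM. User-facing coordinates are 1-based inclusive and converted
at the I/O boundary.

## Notes

- Enzyme definitions, diagnostic fragment patterns, and polymorphic-region
  coordinates ship as editable JSON under `src/cidscope/data/`.
- Every generator and the pipeline are deterministic given a seed; the run
  manifest records seeds and SHA-256 checksums of all outputs.
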