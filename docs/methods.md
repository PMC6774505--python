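# Methods

## Model and assumptions

`phagescan` detects prophages as local excesses of *phage-like genes* —
host-annotated genes whose translated product matches a phage reference
protein. The underlying assumptions are that (i) an integrated prophage
retains enough recognisably phage-derived coding sequence to produce a run
of strong protein-level matches, (ii) gene annotation is given and roughly
complete (the tool performs no ORF calling; fragmented annotation lowers
the measured density and therefore sensitivity), and (iii) contigs are
linear — features spanning the origin of a circular chromosome are not
modelled, and windows never wrap. Prophages wholly contained within one
contig of a draft assembly are still found, since every contig is scanned
independently.

## Pipeline stages and parameters

| parameter | default | unit | role |
|---|---|---|---|
| e-value cutoff | 1e-5 (strict `<`) | — | gene is phage-like iff ≥ 1 hit below this |
| window length | 10 000 | bp | sliding window of the density scan |
| step | 1 000 | bp | window stride (grid anchored at contig coordinate 0) |
| min genes | 8 | count | inclusive lower bound per selected window |
| min span | window/2 = 5 000 | bp | strict lower bound on window length |
| tRNA flank | 3 000 | bp | search range on both sides of each trimmed border |

The window/gene-count defaults mirror the size distribution of sequenced
phage genomes (few are under 10 kb, and those still exceed 8 genes); the
scan is deliberately simple and parametric rather than probabilistic —
HMM-style segmentation is a different method family and a non-goal here.

Design choices made where the behaviour was genuinely open:

- **Window membership** is any overlap ≥ 1 bp between gene hull and
  window. Midpoint or full-containment rules are strictly less sensitive,
  and the overhang they would avoid is removed later by trimming anyway.
- **"Span" of a window** is read as the window instance's own length, so
  the 5 kb bound only excludes truncated terminal windows. The alternative
  reading — the extent of phage-like genes inside the window — is kept
  available as `span_rule="genespan"` / `--span-rule genespan`.
- **A contig shorter than one window** is scanned as the single truncated
  window `[0, contig_len)` rather than a grid of sub-windows.
- **Trimming** moves borders to the outermost phage-like genes overlapping
  the preliminary region, *clipped to that region*: a gene overhanging a
  window edge must not enlarge the prediction (containment of trimmed in
  preliminary is an invariant the tests enforce).
- **tRNA adjustment** considers all tRNAs overlapping the symmetric
  ±3 kb window around each border and takes the most outward coordinate
  (minimum start on the left, maximum end on the right): deterministic,
  and the choice that maximises capture of the integration site. tRNA
  strand is ignored. With symmetric flanks an adjustment can provably
  never invert the interval (any candidate that could push the left border
  past the new right border would itself be in the right border's search
  window); the guard for that case is defensive only.
- **Post-extension overlaps** between neighbouring predictions are merged
  so BED output is always disjoint; ids `prophage_1..n` are assigned by
  (contig, start) after merging.
- **Gene identity**: CDS segments sharing an ID/Parent are one gene; its
  interval for counting is the hull of its segments and its protein the
  spliced translation (prokaryotic annotations are effectively always
  single-segment, so this is a graceful degradation, not a feature).
- **Pseudogenes**: internal stop codons are masked to `X` with a warning
  instead of dropping the protein — silently removing genes would change
  the density signal. The genetic code is fixed to NCBI table 11.
- **Reference database filter**: case-insensitive substring match of the
  exclusion terms (default `"ABC transporter"`) against the product
  annotation only; the filter is label-based by construction, conserves
  records (`kept + excluded = input`) and is idempotent.

## Evaluation statistic

TP/FP/FN are base-pair lengths measured on the *disjoint unions* of the
prediction and gold sets per contig — the only reading under which the
three lengths partition cleanly and `TP+FN = |gold|`, `TP+FP = |pred|`
hold exactly. Undefined ratios (empty gold → sensitivity undefined; empty
predictions → PPV undefined) are reported as NA, never 0. Both pooled
(lengths summed over all contigs) and per-genome (ratios averaged per
contig, NAs skipped) modes are available, since gold-standard collections
can reasonably be scored either way.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the detector keys on:
background genes at 0.9 genes/kb (typical bacterial coding density) with
random strands, implanted islands of densely spaced genes (default 12
genes of 900 bp at 100 bp spacing), optional flanking tRNAs (75 bp) at
stated offsets, and a hit table in which phage-grade e-values are drawn
log-uniform from [1e-50, 1e-6] and background noise from [1e-4, 10] — the
gap straddles the 1e-5 cutoff so threshold behaviour is exercised from
both sides. Gene bodies in the emitted sequence are well-formed CDSs
(forced ATG/TAA, no internal stop) so translation round-trips. Decoy
injection adds isolated genes with very strong hits (1e-30) spaced ≥ 15 kb
apart — sub-threshold signal the detector must ignore. Everything is a
pure function of the seed; outputs are byte-identical across runs.

What it does **not** emulate: real phage sequence homology (e-values are
sampled, not computed from alignments), annotation errors, partially
decayed prophages with weak or missing gene models, overlapping or nested
prophages, and compositional signals (GC skew, codon usage). Passing the
synthetic recovery tests therefore demonstrates that the interval logic,
thresholds and border rules are implemented exactly as specified — not
that real-genome sensitivity will match, which depends on reference
database coverage.

## Numerical and engineering notes

- All internal coordinates are 0-based half-open; GFF3 converts at the I/O
  boundary, BED needs no conversion.
- The scan maps each gene arithmetically onto the contiguous range of
  window indices it overlaps (O((genes + windows)·overlap)); tests compare
  it against an independent brute-force O(windows × genes) counter.
- Window selection ties: the gene-count bound is inclusive (≥ 8), the span
  bound strict (> 5 kb), the e-value bound strict (< 1e-5) — all three
  edges are pinned by tests.
- Determinism: identical inputs and parameters give byte-identical BED and
  manifest; the manifest records parameters and input SHA-256 checksums
  and deliberately contains no timestamps.
- Problem sizes in the test-suite and acceptance script (genomes of
  50–500 kb for oracle checks, batches of 60–100 scenarios of 100 kb for
  end-to-end recovery) were chosen as the smallest sizes at which every
  code path — truncated windows, multi-window islands, tRNA flanks,
  decoys — is exercised with comfortable margins.

## Known limitations

Short prophages whose genes have no reference match are invisible to a
similarity-density method by construction; the window grid anchored at 0
means predictions can shift by up to one step relative to a differently
anchored grid before trimming (trimming removes the dependence in
practice); circular replicons and origin-spanning features are rejected
rather than handled; and the external-aligner wrapper assumes a BLAST+-
compatible command line.
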