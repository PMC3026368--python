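# dyadscan

Genome-wide detection and enrichment of hairpin-forming inverted repeats
(IRs), such as pre-miRNA candidates.

The pipeline:

1. **Scan** — multi-scale windows (600/300/150 bp, half-window skips) slide
   across each contig; each window's optimal inverted repeat is found by a
   Smith–Waterman-style local alignment of the window against its own
   reverse complement with a custom 5×5 scoring matrix (gap −6, G·U wobble
   columns scored −2). Arms that would overlap on the original sequence are
   rejected during cell selection, so every reported alignment reads as a
   hairpin.
2. **Metrics** — each candidate is scored with four hairpin metrics:
   pairing density `D` (%), binomial symmetry probability
   `P(n, k) = 0.25^n · 0.75^(k−n) · C(k, n)` (carried in log10 space),
   mean contiguous paired-run length `A` (bp), and stem GC content `G`
   (% of G–C pairs inside runs longer than 3 bp).
3. **Filters** — inclusive thresholds `D_min ≤ D ≤ D_max`, `P ≤ P_max`,
   `A ≥ A_min`, `G ≥ G_min`, span `≥ L_min`. Two named profiles are built
   in: `base` (59 / 95 / 9.99e-9 / 2.2 / 18 / 50) and `optimal`
   (60 / 95 / 9.99e-11 / 2.3 / 24 / 50).
4. **Dedup** — the shorter of two overlapping candidates from adjacent
   windows of the same size track is removed (runs after the filters).
5. **Validate / tune** — candidates are matched against a known precursor
   FASTA by substring/superstring containment (IIR counting), and a grid
   or greedy coordinate search over thresholds minimizes the candidate
   count subject to retaining a target number of known precursors.

A synthetic-genome module (`dyadscan.simulate`) plants degradable hairpins
(wobble conversions, substitutions, indels on one arm) in i.i.d. background
with a truth BED, so the whole pipeline is testable without downloads.

## CLI

```sh
# scan a genome with the base profile; writes .candidates.tsv/.bed/.raw.tsv/.summary.txt
dyadscan scan genome.fa --out results/run1 --profile base

# only the 150 bp track, custom thresholds
dyadscan scan genome.fa --out results/run2 --windows 150 --g-min 24 --p-max 9.99e-11

# count known precursors identified by a candidate table
dyadscan validate results/run1.raw.tsv known.fa --out results/val

# threshold search on a cached scan (grid over A_min x G_min by default)
dyadscan tune results/run1.raw.tsv known.fa --out results/tune --target 171

# synthetic genome + truth BED
dyadscan simulate --out fixtures/sim --count 20 --background-length 100000 \
    --substitution-rate 0.1 --seed 1

# D/P/A/G metric table for a known precursor set
dyadscan profile known.fa --out results/known
```

All thresholds can also come from a flat YAML config (`--config`), with CLI
flags taking precedence. Candidate tables are TSV with 0-based half-open
coordinates and carry every filter input (n, k, D, log10P, A, G, spans,
pairing string, sequence).

## Library

```python
import dyadscan as ds

seq = ds.dna_to_rna("GGGGG" + "AAAA" + "CCCCC")
aln = ds.self_ir_align(seq)
aln.score, aln.n, aln.k          # 25, 5, 5
ds.pairing_string(aln)           # '(((((....)))))'
ds.density_D(aln), ds.log10_probability(aln.n, aln.k)

result = ds.run_pipeline(ds.read_fasta("genome.fa"), ds.FilterParams.base())
result.counts                    # scanned / filtered / deduplicated
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes an independently coded brute-force alignment oracle,
exhaustive/rational references for the binomial engine, property tests
(hypothesis), and `tests/test_acceptance.py` with one test per acceptance
criterion (runs a seeded 100 kb planted-hairpin genome end to end; about
two minutes total).

## Notes

- Input is translated to the RNA alphabet on ingest (T→U; ambiguity codes
  other than N become N). Scanning is forward-strand only: an inverted
  repeat's reverse complement is itself an inverted repeat. Note that G·U
  wobble pairs are strand-specific (a G·U on one strand is an A·C
  opposition on the other), so scores of heavily wobbled hairpins can
  differ slightly between strands.
- `density_D` supports two conventions: `column` (paired columns / total
  alignment columns, the default) and `span` (paired bases / hairpin span
  length).
- The dedup stage deliberately cannot distinguish nearby identical IRs
  from window-scan duplicates; see `dyadscan/dedup.py`.
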