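# protscape

Metaproteomic protein-landscape analysis for microbial communities: from
peptide-spectrum-match (PSM) tables, genome annotations and host phenotype
labels to genome-level quantification, host-phenotype-specificity scores,
protein co-expression modules, spectrally supported operon candidates and
rescued ORFs — plus a synthetic community generator that provides full
ground truth, so every stage is testable without any external MS data.

## What it does

| Module | Role |
| --- | --- |
| `protscape.io_formats` | FASTA / GFF3 / PSM TSV / manifest / hit-table I/O; target-decoy FDR filtering; per-sample unique-peptide QC |
| `protscape.synthetic_data` | Communities with planted operons, hidden ORFs (opposite strand / shifted frame / intergenic), co-expressed blocks, phenotype-specific proteins, shared peptides and decoy score mixtures |
| `protscape.quantify` | Unique-spectrum assignment, weighted allocation of multi-genome spectra, per-million-amino-acid + per-sample-depth normalization |
| `protscape.hps` | Entropy-based host-phenotype-specificity score in [0, 1] |
| `protscape.coexpress` | sparCC correlations (log-ratio variances, sparse basis solve, iterative pair exclusion), 0.3-threshold networks, iterative maximum-clique module extraction, phenotype assignment, guilt-by-association pathway suggestions |
| `protscape.operons` | Same-contig/strand gene clustering within 100 bp, spectral-support partitioning, overlap comparison against external operon lists |
| `protscape.orf_rescue` | Six-frame translation DB with exact coordinate maps, peptide-anchored ORF extraction, novelty filtering by local alignment, strand/frame relation classification, ORF grouping |
| `protscape.annotate` | COG hit-acceptance rule with category-S fallback, parsimonious (minimal set cover) pathway minimization, COG-category abundance profiles |
| `protscape.pipeline` / `protscape.cli` | End-to-end orchestration with byte-stable artifacts and a manifest of hashes |

## Quick start

Run the whole analysis on a synthetic community (deterministic per seed,
a few seconds):

```sh
protscape all --synthetic small --seed 7 --out out/
```

This writes, in order: the synthetic inputs (`out/synthetic/`), filtered
PSMs, raw and normalized genome count matrices, an HPS table, per-genome
co-expression edge lists and modules, an operon CSV, rescued-ORF GFF3/FASTA
and COG category profiles, ending with `out/manifest.json` (seed, row
counts, sha256 per artifact). Two runs with the same seed are
byte-identical.

Individual stages:

```sh
protscape simulate --seed 7 --out sim/            # synthetic community only
protscape filter sim/psms/CD_s00.tsv --fdr 0.01 \
    --min-unique-peptides 50 --out kept.tsv       # FDR + QC filter one table
protscape validate-manifest sim/manifest.csv
```

Library use mirrors the CLI; for example:

```python
from protscape.synthetic_data import generate_community, simulate_psms, small_config
from protscape.coexpress import sparcc, build_network, extract_modules

community = generate_community(small_config(seed=7))
psms = simulate_psms(community)
```

## Tests

```sh
python -m pytest -q tests/
```

The suite covers each module (unit + property tests, hypothesis where it
pays off) and `tests/test_acceptance.py` holds the ten acceptance criteria.
One assertion is expected to fail: the sparCC null-simulation bound in
criterion 3 asks for max off-diagonal |ρ̂| < 0.15 at M=20, Nₛ=200, which is
below the sampling-noise floor of any correlation estimator at those
dimensions (190 estimates with sd ≈ 1/√200 give an expected max ≈ 0.20);
the assertion is kept as specified rather than weakened.

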