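# ssrna-fragdock

Fragment-based docking of single-stranded RNA (ssRNA) onto coarse-grained
proteins. The pipeline models a protein-bound ssRNA from the protein
structure and the RNA sequence alone:

1. **Fragment cutting** — the RNA sequence is cut into overlapping
   trinucleotides; each trinucleotide is represented by a conformer
   ensemble from a library built out of protein-bound RNA structures
   (homo-pyrimidine windows canonicalised to UUU, homo-purines to AAA,
   greedy redundancy removal).
2. **Ensemble docking** — each conformer is rigid-body docked from
   thousands of sphere-surface starts, minimised on a pre-computed receptor
   grid (8-6 pair potential + Coulomb, COM restraint), re-scored without
   the grid, de-duplicated, and the top fraction kept.
3. **Chain-propensity filtering** — poses are connected when the
   flat-bottom overlap penalty between their shared nucleotides stays under
   a violation budget; a forward/backward dynamic program counts, for every
   pose, the number of N-fragment chains it participates in, and poses
   below a propensity threshold are discarded.
4. **Clustering & assembly** — leader clustering (single- or multi-radius),
   chain enumeration from cluster representatives with loosened margins,
   and a coarse-to-fine hierarchical assembly.
5. **Scoring & evaluation** — pose score `ln(propensity)/rank`, chain score
   combining junction overlaps with member ranks, hit/near-hit/close-hit
   classification, geometric-mean chain RMSD, binding-site delineation
   statistics, fit-vs-dock correlation and hypergeometric enrichment.

A deterministic synthetic scenario (`ssrna_fragdock.toybench`) provides a
receptor with a planted fragment chain, a conformer library with decoys,
and far-away decoy poses, so the full pipeline is testable end to end
without any external structure downloads.

## CLI

```bash
# generate a synthetic scenario
ssrna-fragdock toybench --seed 1 --out scen/

# build a conformer library from protein–RNA complex structures
ssrna-fragdock library-build --complex-list complexes.txt \
    --classes UUU,AAA --dedup 0.2 --contact-cutoff 5.0 --out lib/

# run the five-stage toy pipeline end to end
ssrna-fragdock run --seed 1 --out out/        # or --config config.yaml

# propensity-filter a pose table and enumerate chains
ssrna-fragdock assemble --poses out/poses.tsv --library lib/ \
    --chain-length 5 --margin-bb 2.3 --margin-base 2.8 --k 100 \
    --max-violation 2.0 --propensity 1e-4 --out assembled/
```

All tables are tab-separated with `#`-prefixed headers; CG structures are
written as plain-text pseudo-atom PDB files.

## Package layout

```
src/ssrna_fragdock/
  cg.py          coarse-grained types, bead mapping, PDB/mmCIF + CG-PDB I/O
  library.py     trinucleotide extraction, canonicalisation, dedup, best-fit
  docking.py     force field, receptor grid, starts, minimisers, pools
  assembly.py    overlap energy, chain graph, chain-count DP, filters
  clustering.py  leader clustering, hierarchies, clustered assembly
  evaluation.py  RMSD metrics, hits, scores, statistics
  benchmarks.py  published per-fragment reference tables (1B7F / 1CVJ)
  toybench.py    synthetic scenario generator
  pipeline.py    configuration, orchestration, table I/O
  cli.py         click command-line interface
  data/          editable bead-mapping table
```
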