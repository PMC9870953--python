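# kelppop

Population-genetic and paleodistribution analysis for kelp COI barcode
data. `kelppop` answers two linked questions about a habitat-forming kelp
at its warm, equatorward range edge: *where does its evolutionary genetic
diversity reside?* and *where could it have persisted through the Last
Glacial Maximum (LGM)?*

It provides, as importable functions and a small CLI:

1. **Haplotype diversity and networks** — collapse an aligned COI barcode
   dataset (~658 bp) into haplotypes per regional population; compute the
   standard polymorphism table (N, K, S, π, H, Hd, with the unbiased
   estimator Hd = n(1 − Σp²)/(n − 1) and π = K/L); and build a
   Templeton–Crandall–Sing-style statistical-parsimony network with a 95%
   connection limit and inferred intermediate nodes, exported to
   GraphML/GML/TSV.
2. **LGM hindcast** — predict percentage kelp cover from mean annual SST
   through a pluggable thermal response curve (optimum 23 °C, threshold
   26 °C by default), mask to the species' depth band below *scenario* sea
   level (0–80 m; at the LGM, sea level ~120 m lower, this is today's
   120–200 m shelf), average latitudinally, and measure the equatorward
   shift of cover features between scenarios.
3. **Synthetic data** — a deterministic 119-sequence study fixture
   encoding a known six-haplotype structure, random alignments with full
   ground-truth manifests, and latitudinally graded SST/bathymetry grids,
   so every stage is testable offline.

Sequence QC (degenerate-primer trimming with IUPAC matching, translation
checks for internal stop codons) is included; alignment is not — inputs
are pre-aligned FASTA (or NEXUS) plus a sample→population TSV.

## Worked example

Run the genetics stage on the built-in fixture (119 COI sequences, 658 bp,
four regional populations):

```sh
kelppop genetics --fixture --out out/genetics --seed 1
```

prints the diversity table (and writes TSV/NEXUS/GraphML artifacts plus a
run manifest to `out/genetics/`):

```
     population   N        K  S       pi  H       Hd  L_used
   SA, Vic, Tas  63 0.501792  1 0.000763  2 0.501792     658
            NSW  26 0.076923  1 0.000117  2 0.076923     658
            QLD  12 1.151515  5 0.001750  4 0.636364     658
LHI, NI, KI, NZ  18 0.000000  0 0.000000  1 0.000000     658
            All 119 0.629255  7 0.000956  6 0.527560     658
```

Reading it: the small Queensland population is by far the most diverse
(Hd = 0.636 — four haplotypes among 12 sequences, five segregating
sites), the island group is monomorphic, and New South Wales is nearly so
(Hd = 0.077: a single variant among 26 sequences). That is the genetic
signature of a warm-edge refugium: unique diversity concentrated in the
low-latitude, deep-water population. The network (written to
`network.graphml`) is a single connected component — the 95% parsimony
connection limit at 658 bp is 7 steps, so even the haplotype three
substitutions from the common one attaches, via two inferred
intermediates.

The hindcast on synthetic grids (0.8 °C/° latitudinal SST gradient, 4 °C
uniform glacial cooling, 120 m sea-level offset):

```sh
kelppop hindcast --out out/hindcast
```

```
equatorward shift (peak): +5.00 degrees latitude
```

Cooling by 4 °C on a 0.8 °C/° gradient must move the optimal isotherm
4/0.8 = 5° toward the equator, and the cover-peak shift recovered from
the masked, binned profiles matches that analytic value exactly. Profiles
and a JSON shift summary land in `out/hindcast/`.

The library API mirrors the CLI; e.g.:

```python
from kelppop import (make_paper_fixture, complete_deletion,
                     collapse_haplotypes, diversity_report,
                     connection_limit, build_network)

seqs, pops, manifest = make_paper_fixture(seed=1)
seqs, sites = complete_deletion(seqs)
table = collapse_haplotypes(seqs, pops)
report = diversity_report(table, sites.length_used)
net = build_network(table, connection_limit(sites.length_used))
```

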