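# Methods

`kelppop` implements two analytical engines for studying how past climate
shaped the genetic structure and distribution of a habitat-forming kelp:
a COI-barcode haplotype analysis (diversity statistics plus a statistical-
parsimony network) and a sea-surface-temperature (SST) driven hindcast of
kelp cover at the Last Glacial Maximum (LGM). A synthetic-data module
generates every input, so the whole pipeline is testable offline against
known ground truth.

## Sequence handling and quality control

Inputs are pre-aligned DNA sequences (the package does not align; alignment
is an off-the-shelf upstream step). On read, symbols are uppercased, `U` is
mapped to `T`, and only IUPAC nucleotide codes plus `-` are accepted;
ragged alignments and duplicate sample ids are rejected with the offending
records named.

**Primer trimming.** The COI-5' barcode amplicon is flanked by a degenerate
primer pair (forward `CCAACCAYAAAGATATWGGTAC`, reverse
`GGATGACCAAARAACCAAAA`, the reverse given 5'→3' on the opposite strand). A
primer matches a sequence window when every degeneracy set intersects the
sequence symbol's set; gaps never match. The forward primer is searched in
the leading `len(primer) + 10` columns, the reverse complement of the
reverse primer in the trailing window, each with a default tolerance of one
mismatch (standard barcode practice; tunable). Trimming removes whole
columns — the modal matching interval across samples — so the output
remains an alignment, and a per-sample log records what happened.
Coordinates are 0-based half-open internally, 1-based inclusive in logs.

**Translation QC.** Each sequence is translated in the three forward frames
and the frame minimising internal stop codons is chosen (ties to the lowest
frame); codons containing a gap or ambiguity are skipped, and the final
codon of a frame is not counted as internal. A sequence passes iff its best
frame has zero internal stops. The genetic code is a parameter (NCBI table
id, default 1, the standard code). COI is organellar and a mitochondrial
table may be more biologically apt for some taxa; because reported
analyses of this locus have used the standard code, that is the default,
and the choice is explicit rather than hard-wired.

## Haplotype collapsing and diversity statistics

**Site filter.** Before any statistic, complete deletion removes every
column containing a gap or ambiguity code in *any* sequence — the default
site handling of the standard DNA-polymorphism software this module
mirrors. The filter is applied once to the full dataset, so every
population row shares one effective length `L_used`, which is reported
alongside π so results are auditable.

**Collapsing.** Identical sequences (exact match over retained columns)
form a haplotype. Ids are assigned deterministically: descending total
count, ties by first appearance in the input, so outputs are reproducible
and order-independent up to relabelling among equal-count haplotypes. The
table stores per-population counts and the full pairwise Hamming distance
matrix (uncorrected differences; no Jukes–Cantor-style correction, as none
is needed at intraspecific divergences of a few substitutions).

**Statistics** (per population and pooled):

- `S` — columns with ≥ 2 observed bases among the subset's sequences;
- `K` — mean pairwise differences, `K = Σ_{i<j} n_i n_j d_ij / C(n,2)`;
- `π = K / L_used`;
- `H` — number of distinct haplotypes in the subset (the pooled row's H
  comes from pooled counts, never from summing per-population H);
- `Hd` — Nei's unbiased haplotype diversity
  `Hd = n(1 − Σ p_i²)/(n − 1)`, equal to the probability that two
  sequences drawn without replacement carry different haplotypes. The
  unbiased (not the plug-in) form is used because it is what the standard
  software reports.

Statistics are computed in full precision; the TSV report renders K and Hd
to 3 decimal places and π to 3 significant figures. Populations need n ≥ 2
(Hd is undefined for a single sequence and the function raises).

## Statistical-parsimony network

Haplotypes are linked, most-similar pairs first, as long as the observed
number of differences j stays within the **95% parsimony connection
limit** — the largest j for which the probability that j differences arose
with no superimposed (homoplasious) changes is at least 0.95. A link of
length j inserts j − 1 inferred intermediate nodes ("median vectors", ids
`mv1, mv2, …`), so every edge represents exactly one substitution.

The probability of parsimony is computed on a finite-sites, two-state,
uniform-hits model. Let m = `L_used`. Mutations strike columns uniformly at
random; a column differs between two sequences iff it was hit an odd
number of times, so the visible difference count D performs a birth–death
walk on {0..m} (D→D+1 with probability (m−D)/m, else D→D−1). The true
number of mutations H separating a random sequence pair is geometric — the
pairwise-coalescent distribution for a neutral locus — with mean θ fixed
by method of moments so that E[D] = j; using E[D | θ] = θm/(m + 2θ) this
gives the closed form θ = jm/(m − 2j). The probability of parsimony is the
posterior

    P(parsimony | j) = P(H = j | D = j)
                     = w_j P(D=j|H=j) / Σ_{h ≥ j} w_h P(D=j|H=h),

with geometric weights w_h ∝ (θ/(1+θ))^h and the likelihoods from the
walk (only h with the parity of j contribute). The series is truncated
when terms fall below 10⁻¹⁵ of the running sum. The function is exposed
for audit; it is exactly 1 at j = 0, strictly decreasing in j, and yields
a limit that is non-decreasing in m and decreasing in the confidence
level. At m = 658 (the COI barcode) the 95% limit evaluates to 7 steps:
single-step differences are parsimonious with probability ≈ 0.999, and a
three-step divergent haplotype is comfortably connectable. Published
implementations of this method differ in their numerical transcription of
the underlying equations; this package's transcription is the model above,
stated in full so its behaviour is reproducible from this note alone.

Construction details: candidate pairs are sorted by (distance, larger
combined haplotype count first, lexicographic id pair) — the "connect
high-frequency haplotypes first" heuristic made deterministic. A candidate
whose endpoints are already in one component is skipped, so no loops are
formed (no probabilistic resolution of alternative connections; a
limitation, acceptable for tree-like intraspecific networks). Exports:
GraphML/GML with per-node total and per-population counts and an
`is_inferred` flag, or a plain TSV edgelist.

## Paleodistribution hindcast

Kelp cover is predicted from mean annual SST through a pluggable response
function. The default is a symmetric smooth bump

    cover(T) = peak · cos²( (π/2) · (T − T_opt)/(T_max − T_opt) ),  |T − T_opt| < T_max − T_opt,

zero outside, with `T_opt = 23 °C` (the optimal isotherm for this kelp),
`T_max = 26 °C` (its upper thermal threshold), and `peak = 50 %` cover. The
empirical cover–SST curve from field surveys is not published in a
reusable form, so the functional form is deliberately user-replaceable: any
(temperature, cover) table can be supplied and is linearly interpolated.
The default peak value is a plausible dense-kelp mean cover; none of the
package's tested properties depend on it.

A scenario couples an SST grid, a bathymetry grid (m, positive down), a
**sea-level offset** (0 m for the present day; 120 m for the LGM, within
the reconstructed 65–125 m lowstand range and exposed as a sensitivity
parameter), a habitat **depth band** (default 0–80 m below scenario sea
level — so the LGM band selects shelf that is 120–200 m deep today), and a
latitude window (default 18–38° S). Cover is evaluated everywhere on the
grid (for full-shelf maps); the depth/latitude mask is applied only when
averaging. Latitudinal profiles are unweighted means of masked cells in
0.5° bins (no area weighting — none is implied by a plain latitudinal
average); bins with no eligible cells are flagged NaN, never zero-filled.
No cross-shelf habitat (rocky-reef) availability is modelled, and no
drivers other than temperature enter the prediction.

Range shifts between two profiles are signed degrees of equatorward
displacement (positive toward the equator) of a chosen feature: the
profile peak, the cover-weighted centroid, or the equatorward edge of the
band above a threshold fraction of the profile maximum (default 0.5).

## Synthetic data

**Study fixture.** A deterministic 119-sequence, 658 bp alignment encodes
the observed haplotype structure: six haplotypes with totals 74, 35, 7, 1,
1, 1 over four regional populations of sizes 63, 26, 12, 18
("SA, Vic, Tas" = 35 + 28; "NSW" = 25 + 1; "QLD" = 3 + 7 + 1 + 1;
"LHI, NI, KI, NZ" = 18). The widespread haplotype H1 is the reference;
H12, H8, H10 differ by one substitution each, H9 by three, and H11 by one
substitution from its parent (H10 by default; attaching to H1 is
supported, since either is consistent with the five segregating sites in
the Queensland subset). The 28 H1 copies in the southern group follow
arithmetically from the totals (74 − 25 − 3 − 18); the haplotype
diversities this implies for that group (0.502) and for the pooled data
(0.528) differ from some reported values (0.486 / 0.543), which are not
reproducible from any counts summing to the reported totals — the
generator manifest documents this. Substituted columns are evenly spaced
(deterministic across releases), bases are chosen to avoid creating stop
codons on the stop-free coding reference, and mutations never share a
column, so pairwise distances are additive along the designed topology (no
homoplasy). Optional concrete primer flanks produce 700 bp reads
(22 + 658 + 20).

What the fixture does *not* emulate: sequencing error, indels, ambiguity
codes, intra-population rate variation, or homoplasy. Passing tests
therefore demonstrate correctness of the statistics and network logic, not
robustness to messy real-world barcode data (the gap/ambiguity handling is
exercised by separate constructed cases).

**Grids.** SST(lat) = `sst_ref + gradient·(lat − lat_ref) − cooling +
noise`, default 16.6 °C at 38° S with 0.8 °C per degree of latitude —
representative of the eastern-Australian coastal gradient — plus an
optional uniform glacial cooling (default 4 °C for the LGM scenario) and
optional Gaussian noise; bathymetry ramps monotonically offshore 0–250 m,
independent of latitude. On these defaults the 23 °C isotherm sits at
30° S today and 25° S under 4 °C cooling, giving an analytic 5.0°
equatorward peak shift (cooling/gradient) that the tests check to bin
resolution. The published 3–10° shift estimate depends on external
reconstructed SST fields and an unpublished cover curve, so it is
reproduced qualitatively (equatorward sign, monotone response to cooling),
never numerically. Grid resolution is 0.1°, small enough that a 20° × 5°
domain runs in well under a second.

All generators are seed-deterministic (NumPy `default_rng`) and emit
manifests with the full ground truth (reference sequence, substitution
maps, expected counts and distances).

## Numerical and design choices

- Distances, counts and S are exact integers; Hd/K/π are IEEE doubles with
  no rounding until rendering.
- The parsimony-probability series truncation (10⁻¹⁵ relative) is far
  below any decision threshold; the geometric prior's closed-form mean
  avoids iterative root-finding.
- Degenerate inputs raise early with precise messages: empty alignments,
  all-columns-deleted, n < 2 populations, flat profiles (no feature),
  empty depth masks (warning, not error).
- netCDF output uses the netCDF3 (scipy) backend; inputs are equally
  accepted as in-memory `xarray` objects, which is how the synthetic
  module supplies them.
- The CLI (`kelppop fixture|genetics|hindcast|all`) is a thin veneer:
  every operation is importable, and two runs with the same config and
  seed produce byte-identical TSV/JSON artifacts, with a run manifest
  listing outputs and input hashes.

## Known limitations

- The parsimony limit is a model-based transcription (documented above);
  other implementations of the same method may print a different numeric
  limit for the same alignment length, though all agree on the behaviours
  that matter here (short links are accepted; the limit grows with
  alignment length).
- No reticulation: alternative equally parsimonious connections are
  dropped, not resolved probabilistically.
- The hindcast treats SST as the sole driver and the response curve as
  spatially stationary; profiles are cell means, not area-weighted.
- Indels are treated purely as missing data (complete deletion), never as
  characters.
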