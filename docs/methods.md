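# Methods

## The problem

A clonal family (CF) is the set of B cells — and hence BCR sequences —
descending from one unmutated common ancestor. Somatic hypermutation (SHM)
spreads the members of a CF apart in sequence space while junctional
diversity keeps unrelated rearrangements far from each other, so CF
inference is a clustering problem whose difficulty is set by the ratio of
within-clone to between-clone distances. `cfbench` simulates repertoires in
which that structure is known, runs a panel of inference definitions, and
scores them against the truth.

## The generative model

A repertoire is simulated in five stages, all driven by one integer seed.

1. **Germline catalogue.** `n_v_segments` V and `n_j_segments` J nucleotide
   segments are drawn at random (defaults 20 and 6; lengths 294 nt and
   48 nt, typical of a rearranged heavy-chain V region and J segment). V
   segments end in the Cys104 anchor codon `TGT` and J segments begin with
   the Trp118 anchor `TGG`. Any two segments of the same type differ at
   ≥ 3 positions (rejection sampling), so gene-level assignment is
   unambiguous and VJ partitioning is well defined.

2. **Naive rearrangement.** Each clone's ancestor is V + insertion + J with
   uniform V/J usage. The junction runs from the Cys anchor to the Trp
   anchor; insertion lengths are Poisson (default mean 39 nt, giving
   junctions around 45 nt / 15 aa, in the range seen in human heavy
   chains), padded to a multiple of 3 so every junction translates.
   Ancestors are forced to distinct (V, J, junction-length) triples unless
   `collision_rate` permits collisions; this makes the perfect-recovery
   regime constructible and the difficulty of the problem controllable.
   D segments and allele polymorphism are not modeled.

3. **Clone sizes.** Drawn per clone from a configurable distribution
   (geometric p = 0.2 by default, giving a long-tailed size spectrum), with
   `singleton_fraction` (default 0.3) of clones forced to size 1 —
   experimental repertoires are singleton-rich.

4. **Lineage tree.** Each clone expands along a random recursive tree
   (node i attaches to a uniform earlier node, depth-capped) whose nodes
   are subclones; node copy numbers are geometric (p = 0.5). Topologies are
   generated, not reconstructed from data.

5. **Hypermutation.** On each tree edge every site mutates independently
   with probability `rate × normalized 5-mer mutability` of its context in
   the parent (substitutions only — no indels, so all members of a clone
   keep the ancestor's length). The default targeting model is flat with
   classical AID hotspots WRC/GYW at 5× and coldspots SYC/GRS at 0.3×,
   normalized to mean 1 over all 1024 5-mers so the realized per-site rate
   matches the configured rate on typical composition; an empirical 5-mer
   table (mutability TSV plus substitution TSV) can be loaded instead. The
   default per-edge rate of 0.005 produces V/J mutation loads below ~1%,
   i.e. a lightly mutated repertoire; raising it toward 0.02 emulates
   mature, heavily mutated repertoires.

Records carry V/J mutation counts relative to their germline segments with
the junction excluded (it has no reliable germline reference). Members are
split across samples by largest-remainder allocation of the configured
proportions, so a stated mixing is realized exactly. If light chains are
emitted, each clone receives one LC V/J pair on all members;
`lc_discordance_rate` reassigns a random pair per record.

All randomness flows through named streams keyed on (seed, purpose, clone
index), so adding clones or approaches never perturbs earlier draws and an
identical config yields byte-identical AIRR output.

**What the simulator does not emulate:** sequencing error, indels, D-gene
structure, allele polymorphism, selection on the lineage, realistic V/J
usage skews, and empirical clone-size laws. Passing tests therefore show
that an approach recovers clonal structure under idealized, controllable
conditions; they bound behavior on real data from the easy side.

## Inference approaches

A1/A2 are exact-match definitions (junction AA; plus V/J genes for A2).
A3–A6 first partition by (allele-stripped V gene, J gene, junction length),
then single-linkage cluster within each partition: connected components of
the graph whose edges are junction pairs at distance ≤ threshold. The edge
criterion is inclusive (≤). Single linkage is used because removing
above-threshold edges from a complete graph and grouping what remains
connected is exactly connected components.

* A3: absolute junction AA Hamming ≤ 1.
* A4/A5: length-normalized Hamming ≤ 0.15 (AA and NT respectively).
* A6: as A5 with a per-sample threshold fitted from the distance-to-nearest
  distribution (below).
* A10: no partitioning; tf = raw k-mer count (k = 4) over the full
  sequence, idf = ln(N/df), cosine distance between tf-idf vectors; the
  clonal threshold is the 10% quantile of each sequence's distance to its
  nearest *negation* sequence (a repertoire from a different individual);
  components at that threshold are the CFs. idf is computed over the
  pooled repertoire + negation so both live in one vector space.

Records whose junction cannot be translated are excluded from AA-based
approaches (listed in `params["skipped_ids"]`); NT-based approaches keep
them.

### A6 threshold detection

Per record, the normalized Hamming distance to its nearest *non-identical*
junction within its VJ/length group; excluding zero-distance duplicates
prevents a spurious spike at 0. A Gaussian KDE (Silverman bandwidth) is
evaluated on a 512-point grid over [0, 1]; modes are local maxima with
prominence ≥ 5% of the peak density (KDE ripple in a tail is not a mode;
grid endpoints may be modes because clipping at 0 can put the within-clone
mode on the boundary). The threshold is the density minimum between the
two highest modes, clamped to the observed distance range. With fewer than
two modes — including the degenerate case where every group is internally
identical and the distance list is empty — the fit reports
`bimodal = False` and falls back to the fixed relative threshold 0.15.

## Evaluation

Each partition's CFs are cliques; over the C(n,2) pair universe the
TP/FP/TN/FN edge counts are computed from the (true clone × inferred
clone) contingency table — TP = Σ C(n_ij, 2), with truth and inference
marginals giving FN and FP and TN closing the universe algebraically. A
brute-force all-pairs enumerator is kept as a test oracle, and the counts
are cross-checked against an independent pair-confusion implementation in
the test suite. Ratios with zero denominators (e.g. precision when nothing
is co-clustered) are reported as `None`/`null`, never silently 0 or 1.

## Downstream analyses

Shared CFs: samples are merged with their sample annotation kept
(sequence-id collisions resolved by sample prefixing), the merged
repertoire is partitioned, and a CF is shared when its members span ≥ 2
samples. Similarity thresholds are not loosened for shared-CF detection.
The shared fraction uses the merged CF total as denominator; shared-
dominant CFs exceed the 0.5% frequency threshold on the merged repertoire.

LC concordance: a CF is concordant when all members pair to one LC V/J
gene pair (allele-stripped); singletons are concordant by definition. CFs
containing a record without LC calls are excluded from the denominator and
reported, rather than counted discordant — a conservative choice.

## Numerical and design choices

* Clonal frequencies count records (rows); a distinct-sequence mode exists
  behind a flag. Shannon is reported in natural log by default (maximum
  ln n_CF), with a `log2` option.
* D50 is the smallest k whose k largest clones cover ≥ 50% of records;
  ties broken by label order (deterministic).
* Dominance is strict: frequency > 0.5%.
* Multi-assigned V/J calls resolve to the first-listed gene; allele
  suffixes are stripped at analysis time only.
* Benchmark replicate r uses seed base_seed + r; A10's negation sample is
  an independent simulation at seed + 1,000,003 (a different simulated
  "individual").
* Summary TSVs format floats at 10 significant digits, making reruns
  byte-identical.

## Problem sizes

Tests and the acceptance script use repertoires of roughly 400–2000
records (15–50 clones): large enough that edge-based measures are stable
at the reported precision, small enough that the full benchmark completes
in seconds. The perfect-recovery analysis uses 50 clones × 40 records =
2000 sequences.

## Known limitations

A10's behavior depends strongly on how much of the sequence is shared
germline: with a small synthetic V/J catalogue, full-length tf-idf vectors
of unrelated clones are more similar than in real repertoires, so its
calibrated threshold tends to merge aggressively here. The regression-based
comparison of approaches across datasets, and external spectral/HMM
clustering tools, are out of scope.
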