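# Methods

`eetcensus` mines an annotated bacterial genome for the machinery of
extracellular electron transfer (EET): multiheme c-type cytochromes,
their homologs in reference organisms, and the type IV pilus (T4P)
apparatus with its conductive major pilin. It was built around the
genomic characterisation of electrogenic *Desulfuromonas*-clade
isolates, where the headline quantities are the c-type cytochrome
census (heme counts, subcellular distribution, genes unique to the
strain), the aromatic content of the PilA pilin, genome composition
statistics, and a 16S rRNA neighbor-joining phylogeny placing the
isolate among its relatives.

## Heme-motif screen and cytochrome evidence rule

c-type cytochromes bind heme covalently at C(X)nCH motifs — cysteine,
n spacer residues, cysteine, histidine. The census screens every CDS
translation for these motifs with n = 2–4 (the `heme_n_min`/`heme_n_max`
range), the spacer range that covers the overwhelming majority of
CxxCH-family attachment sites in bacteria.

The scan is greedy, left to right: at each cysteine the shortest valid
spacer is accepted, and scanning resumes after the matched histidine, so
reported sites never overlap and the heme count of a protein is
well-defined. The unknown-residue code X may occur in a spacer but is
never accepted as one of the motif's cysteines or the histidine; a
sequence with an internal stop is reported motif-free with a warning.
The suite checks this policy against an independent brute-force
enumerator (regex lookaheads plus explicit left-to-right shortest-first
overlap resolution) on a thousand random sequences.

A motif hit alone is not a call. A protein is accepted as a putative
c-type cytochrome iff it has at least one motif AND at least one of two
evidence branches fires:

* **domain branch** — an externally produced conserved-domain hit with
  e-value below `domain_e` (default 0.01). Domain searching itself is
  out of scope; hits are ingested as a TSV (`locus_tag`, accession,
  e-value), because HMM libraries are large, versioned databases best
  queried with their own tooling.
* **alignment branch** — a local alignment against a reference
  cytochrome set with e-value below `aln_e` (default 1e-10).

Subcellular localization (CM/PP/EX/CY) is likewise ingested as a table
from an external predictor and only attached and tallied, never
predicted.

## Pairwise alignment, E-values, reciprocal best hits

Protein comparisons use exact local Smith–Waterman with affine gaps
(BLOSUM62, gap open 11, gap extend 1 — the familiar BLASTP parameter
set) rather than a heuristic seeded search: at census scale exactness
and determinism are worth more than speed. The dynamic programming is
delegated to Biopython's `PairwiseAligner`; the test suite keeps an
independently written Gotoh DP oracle and checks score agreement
cell-for-cell-equivalent on exhaustive short pairs.

Two conventions differ between tools, so both are fixed and stamped in
output metadata: identity is identical columns over all alignment
columns (gap columns count in the denominator), and coverage is the
aligned span on the named sequence over its full length.

E-values follow Karlin–Altschul statistics, `E = K·m·n·exp(−λ·S)`, with
gapped-BLOSUM62 constants K = 0.041, λ = 0.267 as configurable defaults;
m is the query length and n the summed database length.

Ortholog mapping uses bidirectional best hits (BBH): each member of a
pair must be the other's best-scoring hit, with identity ≥ 40% and
coverage ≥ 80% in the query direction of each member. Best hits are
made deterministic by tie-breaking on score, then identity, then the
lexicographically smallest subject tag.

Closest-homolog assignment (and the "unique gene" call, identity < 40%
to every reference) takes the best-scoring *significant* hit, where
significance means E < 1e-5. The gate matters: optimal local alignments
between entirely unrelated proteins routinely contain 12–15-column
fragments at 40–50% identity, and without the significance filter such
fragments would hide genuinely unique genes. The suite constructs this
trap explicitly and checks the gate defeats it.

T4P detection maps gene names (PilA, PilQ, PilT, …) onto a proteome by
assigning each locus to the gene name of its best-scoring exemplar when
that hit passes the BBH identity/coverage thresholds in both directions.
Assignment is per-locus rather than strict 1:1 mutual-best so paralog
expansions — several retraction ATPase PilT copies is the canonical
case — all map to the same name.

## Pilin maturation and aromatic content

Major pilins are exported with a short, positively charged class-III
signal peptide that prepilin peptidase cleaves after an invariant
glycine; the mature filament subunit starts at the hydrophobic residue
(canonically phenylalanine) that follows. Cleavage is detected as the
first `G[FMLI]` consensus within the leading 40 residues — prepilin
leaders are strictly N-terminal, and taking the first site rather than
a later one is what recovers the canonical 61-residue mature peptide of
the *G. sulfurreducens* PCA PilA shipped with the package (a later
glycine-before-hydrophobic also exists in its transmembrane segment and
must not be chosen). When no site is found the full-length content is
reported, flagged `full_length`, with a warning.

Aromatic content is `100·(#F + #W + #Y)/length` of the mature peptide.
Histidine is excluded from the aromatic set: on the PCA PilA 61-mer,
F/W/Y gives 6/61 = 9.84%, matching the accepted literature value
(9.83%), whereas including H would not. The set is configurable for
sensitivity analyses.

## 16S distances, neighbor joining, bootstrap

Pairwise 16S identity aligns globally (match +1, mismatch −1, gap open
2, gap extend 0.5) and counts identical columns over columns with a
residue in both sequences, so end overhangs do not dilute identity.
Argument order is canonicalised before aligning because co-optimal
alignments can differ between orders; this makes identity exactly
symmetric.

Distance matrices from pre-aligned sets use p-distance under pairwise
deletion of gap/N sites (the common default for 16S work), with the
Jukes–Cantor transform `−(3/4)·ln(1 − 4p/3)` available by flag; p ≥ 0.75
raises a saturation error naming the pair.

Tree building is Saitou–Nei neighbor joining with the standard
Q-criterion. Determinism is guaranteed by tie-breaking joins on the
lexicographically smallest pair of cluster representatives (the smallest
leaf label in each cluster); negative branch lengths are clamped to zero
and counted. The output is rendered unrooted with a basal
trifurcation. On additive matrices NJ provably recovers the generating
tree; the suite verifies exact recovery of random 4–10-taxon additive
matrices and cross-checks topology against an independent NJ
implementation (scikit-bio).

Bootstrap support resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and reports for each internal
bipartition of the full-data tree the percentage of replicates
containing it. The replicate count defaults to 1000 by convention; the
seed is mandatory.

## Synthetic data: what it does and does not emulate

Every stage is exercised on generated inputs with planted, exactly
known truth:

* **Motif-planted proteins** draw background residues from an
  18-letter pool excluding C and H, so no accidental heme motif can
  form and the planted count is exact by construction (no rejection
  sampling). Consequently motif recovery tests prove the scanner, not
  robustness to near-motif noise — that is covered separately by the
  brute-force-oracle comparison on C/H-enriched random sequences.
* **Homolog pairs** apply point substitutions (plus ≤5% single-residue
  indels) and calibrate against the package's own aligner until the
  realized identity is within ±2 points of target, so threshold tests
  (40% identity and the like) operate at known effect sizes.
* **Genomes** hit the requested G+C within ±0.1 by exact composition
  accounting (codon choices greedily balanced toward the target,
  background assembled from an exact base multiset), plant rRNA operons
  as 16S+23S+5S triples and CDSs with valid table-11 translations on
  both strands. They emulate composition and annotation structure only:
  no codon-usage realism, no operon regulation, no repeats — so
  statistics and feature plumbing are tested, not gene finding.
* **Alignments on trees** evolve i.i.d. uniform root sites under
  Jukes–Cantor along a given newick tree. Columns are independent;
  there is no rate heterogeneity or indel process, which is exactly the
  regime where NJ on JC/p-distances is consistent — passing tests show
  correctness of the estimator, not robustness to model violation.

The default study-scale parameters mirror the organism that motivated
the package: genomes are generated at 63.1% G+C with four rRNA operons,
and the census fixture plants a maximal cytochrome carrying 53
heme-binding motifs — matching a real genome in which the largest
multiheme cytochrome carries 53 sites and heme counts range from 1 to
that maximum.

All generators route randomness through one `numpy.random.default_rng`
per call: identical arguments give byte-identical output.

## Pipeline determinism and numerical choices

* Coordinates are 0-based half-open internally; GenBank's 1-based
  inclusive convention is converted on read and restored on write.
  Origin-spanning features on circular replicons carry a wrap flag and
  are spliced on extraction.
* G+C content ignores N and other ambiguity codes in the denominator;
  G+C skew `(G−C)/(G+C)` reports a window with no G or C as 0 with a
  `defined=False` flag; windows wrap on circular replicons.
* rRNA class (5S/16S/23S) is inferred case-insensitively from the
  product string, since flat files carry no structured field for it.
* TSV outputs are tab-separated UTF-8 with a header row and '.'
  decimals; every output carries the tool version and a hash of the
  scientific configuration (inputs and thresholds — not the output
  directory). Reruns on identical inputs are byte-identical; to keep
  that guarantee, wall-clock stage timings go to stderr only and the
  run log records stage order and record counts instead.
* Analysis drivers under `analysis/` use small problem sizes (a ~35 kb
  genome with 14 planted CDSs, 150–600-residue proteins, 1.5 kb
  simulated 16S alignments, 200 bootstrap replicates) — ample for
  exact-recovery checks on planted truth while keeping every script
  near-instant on one CPU.

## Known limitations

* The alignment stage is exact but quadratic; it is meant for focused
  censuses (tens to a few thousand proteins), not all-vs-all scans of
  large databases.
* E-values use fixed Karlin–Altschul constants rather than per-matrix
  estimation; they are calibrated for ranking and thresholding, not for
  publication-grade significance claims.
* The heme scanner's greedy shortest-first policy is one defensible
  overlap convention; counts for pathological motif clusters could
  differ under other conventions, which is why the policy is stated and
  oracle-tested rather than treated as ground truth.
* Prepilin cleavage detection is a consensus heuristic, not a trained
  signal-peptide model; sequences with unusual leaders fall back to
  full-length scoring with an explicit flag.
* Multiple sequence alignment is out of scope; tree building expects
  pre-aligned input (the pairwise-identity operation does its own
  global alignment).
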