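# Methods

`rapscan` implements the computational analyses behind a genomic-SELEX
screen for RNA segments that bind RNA polymerase II directly ("RAPs",
RNA polymerase-binding aptamers). An RNA library transcribed from
genomic DNA in short (30–400 nt) fragments is repeatedly bound to
purified Pol II and amplified; after several cycles the surviving pool
is sequenced and mapped back to the genome. The package covers the
downstream statistics — which repeat families are enriched and on which
strand, whether the in-silico translation of an enriched satellite unit
resembles the Pol II carboxy-terminal domain (CTD), and whether the
selected pool as a whole carries a codon-level compositional bias
toward the CTD — plus a ground-truthed simulator of the whole
experiment so that every stage can be validated without external data.

## Sequence model (`seqcore`)

Sequences are held as DNA over {A,C,G,T,N}; RNA input is mapped U→T on
ingest, since the library and genome are both handled as DNA and the
selection acts on transcripts of it. Coordinates are 0-based half-open
(BED convention) everywhere. Translation uses the universal genetic
code; the trailing partial codon of a frame is dropped, stop codons are
emitted as `*`, and codons containing N are emitted as `X` with a
logged tally. Both `*` and `X` are excluded (with renormalisation) from
every amino-acid frequency vector: the 20-letter comparison to the CTD
cannot contain stops, and N-codons would otherwise bias the
composition. Reading frames are always the three 5′→3′ frames of the
given strand — the selected molecule is an RNA, so the reverse
complement is never translated implicitly.

## Global alignment (`alignment`)

The satellite-vs-CTD comparison uses strict global Needleman–Wunsch
(Gotoh three-state) with BLOSUM62 and affine gaps, gap opening 12 and
extension 2. A gap run of length L costs `12 + 2·L` — the FASTA/lalign
reading of "opening −12, extending −2" — with the
`open + (L−1)·extend` dialect available via `ScoringScheme(gap_style=...)`.
End gaps are penalised (a true global alignment); a semiglobal mode
exists for exploration (`penalize_end_gaps=False`). The traceback is
deterministic with tie order substitution > gap-in-b > gap-in-a, and
the identity count is reported from that single traceback, so repeated
runs agree column for column. BLOSUM62 ships as a plain-text data file
checked against the canonical matrix in the test suite.

Because the original figure does not state which CTD residue range or
which reading frame of the satellite unit was used,
`best_ctd_fragment` scans every contiguous CTD window of the query's
length (ties to the smallest start), and
`pipeline.best_frame_ctd_alignment` additionally scans the three
frames, reducing each translation to its longest stop-free segment
first. This is the package's reconstruction strategy for "aligned
globally against a fragment of equivalent length", not a claim about
the original procedure.

The aligner is validated two independent ways: exhaustive enumeration
of all global alignments for short peptides, and Biopython's
`PairwiseAligner` configured to the same gap convention.

## Composition bias statistic (`ctd_bias`)

The headline statistic asks whether selected sequences are enriched in
codons for the amino acids of the CTD heptad YSPTSPS. The pipeline:

1. translate every sequence in all three 5′→3′ frames and pool
   amino-acid counts into one frequency vector (per unique sequence,
   unweighted by read count; a `weights` argument exposes
   count-weighting, which the analysis does not use by default);
2. divide each amino acid's frequency by its codon multiplicity (the
   number of sense codons encoding it: L/S/R 6, A/G/P/T/V 4, I 3, most
   others 2, M/W 1) and renormalise — without this step the statistic
   would reward amino acids merely for having many codons;
3. measure the Jensen–Shannon divergence, with base-2 logarithms so
   JSD ∈ [0,1], against the equally codon-normalised CTD composition
   (consensus heptad by default: Y 2/7, S 2/7, P 2/7, T 1/7 after
   normalisation). The log base rescales JSD, mean and sd identically,
   so z and p are base-invariant.

Significance comes from a Monte-Carlo null: each replicate draws one
i.i.d. random sequence per observed sequence length (matched
sequence-by-sequence, not just in total) from background mononucleotide
frequencies — genome-wide human values A/T 0.295, C/G 0.205 by
default — and runs the identical pipeline. CTD-likeness means a LOW
divergence, so the test is lower-tailed: empirical
p = (m+1)/(n+1) with m the number of null JSDs ≤ observed. The z-score
(observed − null mean)/null sd feeds a one-sided normal lower-tail
p-value for extrapolation beyond Monte-Carlo resolution; at z = −10
this gives 7.6×10⁻²⁴, the "ten standard deviations ⇒ p < 10⁻²³" logic.
When the null sd is zero, z is flagged undefined and only the empirical
p is reported.

The null is computed by a vectorised path (numpy base-index arrays, a
64-entry codon→amino-acid lookup, batched bincounts) whose counts are
asserted, in the unit tests, to equal the string-translation path
exactly. Default replicate count is 10⁴ at the desk (configurable; the
full-scale analysis used 10⁶ — the statistic is identical, only the
Monte-Carlo resolution of p changes).

`codon_usage` reports raw counts of every codon over all complete
codons in all three frames (stop codons included but tallied), the
profile behind per-codon frequency figures.

## Enrichment counting (`enrichment`)

Read mapping is out of scope; the module consumes placements (read id,
chrom, 0-based interval, strand) from the simulator's ground truth or
any external aligner. A read is assigned to a repeat family when its
midpoint lies inside an annotated interval (midpoint rather than
overlap avoids double counting at boundaries); the read strand against
the repeat's annotated strand decides sense/antisense. If intervals of
different families overlap a midpoint, the interval with the smallest
start (then lexicographic family name) wins, so
sense + antisense + unannotated always equals the read total.

Fold enrichment of a family is the dominant strand's share of all
placed reads over that strand's share of the genome's strand space:

    fold = (dominant_count / total_reads) / (family_bp / (2·genome_bp))

Reads are sampled from both genome strands, and a family's dominant
strand covers `family_bp` of the `2·genome_bp` strand-bases, so
uniformly placed reads with uniform strands give fold = 1 in
expectation for every family — the normalisation identity the test
suite checks. The plain base-pair-fraction denominator
(`family_bp/genome_bp`, under which uniform placement converges to 0.5
because the dominant strand holds only half the family's reads) is
available via `strand_aware_abundance=False`. Per-base abundance is
used rather than locus counts, which are unreliable when source and
reference genomes differ. Each placement counts once;
fractional weighting of multi-mapping reads is not implemented.

`contig_stacks` tiles each chromosome with fixed 400-nt windows from
position 0 and stacks reads by midpoint, the aggregation behind
read-stack displays. `ca_richness` tests whether a sequence set is
richer in C+A bases than background: the observed statistic is the
pooled C+A fraction; under the stated null (same-length i.i.d.
background sequences) that statistic is exactly
Binomial(total_length, p_C+p_A)/total_length, so the null is drawn from
that binomial directly — the exact null distribution, not an
approximation. The overlapping CA-dinucleotide frequency is reported
descriptively (note a pure (CA)ₙ tract has CA frequency ≈ 0.5: one CA
per two positions).

## Simulator (`synthetic_data`)

The generator emulates the statistical structure of the experiment
with full ground truth:

- **Genome**: i.i.d. background bases at the configured frequencies
  (human-genome values by default), with repeat units planted at
  non-overlapping uniformly drawn positions. Builders: `random`
  (background-composition unit), `simple_repeat` (tiled motif, e.g.
  (CA)ₙ), and `ctd_reverse_translation` — tandem reverse-translated
  YSPTSPS heptads with each codon drawn uniformly among that amino
  acid's synonymous codons (a human codon-usage table could be
  substituted; uniform is the default). Seven noiseless heptads give a
  147-nt unit, the satellite consensus length, whose frame-0
  translation is exact heptads. Antisense copies are inserted as
  reverse complements.
- **Reads**: the SELEX selection is collapsed into a single
  affinity-weighted sampling round: a read's **midpoint** is drawn with
  probability proportional to the local weight (the family's affinity
  weight inside a planted interval, 1 elsewhere), length uniform over
  the 30–400 nt library range, strand uniform, with optional per-base
  substitution noise (default 0; substitution-only, no indels, so
  frame analyses stay interpretable). Midpoint-weighting is chosen over
  start-weighting deliberately: a fragment is selected when it contains
  the binding site, and downstream family assignment is also by
  midpoint, which makes the analytic fold expectation exact rather than
  blurred by read-length edge effects. With per-base weight w on a
  family covering genome fraction f, the expected fraction of read
  midpoints in the family is wf/(wf + 1 − f); halving per strand and
  dividing by f/2 gives the per-strand fold (`expected_fold`) the
  counting pipeline recovers. Note the saturation: w = 50 at f = 0.01
  yields an expected per-strand fold of ≈ 33.6, not 50. Multi-round
  compounding (effective weight w^rounds) is exposed but off by
  default; the recovered-fraction dynamics of the real cycles are not
  modelled quantitatively.
- **Composition fixtures**: `make_rap_set` builds mosaic sequences in
  which each codon position is CTD-derived with probability
  `ctd_fraction` (tracking heptad phase) and background otherwise —
  the planted-signal fixtures for the bias test.

Every generator is a pure function of (config, seed): identical inputs
give byte-identical FASTA/BED/TSV output.

What the simulator does **not** emulate: real repeat-family sequence
divergence and subfamily structure, mappability and multi-mapping
ambiguity, PCR amplification bias, indels, round-by-round binding
kinetics, and chromosomal clustering of repeats. Passing tests
therefore demonstrate that the statistics recover planted truth under
the stated sampling model, not that they are robust to every artefact
of real SELEX sequencing data.

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_pipeline` chains simulate → enrich → ctd-align → codon-bias; each
stage reads the previous stage's declared files, so a failure leaves
earlier outputs intact and stage subsets re-run cleanly. Every run
writes `manifest.json` (command, config snapshot, seed, package
version, sha256 of each output, timestamp). Floats in TSVs are
rendered at 6 significant digits, making repeated runs with the same
(config, seed) byte-identical. Stage sub-seeds are derived by fixed
offsets from the run seed and recorded. The `rapscan` command exposes
`simulate`, `enrich`, `ctd-align`, `codon-bias` and `replay` as thin
wrappers over the library.

## Problem sizes and numerical choices

Desk-scale defaults keep every check fast while preserving the study's
structure: null calibration uses 200 runs of 30×150 nt background sets
at 500 null replicates; planted-signal recovery uses 100×150 nt mosaics
at 70% CTD codons and 10³ replicates; enrichment recovery uses a 100 kb
genome, a family at 1% abundance with weight 50, and 10⁵ reads. The
alignment oracle check enumerates all global alignments for peptides of
length ≤ 6. Ties: traceback preference is fixed (above); strand ties in
dominant-strand calls break toward sense; equal-scoring CTD windows take
the smallest start. Degenerate inputs fail loudly: empty compositions,
alignment inputs containing `*`/`X`, windows longer than the sequence,
null sets under 100 replicates, families absent from the annotation.

## Known limitations

- The real satellite consensus unit and the deposited read pool are
  external data; analyses that depend on them (the published 23/49
  identity figure, absolute fold-enrichment tables) plug into the same
  entry points but are not reproduced here.
- The lalign E-value of the published alignment is not computed
  (unpublished statistical parameters); no local alignment mode.
- Nucleobase-affinity profile matching is out of scope; only the
  nucleobase *density* profile primitive is provided.
- The empirical p-value resolution is 1/(n_sets+1); claims beyond that
  rest on the Gaussian extrapolation and its normality assumption,
  which holds well for the pooled-composition JSD at these set sizes
  (the null calibration check exercises it).
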