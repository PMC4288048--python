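# Methods

## The census procedure

`luxcart` treats a genome as a set of contigs carrying protein-coding genes
with 1-based inclusive coordinates and a strand, each gene optionally backed
by a protein sequence and a set of domain-signature hits. The census runs in
three stages: per-protein authentication, per-contig arrangement calling,
and per-genome/per-genus aggregation.

### Authentication

Authentication is a deliberately conservative two-tier rule. Tier one is a
profile-HMM prefilter: the protein must carry the Pfam autoinducer-synthase
domain (PF00765, LuxI side) or autoinducer-binding domain (PF03472, LuxR
side) with a per-domain independent e-value strictly below 1e-5. We use the
domain i-Evalue rather than the full-sequence e-value because the criterion
is per-domain. Tier two is an InterPro completeness test: all four LuxR
signatures (IPR005143 autoinducer binding; IPR016032 response-regulator
C-terminal effector; IPR011991 winged HTH; IPR000792 LuxR-type C-terminal)
or both LuxI signatures (IPR001690; IPR018311). The rule is set-membership:
a signature hit repeated on several regions counts once.

Two-dialect behavior: with InterProScan-only input there are no e-values for
tier one to act on, so such proteins go straight to the completeness test.
A protein with e-valued prefilter evidence that all sits above the threshold
cannot be authenticated even if InterPro-complete; it is reported `NONE`.
A protein carrying a non-empty proper subset of the LuxR set is
`LUXR_LIKE_INCOMPLETE`; when the missing part includes the N-terminal
IPR005143 while the C-terminal IPR000792 is present, the protein is flagged
as a suspected N-terminally truncated LuxR. A protein complete for both
families would be reported twice with a `dual_authentic` flag; none occurs
in real data and arrangement calling resolves such a gene as a LuxR.

### Arrangement calling

"Close proximity" is quantified as at most 3 intervening genes AND at most
5,000 bp between partners, on the same contig (both limits configurable).
The 5 kb / 3-gene default keeps a regulator four genes away from a pair
classified as a solo, which matches how such cases are conventionally read.

Doubles (two same-strand luxR genes within policy of each other, plus a
distinct luxI within policy of either) take precedence over canonical pairs:
otherwise the middle luxR of a luxR-luxR-luxI trio would be stolen as a pair
partner. Within that precedence the per-contig assignment maximizes the
number of doubles, then the number of canonical pairs, then minimizes the
summed intergenic distance, breaking residual ties toward smaller start
coordinates. The maximization is exact: candidate tandem-pair subsets and
their luxI assignments are enumerated (contigs essentially never carry more
than a handful of lux genes), and leftover luxR/luxI genes are paired by
minimum-cost maximum-cardinality assignment. A plain nearest-first greedy is
not used because it is a maximal, not maximum, matching and can strand a
formable pair; a greedy sweep remains only as a fallback for pathologically
lux-dense contigs (more than 16 candidate tandem pairs). A conservation law
— #luxR = 2·doubles + pairs + luxR solos, #luxI = doubles + pairs + luxI
solos — is asserted on every invocation.

The luxR-pair "tandem" requirement is same-strand adjacency; the strand
relation of the luxI to the pair (convergent/divergent/tandem) is reported,
not enforced, because the published topology drawings admit several
variants. For each call we also report immediately adjacent
`LUXR_LIKE_INCOMPLETE` genes (the truncated-LuxR-next-to-a-luxI-solo
geometry) and, for luxI solos, the intergenic distance on the gene's 5'
side (long upstream non-coding stretches argue against descent from a
broken pair).

Topology typing reads the product labels of up to 8 genes downstream of the
double's luxI (away from the luxR pair) and matches them, longest pattern
first, against a YAML catalog; `X` matches exactly one hypothetical-protein
gene and named tokens resolve through a configurable synonym map
(annotation strings for the same product vary across annotators). Only the
fully described topology T (*phyH*–X–*virB1*–*virB2*–*virB3*) ships
pre-populated; the T1–T6 variants exist in the literature only as drawings,
so the catalog leaves them to the user rather than guessing.

### Aggregation

Per-genome rows count calls by category; `has_any_luxR/luxI` derive from the
counts. Genus roll-ups need the total number of sequenced genomes per genus
as an input (rows exist only for lux-positive genomes). The packaged census
fixture transcribes a published 62-genome survey verbatim, including its
internal inconsistencies, which are listed in `census_notes.md` and
deliberately not reconciled; genus comes from the fixture's own column,
never from parsing organism names.

## Alignment and identity

Residue numbering and identity both use global Needleman–Wunsch alignment
with BLOSUM62 and affine gaps; a gap of length k scores −10 − (k−1)·1, end
gaps included (the first gap residue costs the open score; this convention
is mirrored by the brute-force Gotoh oracle in the test suite). Among
co-optimal alignments the engine's first enumeration is taken, which is
deterministic for fixed inputs; for percent identity the two sequences are
put in canonical (lexicographic) order first so the measure is symmetric by
construction. Default identity divides identical aligned pairs by the
number of columns where both sequences have a residue; the gap-inclusive
mode divides by full alignment length and therefore never exceeds it. Both
are exposed because published identity-matrix tools differ and the settings
behind the original figures are not recorded.

Site maps are YAML fixtures. The packaged TraR map carries the seven
LuxR-family invariant sites (W57, Y61, D70, W85; E178, L182, G188) on a
synthetic backbone constructed to hold those residues at those positions —
the natural TraR sequence is not distributed with the package, and the
machinery is generic over any user-supplied map with a real sequence. The
TraI map ships with an empty site list: the 10 AHL-synthase active-site
residues are defined in the literature only by figure highlighting, so the
fixture is a fill-in template rather than a guess.

## The synthetic-genome generator

The generator emulates annotated draft genomes at the level the pipeline
consumes: multi-contig gene coordinate sets, protein sequences, and
domain-hit tables in the exact dialects the readers parse, plus truth
labels. Defaults and conditions:

- background gene lengths uniform in 750–900 bp; intergenic gaps uniform in
  50–400 bp (documented, configurable constants);
- planted arrangements use fixed geometries: canonical pair = convergent
  luxI(+)/luxR(−); double = tandem luxR(+) luxR(+) with convergent luxI(−),
  optionally followed by the product labels of a named topology;
- each arrangement is preceded by a 5.5–9 kb spacer so lux genes of
  different planted arrangements always exceed the default proximity
  policy's bp limit and cannot merge into one call;
- planted LuxR genes get PF03472 with e-value drawn log-uniform in
  [1e-50, 1e-6] plus the four LuxR InterPro signatures; LuxI genes get
  PF00765 plus the two LuxI signatures; truncated-LuxR genes get the
  C-terminal signature subset only (missing IPR005143);
- decoys (a configurable fraction of background genes) get either a one- or
  two-signature subset or a prefilter-domain hit with e-value log-uniform in
  [1e-4, 1] — straddling, never touching, the 1e-5 cut;
- planted proteins derive from packaged synthetic seed sequences; at
  mutation rate 0 they equal the seeds exactly. The second luxR partner of a
  double uses a pre-diverged paralog seed (~59% ungapped identity to the
  first), emulating the strong within-locus divergence of real double-LuxR
  partners. Per-residue substitution is the only mutation process: no
  indels, no nucleotide-level evolution, no annotation noise beyond the
  planted decoys.

Identical (config, seed) inputs yield byte-identical bundles; all
randomness flows through one `numpy` generator.

Because the generator writes the same conventions the pipeline reads,
passing tests show the rule engine, geometry logic and aggregation are
self-consistent and exactly recover planted truth; they do not show that
real annotation pipelines produce signature sets this clean, and census
counts on real genomes can shift with the upstream gene caller and
annotator.

## Numerical and design choices

- Coordinates stay 1-based inclusive end-to-end; no half-open conversion.
- The e-value threshold is a strict inequality (< 1e-5), as printed in the
  protocol this rule set encodes.
- The acceptance script runs 50 randomized recovery bundles (1–5 planted
  arrangements, 1–3 contigs, 5–30 background genes, decoy rate 0.3,
  mutation 0) and a 3-locus identity contrast with partners diverged at
  per-residue rate 0.5 — sizes chosen to exercise every category and both
  decoy modes while keeping the run interactive.
- Report writing uses stable sort keys and fixed float formatting, so reruns
  are byte-identical.

## Known limitations

- Cross-contig pairing is not attempted; a pair split by a contig break is
  counted as two solos.
- The dual-authentic case (a protein complete for both families) has no
  published precedent; it is reported with a flag and resolved as LuxR for
  arrangement purposes rather than guessed further.
- Identity values for real double-LuxR sets depend on alignment settings;
  the published cross-locus figure (~94%) derives from the original survey's
  own alignments, which are not desk-reproducible here — the packaged
  stand-in is the generator round-trip contrast.
- Product-label matching is only as good as the synonym map; unmapped
  annotation strings leave a neighborhood `UNTYPED`.
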