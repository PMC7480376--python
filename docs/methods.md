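# Methods

This note documents the models, rules and numerical choices behind
`cazloci`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying conventions are
genuinely open.

## Domain-hit filtering

Input is the HMMER3 `--domtblout` layout in the `hmmscan` orientation
(target = profile model, query = protein); 22 fixed columns plus a
description. Of these the parser consumes the model name and length,
the protein name and length, the per-domain independent E-value
(i-Evalue), the domain bit score, and the model-side (`hmm from/to`) and
protein-side (`ali from/to`) coordinates, all 1-based inclusive.

A hit is retained iff

* `i_evalue <= 1e-6`, and
* model coverage `(hmm_to - hmm_from + 1) / model_length >= 0.30`.

Three conventions deserve note:

* **Which E-value.** The per-domain i-Evalue is used, not the
  full-sequence E-value: the filter is applied hit-wise and a single
  strong domain must not rescue a weak second hit on the same protein.
* **Boundary.** A hit at exactly E = 1e−6 is kept; the cutoff removes
  `E > 1e-6`, the conventional reading of a ≤-threshold.
* **Coverage side.** Coverage is measured on the model
  (`hmm_from..hmm_to` over the model length), not on the protein — the
  criterion asks how much of the profile HMM the hit spans.

Both thresholds are parameters of `filter_hits` and the CLI.

## Overlap resolution

Profile collections contain related models, so one protein region often
hits several families. Among any two hits whose protein-side intervals
overlap by more than half the shorter interval, only one may survive.
Resolution is greedy: hits are admitted in order of increasing i-Evalue
(ties: higher bit score, then lexicographic model name, then leftmost
start); a hit conflicting with an already admitted one is dropped. The
tie-break chain makes the outcome total-order deterministic. The
overlap fraction (default 0.5) is configurable; disjoint hits are never
in conflict.

## Architectures and classification

Surviving hits, sorted by alignment start, define the protein's
architecture string (dash-joined model names, N→C). Classification
rules:

* **CAZyme**: ≥ 1 module of class GH, GT, CE, PL, AA or CBM. CBM-only
  proteins count as CAZymes (CAZy treats binding modules as associated
  modules) but never as multimodular enzymes.
* **Multimodular enzyme**: ≥ 1 catalytic GH/CE/PL module **and** ≥ 1
  accessory module (CBM, SLH, dockerin, cohesin). GT-bearing proteins
  are censused but excluded from multimodular reporting: GTs are
  synthesis-side housekeeping enzymes, and the multimodularity question
  concerns degradative enzymes.
* **Scaffoldin candidate**: ≥ 1 cohesin module and no catalytic module.
* **DUF-accessory**: ≥ 1 accessory (CBM/dockerin/SLH) module, ≥ 1 DUF
  module, no catalytic module — candidates for new CAZyme families.

Model classes are inferred from model names: CAZy prefixes
(`GH|GT|CE|PL|AA|CBM|SLH` followed by a digit, underscore or
end-of-name), `cohesin*`/PF00963, `dockerin*`/PF00404, `SusD`/PF07980,
`SusC`/TIGR04056, `DUF*`; anything else is OTHER. Subfamily suffixes
(`GH5_4`, `dockerin_I`) are preserved verbatim in architecture strings,
and the distinct-architecture count is subfamily-sensitive — `GH5_1`
and `GH5_4` index different substrate specificities, so collapsing them
would undercount architecture diversity.

The module census counts domain *occurrences* (a protein with two CBM6
modules contributes 2), is additive over disjoint protein sets, and its
family totals equal the genome-matrix row sums by construction.

## PUL calling

Gene order, not nucleotide distance, is the coordinate system: ranks
are re-derived from coordinates per contig, so calls are invariant to
gene-table row order. A *tandem susC/susD pair* is a rank-adjacent gene
pair on one contig carrying SusC and SusD in either order, strand
ignored (strict susC-then-susD order and same-strand requirements are
optional flags); pairing is greedy left-to-right so each gene joins at
most one pair. Each pair spans
`[min(pair ranks) − w, max(pair ranks) + w]` with `w = 5` gene
predictions by default, clipped at contig ends; windows measured from
the pair's outer boundaries. Overlapping windows (sharing ≥ 1 gene) on
one contig merge transitively into a single multi-anchor call; adjacent
but disjoint windows do not merge. Cargo genes are categorized from
their domain content (GH/GT/CE/PL/AA/CBM classes, peptidases,
transcriptional regulators — AraC, MarR, LacI, GntR, HTCS — and
non-PUL for everything else). Calls with no CAZy-class cargo are kept
and flagged `no_cazyme`, so anchored-locus counts and
CAZyme-associated counts can be reported separately. Dockerin-bearing
proteins inside a window are ordinary members and never alter locus
boundaries.

## Cellulosome capability

Per genome: scaffoldins are cohesin-bearing proteins; dockerin
catalytic enzymes carry a dockerin plus ≥ 1 GH/CE/PL module; the
multimodular subset additionally carries an accessory module beyond the
dockerin itself (CBM, SLH or cohesin). A genome is cellulosome-capable
iff it has ≥ 1 scaffoldin **and** ≥ 1 multimodular dockerin enzyme —
cohesin-only genomes, dockerin-only genomes, and genomes whose only
dockerin enzymes are plain (no extra accessory module) are not capable.
No attempt is made to type scaffoldins or predict cohesin–dockerin
binding specificity.

## Sequence novelty

For each query the best local alignment against every reference is
computed with Smith–Waterman under BLOSUM62, gap open −11, gap extend
−1 (the BLASTp defaults). Percent identity follows the BLAST
convention — identical columns over alignment columns, gap columns
included — and only the maximum over references is kept, with ties
broken toward the smallest reference id. A reference counts as a hit
only if the alignment's raw score reaches a floor (default 80):
unrelated protein pairs routinely produce short local segments of
deceptively high identity, and the score floor plays the role of the
E-value cutoff of a database search (unrelated ~200-residue pairs score
below ~55 under this scheme; homologs at ≥ 50% identity score in the
hundreds). Queries with no reference above the floor are reported as
no-hit and excluded from the novel-fraction denominator. The novel
fraction counts identities *strictly below* the threshold (default
90%), and is monotone non-decreasing in the threshold.

## Metaproteome integration

The spectral-count table is taken as already validated (protein
probability, peptide minimums and FDR control happen upstream in the
search engine); counts are raw integers, with no NSAF-style
normalization. Integration reports, per genome, distinct detected
proteins and summed counts plus detection flags (any cohesin/dockerin
protein ⇒ cellulosomal components produced; any SusC/SusD protein ⇒ PUL
components produced), and per substrate category two totals: a *multi*
total where a bifunctional protein (e.g. `GH5_4-CBM22-CE3-dockerin_I`,
cellulase + esterase) contributes its full count to each matching
category, and a *primary* total where its count goes only to the
category of its N-terminal-most catalytic domain. The category
partition of a bifunctional chain is genuinely ambiguous; reporting
both makes the double-counting explicit while keeping one conserving
partition. Proteins absent from the annotation tables are reported as
unannotated, never dropped, so summed counts are conserved exactly.
Signal-peptide flags are pass-through metadata.

The family-to-substrate map (cellulases GH5, GH9, GH30, GH51, GH74,
GH94, …; hemicellulose-active GH and CE families; amylases GH13/GH77;
pectin-active GH/PL families; oligosaccharide-degrading exo-families
GH2, GH3, GH29, GH31, GH42, GH97, …) is a static total function;
lookups strip subfamily suffixes and unknown families map to "other".
It is a coarse, replaceable convention, not a substrate prediction.

## Synthetic-data generator

The generator emulates the downstream products of a binned-metagenome
study: per-bin GFF3 gene models, protein FASTA, a domtblout hit table, a
spectral-count TSV, and a JSON truth manifest. Defaults: 10 bins of
200 genes on 2 contigs each plus a 1,000-gene unbinned contig pool
(sized so ~70% of CAZyme proteins fall in named bins), 25 planted PULs,
2 cellulosome genomes, 20 multimodular proteins, 3 DUF-accessory
proteins, 10 standalone decoys, ~15% background CAZyme density, and
novelty queries at 50/70/90% identity. Bin sizes are a deliberate
~10× scale-down of real bins (which carry 1,200–3,900 genes) to keep
the test suite fast; gene coordinates sit on a fixed grid (900 bp genes,
100 bp gaps) because locus calling consumes gene order only.

Planted structures are placed by a block allocator that keeps ≥ 2
filler genes between blocks, so nothing planted in one block can fall
inside another block's calling window. Each PUL block carries the
susCD pair at its center, cargo (GH/CE/PL families, a regulator, a
peptidase) inside the window, *boundary cargo at exactly the window
distance* and *decoy CAZymes at exactly window + 1* — so shrinking the
window by one drops known cargo and enlarging it by one absorbs known
decoys. Additional decoys are fixed in code: lone SusC genes without an
adjacent SusD, far CAZymes, a cohesin-only genome whose single dockerin
enzyme is plain, and a dockerin-only genome with multimodular dockerin
enzymes but no cohesin. Hit-level decoys (hits failing the E-value or
coverage cutoff; fully-overlapping weaker hits on true architectures)
exercise the filter and the overlap resolver; the manifest's
architecture map covers every protein with hits, so architecture
recovery is checked exactly.

Spectral counts are drawn for the planted "secreted" set (cellulosome
proteins, susCD pairs, ~30% of PUL cargo) from a negative binomial
(mean 10, dispersion 2, shifted by +1 so detected proteins have ≥ 1
spectrum) — spectral counts are overdispersed count data — plus one
unannotated contaminant row, as real tables contain.

Identity-controlled queries overwrite the sequences of selected CAZyme
proteins: a random reference of the same length is emitted to the
reference FASTA and the query is the reference with exactly
`round((1 − target) · L)` substituted positions. Substitutions are
spread evenly along the chain (one per stratum) and the terminal
residues are protected: clustered substitutions would let a gap-shifted
local alignment outscore the ungapped one and drag BLAST-style identity
away from the planted value, and mismatch-rich termini would invite
end-trimming. Substitution-only mutation keeps the target exactly
controllable; the alignment stage itself handles indels, which real
data will contain.

All randomness flows from a single seed; identical configurations give
byte-identical files. Planting requests that exceed the configured
genome capacity raise a sizing error naming the constraint; the PUL
block layout requires a window of at least 4.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequence-level realism (proteins are
i.i.d. random residues, so profile scanning itself is not exercised;
hit tables are consumed as given), gene-calling and binning errors,
fragmented or mis-assembled contigs splitting loci, compositional bias,
homology between background proteins, indels between queries and
references, and any taxonomic structure. Recovery being exact on these
fixtures validates the calling logic, not the upstream annotation
quality.

## Known limitations

* Profile-HMM scoring is out of scope; the pipeline starts from hit
  tables (a `pyhmmer`-based scanner could be slotted in front).
* The window anchor convention (pair boundaries vs. per-gene) and
  whether overlapping windows merge are study-dependent; both defaults
  are exposed as parameters.
* The novelty score floor is calibrated for the ~120–400-residue
  proteins the generator emits; very short real proteins may need a
  lower floor.
* The substrate map is intentionally small; families outside it fall
  into "other" rather than being guessed.
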