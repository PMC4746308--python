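# Methods

This note records the models and procedures `quinrec` implements, the
defaults that matter, what the synthetic benchmark does and does not show,
and the design choices made where the design was genuinely open.

## Orthology

Pairwise comparison is exact local Smith–Waterman under BLOSUM62 with
affine gaps (open 11, extend 1; a gap of length L costs `open +
(L−1)·extend`), via Biopython's `PairwiseAligner`. Identity is counted over
all aligned columns including gap columns — stricter than match-column-only
identity and configurable.

A hit is accepted when it passes three thresholds
(`OrthologyParams`):

| parameter      | default | meaning |
|----------------|---------|---------|
| `min_identity` | 0.20    | identity over aligned columns |
| `min_bits`     | 25.0    | Karlin–Altschul bit score `(λS − ln K)/ln 2` with gapped-BLOSUM62 λ = 0.267, K = 0.041 — a surrogate for a BLAST E-value cutoff, set so that full-length matches of ~100 aa at 20–25% identity pass |
| `min_coverage` | 0.50    | aligned columns relative to the **longer** sequence (mutual coverage) |

The coverage floor exists because the dominant false-positive mode is a
short high-scoring window between unrelated proteins; requiring the
alignment to span half of the longer sequence rejects those windows — and
also keeps a single-domain protein from pairing with one domain of a
multi-domain fusion, which is the family semantics the displacement logic
needs.

Orthologs are reciprocal best hits (ties broken to the lexicographically
smallest gene id, making runs bit-reproducible). Each pair carries a
genomic-context similarity: the Jaccard index between the actual neighbors
of the target gene (±5 gene ranks) and the best-hit images of the query
gene's neighbors. Because "similar context" has no standard quantitative
reading, the context threshold defaults to 0 (advisory): failing pairs are
flagged, never dropped.

Families are connected components of the cross-genome BBH graph
(single-linkage); singletons form singleton families. Single linkage is
fragile — one spurious edge merges two families — so edges below
`strong_bits` (50) must be *triangle-supported*: some third gene strongly
paired with both endpoints. Orthology is transitive within a family across
genomes, so genuine weak edges have such witnesses; one-off (or even
recurrent) spurious similarities do not, because their would-be witnesses
hang on weak edges themselves. Known limitation: a genuinely weak ortholog
pair present in only two genomes loses its edge and splits.

A shared-k-mer prescreen (k = 4, ≥ 1 shared k-mer) skips Smith–Waterman for
sequence pairs that cannot be meaningfully similar; at the divergences the
generator produces (≤ 0.6 substitutions/site pairwise) true pairs share
dozens of k-mers, so the prescreen only removes noise comparisons. It can
be disabled (`prefilter_kmer=0`), which the oracle-equivalence tests do.

## Pathway reconstruction

Pathway definitions are data: an ordered list of roles, each with a set of
alternative gene-family forms (e.g. the Ubi carboxy-lyase role is satisfied
by `ubiD`, `ubiX` or `ubiZ`). A pathway is *complete* in a genome when
every role has at least one present form ("uninterrupted route from
chorismate"), *absent* when none has, *incomplete* otherwise — so a single
present gene is an incomplete pathway, not an absent one. A prefix variant
(`classify_prefix`) reports how far the pathway runs from the chorismate
end, which is the natural summary for the recurring real-data configuration
"early steps missing, late steps present".

Quinone inference: UQ requires a complete Ubi pathway; DMK requires the Men
or Mqn route up to DMK — the methylation role (MenG) is the MK/DMK branch
point, not a DMK step, so a Men pathway missing only MenG still confers
DMK; MK additionally requires the shared UbiE/MenG methyltransferase, which
is modeled as one family referenced by the Ubi, Men and extended-Mqn
rosters. Because UbiE is itself a Ubi role, "Ubi complete but menG absent"
is contradictory input and raises. These rules admit exactly five patterns:
{}, {UQ}, {DMK}, {MK, DMK}, {UQ, MK, DMK}.

Two modes ship: `legacy` stops the Mqn definition at
1,4-dihydroxy-6-naphthoate (the long-known boundary); `extended` adds the
predicted late steps (MqnP, MqnL, MqnM, MenG) as a fourth definition.

## Displacement prediction

A *gap* is a (pathway, role) pair with ≥ 1 genome missing that role while
missing at most `max_missing` (default 1) roles overall. For each gap,
every family not already assigned to the gapped role is scored on:

* **profile** — one-sided hypergeometric tail p for enrichment in gap
  genomes, with an `exact_match` flag for the perfect profile (present in
  all gap genomes, absent elsewhere; its p, e.g. 1/C(25,5) for 5 gap
  genomes in 25, is the minimum achievable for the margin). Keeping a
  p-value alongside the binary flag lets draft-genome noise degrade
  gracefully instead of breaking exact profiles.
* **co-localization** — candidate genes within `max_intervening` (default
  3) intervening genes of a pathway gene on the same contig, strand-
  agnostic. Rank distance, not base pairs, so draft-assembly coordinate
  noise is irrelevant. Operon-scale adjacency is the standard reading of
  "co-localized"; nothing in the analysis is sensitive to the exact window
  within 2–5.
* **fusion** — a protein carrying both a candidate-diagnostic and a
  pathway-role-diagnostic domain (either N→C order; the architecture
  string records which).

The combined score is `w·(−log10 p) + w·f_coloc + w·[fusion]` with default
weights (1, 1, 1) — a deliberately transparent analogue of manual evidence
triangulation, not a trained model. Ranking is dense, descending,
lexicographic on ties. A strict co-occurrence check
(`co_occurrence_check`) supports the complementary claim form "these
families occur in exactly the pathway-positive genomes", reporting
violation counts.

## Phylogenetics

The separation questions the package answers are topological (is each
homolog group a clade?), so distance methods suffice: neighbor-joining
(scikit-bio) on Poisson-corrected distances (`−ln(1−p)`, pairwise gap
deletion; p capped just below 1 for saturated pairs), midpoint rooting
(two-leaf trees handled explicitly), and monophyly by clade/tip-set
equality. Maximum-likelihood inference would change branch lengths, not
these verdicts.

The progressive aligner (guide tree from 3-mer distances + NJ;
profile–profile Needleman–Wunsch merges; gap open 15, extend 0.5 — the
classic ClustalX-era settings) is minimal by design: the generator evolves
sequences without indels by default, so alignments are near-trivial and
the tests exercise the inference logic, not alignment heuristics. An indel
rate option exists for stress tests.

`separation_report` gives per-group monophyly and flags group *pairs*
whose union is a clade although the groups individually are not — the
signature of two labels drawn from one homogeneous family (the
methyltransferase outcome), as opposed to genuinely distinct specificity
groups (the polyprenyltransferase/carboxy-lyase outcome).

## SDP analysis

Columns where any group exceeds 50% gaps are excluded; within retained
columns, gaps and `X` are dropped. The per-column statistic is the mutual
information (bits) between group label and residue. Significance: row
labels are permuted (default 1000 shuffles; benchmarks use 300), the
observed MI is z-scored against the permutation null, and the normal tail
of z is compared at the Bonferroni level α/#retained — the raw permutation
p cannot resolve such levels at practical shuffle counts. Columns with
zero null variance (constant, or maximally variable so that any labeling
yields the same MI) cannot be significant, which is the correct verdict
for both.

De-novo grouping (`optimize_groups`) restarts from random partitions
(default 10 restarts, ≥ 2 groups, minimum group size 2 for benchmark-scale
alignments — 10 is the conventional floor for real families) and greedily
applies single-sequence moves and pairwise swaps while the objective
improves. The objective is the *bias-corrected* total MI over retained
columns: plug-in MI carries a positive finite-sample bias of roughly
(R−1)(G−1)/(2N ln 2) bits per column (Miller–Madow), which would otherwise
reward tiny lopsided groups summed over many columns. The reported
statistic stays the raw MI; the permutation null absorbs the bias there.

## Co-distribution

The shipped catalog names 17 reductase types (three oxygen reductases, two
nitrate, one nitrite, tetrathionate, two thiosulfate, sulfite, polysulfide,
TMAO, DMSO, selenate, fumarate, arsenate, plus a second Ynf-type entry of
unknown acceptor specificity, `YnfX`). Each type lists required
quinone-interacting membrane-subunit families and compatible quinones; the
subunit labels are editable placeholders because the statistics are
catalog-agnostic — real analyses should substitute curated family labels.
Compatibility defaults: Cyo is UQ-specific; reductases of strictly
anaerobic acceptors pair with MK; the rest are treated as promiscuous.

A genome's category depends only on (any reductase present, any quinone
producible): `both` / `neither` (agreement) or `reductase_only` /
`quinone_only` (disagreement); "quinone producible" means the inferred
pattern is nonempty, which reproduces the printed-table arithmetic of the
reference cohort. Percentages round half-up to one decimal, matching the
convention of printed tables. Compatibility conflicts (a present reductase
none of whose quinones the genome makes) are listed per genome but do not
change the category.

## Synthetic pan-genome generator

`synthgen` emulates the statistical structure the inference assumes, not
sequence biology: a clade-structured genome tree (balanced by default,
root-to-tip 0.3 substitutions/site — within-family identity stays ≥ ~40%,
comfortably above the 20% ortholog threshold, and decreases monotonically
with tree distance); per-family ancestral random proteins (120 aa; fusion
candidates 240 aa) evolved by substitutions only; pathway genes laid out as
operon blocks flanked by decoy genes, one contig per pathway plus a
miscellaneous contig; three universal "core" families (no real genome is
empty); 25 decoy families with clade-structured presence plus 8%
per-genome gain/loss flips; reductase clusters present with a configurable
correlation ρ to true quinone capability (ρ = 1 ⇒ only agreeing
co-distribution categories). Displacement injections delete the canonical
role family in a chosen clade and insert a novel family exactly there —
inside the operon at the removed role's slot when co-localized, on the
miscellaneous contig otherwise, and with a two-domain fusion annotation
when requested (real accession strings PF08282/PF03061 are reused as
labels in the fusion scenario for documentation fidelity). Gain/loss noise
applies to decoys only, so the truth manifest is exact by construction.
Everything derives from one seed; emission is byte-deterministic.

Three canned scenarios reproduce the discovery archetypes at 16 genomes:
occurrence + co-localization (`ubiZ`), domain fusion (`menY`), and operon
context (`mqnZ`).

What passing benchmarks show — and what they do not: the planted
displacement families are recovered at rank 1 across seeds, and SDP group
optimization recovers planted two-group partitions, *under the generator's
assumptions*: substitution-only evolution, exact presence/absence for
pathway genes, operon layouts preserved across genomes, and noise columns
varying over small residue repertoires (2–4 residues with a dominant one,
as real alignment columns do — uniform 20-way noise is adversarial beyond
anything an alignment produces, and under it the highest-scoring partition
is genuinely not always the planted one). Real data add misassembly,
annotation error, paralogy and horizontal transfer that the generator does
not model; the benchmarks validate the inference logic, not performance on
such data.

## Pipeline

Stages hand off through flat files (TSV/JSON/FASTA/Newick) in the run
directory, so each is independently testable and replaceable. Role labels
reach inferred families by annotation transfer from reference seed genes
(the model-organism device: a family containing the annotated exemplar
inherits its label), shipped by the generator in a file separate from the
truth manifest — the pipeline never reads the truth. All randomness flows
from the top-level seed; a rerun with the same config reproduces every
output byte for byte. Problem sizes in the shipped benchmarks (16-genome
cohorts, ≤ 200 families, 10 scenarios / 10 SDP bundles, 300-shuffle nulls)
were chosen so the whole benchmark suite runs in minutes on one CPU while
every planted effect is comfortably detectable.
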