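# Methods

## Synthetic data model

The generator (`hemasm.simulate`) emulates the statistical structure that
makes hemocyanin transcript assembly hard: two paralogous genes that are
highly similar in their conserved cores, internal repetition from the tandem
FU architecture, and a repeat-rich hydrophilic insertion.

**Architecture.** A subunit is `n_fu` functional units of `fu_length_aa`
residues plus a C-terminal tail attributed to the last FU. The full-scale
default is the canonical gastropod subunit, 8 × 420 aa + 100 aa
(3,460 aa, ≈10.4 kb of CDS). FU domains within one gene are derived from a
single ancestral domain mutated to a target intra-gene identity (default
0.55 at the protein level), reproducing the "paralogous domains with
conserved sections" character of real subunits.

**Transcripts, not bare CDS.** Templates are mRNA-like: a 200-nt 5′UTR, the
CDS (ATG … stop), and a 200-nt 3′UTR. This matters: transcriptome fragments
sample the UTRs, which is what lets an assembly recover the CDS out to its
first and last base; without flanks, coverage tapers to zero at the CDS
termini and no mapper can finish them at ordinary depth. The 5′UTR carries an
in-frame stop at the UTR/CDS junction (as real 5′UTRs terminate upstream
reading frames), so the longest ATG-initiated ORF equals the CDS.

**Divergence.** The H1/H2 duplication is simulated by placing the two
branches' substitutions at *disjoint* transcript sites, each substitution to
a different base, so realized pairwise divergence equals the requested value
exactly (default 0.30) — no homoplasy correction needed. Coding substitutions
are synonymous-biased 2:1 and never create stops; UTR sites substitute
freely. A second species (default divergence 0.15) is derived from each sp1
gene the same way. Substitutions inside the insertion on the species branch
are restricted to synonymous changes: in the real animals both species retain
the insertion's His/Asp character, i.e. it is under compositional purifying
selection.

**The FU-g insertion.** The H2 paralog receives an insertion (default 340 aa,
as in NlH2; RtH2-like runs use 118 aa) near the N-terminus of FU-g, built as
tandem repeats of a 6-residue motif whose positions are His/Asp with the
target fraction (default 0.7, enforced as a lower bound on the realized
count). The truth record stores exact coordinates and realized composition.

**Reads.** Paired-end, forward–reverse, fragment length normal(450, 50) nt
clipped to [read length, template length], constant Q30 qualities,
substitution-only errors at a per-base rate (default 0.01). The
substitution-only model matches the mapper semantics (overlap identity and
mismatch caps are substitution-centric); indel errors, quality-dependent
error profiles and expression-level variation are deliberately out of scope,
so passing tests say nothing about indel robustness on real data.

**Chimeras.** `make_chimera` fuses H1[0:b] with H2[b:] (coordinates mapped
through the insertion), the classic hybrid-misassembly failure mode, with the
true breakpoint recorded for scoring the verifier.

## Assembly

Seeding maps all reads to a heterologous reference at ≥70% nucleotide
identity over ≥60 nt (both strands, 8-mer indexed). Recruited reads
*themselves* become the initial contigs (a tiling subset, up to six per
100-nt reference window): starting from reads rather than a
reference-projected consensus is what keeps paralogs separate from the first
iteration.

Each iteration then (i) maps every read to every contig (13-mer seeding,
ungapped evaluation) under the strict acceptance rule — overlap ≥ 60 nt,
overlap identity ≥ 99%, and mismatches ≤ floor(1% × overlap), the two caps
applied independently so the stricter floor wins at short overlaps; (ii)
assigns each read to the contig(s) with the fewest mismatches, breaking ties
by overlap length (a read bridging two co-linear fragments of one gene
overlaps them unequally; a genuinely paralog-ambiguous read ties on both
counts and is excluded from end extension while still counting toward
coverage of all tied contigs); (iii) rebuilds each consensus by per-column
majority and extends ends through overhang columns; (iv) merges contigs
whose ends overlap under the acceptance rule; and (v) culls redundant
contigs. Iteration stops at a fixed point (nothing grew, merged, was culled,
or was newly recruited). Read order is fixed by id sort; the result is
deterministic.

Numerical/robustness choices, each adopted after the corresponding
deterministic deadlock was observed on the default conditions (50×, 1%
error):

- *Confidence masking.* Merge comparisons and a small part of the read
  acceptance budget treat thinly covered columns (< 3×) as unreliable:
  merges count mismatches only on confidently covered columns (taking the
  better-covered base in the overlap), and read acceptance forgives
  mismatches at unconfident columns up to 3% of the overlap. Residual
  consensus errors live precisely at such columns, and without forgiveness
  they reject every read able to correct them. 3% + 1% stays far below any
  paralog divergence of interest, so separation is unaffected.
- *Extension dissent cap.* An overhang column extends when it has ≥ 3 reads
  and the runner-up base has at most 1 + floor(20% × depth) reads. Overhang
  reads are already paralog-filtered by their accepted anchors, so dissent
  above that cap (≈50/50 at a would-be chimeric junction) stops extension,
  while one or two coincident sequencing errors (expected about once per
  assembly at modest depth) do not.
- *Pair-supported junction closure.* When the fixed point is reached with
  two contigs whose junction reads are split between them and rejected by
  the short-overlap budgets, the contigs are merged if they share a
  *unique* clean overlap of ≥ 25 confidently covered nt (zero mismatches)
  and at least three read pairs bridge the junction with implied fragment
  lengths consistent with the same-contig fragment distribution. Junctions
  with several clean candidate offsets (tandem repeats) are never closed
  this way — they are exactly what the pair-spanning verification reports.
- Consensus ties take the lexicographically smallest base; coordinates are
  0-based half-open internally and 1-based inclusive in reports.

## Verification

(i) *Low-stringency remapping*: each read is placed where it holds its
longest exact anchor (≥ 25 nt); up to 60% of the read may disagree beyond the
anchor. Reads whose off-anchor disagreement exceeds 10% of the read length
vote for a breakpoint at the anchor edge facing the disagreement; votes
within 50 nt cluster, and clusters with ≥ 3 reads are flagged (position =
median anchor edge, 1-based). On clean assemblies reads disagree only at the
~1% error level, far under the 10% trigger. (ii) *Identity-window scan*:
gapless identity in 100-nt windows (step 50) after anchoring two consensi
(direct columns at equal length, global alignment otherwise); windows
≥ 95% identity are hybrid-risk regions. (iii) *Pair spanning*: a flagged
window passes if at least one read pair has one mate wholly in unique
sequence (outside all flagged windows) on each side, same contig, implied
fragment within mean ± 4 sd.

## Protein characterization

Translation uses the standard code; the longest ATG-initiated,
stop-terminated ORF on either strand is taken (minimum 300 nt; N codons
translate to X and set a flag). Masses are average residue masses plus one
water (18.0153 Da); monoisotopic tables are available behind a flag. Average
masses are the right default because literature subunit masses of ~400-kDa
proteins are averages.

Pairwise alignments (FU projection, insertion calling, cysteine census) are
global with affine gaps, BLOSUM62, open 10 / extend 0.5, and free end gaps —
a truncated subunit (e.g. collar loss) must not have its tail force-aligned
across the reference's remaining domains.

Insertion calls are maximal runs of query residues aligned to counterpart
gaps (≥ 20 aa). Two artifacts of affine-gap alignment are corrected: runs
split by short stretches of coincidentally anchored residues inside one
insertion are bridged (allowance 25% of the combined run length), and, when a
single large run remains against a counterpart with a net residue deficit,
the boundary is re-placed by maximizing a log-likelihood score that combines
ungapped flank agreement with the segment's His/Asp enrichment (the
insertion is, by definition, the hydrophilic block interrupting the conserved
FU-g structure), searching ±25 aa around the aligner's boundary. Measured on
the generator, recovered lengths are exact and the His/Asp fraction is
reproduced to ~0.002 mean absolute error.

Hydropathy is Kyte–Doolittle (the scale's His −3.2 and Asp −3.5 make any
genuine His/Asp insert strongly negative), centered windows of 9 with
truncated ends. The cysteine census partitions the query's cysteines by
whether they align to a reference cysteine (canonical intra-FU disulfide
partners) or not (novel).

## Phylogenetics

Distances are Poisson-corrected p-distances, d = −ln(1 − p), computed on a
star alignment (every sequence globally aligned to the longest one; columns
are the center's residues — a documented approximation that drops
center-absent insertions). Pairwise deletion keeps lineage-specific segments,
such as the insertion shared by the H2 orthologs, as signal for the pairs
that carry them. Neighbor joining is canonical Saitou–Nei with lexicographic
tie-breaking and negative branch lengths clamped to zero (deficit moved to
the sibling). Support is the percentage of column-resampled replicates
containing each original bipartition (default 100 replicates, seeded).
Rooting is by explicit outgroup label at the midpoint of its branch.

The synthetic outgroup (a stand-in for a non-gastropod hemocyanin such as
*Nautilus*) is generated at 0.30 nt divergence from the ancestor. This was
calibrated to the biology rather than to the nominal taxonomy: the real
outgroup shares ~45–50% protein identity with gastropod hemocyanins and is
comfortably alignable, and 0.30 in this generator's codon model reproduces
that identity. A nominally "deeper" synthetic outgroup would fall below the
alignment twilight zone, which the real protein does not — random-sequence
divergence has no conserved motifs to anchor on.

Maximum-likelihood inference under WAG+Γ+F is intentionally not
reimplemented: the tree's role here is orthology-topology recovery, which
NJ on corrected distances achieves throughout this divergence regime.

## Problem sizes

Sequence-level experiments (assembly recovery, chimera detection,
phylogenies) run on a reduced architecture — 4 FUs × 160 aa + 60-aa tail
(≈2.1 kb CDS, 60-aa insert) — with full-scale read parameters (coverage 50×,
reads 150 nt, error 1%, paralog divergence 0.30, species divergence 0.15,
seed reference ≈0.25 from each paralog). Insertion-recovery experiments run
on the full 8 × 420 + 100 architecture across insert lengths of 50, 118, 150
and 340 aa. These sizes are the package's default experiment design; every
stage also runs unchanged at full scale.

## Limitations

- The error model is substitution-only; indel sequencing errors, quality
  profiles and coverage biases of real libraries are not represented.
- Divergence is uniform along the gene apart from the constrained insertion;
  real paralogs alternate conserved cores and variable linkers, which makes
  real seed mapping patchier than simulated seed mapping.
- The star alignment is a heuristic multiple alignment; distances inherit its
  registration noise at deep divergence.
- The verifier's breakpoint statistic assumes breakpoints between diverged
  regions; a chimera switching inside a long perfectly conserved tract is
  undetectable in principle (and is flagged instead by the identity-window
  scan as hybrid risk).
- Deposited-accession workflows (fetching the real RtH/NlH records) require
  network access and are exercised only in an optional test tier.
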