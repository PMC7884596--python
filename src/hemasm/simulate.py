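"""Synthetic paralogous hemocyanin genes and paired-end reads with ground truth.

Molluscan hemocyanin subunits are tandem arrays of ~420-aa functional units
(FU-a ... FU-h, the last one carrying a ~100-aa C-terminal tail).  Muricidae
carry two paralogous subunit genes (H1, H2) descended from a duplication that
predates the speciation of the studied species, and the H2 paralog carries a
hydrophilic, His/Asp-rich insertion in the N-terminal region of FU-g.

This module generates such gene pairs (optionally for two species) as mRNA-like
transcripts — the coding sequence flanked by untranslated regions, which is
what transcriptome reads actually sample and what lets an assembly recover the
CDS out to its very ends — plus paired-end substitution-error reads and
chimeric fusions for testing the misassembly-verification stage.  Every output
is reproducible from a single integer seed, and a :class:`TruthSet` records
transcript/CDS/protein sequences, insert coordinates and the read-origin table
so downstream stages can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._seq import revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NON_HD = "".join(a for a in AMINO_ACIDS if a not in "HD")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class FUArchitecture:
    """Tandem functional-unit layout of one hemocyanin subunit."""

    fu_names: tuple[str, ...] = tuple("abcdefgh")
    fu_length_aa: int = 420
    terminal_tail_aa: int = 100
    intra_gene_fu_identity: float = 0.55

    def __post_init__(self) -> None:
        if len(self.fu_names) < 1:
            raise ValueError("architecture needs at least one functional unit")
        if self.fu_length_aa < 1:
            raise ValueError("fu_length_aa must be >= 1")
        if self.terminal_tail_aa < 0:
            raise ValueError("terminal_tail_aa must be >= 0")
        if not 0.0 <= self.intra_gene_fu_identity <= 1.0:
            raise ValueError("intra_gene_fu_identity must be in [0, 1]")

    @property
    def protein_length_aa(self) -> int:
        return self.fu_length_aa * len(self.fu_names) + self.terminal_tail_aa

    def fu_boundaries(self) -> list[tuple[str, int, int]]:
        """0-based half-open FU segments on the insert-free protein.

        The terminal tail is attributed to the last FU.
        """
        bounds = []
        pos = 0
        for i, name in enumerate(self.fu_names):
            length = self.fu_length_aa
            if i == len(self.fu_names) - 1:
                length += self.terminal_tail_aa
            bounds.append((name, pos, pos + length))
            pos += length
        return bounds


@dataclass(frozen=True)
class InsertSpec:
    """His/Asp-rich hydrophilic insertion carried by the H2 paralog."""

    length_aa: int = 340
    host_fu: str = "g"
    offset_in_fu_aa: int = 25
    his_asp_fraction: float = 0.7
    motif_period: int = 6

    def __post_init__(self) -> None:
        if self.length_aa < 0:
            raise ValueError("insert length must be >= 0")
        if not 0.0 <= self.his_asp_fraction <= 1.0:
            raise ValueError("his_asp_fraction must be in [0, 1]")
        if self.motif_period < 1:
            raise ValueError("motif_period must be >= 1")


@dataclass(frozen=True)
class ParalogPairSpec:
    architecture: FUArchitecture = field(default_factory=FUArchitecture)
    paralog_divergence: float = 0.30
    species_divergence: float = 0.15
    h2_insert: InsertSpec = field(default_factory=InsertSpec)
    utr5_nt: int = 200
    utr3_nt: int = 200
    codon_table_id: int = 1
    synonymous_weight: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paralog_divergence", "species_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.utr5_nt < 0 or self.utr3_nt < 0:
            raise ValueError("UTR lengths must be >= 0")
        if self.h2_insert.host_fu not in self.architecture.fu_names:
            raise ValueError("insert host FU not present in architecture")
        if not 0 <= self.h2_insert.offset_in_fu_aa <= self.architecture.fu_length_aa:
            raise ValueError("insert offset outside host FU")

    @property
    def n_species(self) -> int:
        return 2 if self.species_divergence > 0 else 1


@dataclass(frozen=True)
class ReadSimSpec:
    read_length_nt: int = 150
    fragment_mean_nt: float = 450.0
    fragment_sd_nt: float = 50.0
    coverage: float = 50.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length_nt < 1:
            raise ValueError("read_length_nt must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.fragment_mean_nt < self.read_length_nt:
            raise ValueError("fragment_mean_nt must be >= read_length_nt")


# ---------------------------------------------------------------------------
# results


@dataclass
class TruthSet:
    """Ground truth for one simulated paralog pair."""

    transcripts: dict[str, str]  # UTR5 + CDS + UTR3
    cds_ranges: dict[str, tuple[int, int]]  # CDS span on the transcript, incl. stop
    genes: dict[str, str]  # CDS incl. stop codon
    proteins: dict[str, str]
    insert_coords: dict[str, tuple[int, int]]  # protein aa, 0-based half-open
    insert_nt_coords: dict[str, tuple[int, int]]  # CDS nt, 0-based half-open
    his_asp_fraction: dict[str, float]  # realized, per inserted gene
    fu_boundaries: list[tuple[str, int, int]]  # on the insert-free protein
    ancestor_cds: str
    spec: ParalogPairSpec

    def gene_labels(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class ReadRecord:
    id: str
    seq: str
    qual: str


@dataclass
class SimulatedReads:
    r1: list[ReadRecord]
    r2: list[ReadRecord]
    origins: pd.DataFrame  # read_id, pair_id, gene, start, end, strand, mate, n_errors

    @property
    def reads(self) -> list[tuple[str, str]]:
        """All mates as (id, sequence), R1 then R2, order deterministic."""
        return [(r.id, r.seq) for r in self.r1] + [(r.id, r.seq) for r in self.r2]


@dataclass
class ChimeraTruth:
    seq: str
    breakpoint: int  # nt position on the chimera (== on the left parent)
    left_parent: str
    right_parent: str


# ---------------------------------------------------------------------------
# codon helpers


def _codon_maps(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    stops = set(table.stop_codons)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        by_aa.setdefault(aa, []).append(codon)
    return fwd, stops, by_aa


def _back_translate(protein: str, by_aa: dict[str, list[str]], rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = by_aa[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _mutate_sites(
    transcript: str,
    sites: np.ndarray,
    rng: np.random.Generator,
    fwd: dict[str, str],
    stops: set[str],
    syn_weight: float,
    cds_range: tuple[int, int],
    synonymous_only: tuple[int, int] | None = None,
) -> str:
    """Substitute one base at each site; coding sites never create a stop.

    Within the CDS, synonymous changes are favoured ``syn_weight``:1 over
    nonsynonymous ones, keeping protein identity realistic for a given
    nucleotide divergence; UTR sites substitute uniformly.  Sites in the
    ``synonymous_only`` range (the compositionally conserved His/Asp insert)
    accept synonymous substitutions exclusively; a site without a synonymous
    alternative is skipped.
    """
    seq = list(transcript)
    c0, c1 = cds_range
    for site in sites:
        site = int(site)
        if site < c0 or site >= c1:
            current = seq[site]
            alternatives = [b for b in _BASES if b != current]
            seq[site] = alternatives[rng.integers(3)]
            continue
        rel = site - c0
        ci, within = rel // 3, rel % 3
        codon = "".join(seq[c0 + 3 * ci : c0 + 3 * ci + 3])
        constrained = (
            synonymous_only is not None and synonymous_only[0] <= site < synonymous_only[1]
        )
        cur_aa = fwd.get(codon)
        choices, weights = [], []
        for base in _BASES:
            if base == codon[within]:
                continue
            alt = codon[:within] + base + codon[within + 1 :]
            if alt in stops:
                continue
            synonymous = fwd.get(alt) == cur_aa
            if constrained and not synonymous:
                continue
            choices.append(base)
            weights.append(syn_weight if synonymous else 1.0)
        if not choices:
            continue
        w = np.asarray(weights) / sum(weights)
        seq[site] = choices[rng.choice(len(choices), p=w)]
    return "".join(seq)


def _mutable_sites(transcript_len: int, cds_range: tuple[int, int]) -> np.ndarray:
    """All sites except the start codon, the stop codon and the 5'UTR stop.

    The in-frame stop terminating upstream reading frames at the UTR/CDS
    junction is conserved, as is the reading frame itself.
    """
    c0, c1 = cds_range
    protected = set(range(max(0, c0 - 3), c0 + 3)) | set(range(c1 - 3, c1))
    return np.array([i for i in range(transcript_len) if i not in protected])


# ---------------------------------------------------------------------------
# gene-pair generation


def _make_insert_protein(spec: InsertSpec, rng: np.random.Generator) -> str:
    """Tandem-repeat His/Asp-rich peptide with realized fraction >= target."""
    if spec.length_aa == 0:
        return ""
    p = spec.motif_period
    n_hd = int(round(spec.his_asp_fraction * p))
    hd_positions = set(rng.choice(p, size=min(n_hd, p), replace=False).tolist())
    motif = [
        "HD"[rng.integers(2)] if i in hd_positions else _NON_HD[rng.integers(len(_NON_HD))]
        for i in range(p)
    ]
    insert = (motif * math.ceil(spec.length_aa / p))[: spec.length_aa]
    target = math.ceil(spec.his_asp_fraction * spec.length_aa)
    non_hd = [i for i, a in enumerate(insert) if a not in "HD"]
    rng.shuffle(non_hd)
    while sum(a in "HD" for a in insert) < target and non_hd:
        insert[non_hd.pop()] = "HD"[rng.integers(2)]
    return "".join(insert)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


def generate_paralog_pair(spec: ParalogPairSpec) -> TruthSet:
    """Generate H1/H2 transcripts (and orthologs for a second species).

    The two paralog branches place their substitutions at disjoint transcript
    sites, each substitution to a different base, so the realized pairwise
    divergence between H1 and H2 equals ``paralog_divergence`` exactly (up to
    rounding).  The H2 paralog carries the configured FU-g insertion; the
    insertion is added before the species split so both species inherit it,
    and between-species substitutions inside it are restricted to synonymous
    changes (its His/Asp composition is conserved in both species).
    """
    rng = np.random.default_rng(spec.seed)
    fwd, stops, by_aa = _codon_maps(spec.codon_table_id)
    arch = spec.architecture

    # ancestral protein: FU family derived from one base domain
    base_fu = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=arch.fu_length_aa))
    n_mut = int(round((1.0 - arch.intra_gene_fu_identity) * arch.fu_length_aa))
    fus = []
    for _ in arch.fu_names:
        fu = list(base_fu)
        for pos in rng.choice(arch.fu_length_aa, size=n_mut, replace=False):
            alternatives = [a for a in AMINO_ACIDS if a != fu[pos]]
            fu[pos] = alternatives[rng.integers(len(alternatives))]
        fus.append("".join(fu))
    tail = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=arch.terminal_tail_aa))
    protein_anc = "M" + ("".join(fus) + tail)[1:]
    cds_anc = _back_translate(protein_anc, by_aa, rng) + "TAA"
    utr5 = _random_nt(spec.utr5_nt, rng)
    if spec.utr5_nt >= 3:
        # in-frame stop at the UTR/CDS junction, as real 5' UTRs terminate
        # upstream reading frames; keeps the longest ORF equal to the CDS
        utr5 = utr5[:-3] + "TAA"
    utr3 = _random_nt(spec.utr3_nt, rng)
    transcript_anc = utr5 + cds_anc + utr3
    cds_range = (spec.utr5_nt, spec.utr5_nt + len(cds_anc))

    # duplication: disjoint substitution sites on the two paralog branches
    eligible = _mutable_sites(len(transcript_anc), cds_range)
    n_total = min(int(round(spec.paralog_divergence * len(transcript_anc))), len(eligible))
    perm = rng.permutation(eligible)
    h1 = _mutate_sites(
        transcript_anc, perm[: n_total // 2], rng, fwd, stops, spec.synonymous_weight, cds_range
    )
    h2 = _mutate_sites(
        transcript_anc, perm[n_total // 2 : n_total], rng, fwd, stops, spec.synonymous_weight, cds_range
    )

    # FU-g insertion on the H2 branch
    ins = spec.h2_insert
    bounds = arch.fu_boundaries()
    host_start = next(s for name, s, _e in bounds if name == ins.host_fu)
    ins_aa_start = host_start + ins.offset_in_fu_aa
    insert_protein = _make_insert_protein(ins, rng)
    insert_cds = _back_translate(insert_protein, by_aa, rng) if insert_protein else ""
    cds_nt_pos = 3 * ins_aa_start  # on the CDS
    tx_nt_pos = cds_range[0] + cds_nt_pos  # on the transcript
    h2 = h2[:tx_nt_pos] + insert_cds + h2[tx_nt_pos:]
    h2_cds_range = (cds_range[0], cds_range[1] + len(insert_cds))

    transcripts = {"H1_sp1": h1, "H2_sp1": h2}
    cds_ranges = {"H1_sp1": cds_range, "H2_sp1": h2_cds_range}
    if spec.n_species == 2:
        for label in ("H1_sp1", "H2_sp1"):
            seq, crange = transcripts[label], cds_ranges[label]
            sites = _mutable_sites(len(seq), crange)
            n_sp = min(int(round(spec.species_divergence * len(seq))), len(sites))
            chosen = rng.choice(sites, size=n_sp, replace=False)
            constrained = (
                (tx_nt_pos, tx_nt_pos + len(insert_cds)) if label == "H2_sp1" and insert_cds else None
            )
            label2 = label.replace("sp1", "sp2")
            transcripts[label2] = _mutate_sites(
                seq, chosen, rng, fwd, stops, spec.synonymous_weight, crange,
                synonymous_only=constrained,
            )
            cds_ranges[label2] = crange

    genes = {label: transcripts[label][c[0] : c[1]] for label, c in cds_ranges.items()}
    proteins = {label: _translate_cds(cds, fwd, stops) for label, cds in genes.items()}

    insert_coords, insert_nt, hd_frac = {}, {}, {}
    if ins.length_aa > 0:
        for label in genes:
            if not label.startswith("H2"):
                continue
            insert_coords[label] = (ins_aa_start, ins_aa_start + ins.length_aa)
            insert_nt[label] = (cds_nt_pos, cds_nt_pos + 3 * ins.length_aa)
            segment = proteins[label][ins_aa_start : ins_aa_start + ins.length_aa]
            hd_frac[label] = (segment.count("H") + segment.count("D")) / len(segment)

    if spec.paralog_divergence <= spec.species_divergence and spec.n_species == 2:
        import warnings

        warnings.warn(
            "paralog_divergence <= species_divergence: orthology topology is not identifiable",
            stacklevel=2,
        )

    return TruthSet(
        transcripts=transcripts,
        cds_ranges=cds_ranges,
        genes=genes,
        proteins=proteins,
        insert_coords=insert_coords,
        insert_nt_coords=insert_nt,
        his_asp_fraction=hd_frac,
        fu_boundaries=bounds,
        ancestor_cds=cds_anc,
        spec=spec,
    )


def _translate_cds(cds: str, fwd: dict[str, str], stops: set[str]) -> str:
    aa = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in stops:
            break
        aa.append(fwd.get(codon, "X"))
    return "".join(aa)


def heterologous_reference(truth: TruthSet, divergence: float, seed: int = 0) -> str:
    """A seed-reference CDS at the requested divergence from the ancestor.

    Stands in for the published hemocyanin cDNA of a related species used to
    initiate read recruitment.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fwd, stops, _ = _codon_maps(truth.spec.codon_table_id)
    crange = (0, len(truth.ancestor_cds))
    sites = _mutable_sites(len(truth.ancestor_cds), crange)
    n = min(int(round(divergence * len(truth.ancestor_cds))), len(sites))
    chosen = rng.choice(sites, size=n, replace=False)
    return _mutate_sites(
        truth.ancestor_cds, chosen, rng, fwd, stops, truth.spec.synonymous_weight, crange
    )


def homolog_protein(truth: TruthSet, divergence: float, seed: int = 0) -> str:
    """Protein of a homolog at the given nucleotide divergence from the ancestor.

    Useful as a phylogenetic outgroup (a hemocyanin from outside the studied
    clade, diverged before the H1/H2 duplication).
    """
    cds = heterologous_reference(truth, divergence, seed=seed)
    fwd, stops, _ = _codon_maps(truth.spec.codon_table_id)
    return _translate_cds(cds, fwd, stops)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(truth: TruthSet | dict[str, str], spec: ReadSimSpec) -> SimulatedReads:
    """Paired-end substitution-error reads at the requested coverage.

    Templates are the transcripts of a :class:`TruthSet` (or any label->sequence
    mapping).  Fragment lengths are normal(mean, sd) clipped to
    [read_length, template length]; mates are forward-reverse; qualities are
    constant Q30 (Phred+33).  The origin table records template, 0-based
    half-open coordinates, strand and the number of injected errors per mate.
    """
    templates = truth.transcripts if isinstance(truth, TruthSet) else dict(truth)
    if not templates:
        raise ValueError("no templates to simulate from")
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length_nt
    qual = chr(30 + 33) * rl
    r1, r2, rows = [], [], []
    pair_no = 0
    for label in sorted(templates):
        template = templates[label]
        length = len(template)
        if length < rl:
            raise ValueError(f"template {label} shorter than read length")
        n_pairs = max(1, int(round(spec.coverage * length / (2 * rl))))
        frags = np.clip(
            np.rint(rng.normal(spec.fragment_mean_nt, spec.fragment_sd_nt, size=n_pairs)),
            rl,
            length,
        ).astype(int)
        starts = rng.integers(0, length - frags + 1)
        flips = rng.integers(0, 2, size=n_pairs)
        for frag, start, flip in zip(frags, starts, flips):
            pair_id = f"p{pair_no:07d}"
            pair_no += 1
            fwd_seq = template[start : start + rl]
            rev_seq = revcomp(template[start + frag - rl : start + frag])
            fwd_seq, n_err_f = _inject_errors(fwd_seq, spec.error_rate, rng)
            rev_seq, n_err_r = _inject_errors(rev_seq, spec.error_rate, rng)
            mate_info = [
                (fwd_seq, start, start + rl, "+", n_err_f),
                (rev_seq, start + frag - rl, start + frag, "-", n_err_r),
            ]
            if flip:
                mate_info.reverse()
            for mate, (seq, s, e, strand, n_err) in enumerate(mate_info, start=1):
                rid = f"{pair_id}/{mate}"
                (r1 if mate == 1 else r2).append(ReadRecord(rid, seq, qual))
                rows.append((rid, pair_id, label, s, e, strand, mate, n_err))
    origins = pd.DataFrame(
        rows, columns=["read_id", "pair_id", "gene", "start", "end", "strand", "mate", "n_errors"]
    )
    return SimulatedReads(r1=r1, r2=r2, origins=origins)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out), int(n)


# ---------------------------------------------------------------------------
# chimeras


def make_chimera(truth: TruthSet, breakpoint: int, species: str = "sp1") -> ChimeraTruth:
    """Fuse H1[0:breakpoint] with H2[breakpoint:] (transcript coordinates on H1).

    Emulates the misassembly failure mode in which reads of two paralogs are
    merged into one consensus; the true breakpoint is returned for scoring the
    verification stage.  Positions downstream of the H2 insertion are shifted
    by the insertion length when slicing H2.
    """
    h1_label, h2_label = f"H1_{species}", f"H2_{species}"
    h1, h2 = truth.transcripts[h1_label], truth.transcripts[h2_label]
    if not 0 <= breakpoint <= len(h1):
        raise ValueError("breakpoint outside transcript coordinates")
    ins = truth.insert_nt_coords.get(h2_label)
    bp2 = breakpoint
    if ins is not None:
        tx_ins_start = truth.cds_ranges[h2_label][0] + ins[0]
        if breakpoint >= tx_ins_start:
            bp2 = breakpoint + (ins[1] - ins[0])
    return ChimeraTruth(
        seq=h1[:breakpoint] + h2[bp2:],
        breakpoint=breakpoint,
        left_parent=h1_label,
        right_parent=h2_label,
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for label in sequences:
            fh.write(f">{label}\n")
            seq = sequences[label]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


def write_truth_tables(truth: TruthSet, sim: SimulatedReads, outdir) -> None:
    """FASTA transcripts/CDS/proteins plus TSV truth tables (0-based half-open)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(truth.transcripts, os.path.join(outdir, "transcripts.fasta"))
    write_fasta(truth.genes, os.path.join(outdir, "cds.fasta"))
    write_fasta(truth.proteins, os.path.join(outdir, "proteins.fasta"))
    write_fastq(sim.r1, os.path.join(outdir, "reads_1.fastq"))
    write_fastq(sim.r2, os.path.join(outdir, "reads_2.fastq"))
    sim.origins.to_csv(os.path.join(outdir, "read_origins.tsv"), sep="\t", index=False)
    rows = [
        {"gene": label, "aa_start": c[0], "aa_end": c[1], "his_asp_fraction": truth.his_asp_fraction[label]}
        for label, c in truth.insert_coords.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "insert_truth.tsv"), sep="\t", index=False)


def scaled_down_spec(seed: int = 0, **overrides) -> ParalogPairSpec:
    """A reduced architecture (4 FUs x 160 aa + 60-aa tail) for fast pipelines.

    Read-level parameters and divergences keep their full-scale defaults; only
    the gene length is reduced.
    """
    arch = FUArchitecture(fu_names=tuple("abcd"), fu_length_aa=160, terminal_tail_aa=60)
    insert = InsertSpec(length_aa=60, host_fu="c", offset_in_fu_aa=20)
    spec = ParalogPairSpec(architecture=arch, h2_insert=insert, seed=seed)
    return replace(spec, **overrides) if overrides else spec
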