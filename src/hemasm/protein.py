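"""Protein-level characterization of assembled hemocyanin coding sequences.

Covers ORF finding and translation, average molecular mass, functional-unit
(FU) annotation by alignment to an annotated reference subunit, detection of
the His/Asp-rich hydrophilic insertion in FU-g, Kyte-Doolittle hydropathy
profiling, residue composition, and a cysteine census distinguishing the
conserved intra-FU cysteines from newly evolved ones.

Pairwise alignments are global with affine gaps (BLOSUM62, open 10,
extend 0.5) via Biopython's PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np

from ._seq import revcomp

WATER_DA = 18.0153

#: Average residue (i.e. water-free) masses in Da, standard 20 amino acids.
AVERAGE_RESIDUE_MASS = MappingProxyType(
    {
        "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
        "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
        "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
        "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    }
)

MONOISOTOPIC_RESIDUE_MASS = MappingProxyType(
    {
        "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694, "C": 103.00919,
        "E": 129.04259, "Q": 128.05858, "G": 57.02146, "H": 137.05891, "I": 113.08406,
        "L": 113.08406, "K": 128.09496, "M": 131.04049, "F": 147.06841, "P": 97.05276,
        "S": 87.03203, "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
    }
)
MONOISOTOPIC_WATER_DA = 18.010565

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE = MappingProxyType(
    {
        "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
        "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
        "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
    }
)

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TO_AA: dict[str, str] = {}


def _codon_to_aa() -> dict[str, str]:
    if not _CODON_TO_AA:
        from Bio.Data import CodonTable

        _CODON_TO_AA.update(CodonTable.unambiguous_dna_by_id[1].forward_table)
    return _CODON_TO_AA


@dataclass
class ProteinRecord:
    id: str
    seq: str
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty protein sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mass_da(self) -> float:
        return molecular_weight(self)


# ---------------------------------------------------------------------------
# ORF finding and translation


def find_orf_translate(nucleotides: str, min_orf_nt: int = 300, record_id: str = "orf") -> ProteinRecord:
    """Longest ATG-initiated, stop-terminated ORF on either strand, translated.

    The returned protein excludes the terminal stop, so its length is
    (ORF nt)/3 - 1.  Codons containing N translate to X and set the record's
    ``has_ambiguous`` flag.  Raises ValueError when no ORF of at least
    ``min_orf_nt`` nucleotides (start through stop) exists.
    """
    seq = nucleotides.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    best: tuple[int, str] | None = None  # (orf length nt, orf sequence)
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            open_start: int | None = None
            for pos in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[pos : pos + 3]
                if codon in _STOPS:
                    if open_start is not None:
                        length = pos + 3 - open_start
                        if best is None or length > best[0]:
                            best = (length, strand_seq[open_start : pos + 3])
                        open_start = None
                elif codon == "ATG" and open_start is None:
                    open_start = pos
    if best is None or best[0] < min_orf_nt:
        raise ValueError(f"no ATG-initiated ORF of >= {min_orf_nt} nt found")
    orf = best[1]
    table = _codon_to_aa()
    residues = []
    ambiguous = False
    for pos in range(0, len(orf) - 3, 3):
        codon = orf[pos : pos + 3]
        aa = table.get(codon)
        if aa is None:
            aa = "X"
            ambiguous = True
        residues.append(aa)
    return ProteinRecord(id=record_id, seq="".join(residues), has_ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# mass and composition


def molecular_weight(protein: ProteinRecord | str, monoisotopic: bool = False) -> float:
    """Sum of residue masses plus one water, in Da.

    Average masses by default (subunit masses in the literature are averages);
    ``monoisotopic=True`` switches tables.  Raises on nonstandard residues,
    listing their 1-based positions.
    """
    seq = protein.seq if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("empty protein sequence")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    bad = [i + 1 for i, aa in enumerate(seq) if aa not in table]
    if bad:
        raise ValueError(f"nonstandard residues at positions {bad[:10]}")
    water = MONOISOTOPIC_WATER_DA if monoisotopic else WATER_DA
    return sum(table[aa] for aa in seq) + water


def composition(seq: str) -> dict[str, float]:
    """Residue fractions over a segment; values sum to 1."""
    if not seq:
        raise ValueError("empty segment")
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in sorted(set(seq))}


# ---------------------------------------------------------------------------
# alignment plumbing


def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # free end gaps: a truncated subunit (e.g. collar loss) should not have
    # its tail force-aligned across the reference's remaining domains
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _align_indices(query: str, target: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (query index, target index), -1 for a gap."""
    alignment = _aligner().align(query, target)[0]
    q_idx, t_idx = alignment.indices
    return q_idx, t_idx


# ---------------------------------------------------------------------------
# FU annotation


@dataclass
class FUAnnotation:
    """Ordered FU segments on a protein, 1-based inclusive coordinates."""

    segments: list[tuple[str, int, int]]
    method: str = "anchor-alignment"

    def segment(self, name: str) -> tuple[int, int] | None:
        for label, start, end in self.segments:
            if label == name:
                return start, end
        return None


def annotate_fus(
    protein: ProteinRecord | str,
    reference: ProteinRecord | str,
    reference_fus: list[tuple[str, int, int]],
) -> FUAnnotation:
    """Project FU boundaries from an annotated reference through an alignment.

    ``reference_fus`` are (name, start, end) 0-based half-open on the
    reference.  Query residues aligned within a reference FU inherit its
    label; unaligned insertions inherit the FU of their left flank.  Raises
    when fewer than half the reference residues align to query residues.
    """
    qseq = protein.seq if isinstance(protein, ProteinRecord) else protein
    rseq = reference.seq if isinstance(reference, ProteinRecord) else reference
    q_idx, r_idx = _align_indices(qseq, rseq)
    aligned_ref = int(np.count_nonzero((q_idx >= 0) & (r_idx >= 0)))
    if aligned_ref < 0.5 * len(rseq):
        raise ValueError("alignment covers <50% of the reference; not a comparable subunit")

    fu_of_ref = np.full(len(rseq), -1)
    names = [name for name, _s, _e in reference_fus]
    for fu_i, (_name, start, end) in enumerate(reference_fus):
        fu_of_ref[start:end] = fu_i

    assignment = np.full(len(qseq), -1)
    current = 0
    for q, r in zip(q_idx, r_idx):
        if r >= 0 and fu_of_ref[r] >= 0:
            current = int(fu_of_ref[r])
        if q >= 0:
            assignment[q] = current
    segments: list[tuple[str, int, int]] = []
    for fu_i, name in enumerate(names):
        where = np.flatnonzero(assignment == fu_i)
        if where.size == 0:
            continue
        segments.append((name, int(where[0]) + 1, int(where[-1]) + 1))
    return FUAnnotation(segments=segments)


# ---------------------------------------------------------------------------
# insertion detection


@dataclass
class InsertionCall:
    """A run of query residues aligned to gaps in an insert-free counterpart."""

    start: int  # 1-based inclusive on the query protein
    end: int
    length_aa: int
    mass_da: float
    his_fraction: float
    asp_fraction: float
    mean_hydropathy: float
    host_fu: str | None = None

    @property
    def his_asp_fraction(self) -> float:
        return self.his_fraction + self.asp_fraction

    @property
    def mass_kda(self) -> float:
        return self.mass_da / 1000.0


def call_insertion(
    protein: ProteinRecord | str,
    counterpart: ProteinRecord | str,
    min_insert_aa: int = 20,
    counterpart_fus: list[tuple[str, int, int]] | None = None,
    bridge_aa: int = 10,
) -> list[InsertionCall]:
    """Maximal gap-runs of the query against an insert-free homolog.

    Each run of at least ``min_insert_aa`` query residues aligned to gaps in
    the counterpart becomes one call, reported with its mass, His/Asp content
    and mean Kyte-Doolittle hydropathy.  Gap runs separated by at most
    ``bridge_aa`` aligned columns are merged into one call: inside a long
    insertion the aligner occasionally anchors a handful of coincidentally
    matching residues, splitting what is biologically one event.  When
    ``counterpart_fus`` (0-based half-open) is given, the host FU is the one
    containing the counterpart residue at the insertion's left flank.
    """
    qseq = protein.seq if isinstance(protein, ProteinRecord) else protein
    cseq = counterpart.seq if isinstance(counterpart, ProteinRecord) else counterpart
    q_idx, c_idx = _align_indices(qseq, cseq)

    calls: list[InsertionCall] = []
    run: list[int] = []
    last_c = -1
    runs: list[tuple[list[int], int]] = []
    for q, c in zip(q_idx, c_idx):
        if q >= 0 and c < 0:
            run.append(int(q))
        else:
            if run:
                runs.append((run, last_c))
                run = []
            if c >= 0:
                last_c = int(c)
    if run:
        runs.append((run, last_c))

    merged: list[tuple[list[int], int]] = []
    for positions, left_c in runs:
        if merged:
            prev_positions, prev_left = merged[-1]
            q_gap = positions[0] - prev_positions[-1] - 1
            c_gap = left_c - prev_left
            # inside a long insertion the aligner can anchor a longer stretch
            # of coincidental matches, so the allowance scales with run size
            allowance = max(bridge_aa, int(0.25 * (len(prev_positions) + len(positions))))
            if 0 <= q_gap <= allowance and 0 <= c_gap <= allowance:
                merged[-1] = (prev_positions + list(range(prev_positions[-1] + 1, positions[0])) + positions, prev_left)
                continue
        merged.append((list(positions), left_c))

    large_runs = [r for r, _lc in merged if len(r) >= min_insert_aa]
    single_insert = len(large_runs) == 1 and len(qseq) > len(cseq)
    for positions, left_c in merged:
        if len(positions) < min_insert_aa:
            continue
        if single_insert:
            start, end = _refine_boundaries(qseq, cseq, positions)
        else:
            start, end = positions[0], positions[-1]
        segment = qseq[start : end + 1]
        host = None
        if counterpart_fus is not None:
            for name, fu_start, fu_end in counterpart_fus:
                if fu_start <= max(left_c, 0) < fu_end:
                    host = name
                    break
        kd = [KYTE_DOOLITTLE[a] for a in segment if a in KYTE_DOOLITTLE]
        calls.append(
            InsertionCall(
                start=start + 1,
                end=end + 1,
                length_aa=len(segment),
                mass_da=molecular_weight(segment) - WATER_DA,
                his_fraction=segment.count("H") / len(segment),
                asp_fraction=segment.count("D") / len(segment),
                mean_hydropathy=float(np.mean(kd)) if kd else 0.0,
                host_fu=host,
            )
        )
    return calls


def _refine_boundaries(
    qseq: str, cseq: str, positions: list[int], context: int = 30
) -> tuple[int, int]:
    """Re-place a single insertion's boundaries under the one-event model.

    With exactly one insertion and substitution-level divergence elsewhere,
    query and counterpart are positionally aligned 1:1 outside the insert, so
    the insert length is the full length difference and a breakpoint at ``k``
    implies q[:k] ~ c[:k] and q[k+net:] ~ c[k:].  Candidate breakpoints near
    the aligner's call are scored by flank identity under that model; the best
    placement wins, ties resolving toward the aligner's original position.
    Fixes the few-residue boundary wobble the affine-gap aligner leaves on
    short or repeat-rich insertions.
    """
    q0, q1 = positions[0], positions[-1]
    net = len(qseq) - len(cseq)
    if net < 1:
        return q0, q1

    # log-likelihood-ratio weights: flank columns match the counterpart at a
    # far higher rate than insert-vs-flank coincidences, and insert residues
    # are predominantly His/Asp while flanks are not.  Rates are generic for
    # diverged hemocyanin paralogs and their hydrophilic inserts.
    llr_match, llr_mismatch = 2.2, -0.55
    llr_hd, llr_other = 1.9, -1.1

    def placement_score(k: int) -> float:
        score = 0.0
        for j in range(1, context + 1):
            qi = k - j
            if qi < 0:
                break
            score += llr_match if qseq[qi] == cseq[qi] else llr_mismatch
        for j in range(context):
            qi, ci = k + net + j, k + j
            if qi >= len(qseq) or ci >= len(cseq):
                break
            score += llr_match if qseq[qi] == cseq[ci] else llr_mismatch
        for qi in range(k, k + net):
            score += llr_hd if qseq[qi] in "HD" else llr_other
        return score

    slack = 25  # the affine aligner's boundary wobble is local
    best = (placement_score(q0), 0, q0)
    for k in range(max(0, q0 - slack), min(q0 + slack + 1, len(cseq) + 1)):
        cand = (placement_score(k), -abs(k - q0), k)
        if cand[:2] > best[:2]:
            best = cand
    k = best[2]
    return k, k + net - 1


# ---------------------------------------------------------------------------
# hydropathy


@dataclass
class HydropathyProfile:
    window: int
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)


def hydropathy_profile(protein: ProteinRecord | str, window: int = 9) -> HydropathyProfile:
    """Mean Kyte-Doolittle value per centered window; ends use what's there."""
    seq = protein.seq if isinstance(protein, ProteinRecord) else protein
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than the sequence")
    kd = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    half = window // 2
    values = np.empty(len(seq))
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        values[i] = kd[lo:hi].mean()
    return HydropathyProfile(window=window, values=values)


# ---------------------------------------------------------------------------
# cysteine census


@dataclass
class CysteineReport:
    positions: list[int]  # all Cys, 1-based
    canonical: list[int]  # aligned to a reference Cys
    additional: list[int]  # aligned to a non-Cys or to a gap


def cysteine_census(protein: ProteinRecord | str, reference: ProteinRecord | str) -> CysteineReport:
    """Partition the query's cysteines by conservation against a reference.

    Cysteines aligned to a reference cysteine are the canonical intra-FU
    disulfide partners; any other cysteine (aligned to a different residue or
    to a gap) is reported as additional.
    """
    qseq = protein.seq if isinstance(protein, ProteinRecord) else protein
    rseq = reference.seq if isinstance(reference, ProteinRecord) else reference
    q_idx, r_idx = _align_indices(qseq, rseq)
    partner = np.full(len(qseq), -1)
    for q, r in zip(q_idx, r_idx):
        if q >= 0:
            partner[q] = r
    positions, canonical, additional = [], [], []
    for i, aa in enumerate(qseq):
        if aa != "C":
            continue
        positions.append(i + 1)
        r = int(partner[i])
        if r >= 0 and rseq[r] == "C":
            canonical.append(i + 1)
        else:
            additional.append(i + 1)
    return CysteineReport(positions=positions, canonical=canonical, additional=additional)
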