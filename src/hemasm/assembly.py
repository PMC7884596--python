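"""Iterative reference-guided, paralog-separating read-mapping assembly.

The strategy mirrors how full-length hemocyanin coding sequences are built
from short reads when only a diverged heterologous reference is available:

1. *Seeding*: reads are recruited against the heterologous reference at a
   permissive nucleotide identity (default 70%), which catches reads from the
   conserved cores of all paralogs.  The recruited reads themselves — not a
   reference-projected consensus — become the initial contigs, so paralogs are
   never pooled into one consensus.
2. *High-stringency iteration*: further reads are mapped to the growing
   contigs under strict acceptance rules (minimum overlap 60 nt, overlap
   identity >= 99%, mismatches <= 1% of the overlap), contig ends are extended
   by overhang consensus, and contigs whose ends overlap under the same rules
   are merged.  Iteration continues until no contig grows and no new read is
   recruited.

Paralog separation relies on the strict identity threshold plus a best-hit
rule: a read contributes to the consensus only of the contig(s) it matches
with the fewest mismatches; ties are flagged ambiguous and excluded from end
extension so that paralog-undiagnostic reads can never steer growth.

All mapping is ungapped (substitution-only), matching the read simulator's
error model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, encode, revcomp


@dataclass(frozen=True)
class MappingParams:
    """Stringency settings of the iterative mapper.

    The high-stringency trio (min_overlap_nt, min_overlap_identity,
    max_mismatch_fraction) are applied as independent caps on the overlap
    region: at short overlaps the floor of the mismatch budget is the stricter
    of the two identity-style rules.
    """

    min_overlap_nt: int = 60
    min_overlap_identity: float = 0.99
    max_mismatch_fraction: float = 0.01
    seed_identity: float = 0.70
    kmer_size: int = 13
    seed_kmer_size: int = 8
    kmer_step: int = 7
    max_candidates: int = 8
    min_extension_coverage: int = 3
    min_extension_agreement: float = 0.80
    seed_window_nt: int = 100
    seed_reads_per_window: int = 6
    weak_column_leniency: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("min_overlap_identity must be in (0, 1]")
        if self.min_overlap_nt < self.kmer_size:
            raise ValueError("min_overlap_nt must be >= kmer_size")

    def mismatch_budget(self, overlap: int) -> int:
        by_fraction = math.floor(self.max_mismatch_fraction * overlap)
        by_identity = math.floor((1.0 - self.min_overlap_identity) * overlap)
        return min(by_fraction, by_identity)


@dataclass
class ReadHit:
    read_id: str
    contig_id: str
    start: int  # contig coordinate of read base 0 (may be negative: left overhang)
    strand: str  # '+' read as given, '-' reverse complement
    overlap_length: int
    mismatches: int
    left_overhang: int
    right_overhang: int
    ambiguous: bool = False


@dataclass
class Contig:
    id: str
    seq: str
    coverage: np.ndarray
    last_grown: int = 0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyState:
    contigs: list[Contig]
    recruited: set[str]
    iteration: int = 0
    converged: bool = False
    placements: dict[str, ReadHit] = field(default_factory=dict)

    def consensus(self) -> dict[str, str]:
        return {c.id: c.seq for c in self.contigs}

    def report(self) -> dict:
        return {
            "iterations": self.iteration,
            "converged": self.converged,
            "n_contigs": len(self.contigs),
            "n_recruited": len(self.recruited),
            "contig_lengths": {c.id: len(c.seq) for c in self.contigs},
        }


# ---------------------------------------------------------------------------
# hit evaluation


def accept_hit(
    read: str, contig: str | Contig, offset: int, params: MappingParams, read_id: str = "read"
) -> ReadHit | None:
    """Evaluate one ungapped placement of a read on a contig.

    Accepted iff the overlap with the contig is >= ``min_overlap_nt`` long,
    its identity is >= ``min_overlap_identity``, and the mismatch count is
    within ``floor(max_mismatch_fraction * overlap)``.  Overhang beyond either
    contig end is allowed and not compared.  Returns None on rejection.
    """
    contig_id = contig.id if isinstance(contig, Contig) else "contig"
    cseq = contig.seq if isinstance(contig, Contig) else contig
    return _evaluate(encode(read), encode(cseq), offset, params, read_id, contig_id, "+")


def _evaluate(
    read_enc: np.ndarray,
    contig_enc: np.ndarray,
    offset: int,
    params: MappingParams,
    read_id: str,
    contig_id: str,
    strand: str,
    conf_mask: np.ndarray | None = None,
) -> ReadHit | None:
    rl, cl = len(read_enc), len(contig_enc)
    lo = max(0, offset)
    hi = min(cl, offset + rl)
    overlap = hi - lo
    if overlap < params.min_overlap_nt:
        return None
    seg_r = read_enc[lo - offset : hi - offset]
    seg_c = contig_enc[lo:hi]
    mism = (seg_r != seg_c) | (seg_r == 4) | (seg_c == 4)
    mismatches = int(np.count_nonzero(mism))
    if conf_mask is not None:
        # residual consensus errors sit at thinly covered columns and would
        # otherwise reject every read able to correct them; forgive a small
        # number of mismatches there (far below any paralog's divergence)
        weak = int(np.count_nonzero(mism & ~conf_mask[lo:hi]))
        forgiven = min(weak, math.floor(params.weak_column_leniency * overlap))
        mismatches -= forgiven
    if mismatches > params.mismatch_budget(overlap):
        return None
    return ReadHit(
        read_id=read_id,
        contig_id=contig_id,
        start=offset,
        strand=strand,
        overlap_length=overlap,
        mismatches=mismatches,
        left_overhang=max(0, -offset),
        right_overhang=max(0, offset + rl - cl),
    )


def _candidate_offsets(seq: str, index: dict[str, list], k: int, step: int, cap: int):
    votes: dict[tuple, int] = {}
    for pos in range(0, len(seq) - k + 1, step):
        for where in index.get(seq[pos : pos + k], ()):
            key = (where[0], where[1] - pos)
            votes[key] = votes.get(key, 0) + 1
    return sorted(votes, key=lambda key: (-votes[key], key))[:cap]


class _ContigIndex:
    def __init__(self, contigs: list[Contig], k: int, min_conf_coverage: int | None = None):
        self.k = k
        self.enc = [encode(c.seq) for c in contigs]
        self.ids = [c.id for c in contigs]
        self.conf = [
            None if min_conf_coverage is None else (c.coverage >= min_conf_coverage)
            for c in contigs
        ]
        self.index: dict[str, list] = {}
        for ci, contig in enumerate(contigs):
            seq = contig.seq
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((ci, pos))

    def best_hits(self, read_id: str, read: str, params: MappingParams) -> dict[int, tuple[ReadHit, np.ndarray]]:
        """Best accepted hit per contig, searching both strands."""
        best: dict[int, tuple[ReadHit, np.ndarray]] = {}
        for strand, seq in (("+", read), ("-", revcomp(read))):
            enc = encode(seq)
            for ci, offset in _candidate_offsets(seq, self.index, self.k, params.kmer_step, params.max_candidates):
                hit = _evaluate(
                    enc, self.enc[ci], offset, params, read_id, self.ids[ci], strand,
                    conf_mask=self.conf[ci],
                )
                if hit is None:
                    continue
                prev = best.get(ci)
                if prev is None or (hit.mismatches, -hit.overlap_length) < (
                    prev[0].mismatches,
                    -prev[0].overlap_length,
                ):
                    best[ci] = (hit, enc)
        return best


def assign_paralog(
    read: str, contigs: list[Contig], params: MappingParams, read_id: str = "read"
) -> list[ReadHit]:
    """Best-hit paralog assignment for one read.

    Returns the accepted hit(s) on the contig(s) with the fewest mismatches;
    with more than one tied contig every returned hit carries
    ``ambiguous=True`` (such reads count toward coverage but are barred from
    end extension).  Empty list when no contig accepts the read.
    """
    if not contigs:
        raise ValueError("assign_paralog requires at least one contig")
    idx = _ContigIndex(contigs, params.kmer_size)
    best = idx.best_hits(read_id, read, params)
    return _pick_best(best)


def _pick_best(best: dict[int, tuple[ReadHit, np.ndarray]]) -> list[ReadHit]:
    # fewest mismatches wins; a longer overlap breaks mismatch ties (a read
    # bridging two co-linear fragments of one gene overlaps them unequally,
    # whereas a genuinely paralog-ambiguous read ties on both counts)
    if not best:
        return []
    key = min((hit.mismatches, -hit.overlap_length) for hit, _ in best.values())
    chosen = [
        hit
        for hit, _ in best.values()
        if (hit.mismatches, -hit.overlap_length) == key
    ]
    if len(chosen) > 1:
        for hit in chosen:
            hit.ambiguous = True
    return sorted(chosen, key=lambda h: h.contig_id)


# ---------------------------------------------------------------------------
# seeding


def seed_map(reads, reference: str, params: MappingParams | None = None) -> AssemblyState:
    """Recruit reads against a diverged reference and seed read-contigs.

    Acceptance at this stage requires an overlap >= ``min_overlap_nt`` with
    nucleotide identity >= ``seed_identity`` (no mismatch-fraction cap: the
    reference is expected to be heterologous).  Recruited reads tile the
    reference; per ``seed_window_nt`` window up to ``seed_reads_per_window``
    of them (oriented to the reference strand) become initial contigs.
    """
    params = params or MappingParams()
    read_list = _as_read_list(reads)
    if not read_list:
        raise ValueError("empty read set")
    if len(reference) < params.seed_kmer_size:
        raise ValueError("reference shorter than k-mer size")
    ref_enc = encode(reference)
    index: dict[str, list] = {}
    k = params.seed_kmer_size
    for pos in range(len(reference) - k + 1):
        index.setdefault(reference[pos : pos + k], []).append((0, pos))

    accepted: list[tuple[int, str, str]] = []  # (ref position, read id, oriented seq)
    for rid, seq in read_list:
        best = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            enc = encode(oriented)
            for _ci, offset in _candidate_offsets(oriented, index, k, params.kmer_step, params.max_candidates):
                lo, hi = max(0, offset), min(len(ref_enc), offset + len(enc))
                overlap = hi - lo
                if overlap < params.min_overlap_nt:
                    continue
                seg_r = enc[lo - offset : hi - offset]
                seg_c = ref_enc[lo:hi]
                mism = int(np.count_nonzero((seg_r != seg_c) | (seg_r == 4) | (seg_c == 4)))
                identity = 1.0 - mism / overlap
                if identity < params.seed_identity:
                    continue
                if best is None or identity > best[0]:
                    best = (identity, lo, oriented)
        if best is not None:
            accepted.append((best[1], rid, best[2]))

    accepted.sort(key=lambda t: (t[0], t[1]))
    per_window: dict[int, int] = {}
    contigs: list[Contig] = []
    for pos, _rid, oriented in accepted:
        w = pos // params.seed_window_nt
        if per_window.get(w, 0) >= params.seed_reads_per_window:
            continue
        per_window[w] = per_window.get(w, 0) + 1
        contigs.append(
            Contig(id=f"c{len(contigs):04d}", seq=oriented, coverage=np.ones(len(oriented), dtype=int))
        )
    return AssemblyState(contigs=contigs, recruited={rid for _p, rid, _s in accepted})


def _as_read_list(reads) -> list[tuple[str, str]]:
    out = []
    for item in reads if not hasattr(reads, "reads") else reads.reads:
        if isinstance(item, tuple):
            out.append((item[0], item[1]))
        elif hasattr(item, "seq") and hasattr(item, "id"):
            out.append((item.id, str(item.seq)))
        else:
            raise TypeError("reads must be (id, seq) tuples or records")
    return sorted(out)


# ---------------------------------------------------------------------------
# iterative extension


def extend_iterate(
    state: AssemblyState, reads, params: MappingParams | None = None, max_iter: int = 40
) -> AssemblyState:
    """Recruit/extend/merge until convergence (fixed point) or ``max_iter``.

    Per iteration: every read is scored against every contig (k-mer seeded,
    both strands) and assigned by the best-hit rule; consensi are recomputed
    by per-column majority; ends grow while the overhang consensus has
    coverage >= ``min_extension_coverage`` and agreement >=
    ``min_extension_agreement``; contigs overlapping under the acceptance rule
    are merged.  Read order is fixed by id sort, making the result
    deterministic.
    """
    params = params or MappingParams()
    read_list = _as_read_list(reads)
    for iteration in range(1, max_iter + 1):
        state.iteration = iteration
        idx = _ContigIndex(state.contigs, params.kmer_size, params.min_extension_coverage)
        per_contig: dict[int, list[tuple[ReadHit, np.ndarray]]] = {i: [] for i in range(len(state.contigs))}
        recruited_before = set(state.recruited)
        placements: dict[str, ReadHit] = {}
        for rid, seq in read_list:
            best = idx.best_hits(rid, seq, params)
            chosen = _pick_best(best)
            if not chosen:
                continue
            state.recruited.add(rid)
            by_id = {hit.contig_id: hit for hit in chosen}
            for ci, (hit, enc) in best.items():
                if hit.contig_id in by_id:
                    per_contig[ci].append((by_id[hit.contig_id], enc))
            placements[rid] = chosen[0]
        state.placements = placements

        grew = False
        new_contigs: list[Contig] = []
        for ci, contig in enumerate(state.contigs):
            updated, contig_grew = _rebuild_consensus(contig, per_contig[ci], params, iteration)
            grew = grew or contig_grew
            new_contigs.append(updated)
        state.contigs = new_contigs

        merged = _merge_contigs(state, params)
        culled = _cull_redundant(state, params)
        new_reads = state.recruited != recruited_before
        if not grew and not merged and not culled and not new_reads:
            # stuck: close junctions that paired-mate evidence supports
            if _pair_supported_merges(state, params):
                continue
            state.converged = True
            break
    else:
        warnings.warn(f"assembly did not converge within {max_iter} iterations", stacklevel=2)
        state.converged = False
    return state


def _rebuild_consensus(
    contig: Contig, hits: list[tuple[ReadHit, np.ndarray]], params: MappingParams, iteration: int
) -> tuple[Contig, bool]:
    length = len(contig.seq)
    left = max((h.left_overhang for h, _ in hits), default=0)
    right = max((h.right_overhang for h, _ in hits), default=0)
    counts = np.zeros((left + length + right, 4), dtype=np.int32)
    for hit, enc in hits:
        if hit.ambiguous:
            lo = max(0, hit.start)
            hi = min(length, hit.start + len(enc))
            seg = enc[lo - hit.start : hi - hit.start]
        else:
            lo, hi = hit.start, hit.start + len(enc)
            seg = enc
        span = np.arange(lo + left, hi + left)
        valid = seg < 4
        np.add.at(counts, (span[valid], seg[valid]), 1)

    old_enc = encode(contig.seq)
    body = counts[left : left + length]
    cov = body.sum(axis=1)
    winner = body.argmax(axis=1).astype(np.uint8)
    new_body = np.where(cov > 0, winner, old_enc)

    def _grow(indices) -> list[int]:
        grown = []
        for pos in indices:
            col = counts[pos]
            total = int(col.sum())
            if total < params.min_extension_coverage:
                break
            top = int(col.max())
            second = int(np.partition(col, -2)[-2])
            # dissent cap: one erroneous read plus the fractional allowance.
            # Overhang reads are already paralog-filtered by their accepted
            # anchors, so dissent beyond what the sequencing error rate can
            # produce (near 50/50 at a would-be chimeric junction) stops
            # extension, while coincident errors at modest depth do not.
            if second > 1 + math.floor((1 - params.min_extension_agreement) * total):
                break
            # strict majority required: a tie stops extension at this base
            if np.count_nonzero(col == top) > 1:
                break
            grown.append(int(col.argmax()))
        return grown

    left_ext = _grow(range(left - 1, -1, -1))[::-1]
    right_ext = _grow(range(left + length, left + length + right))
    new_enc = np.concatenate(
        [np.array(left_ext, dtype=np.uint8), new_body, np.array(right_ext, dtype=np.uint8)]
    ).astype(np.uint8)
    new_cov = np.concatenate(
        [
            counts[left - len(left_ext) : left].sum(axis=1),
            np.maximum(cov, 1),
            counts[left + length : left + length + len(right_ext)].sum(axis=1),
        ]
    )
    contig_grew = len(new_enc) > length
    return (
        Contig(
            id=contig.id,
            seq=decode(new_enc),
            coverage=new_cov.astype(int),
            last_grown=iteration if contig_grew else contig.last_grown,
        ),
        contig_grew,
    )


def _merge_contigs(state: AssemblyState, params: MappingParams) -> bool:
    """Merge contigs whose ends overlap under the acceptance rule.

    The identity/mismatch caps are evaluated on confidently covered columns
    only (coverage >= ``min_extension_coverage`` on both contigs): a residual
    error in a thinly covered contig end must not veto a merge that deep
    coverage on the partner contig contradicts.  In the overlap the base of
    the better-covered contig wins.
    """
    merged_any = False
    changed = True
    while changed and len(state.contigs) > 1:
        changed = False
        contigs = state.contigs
        idx = _ContigIndex(contigs, params.kmer_size)
        for cj in range(len(contigs) - 1, -1, -1):
            source = contigs[cj]
            found = None
            for strand, oriented in (("+", source.seq), ("-", revcomp(source.seq))):
                enc_s = encode(oriented)
                cov_s = source.coverage if strand == "+" else source.coverage[::-1]
                for ci, offset in _candidate_offsets(
                    oriented, idx.index, idx.k, params.kmer_step, params.max_candidates
                ):
                    if ci == cj:
                        continue
                    target = contigs[ci]
                    enc_t = idx.enc[ci]
                    lo, hi = max(0, offset), min(len(enc_t), offset + len(enc_s))
                    if hi - lo < params.min_overlap_nt:
                        continue
                    seg_s = enc_s[lo - offset : hi - offset]
                    seg_t = enc_t[lo:hi]
                    conf = (
                        (cov_s[lo - offset : hi - offset] >= params.min_extension_coverage)
                        & (target.coverage[lo:hi] >= params.min_extension_coverage)
                    )
                    n_conf = int(conf.sum())
                    if n_conf < params.min_overlap_nt:
                        continue
                    mism = int(
                        np.count_nonzero(((seg_s != seg_t) | (seg_s == 4) | (seg_t == 4)) & conf)
                    )
                    if mism > params.mismatch_budget(n_conf):
                        continue
                    found = (ci, offset, oriented, cov_s)
                    break
                if found:
                    break
            if not found:
                continue
            ci, offset, src_seq, cov_s = found
            _apply_merge(state, ci, cj, offset, src_seq, cov_s)
            merged_any = changed = True
            break
    return merged_any


def _apply_merge(
    state: AssemblyState, ci: int, cj: int, offset: int, src_seq: str, cov_s: np.ndarray
) -> None:
    """Replace contigs ci (target) and cj (source) by their union.

    ``src_seq``/``cov_s`` are the source contig oriented to the target strand;
    in the overlap the base of the better-covered contig wins.
    """
    contigs = state.contigs
    target, source = contigs[ci], contigs[cj]
    lo, hi = max(0, offset), min(len(target.seq), offset + len(src_seq))
    body = list(target.seq)
    for pos in range(lo, hi):
        if cov_s[pos - offset] > target.coverage[pos]:
            body[pos] = src_seq[pos - offset]
    prefix = src_seq[: -offset] if offset < 0 else ""
    n_suffix = max(0, offset + len(src_seq) - len(target.seq))
    suffix = src_seq[len(src_seq) - n_suffix :] if n_suffix else ""
    merged_seq = prefix + "".join(body) + suffix
    merged_cov = np.concatenate(
        [
            cov_s[: len(prefix)],
            np.maximum(
                target.coverage,
                np.pad(cov_s[len(prefix) : len(src_seq) - n_suffix],
                       (lo, len(target.seq) - hi)),
            ),
            cov_s[len(src_seq) - n_suffix :],
        ]
    )
    merged = Contig(
        id=target.id,
        seq=merged_seq,
        coverage=merged_cov.astype(int),
        last_grown=max(target.last_grown, source.last_grown),
    )
    state.contigs = [c for k, c in enumerate(contigs) if k not in (ci, cj)]
    state.contigs.append(merged)
    state.contigs.sort(key=lambda c: c.id)


def _pair_supported_merges(state: AssemblyState, params: MappingParams) -> bool:
    """Close near-touching junctions backed by paired-mate evidence.

    When two co-linear contigs approach each other, reads over the junction
    split between them and the strict budgets can starve both end extension
    and the standard merge.  Read pairs with one mate on each contig resolve
    this: if the contigs also share a clean overlap of at least the
    low-stringency anchor length (25 nt, zero mismatches on confidently
    covered columns) and at least three bridging pairs imply fragment lengths
    consistent with the same-contig fragment distribution, the contigs are
    merged.  Paralog contigs can never qualify — at their divergence no clean
    25-nt overlap exists and no read pair bridges them.
    """
    if len(state.contigs) < 2 or not state.placements:
        return False
    by_pair: dict[str, list[ReadHit]] = {}
    for rid, hit in state.placements.items():
        by_pair.setdefault(rid.rsplit("/", 1)[0], []).append(hit)
    frags: list[int] = []
    cross: dict[tuple[str, str], list[tuple[ReadHit, ReadHit]]] = {}
    for mates in by_pair.values():
        if len(mates) != 2 or any(m.ambiguous for m in mates):
            continue
        a, b = mates
        if a.contig_id == b.contig_id:
            spans = [
                (m.start, m.start + m.overlap_length + m.left_overhang + m.right_overhang)
                for m in mates
            ]
            frags.append(max(e for _s, e in spans) - min(s for s, _e in spans))
        else:
            key = tuple(sorted((a.contig_id, b.contig_id)))
            cross.setdefault(key, []).append((a, b))

    if frags:
        f_arr = np.asarray(frags, dtype=float)
        f_lo = 0.0
        f_hi = float(np.median(f_arr) + 4 * max(f_arr.std(), 10.0))
    else:
        f_lo, f_hi = 0.0, 2000.0

    by_id = {c.id: k for k, c in enumerate(state.contigs)}
    for (id_a, id_b), pairs in sorted(cross.items(), key=lambda kv: -len(kv[1])):
        if len(pairs) < 3 or id_a not in by_id or id_b not in by_id:
            continue
        ci, cj = by_id[id_a], by_id[id_b]
        target, source = state.contigs[ci], state.contigs[cj]
        overlap = _junction_overlap(target, source, params)
        if overlap is None:
            continue
        offset, oriented, cov_s, strand = overlap
        n_consistent = 0
        for a, b in pairs:
            hit_t, hit_s = (a, b) if a.contig_id == id_a else (b, a)
            rl = hit_s.overlap_length + hit_s.left_overhang + hit_s.right_overhang
            s = hit_s.start
            if strand == "-":
                s = len(source.seq) - (s + rl)
            lo = min(hit_t.start, offset + s)
            hi = max(
                hit_t.start + hit_t.overlap_length + hit_t.left_overhang + hit_t.right_overhang,
                offset + s + rl,
            )
            if f_lo < hi - lo <= f_hi:
                n_consistent += 1
        if n_consistent < 3:
            continue
        _apply_merge(state, ci, cj, offset, oriented, cov_s)
        return True
    return False


def _junction_overlap(target: Contig, source: Contig, params: MappingParams):
    """Clean low-stringency overlap of source on target, or None.

    Requires >= 25 confidently covered overlap columns with zero mismatches
    among them, and a UNIQUE qualifying placement: inside tandem repeats
    several shifted offsets can look clean, and merging there would slip the
    register — such repeat-ambiguous junctions are left alone (they are
    exactly what the pair-spanning verification reports on).
    """
    idx = _ContigIndex([target], params.kmer_size)
    qualifying = []
    for strand, oriented in (("+", source.seq), ("-", revcomp(source.seq))):
        enc = encode(oriented)
        cov_s = source.coverage if strand == "+" else source.coverage[::-1]
        for _ci, offset in _candidate_offsets(
            oriented, idx.index, idx.k, params.kmer_step, params.max_candidates
        ):
            enc_t = idx.enc[0]
            lo, hi = max(0, offset), min(len(enc_t), offset + len(enc))
            if hi - lo < 25:
                continue
            seg_s = enc[lo - offset : hi - offset]
            seg_t = enc_t[lo:hi]
            conf = (
                (cov_s[lo - offset : hi - offset] >= params.min_extension_coverage)
                & (target.coverage[lo:hi] >= params.min_extension_coverage)
            )
            if int(conf.sum()) < 25:
                continue
            mism = int(
                np.count_nonzero(((seg_s != seg_t) | (seg_s == 4) | (seg_t == 4)) & conf)
            )
            if mism == 0:
                qualifying.append((offset, oriented, cov_s, strand))
    if len(qualifying) == 1:
        return qualifying[0]
    return None


def _cull_redundant(state: AssemblyState, params: MappingParams) -> bool:
    """Drop contigs that duplicate or starve better-supported contigs.

    Two situations leave junk contigs behind: (i) a seed read persisting as a
    stagnant contig fully contained in a grown consensus, and (ii) an
    error-bearing seed contig straddling a consensus end — it wins boundary
    reads by overlap but rejects most of them because of its own uncorrectable
    errors, starving the true contig's extension.  A contig is culled when
    >=90% of it matches another contig at >=95% identity, or when its median
    recruited coverage is below the extension threshold while it still
    overlaps a better-covered contig (its region stays represented).
    """
    if len(state.contigs) < 2:
        return False
    contigs = sorted(state.contigs, key=lambda c: (len(c.seq), c.id))
    keep: list[Contig] = []
    removed = False
    for contig in contigs:
        hosts = [
            c
            for c in state.contigs
            if c.id != contig.id and (len(c.seq), c.id) > (len(contig.seq), contig.id)
        ]
        # a contig whose median coverage stays below the extension threshold
        # after recruitment has essentially no exclusive read support: either
        # its reads prefer another contig or it is an unsalvageable seed read
        starving = float(np.median(contig.coverage)) < params.min_extension_coverage
        if starving or _overlaps_any(contig, hosts, params, min_cover_frac=0.9):
            removed = True
        else:
            keep.append(contig)
    if removed:
        state.contigs = sorted(keep, key=lambda c: c.id)
    return removed


def _overlaps_any(
    contig: Contig, others: list[Contig], params: MappingParams, min_cover_frac: float
) -> bool:
    """True when the contig matches another at >=95% identity over an overlap
    of at least ``max(min_overlap_nt, min_cover_frac * len(contig))``."""
    if not others:
        return False
    idx = _ContigIndex(others, params.kmer_size)
    seq = contig.seq
    required = max(params.min_overlap_nt, int(min_cover_frac * len(seq)))
    for _strand, oriented in (("+", seq), ("-", revcomp(seq))):
        enc = encode(oriented)
        for ci, offset in _candidate_offsets(
            oriented, idx.index, idx.k, params.kmer_step, params.max_candidates
        ):
            cenc = idx.enc[ci]
            lo, hi = max(0, offset), min(len(cenc), offset + len(enc))
            overlap = hi - lo
            if overlap < required:
                continue
            seg_r = enc[lo - offset : hi - offset]
            seg_c = cenc[lo:hi]
            mism = int(np.count_nonzero((seg_r != seg_c) | (seg_r == 4) | (seg_c == 4)))
            if mism <= 0.05 * overlap:
                return True
    return False


# ---------------------------------------------------------------------------
# one-call pipeline


def assemble(
    reads,
    reference: str,
    params: MappingParams | None = None,
    max_iter: int = 40,
) -> AssemblyState:
    """Seed against a heterologous reference, then iterate to convergence."""
    params = params or MappingParams()
    state = seed_map(reads, reference, params)
    if not state.contigs:
        warnings.warn("no reads recruited at seed stage; nothing to extend", stacklevel=2)
        return state
    return extend_iterate(state, reads, params, max_iter=max_iter)
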