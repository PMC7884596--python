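"""Three-step verification against chimeric (hybrid) hemocyanin assemblies.

Paralogous multi-FU hemocyanin transcripts contain highly similar internal
repeats, so a reference-guided assembly can erroneously fuse reads from two
paralogs into one consensus.  Three independent checks guard against this:

1. :func:`remap_low_stringency` — remap the full read set with permissive
   settings (anchor of >= 25 exactly matching nucleotides, mismatches allowed
   over up to 60% of the read beyond the anchor).  Over a true breakpoint many
   reads anchor on one side and disagree heavily on the other, and their
   anchor ends pile up at one coordinate; such clusters are flagged.
2. :func:`scan_identity_windows` — align two consensi and flag windows of
   near-identical sequence where reads could have been swapped.
3. :func:`check_pair_spanning` — require flagged repetitive windows to be
   bridged by read pairs whose mates sit in unique flanking sequence with a
   plausible implied fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .assembly import Contig, ReadHit, _as_read_list, _candidate_offsets


@dataclass(frozen=True)
class VerifyParams:
    low_min_overlap_nt: int = 25
    max_offoverlap_mismatch_fraction: float = 0.60
    identity_window_nt: int = 100
    identity_flag_threshold: float = 0.95
    min_spanning_pairs: int = 1
    # breakpoint-cluster statistic
    disagreement_fraction: float = 0.10
    cluster_radius_nt: int = 50
    min_support: int = 3
    kmer_size: int = 13
    kmer_step: int = 7
    max_candidates: int = 8


@dataclass
class MisassemblyFlag:
    contig_id: str
    position: int  # 1-based consensus coordinate of the breakpoint cluster
    support: int
    mean_disagreement: float
    verdict: str  # "suspect"


@dataclass
class IdentityWindow:
    start_a: int  # 1-based inclusive on sequence a
    end_a: int
    identity: float
    flagged: bool


@dataclass
class IdentityWindowReport:
    windows: list[IdentityWindow]

    @property
    def flagged(self) -> list[IdentityWindow]:
        return [w for w in self.windows if w.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.start_a, w.end_a, w.identity, w.flagged) for w in self.windows],
            columns=["start", "end", "identity", "flagged"],
        )


@dataclass
class SpanWindow:
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    n_spanning_pairs: int
    passed: bool


@dataclass
class SpanReport:
    windows: list[SpanWindow]

    @property
    def all_passed(self) -> bool:
        return all(w.passed for w in self.windows)


# ---------------------------------------------------------------------------
# (i) low-stringency remapping


def _normalize_contigs(contigs) -> list[tuple[str, str]]:
    if isinstance(contigs, dict):
        return sorted(contigs.items())
    out = []
    for item in contigs:
        if isinstance(item, Contig):
            out.append((item.id, item.seq))
        elif isinstance(item, tuple):
            out.append((item[0], item[1]))
        else:
            raise TypeError("contigs must be Contig, (id, seq) or dict")
    return sorted(out)


def _longest_match_run(mismatch: np.ndarray) -> tuple[int, int]:
    """(start, end) of the longest run of matches, end exclusive."""
    bad = np.flatnonzero(mismatch)
    if bad.size == 0:
        return 0, len(mismatch)
    starts = np.concatenate(([0], bad + 1))
    ends = np.concatenate((bad, [len(mismatch)]))
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def remap_low_stringency(reads, contigs, params: VerifyParams | None = None) -> list[MisassemblyFlag]:
    """Flag breakpoint clusters by permissive remapping of the full read set.

    A read is placed where it holds an exact anchor of at least
    ``low_min_overlap_nt`` nucleotides; up to ``max_offoverlap_mismatch_fraction``
    of the read may disagree beyond the anchor.  Reads whose off-anchor
    disagreement exceeds ``disagreement_fraction`` of the read length vote for
    a breakpoint at the anchor boundary facing the disagreement; votes within
    ``cluster_radius_nt`` of each other form a cluster, and clusters with at
    least ``min_support`` reads are reported as suspect.
    """
    params = params or VerifyParams()
    read_list = _as_read_list(reads)
    if not read_list:
        raise ValueError("empty read set")
    contig_list = _normalize_contigs(contigs)
    enc_contigs = [encode(seq) for _cid, seq in contig_list]
    index: dict[str, list] = {}
    k = params.kmer_size
    for ci, (_cid, seq) in enumerate(contig_list):
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ci, pos))

    votes: dict[int, list[tuple[int, float]]] = {ci: [] for ci in range(len(contig_list))}
    for rid, seq in read_list:
        best = None  # (anchor_len, -mismatches, ci, offset, anchor, mism_frac)
        rl = len(seq)
        for _strand, oriented in (("+", seq), ("-", revcomp(seq))):
            enc = encode(oriented)
            for ci, offset in _candidate_offsets(
                oriented, index, k, params.kmer_step, params.max_candidates
            ):
                cenc = enc_contigs[ci]
                lo, hi = max(0, offset), min(len(cenc), offset + rl)
                if hi - lo < params.low_min_overlap_nt:
                    continue
                seg_r = enc[lo - offset : hi - offset]
                seg_c = cenc[lo:hi]
                mism = (seg_r != seg_c) | (seg_r == 4) | (seg_c == 4)
                a0, a1 = _longest_match_run(mism)
                if a1 - a0 < params.low_min_overlap_nt:
                    continue
                n_mism = int(mism.sum())
                frac = n_mism / rl
                if frac > params.max_offoverlap_mismatch_fraction:
                    continue
                cand = (a1 - a0, -n_mism, ci, offset, (a0 + lo, a1 + lo), frac)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            continue
        _alen, neg_mm, ci, offset, (anchor_lo, anchor_hi), frac = best
        if frac < params.disagreement_fraction:
            continue
        # point the vote at the anchor edge adjacent to the disagreement
        cenc = enc_contigs[ci]
        left_bad = anchor_lo - max(0, offset)
        right_bad = min(len(cenc), offset + rl) - anchor_hi
        position = anchor_hi if right_bad >= left_bad else anchor_lo
        votes[ci].append((position, frac))

    flags: list[MisassemblyFlag] = []
    for ci, (cid, _seq) in enumerate(contig_list):
        entries = sorted(votes[ci])
        cluster: list[tuple[int, float]] = []
        for entry in entries + [(None, None)]:
            if cluster and (entry[0] is None or entry[0] - cluster[-1][0] > params.cluster_radius_nt):
                if len(cluster) >= params.min_support:
                    positions = [p for p, _f in cluster]
                    flags.append(
                        MisassemblyFlag(
                            contig_id=cid,
                            position=int(np.median(positions)) + 1,
                            support=len(cluster),
                            mean_disagreement=float(np.mean([f for _p, f in cluster])),
                            verdict="suspect",
                        )
                    )
                cluster = []
            if entry[0] is not None:
                cluster.append(entry)
    return flags


# ---------------------------------------------------------------------------
# (ii) identity-window scan


def scan_identity_windows(
    contig_a: str, contig_b: str, params: VerifyParams | None = None
) -> IdentityWindowReport:
    """Sliding-window gapless identity between two consensi after anchoring.

    Step is half the window.  Windows at identity >= the flag threshold mark
    regions where paralog reads are interchangeable (hybrid risk).
    """
    params = params or VerifyParams()
    w = params.identity_window_nt
    if len(contig_a) < w or len(contig_b) < w:
        raise ValueError("sequences shorter than the identity window")
    if len(contig_a) == len(contig_b):
        a_pos = np.arange(len(contig_a))
        match = encode(contig_a) == encode(contig_b)
    else:
        a_pos, match = _aligned_columns(contig_a, contig_b)
    step = max(1, w // 2)
    windows = []
    for start in range(0, len(match) - w + 1, step):
        ident = float(match[start : start + w].mean())
        windows.append(
            IdentityWindow(
                start_a=int(a_pos[start]) + 1,
                end_a=int(a_pos[start + w - 1]) + 1,
                identity=ident,
                flagged=ident >= params.identity_flag_threshold,
            )
        )
    return IdentityWindowReport(windows=windows)


def _aligned_columns(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3, open_gap_score=-5, extend_gap_score=-2
    )
    alignment = aligner.align(a, b)[0]
    a_idx, b_idx = alignment.indices  # -1 marks a gap
    keep = (a_idx >= 0) & (b_idx >= 0)
    enc_a, enc_b = encode(a), encode(b)
    match = enc_a[a_idx[keep]] == enc_b[b_idx[keep]]
    return a_idx[keep], match


# ---------------------------------------------------------------------------
# (iii) paired-mate spanning


def check_pair_spanning(
    placements: dict[str, ReadHit],
    contigs,
    flagged_windows: list[tuple[str, int, int]],
    fragment_mean: float,
    fragment_sd: float,
    params: VerifyParams | None = None,
) -> SpanReport:
    """Count read pairs bridging each flagged window through unique flanks.

    ``flagged_windows`` are (contig_id, start, end), 0-based half-open.  A pair
    spans a window when one mate lies wholly in unique sequence left of it,
    the other wholly in unique sequence right of it, both on the same contig,
    and the implied fragment length is within mean +/- 4 sd.  Unique sequence
    is everything outside all flagged windows of that contig.
    """
    params = params or VerifyParams()
    contig_list = dict(_normalize_contigs(contigs))
    by_contig_windows: dict[str, list[tuple[int, int]]] = {}
    for cid, start, end in flagged_windows:
        by_contig_windows.setdefault(cid, []).append((start, end))

    pairs: dict[str, list[ReadHit]] = {}
    for rid, hit in placements.items():
        pairs.setdefault(rid.rsplit("/", 1)[0], []).append(hit)

    lo_frag = fragment_mean - 4 * fragment_sd
    hi_frag = fragment_mean + 4 * fragment_sd

    windows_out: list[SpanWindow] = []
    for cid, start, end in flagged_windows:
        if cid not in contig_list:
            raise KeyError(f"unknown contig {cid!r} in flagged windows")
        others = [wnd for wnd in by_contig_windows[cid]]
        count = 0
        for mates in pairs.values():
            if len(mates) != 2:
                continue
            m1, m2 = mates
            if m1.contig_id != cid or m2.contig_id != cid:
                continue
            for left, right in ((m1, m2), (m2, m1)):
                l_lo, l_hi = left.start, left.start + left.overlap_length + left.left_overhang + left.right_overhang
                r_lo, r_hi = right.start, right.start + right.overlap_length + right.left_overhang + right.right_overhang
                if l_hi <= start and r_lo >= end:
                    if any(_intersects(l_lo, l_hi, ws, we) or _intersects(r_lo, r_hi, ws, we) for ws, we in others):
                        continue
                    frag = r_hi - l_lo
                    if lo_frag <= frag <= hi_frag:
                        count += 1
                        break
        windows_out.append(
            SpanWindow(
                contig_id=cid,
                start=start + 1,
                end=end,
                n_spanning_pairs=count,
                passed=count >= params.min_spanning_pairs,
            )
        )
    return SpanReport(windows=windows_out)


def _intersects(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi
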