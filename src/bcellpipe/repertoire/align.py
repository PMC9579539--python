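"""Germline V/J segment assignment by local alignment, and mutation counting.

Scoring is fixed to match +1 / mismatch -1 / gap open -2 / gap extend -1
(configurable), with ties broken by reference order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from ..synthetic.germline import V_CDR3_LEN, V_REGIONS, GermlineReference


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    v_min_score: float = 25.0
    j_min_score: float = 10.0


@dataclass
class SegmentCall:
    """Best V and J assignments for one contig.

    Spans are 0-based half-open coordinates on the contig; ``junction_span``
    covers the CDR3 nucleotides (V-encoded tail through the V-J joint).
    """

    v_gene: str
    v_score: float
    j_gene: str
    j_score: float
    v_span: tuple[int, int]
    j_span: tuple[int, int]
    junction_span: tuple[int, int]
    v_tie: bool = False
    j_tie: bool = False


class UnproductiveCallError(ValueError):
    """No germline segment scores above the configured minimum."""


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _best_segment(aligner, contig: str, segments) -> tuple[str, float, bool]:
    best_name, best_score, tie = None, float("-inf"), False
    for seg in segments:
        score = aligner.score(contig, seg.seq)
        if score > best_score:
            best_name, best_score, tie = seg.name, score, False
        elif score == best_score:
            tie = True  # reference order keeps the earlier hit
    return best_name, best_score, tie


def _contig_span(aligner, contig: str, ref_seq: str) -> tuple[int, int]:
    aln = aligner.align(contig, ref_seq)[0]
    blocks = aln.aligned[0]  # blocks on the contig (alignment target)
    return int(blocks[0][0]), int(blocks[-1][1])


def assign_germline(
    contig_nt: str,
    reference: GermlineReference,
    params: AlignParams | None = None,
) -> SegmentCall:
    """Pick the best-scoring V and J germline segments for a contig."""
    if params is None:
        params = AlignParams()
    if len(contig_nt) < 50:
        raise ValueError("contig shorter than 50 nt")
    if not reference.v_segments or not reference.j_segments:
        raise ValueError("empty germline reference")

    aligner = _make_aligner(params)
    v_name, v_score, v_tie = _best_segment(aligner, contig_nt, reference.v_segments)
    j_name, j_score, j_tie = _best_segment(aligner, contig_nt, reference.j_segments)
    if v_score < params.v_min_score or j_score < params.j_min_score:
        raise UnproductiveCallError(
            f"best V/J scores {v_score}/{j_score} below minima "
            f"{params.v_min_score}/{params.j_min_score}"
        )

    v_span = _contig_span(aligner, contig_nt, reference.get(v_name).seq)
    j_span = _contig_span(aligner, contig_nt, reference.get(j_name).seq)
    junction = (v_span[1] - 3 * V_CDR3_LEN, j_span[0])
    return SegmentCall(
        v_gene=v_name, v_score=v_score, j_gene=j_name, j_score=j_score,
        v_span=v_span, j_span=j_span, junction_span=junction,
        v_tie=v_tie, j_tie=j_tie,
    )


def assign_germline_many(
    sequences: dict[str, str],
    reference: GermlineReference,
    params: AlignParams | None = None,
) -> dict[str, SegmentCall]:
    """Assign many contigs, memoizing on the nucleotide sequence.

    Unmutated repertoires collapse to a handful of unique sequences, so the
    cache turns a quadratic workload into a constant one.
    """
    cache: dict[str, SegmentCall] = {}
    out: dict[str, SegmentCall] = {}
    for cid, seq in sequences.items():
        if seq not in cache:
            cache[seq] = assign_germline(seq, reference, params)
        out[cid] = cache[seq]
    return out


def count_mutations(
    contig_nt: str,
    reference: GermlineReference,
    call: SegmentCall,
    params: AlignParams | None = None,
) -> dict[str, int]:
    """Count substitutions vs the called germline, split by region.

    V-segment positions are classified into CDR1/CDR2/CDR3 or framework by
    the reference amino-acid spans; all J positions count as framework.
    """
    if params is None:
        params = AlignParams()
    aligner = _make_aligner(params)
    counts = {"CDR1": 0, "CDR2": 0, "CDR3": 0, "framework": 0}

    v_seq = reference.get(call.v_gene).seq
    aln = aligner.align(contig_nt, v_seq)[0]
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            if contig_nt[ts + off] != v_seq[qs + off]:
                counts[_v_region(qs + off)] += 1

    j_seq = reference.get(call.j_gene).seq
    aln = aligner.align(contig_nt, j_seq)[0]
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            if contig_nt[ts + off] != j_seq[qs + off]:
                counts["framework"] += 1
    return counts


def _v_region(nt_pos: int) -> str:
    aa = nt_pos // 3 + 1  # 1-based residue number on the V segment
    for region, (lo, hi) in V_REGIONS.items():
        if lo <= aa <= hi:
            return region
    return "framework"
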