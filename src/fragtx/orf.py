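"""Six-frame longest-ORF detection with four completeness classes.

Reading is allowed to start and end outside the given sequence: a frame may
open at the sequence edge without an ATG (``missing_start``) and/or run off
the edge without reaching a stop (``missing_stop``). The reported call is
the longest reading segment over all six frames; ties break by frame order
+1, +2, +3, -1, -2, -3, then by leftmost start. Peptides exclude the stop;
codons containing N match neither start nor stop. Standard nuclear code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .io_utils import reverse_complement

STOPS = {"TAA", "TAG", "TGA"}
START = "ATG"

COMPLETE = "complete"
MISSING_START = "missing_start"
MISSING_STOP = "missing_stop"
MISSING_BOTH = "missing_both"


@dataclass
class OrfCall:
    transcript_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 on the reverse complement
    start: int  # 0-based half-open on the transcript's forward coordinates
    end: int
    peptide: str
    orf_class: str

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


def _frame_candidates(codons: list[str], at_left_edge: bool, at_right_edge: bool):
    """(start_codon_idx, end_codon_idx_exclusive, class) per reading segment.

    ``codons`` is the frame's codon list; edge flags say whether the frame
    touches the sequence boundary on that side (frames always do on the
    left by construction; the right edge holds when no trailing bases are
    dropped... both are passed explicitly for clarity).
    """
    stops = [i for i, c in enumerate(codons) if c in STOPS]
    out = []
    bounds = [-1] + stops  # segment starts just after each stop (or the edge)
    for bi, left_stop in enumerate(bounds):
        seg_start = left_stop + 1
        if bi < len(stops):
            seg_end, has_stop = stops[bi], True
        else:
            seg_end, has_stop = len(codons), False
        if seg_start > seg_end:
            continue
        # candidate a: begin at the first ATG in the segment
        atg = next(
            (i for i in range(seg_start, seg_end) if codons[i] == START), None
        )
        if atg is not None:
            out.append((atg, seg_end, COMPLETE if has_stop else MISSING_STOP))
        # candidate b: begin at the sequence edge (leading segment only)
        if left_stop == -1 and at_left_edge and (atg is None or atg != seg_start):
            if seg_end > seg_start:
                out.append(
                    (seg_start, seg_end, MISSING_START if has_stop else MISSING_BOTH)
                )
    return out


def longest_orf(sequence: str, transcript_id: str = "") -> OrfCall | None:
    """Longest reading segment over all six frames, or None if < 1 codon."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        return None
    # anchored readings (a start codon and/or a stop) outrank fully open
    # ones; within a class-rank the longest wins, then frame order, then
    # leftmost start on the frame's own strand
    best: tuple[int, int, int, int] | None = None
    best_call: OrfCall | None = None
    frames = [(+1, seq), (+2, seq), (+3, seq)]
    rc = reverse_complement(seq)
    frames += [(-1, rc), (-2, rc), (-3, rc)]
    for rank, (frame, s) in enumerate(frames):
        off = abs(frame) - 1
        codons = [s[i : i + 3] for i in range(off, n - 2, 3)]
        if not codons:
            continue
        for c_start, c_end, klass in _frame_candidates(codons, True, True):
            n_codons = c_end - c_start
            if n_codons <= 0:
                continue
            # coordinates on the frame's own strand
            a = off + 3 * c_start
            b = off + 3 * c_end + (3 if klass in (COMPLETE, MISSING_START) else 0)
            b = min(b, n)
            if frame > 0:
                start, end = a, b
            else:  # mirror to forward coordinates
                start, end = n - b, n - a
            key = (0 if klass != MISSING_BOTH else 1, -n_codons, rank, a)
            if best is None or key < best:
                pep = str(Seq(s[off + 3 * c_start : off + 3 * c_end]).translate())
                best = key
                best_call = OrfCall(
                    transcript_id=transcript_id,
                    frame=frame,
                    start=start,
                    end=end,
                    peptide=pep,
                    orf_class=klass,
                )
    return best_call


def classify_orfs(
    transcripts: dict[str, str],
    min_codons: int = 10,
    histogram_bin: int = 50,
) -> tuple[dict[str, OrfCall], Counter, Counter]:
    """One longest-ORF call per transcript, class counts, length histogram.

    Calls shorter than ``min_codons`` codons are not reported (the short-ORF
    pileup near 50 aa is dominated by spurious reading frames in UTR-like
    sequence). The histogram bins peptide lengths at ``histogram_bin`` aa.
    """
    calls: dict[str, OrfCall] = {}
    class_counts: Counter = Counter()
    hist: Counter = Counter()
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        if len(seq) < 3:
            continue
        call = longest_orf(seq, tid)
        if call is None or call.n_codons < min_codons:
            continue
        calls[tid] = call
        class_counts[call.orf_class] += 1
        hist[(len(call.peptide) // histogram_bin) * histogram_bin] += 1
    return calls, class_counts, hist
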