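"""Merging of long-read and short-read transcript sets.

The long-read assembly acts as a scaffold. Isoforms differing only in
terminal extensions are collapsed; short-read cDNAs are screened against
the collapsed contigs by local alignment (matched iff >= ``min_identity``
over >= ``min_match_length`` nucleotides, both strands); unmatched
multi-exon short-read models are kept while unmatched single-exon ones are
dropped (pseudogene/duplication confounders); the retained pool is
co-assembled by the collapse rule; and singletons supported only by
single-exon short-read evidence are removed. Every drop/keep decision is
logged so the report is recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .io_utils import TranscriptModel, reverse_complement


@dataclass
class MergeParams:
    min_identity: float = 0.95
    min_match_length: int = 50
    min_overlap_collapse: int = 40
    seed_k: int = 16  # seed-hit significance stand-in for an E-value cutoff

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_match_length < 1:
            raise ValueError("min_match_length must be >= 1")


@dataclass
class MergeReport:
    n_matched_short: int = 0
    n_unmatched_multi_exon_kept: int = 0
    n_unmatched_single_exon_dropped: int = 0
    n_assembled_contigs: int = 0
    n_singletons_kept: int = 0
    n_singletons_dropped_single_exon: int = 0
    final_transcripts: int = 0
    decision_log: list[dict] = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -3
    al.extend_gap_score = -2
    return al


def _identity_windows(alignment, min_len: int, min_ident: float) -> tuple[int, float, bool]:
    """Best (length, identity) column window of a local alignment and
    whether some window of >= min_len columns reaches min_ident."""
    a, b = alignment[0], alignment[1]
    cols = [x == y and x != "-" for x, y in zip(a, b)]
    n = len(cols)
    if n == 0:
        return 0, 0.0, False
    matches = sum(cols)
    best = (n, matches / n)
    if n >= min_len and matches / n >= min_ident:
        return n, matches / n, True
    # scan windows of exactly min_len (longer qualifying windows contain one)
    if n >= min_len:
        w = sum(cols[:min_len])
        if w / min_len >= min_ident:
            return min_len, w / min_len, True
        for i in range(1, n - min_len + 1):
            w += cols[i + min_len - 1] - cols[i - 1]
            if w / min_len >= min_ident:
                return min_len, w / min_len, True
    return best[0], best[1], False


def local_match(query: str, subject: str, params: MergeParams) -> tuple[bool, float, int]:
    """Does any local alignment reach the identity/length thresholds?

    Returns ``(matched, identity, length)`` of the best qualifying (or
    best overall) alignment over both query strands.
    """
    al = _aligner()
    best = (False, 0.0, 0)
    for q in (query, reverse_complement(query)):
        try:
            alns = al.align(q, subject)
            if len(alns) == 0:
                continue
            aln = alns[0]
        except (ValueError, OverflowError):
            continue
        length, ident, ok = _identity_windows(
            aln, params.min_match_length, params.min_identity
        )
        if ok:
            return True, ident, length
        if ident * length > best[1] * best[2]:
            best = (False, ident, length)
    return best


def _shares_seed(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    rc = reverse_complement(a)
    kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def homology_screen(
    queries: dict[str, str],
    subjects: dict[str, str],
    params: MergeParams,
) -> tuple[list[str], list[str], list[tuple[str, str, float, int]]]:
    """Screen queries against subjects by thresholded local alignment.

    A query is matched iff some subject alignment spans at least
    ``min_match_length`` columns at ``min_identity``; candidate pairs are
    pre-filtered by an exact shared k-mer (the seed-significance stand-in
    for a BLAST E-value cutoff). Returns matched ids, unmatched ids, and a
    best-hit table scored by identity x length.
    """
    matched, unmatched, hits = [], [], []
    for qid in sorted(queries):
        best = None
        for sid in sorted(subjects):
            if not _shares_seed(queries[qid], subjects[sid], params.seed_k):
                continue
            ok, ident, length = local_match(queries[qid], subjects[sid], params)
            if ok and (best is None or ident * length > best[2] * best[3]):
                best = (qid, sid, ident, length)
        if best is not None:
            matched.append(qid)
            hits.append(best)
        else:
            unmatched.append(qid)
    return matched, unmatched, hits


# ---------------------------------------------------------------------------
# terminal-variant collapse (containment + dovetail merging)


def _contained(short: str, long_: str, max_div: float) -> bool:
    """Is `short` an infix of `long_` within the divergence budget?"""
    if len(short) > len(long_):
        return False
    k = max(0, int(len(short) * max_div))
    for s in (short, reverse_complement(short)):
        res = edlib.align(s, long_, mode="HW", task="distance", k=k)
        if res["editDistance"] != -1:
            return True
    return False


def collapse_isoforms(
    sequences: dict[str, str], params: MergeParams
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Collapse sequences whose differences are confined to the termini.

    A sequence contained in a longer one (within the identity budget)
    merges into it; two sequences with a proper suffix-prefix overlap of
    >= ``min_overlap_collapse`` bases at ``min_identity`` merge into their
    superstring. Internally divergent sequences stay separate. Returns the
    collapsed contigs and the membership map contig -> source ids.
    """
    max_div = 1.0 - params.min_identity
    order = sorted(sequences, key=lambda r: (-len(sequences[r]), r))
    reps: list[str] = []  # representative ids, sequence in `out`
    out: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    from .longread import best_overlap  # local import to avoid a cycle

    for rid in order:
        seq = sequences[rid]
        placed = False
        for rep in reps:
            if _contained(seq, out[rep], max_div):
                members[rep].append(rid)
                placed = True
                break
            for s in (seq, reverse_complement(seq)):
                o, ident = best_overlap(
                    out[rep], s, params.min_overlap_collapse, params.min_identity
                )
                if o >= params.min_overlap_collapse and o < min(len(out[rep]), len(s)):
                    out[rep] = out[rep] + s[o:]
                    members[rep].append(rid)
                    placed = True
                    break
                o, ident = best_overlap(
                    s, out[rep], params.min_overlap_collapse, params.min_identity
                )
                if o >= params.min_overlap_collapse and o < min(len(out[rep]), len(s)):
                    out[rep] = s + out[rep][o:]
                    members[rep].append(rid)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            reps.append(rid)
            out[rid] = seq
            members[rid] = [rid]
    return out, members


# ---------------------------------------------------------------------------


def merge_datasets(
    longread_contigs: dict[str, str],
    shortread_models: list[TranscriptModel],
    shortread_cdna: dict[str, str],
    params: MergeParams,
) -> tuple[MergeReport, dict[str, str], dict[str, str]]:
    """Merge the two platform transcript sets by the published rule order.

    Returns (report, merged sequences, provenance per merged id). The
    short-read models must carry exon counts; their cDNA sequences are
    given separately keyed by transcript id.
    """
    n_exons = {m.transcript_id: m.n_exons for m in shortread_models}
    for tid in shortread_cdna:
        if tid not in n_exons:
            raise KeyError(f"short-read cDNA {tid} lacks a model with an exon count")
    log: list[dict] = []
    report = MergeReport(decision_log=log)

    # 1. screen short-read cDNAs against the collapsed long-read contigs
    matched, unmatched, hits = homology_screen(
        shortread_cdna, longread_contigs, params
    )
    report.n_matched_short = len(matched)
    for qid, sid, ident, length in hits:
        log.append(
            {"step": "screen", "id": qid, "action": "matched", "subject": sid,
             "identity": round(ident, 4), "length": length}
        )

    # 2. partition unmatched by exon count
    kept_multi, dropped = [], []
    for tid in unmatched:
        if n_exons[tid] >= 2:
            kept_multi.append(tid)
            log.append({"step": "partition", "id": tid, "action": "kept_multi_exon"})
        else:
            dropped.append(tid)
            log.append(
                {"step": "partition", "id": tid, "action": "dropped_single_exon"}
            )
    report.n_unmatched_multi_exon_kept = len(kept_multi)
    report.n_unmatched_single_exon_dropped = len(dropped)

    # 3. co-assemble long-read contigs + matched short + kept multi-exon short
    pool = dict(longread_contigs)
    for tid in matched + kept_multi:
        pool[tid] = shortread_cdna[tid]
    contigs, membership = collapse_isoforms(pool, params)

    def origin(member_id: str) -> str:
        return "longread" if member_id in longread_contigs else "shortread"

    merged: dict[str, str] = {}
    provenance: dict[str, str] = {}
    singleton_ids: list[str] = []
    for rep, mem in membership.items():
        origins = {origin(m) for m in mem}
        if len(mem) > 1:
            report.n_assembled_contigs += 1
            merged[rep] = contigs[rep]
            provenance[rep] = (
                "combined" if len(origins) == 2 else f"{next(iter(origins))}_only"
            )
            log.append({"step": "coassembly", "id": rep, "action": "assembled",
                        "members": len(mem)})
        else:
            singleton_ids.append(rep)

    # 4. drop singletons supported only by single-exon short-read evidence
    for rep in singleton_ids:
        if origin(rep) == "shortread" and n_exons[rep] < 2:
            report.n_singletons_dropped_single_exon += 1
            log.append({"step": "singletons", "id": rep,
                        "action": "dropped_single_exon_shortread"})
        else:
            report.n_singletons_kept += 1
            merged[rep] = contigs[rep]
            provenance[rep] = (
                "longread_only" if origin(rep) == "longread"
                else "shortread_only_multiexon"
            )
            log.append({"step": "singletons", "id": rep, "action": "kept"})

    report.final_transcripts = report.n_assembled_contigs + report.n_singletons_kept
    assert report.final_transcripts == len(merged)
    return report, merged, provenance


def compare_annotation(
    set_a: dict[str, str], set_b: dict[str, str], params: MergeParams
) -> tuple[int, int]:
    """Directional reciprocal counts: (A members hit in B, B members hit in A)."""
    a_hits, _, _ = homology_screen(set_a, set_b, params)
    b_hits, _, _ = homology_screen(set_b, set_a, params)
    return len(a_hits), len(b_hits)
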