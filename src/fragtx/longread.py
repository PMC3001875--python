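"""Greedy overlap-layout-consensus assembly of long cDNA reads.

Reads are joined by suffix-prefix overlaps (either orientation) of at
least ``min_overlap`` bases at ``min_identity``; connected components of
the overlap graph are reported as isogroups (putative genes) and maximal
unambiguous paths through a component as isotigs (putative isoforms).
Includes N50 and assembly saturation analytics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_utils import reverse_complement


@dataclass
class Isotig:
    isotig_id: str
    isogroup_id: str
    sequence: str
    member_read_ids: list[str]


@dataclass
class SaturationPoint:
    n_reads: int
    n_isogroups: int
    n_isotigs: int
    n50: int
    mean_contig_length: float


def best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> tuple[int, float]:
    """Best suffix(a)-prefix(b) overlap length and identity (0 if none).

    Exhaustive over all overlap lengths; quadratic, used as the reference
    implementation and for small inputs.
    """
    best = (0, 0.0)
    max_o = min(len(a), len(b))
    for o in range(max_o, min_overlap - 1, -1):
        sa = a[len(a) - o :]
        sb = b[:o]
        matches = sum(x == y for x, y in zip(sa, sb))
        ident = matches / o
        if ident >= min_identity:
            return o, ident
    return best


def _kmer_positions(seq: str, k: int = 16) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(max(0, len(seq) - k + 1)):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _fast_overlap(
    a: str,
    b: str,
    pb: dict[str, list[int]],
    min_overlap: int,
    min_identity: float,
    k: int = 16,
) -> tuple[int, float]:
    """Like :func:`best_overlap` but only on shared-k-mer diagonals."""
    diags: set[int] = set()
    for i in range(max(0, len(a) - k + 1)):
        for j in pb.get(a[i : i + k], ()):
            diags.add(i - j)
    max_o = min(len(a), len(b))
    best_o = 0
    best_ident = 0.0
    for d in sorted(diags):  # small d = large overlap first
        o = len(a) - d
        if o < min_overlap or o > max_o:
            continue
        sa = a[len(a) - o :]
        sb = b[:o]
        matches = sum(x == y for x, y in zip(sa, sb))
        if matches / o >= min_identity and o > best_o:
            best_o, best_ident = o, matches / o
    return best_o, best_ident


def _seed_pairs(seqs: dict[str, str], k: int = 16) -> set[tuple[str, str]]:
    """Candidate read pairs sharing at least one exact k-mer."""
    table: dict[str, list[str]] = {}
    for rid, s in seqs.items():
        for i in range(0, max(1, len(s) - k + 1)):
            table.setdefault(s[i : i + k], []).append(rid)
    pairs: set[tuple[str, str]] = set()
    for ids in table.values():
        if len(ids) < 2:
            continue
        uniq = sorted(set(ids))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pairs.add((uniq[i], uniq[j]))
    return pairs


def overlap_graph(
    reads: dict[str, str], min_overlap: int = 40, min_identity: float = 0.95
) -> dict[tuple[str, str], tuple[int, float, str]]:
    """Suffix-prefix overlap edges between reads, both orientations.

    Returns ``{(id_a, id_b): (overlap, identity, orient)}`` where orient is
    ``"ff"`` (suffix of a onto prefix of b, both forward) or ``"fr"``
    (suffix of a onto prefix of revcomp(b)).
    """
    if min_overlap < 20:
        raise ValueError("min_overlap must be >= 20")
    if not 0.8 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.8, 1]")
    rc = {rid: reverse_complement(s) for rid, s in reads.items()}
    # seed over both orientations so fr overlaps are found
    seed_seqs = dict(reads)
    seed_seqs.update({rid + "~rc": s for rid, s in rc.items()})
    pairs = set()
    for x, y in _seed_pairs(seed_seqs):
        a = x.removesuffix("~rc")
        b = y.removesuffix("~rc")
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    pf = {rid: _kmer_positions(s) for rid, s in reads.items()}
    pr = {rid: _kmer_positions(s) for rid, s in rc.items()}
    edges: dict[tuple[str, str], tuple[int, float, str]] = {}
    for a, b in sorted(pairs):
        cands = [
            (_fast_overlap(reads[a], reads[b], pf[b], min_overlap, min_identity), (a, b), "ff"),
            (_fast_overlap(reads[b], reads[a], pf[a], min_overlap, min_identity), (b, a), "ff"),
            (_fast_overlap(reads[a], rc[b], pr[b], min_overlap, min_identity), (a, b), "fr"),
            (_fast_overlap(rc[b], reads[a], pf[a], min_overlap, min_identity), (b, a), "rf"),
        ]
        for (o, ident), pair, orient in cands:
            if o >= min_overlap:
                cur = edges.get(pair)
                if cur is None or o > cur[0]:
                    edges[pair] = (o, ident, orient)
    return edges


def _components(read_ids, edges) -> list[list[str]]:
    parent = {r: r for r in read_ids}

    def root(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[root(a)] = root(b)
    comps: dict[str, list[str]] = {}
    for r in read_ids:
        comps.setdefault(root(r), []).append(r)
    return [sorted(v) for _, v in sorted(comps.items())]


def _layout_paths(comp: list[str], edges) -> list[list[str]]:
    """Maximal unambiguous-ish paths: greedy walk by descending overlap."""
    out_edges: dict[str, list[tuple[int, str]]] = {}
    in_deg: dict[str, int] = {r: 0 for r in comp}
    for (a, b), (o, ident, orient) in edges.items():
        if a in in_deg and b in in_deg:
            out_edges.setdefault(a, []).append((o, b))
            in_deg[b] += 1
    starts = [r for r in comp if in_deg[r] == 0] or comp[:1]
    paths: list[list[str]] = []
    for start in starts:
        frontier = [[start]]
        while frontier:
            path = frontier.pop()
            outs = sorted(out_edges.get(path[-1], []), reverse=True)
            outs = [(o, b) for o, b in outs if b not in path]
            if not outs:
                paths.append(path)
                continue
            best_o = outs[0][0]
            # branch only on alternatives of comparable overlap
            for o, b in outs:
                if o >= 0.5 * best_o:
                    frontier.append(path + [b])
            if len(paths) + len(frontier) > 50:
                paths.extend(frontier)
                break
    # drop paths strictly contained in another
    paths.sort(key=len, reverse=True)
    kept: list[list[str]] = []
    for p in paths:
        sp = set(p)
        if not any(sp <= set(q) for q in kept):
            kept.append(p)
    return kept


def _consensus(path: list[str], seqs: dict[str, str], edges) -> str:
    """Chain reads along a forward-oriented path, keeping first-read bases
    on overlap disagreements (majority is 2-deep at most here)."""
    cur = seqs[path[0]]
    for a, b in zip(path, path[1:]):
        o = edges[(a, b)][0]
        nxt = seqs[b]
        cur = cur[: len(cur) - o] + cur[len(cur) - o :] + nxt[o:]
    return cur


def _find_containments(
    reads: dict[str, str], k: int = 16
) -> dict[str, tuple[str, str]]:
    """Absorb reads that are exact substrings of a longer (non-absorbed)
    read; returns read -> (container, orientation)."""
    order = sorted(reads, key=lambda r: (-len(reads[r]), r))
    kindex: dict[str, set[str]] = {}
    container: dict[str, tuple[str, str]] = {}
    for rid in order:
        s = reads[rid]
        rcs = reverse_complement(s)
        cands: set[str] = set()
        for seq in (s, rcs):
            for i in range(0, max(1, len(seq) - k + 1), max(1, k // 2)):
                cands |= kindex.get(seq[i : i + k], set())
        found = None
        for q in sorted(cands, key=lambda q: (len(reads[q]), q)):
            if s in reads[q]:
                found = (q, "f")
                break
            if rcs in reads[q]:
                found = (q, "r")
                break
        if found is not None:
            container[rid] = found
        else:
            for i in range(max(1, len(s) - k + 1)):
                kindex.setdefault(s[i : i + k], set()).add(rid)
    return container


def _transitive_reduction(edges: dict[tuple[str, str], tuple]) -> dict:
    """Drop a->c whenever a->b and b->c exist (Myers-style reduction)."""
    out: dict[str, set[str]] = {}
    for a, b in edges:
        out.setdefault(a, set()).add(b)
    removed = set()
    for a, succs in out.items():
        for b in succs:
            for c in out.get(b, ()):
                if c in succs and c != b:
                    removed.add((a, c))
    return {e: v for e, v in edges.items() if e not in removed}


def assemble_isotigs(
    graph: dict[tuple[str, str], tuple[int, float, str]],
    reads: dict[str, str],
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> list[Isotig]:
    """Greedy path consensus per connected component.

    Contained reads are absorbed first; each component is consistently
    oriented; proper forward dovetail overlaps are recomputed inside the
    component, transitively reduced, and one isotig is emitted per maximal
    path (branches yield one isotig per alternative).
    """
    container = _find_containments(reads)
    # union containment links with overlap edges to define isogroups
    link_edges = dict(graph)
    for rid, (q, _) in container.items():
        link_edges[(rid, q)] = (0, 1.0, "ff")
    comps = _components(sorted(reads), link_edges)
    isotigs: list[Isotig] = []
    for gi, comp in enumerate(comps, 1):
        isogroup = f"isogroup{gi:05d}"
        active = [r for r in comp if r not in container]
        if len(active) == 1:
            members = sorted(comp)
            isotigs.append(
                Isotig(
                    isotig_id=f"{isogroup}.t1",
                    isogroup_id=isogroup,
                    sequence=reads[active[0]],
                    member_read_ids=members,
                )
            )
            continue
        adj = dict(graph)
        for rid, (q, orient) in container.items():
            adj[(rid, q)] = (0, 1.0, "ff" if orient == "f" else "fr")
        oriented = _orient_component(comp, adj, reads)
        pos = {r: _kmer_positions(oriented[r]) for r in active}
        sub_edges: dict[tuple[str, str], tuple[int, float, str]] = {}
        for a in active:
            for b in active:
                if a == b:
                    continue
                o, ident = _fast_overlap(
                    oriented[a], oriented[b], pos[b], min_overlap, min_identity
                )
                # require a proper dovetail, not a containment artefact
                if o >= min_overlap and o < min(len(oriented[a]), len(oriented[b])):
                    sub_edges[(a, b)] = (o, ident, "ff")
        sub_edges = _transitive_reduction(sub_edges)
        paths = _layout_paths(active, sub_edges)
        seen: set[str] = set()
        ti = 0
        for path in paths:
            seq = _consensus(path, oriented, sub_edges)
            if seq in seen:
                continue
            seen.add(seq)
            ti += 1
            isotigs.append(
                Isotig(
                    isotig_id=f"{isogroup}.t{ti}",
                    isogroup_id=isogroup,
                    sequence=seq,
                    member_read_ids=path,
                )
            )
    return isotigs


def _orient_component(comp, graph, reads) -> dict[str, str]:
    """Flip reads so that all overlaps in the component are forward-forward."""
    flip: dict[str, bool] = {}
    adj: dict[str, list[tuple[str, str]]] = {}
    for (a, b), (o, ident, orient) in graph.items():
        if a in comp and b in comp:
            adj.setdefault(a, []).append((b, orient))
            adj.setdefault(b, []).append((a, orient))
    stack = [comp[0]]
    flip[comp[0]] = False
    while stack:
        x = stack.pop()
        for y, orient in adj.get(x, []):
            want = flip[x] if orient == "ff" else not flip[x]
            if y not in flip:
                flip[y] = want
                stack.append(y)
    return {
        r: (reverse_complement(reads[r]) if flip.get(r, False) else reads[r])
        for r in comp
    }


def n50(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2
    acc = 0
    for L in arr:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def saturation_curve(
    reads: dict[str, str],
    subset_sizes: list[int],
    seed: int = 0,
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> list[SaturationPoint]:
    """Assemble nested random subsets of increasing size and record metrics."""
    rng = np.random.default_rng(seed)
    ids = sorted(reads)
    order = [ids[i] for i in rng.permutation(len(ids))]
    points = []
    for size in subset_sizes:
        if size > len(ids):
            raise ValueError(f"subset size {size} exceeds read count {len(ids)}")
        subset = {r: reads[r] for r in order[:size]}
        if not subset:
            points.append(SaturationPoint(0, 0, 0, 0, 0.0))
            continue
        graph = overlap_graph(subset, min_overlap, min_identity)
        isotigs = assemble_isotigs(graph, subset, min_overlap, min_identity)
        lengths = [len(t.sequence) for t in isotigs]
        points.append(
            SaturationPoint(
                n_reads=size,
                n_isogroups=len({t.isogroup_id for t in isotigs}),
                n_isotigs=len(isotigs),
                n50=n50(lengths),
                mean_contig_length=float(np.mean(lengths)),
            )
        )
    return points
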