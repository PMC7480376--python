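"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is coded from the rule's plain statement, without reusing the
package's logic, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

BLOSUM62 = None  # loaded lazily


def filter_predicate(hit, evalue_max=1e-6, coverage_min=0.30) -> bool:
    """Per-hit keep/remove predicate, written directly from the rule."""
    span = hit.hmm_to - hit.hmm_from + 1
    cov = span / hit.model_length
    return hit.i_evalue <= evalue_max and cov >= coverage_min


def greedy_overlap_sim(hits, max_overlap_fraction=0.5):
    """Exhaustive greedy-by-E-value simulation of overlap resolution.

    Repeatedly takes the best remaining hit (lowest i-Evalue, then highest
    score, then model name, then position) and deletes every remaining hit
    conflicting with it, until none remain.
    """
    remaining = list(hits)
    accepted = []
    while remaining:
        remaining.sort(key=lambda h: (h.i_evalue, -h.score, h.model_name, h.ali_from, h.ali_to))
        best = remaining.pop(0)
        accepted.append(best)
        keep = []
        for h in remaining:
            ov = min(best.ali_to, h.ali_to) - max(best.ali_from, h.ali_from) + 1
            shorter = min(
                best.ali_to - best.ali_from + 1, h.ali_to - h.ali_from + 1
            )
            if ov <= 0 or ov <= max_overlap_fraction * shorter:
                keep.append(h)
        remaining = keep
    return sorted(accepted, key=lambda h: (h.ali_from, h.ali_to, h.model_name))


def brute_force_sus_pairs(genes):
    """All maximum-cardinality matchings of adjacent SusC/SusD genes.

    Returns the set of frozensets of (susC rank, susD rank) pairs over all
    maximal matchings, per contig combined.  Used to verify that greedy
    left-to-right pairing yields one maximum matching.
    """
    by_contig = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    all_edges = []
    for key, contig_genes in by_contig.items():
        contig_genes.sort(key=lambda g: g.rank)
        for a, b in zip(contig_genes, contig_genes[1:]):
            if b.rank != a.rank + 1:
                continue
            la, lb = a.has_label("SUSC"), a.has_label("SUSD")
            ra, rb = b.has_label("SUSC"), b.has_label("SUSD")
            if (la and rb) or (lb and ra):
                c, d = (a, b) if la else (b, a)
                all_edges.append((key, c.rank, d.rank))

    best = [frozenset()]
    best_size = 0

    def extend(i, used, chosen):
        nonlocal best, best_size
        if i == len(all_edges):
            if len(chosen) > best_size:
                best_size = len(chosen)
                best = [frozenset(chosen)]
            elif len(chosen) == best_size:
                best.append(frozenset(chosen))
            return
        key, c, d = all_edges[i]
        extend(i + 1, used, chosen)
        if (key, c) not in used and (key, d) not in used:
            extend(
                i + 1,
                used | {(key, c), (key, d)},
                chosen + [(key, c, d)],
            )

    extend(0, set(), [])
    return set(best), best_size


def brute_force_pul_scan(genes, pairs, window):
    """Exhaustive interval-merge enumeration of PUL regions.

    Marks every rank within ``window`` of a pair on a boolean array per
    contig, takes connected runs of marked ranks, and reports each run as
    (contig key, frozenset of anchor rank-pairs inside, frozenset of member
    ranks).
    """
    genes_by_contig = {}
    for g in genes:
        genes_by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    out = set()
    for key, contig_genes in genes_by_contig.items():
        contig_pairs = [
            p for p in pairs if (p.susc.genome_id, p.contig_id) == key
        ]
        if not contig_pairs:
            continue
        max_rank = max(g.rank for g in contig_genes)
        regions = []
        for p in contig_pairs:
            lo = max(0, min(p.susc.rank, p.susd.rank) - window)
            hi = min(max_rank, max(p.susc.rank, p.susd.rank) + window)
            regions.append(set(range(lo, hi + 1)))
        # transitive closure of region overlap (shared ranks); adjacent but
        # disjoint regions stay separate
        merged = []
        for reg in regions:
            grp = set(reg)
            rest = []
            for m in merged:
                if m & grp:
                    grp |= m
                else:
                    rest.append(m)
            merged = rest + [grp]
        for ranks in merged:
            anchors = frozenset(
                (min(p.susc.rank, p.susd.rank), max(p.susc.rank, p.susd.rank))
                for p in contig_pairs
                if p.susc.rank in ranks
            )
            members = frozenset(g.rank for g in contig_genes if g.rank in ranks)
            out.add((key, anchors, members))
    return out


def _blosum62():
    global BLOSUM62
    if BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return BLOSUM62


def sw_affine_identity(a: str, b: str, gap_open=11.0, gap_extend=1.0):
    """Quadratic-time Smith-Waterman with affine gaps; returns (score, pct identity).

    Gotoh three-state recursion with traceback preferring diagonal moves;
    percent identity = identical columns / alignment columns * 100 over the
    best-scoring local alignment.
    """
    mat = _blosum62()
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = mat[ai, b[j - 1]]
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            E[i, j] = max(e_open, e_ext)
            ptr[i, j, 1] = 0 if e_open >= e_ext else 1
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            F[i, j] = max(f_open, f_ext)
            ptr[i, j, 2] = 0 if f_open >= f_ext else 1
            diag = H[i - 1, j - 1] + s
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h == diag:
                ptr[i, j, 0] = 1  # diagonal
            elif h == F[i, j]:
                ptr[i, j, 0] = 2  # up
            elif h == E[i, j]:
                ptr[i, j, 0] = 3  # left
            else:
                ptr[i, j, 0] = 0  # local start
            if h > best:
                best, bi, bj = h, i, j
    if best == 0.0:
        return 0.0, 0.0
    i, j = bi, bj
    ident = cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            move = ptr[i, j, 0]
            if move == 0:
                break
            if move == 1:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i, j = i - 1, j - 1
            elif move == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            cols += 1
            came_open = ptr[i, j, 1] == 0
            j -= 1
            state = 0 if came_open else 1
        else:
            cols += 1
            came_open = ptr[i, j, 2] == 0
            i -= 1
            state = 0 if came_open else 2
    return float(best), 100.0 * ident / cols
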