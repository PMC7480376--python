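"""Domain-hit table I/O, hit filtering, overlap resolution, architectures.

The input format mirrors HMMER3 ``hmmscan --domtblout``: 22 fixed
whitespace-separated columns followed by a free-text description.  In that
orientation the *target* is the profile model and the *query* is the
protein.  Only a subset of the columns is consumed:

====== ======================= =========================
column meaning                  DomainHit field
====== ======================= =========================
1      target (model) name      model_name
3      tlen                     model_length
4      query (protein) name     protein_id
6      qlen                     protein_length
13     i-Evalue (independent)   i_evalue
14     domain bit score         score
16,17  hmm from/to              hmm_from, hmm_to
18,19  ali from/to              ali_from, ali_to
====== ======================= =========================

Filtering follows the dbCAN convention: a hit survives when its
independent (per-domain) E-value is at or below the cutoff *and* its
model-side span covers at least the minimum fraction of the profile HMM.
The per-domain i-Evalue is used rather than the full-sequence E-value
because the filter is applied hit-wise, and coverage is measured on the
model (``hmm_from..hmm_to`` over ``model_length``), not on the protein.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from .model import DomainHit, ProteinArchitecture

N_DOMTBL_COLUMNS = 22

#: Default dbCAN-style thresholds: remove hits with E > 1e-6 or
#: model coverage < 30%.  A hit at exactly E = 1e-6 is kept.
DEFAULT_EVALUE_MAX = 1e-6
DEFAULT_COVERAGE_MIN = 0.30


class DomtbloutParseError(ValueError):
    """Raised on a malformed domain-table line, carrying the line number."""


def parse_domtblout(path) -> list:
    """Parse a ``--domtblout``-style table into :class:`DomainHit` records.

    Lines starting with ``#`` are comments.  Raises
    :class:`DomtbloutParseError` (with the 1-based line number) when a data
    line has fewer than 22 columns or non-numeric numeric fields.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, N_DOMTBL_COLUMNS)
            if len(fields) < N_DOMTBL_COLUMNS:
                raise DomtbloutParseError(
                    f"{path}:{lineno}: expected {N_DOMTBL_COLUMNS} columns, "
                    f"found {len(fields)}"
                )
            try:
                hits.append(
                    DomainHit(
                        model_name=fields[0],
                        model_length=int(fields[2]),
                        protein_id=fields[3],
                        protein_length=int(fields[5]),
                        i_evalue=float(fields[12]),
                        score=float(fields[13]),
                        hmm_from=int(fields[15]),
                        hmm_to=int(fields[16]),
                        ali_from=int(fields[17]),
                        ali_to=int(fields[18]),
                    )
                )
            except ValueError as exc:
                raise DomtbloutParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domtblout(hits: Iterable[DomainHit], path) -> None:
    """Write hits in the 22-column ``--domtblout`` layout (plus description)."""
    with open(path, "w") as fh:
        fh.write(
            "# target_name accession tlen query_name accession qlen "
            "full_evalue full_score full_bias dom_n dom_of c_evalue i_evalue "
            "dom_score dom_bias hmm_from hmm_to ali_from ali_to env_from env_to "
            "acc description\n"
        )
        for h in hits:
            fh.write(
                f"{h.model_name} - {h.model_length} {h.protein_id} - "
                f"{h.protein_length} {h.i_evalue:.3g} {h.score:.1f} 0.0 1 1 "
                f"{h.i_evalue:.3g} {h.i_evalue:.3g} {h.score:.1f} 0.0 "
                f"{h.hmm_from} {h.hmm_to} {h.ali_from} {h.ali_to} "
                f"{h.ali_from} {h.ali_to} 0.90 -\n"
            )


def filter_hits(
    hits: Sequence[DomainHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> list:
    """Keep hits with ``i_evalue <= evalue_max`` and HMM coverage ``>= coverage_min``.

    Pure subset operation: input order is preserved and the filter is
    idempotent.
    """
    return [
        h for h in hits if h.i_evalue <= evalue_max and h.hmm_coverage >= coverage_min
    ]


def resolve_overlaps(
    hits_for_one_protein: Sequence[DomainHit],
    max_overlap_fraction: float = 0.5,
) -> list:
    """Greedily resolve conflicting domain hits on one protein.

    Two hits conflict when their protein-side alignment intervals overlap
    by more than ``max_overlap_fraction`` of the shorter interval.  Hits
    are admitted in order of increasing i-Evalue (ties: higher bit score,
    then lexicographic model name, then leftmost start); a hit conflicting
    with an already admitted hit is dropped.  Survivors are returned in
    N->C (ali_from) order.
    """
    pids = {h.protein_id for h in hits_for_one_protein}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    ordered = sorted(
        hits_for_one_protein,
        key=lambda h: (h.i_evalue, -h.score, h.model_name, h.ali_from, h.ali_to),
    )
    kept: list = []
    for h in ordered:
        if all(not _conflicts(h, k, max_overlap_fraction) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.ali_from, h.ali_to, h.model_name))
    return kept


def _conflicts(a: DomainHit, b: DomainHit, max_overlap_fraction: float) -> bool:
    overlap = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    if overlap <= 0:
        return False
    return overlap > max_overlap_fraction * min(a.ali_length, b.ali_length)


def build_architecture(hits_for_one_protein: Sequence[DomainHit], protein_id: str | None = None) -> ProteinArchitecture:
    """Assemble the ordered domain architecture of one protein.

    Input hits should already be filtered and overlap-resolved.  Domains
    are sorted by alignment start, so the result is invariant to input
    order.  An empty hit list yields an empty architecture (requires
    ``protein_id``).
    """
    if not hits_for_one_protein:
        if protein_id is None:
            raise ValueError("protein_id required for an empty architecture")
        return ProteinArchitecture(protein_id=protein_id, domains=())
    pids = {h.protein_id for h in hits_for_one_protein}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    ordered = sorted(
        hits_for_one_protein, key=lambda h: (h.ali_from, h.ali_to, h.model_name)
    )
    return ProteinArchitecture(
        protein_id=ordered[0].protein_id,
        domains=tuple(
            (h.model_name, h.model_class, h.ali_from, h.ali_to) for h in ordered
        ),
    )


def group_by_protein(hits: Iterable[DomainHit]) -> dict:
    """Group hits by protein_id, preserving encounter order of proteins."""
    grouped: dict = defaultdict(list)
    for h in hits:
        grouped[h.protein_id].append(h)
    return dict(grouped)


def build_architectures(
    hits: Iterable[DomainHit],
    max_overlap_fraction: float = 0.5,
    all_protein_ids: Iterable[str] | None = None,
) -> dict:
    """Filter-ready convenience: overlap-resolve and build per-protein architectures.

    ``all_protein_ids`` optionally adds hit-less proteins as empty
    architectures so that downstream tables cover every gene.
    """
    grouped = group_by_protein(hits)
    archs = {
        pid: build_architecture(resolve_overlaps(phits, max_overlap_fraction))
        for pid, phits in grouped.items()
    }
    if all_protein_ids is not None:
        for pid in all_protein_ids:
            if pid not in archs:
                archs[pid] = ProteinArchitecture(protein_id=pid, domains=())
    return archs


def write_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    """Write filtered hits as a plain TSV (stable column order)."""
    cols = [
        "protein_id", "protein_length", "model_name", "model_class",
        "model_length", "hmm_from", "hmm_to", "ali_from", "ali_to",
        "i_evalue", "score",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.protein_length}\t{h.model_name}\t"
                f"{h.model_class.value}\t{h.model_length}\t{h.hmm_from}\t"
                f"{h.hmm_to}\t{h.ali_from}\t{h.ali_to}\t{h.i_evalue:.6g}\t"
                f"{h.score:.1f}\n"
            )


def write_architectures_tsv(architectures: dict, path) -> None:
    """Write per-protein architecture strings as TSV, sorted by protein_id."""
    with open(path, "w") as fh:
        fh.write("protein_id\tarchitecture\tn_domains\n")
        for pid in sorted(architectures):
            arch = architectures[pid]
            fh.write(f"{pid}\t{arch.architecture_string}\t{len(arch)}\n")


def read_hits_tsv(path) -> list:
    """Read back a TSV written by :func:`write_hits_tsv`."""
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                DomainHit(
                    protein_id=f[idx["protein_id"]],
                    protein_length=int(f[idx["protein_length"]]),
                    model_name=f[idx["model_name"]],
                    model_length=int(f[idx["model_length"]]),
                    hmm_from=int(f[idx["hmm_from"]]),
                    hmm_to=int(f[idx["hmm_to"]]),
                    ali_from=int(f[idx["ali_from"]]),
                    ali_to=int(f[idx["ali_to"]]),
                    i_evalue=float(f[idx["i_evalue"]]),
                    score=float(f[idx["score"]]),
                )
            )
    return hits
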