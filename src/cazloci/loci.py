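"""Gene-neighborhood locus calling: PULs and cellulosome components.

Polysaccharide utilization loci (PULs) are Bacteroidetes gene clusters
organized around a tandem *susC/susD* pair — a TonB-dependent transporter
gene immediately adjacent to an outer-membrane glycan-binding lipoprotein
gene.  A PUL call takes every gene within a window of ±``window`` gene
predictions around the pair (measured in gene ranks from the pair's outer
boundaries, clipped at contig ends); pairs whose windows overlap on the
same contig are merged into one locus with multiple anchors.  Calls
without CAZyme cargo are retained but flagged, so that the anchored-locus
count and the CAZyme-associated count can be reported separately.

Cellulosome capability is a genome-level property: a genome must encode
at least one cohesin-bearing scaffoldin *and* at least one multimodular
dockerin enzyme (dockerin + GH/CE/PL catalytic module + a further
accessory module), mirroring the observation that cohesin-bearing bins
without multimodular dockerin enzymes cannot assemble a functional
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .architecture import CAZymeClassification
from .model import Gene, ModelClass

#: Default neighborhood half-width, in gene predictions.
DEFAULT_WINDOW = 5

CAZY_CARGO_CLASSES = ("GH", "GT", "CE", "PL", "AA", "CBM")


@dataclass(frozen=True)
class SusPair:
    """A tandem susC/susD gene pair (rank-adjacent, same contig)."""

    susc: Gene
    susd: Gene

    @property
    def min_rank(self) -> int:
        return min(self.susc.rank, self.susd.rank)

    @property
    def max_rank(self) -> int:
        return max(self.susc.rank, self.susd.rank)

    @property
    def contig_id(self) -> str:
        return self.susc.contig_id


@dataclass
class PULCall:
    """A called polysaccharide utilization locus."""

    pul_id: str
    genome_id: str
    contig_id: str
    anchor_pairs: list            # of SusPair
    member_genes: list            # ordered by rank
    cargo: dict = field(default_factory=dict)  # category -> list of genes
    no_cazyme: bool = False

    @property
    def rank_span(self) -> tuple:
        ranks = [g.rank for g in self.member_genes]
        return (min(ranks), max(ranks))


@dataclass
class CellulosomeReport:
    """Per-genome cellulosome component inventory."""

    genome_id: str
    scaffoldins: list
    dockerin_catalytic: list
    dockerin_multimodular: list
    is_cellulosome_capable: bool

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "scaffoldins": sorted(self.scaffoldins),
            "dockerin_catalytic": sorted(self.dockerin_catalytic),
            "dockerin_multimodular": sorted(self.dockerin_multimodular),
            "is_cellulosome_capable": self.is_cellulosome_capable,
        }


def assign_ranks(genes: Iterable[Gene]) -> list:
    """Re-derive gene ranks from coordinates, per contig, 0-based.

    Makes downstream calls invariant to gene-table row order.
    """
    by_contig: dict = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    out = []
    for key in sorted(by_contig):
        contig_genes = sorted(by_contig[key], key=lambda g: (g.start, g.end))
        for rank, g in enumerate(contig_genes):
            out.append(
                Gene(
                    genome_id=g.genome_id,
                    contig_id=g.contig_id,
                    protein_id=g.protein_id,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank=rank,
                    functional_labels=g.functional_labels,
                )
            )
    return out


def detect_sus_pairs(
    genes: Sequence[Gene],
    require_susc_first: bool = False,
    require_same_strand: bool = False,
) -> list:
    """Find tandem susC/susD pairs among ranked genes.

    "Tandem" means rank-adjacent on the same contig, in either gene order
    and on either strand by default; the strictness flags restore the
    canonical susC-then-susD order or a same-strand requirement.  Pairing
    is greedy left-to-right, so each gene joins at most one pair.
    """
    by_contig: dict = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    pairs = []
    for key in sorted(by_contig):
        contig_genes = sorted(by_contig[key], key=lambda g: g.rank)
        i = 0
        while i < len(contig_genes) - 1:
            a, b = contig_genes[i], contig_genes[i + 1]
            if b.rank == a.rank + 1 and _is_sus_pair(
                a, b, require_susc_first, require_same_strand
            ):
                susc, susd = (a, b) if a.has_label("SUSC") else (b, a)
                pairs.append(SusPair(susc=susc, susd=susd))
                i += 2
            else:
                i += 1
    return pairs


def _is_sus_pair(a: Gene, b: Gene, susc_first: bool, same_strand: bool) -> bool:
    forward = a.has_label("SUSC") and b.has_label("SUSD")
    reverse = a.has_label("SUSD") and b.has_label("SUSC")
    if not (forward or (reverse and not susc_first)):
        return False
    if same_strand and a.strand != b.strand:
        return False
    return True


def call_puls(
    genes: Sequence[Gene],
    pairs: Sequence[SusPair],
    window: int = DEFAULT_WINDOW,
) -> list:
    """Call PULs from susCD pairs via a ±``window`` gene-rank neighborhood.

    Each pair spans ranks ``[min_rank - window, max_rank + window]``
    clipped to the contig; overlapping regions on one contig are merged
    (transitively) into a single call with multiple anchor pairs.  Cargo
    genes are categorized from their functional labels.  Calls with no
    CAZy-class cargo are emitted with ``no_cazyme`` set.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    genes_by_contig: dict = {}
    for g in genes:
        genes_by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)

    pairs_by_contig: dict = {}
    for p in pairs:
        pairs_by_contig.setdefault((p.susc.genome_id, p.contig_id), []).append(p)

    calls = []
    serial = 0
    for key in sorted(pairs_by_contig):
        genome_id, contig_id = key
        contig_genes = sorted(genes_by_contig.get(key, []), key=lambda g: g.rank)
        if not contig_genes:
            continue
        max_rank = contig_genes[-1].rank
        regions = []
        for p in sorted(pairs_by_contig[key], key=lambda p: p.min_rank):
            lo = max(0, p.min_rank - window)
            hi = min(max_rank, p.max_rank + window)
            regions.append([lo, hi, [p]])
        merged = [regions[0]]
        for lo, hi, ps in regions[1:]:
            if lo <= merged[-1][1]:  # rank intervals are inclusive
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].extend(ps)
            else:
                merged.append([lo, hi, ps])
        for lo, hi, ps in merged:
            serial += 1
            members = [g for g in contig_genes if lo <= g.rank <= hi]
            call = PULCall(
                pul_id=f"PUL_{genome_id}_{serial:03d}",
                genome_id=genome_id,
                contig_id=contig_id,
                anchor_pairs=ps,
                member_genes=members,
            )
            call.cargo = _categorize_cargo(call)
            call.no_cazyme = not any(
                call.cargo.get(c) for c in CAZY_CARGO_CLASSES
            )
            calls.append(call)
    return calls


def _categorize_cargo(call: PULCall) -> dict:
    anchor_ids = {p.susc.protein_id for p in call.anchor_pairs} | {
        p.susd.protein_id for p in call.anchor_pairs
    }
    cargo: dict = {
        c: [] for c in ("susC", "susD", *CAZY_CARGO_CLASSES, "peptidase", "regulator", "non_PUL")
    }
    for g in call.member_genes:
        if g.protein_id in anchor_ids:
            cargo["susC" if g.has_label("SUSC") else "susD"].append(g)
            continue
        fams = g.cazyme_families()
        placed = False
        for cls, _fam in fams:
            if cls in CAZY_CARGO_CLASSES and g not in cargo[cls]:
                cargo[cls].append(g)
                placed = True
        if g.has_label("PEPTIDASE"):
            cargo["peptidase"].append(g)
            placed = True
        if g.has_label("REGULATOR"):
            cargo["regulator"].append(g)
            placed = True
        if not placed:
            cargo["non_PUL"].append(g)
    return cargo


def summarize_pul(pul: PULCall, function_map=None) -> dict:
    """Composition record for one PUL: category counts, families, flags.

    With a :class:`~cazloci.summarize.FunctionMap`, also counts cargo
    families per substrate category (cellulase, oligosaccharide-degrading,
    ...).
    """
    counts = {cat: len(genes) for cat, genes in pul.cargo.items()}
    families = sorted(
        {
            fam
            for g in pul.member_genes
            for cls, fam in g.cazyme_families()
            if cls in CAZY_CARGO_CLASSES
            and g.protein_id
            not in {
                p.susc.protein_id for p in pul.anchor_pairs
            } | {p.susd.protein_id for p in pul.anchor_pairs}
        }
    )
    record = {
        "pul_id": pul.pul_id,
        "genome_id": pul.genome_id,
        "contig_id": pul.contig_id,
        "n_anchor_pairs": len(pul.anchor_pairs),
        "n_genes": len(pul.member_genes),
        "category_counts": counts,
        "distinct_cazy_families": families,
        "n_distinct_cazy_families": len(families),
        "has_regulator": bool(pul.cargo.get("regulator")),
        "has_peptidase": bool(pul.cargo.get("peptidase")),
        "no_cazyme": pul.no_cazyme,
    }
    if function_map is not None:
        by_substrate: dict = {}
        for fam in families:
            by_substrate.setdefault(function_map.category(fam), []).append(fam)
        record["substrate_categories"] = {
            k: sorted(v) for k, v in sorted(by_substrate.items())
        }
    return record


def detect_cellulosomes(
    genome_id: str,
    classifications: Mapping[str, CAZymeClassification],
) -> CellulosomeReport:
    """Inventory cellulosome components for one genome's proteins.

    ``classifications`` maps protein_id -> classification for the proteins
    of this genome only.
    """
    scaffoldins = []
    dock_cat = []
    dock_mm = []
    for pid in sorted(classifications):
        c = classifications[pid]
        if c.has_cohesin:
            scaffoldins.append(pid)
        if c.has_dockerin:
            catalytic_mm = any(
                _cls(f) in (ModelClass.GH, ModelClass.CE, ModelClass.PL)
                for f in c.catalytic_families
            )
            if catalytic_mm:
                dock_cat.append(pid)
                # multimodular: an accessory module beyond the dockerin itself
                extra_accessory = any(
                    _cls(f) is not ModelClass.DOCKERIN for f in c.accessory_families
                )
                if extra_accessory:
                    dock_mm.append(pid)
    return CellulosomeReport(
        genome_id=genome_id,
        scaffoldins=scaffoldins,
        dockerin_catalytic=dock_cat,
        dockerin_multimodular=dock_mm,
        is_cellulosome_capable=bool(scaffoldins) and bool(dock_mm),
    )


def _cls(family_name: str) -> ModelClass:
    from .model import classify_model_name

    return classify_model_name(family_name)


def write_pul_table(calls: Sequence[PULCall], path) -> None:
    """One row per member gene, with its PUL id and cargo category."""
    with open(path, "w") as fh:
        fh.write(
            "pul_id\tgenome_id\tcontig_id\trank\tprotein_id\tstrand\tcategories\tno_cazyme\n"
        )
        for call in calls:
            cat_of: dict = {}
            for cat, genes in call.cargo.items():
                for g in genes:
                    cat_of.setdefault(g.protein_id, []).append(cat)
            for g in call.member_genes:
                cats = ",".join(sorted(cat_of.get(g.protein_id, ["non_PUL"])))
                fh.write(
                    f"{call.pul_id}\t{call.genome_id}\t{call.contig_id}\t"
                    f"{g.rank}\t{g.protein_id}\t{g.strand}\t{cats}\t"
                    f"{int(call.no_cazyme)}\n"
                )
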