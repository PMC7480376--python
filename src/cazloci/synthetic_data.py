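"""Synthetic genome-bin generator with planted loci and ground truth.

Emulates the downstream products of a binned metagenome study — per-bin
gene models (GFF3), protein sequences (FASTA), domain-hit tables
(``--domtblout`` layout) and a spectral-count table — with polysaccharide
utilization loci (PULs), cellulosome loci, multimodular proteins and
identity-controlled novelty queries planted at known positions.  A
machine-readable truth manifest records everything planted, so every
downstream stage can be scored for exact recovery.

Decoy structures are fixed in code so recovery tests are sharp:

* a lone SusC gene with no adjacent SusD (must not seed a PUL);
* CAZyme genes exactly one rank beyond the PUL window (distance
  ``window + 1`` from the susCD anchor — absorbed only if the window is
  widened);
* a cohesin-only genome whose sole dockerin enzyme is not multimodular
  (must not be called cellulosome-capable);
* a dockerin-only genome with multimodular dockerin enzymes but no
  cohesin (likewise not capable);
* domain hits failing the E-value or HMM-coverage filter, and
  fully-overlapping weaker hits, planted on top of true architectures.

Every planted PUL carries boundary cargo at exactly the window distance
and decoy CAZymes at distance ``window + 1``, so shrinking or enlarging
the calling window by one gene demonstrably changes the result.

Gene coordinates sit on a fixed non-overlapping grid (constant gene
length and intergenic gap): locus calling operates on gene order, so
nucleotide geometry exists only for format fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain_io import filter_hits, write_domtblout, parse_domtblout
from .model import (
    DomainHit,
    Gene,
    ProteinArchitecture,
    classify_model_name,
    gene_labels_from_architecture,
)
from .summarize import SpectralRecord, write_spectral_tsv, read_spectral_tsv

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Background CAZyme families, drawn from the most common families in
#: rumen fibrolytic communities.
DEFAULT_FAMILY_POOL = (
    "GH13", "GH3", "GH2", "GH43", "GH23", "GH5", "GH25", "GH77", "GH31",
    "CBM50", "CBM32", "CBM48", "CBM6", "CBM67",
    "CE1", "CE10", "CE4", "CE3", "CE9",
    "PL12", "PL22", "PL1", "AA6", "AA3", "GT2", "GT4", "SLH",
)

#: Multimodular architectures planted outside loci (catalytic + accessory,
#: deliberately free of dockerin/cohesin so cellulosome calls stay sharp).
MULTIMODULAR_ARCHS = (
    "CBM48-GH13_9", "CBM67-GH78", "CBM34-GH13_20", "CBM48-CE1",
    "GH43_35-CBM6", "SLH-GH10", "GH5_4-CBM22-CE3", "CBM4-CBM30-GH9",
    "CBM35-GH26", "CBM22-GH10-CBM22",
)

#: Cellulosome locus content: a cohesin scaffoldin, multimodular dockerin
#: enzymes, a non-catalytic dockerin protein, and a dockerin peptidase.
CELLULOSOME_LOCUS_ARCHS = (
    "cohesin_I-cohesin_I-cohesin_I-SLH",
    "GH5_4-CBM22-CE3-dockerin_I",
    "GH9-CBM3-dockerin_I",
    "LRR_5-dockerin_I",
    "dockerin_I-Peptidase_M10",
)

DUF_ACCESSORY_ARCHS = ("DUF4874-DUF4832-dockerin_I", "DUF1234-CBM6", "DUF2345-SLH")

PUL_GH_POOL = ("GH2", "GH3", "GH5", "GH9", "GH13", "GH16", "GH29", "GH31", "GH43", "GH97")
PUL_CE_POOL = ("CE1", "CE3", "CE6", "CE10", "CE12")
PUL_PL_POOL = ("PL1", "PL9")
REGULATOR_POOL = ("AraC", "MarR", "LacI", "GntR", "HTCS")


class SizingError(ValueError):
    """A planting request exceeds the configured genome capacity."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic consortium.

    Defaults emulate a ten-bin consortium with bins of ~200 genes
    (a scaled-down analog of bins carrying 1,245–3,935 genes), 25 planted
    PULs, two cellulosome genomes, novelty queries at 50/70/90 percent
    identity, and an unbinned contig pool sized so that roughly
    seventy percent of CAZyme proteins fall in named bins.
    """

    n_genomes: int = 10
    genes_per_genome: int = 200
    contigs_per_genome: int = 2
    n_puls: int = 25
    n_cellulosome_loci: int = 2
    n_multimodular: int = 20
    n_decoys: int = 10
    n_unbinned_genes: int = 1000
    family_pool: tuple = DEFAULT_FAMILY_POOL
    identity_targets: tuple = (0.5, 0.7, 0.9)
    queries_per_target: int = 4
    spectral_mean: float = 10.0
    spectral_dispersion: float = 2.0
    window: int = 5
    gene_length: int = 900
    intergenic_gap: int = 100
    background_cazyme_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genomes", "genes_per_genome", "contigs_per_genome", "n_puls",
            "n_cellulosome_loci", "n_multimodular", "n_decoys",
            "n_unbinned_genes", "queries_per_target", "window",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genomes > 0 and self.contigs_per_genome < 1:
            raise ValueError("contigs_per_genome must be >= 1")
        for t in self.identity_targets:
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"identity target {t} outside [0, 1]")
        if self.n_puls > 0 and self.window < 4:
            raise ValueError("PUL planting requires window >= 4")
        object.__setattr__(self, "family_pool", tuple(self.family_pool))
        object.__setattr__(self, "identity_targets", tuple(self.identity_targets))


@dataclass(frozen=True)
class GenomeBin:
    """One genome bin: an ordered collection of genes."""

    genome_id: str
    genes: tuple

    @property
    def contigs(self) -> list:
        seen: dict = {}
        for g in self.genes:
            seen.setdefault(g.contig_id, True)
        return list(seen)


@dataclass
class SequenceSet:
    """Protein sequences of the bins plus the novelty reference set."""

    proteins: dict = field(default_factory=dict)
    references: dict = field(default_factory=dict)


@dataclass
class TruthManifest:
    """Ground truth of everything planted by the simulator."""

    config: dict = field(default_factory=dict)
    gene_counts: dict = field(default_factory=dict)       # genome -> n genes
    planted_puls: list = field(default_factory=list)
    planted_cellulosome_loci: list = field(default_factory=list)
    capable_genomes: list = field(default_factory=list)
    decoy_genomes: dict = field(default_factory=dict)
    planted_architectures: dict = field(default_factory=dict)
    planted_multimodular: list = field(default_factory=list)
    planted_duf_accessory: list = field(default_factory=list)
    planted_identities: dict = field(default_factory=dict)  # query -> [ref, pct]
    cazyme_protein_counts: dict = field(default_factory=dict)  # genome -> n CAZymes
    planted_secreted: dict = field(default_factory=dict)    # genome -> [protein ids]
    family_counts: dict = field(default_factory=dict)       # genome -> family -> n
    n_hits_emitted: int = 0
    n_hits_passing: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


class _Allocator:
    """Sequential rank-block allocator for one genome's contigs.

    Blocks are separated by at least ``gap`` filler genes so that nothing
    planted in one block falls inside the calling window of another.
    """

    def __init__(self, contig_sizes: dict, gap: int = 2):
        self.sizes = dict(contig_sizes)
        self.cursor = {c: 0 for c in contig_sizes}
        self.gap = gap

    def alloc(self, n: int, what: str, genome_id: str) -> tuple:
        for contig in self.cursor:
            if self.cursor[contig] + n <= self.sizes[contig]:
                start = self.cursor[contig]
                self.cursor[contig] = start + n + self.gap
                return contig, start
        raise SizingError(
            f"cannot place {what} in genome {genome_id}: "
            f"{n} consecutive gene slots requested but all contigs are full "
            f"(genes_per_genome={sum(self.sizes.values())}, "
            f"contigs={len(self.sizes)}); reduce planted-structure counts "
            f"or increase genes_per_genome"
        )


def mutate_to_identity(reference: str, target_identity: float, seed: int) -> str:
    """Substitute residues to reach a target global identity, length preserved.

    Exactly ``round((1 - target) * L)`` positions are substituted (each to
    a different residue), so the realized Hamming identity is within half
    a position of the target.  Substituted positions are spread evenly
    along the chain (one per stratum of the eligible region) and the
    terminal residues are left intact: clustered substitutions would let
    a gap-shifted local alignment outscore the ungapped one and drag the
    alignment identity away from the planted value.
    """
    if not reference:
        raise ValueError("reference sequence is empty")
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(reference)
    n_sub = int(round((1.0 - target_identity) * L))
    seq = list(reference)
    protected = min(3, max(0, (L - n_sub) // 2))
    candidates = np.arange(protected, L - protected)
    if n_sub > len(candidates):
        candidates = np.arange(L)
    if n_sub > 0:
        positions = np.array(
            [
                stratum[rng.integers(len(stratum))]
                for stratum in np.array_split(candidates, n_sub)
            ]
        )
    else:
        positions = np.array([], dtype=int)
    for pos in sorted(positions):
        current = seq[pos]
        choices = [a for a in AMINO_ACIDS if a != current]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _random_protein(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])


def _arch_hits(protein_id: str, arch: str, rng) -> tuple:
    """Domain hits realizing an architecture string; returns (hits, protein_length)."""
    names = arch.split("-")
    protein_length = 10 + (len(names) - 1) * 140 + 119 + 15
    hits = []
    ali_from = 10
    for name in names:
        ali_to = ali_from + 119
        hits.append(
            DomainHit(
                protein_id=protein_id,
                protein_length=protein_length,
                model_name=name,
                model_length=150,
                hmm_from=8,
                hmm_to=127,
                ali_from=ali_from,
                ali_to=ali_to,
                i_evalue=float(f"{10 ** rng.uniform(-30.0, -10.0):.3g}"),
                score=round(float(rng.uniform(60.0, 300.0)), 1),
            )
        )
        ali_from = ali_to + 21
    return hits, protein_length


def simulate_bins(config: SimConfig):
    """Generate genome bins, domain hits, sequences and the truth manifest.

    Returns ``(bins, hits, sequences, manifest)`` where *bins* is a list
    of :class:`GenomeBin`, *hits* the full (pre-filter) domain-hit list,
    *sequences* a :class:`SequenceSet` and *manifest* the ground truth.
    All randomness flows from ``config.seed``; identical configs yield
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"g{i + 1:02d}" for i in range(config.n_genomes)]
    w = config.window

    # -- contig layout and per-genome allocators ------------------------
    # an "unbinned" pseudo-bin holds background genes on contigs that were
    # never binned, so binned-vs-unbinned accounting is non-trivial
    all_genome_ids = list(genome_ids)
    if config.n_unbinned_genes > 0:
        all_genome_ids.append("unbinned")
    contig_sizes: dict = {}
    allocators: dict = {}
    if config.n_unbinned_genes > 0:
        contig_sizes["unbinned"] = {"unbinned_c1": config.n_unbinned_genes}
        allocators["unbinned"] = _Allocator(contig_sizes["unbinned"])
    for gid in genome_ids:
        base = config.genes_per_genome // config.contigs_per_genome
        sizes = {}
        for c in range(config.contigs_per_genome):
            n = base if c < config.contigs_per_genome - 1 else (
                config.genes_per_genome - base * (config.contigs_per_genome - 1)
            )
            sizes[f"{gid}_c{c + 1}"] = n
        contig_sizes[gid] = sizes
        allocators[gid] = _Allocator(sizes)

    # planted[(genome, contig, rank)] = (architecture string or None, role)
    planted: dict = {}
    # json round-trip normalizes tuples to lists so the manifest compares
    # equal after serialization
    manifest = TruthManifest(config=json.loads(json.dumps(asdict(config))))

    # -- genome roles ----------------------------------------------------
    n_cell_genomes = min(config.n_cellulosome_loci, config.n_genomes)
    cell_genomes = genome_ids[:n_cell_genomes]
    spare = genome_ids[n_cell_genomes:]
    cohesin_only = spare[0] if spare and config.n_genomes >= n_cell_genomes + 1 else None
    dockerin_only = spare[1] if len(spare) >= 2 else None
    manifest.decoy_genomes = {
        "cohesin_only": [cohesin_only] if cohesin_only else [],
        "dockerin_only": [dockerin_only] if dockerin_only else [],
    }
    pul_genomes = [g for g in genome_ids if g not in cell_genomes] or genome_ids

    # -- plant PULs ------------------------------------------------------
    # Block layout (relative ranks, window w): decoy CAZymes at 0 and
    # 2w + 3 sit exactly w + 1 from the anchors; boundary cargo at 1 and
    # 2w + 2 sit exactly w away.
    block_len = 2 * w + 4
    for i in range(config.n_puls):
        gid = pul_genomes[i % len(pul_genomes)]
        contig, b = allocators[gid].alloc(block_len, f"PUL {i + 1}", gid)
        gh = PUL_GH_POOL[rng.integers(len(PUL_GH_POOL))]
        gh2 = PUL_GH_POOL[rng.integers(len(PUL_GH_POOL))]
        ce = PUL_CE_POOL[rng.integers(len(PUL_CE_POOL))]
        boundary_lo = PUL_CE_POOL[rng.integers(len(PUL_CE_POOL))]
        boundary_hi = PUL_GH_POOL[rng.integers(len(PUL_GH_POOL))]
        decoy_lo = "GH13"
        decoy_hi = "CE1"
        reg = REGULATOR_POOL[rng.integers(len(REGULATOR_POOL))]
        susc_rank, susd_rank = b + w + 1, b + w + 2
        layout = {
            b + 0: (decoy_lo, "pul_decoy_cazyme"),
            b + 1: (boundary_lo, "pul_cargo"),
            b + 2: (reg, "pul_regulator"),
            b + 4: (gh, "pul_cargo"),
            susc_rank: ("TIGR04056", "pul_susc"),
            susd_rank: ("SusD", "pul_susd"),
            b + w + 3: (gh2, "pul_cargo"),
            b + w + 4: ("Peptidase_M50", "pul_peptidase"),
            b + 2 * w + 1: (ce, "pul_cargo"),
            b + 2 * w + 2: (boundary_hi, "pul_cargo"),
            b + 2 * w + 3: (decoy_hi, "pul_decoy_cazyme"),
        }
        for rank, (arch, role) in layout.items():
            planted[(gid, contig, rank)] = (arch, role)
        cargo = [
            {"rank": r, "family": a, "category": classify_model_name(a).value}
            for r, (a, role) in sorted(layout.items())
            if role == "pul_cargo"
        ]
        manifest.planted_puls.append(
            {
                "genome": gid,
                "contig": contig,
                "susc_rank": susc_rank,
                "susd_rank": susd_rank,
                "cargo": cargo,
                "regulator_rank": b + 2,
                "peptidase_rank": b + w + 4,
                "boundary_cargo_ranks": [b + 1, b + 2 * w + 2],
                "decoy_cazyme_ranks": [b + 0, b + 2 * w + 3],
                "window_span": [b + 1, b + 2 * w + 2],
            }
        )

    # -- plant cellulosome loci ------------------------------------------
    for i in range(config.n_cellulosome_loci):
        gid = cell_genomes[i % len(cell_genomes)] if cell_genomes else None
        if gid is None:
            break
        contig, b = allocators[gid].alloc(
            len(CELLULOSOME_LOCUS_ARCHS), f"cellulosome locus {i + 1}", gid
        )
        ranks = {"scaffoldin": [], "dockerin_enzyme": [], "other": []}
        for j, arch in enumerate(CELLULOSOME_LOCUS_ARCHS):
            planted[(gid, contig, b + j)] = (arch, "cellulosome")
            cls = [classify_model_name(n) for n in arch.split("-")]
            if any(c.value == "COHESIN" for c in cls):
                ranks["scaffoldin"].append(b + j)
            elif any(c.value == "DOCKERIN" for c in cls) and any(
                c.value in ("GH", "CE", "PL") for c in cls
            ):
                ranks["dockerin_enzyme"].append(b + j)
            else:
                ranks["other"].append(b + j)
        manifest.planted_cellulosome_loci.append(
            {
                "genome": gid,
                "contig": contig,
                "scaffoldin_ranks": ranks["scaffoldin"],
                "dockerin_enzyme_ranks": ranks["dockerin_enzyme"],
                "other_ranks": ranks["other"],
            }
        )
    manifest.capable_genomes = sorted({e["genome"] for e in manifest.planted_cellulosome_loci})

    # -- cellulosome decoy genomes ---------------------------------------
    if cohesin_only is not None and (config.n_cellulosome_loci > 0 or config.n_decoys > 0):
        contig, b = allocators[cohesin_only].alloc(2, "cohesin-only decoy", cohesin_only)
        planted[(cohesin_only, contig, b)] = ("cohesin_I-cohesin_I", "decoy_cohesin_only")
        # plain dockerin enzyme: catalytic but not multimodular
        planted[(cohesin_only, contig, b + 1)] = ("GH5-dockerin_I", "decoy_plain_dockerin")
    if dockerin_only is not None and (config.n_cellulosome_loci > 0 or config.n_decoys > 0):
        contig, b = allocators[dockerin_only].alloc(1, "dockerin-only decoy", dockerin_only)
        planted[(dockerin_only, contig, b)] = ("GH9-CBM3-dockerin_I", "decoy_dockerin_only")

    # -- multimodular proteins -------------------------------------------
    safe_genomes = [g for g in genome_ids if g != cohesin_only] or genome_ids
    for i in range(config.n_multimodular):
        gid = safe_genomes[i % len(safe_genomes)]
        arch = MULTIMODULAR_ARCHS[i % len(MULTIMODULAR_ARCHS)]
        contig, b = allocators[gid].alloc(1, f"multimodular protein {i + 1}", gid)
        planted[(gid, contig, b)] = (arch, "multimodular")

    # -- DUF-accessory proteins (fixed taxonomy, 3 planted when room) -----
    if config.n_genomes > 0 and config.genes_per_genome > 0:
        duf_host = dockerin_only or (cell_genomes[0] if cell_genomes else None)
        for i, arch in enumerate(DUF_ACCESSORY_ARCHS):
            has_dockerin = "dockerin" in arch
            gid = duf_host if has_dockerin else safe_genomes[i % len(safe_genomes)]
            if gid is None:
                continue
            try:
                contig, b = allocators[gid].alloc(1, f"DUF protein {i + 1}", gid)
            except SizingError:
                continue
            planted[(gid, contig, b)] = (arch, "duf_accessory")

    # -- standalone decoys: lone SusC and far CAZymes ---------------------
    for i in range(config.n_decoys):
        gid = genome_ids[i % config.n_genomes] if config.n_genomes else None
        if gid is None:
            break
        if i % 2 == 0:
            contig, b = allocators[gid].alloc(3, f"lone-SusC decoy {i + 1}", gid)
            planted[(gid, contig, b + 1)] = ("TIGR04056", "decoy_lone_susc")
        else:
            contig, b = allocators[gid].alloc(1, f"far-CAZyme decoy {i + 1}", gid)
            fam = config.family_pool[rng.integers(len(config.family_pool))]
            planted[(gid, contig, b)] = (fam, "decoy_far_cazyme")

    # -- background fill ---------------------------------------------------
    for gid in all_genome_ids:
        for contig, size in contig_sizes[gid].items():
            used = {r for (g, c, r) in planted if g == gid and c == contig}
            alloc = allocators[gid]
            # ranks inside allocated blocks (incl. inter-block gaps) below
            # the cursor may host background; only keep clear of windows by
            # skipping ranks adjacent to nothing — allocator gaps already
            # guarantee separation, so any unused rank is fair game for
            # OTHER genes, and background CAZymes go only beyond the cursor
            # plus a window margin.
            cazyme_floor = alloc.cursor[contig] + w
            for rank in range(size):
                if rank in used:
                    continue
                u = rng.uniform()
                if u < config.background_cazyme_prob and rank >= cazyme_floor:
                    fam = config.family_pool[rng.integers(len(config.family_pool))]
                    planted[(gid, contig, rank)] = (fam, "background_cazyme")
                elif u < config.background_cazyme_prob + 0.05:
                    planted[(gid, contig, rank)] = (None, "junk_hit_host")
                else:
                    planted[(gid, contig, rank)] = (None, "filler")

    # -- materialize genes, hits, sequences --------------------------------
    bins = []
    all_hits = []
    sequences = SequenceSet()
    gene_index: dict = {}
    for gid in all_genome_ids:
        genes = []
        serial = 0
        fam_counts: dict = {}
        for contig in contig_sizes[gid]:
            for rank in range(contig_sizes[gid][contig]):
                serial += 1
                pid = f"{gid}_{serial:05d}"
                arch_str, role = planted[(gid, contig, rank)]
                start = 1 + rank * (config.gene_length + config.intergenic_gap)
                end = start + config.gene_length - 1
                strand = "+" if rng.uniform() < 0.5 else "-"
                if arch_str is not None:
                    hits, plen = _arch_hits(pid, arch_str, rng)
                    all_hits.extend(hits)
                    manifest.planted_architectures[pid] = arch_str
                    arch = ProteinArchitecture(
                        protein_id=pid,
                        domains=tuple(
                            (h.model_name, h.model_class, h.ali_from, h.ali_to)
                            for h in hits
                        ),
                    )
                    labels = gene_labels_from_architecture(arch)
                    for name in arch_str.split("-"):
                        fam_counts[name] = fam_counts.get(name, 0) + 1
                    if role == "multimodular":
                        manifest.planted_multimodular.append(pid)
                    if role == "duf_accessory":
                        manifest.planted_duf_accessory.append(pid)
                    # overlap decoy: a weaker same-interval hit that must be
                    # resolved away
                    if role == "multimodular" and rng.uniform() < 0.3:
                        h0 = hits[0]
                        alt = "GH8" if h0.model_name != "GH8" else "GH5"
                        all_hits.append(
                            DomainHit(
                                protein_id=pid,
                                protein_length=plen,
                                model_name=alt,
                                model_length=150,
                                hmm_from=8,
                                hmm_to=127,
                                ali_from=h0.ali_from,
                                ali_to=h0.ali_to,
                                i_evalue=1e-7,
                                score=40.0,
                            )
                        )
                else:
                    plen = int(rng.integers(150, 400))
                    labels = frozenset({"OTHER"})
                    if role == "junk_hit_host":
                        fam = config.family_pool[rng.integers(len(config.family_pool))]
                        if rng.uniform() < 0.5:
                            # fails the E-value cutoff
                            all_hits.append(
                                DomainHit(
                                    protein_id=pid, protein_length=plen,
                                    model_name=fam, model_length=150,
                                    hmm_from=8, hmm_to=127,
                                    ali_from=10, ali_to=min(plen, 129),
                                    i_evalue=float(f"{10 ** rng.uniform(-5.0, -3.0):.3g}"),
                                    score=12.0,
                                )
                            )
                        else:
                            # fails the HMM-coverage cutoff
                            all_hits.append(
                                DomainHit(
                                    protein_id=pid, protein_length=plen,
                                    model_name=fam, model_length=150,
                                    hmm_from=10, hmm_to=45,
                                    ali_from=10, ali_to=min(plen, 45),
                                    i_evalue=1e-15, score=35.0,
                                )
                            )
                sequences.proteins[pid] = _random_protein(rng, plen)
                gene = Gene(
                    genome_id=gid, contig_id=contig, protein_id=pid,
                    start=start, end=end, strand=strand, rank=rank,
                    functional_labels=labels,
                )
                genes.append(gene)
                gene_index[pid] = gene
        manifest.family_counts[gid] = dict(sorted(fam_counts.items()))
        manifest.gene_counts[gid] = len(genes)
        manifest.cazyme_protein_counts[gid] = sum(
            1
            for g in genes
            if g.protein_id in manifest.planted_architectures
            and any(
                classify_model_name(n).value in ("GH", "GT", "CE", "PL", "AA", "CBM")
                for n in manifest.planted_architectures[g.protein_id].split("-")
            )
        )
        bins.append(GenomeBin(genome_id=gid, genes=tuple(genes)))

    # -- novelty queries: overwrite selected CAZyme sequences ---------------
    cazyme_pids = sorted(
        pid
        for pid, arch in manifest.planted_architectures.items()
        if any(
            classify_model_name(n).value in ("GH", "GT", "CE", "PL", "AA", "CBM")
            for n in arch.split("-")
        )
    )
    qi = 0
    for t in config.identity_targets:
        for _ in range(config.queries_per_target):
            if qi >= len(cazyme_pids):
                break
            pid = cazyme_pids[qi]
            qi += 1
            ref_id = f"ref_{pid}"
            ref_seq = _random_protein(rng, len(sequences.proteins[pid]))
            sequences.references[ref_id] = ref_seq
            sub_seed = int(rng.integers(2**31))
            sequences.proteins[pid] = mutate_to_identity(ref_seq, t, sub_seed)
            manifest.planted_identities[pid] = [ref_id, round(100.0 * t, 4)]

    # -- spectral counts -----------------------------------------------------
    secreted: dict = {}
    for entry in manifest.planted_cellulosome_loci:
        gid = entry["genome"]
        contig_genes = {
            g.rank: g
            for b_ in bins if b_.genome_id == gid
            for g in b_.genes if g.contig_id == entry["contig"]
        }
        for r in (
            entry["scaffoldin_ranks"] + entry["dockerin_enzyme_ranks"] + entry["other_ranks"]
        ):
            secreted.setdefault(gid, set()).add(contig_genes[r].protein_id)
    for entry in manifest.planted_puls:
        gid = entry["genome"]
        contig_genes = {
            g.rank: g
            for b_ in bins if b_.genome_id == gid
            for g in b_.genes if g.contig_id == entry["contig"]
        }
        for r in (entry["susc_rank"], entry["susd_rank"]):
            secreted.setdefault(gid, set()).add(contig_genes[r].protein_id)
        for c in entry["cargo"]:
            if rng.uniform() < 0.3:
                secreted.setdefault(gid, set()).add(contig_genes[c["rank"]].protein_id)
    spectra = []
    p = config.spectral_dispersion / (config.spectral_dispersion + config.spectral_mean)
    for gid in sorted(secreted):
        for pid in sorted(secreted[gid]):
            count = int(rng.negative_binomial(config.spectral_dispersion, p)) + 1
            spectra.append(
                SpectralRecord(
                    protein_id=pid, genome_id=gid,
                    spectral_count=count, signal_peptide=True,
                )
            )
    if spectra:
        # one unannotated contaminant, as real spectral tables contain
        spectra.append(
            SpectralRecord(
                protein_id="contaminant_01", genome_id="unbinned",
                spectral_count=int(rng.negative_binomial(config.spectral_dispersion, p)) + 1,
                signal_peptide=None,
            )
        )
    manifest.planted_secreted = {g: sorted(s) for g, s in sorted(secreted.items())}

    manifest.n_hits_emitted = len(all_hits)
    manifest.n_hits_passing = len(filter_hits(all_hits))
    return bins, all_hits, sequences, manifest, spectra


def write_gff3(bin_: GenomeBin, path) -> None:
    """Write one genome bin as GFF3 (CDS features, ``ID=`` carries protein_id)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_contig: dict = {}
        for g in bin_.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for contig in by_contig:
            end = max(g.end for g in by_contig[contig])
            fh.write(f"##sequence-region {contig} 1 {end}\n")
        for g in bin_.genes:
            fh.write(
                f"{g.contig_id}\tcazloci_sim\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.protein_id};genome_id={g.genome_id}\n"
            )


def read_gff3_genes(path, genome_id: str | None = None) -> list:
    """Read CDS features from a GFF3 file into unranked, unlabeled genes.

    Ranks are assigned afterwards with :func:`cazloci.loci.assign_ranks`;
    functional labels come from domain architectures.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gid = genome_id or feat.attributes.get("genome_id", ["unbinned"])[0]
        genes.append(
            Gene(
                genome_id=gid,
                contig_id=feat.seqid,
                protein_id=feat.attributes["ID"][0],
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                rank=0,
            )
        )
    return genes


def emit_fixture_set(bins, hits, sequences, manifest, spectra, out_dir) -> dict:
    """Write the complete fixture: GFF3 per genome, FASTAs, hits, spectra, manifest.

    Returns a dict of written paths.  Re-reading with
    :func:`load_fixture_set` reproduces the in-memory objects exactly.
    """
    out = Path(out_dir)
    try:
        (out / "genomes").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths = {"genomes": {}}
    for b in bins:
        p = out / "genomes" / f"{b.genome_id}.gff3"
        write_gff3(b, p)
        paths["genomes"][b.genome_id] = str(p)
    prot_path = out / "proteins.faa"
    SeqIO.write(
        (
            SeqRecord(Seq(seq), id=pid, description="")
            for pid, seq in sorted(sequences.proteins.items())
        ),
        str(prot_path), "fasta",
    )
    ref_path = out / "references.faa"
    SeqIO.write(
        (
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in sorted(sequences.references.items())
        ),
        str(ref_path), "fasta",
    )
    hits_path = out / "hits.domtbl"
    write_domtblout(hits, hits_path)
    spectra_path = out / "spectra.tsv"
    write_spectral_tsv(spectra, spectra_path)
    manifest_path = out / "manifest.json"
    manifest.to_json(manifest_path)
    paths.update(
        proteins=str(prot_path), references=str(ref_path),
        hits=str(hits_path), spectra=str(spectra_path),
        manifest=str(manifest_path),
    )
    return paths


def load_fixture_set(fixture_dir):
    """Re-read an emitted fixture into in-memory objects.

    Gene functional labels are reconstructed from the manifest's planted
    architectures, so a loaded fixture compares equal to the simulated
    one.
    """
    from .loci import assign_ranks

    d = Path(fixture_dir)
    manifest = TruthManifest.from_json(d / "manifest.json")
    bins = []
    for gff in sorted((d / "genomes").glob("*.gff3")):
        genome_id = gff.stem
        genes = read_gff3_genes(gff, genome_id=genome_id)
        ranked = assign_ranks(genes)
        labeled = []
        for g in ranked:
            arch_str = manifest.planted_architectures.get(g.protein_id)
            if arch_str:
                domains = []
                ali_from = 10
                for name in arch_str.split("-"):
                    domains.append((name, classify_model_name(name), ali_from, ali_from + 119))
                    ali_from += 140
                arch = ProteinArchitecture(protein_id=g.protein_id, domains=tuple(domains))
                labels = gene_labels_from_architecture(arch)
            else:
                labels = frozenset({"OTHER"})
            labeled.append(
                Gene(
                    genome_id=g.genome_id, contig_id=g.contig_id,
                    protein_id=g.protein_id, start=g.start, end=g.end,
                    strand=g.strand, rank=g.rank, functional_labels=labels,
                )
            )
        bins.append(GenomeBin(genome_id=genome_id, genes=tuple(labeled)))
    hits = parse_domtblout(d / "hits.domtbl")
    sequences = SequenceSet(
        proteins={r.id: str(r.seq) for r in SeqIO.parse(str(d / "proteins.faa"), "fasta")},
        references={r.id: str(r.seq) for r in SeqIO.parse(str(d / "references.faa"), "fasta")},
    )
    spectra = read_spectral_tsv(d / "spectra.tsv")
    return bins, hits, sequences, manifest, spectra
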