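"""Genome-level summaries and spectral-count metaproteome integration.

Spectral counts — the number of MS/MS spectra assigned to a protein — are
consumed as already-validated integers per protein; PSM-level filtering
(protein probability, peptide minimums, FDR) is upstream of this package.
Integration joins the counts onto domain classifications, reports
per-genome and per-substrate-category totals, and flags genomes whose
secreted proteins include cellulosome components (cohesin/dockerin) or
PUL components (SusC/SusD), the proteomic evidence that those complexes
are actually produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .architecture import CAZymeClassification
from .model import ModelClass, ProteinArchitecture, family_root

UNBINNED = "unbinned"


@dataclass(frozen=True)
class SpectralRecord:
    """One protein row of a spectral-count table."""

    protein_id: str
    genome_id: str
    spectral_count: int
    signal_peptide: bool | None = None

    def __post_init__(self) -> None:
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be non-negative")


class FunctionMap:
    """Total map from CAZy family to substrate category.

    Families are grouped by their action on plant cell-wall components;
    lookups strip subfamily suffixes (GH5_4 -> GH5) and unknown families
    map to ``other``.  The seed groupings follow the conventional
    assignments for rumen fibrolytic communities: cellulases GH5, GH9,
    GH30, GH51, GH74, GH94; xylan/hemicellulose-active GH and CE
    families; amylases GH13/GH77; pectin-active GH and PL families; and
    oligosaccharide-degrading exo-acting families (GH2, GH3, GH29, GH31,
    GH42, GH97, ...).
    """

    DEFAULT_GROUPS = {
        "cellulase": ["GH5", "GH9", "GH30", "GH51", "GH74", "GH94", "GH44", "GH45", "GH48"],
        "hemicellulase": [
            "GH8", "GH10", "GH11", "GH16", "GH26", "GH43", "GH53", "GH115",
            "CE1", "CE2", "CE3", "CE4", "CE6", "CE7", "CE9", "CE10", "CE12",
        ],
        "amylase": ["GH13", "GH57", "GH77"],
        "pectinase": ["GH28", "GH78", "GH88", "GH105", "GH106",
                      "PL1", "PL9", "PL10", "PL11", "PL12", "PL22", "CE8"],
        "oligosaccharide-degrading": [
            "GH1", "GH2", "GH3", "GH4", "GH29", "GH31", "GH35", "GH36",
            "GH38", "GH39", "GH42", "GH97",
        ],
    }

    def __init__(self, groups: Mapping[str, Sequence[str]] | None = None):
        groups = groups if groups is not None else self.DEFAULT_GROUPS
        self._by_family: dict = {}
        for cat, fams in groups.items():
            for fam in fams:
                self._by_family[fam] = cat

    def category(self, family: str) -> str:
        return self._by_family.get(family_root(family), "other")


def genome_matrix(
    architectures: Mapping[str, ProteinArchitecture],
    genome_of: Mapping[str, str],
) -> pd.DataFrame:
    """Family × genome module-count matrix (heatmap-ready).

    Cells count domain occurrences of each family per genome; proteins
    without a genome assignment fall in the ``unbinned`` column.  Row and
    column sums are consistent with the module census by construction.
    """
    counts: dict = {}
    for pid, arch in architectures.items():
        genome = genome_of.get(pid, UNBINNED)
        for name, _cls, _, _ in arch.domains:
            counts[(name, genome)] = counts.get((name, genome), 0) + 1
    if not counts:
        return pd.DataFrame(dtype=int)
    families = sorted({k[0] for k in counts})
    genomes = sorted({k[1] for k in counts})
    mat = pd.DataFrame(0, index=families, columns=genomes, dtype=int)
    for (fam, genome), n in counts.items():
        mat.loc[fam, genome] = n
    mat.index.name = "family"
    return mat


def binned_fraction(
    classifications: Mapping[str, CAZymeClassification],
    genome_of: Mapping[str, str],
) -> float | None:
    """Fraction of CAZyme proteins assigned to a named genome bin.

    Returns None when no CAZymes are present (undefined ratio).
    """
    cazymes = [pid for pid, c in classifications.items() if c.is_cazyme]
    if not cazymes:
        return None
    binned = sum(1 for pid in cazymes if genome_of.get(pid, UNBINNED) != UNBINNED)
    return binned / len(cazymes)


def read_spectral_tsv(path) -> list:
    """Read a spectral-count TSV (protein_id, genome_id, spectral_count[, signal_peptide])."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sp = None
            if "signal_peptide" in idx and f[idx["signal_peptide"]] != "":
                sp = f[idx["signal_peptide"]] in ("1", "True", "true", "yes", "Yes")
            records.append(
                SpectralRecord(
                    protein_id=f[idx["protein_id"]],
                    genome_id=f[idx["genome_id"]],
                    spectral_count=int(f[idx["spectral_count"]]),
                    signal_peptide=sp,
                )
            )
    return records


def write_spectral_tsv(records: Iterable[SpectralRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgenome_id\tspectral_count\tsignal_peptide\n")
        for r in records:
            sp = "" if r.signal_peptide is None else str(int(r.signal_peptide))
            fh.write(f"{r.protein_id}\t{r.genome_id}\t{r.spectral_count}\t{sp}\n")


def integrate_metaproteome(
    spectral_records: Sequence[SpectralRecord],
    classifications: Mapping[str, CAZymeClassification],
    architectures: Mapping[str, ProteinArchitecture],
    function_map: FunctionMap | None = None,
) -> dict:
    """Join spectral counts onto annotations and summarize per genome/category.

    Per genome: number of distinct detected proteins, summed spectral
    counts, and detection flags for cellulosome components
    (cohesin/dockerin proteins) and PUL components (SusC/SusD proteins).
    Per substrate category: a *multi* total where a bifunctional protein
    contributes its full count to every category it matches, and a
    *primary* total where its count goes only to the category of its
    N-terminal-most catalytic domain (an unambiguous partition whose sum
    is conserved).  Detected proteins missing from the annotation tables
    are reported as unannotated, never dropped.
    """
    function_map = function_map or FunctionMap()
    seen_genome: dict = {}
    for r in spectral_records:
        prev = seen_genome.get(r.protein_id)
        if prev is not None and prev != r.genome_id:
            raise ValueError(
                f"protein {r.protein_id} mapped to conflicting genomes "
                f"{prev!r} and {r.genome_id!r}"
            )
        seen_genome[r.protein_id] = r.genome_id

    per_genome: dict = {}
    category_multi: dict = {}
    category_primary: dict = {}
    unannotated: dict = {}
    annotated_total = 0

    for r in sorted(spectral_records, key=lambda r: (r.genome_id, r.protein_id)):
        g = per_genome.setdefault(
            r.genome_id,
            {
                "n_proteins": 0,
                "total_spectral_count": 0,
                "cazyme_spectral_count": 0,
                "cellulosomal_protein_detected": False,
                "pul_component_detected": False,
                "proteins": [],
            },
        )
        g["n_proteins"] += 1
        g["total_spectral_count"] += r.spectral_count
        g["proteins"].append(r.protein_id)
        cls = classifications.get(r.protein_id)
        if cls is None:
            unannotated[r.protein_id] = (
                unannotated.get(r.protein_id, 0) + r.spectral_count
            )
            continue
        annotated_total += r.spectral_count
        arch = architectures[r.protein_id]
        if cls.has_cohesin or cls.has_dockerin:
            g["cellulosomal_protein_detected"] = True
        domain_classes = set(arch.classes)
        if ModelClass.SUSC in domain_classes or ModelClass.SUSD in domain_classes:
            g["pul_component_detected"] = True
        if cls.is_cazyme:
            g["cazyme_spectral_count"] += r.spectral_count
        cats = sorted({function_map.category(f) for f in cls.catalytic_families})
        for cat in cats:
            category_multi[cat] = category_multi.get(cat, 0) + r.spectral_count
        primary = _primary_category(arch, function_map)
        if primary is not None:
            category_primary[primary] = (
                category_primary.get(primary, 0) + r.spectral_count
            )

    total_in = sum(r.spectral_count for r in spectral_records)
    return {
        "n_proteins_detected": len({r.protein_id for r in spectral_records}),
        "total_spectral_count": total_in,
        "annotated_spectral_count": annotated_total,
        "unannotated_spectral_count": sum(unannotated.values()),
        "unannotated_proteins": dict(sorted(unannotated.items())),
        "per_genome": dict(sorted(per_genome.items())),
        "category_totals_multi": dict(sorted(category_multi.items())),
        "category_totals_primary": dict(sorted(category_primary.items())),
    }


def _primary_category(arch: ProteinArchitecture, function_map: FunctionMap) -> str | None:
    """Substrate category of the N-terminal-most catalytic domain, if any."""
    from .model import CATALYTIC_CLASSES

    for name, cls, _, _ in arch.domains:
        if cls in CATALYTIC_CLASSES:
            return function_map.category(name)
    return None
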