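"""Protein-level classification of domain architectures and module census.

A protein is a CAZyme when it carries at least one GH, GT, CE, PL, AA or
CBM module.  A *multimodular* CAZyme couples a catalytic GH/CE/PL module
with at least one non-catalytic accessory module (CBM, SLH, dockerin or
cohesin); GT-bearing proteins are censused but not reported as
multimodular enzymes, and CBM-only proteins count as CAZymes but never as
multimodular.  Cohesin-bearing proteins without any catalytic module are
scaffoldin candidates — the structural backbone of a cellulosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .model import (
    ACCESSORY_CLASSES,
    CATALYTIC_CLASSES,
    CAZYME_CLASSES,
    MULTIMODULAR_CATALYTIC,
    ModelClass,
    ProteinArchitecture,
)


@dataclass(frozen=True)
class CAZymeClassification:
    """Classification flags for one protein's architecture."""

    protein_id: str
    catalytic_families: tuple
    accessory_families: tuple
    is_cazyme: bool
    is_multimodular: bool
    has_dockerin: bool
    has_cohesin: bool
    has_slh: bool
    is_scaffoldin_candidate: bool
    duf_accessory: bool


def classify_protein(arch: ProteinArchitecture) -> CAZymeClassification:
    """Classify one protein from its filtered, overlap-resolved architecture."""
    classes = arch.classes
    catalytic = tuple(
        name for name, cls, _, _ in arch.domains if cls in CATALYTIC_CLASSES
    )
    accessory = tuple(
        name for name, cls, _, _ in arch.domains if cls in ACCESSORY_CLASSES
    )
    has_dockerin = ModelClass.DOCKERIN in classes
    has_cohesin = ModelClass.COHESIN in classes
    has_slh = ModelClass.SLH in classes
    has_duf = ModelClass.DUF in classes
    is_cazyme = any(cls in CAZYME_CLASSES for cls in classes)
    is_multimodular = (
        any(cls in MULTIMODULAR_CATALYTIC for cls in classes) and bool(accessory)
    )
    # Scaffoldins are non-catalytic structural proteins bearing cohesins.
    is_scaffoldin = has_cohesin and not catalytic
    duf_accessory = has_duf and bool(accessory) and not catalytic
    return CAZymeClassification(
        protein_id=arch.protein_id,
        catalytic_families=catalytic,
        accessory_families=accessory,
        is_cazyme=is_cazyme,
        is_multimodular=is_multimodular,
        has_dockerin=has_dockerin,
        has_cohesin=has_cohesin,
        has_slh=has_slh,
        is_scaffoldin_candidate=is_scaffoldin,
        duf_accessory=duf_accessory,
    )


def duf_screen(
    classifications: Mapping[str, CAZymeClassification],
    architectures: Mapping[str, ProteinArchitecture],
) -> list:
    """Find accessory-module proteins whose only other content is DUFs.

    Returns ``(protein_id, duf_names, accessory_names)`` for proteins with
    at least one accessory module (CBM/dockerin/SLH), at least one domain
    of unknown function, and no catalytic module — candidates for new
    CAZyme family discovery.
    """
    out = []
    for pid in sorted(classifications):
        cls = classifications[pid]
        arch = architectures[pid]
        dufs = tuple(
            name for name, c, _, _ in arch.domains if c is ModelClass.DUF
        )
        screen_accessory = tuple(
            name
            for name, c, _, _ in arch.domains
            if c in (ModelClass.CBM, ModelClass.DOCKERIN, ModelClass.SLH)
        )
        if dufs and screen_accessory and not cls.catalytic_families:
            out.append((pid, dufs, screen_accessory))
    return out


@dataclass
class ModuleCensus:
    """Module-level counts over a protein set.

    ``module_counts`` counts domain occurrences (a protein with two CBM6
    modules contributes 2 to CBM); ``distinct_architectures`` counts unique
    architecture strings among multimodular proteins, subfamily-sensitive.
    """

    module_counts: Counter = field(default_factory=Counter)      # class -> modules
    distinct_families: dict = field(default_factory=dict)        # class -> n families
    family_counts: Counter = field(default_factory=Counter)      # family name -> modules
    architecture_frequency: Counter = field(default_factory=Counter)
    distinct_architectures: int = 0
    n_proteins: int = 0
    n_cazyme_proteins: int = 0
    n_multimodular: int = 0

    def __add__(self, other: "ModuleCensus") -> "ModuleCensus":
        merged_fams: dict = {}
        out = ModuleCensus(
            module_counts=self.module_counts + other.module_counts,
            family_counts=self.family_counts + other.family_counts,
            architecture_frequency=self.architecture_frequency
            + other.architecture_frequency,
            n_proteins=self.n_proteins + other.n_proteins,
            n_cazyme_proteins=self.n_cazyme_proteins + other.n_cazyme_proteins,
            n_multimodular=self.n_multimodular + other.n_multimodular,
        )
        # family sets are recomputed from merged family counts
        for fam in out.family_counts:
            cls = _family_class(fam)
            merged_fams.setdefault(cls, set()).add(fam)
        out.distinct_families = {c: len(s) for c, s in merged_fams.items()}
        out.distinct_architectures = len(
            set(self._multimodular_archs) | set(other._multimodular_archs)
        )
        out._multimodular_archs = sorted(
            set(self._multimodular_archs) | set(other._multimodular_archs)
        )
        return out

    _multimodular_archs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "module_counts": {k.value: v for k, v in sorted(self.module_counts.items())},
            "distinct_families": {
                k.value: v for k, v in sorted(self.distinct_families.items())
            },
            "family_counts": dict(sorted(self.family_counts.items())),
            "architecture_frequency": dict(sorted(self.architecture_frequency.items())),
            "distinct_architectures": self.distinct_architectures,
            "n_proteins": self.n_proteins,
            "n_cazyme_proteins": self.n_cazyme_proteins,
            "n_multimodular": self.n_multimodular,
        }


def _family_class(family: str) -> ModelClass:
    from .model import classify_model_name

    return classify_model_name(family)


def census(
    classifications: Mapping[str, CAZymeClassification],
    architectures: Mapping[str, ProteinArchitecture],
) -> ModuleCensus:
    """Count modules, families and architectures over a classified protein set."""
    out = ModuleCensus()
    fams: dict = {}
    mm_archs = set()
    for pid, arch in architectures.items():
        out.n_proteins += 1
        cls = classifications[pid]
        if cls.is_cazyme:
            out.n_cazyme_proteins += 1
        if cls.is_multimodular:
            out.n_multimodular += 1
            mm_archs.add(arch.architecture_string)
        for name, dcls, _, _ in arch.domains:
            out.module_counts[dcls] += 1
            out.family_counts[name] += 1
            fams.setdefault(dcls, set()).add(name)
        if len(arch) > 0:
            out.architecture_frequency[arch.architecture_string] += 1
    out.distinct_families = {c: len(s) for c, s in fams.items()}
    out.distinct_architectures = len(mm_archs)
    out._multimodular_archs = sorted(mm_archs)
    return out


def write_classifications_tsv(
    classifications: Mapping[str, CAZymeClassification],
    architectures: Mapping[str, ProteinArchitecture],
    path,
    genome_of: Mapping[str, str] | None = None,
) -> None:
    """Stable-ordered TSV of per-protein classifications."""
    cols = [
        "protein_id", "genome_id", "architecture", "is_cazyme", "is_multimodular",
        "has_dockerin", "has_cohesin", "has_slh", "is_scaffoldin_candidate",
        "duf_accessory", "catalytic_families", "accessory_families",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for pid in sorted(classifications):
            c = classifications[pid]
            g = genome_of.get(pid, "unbinned") if genome_of else "unbinned"
            fh.write(
                "\t".join(
                    [
                        pid,
                        g,
                        architectures[pid].architecture_string,
                        str(int(c.is_cazyme)),
                        str(int(c.is_multimodular)),
                        str(int(c.has_dockerin)),
                        str(int(c.has_cohesin)),
                        str(int(c.has_slh)),
                        str(int(c.is_scaffoldin_candidate)),
                        str(int(c.duf_accessory)),
                        ",".join(c.catalytic_families),
                        ",".join(c.accessory_families),
                    ]
                )
                + "\n"
            )
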