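"""Core domain model: domain hits, protein architectures, genes, locus calls.

Coordinates are 1-based inclusive throughout (HMMER / GFF3 convention).
Gene order along a contig is expressed as a 0-based ``rank`` — the ordinal
of the protein prediction in coordinate order — because locus calling works
in units of gene predictions, not base pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class ModelClass(str, Enum):
    """Functional class of a profile model, inferred from its name."""

    GH = "GH"
    GT = "GT"
    CE = "CE"
    PL = "PL"
    AA = "AA"
    CBM = "CBM"
    SLH = "SLH"
    COHESIN = "COHESIN"
    DOCKERIN = "DOCKERIN"
    SUSC = "SUSC"
    SUSD = "SUSD"
    DUF = "DUF"
    OTHER = "OTHER"


#: CAZy catalytic classes (enzymatically active modules).
CATALYTIC_CLASSES = frozenset(
    {ModelClass.GH, ModelClass.GT, ModelClass.CE, ModelClass.PL, ModelClass.AA}
)
#: Catalytic classes eligible to anchor a multimodular enzyme call
#: (GTs are housekeeping transferases and are excluded from that call).
MULTIMODULAR_CATALYTIC = frozenset({ModelClass.GH, ModelClass.CE, ModelClass.PL})
#: Non-catalytic accessory module classes.
ACCESSORY_CLASSES = frozenset(
    {ModelClass.CBM, ModelClass.SLH, ModelClass.DOCKERIN, ModelClass.COHESIN}
)
#: Classes that make a protein a CAZyme when present.
CAZYME_CLASSES = frozenset(
    {ModelClass.GH, ModelClass.GT, ModelClass.CE, ModelClass.PL, ModelClass.AA, ModelClass.CBM}
)

_CAZY_PREFIX = re.compile(r"^(GH|GT|CE|PL|AA|CBM|SLH)(?=\d|_|$)")

#: Transcriptional-regulator model names recognised in locus cargo
#: (AraC/MarR/LacI/GntR families and hybrid two-component systems).
REGULATOR_NAMES = frozenset({"AraC", "MarR", "LacI", "GntR", "HTCS"})


def classify_model_name(name: str) -> ModelClass:
    """Infer the functional class of a profile model from its name.

    CAZy-style prefixes (``GH5_4`` -> GH, ``CBM22`` -> CBM, ...) are matched
    before the subfamily token; ``cohesin``/``dockerin`` (PF00963/PF00404),
    ``SusD`` (PF07980), ``SusC``/``TIGR04056`` and ``DUF*`` names are matched
    case-insensitively on their stems.  Anything else is OTHER.
    """
    m = _CAZY_PREFIX.match(name)
    if m:
        return ModelClass(m.group(1))
    low = name.lower()
    if low.startswith("cohesin") or name == "PF00963":
        return ModelClass.COHESIN
    if low.startswith("dockerin") or name == "PF00404":
        return ModelClass.DOCKERIN
    if low.startswith("susd") or name == "PF07980":
        return ModelClass.SUSD
    if low.startswith("susc") or name == "TIGR04056":
        return ModelClass.SUSC
    if low.startswith("duf"):
        return ModelClass.DUF
    return ModelClass.OTHER


def family_root(model_name: str) -> str:
    """Strip the subfamily token: ``GH5_4`` -> ``GH5``, ``dockerin_I`` -> ``dockerin``."""
    return model_name.split("_", 1)[0]


@dataclass(frozen=True)
class DomainHit:
    """One protein-vs-model alignment row from a domain table."""

    protein_id: str
    protein_length: int
    model_name: str
    model_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    i_evalue: float
    score: float
    model_class: ModelClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model_class is None:
            object.__setattr__(self, "model_class", classify_model_name(self.model_name))
        if self.model_length <= 0:
            raise ValueError(f"model_length must be positive, got {self.model_length}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValueError(
                f"invalid HMM span {self.hmm_from}..{self.hmm_to} "
                f"for model {self.model_name} of length {self.model_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to <= self.protein_length):
            raise ValueError(
                f"invalid alignment span {self.ali_from}..{self.ali_to} "
                f"for protein {self.protein_id} of length {self.protein_length}"
            )
        if self.i_evalue < 0:
            raise ValueError("i_evalue must be non-negative")

    @property
    def hmm_coverage(self) -> float:
        """Fraction of the profile model spanned by the hit (model side)."""
        return (self.hmm_to - self.hmm_from + 1) / self.model_length

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered (N->C) domain content of one protein.

    ``architecture_string`` dash-joins model names in alignment order,
    e.g. ``GH5_4-CBM22-CE3-dockerin_I``.
    """

    protein_id: str
    domains: tuple  # of (model_name, ModelClass, ali_from, ali_to)

    @property
    def architecture_string(self) -> str:
        return "-".join(d[0] for d in self.domains)

    @property
    def classes(self) -> tuple:
        return tuple(d[1] for d in self.domains)

    def __len__(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with its position and functional labels.

    ``functional_labels`` is a frozenset of strings of the form ``SUSC``,
    ``SUSD``, ``COHESIN``, ``DOCKERIN``, ``CAZYME:<class>:<family>``,
    ``REGULATOR:<name>``, ``PEPTIDASE`` or ``OTHER``.
    """

    genome_id: str
    contig_id: str
    protein_id: str
    start: int
    end: int
    strand: str
    rank: int
    functional_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.protein_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.protein_id}: strand must be + or -")

    def has_label(self, prefix: str) -> bool:
        return any(lab == prefix or lab.startswith(prefix + ":") for lab in self.functional_labels)

    def cazyme_families(self) -> list:
        """CAZy families carried by the gene, as (class, family) pairs."""
        out = []
        for lab in sorted(self.functional_labels):
            if lab.startswith("CAZYME:"):
                _, cls, fam = lab.split(":", 2)
                out.append((cls, fam))
        return out


def gene_labels_from_architecture(arch: ProteinArchitecture) -> frozenset:
    """Derive a gene's functional labels from its domain architecture."""
    labels = set()
    for name, cls, _, _ in arch.domains:
        if cls in CAZYME_CLASSES:
            labels.add(f"CAZYME:{cls.value}:{name}")
        elif cls is ModelClass.SUSC:
            labels.add("SUSC")
        elif cls is ModelClass.SUSD:
            labels.add("SUSD")
        elif cls is ModelClass.COHESIN:
            labels.add("COHESIN")
        elif cls is ModelClass.DOCKERIN:
            labels.add("DOCKERIN")
        elif name in REGULATOR_NAMES:
            labels.add(f"REGULATOR:{name}")
        elif "peptidase" in name.lower():
            labels.add("PEPTIDASE")
    if not labels:
        labels.add("OTHER")
    return frozenset(labels)
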