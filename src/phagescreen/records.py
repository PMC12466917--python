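"""Shared coordinate-system records: replicons, gene features, candidates, calls.

Every pipeline stage exchanges data through these containers. Coordinates are
1-based inclusive (GFF3 convention); gene order on a replicon is given by
``gene_index`` (0-based position in the annotation, not a genomic coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneFeature:
    """One annotated gene on a replicon.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    forward strand; ``strand`` is '+' or '-'.
    """

    gene_index: int
    start: int
    end: int
    strand: str
    product: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid feature coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A replicon sequence plus its ordered, stranded gene annotation."""

    id: str
    name: str
    accession: str
    sequence: str
    genes: list[GeneFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def protein_id(phage_id: str, gene_index: int) -> str:
    """Canonical protein identifier ``phageID|geneIndex``."""
    return f"{phage_id}|{gene_index}"


def split_protein_id(pid: str) -> tuple[str, int]:
    phage, idx = pid.rsplit("|", 1)
    return phage, int(idx)


#: The six resistance-mechanism classes used to annotate reference ARGs.
MECHANISM_CLASSES = (
    "inactivation",
    "efflux",
    "target alteration",
    "target protection",
    "target replacement",
    "other/reduced permeability",
)


@dataclass
class ReferenceProtein:
    """Entry of the reference ARG protein database.

    FASTA headers follow ``accession|family|mechanism|drugClass``.
    """

    accession: str
    family: str
    mechanism: str
    drug_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISM_CLASSES:
            raise ValueError(f"unknown mechanism class {self.mechanism!r}")

    @property
    def header(self) -> str:
        return f"{self.accession}|{self.family}|{self.mechanism}|{self.drug_class}"

    @classmethod
    def from_header(cls, header: str, sequence: str) -> "ReferenceProtein":
        parts = header.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed reference header {header!r}")
        return cls(*parts, sequence=sequence)


@dataclass
class ARGCandidate:
    """A phage protein flagged by at least one detection channel."""

    protein_id: str
    phage_id: str
    gene_index: int
    channels: set[str]
    best_family: str
    mechanism: str
    best_identity_pct: float
    best_qcov_pct: float
    product: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("candidate must be supported by >=1 channel")
        bad = self.channels - {"homology", "domain", "structure"}
        if bad:
            raise ValueError(f"unknown channels {bad}")


@dataclass
class LifestyleCall:
    """Lytic/temperate label with the ordered trail of rules that fired."""

    phage_id: str
    label: str
    evidence: list[str]

    def __post_init__(self) -> None:
        if self.label not in ("lytic", "temperate"):
            raise ValueError(f"invalid lifestyle label {self.label!r}")
        if not self.evidence:
            raise ValueError("evidence trail must be non-empty")


@dataclass
class NucleotideHit:
    """One nucleotide local-alignment hit of a gene against a replicon."""

    gene_id: str
    replicon_id: str
    identity_pct: float
    query_coverage_pct: float
    subject_start: int
    subject_end: int
    strand: str
    raw_score: float = 0.0


@dataclass
class DisseminationCall:
    gene_id: str
    disseminated: bool
    verified_origin: str  # bacterial | phage-derived | unknown
    hits: list[NucleotideHit] = field(default_factory=list)


@dataclass
class MGEHit:
    phage_id: str
    gene_index: int
    mge_type: str  # IS | conjugative | integron
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mge_type not in ("IS", "conjugative", "integron"):
            raise ValueError(f"unknown MGE type {self.mge_type!r}")


@dataclass
class AdjacencyCall:
    arg_gene_index: int
    mge_gene_index: int
    intervening_gene_count: int | None
    adjacent: bool
    comparable: bool = True
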