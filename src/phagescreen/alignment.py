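"""Exact pairwise alignment and Karlin–Altschul E-values.

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment with affine
gaps is delegated to :class:`Bio.Align.PairwiseAligner`, configured so that a
gap of length L costs ``gap_open + L * gap_extend`` (the BLAST convention).
Identity is counted over all alignment columns including gap columns, and
query coverage is the span of the single best local alignment — no HSP
tiling.

E-values use the Karlin–Altschul form E = m * n * 2**(-S') with
S' = (lambda * S - ln K) / ln 2, with fixed gapped-BLOSUM62 constants
lambda = 0.267 nats, K = 0.041, so results are deterministic and do not
depend on any external search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Gapped BLOSUM62 (open 11, extend 1) Karlin–Altschul constants.
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and K-A constants.

    ``gap_open`` and ``gap_extend`` are positive penalties; a gap of length L
    costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str
    gap_open: int
    gap_extend: int
    lam: float
    k: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    if name == "BLOSUM62X":
        # BLOSUM62 with the ambiguity code X scored 0 against everything.
        m = substitution_matrices.load("BLOSUM62").copy()
        for a in m.alphabet:
            m[a, "X"] = 0.0
            m["X", a] = 0.0
        return m
    if name.startswith("NT:"):
        match, mismatch = (float(x) for x in name[3:].split(","))
        alphabet = "ACGTN"
        m = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                if "N" in (a, b):
                    m[a, b] = 0.0
                else:
                    m[a, b] = match if a == b else mismatch
        return m
    return substitution_matrices.load(name)


def protein_scheme() -> ScoringScheme:
    """Default protein scheme: BLOSUM62 (X scored 0), gaps 11/1."""
    return ScoringScheme("BLOSUM62X", 11, 1, LAMBDA_GAPPED, K_GAPPED)


def nucleotide_scheme() -> ScoringScheme:
    """Default nucleotide scheme: match +2 / mismatch -3, gaps 5/2.

    The K-A constants are the standard ones for this reward/penalty pair.
    """
    return ScoringScheme("NT:2,-3", 5, 2, 0.625, 0.41)


@dataclass
class AlignmentHit:
    """One local alignment with score, E-value, identity and coverage."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity_pct: float
    qcov_pct: float
    query_start: int  # 1-based inclusive
    query_end: int
    subject_start: int
    subject_end: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if not 0.0 <= self.qcov_pct <= 100.0:
            raise ValueError("qcov_pct outside [0, 100]")


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int, mode: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _load_matrix(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalised score S' = (lambda*S - ln K) / ln 2, in bits."""
    return (scheme.lam * raw_score - math.log(scheme.k)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Karlin–Altschul expectation E = m * n * 2**(-S')."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    # Guard 2**(-bits) against overflow for strongly negative scores.
    return float(m) * float(n) * math.exp(-bits * math.log(2.0)) if bits > -500 else math.inf


def local_score(query: str, subject: str, scheme: ScoringScheme) -> float:
    """Raw Smith–Waterman score only (cheaper than a full traceback)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "local")
    return float(aligner.score(query, subject))


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int]:
    """(identities, columns, qstart, qend, sstart, send, aligned_query_span)."""
    counts = alignment.counts()
    gaps = counts.internal_gaps  # local alignments have no terminal gaps
    identities = counts.identities
    columns = identities + counts.mismatches + gaps
    qblocks, sblocks = alignment.aligned
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    return identities, columns, qstart, qend, sstart, send, qend - qstart


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    m: int | None = None,
    n: int | None = None,
) -> AlignmentHit:
    """Best-scoring Smith–Waterman local alignment with affine gaps.

    ``m``/``n`` set the E-value search space (default: the two sequence
    lengths; detection channels pass the database residue total as ``n``).
    """
    if scheme is None:
        scheme = protein_scheme()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "local")
    alignments = aligner.align(query, subject)
    best = alignments[0]
    score = float(best.score)
    identities, columns, qs, qe, ss, se, qspan = _alignment_stats(best)
    bits = bit_score(score, scheme)
    ident = 100.0 * identities / columns if columns else 0.0
    qcov = 100.0 * qspan / len(query)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bits,
        evalue=evalue(bits, m or len(query), n or len(subject)),
        identity_pct=ident,
        qcov_pct=qcov,
        query_start=qs + 1,
        query_end=qe,
        subject_start=ss + 1,
        subject_end=se,
    )


def global_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Percent identity of the global alignment, gap columns included."""
    if scheme is None:
        scheme = protein_scheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "global")
    best = aligner.align(a, b)[0]
    counts = best.counts()
    identities = counts.identities
    columns = identities + counts.mismatches + counts.gaps
    return 100.0 * identities / columns if columns else 0.0


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform random amino-acid sequence over the 20-letter alphabet."""
    return "".join(rng.choice(list(PROTEIN_ALPHABET), size=length))


def random_nucleotide(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
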