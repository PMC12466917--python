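"""The three ARG detection channels and candidate-level filters.

Channel thresholds are the screen's lenient defaults: homology keeps hits
with E <= 1e-5 and query coverage >= 60%; the domain channel keeps profile
windows with score >= 40 bits and decoy-Gumbel E <= 1e-5; the structure
stand-in scores 3-mer composition cosine similarity against family
centroids. Candidates flagged by any channel form the union, partitioned by
seven-region Venn accounting. A "reported ARG" is a candidate at >= 90%
identity and >= 85% query coverage to the reference database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentHit,
    ScoringScheme,
    bit_score,
    evalue,
    local_align,
    local_score,
    protein_scheme,
)
from .profiles import PSSMProfile, domain_evalue, scan_best_window
from .records import ARGCandidate, GenomeRecord, ReferenceProtein, split_protein_id

logger = logging.getLogger(__name__)

E_MAX_DEFAULT = 1e-5
QCOV_MIN_DEFAULT = 60.0
SCORE_MIN_DEFAULT = 40.0
REPORTED_ID_MIN = 90.0
REPORTED_QCOV_MIN = 85.0


def passes_homology(
    e: float, qcov: float, e_max: float = E_MAX_DEFAULT, qcov_min: float = QCOV_MIN_DEFAULT
) -> bool:
    """Homology-channel rule: E <= e_max AND query coverage >= qcov_min."""
    return e <= e_max and qcov >= qcov_min


def passes_domain(
    score: float, e: float, score_min: float = SCORE_MIN_DEFAULT, e_max: float = E_MAX_DEFAULT
) -> bool:
    """Domain-channel rule: window score >= score_min AND E <= e_max."""
    return score >= score_min and e <= e_max


def passes_reported(
    identity: float,
    qcov: float,
    id_min: float = REPORTED_ID_MIN,
    qcov_min: float = REPORTED_QCOV_MIN,
) -> bool:
    """Reported-ARG rule: identity >= id_min AND coverage >= qcov_min."""
    return identity >= id_min and qcov >= qcov_min


def _min_raw_score(e_max: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Smallest raw score whose E-value can still pass ``e_max``."""
    # E = m n 2^{-S'} <= e_max  <=>  S' >= log2(mn/e_max)
    bits_needed = math.log2(m * n / e_max)
    return (bits_needed * math.log(2.0) + math.log(scheme.k)) / scheme.lam


def channel_homology(
    proteins: dict[str, str],
    refdb: list[ReferenceProtein],
    scheme: ScoringScheme | None = None,
    e_max: float = E_MAX_DEFAULT,
    qcov_min: float = QCOV_MIN_DEFAULT,
) -> dict[str, list[AlignmentHit]]:
    """Local-alignment homology channel against the reference ARG database.

    Retains, per protein, every reference hit with E <= e_max AND query
    coverage >= qcov_min; hits are sorted best-first by (bit score, E,
    subject accession). The E-value search space is query length x total
    database residues. A score-only pass skips the traceback for pairs whose
    E-value already fails, which is exact because E depends only on score.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    if scheme is None:
        scheme = protein_scheme()
    n_db = sum(len(r.sequence) for r in refdb)
    results: dict[str, list[AlignmentHit]] = {}
    for pid, seq in proteins.items():
        hits = []
        for ref in refdb:
            score = local_score(seq, ref.sequence, scheme)
            bits = bit_score(score, scheme)
            e = evalue(bits, len(seq), n_db)
            if not passes_homology(e, 100.0, e_max, 0.0):
                continue
            hit = local_align(
                seq, ref.sequence, scheme, query_id=pid, subject_id=ref.accession,
                m=len(seq), n=n_db,
            )
            if passes_homology(hit.evalue, hit.qcov_pct, e_max, qcov_min):
                hits.append(hit)
        hits.sort(key=lambda h: (-h.bit_score, h.evalue, h.subject_id))
        if hits:
            results[pid] = hits
    return results


@dataclass
class DomainHit:
    protein_id: str
    profile_name: str
    score: float
    evalue: float
    profile_coverage_pct: float


def channel_domain(
    proteins: dict[str, str],
    profiles: list[PSSMProfile],
    score_min: float = SCORE_MIN_DEFAULT,
    e_max: float = E_MAX_DEFAULT,
) -> dict[str, list[DomainHit]]:
    """Profile-scan channel: best ungapped window per (protein, profile).

    A hit is kept iff window score >= score_min AND decoy-Gumbel E <= e_max,
    with the search space taken as the number of proteins scanned.
    Uncalibrated profiles raise.
    """
    from .profiles import UncalibratedProfileError

    for prof in profiles:
        if not prof.calibrated:
            raise UncalibratedProfileError(
                f"profile {prof.name!r} has no decoy calibration"
            )
    n_targets = max(1, len(proteins))
    results: dict[str, list[DomainHit]] = {}
    for pid, seq in proteins.items():
        hits = []
        for prof in profiles:
            score, _qstart, span = scan_best_window(prof, seq)
            if score < score_min:
                continue  # skip the E-value computation for hopeless windows
            e = domain_evalue(prof, score, n_targets)
            if not passes_domain(score, e, score_min, e_max):
                continue
            hits.append(
                DomainHit(pid, prof.name, score, e, 100.0 * span / prof.length)
            )
        hits.sort(key=lambda h: (-h.score, h.evalue, h.profile_name))
        if hits:
            results[pid] = hits
    return results


@dataclass
class StructureHit:
    protein_id: str
    family: str
    similarity: float


def kmer_vector(seq: str, k: int = 3) -> np.ndarray:
    """Amino-acid k-mer count vector (20**k dims, unknown letters skipped)."""
    from .profiles import encode_protein

    codes = encode_protein(seq)
    vec = np.zeros(20**k)
    for i in range(len(codes) - k + 1):
        window = codes[i : i + k]
        if (window >= 20).any():
            continue
        idx = 0
        for c in window:
            idx = idx * 20 + int(c)
        vec[idx] += 1
    return vec


def build_family_centroids(refdb: list[ReferenceProtein], k: int = 3) -> dict[str, np.ndarray]:
    """Mean (unit-normalised) k-mer composition per reference family."""
    groups: dict[str, list[np.ndarray]] = {}
    for ref in refdb:
        v = kmer_vector(ref.sequence, k)
        norm = np.linalg.norm(v)
        if norm > 0:
            groups.setdefault(ref.family, []).append(v / norm)
    return {fam: np.mean(vs, axis=0) for fam, vs in groups.items()}


def channel_structure(
    proteins: dict[str, str],
    family_centroids: dict[str, np.ndarray],
    similarity_min: float = 0.2,
    k: int = 3,
) -> dict[str, list[StructureHit]]:
    """Structure-similarity stand-in: 3-mer composition cosine to centroids.

    Any external scorer producing (protein id, family, score) rows can be
    merged in place of this baseline via :func:`merge_channels`.
    """
    results: dict[str, list[StructureHit]] = {}
    cent_items = sorted(family_centroids.items())
    for pid, seq in proteins.items():
        v = kmer_vector(seq, k)
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        hits = []
        for fam, cent in cent_items:
            cnorm = np.linalg.norm(cent)
            sim = float(v @ cent / cnorm) if cnorm > 0 else 0.0
            if sim >= similarity_min:
                hits.append(StructureHit(pid, fam, sim))
        hits.sort(key=lambda h: (-h.similarity, h.family))
        if hits:
            results[pid] = hits
    return results


def merge_channels(
    hits_homology: dict[str, list[AlignmentHit]],
    hits_domain: dict[str, list[DomainHit]],
    hits_structure: dict[str, list[StructureHit]],
    refdb: list[ReferenceProtein],
    products: dict[str, str] | None = None,
    best_identity: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[ARGCandidate], dict[str, int]]:
    """Union of the three channels plus seven-region Venn accounting.

    Venn keys: 'H', 'D', 'S' (exclusive), 'HD', 'HS', 'DS' (pairwise
    exclusive), 'HDS' (all three). ``best_identity`` maps protein id ->
    (identity, qcov) versus the reference DB for proteins with no passing
    homology hit (used for the reported-ARG class and sensitivity scan).
    """
    fam_mech = {r.family: r.mechanism for r in refdb}
    acc_fam = {r.accession: r.family for r in refdb}
    in_h, in_d, in_s = set(hits_homology), set(hits_domain), set(hits_structure)
    union = in_h | in_d | in_s
    venn = {"H": 0, "D": 0, "S": 0, "HD": 0, "HS": 0, "DS": 0, "HDS": 0}
    candidates = []
    for pid in sorted(union):
        key = ("H" if pid in in_h else "") + ("D" if pid in in_d else "") + (
            "S" if pid in in_s else ""
        )
        venn[key] += 1
        channels = set()
        family = None
        if pid in in_h:
            channels.add("homology")
            family = acc_fam.get(hits_homology[pid][0].subject_id)
        if pid in in_d:
            channels.add("domain")
            family = family or hits_domain[pid][0].profile_name
        if pid in in_s:
            channels.add("structure")
            family = family or hits_structure[pid][0].family
        if pid in in_h:
            best = hits_homology[pid][0]
            ident, qcov = best.identity_pct, best.qcov_pct
        elif best_identity and pid in best_identity:
            ident, qcov = best_identity[pid]
        else:
            ident, qcov = 0.0, 0.0
        phage_id, gene_index = split_protein_id(pid)
        candidates.append(
            ARGCandidate(
                protein_id=pid,
                phage_id=phage_id,
                gene_index=gene_index,
                channels=channels,
                best_family=family or "unknown",
                mechanism=fam_mech.get(family, "other/reduced permeability"),
                best_identity_pct=ident,
                best_qcov_pct=qcov,
                product=(products or {}).get(pid, ""),
            )
        )
    return candidates, venn


def best_identity_vs_refdb(
    proteins: dict[str, str],
    refdb: list[ReferenceProtein],
    scheme: ScoringScheme | None = None,
) -> dict[str, tuple[float, float]]:
    """Unthresholded best (identity, qcov) per protein versus the DB."""
    if scheme is None:
        scheme = protein_scheme()
    out = {}
    for pid, seq in proteins.items():
        best = None
        for ref in refdb:
            hit = local_align(seq, ref.sequence, scheme, query_id=pid, subject_id=ref.accession)
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best is not None:
            out[pid] = (best.identity_pct, best.qcov_pct)
    return out


def blacklist_filter(
    candidates: list[ARGCandidate], keyword_list: list[str]
) -> list[ARGCandidate]:
    """Drop candidates whose product matches any keyword (case-insensitive
    substring) — the manual exclusion of ARG regulators and
    mutational-resistance genes, automated over product annotations."""
    keywords = [k.lower() for k in keyword_list]
    kept = []
    for cand in candidates:
        product = cand.product.lower()
        matched = next((k for k in keywords if k in product), None)
        if matched is not None:
            logger.info(
                "blacklist: removing %s (product %r matches %r)",
                cand.protein_id, cand.product, matched,
            )
            continue
        kept.append(cand)
    return kept


def reported_arg_class(
    candidates: list[ARGCandidate],
    id_min: float = REPORTED_ID_MIN,
    qcov_min: float = REPORTED_QCOV_MIN,
) -> list[ARGCandidate]:
    """Candidates at >= id_min identity AND >= qcov_min coverage."""
    return [
        c
        for c in candidates
        if passes_reported(c.best_identity_pct, c.best_qcov_pct, id_min, qcov_min)
    ]


def sensitivity_scan(
    candidates: list[ARGCandidate],
    lifestyles: dict[str, str],
    cutoffs: tuple[float, ...] = (30, 40, 50, 60, 70, 80, 90),
) -> pd.DataFrame:
    """Candidate counts per identity cutoff, stratified by phage lifestyle."""
    rows = []
    for c in cutoffs:
        passing = [x for x in candidates if x.best_identity_pct >= c]
        rows.append(
            {
                "cutoff": c,
                "lytic": sum(1 for x in passing if lifestyles.get(x.phage_id) == "lytic"),
                "temperate": sum(
                    1 for x in passing if lifestyles.get(x.phage_id) == "temperate"
                ),
                "total": len(passing),
            }
        )
    return pd.DataFrame(rows)


def dedup_genomes(
    genomes: list[GenomeRecord],
    identity_min: float = 99.9,
    coverage_min: float = 99.9,
    mutant_keyword: str = "mutant",
) -> list[GenomeRecord]:
    """Collapse same-name near-identical genomes; drop mutant-flagged ones.

    Within a name group, genomes whose pairwise nucleotide identity AND
    mutual coverage both exceed the 99.9% thresholds are merged, keeping the
    lexicographically smallest accession. Genomes whose name contains the
    mutant keyword (case-insensitive) are removed first.
    """
    from .dissemination import whole_genome_similarity

    kept = [g for g in genomes if mutant_keyword.lower() not in g.name.lower()]
    by_name: dict[str, list[GenomeRecord]] = {}
    for g in kept:
        by_name.setdefault(g.name, []).append(g)
    result = []
    for name in by_name:
        group = sorted(by_name[name], key=lambda g: g.accession)
        clusters: list[list[GenomeRecord]] = []
        for g in group:
            placed = False
            for cluster in clusters:
                rep = cluster[0]
                id1, cov1 = whole_genome_similarity(g.sequence, rep.sequence)
                id2, cov2 = whole_genome_similarity(rep.sequence, g.sequence)
                if (
                    id1 > identity_min
                    and id2 > identity_min
                    and cov1 > coverage_min
                    and cov2 > coverage_min
                ):
                    cluster.append(g)
                    placed = True
                    break
            if not placed:
                clusters.append([g])
        for cluster in clusters:
            result.append(min(cluster, key=lambda g: g.accession))
    result.sort(key=lambda g: g.accession)
    return result
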