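"""Nucleotide search against bacterial replicons and dissemination calls.

A gene has been disseminated when a bacterial replicon carries a
near-identical copy — strictly more than 90% identity over strictly more
than 90% of the gene length — and the replicon's verified origin is
bacterial (phage-derived records such as pseudo-lysogenic plasmid copies
never count). The nucleotide search is exact-k-mer seeded: seeds are grouped
into diagonal clusters, and each cluster's window is resolved with an exact
local alignment (match +2, mismatch -3, gap 5/2), on both strands.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .alignment import (
    ScoringScheme,
    local_align,
    nucleotide_scheme,
    revcomp,
)
from .records import DisseminationCall, GenomeRecord, NucleotideHit

DISS_ID_MIN = 90.0  # strict >
DISS_COV_MIN = 90.0  # strict >
PSEUDOLYSOGENY_ID_MIN = 95.0  # >=
PSEUDOLYSOGENY_COV_MIN = 95.0  # >=
DEFAULT_K = 15

#: Product keywords marking plasmid-replication machinery; a plasmid whose
#: annotation contains any of these is not called pseudo-lysogenic.
PLASMID_REPLICATION_KEYWORDS = (
    "replication initiator",
    "rep protein",
    "repa",
    "repb",
    "plasmid replication",
)


def passes_dissemination(
    identity: float, coverage: float, id_min: float = DISS_ID_MIN, cov_min: float = DISS_COV_MIN
) -> bool:
    """Dissemination rule: strictly > 90% identity AND strictly > 90% coverage."""
    return identity > id_min and coverage > cov_min


def kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i : i + k]].append(i)
    return index


def _seed_clusters(
    gene: str, index: dict[str, list[int]], k: int, band: int
) -> list[tuple[int, int]]:
    """Cluster seed diagonals; return (min_subject_pos, max_subject_pos) spans."""
    diagonals: list[tuple[int, int]] = []  # (diagonal, subject_pos)
    for qpos in range(len(gene) - k + 1):
        for spos in index.get(gene[qpos : qpos + k], ()):
            diagonals.append((spos - qpos, spos))
    if not diagonals:
        return []
    diagonals.sort()
    clusters = []
    cur_diag, cur_min, cur_max = diagonals[0][0], diagonals[0][1], diagonals[0][1]
    for diag, spos in diagonals[1:]:
        if diag - cur_diag <= band:
            cur_diag = diag
            cur_min = min(cur_min, spos)
            cur_max = max(cur_max, spos)
        else:
            clusters.append((cur_min, cur_max))
            cur_diag, cur_min, cur_max = diag, spos, spos
    clusters.append((cur_min, cur_max))
    return clusters


def nt_search(
    gene: str,
    replicon: str,
    gene_id: str = "gene",
    replicon_id: str = "replicon",
    k: int = DEFAULT_K,
    scheme: ScoringScheme | None = None,
    index: dict[str, list[int]] | None = None,
) -> list[NucleotideHit]:
    """Seeded local nucleotide alignments of a gene against a replicon.

    Both strands are searched; identity counts all alignment columns and
    query coverage is the aligned gene span. Within each seeded window the
    alignment is exact dynamic programming, so hits match a full
    Smith–Waterman whenever the homologous region is seedable. A precomputed
    forward-strand ``index`` of the replicon may be supplied.
    """
    if len(gene) < k:
        raise ValueError(f"gene shorter than seed size k={k}")
    if scheme is None:
        scheme = nucleotide_scheme()
    fwd_index = index if index is not None else kmer_index(replicon, k)
    hits: list[NucleotideHit] = []
    margin = len(gene)
    for strand in ("+", "-"):
        query = gene if strand == "+" else revcomp(gene)
        for smin, smax in _seed_clusters(query, fwd_index, k, band=margin):
            w0 = max(0, smin - margin)
            w1 = min(len(replicon), smax + k + margin)
            window = replicon[w0:w1]
            hit = local_align(
                query, window, scheme, query_id=gene_id, subject_id=replicon_id
            )
            sstart = w0 + hit.subject_start
            send = w0 + hit.subject_end
            hits.append(
                NucleotideHit(
                    gene_id=gene_id,
                    replicon_id=replicon_id,
                    identity_pct=hit.identity_pct,
                    query_coverage_pct=hit.qcov_pct,
                    subject_start=sstart,
                    subject_end=send,
                    strand=strand,
                    raw_score=hit.raw_score,
                )
            )
    # collapse duplicate hits covering the same replicon interval
    hits.sort(key=lambda h: (-h.raw_score, h.subject_start, h.strand))
    kept: list[NucleotideHit] = []
    for h in hits:
        if any(
            not (h.subject_end < k2.subject_start or h.subject_start > k2.subject_end)
            for k2 in kept
        ):
            continue
        kept.append(h)
    return kept


def quick_containment(
    query: str, subject: str, k: int = DEFAULT_K, n_samples: int = 40
) -> float:
    """Fraction of sampled query k-mers found exactly in the subject.

    Both strands are checked. Used as a conservative prescreen before the
    full chained whole-genome comparison: even a 90%-identity copy keeps
    ~20% of its 15-mers intact, while an unrelated replicon shares
    essentially none.
    """
    if len(query) < k:
        return 0.0
    step = max(1, (len(query) - k) // n_samples)
    rc = revcomp(subject)
    found = total = 0
    for i in range(0, len(query) - k + 1, step):
        kmer = query[i : i + k]
        total += 1
        if kmer in subject or kmer in rc:
            found += 1
    return found / total if total else 0.0


def whole_genome_similarity(
    query: str, subject: str, k: int = DEFAULT_K, max_gap_align: int = 5000
) -> tuple[float, float]:
    """Approximate (identity %, query coverage %) of a whole-replicon match.

    Exact k-mer matches on the better strand are chained collinearly; gaps
    between consecutive chained seeds are resolved by exact global alignment
    when short (otherwise they count as unaligned). Near-identical planted
    copies score ~100/100; unrelated sequences score near zero coverage.
    """
    best = (0.0, 0.0)
    for cand in (subject, revcomp(subject)):
        index = kmer_index(cand, k)
        matches = []
        step = max(1, k // 3)
        positions = list(range(0, len(query) - k + 1, step))
        if positions and positions[-1] != len(query) - k:
            positions.append(len(query) - k)  # keep the tail seedable
        for qpos in positions:
            for spos in index.get(query[qpos : qpos + k], ())[:4]:
                matches.append((qpos, spos))
        if not matches:
            continue
        matches.sort()
        # greedy chain with strictly increasing starts (overlaps allowed)
        chain: list[tuple[int, int]] = []
        for qpos, spos in matches:
            if not chain:
                chain.append((qpos, spos))
                continue
            pq, ps = chain[-1]
            if qpos > pq and spos > ps and abs((spos - qpos) - (ps - pq)) < max_gap_align:
                chain.append((qpos, spos))
        # merge same-diagonal overlapping matches into exact blocks
        blocks: list[tuple[int, int, int]] = []  # (qstart, sstart, length)
        for qpos, spos in chain:
            if blocks:
                bq, bs, bl = blocks[-1]
                if spos - qpos == bs - bq and qpos <= bq + bl:
                    blocks[-1] = (bq, bs, qpos + k - bq)
                    continue
            blocks.append((qpos, spos, k))
        identities = columns = covered = 0
        for i, (bq, bs, bl) in enumerate(blocks):
            identities += bl
            columns += bl
            covered += bl
            if i + 1 < len(blocks):
                nq, ns, _ = blocks[i + 1]
                gq = query[bq + bl : nq]
                gs = cand[bs + bl : ns]
                if not gq and not gs:
                    continue
                if 0 < max(len(gq), len(gs)) <= max_gap_align and gq and gs:
                    from .alignment import _aligner, nucleotide_scheme as _nts

                    sch = _nts()
                    aligner = _aligner(sch.matrix_name, sch.gap_open, sch.gap_extend, "global")
                    aln = aligner.align(gq, gs)[0]
                    counts = aln.counts()
                    identities += counts.identities
                    columns += counts.identities + counts.mismatches + counts.gaps
                    covered += len(gq)
                else:
                    columns += max(len(gq), len(gs))
                    covered += len(gq) if len(gq) <= max_gap_align else 0
        identity = 100.0 * identities / columns if columns else 0.0
        coverage = 100.0 * min(covered, len(query)) / len(query)
        if coverage * identity > best[0] * best[1]:
            best = (identity, coverage)
    return best


@dataclass
class DisseminationSummary:
    calls: list[DisseminationCall]
    rate_per_lifestyle: dict[str, float]  # percentage, half-up 2 dp
    counts_per_lifestyle: dict[str, tuple[int, int]]  # (disseminated, total)


def call_dissemination(
    gene_sequences: dict[str, str],
    pool: list[GenomeRecord],
    pool_source: dict[str, str],
    lifestyles: dict[str, str] | None = None,
    id_min: float = DISS_ID_MIN,
    cov_min: float = DISS_COV_MIN,
    k: int = DEFAULT_K,
) -> DisseminationSummary:
    """Dissemination decision for each candidate gene.

    ``pool_source`` maps replicon id -> 'bacterial' | 'phage-derived'. A gene
    is disseminated iff some hit passes identity > id_min AND coverage >
    cov_min on a replicon of verified bacterial origin.
    """
    from .enrichment import proportion
    from .records import split_protein_id

    indexes = {r.id: kmer_index(r.sequence, k) for r in pool}
    calls: list[DisseminationCall] = []
    for gid in sorted(gene_sequences):
        seq = gene_sequences[gid]
        passing: list[NucleotideHit] = []
        for rep in pool:
            for hit in nt_search(
                seq, rep.sequence, gene_id=gid, replicon_id=rep.id, k=k,
                index=indexes[rep.id],
            ):
                if passes_dissemination(hit.identity_pct, hit.query_coverage_pct, id_min, cov_min):
                    passing.append(hit)
        bacterial = [h for h in passing if pool_source.get(h.replicon_id) == "bacterial"]
        if bacterial:
            origin = "bacterial"
        elif passing:
            origin = "phage-derived"
        else:
            origin = "unknown"
        calls.append(
            DisseminationCall(
                gene_id=gid,
                disseminated=bool(bacterial),
                verified_origin=origin,
                hits=passing,
            )
        )
    rates: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    if lifestyles:
        for label in ("lytic", "temperate"):
            group = [
                c for c in calls if lifestyles.get(split_protein_id(c.gene_id)[0]) == label
            ]
            n_pos = sum(c.disseminated for c in group)
            counts[label] = (n_pos, len(group))
            rates[label] = proportion(n_pos, len(group)) if group else 0.0
    return DisseminationSummary(calls=calls, rate_per_lifestyle=rates, counts_per_lifestyle=counts)


def pseudolysogeny_flag(
    plasmid: GenomeRecord,
    phage_genomes: list[GenomeRecord],
    keywords: tuple[str, ...] = PLASMID_REPLICATION_KEYWORDS,
    id_min: float = PSEUDOLYSOGENY_ID_MIN,
    cov_min: float = PSEUDOLYSOGENY_COV_MIN,
) -> bool:
    """True iff the plasmid is a whole-genome copy of some phage (>= id_min
    identity over >= cov_min of the plasmid) and its annotation carries no
    plasmid-replication gene."""
    for feat in plasmid.genes:
        product = feat.product.lower()
        if any(kw in product for kw in keywords):
            return False
    for phage in phage_genomes:
        # coverage is of the plasmid, so a much shorter phage cannot pass
        if len(phage.sequence) < 0.9 * (cov_min / 100.0) * len(plasmid.sequence):
            continue
        if quick_containment(plasmid.sequence, phage.sequence) < 0.05:
            continue
        ident, cov = whole_genome_similarity(plasmid.sequence, phage.sequence)
        if ident >= id_min and cov >= cov_min:
            return True
    return False
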