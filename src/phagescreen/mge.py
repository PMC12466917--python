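"""Mobile-genetic-element detection and the <5-gene adjacency rule.

IS elements: protein length >= 150 aa, alignment E <= 1e-30 and identity
strictly > 40% against the IS reference set. Conjugative proteins: E
strictly < 0.001 with reference (subject) coverage >= 50%. Integrons are an
interface only — externally produced calls are read from TSV. Adjacency
between an ARG and an MGE counts the annotated genes strictly between the
two features in genome order, strand-agnostic; adjacent means fewer than 5
intervening genes on the same replicon.
"""

from __future__ import annotations

import pandas as pd

from .alignment import (
    ScoringScheme,
    bit_score,
    evalue,
    local_align,
    local_score,
    protein_scheme,
)
from .records import AdjacencyCall, MGEHit, split_protein_id

IS_MIN_LENGTH = 150  # aa, >=
IS_E_MAX = 1e-30  # <=
IS_ID_MIN = 40.0  # strict >
CONJ_E_MAX = 0.001  # strict <
CONJ_COV_MIN = 50.0  # >=
ADJACENCY_MAX_INTERVENING = 5  # strict <


def passes_is(
    query_length: int,
    e: float,
    identity: float,
    min_length: int = IS_MIN_LENGTH,
    e_max: float = IS_E_MAX,
    id_min: float = IS_ID_MIN,
) -> bool:
    """IS rule: query length >= 150 aa, E <= 1e-30, identity strictly > 40%."""
    return query_length >= min_length and e <= e_max and identity > id_min


def passes_conjugative(
    e: float, coverage: float, e_max: float = CONJ_E_MAX, cov_min: float = CONJ_COV_MIN
) -> bool:
    """Conjugative rule: E strictly < 0.001, reference coverage >= 50%."""
    return e < e_max and coverage >= cov_min


def detect_is(
    proteins: dict[str, str],
    is_db: dict[str, str],
    scheme: ScoringScheme | None = None,
    min_length: int = IS_MIN_LENGTH,
    e_max: float = IS_E_MAX,
    id_min: float = IS_ID_MIN,
) -> list[MGEHit]:
    """IS-element homologs among phage proteins."""
    if scheme is None:
        scheme = protein_scheme()
    n_db = sum(len(s) for s in is_db.values())
    hits = []
    for pid in sorted(proteins):
        seq = proteins[pid]
        if len(seq) < min_length:
            continue
        for header in sorted(is_db):
            ref = is_db[header]
            score = local_score(seq, ref, scheme)
            e = evalue(bit_score(score, scheme), len(seq), n_db)
            if e > e_max:
                continue
            hit = local_align(seq, ref, scheme, query_id=pid, subject_id=header,
                              m=len(seq), n=n_db)
            if passes_is(len(seq), hit.evalue, hit.identity_pct, min_length, e_max, id_min):
                phage_id, idx = split_protein_id(pid)
                hits.append(
                    MGEHit(
                        phage_id=phage_id,
                        gene_index=idx,
                        mge_type="IS",
                        evidence={
                            "subject": header,
                            "evalue": hit.evalue,
                            "identity_pct": hit.identity_pct,
                            "query_length": len(seq),
                        },
                    )
                )
                break
    return hits


def detect_conjugative(
    proteins: dict[str, str],
    conj_db: dict[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = CONJ_E_MAX,
    cov_min: float = CONJ_COV_MIN,
) -> list[MGEHit]:
    """Conjugative-system homologs; coverage is of the reference model."""
    if scheme is None:
        scheme = protein_scheme()
    n_db = sum(len(s) for s in conj_db.values())
    hits = []
    for pid in sorted(proteins):
        seq = proteins[pid]
        for header in sorted(conj_db):
            ref = conj_db[header]
            score = local_score(seq, ref, scheme)
            e = evalue(bit_score(score, scheme), len(seq), n_db)
            if not e < e_max:
                continue
            hit = local_align(seq, ref, scheme, query_id=pid, subject_id=header,
                              m=len(seq), n=n_db)
            subject_cov = 100.0 * (hit.subject_end - hit.subject_start + 1) / len(ref)
            if passes_conjugative(hit.evalue, subject_cov, e_max, cov_min):
                phage_id, idx = split_protein_id(pid)
                hits.append(
                    MGEHit(
                        phage_id=phage_id,
                        gene_index=idx,
                        mge_type="conjugative",
                        evidence={
                            "subject": header,
                            "evalue": hit.evalue,
                            "subject_coverage_pct": subject_cov,
                        },
                    )
                )
                break
    return hits


def integron_channel(external_calls_path=None) -> list[MGEHit]:
    """Pass-through for externally produced integron calls.

    With no file, returns the empty list. The TSV must carry ``phage_id``
    and ``gene_index`` columns; duplicate rows collapse to one hit per gene.
    """
    if external_calls_path is None:
        return []
    try:
        df = pd.read_csv(external_calls_path, sep="\t")
    except Exception as exc:
        raise ValueError(f"malformed integron calls TSV: {exc}") from exc
    if not {"phage_id", "gene_index"}.issubset(df.columns):
        raise ValueError(
            "integron calls TSV must have columns phage_id, gene_index"
        )
    seen = set()
    hits = []
    for _, row in df.iterrows():
        try:
            key = (str(row["phage_id"]), int(row["gene_index"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed integron calls row {row.to_dict()}") from exc
        if key in seen:
            continue
        seen.add(key)
        hits.append(MGEHit(phage_id=key[0], gene_index=key[1], mge_type="integron"))
    return hits


def adjacency(
    arg_gene_index: int,
    mge_gene_index: int,
    same_replicon: bool = True,
) -> AdjacencyCall:
    """Count genes strictly between the two features in annotation order."""
    if not same_replicon:
        return AdjacencyCall(
            arg_gene_index=arg_gene_index,
            mge_gene_index=mge_gene_index,
            intervening_gene_count=None,
            adjacent=False,
            comparable=False,
        )
    count = abs(arg_gene_index - mge_gene_index) - 1
    count = max(count, 0)  # identical indices: zero intervening
    return AdjacencyCall(
        arg_gene_index=arg_gene_index,
        mge_gene_index=mge_gene_index,
        intervening_gene_count=count,
        adjacent=count < ADJACENCY_MAX_INTERVENING,
    )


def adjacency_table(candidates, mge_hits: list[MGEHit]) -> pd.DataFrame:
    """Nearest-MGE adjacency call per ARG candidate."""
    rows = []
    for cand in candidates:
        same = [h for h in mge_hits if h.phage_id == cand.phage_id]
        if not same:
            rows.append(
                {
                    "gene_id": cand.protein_id,
                    "phage_id": cand.phage_id,
                    "arg_gene_index": cand.gene_index,
                    "mge_gene_index": None,
                    "mge_type": None,
                    "intervening_genes": None,
                    "adjacent": False,
                }
            )
            continue
        best = min(same, key=lambda h: abs(h.gene_index - cand.gene_index))
        call = adjacency(cand.gene_index, best.gene_index)
        rows.append(
            {
                "gene_id": cand.protein_id,
                "phage_id": cand.phage_id,
                "arg_gene_index": cand.gene_index,
                "mge_gene_index": best.gene_index,
                "mge_type": best.mge_type,
                "intervening_genes": call.intervening_gene_count,
                "adjacent": call.adjacent,
            }
        )
    return pd.DataFrame(rows)
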