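"""Lytic/temperate classification by the ordered rule cascade.

Precedence: literature override (forces temperate) > parA AND parB domains
present (integrative rule) > predictor consensus, where the consensus reads
the two external predictors as a union — either predictor calling temperate
makes the phage a candidate temperate, maximising temperate sensitivity.
Whole-genome integration evidence against the bacterial pool is recorded as
supporting metadata only; the parA/parB rule applies regardless.
"""

from __future__ import annotations

from .dissemination import whole_genome_similarity
from .profiles import PSSMProfile, domain_evalue, scan_best_window
from .records import GenomeRecord, LifestyleCall

INTEGRATION_ID_MIN = 90.0  # strict >
INTEGRATION_COV_MIN = 90.0  # strict >

_LABELS = ("lytic", "temperate")


def consensus_lifestyle(call_a: str, call_b: str) -> str:
    """Union reading: temperate iff either predictor says temperate."""
    for call in (call_a, call_b):
        if call not in _LABELS:
            raise ValueError(f"missing or invalid predictor call {call!r}")
    return "temperate" if "temperate" in (call_a, call_b) else "lytic"


def detect_parAB(
    phage_proteins: dict[str, str],
    parA_profile: PSSMProfile,
    parB_profile: PSSMProfile,
    score_min: float = 40.0,
    e_max: float = 1e-5,
) -> tuple[bool, bool]:
    """Presence of ParA and ParB domains among a phage's proteins.

    Uses the domain-channel thresholds (score >= 40, decoy-Gumbel E <= 1e-5).
    """
    n_targets = max(1, len(phage_proteins))
    found = {"parA": False, "parB": False}
    for prof, key in ((parA_profile, "parA"), (parB_profile, "parB")):
        for seq in phage_proteins.values():
            score, _start, _span = scan_best_window(prof, seq)
            if score >= score_min and domain_evalue(prof, score, n_targets) <= e_max:
                found[key] = True
                break
    return found["parA"], found["parB"]


def integration_evidence(
    phage: GenomeRecord,
    pool: list[GenomeRecord],
    id_min: float = INTEGRATION_ID_MIN,
    cov_min: float = INTEGRATION_COV_MIN,
) -> bool:
    """True iff some replicon aligns the whole phage genome at > id_min
    identity over > cov_min of the phage length."""
    if not pool:
        raise ValueError("bacterial pool is empty")
    from .dissemination import quick_containment

    for rep in pool:
        if len(rep.sequence) < 0.9 * (cov_min / 100.0) * len(phage.sequence):
            continue
        if quick_containment(phage.sequence, rep.sequence) < 0.05:
            continue
        ident, cov = whole_genome_similarity(phage.sequence, rep.sequence)
        if ident > id_min and cov > cov_min:
            return True
    return False


def classify(
    phage_id: str,
    call_a: str,
    call_b: str,
    has_parA: bool,
    has_parB: bool,
    override_list: set[str] | frozenset[str] = frozenset(),
) -> LifestyleCall:
    """Apply the rule cascade; the evidence trail records the deciding rule
    first, followed by the remaining observations."""
    evidence = []
    if phage_id in override_list:
        evidence.append("override")
        label = "temperate"
    elif has_parA and has_parB:
        evidence.append("parAB")
        label = "temperate"
    else:
        label = consensus_lifestyle(call_a, call_b)
        evidence.append("predictor_consensus")
    evidence.append(f"predictorA={call_a}")
    evidence.append(f"predictorB={call_b}")
    if has_parA or has_parB:
        evidence.append(f"parA={has_parA},parB={has_parB}")
    return LifestyleCall(phage_id=phage_id, label=label, evidence=evidence)


def classify_cohort(
    phage_ids: list[str],
    predictor_calls,  # DataFrame: phage_id, predictorA, predictorB
    proteins_by_phage: dict[str, dict[str, str]],
    parA_profile: PSSMProfile,
    parB_profile: PSSMProfile,
    override_list: set[str] | frozenset[str] = frozenset(),
) -> dict[str, LifestyleCall]:
    calls = predictor_calls.set_index("phage_id")
    out: dict[str, LifestyleCall] = {}
    for pid in phage_ids:
        if pid not in calls.index:
            raise ValueError(f"no predictor calls for phage {pid}")
        row = calls.loc[pid]
        has_a, has_b = detect_parAB(
            proteins_by_phage.get(pid, {}), parA_profile, parB_profile
        )
        out[pid] = classify(
            pid, row["predictorA"], row["predictorB"], has_a, has_b, override_list
        )
    return out
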