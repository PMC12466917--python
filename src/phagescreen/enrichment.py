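"""Cohort-level statistics: proportions, fold enrichment, host aggregation,
and precision/recall against planted truth.

All printed percentages use half-up rounding to 2 decimal places, the
convention every count-ratio statistic in the screen follows. Fold
enrichment compares a family's share of the lytic ARG total against its
share of the temperate ARG total (proportions of ARG candidates, not of
phage counts); a zero temperate count flags the fold as infinite unless the
optional Haldane 0.5 pseudocount is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


def proportion(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentRow:
    family: str
    lytic_count: int
    temperate_count: int
    lytic_proportion: float
    temperate_proportion: float
    fold: float  # math.inf when temperate share is zero and no pseudocount


def fold_enrichment(
    family_counts: dict[str, tuple[int, int]],
    lytic_total: int,
    temperate_total: int,
    haldane: bool = False,
) -> list[EnrichmentRow]:
    """Per-family lytic/temperate enrichment rows.

    ``family_counts`` maps family -> (lytic_count, temperate_count);
    totals are the lytic and temperate ARG candidate totals.
    """
    if lytic_total < 1 or temperate_total < 1:
        raise ValueError("ARG totals must be >= 1")
    rows = []
    for family in sorted(family_counts):
        lc, tc = family_counts[family]
        lp = lc / lytic_total
        tp = tc / temperate_total
        if tp > 0:
            fold = lp / tp
        elif haldane:
            fold = ((lc + 0.5) / (lytic_total + 0.5)) / ((tc + 0.5) / (temperate_total + 0.5))
        else:
            fold = math.inf if lp > 0 else 1.0
        rows.append(
            EnrichmentRow(
                family=family,
                lytic_count=lc,
                temperate_count=tc,
                lytic_proportion=lp,
                temperate_proportion=tp,
                fold=fold,
            )
        )
    return rows


def load_host_taxonomy() -> pd.DataFrame:
    """The packaged static genus -> (family, gram) table."""
    with resources.files("phagescreen.data").joinpath("host_taxa.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def infer_host_genus(phage_name: str, known_genera: set[str]) -> str | None:
    """First word of the phage name if it is a known genus, else None."""
    first = phage_name.split()[0] if phage_name.split() else ""
    return first if first in known_genera else None


def host_aggregate(
    phage_names: dict[str, str],
    taxonomy: pd.DataFrame | None = None,
) -> dict:
    """Counts per host genus/family plus the gram-negative/positive split.

    Phages whose host genus cannot be resolved from the name are excluded
    from all denominators and tallied separately.
    """
    if taxonomy is None:
        taxonomy = load_host_taxonomy()
    genus_info = taxonomy.set_index("genus")
    known = set(genus_info.index)
    genus_counts: dict[str, int] = {}
    family_counts: dict[str, int] = {}
    gram_counts = {"negative": 0, "positive": 0}
    excluded = 0
    for _pid, name in sorted(phage_names.items()):
        genus = infer_host_genus(name, known)
        if genus is None:
            excluded += 1
            continue
        genus_counts[genus] = genus_counts.get(genus, 0) + 1
        fam = genus_info.loc[genus, "family"]
        family_counts[fam] = family_counts.get(fam, 0) + 1
        gram_counts[genus_info.loc[genus, "gram"]] += 1
    resolved = sum(gram_counts.values())
    return {
        "genus_counts": genus_counts,
        "family_counts": family_counts,
        "gram_counts": gram_counts,
        "gram_negative_pct": proportion(gram_counts["negative"], resolved) if resolved else 0.0,
        "gram_positive_pct": proportion(gram_counts["positive"], resolved) if resolved else 0.0,
        "resolved": resolved,
        "excluded": excluded,
    }


@dataclass
class StageMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def binary_metrics(called: set, truth: set, universe: set) -> StageMetrics:
    """Confusion counts of a called set against a truth set over a universe."""
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = len(universe - called - truth)
    return StageMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_against_truth(
    detected_gene_ids: set[str],
    lifestyle_labels: dict[str, str],
    disseminated_called: set[str],
    adjacent_called: set[str],
    truth,
    all_gene_ids: set[str],
) -> dict[str, dict]:
    """Per-stage precision/recall/F1 with exact confusion counts.

    Stages: detection (gene ids vs planted ARGs), lifestyle (labels vs
    planted lifestyles), dissemination (gene ids vs the planted disseminated
    set), adjacency (planted-ARG ids vs ARGs planted with an adjacent MGE).
    """
    planted = truth.planted_gene_ids()
    detection = binary_metrics(detected_gene_ids, planted, all_gene_ids)

    phages = set(truth.lifestyles)
    correct = {p for p in phages if lifestyle_labels.get(p) == truth.lifestyles[p]}
    lifestyle = StageMetrics(tp=len(correct), fp=len(phages - correct), fn=0, tn=0)

    diss_truth = set(truth.disseminated_gene_ids)
    dissemination = binary_metrics(disseminated_called, diss_truth, planted)

    adj_truth = {
        f"{m['phage_id']}|{m['gene_index']}"  # MGE gene; map back to its ARG
        for m in truth.mges
        if m.get("distance_to_arg") is not None and m["distance_to_arg"] < 5
    }
    arg_with_adjacent = set()
    by_phage: dict[str, list] = {}
    for a in truth.planted_args:
        by_phage.setdefault(a["phage_id"], []).append(a)
    for m in truth.mges:
        if m.get("distance_to_arg") is not None and m["distance_to_arg"] < 5:
            for a in by_phage.get(m["phage_id"], []):
                if abs(a["gene_index"] - m["gene_index"]) - 1 < 5:
                    arg_with_adjacent.add(f"{a['phage_id']}|{a['gene_index']}")
    adjacency = binary_metrics(adjacent_called, arg_with_adjacent, planted)

    return {
        "detection": detection.as_dict(),
        "lifestyle": lifestyle.as_dict()
        | {"accuracy": len(correct) / len(phages) if phages else 1.0},
        "dissemination": dissemination.as_dict(),
        "adjacency": adjacency.as_dict(),
    }
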