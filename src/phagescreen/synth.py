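"""Synthetic phage cohort generator with planted ground truth.

The generator emits everything the screen consumes — phage genomes with gene
annotations and translated proteins, a reference ARG protein database with
family/mechanism metadata, calibrated ARG/parA/parB domain profiles, IS and
conjugative reference proteins, a bacterial replicon pool with origin
metadata, and predictor lifestyle calls — together with the planted truth
(ARG placements and divergences, MGE adjacencies, lifestyles, the
disseminated gene set, pseudo-lysogenic plasmids). Planted homologs are
produced by a BLOSUM62-driven mutation model whose achieved divergence is
verified against the global-alignment oracle, so recovery tests can speak
about known identities rather than nominal ones.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Align import substitution_matrices

from . import io as psio
from .alignment import (
    PROTEIN_ALPHABET,
    global_identity,
    random_nucleotide,
    random_protein,
    revcomp,
)
from .profiles import PSSMProfile, calibrate, make_profile
from .records import GeneFeature, GenomeRecord, ReferenceProtein, protein_id


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a desk-scale cohort with the lytic/temperate balance and
    ARG-carrier rate of large public phage collections (about two-thirds
    lytic, roughly one phage in five carrying an ARG candidate).
    """

    n_phages: int = 200
    lytic_fraction: float = 0.68
    n_arg_families: int = 8
    genes_per_phage: tuple[int, int] = (10, 20)
    planted_arg_rate: float = 0.2
    divergence_levels: tuple[float, ...] = (30, 40, 50, 60, 70, 80, 90, 100)
    mge_rate: float = 0.06
    mge_adjacent_fraction: float = 0.3
    parab_rate: float = 0.15
    predictor_error_rate: float = 0.0
    dissemination_fraction: float = 0.15
    pseudolysogen_count: int = 2
    n_bacterial_replicons: int = 12
    unresolvable_host_fraction: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_phages < 1:
            raise ValueError("need at least one phage")
        if self.n_arg_families < 1:
            raise ValueError("need at least one ARG family")
        for name in (
            "lytic_fraction",
            "planted_arg_rate",
            "mge_rate",
            "mge_adjacent_fraction",
            "parab_rate",
            "predictor_error_rate",
            "dissemination_fraction",
            "unresolvable_host_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for lvl in self.divergence_levels:
            if not 30 <= lvl <= 100:
                raise ValueError("divergence levels must lie in [30, 100]")
        lo, hi = self.genes_per_phage
        if lo < 6 or hi < lo:
            raise ValueError("genes_per_phage range must satisfy 6 <= lo <= hi")


@dataclass
class CohortTruth:
    """Planted ground truth, the reference for recovery testing."""

    lifestyles: dict[str, str]
    planted_args: list[dict]  # phage_id, gene_index, family, target/achieved identity
    mges: list[dict]  # phage_id, gene_index, mge_type, distance_to_arg
    disseminated_gene_ids: list[str]
    pseudolysogen_replicon_ids: list[str]
    integrated_phage_ids: list[str]
    parab_phage_ids: list[str]

    def planted_gene_ids(self) -> set[str]:
        return {protein_id(a["phage_id"], a["gene_index"]) for a in self.planted_args}

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "CohortTruth":
        return cls(**obj)


@dataclass
class Cohort:
    """In-memory synthetic cohort: all inputs plus the planted truth."""

    config: CohortConfig
    phages: list[GenomeRecord]
    proteins: dict[str, str]  # protein id -> amino-acid sequence
    gene_nt: dict[str, str]  # protein id -> gene nucleotide sequence (coding strand)
    refdb: list[ReferenceProtein]
    profiles: list[PSSMProfile]
    parab_profiles: dict[str, PSSMProfile]  # {"parA": ..., "parB": ...}
    is_db: dict[str, str]
    conj_db: dict[str, str]
    pool: list[GenomeRecord]
    pool_meta: pd.DataFrame  # replicon_id, type, source
    predictor_calls: pd.DataFrame  # phage_id, predictorA, predictorB
    hosts: dict[str, str | None]  # phage id -> genus (None if unresolvable)
    truth: CohortTruth

    def products(self) -> dict[str, str]:
        out = {}
        for phage in self.phages:
            for feat in phage.genes:
                out[protein_id(phage.id, feat.gene_index)] = feat.product
        return out


# --- mutation model ---------------------------------------------------------

_IDENTITY_FLOOR = 20.0  # global-alignment identity of unrelated proteins sits near here

_blosum = substitution_matrices.load("BLOSUM62")
_EXCHANGE = np.zeros((20, 20))
for _i, _a in enumerate(PROTEIN_ALPHABET):
    for _j, _b in enumerate(PROTEIN_ALPHABET):
        if _i != _j:
            _EXCHANGE[_i, _j] = 2.0 ** _blosum[_a, _b]
_EXCHANGE /= _EXCHANGE.sum(axis=1, keepdims=True)
_AA_IDX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}


def _substitute(seq: list[str], positions: np.ndarray, rng: np.random.Generator) -> None:
    for pos in positions:
        i = _AA_IDX.get(seq[pos])
        if i is None:
            continue
        seq[pos] = PROTEIN_ALPHABET[rng.choice(20, p=_EXCHANGE[i])]


def mutate_protein(
    sequence: str,
    target_identity: float,
    seed: int,
    indel_rate: float = 0.01,
    tolerance: float = 2.5,
    max_rounds: int = 12,
) -> str:
    """Mutate a protein to a chosen global-alignment identity.

    Substitutions are drawn proportionally to BLOSUM62 exchangeability over
    non-identical residues; indels arrive as a Poisson process (``indel_rate``
    per site) with geometric(p=0.5) lengths, capped at a 5% net length
    change. The achieved identity is measured with the Needleman–Wunsch
    oracle and the substitution load is adjusted until it falls within
    ``tolerance`` points of the target.
    """
    if not 0 <= target_identity <= 100:
        raise ValueError("target_identity must be in [0, 100]")
    if len(sequence) < 20:
        raise ValueError("sequence too short to mutate controllably (< 20 aa)")
    if target_identity < _IDENTITY_FLOOR:
        raise ValueError(
            f"target identity {target_identity} is below the achievable floor "
            f"({_IDENTITY_FLOOR}) for protein sequences"
        )
    if target_identity == 100:
        return sequence

    rng = np.random.default_rng(seed)
    L = len(sequence)
    n_sub = int(round(L * (1 - target_identity / 100.0)))
    max_indel_bases = max(1, int(0.05 * L))

    for _ in range(max_rounds):
        seq = list(sequence)
        n_sub = int(np.clip(n_sub, 0, L - 1))
        positions = rng.choice(L, size=n_sub, replace=False)
        _substitute(seq, positions, rng)
        n_events = rng.poisson(indel_rate * L)
        net = 0
        for _e in range(n_events):
            length = int(rng.geometric(0.5))
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5 and abs(net + length) <= max_indel_bases:
                seq[pos:pos] = rng.choice(list(PROTEIN_ALPHABET), size=length).tolist()
                net += length
            elif abs(net - length) <= max_indel_bases and len(seq) - length >= 20:
                del seq[pos : pos + length]
                net -= length
        mutant = "".join(seq)
        measured = global_identity(sequence, mutant)
        if abs(measured - target_identity) <= tolerance:
            return mutant
        # feedback: shift the substitution load toward the residual error
        n_sub += int(round(L * (measured - target_identity) / 100.0 * 0.8)) or (
            1 if measured > target_identity else -1
        )
    raise RuntimeError(
        f"could not reach {target_identity}% identity within {max_rounds} rounds"
    )


# --- family catalogue -------------------------------------------------------

FAMILY_CATALOG = (
    ("dfrA", "target replacement", "trimethoprim", "trimethoprim-insensitive dihydrofolate reductase DfrA"),
    ("thyA", "target replacement", "para-aminosalicylic acid", "thymidylate synthase ThyA"),
    ("blaTEM", "inactivation", "beta-lactam", "class A beta-lactamase TEM"),
    ("aph3", "inactivation", "aminoglycoside", "aminoglycoside O-phosphotransferase APH(3')"),
    ("tetM", "target protection", "tetracycline", "tetracycline resistance ribosomal protection protein TetM"),
    ("qnrS", "target protection", "quinolone", "quinolone resistance pentapeptide repeat protein QnrS"),
    ("acrB", "efflux", "multidrug", "multidrug efflux RND transporter permease AcrB"),
    ("ermB", "target alteration", "macrolide", "23S rRNA methyltransferase ErmB"),
    ("rpoB2", "target alteration", "rifamycin", "rifampin-resistant RNA polymerase subunit RpoB2"),
    ("mcr1", "other/reduced permeability", "peptide antibiotic", "phosphoethanolamine transferase MCR-1"),
)

_GENERA = (
    "Escherichia",
    "Salmonella",
    "Klebsiella",
    "Pseudomonas",
    "Vibrio",
    "Erwinia",
    "Bacillus",
    "Staphylococcus",
    "Streptococcus",
    "Microbacterium",
)

_CODON_CHOICES: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODON_CHOICES.setdefault(_aa, []).append(_codon)
for _aa in _CODON_CHOICES:
    _CODON_CHOICES[_aa].sort()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide coding sequence with uniformly chosen synonymous codons."""
    codons = [
        _CODON_CHOICES[aa][rng.integers(len(_CODON_CHOICES[aa]))]
        if aa in _CODON_CHOICES
        else "NNN"
        for aa in protein
    ]
    return "".join(codons) + "TAA"


@dataclass
class _FamilySpec:
    name: str
    mechanism: str
    drug_class: str
    product: str
    canonical: str
    domain_start: int


def _family_weights(specs: list[_FamilySpec], lytic: bool) -> np.ndarray:
    """Lytic phages favour dfr/thyA plantings (the enrichment structure)."""
    w = np.ones(len(specs))
    if lytic:
        for i, spec in enumerate(specs):
            if spec.name == "dfrA":
                w[i] = 5.0
            elif spec.name == "thyA":
                w[i] = 3.0
    return w / w.sum()


def _round(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    # -- reference families, DB entries, domain profiles --------------------
    specs: list[_FamilySpec] = []
    refdb: list[ReferenceProtein] = []
    profiles: list[PSSMProfile] = []
    catalog = list(FAMILY_CATALOG)
    while len(catalog) < config.n_arg_families:
        k = len(catalog)
        base = FAMILY_CATALOG[k % len(FAMILY_CATALOG)]
        catalog.append((f"{base[0]}v{k}", base[1], base[2], base[3]))
    for fam_i in range(config.n_arg_families):
        name, mechanism, drug, product = catalog[fam_i]
        length = int(rng.integers(170, 260))
        canonical = random_protein(length, rng)
        domain_start = (length - 60) // 2
        specs.append(_FamilySpec(name, mechanism, drug, product, canonical, domain_start))
        refdb.append(ReferenceProtein(f"REF{fam_i:03d}A", name, mechanism, drug, canonical))
        for v in range(2):
            variant = mutate_protein(
                canonical, 93.0, seed=int(rng.integers(2**31)), indel_rate=0.0
            )
            refdb.append(ReferenceProtein(f"REF{fam_i:03d}{'BC'[v]}", name, mechanism, drug, variant))
        domain = canonical[domain_start : domain_start + 60]
        members = [domain] + [
            mutate_protein(domain, 90.0, seed=int(rng.integers(2**31)), indel_rate=0.0)
            for _ in range(4)
        ]
        prof = make_profile(members, name=name)
        calibrate(prof, seed=int(rng.integers(2**31)))
        profiles.append(prof)

    # -- partition-protein (parA/parB) profiles ------------------------------
    parab_profiles: dict[str, PSSMProfile] = {}
    parab_canonical: dict[str, str] = {}
    for pname in ("parA", "parB"):
        canonical = random_protein(210, rng)
        parab_canonical[pname] = canonical
        domain = canonical[75:135]
        members = [domain] + [
            mutate_protein(domain, 90.0, seed=int(rng.integers(2**31)), indel_rate=0.0)
            for _ in range(4)
        ]
        prof = make_profile(members, name=pname)
        calibrate(prof, seed=int(rng.integers(2**31)))
        parab_profiles[pname] = prof

    # -- mobile-element reference proteins -----------------------------------
    is_canonical = random_protein(320, rng)
    is_db = {
        "ISREF001|IS3-family-transposase": is_canonical,
        "ISREF002|IS6-family-transposase": mutate_protein(
            is_canonical, 80.0, seed=int(rng.integers(2**31)), indel_rate=0.0
        ),
    }
    conj_db = {
        "CONJ001|relaxase-MobA": random_protein(260, rng),
        "CONJ002|coupling-protein-TraG": random_protein(240, rng),
    }

    # -- per-phage planting plan ---------------------------------------------
    n = config.n_phages
    n_lytic = _round(n * config.lytic_fraction)
    order = rng.permutation(n)
    lifestyles = {}
    phage_ids = [f"PSYN{i:05d}" for i in range(n)]
    for rank, i in enumerate(order):
        lifestyles[phage_ids[i]] = "lytic" if rank < n_lytic else "temperate"

    hosts: dict[str, str | None] = {}
    for pid in phage_ids:
        if rng.random() < config.unresolvable_host_fraction:
            hosts[pid] = None
        else:
            hosts[pid] = str(rng.choice(_GENERA))

    n_carriers = _round(n * config.planted_arg_rate)
    carriers = [phage_ids[i] for i in sorted(rng.choice(n, size=n_carriers, replace=False))]
    carrier_family: dict[str, _FamilySpec] = {}
    carrier_level: dict[str, float] = {}
    for ci, pid in enumerate(carriers):
        weights = _family_weights(specs, lifestyles[pid] == "lytic")
        carrier_family[pid] = specs[int(rng.choice(len(specs), p=weights))]
        carrier_level[pid] = float(config.divergence_levels[ci % len(config.divergence_levels)])

    temperate_ids = [p for p in phage_ids if lifestyles[p] == "temperate"]
    n_parab = _round(len(temperate_ids) * config.parab_rate)
    parab_ids = sorted(
        str(x) for x in rng.choice(temperate_ids, size=n_parab, replace=False)
    ) if n_parab else []

    n_adj = _round(n_carriers * config.mge_adjacent_fraction)
    adjacent_carriers = set(
        str(x) for x in rng.choice(carriers, size=n_adj, replace=False)
    ) if n_adj else set()
    n_extra_mge = _round(n * config.mge_rate)
    extra_mge_ids = set(
        str(phage_ids[i]) for i in rng.choice(n, size=n_extra_mge, replace=False)
    ) if n_extra_mge else set()

    # -- assemble phage genomes ----------------------------------------------
    phages: list[GenomeRecord] = []
    proteins: dict[str, str] = {}
    gene_nt: dict[str, str] = {}
    planted_args: list[dict] = []
    planted_mges: list[dict] = []
    lo, hi = config.genes_per_phage

    for i, pid in enumerate(phage_ids):
        n_genes = int(rng.integers(lo, hi + 1))
        prods = ["hypothetical protein"] * n_genes
        prot_seqs: list[str | None] = [None] * n_genes
        reserved: set[int] = set()

        arg_idx = None
        if pid in carrier_family:
            spec = carrier_family[pid]
            level = carrier_level[pid]
            arg_idx = int(rng.integers(0, n_genes))
            mutant = mutate_protein(spec.canonical, level, seed=int(rng.integers(2**31)))
            achieved = global_identity(spec.canonical, mutant)
            prot_seqs[arg_idx] = mutant
            prods[arg_idx] = f"{spec.product} homolog"
            reserved.add(arg_idx)
            planted_args.append(
                {
                    "phage_id": pid,
                    "gene_index": arg_idx,
                    "family": spec.name,
                    "target_identity": level,
                    "achieved_identity": round(achieved, 2),
                }
            )

        def _free_index(constraint=None) -> int:
            choices = [
                j
                for j in range(n_genes)
                if j not in reserved and (constraint is None or constraint(j))
            ]
            if not choices:
                choices = [j for j in range(n_genes) if j not in reserved]
            return int(choices[rng.integers(0, len(choices))])

        mge_plan: list[tuple[int, str, int | None]] = []
        if pid in adjacent_carriers and arg_idx is not None:
            d = int(rng.integers(0, 5))  # intervening genes, 0..4
            options = [j for j in (arg_idx - d - 1, arg_idx + d + 1) if 0 <= j < n_genes]
            j = int(options[rng.integers(0, len(options))])
            mge_plan.append((j, "IS" if rng.random() < 0.6 else "conjugative", d))
        if pid in extra_mge_ids:
            far = (
                (lambda j: abs(j - arg_idx) - 1 >= 5) if arg_idx is not None else None
            )
            j = _free_index(far)
            dist = abs(j - arg_idx) - 1 if arg_idx is not None else None
            mge_plan.append((j, "IS" if rng.random() < 0.6 else "conjugative", dist))
        for j, mtype, dist in mge_plan:
            if j in reserved:
                continue
            if mtype == "IS":
                seq = mutate_protein(is_canonical, 90.0, seed=int(rng.integers(2**31)))
                prods[j] = "IS3 family transposase"
            else:
                header = list(conj_db)[int(rng.integers(0, len(conj_db)))]
                seq = mutate_protein(conj_db[header], 90.0, seed=int(rng.integers(2**31)))
                prods[j] = "conjugative transfer protein " + header.split("|")[1]
            prot_seqs[j] = seq
            reserved.add(j)
            planted_mges.append(
                {"phage_id": pid, "gene_index": j, "mge_type": mtype, "distance_to_arg": dist}
            )

        if pid in parab_ids:
            for pname in ("parA", "parB"):
                j = _free_index()
                prot_seqs[j] = mutate_protein(
                    parab_canonical[pname], 90.0, seed=int(rng.integers(2**31)), indel_rate=0.0
                )
                prods[j] = f"{pname[0].upper() + pname[1:]} partition protein"
                reserved.add(j)

        for j in range(n_genes):
            if prot_seqs[j] is None:
                prot_seqs[j] = random_protein(int(rng.integers(100, 300)), rng)

        # lay the genes on one replicon with 50-200 bp spacers, random strand
        chunks: list[str] = []
        genes: list[GeneFeature] = []
        pos = 1
        for j in range(n_genes):
            spacer = random_nucleotide(int(rng.integers(50, 201)), rng)
            chunks.append(spacer)
            pos += len(spacer)
            nt = back_translate(prot_seqs[j], rng)
            strand = "+" if rng.random() < 0.5 else "-"
            chunks.append(nt if strand == "+" else revcomp(nt))
            genes.append(
                GeneFeature(
                    gene_index=j,
                    start=pos,
                    end=pos + len(nt) - 1,
                    strand=strand,
                    product=prods[j],
                )
            )
            pkey = protein_id(pid, j)
            proteins[pkey] = prot_seqs[j]
            gene_nt[pkey] = nt
            pos += len(nt)
        chunks.append(random_nucleotide(int(rng.integers(50, 201)), rng))
        genus = hosts[pid]
        name = (
            f"{genus} phage synth{i:04d}" if genus else f"Uncultured phage synth{i:04d}"
        )
        phages.append(
            GenomeRecord(id=pid, name=name, accession=pid, sequence="".join(chunks), genes=genes)
        )

    phage_by_id = {p.id: p for p in phages}

    # -- bacterial replicon pool ---------------------------------------------
    pool: list[GenomeRecord] = []
    meta_rows: list[dict] = []
    n_repl = config.n_bacterial_replicons
    n_plasmid = max(1, n_repl // 3)
    for r in range(n_repl):
        is_plasmid = r >= n_repl - n_plasmid
        length = int(rng.integers(6000, 9000)) if is_plasmid else int(rng.integers(18000, 24000))
        seq = random_nucleotide(length, rng)
        rep_product = (
            "plasmid replication initiator protein RepA"
            if is_plasmid
            else "chromosomal replication initiator protein DnaA"
        )
        genes = [
            GeneFeature(0, 101, 1000, "+", rep_product),
            GeneFeature(1, 1101, 2000, "+", "hypothetical protein"),
        ]
        rid = f"BSYN{r:04d}"
        pool.append(
            GenomeRecord(
                id=rid,
                name=f"synthetic bacterial {'plasmid' if is_plasmid else 'chromosome'} {r}",
                accession=rid,
                sequence=seq,
                genes=genes,
            )
        )
        meta_rows.append(
            {"replicon_id": rid, "type": "plasmid" if is_plasmid else "chromosome", "source": "bacterial"}
        )

    planted_ids = [protein_id(a["phage_id"], a["gene_index"]) for a in planted_args]
    n_diss = _round(len(planted_ids) * config.dissemination_fraction)
    disseminated = sorted(
        str(x) for x in rng.choice(planted_ids, size=n_diss, replace=False)
    ) if n_diss else []
    for gid in disseminated:
        target = pool[int(rng.integers(0, len(pool)))]
        insert = gene_nt[gid]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        at = int(rng.integers(2500, len(target.sequence) - 100))
        target.sequence = target.sequence[:at] + insert + target.sequence[at:]

    n_integrated = _round(0.25 * len(parab_ids)) if parab_ids else 0
    integrated = sorted(
        str(x) for x in rng.choice(parab_ids, size=n_integrated, replace=False)
    ) if n_integrated else []
    chromosomes = [p for p, m in zip(pool, meta_rows) if m["type"] == "chromosome"]
    for pid in integrated:
        target = chromosomes[int(rng.integers(0, len(chromosomes)))]
        at = int(rng.integers(2500, len(target.sequence) - 100))
        target.sequence = target.sequence[:at] + phage_by_id[pid].sequence + target.sequence[at:]

    lytic_ids = [p for p in phage_ids if lifestyles[p] == "lytic"]
    n_pl = min(config.pseudolysogen_count, len(lytic_ids))
    pl_sources = sorted(
        str(x) for x in rng.choice(lytic_ids, size=n_pl, replace=False)
    ) if n_pl else []
    pseudolysogen_ids = []
    for k, pid in enumerate(pl_sources):
        src = phage_by_id[pid]
        rid = f"PLSYN{k:03d}"
        pseudolysogen_ids.append(rid)
        pool.append(
            GenomeRecord(
                id=rid,
                name=f"synthetic plasmid copy of {src.name}",
                accession=rid,
                sequence=src.sequence,
                genes=[dataclasses.replace(g) for g in src.genes],
            )
        )
        meta_rows.append({"replicon_id": rid, "type": "plasmid", "source": "phage-derived"})

    # -- predictor calls ------------------------------------------------------
    calls = []
    for pid in phage_ids:
        row = {"phage_id": pid}
        for pred in ("predictorA", "predictorB"):
            label = lifestyles[pid]
            if rng.random() < config.predictor_error_rate:
                label = "lytic" if label == "temperate" else "temperate"
            row[pred] = label
        calls.append(row)

    truth = CohortTruth(
        lifestyles=lifestyles,
        planted_args=planted_args,
        mges=planted_mges,
        disseminated_gene_ids=disseminated,
        pseudolysogen_replicon_ids=pseudolysogen_ids,
        integrated_phage_ids=integrated,
        parab_phage_ids=parab_ids,
    )
    return Cohort(
        config=config,
        phages=phages,
        proteins=proteins,
        gene_nt=gene_nt,
        refdb=refdb,
        profiles=profiles,
        parab_profiles=parab_profiles,
        is_db=is_db,
        conj_db=conj_db,
        pool=pool,
        pool_meta=pd.DataFrame(meta_rows),
        predictor_calls=pd.DataFrame(calls),
        hosts=hosts,
        truth=truth,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit every cohort artefact as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    psio.write_fasta(
        {f"{p.id} {p.name}": p.sequence for p in cohort.phages}, outdir / "phages.fna"
    )
    psio.write_gff3(cohort.phages, outdir / "phages.gff3")
    products = cohort.products()
    psio.write_fasta(
        {f"{pid}|{products[pid]}": seq for pid, seq in cohort.proteins.items()},
        outdir / "proteins.faa",
    )
    psio.write_fasta(
        {f"{pid}": seq for pid, seq in cohort.gene_nt.items()}, outdir / "genes.fna"
    )
    psio.write_fasta({r.header: r.sequence for r in cohort.refdb}, outdir / "refdb.faa")
    from .profiles import write_profiles

    write_profiles(cohort.profiles, outdir / "profiles.pssm")
    write_profiles(list(cohort.parab_profiles.values()), outdir / "parab.pssm")
    psio.write_fasta(cohort.is_db, outdir / "is_db.faa")
    psio.write_fasta(cohort.conj_db, outdir / "conj_db.faa")
    psio.write_fasta(
        {f"{p.id} {p.name}": p.sequence for p in cohort.pool}, outdir / "pool.fna"
    )
    psio.write_gff3(cohort.pool, outdir / "pool.gff3")
    psio.write_tsv(cohort.pool_meta, outdir / "pool_meta.tsv")
    psio.write_tsv(cohort.predictor_calls, outdir / "predictor_calls.tsv")
    (outdir / "override.txt").write_text("")
    psio.write_json(cohort.truth.to_json(), outdir / "truth.json")


def make_dfra_set(
    n_per_clade: int = 6, seed: int = 0, length: int = 180, within_identity: float = 80.0
) -> tuple[dict[str, str], dict[str, str]]:
    """Two diverged DfrA-like clades for the phylogeny stand-in.

    Returns (sequences, clade_of) where each clade descends from its own
    centroid at ``within_identity`` percent identity; the two centroids are
    unrelated random proteins.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    for clade in ("A", "B"):
        centroid = random_protein(length, rng)
        for i in range(n_per_clade):
            name = f"dfrA_{clade}{i}"
            seqs[name] = mutate_protein(
                centroid, within_identity, seed=int(rng.integers(2**31))
            )
            clade_of[name] = clade
    return seqs, clade_of
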