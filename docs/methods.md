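# Methods

This note documents the models, rules and numerical choices behind
`phagescreen`, and what the synthetic cohort does and does not emulate.

## Alignment and statistics

Protein alignments are exact Smith–Waterman (local) or Needleman–Wunsch
(global) with affine gaps under the BLAST convention: a gap of length L
costs `gap_open + L * gap_extend`, defaults 11/1 on BLOSUM62. The ambiguity
code X scores 0 against every residue. Percent identity counts identities
over *all* alignment columns, gap columns included; query coverage is the
span of the single best local alignment — no HSP tiling. Choosing the
best-alignment span is the simplest deterministic reading of "query
coverage"; tiling multiple HSPs would only raise coverage for repetitive
proteins, which the synthetic cohort does not contain.

E-values use the Karlin–Altschul form E = m·n·2^(−S′),
S′ = (λS − ln K)/ln 2 with λ = 0.267 nats and K = 0.041 — the standard
gapped BLOSUM62/11-1 constants — where m is the query length and n the
total residue count of the database searched. Fixing λ and K keeps results
deterministic and independent of any external search tool. Nucleotide
alignments use match +2 / mismatch −3, gaps 5/2, with λ = 0.625, K = 0.41.

Tie-breaking everywhere is deterministic: best hits order by bit score,
then E-value, then lexicographic subject id.

## Domain profiles

A profile is a per-column base-2 log-odds matrix over the 20 residues,
built from an ungapped family alignment with pseudocount 1 against a
uniform background (0.05 per residue). Scanning is ungapped: the best
window over all placements (partial placements allowed only when the
protein is shorter than the profile). Significance comes from decoy
calibration: 1000 shuffles of one background-drawn 200-residue sequence are
scanned, the best-window scores are fitted with a Gumbel law
(`scipy.stats.gumbel_r.fit`), and E = N_targets · P(S ≥ s) under that fit.
The calibration seed is stored on the profile, so E-values are reproducible.
A fixed 200-residue decoy length (a typical phage protein) is used rather
than per-query length matching; at desk scale the length dependence of the
best-window maximum is small compared to the ≥ 40-bit score floor that
dominates the filter.

## Threshold semantics

Every filter boundary is implemented exactly as stated, and the open/closed
distinctions are deliberate:

| rule | boundary |
| --- | --- |
| homology channel | E ≤ 1e−5 **and** qcov ≥ 60% (closed) |
| domain channel | score ≥ 40 **and** E ≤ 1e−5 (closed) |
| reported ARG | identity ≥ 90% **and** qcov ≥ 85% (closed) |
| dissemination | identity > 90% **and** coverage > 90% (strict) |
| IS element | length ≥ 150 aa, E ≤ 1e−30, identity > 40% (strict) |
| conjugative | E < 0.001 (strict), reference coverage ≥ 50% |
| MGE adjacency | intervening genes < 5 (strict) |

"Intervening genes" is read as the count of annotated genes strictly
between the two features in annotation order, strand-agnostic, on the same
replicon — the only reading computable from gene order alone.

## Lifestyle cascade

Precedence: literature override (forces temperate) > parA ∧ parB domain
presence ⇒ temperate > predictor consensus. The consensus reads two
external predictors as a union — either one calling temperate suffices —
because the screen's purpose is to be maximally confident about the *lytic*
label; a union maximises temperate sensitivity (with independent predictor
error rate ε, a temperate phage is missed only with probability ε²).
ParA/ParB detection reuses the domain-channel thresholds (score ≥ 40,
E ≤ 1e−5), and the parA∧parB rule applies regardless of whole-genome
integration evidence, which is computed and reported as supporting metadata
only. Overrides can only force temperate, never lytic.

## Nucleotide search and whole-genome comparison

The gene-versus-replicon search is exact-15-mer seeded: seed diagonals are
clustered, and each cluster's window (gene length margin on both sides) is
resolved with exact local DP on both strands, so scores equal a full
Smith–Waterman whenever the homologous region contains at least one intact
15-mer — guaranteed in practice for the > 90%-identity, full-length copies
the dissemination rule targets. Whole-replicon comparisons (integration
evidence, pseudo-lysogeny, genome dedup) chain collinear exact 15-mer
matches into blocks and resolve inter-block gaps by exact global alignment;
a sampled-k-mer containment prescreen (threshold 5%) skips unrelated pairs
cheaply. Origin verification is automated from replicon metadata
(`source = bacterial | phage-derived`); phage-derived records never count
toward dissemination. Pseudo-lysogeny defaults (≥ 95% identity and
coverage, plasmid-replication keyword list) are configurable, since the
underlying observation describes a single case rather than a sharp rule.

## Enrichment statistics

Percentages are rounded half-up to 2 decimals via `decimal.Decimal`
(`proportion(1596, 8490) = 18.80`), the convention every published ratio in
this line of work follows. Fold enrichment compares a family's share of the
lytic ARG total with its share of the temperate ARG total — proportions of
ARG candidates, not of phage counts; a zero temperate share is flagged
infinite by default, with an optional Haldane 0.5 pseudocount. Host
taxonomy is a static packaged genus → (family, gram) table; the host genus
is inferred from the first word of the phage name and phages with no
resolvable genus are excluded from denominators and tallied separately.

## Phylogeny stand-in

Maximum-likelihood tree inference over a trimmed multiple alignment is out
of scope; the package instead computes p-distances (1 − identity fraction
from pairwise global alignments) and runs Saitou–Nei neighbor joining with
smallest-index tie-breaking. On additive matrices this recovers the
generating topology and branch lengths exactly (property-tested up to 6
taxa, cross-checked against an independent NJ implementation). Negative NJ
branch-length estimates are clamped to zero with a warning, standard
practice that preserves the non-negativity invariant. Midpoint rooting
places the root halfway along the longest leaf-to-leaf path; the two root
subtrees are labelled A (containing the lexicographically smallest leaf)
and B.

## Synthetic cohort

The generator emulates the statistical structure of a large public phage
collection: ~68% lytic phages, ~20% of genomes carrying one ARG candidate,
planted at identities cycling through {30, 40, …, 100}%, dfr/thyA-biased
family choice in lytic phages (the enrichment structure), parA/parB pairs
in 15% of temperate phages, IS/conjugative genes adjacent (< 5 intervening
genes) to 30% of planted ARGs, 15% of planted ARGs copied verbatim into a
bacterial pool, a quarter of parA/parB carriers integrated whole into
chromosomes, and two pseudo-lysogenic plasmid copies of lytic phages.
Defaults were chosen once as desk-scale analogues of those observed rates;
10–20 genes per phage keeps genomes small while leaving room for the
adjacency geometry.

The mutation model draws substitutions proportional to BLOSUM62
exchangeability (2^score over non-identical residues), adds Poisson indels
(1% per site, geometric(0.5) lengths, net length change capped at 5%) and
iteratively adjusts the substitution load until the global-alignment
identity lands within ±2.5 points of the target, so the *achieved*
divergence recorded in the truth set is oracle-verified, not nominal. Gene
nucleotide sequences are back-translations with uniformly chosen synonymous
codons; distinct proteins therefore share at most ~78% nucleotide identity
even within a family, which keeps the strict >90% dissemination rule
specific to the verbatim planted copies.

What the generator does **not** emulate: real phage genome architecture
(modules, terminal repeats), codon-usage bias, sequencing error,
paralogous gene families, or compositionally biased proteins. Passing
recovery tests therefore demonstrates that the rules and thresholds are
implemented correctly and recover planted signal under realistic divergence
— not that the screen's false-positive rate on real proteomes is known.

## Problem sizes and determinism

The default recovery cohort is 200 phages (seed 42; ~3000 proteins, 8 ARG
families, 12 bacterial replicons), which the full pipeline processes in
about a minute; unit tests use 20–30-phage cohorts and the bundled demo
configuration runs 60 phages. All randomness flows from a single
`numpy.random.default_rng` seed per cohort plus stored calibration seeds,
file outputs use sorted keys and fixed float formats, and a fixed
configuration yields byte-identical artefacts — covered by dedicated
determinism tests.

## Known limitations

* The structure channel is a composition heuristic standing behind the
  pluggable interface, not a structure predictor; its similarity floor
  (0.2) is a screening default, not a calibrated statistic.
* Domain-channel E-values inherit the decoy composition assumption; very
  biased query compositions would need per-query calibration.
* The seeded nucleotide search can miss homologs in which every 15-mer is
  disrupted (< ~70% identity); this is far below the > 90% dissemination
  threshold it serves.
* Integron detection is interface-only and expects externally produced
  calls.
* `dedup_genomes` compares only same-name genomes, mirroring the upstream
  curation rule; cross-name duplicates are kept.
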