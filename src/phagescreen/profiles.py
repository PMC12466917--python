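"""Position-specific scoring matrices for ARG-domain scanning.

A profile is a per-column log-odds matrix (base 2, with pseudocount) built
from an ungapped family alignment. Scanning slides the profile over a protein
in ungapped register and reports the best window. Statistical significance
comes from a decoy calibration: the best-window score distribution over
shuffled decoy sequences is fitted with a Gumbel (extreme-value) law, and the
E-value of a score s over a search of N target proteins is
``N * P_gumbel(S >= s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import PROTEIN_ALPHABET

_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
#: Default decoy length for calibration (a typical phage protein).
DECOY_LENGTH = 200


class UncalibratedProfileError(RuntimeError):
    """Raised when an E-value is requested from an uncalibrated profile."""


@dataclass
class PSSMProfile:
    """Log-odds profile over the 20 residues, optionally decoy-calibrated."""

    name: str
    scores: np.ndarray  # (length, 20) bit scores
    background: np.ndarray  # (20,) residue frequencies
    mu: float | None = None
    beta: float | None = None
    calibration_seed: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile scores must be (length, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("calibrated beta must be positive")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.beta is not None

    def consensus(self) -> str:
        """Highest-scoring residue per column (ties: alphabet order)."""
        return "".join(PROTEIN_ALPHABET[i] for i in np.argmax(self.scores, axis=1))

    def max_score(self) -> float:
        """Best achievable window score (the consensus score)."""
        return float(np.max(self.scores, axis=1).sum())


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


def make_profile(
    family_sequences: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    name: str = "profile",
) -> PSSMProfile:
    """Build a log-odds profile from >=2 ungapped, equal-length sequences.

    Column score for residue a: log2(((count_a + pc) / (n + 20 pc)) / bg_a).
    """
    if len(family_sequences) < 2:
        raise ValueError("need >=2 sequences to build a profile")
    length = len(family_sequences[0])
    if any(len(s) != length for s in family_sequences):
        raise ValueError("family sequences must be equal length (ungapped)")
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    counts = np.zeros((length, 20))
    for seq in family_sequences:
        for j, aa in enumerate(seq):
            if aa in _AA_INDEX:  # X and other ambiguity codes carry no count
                counts[j, _AA_INDEX[aa]] += 1
    n = len(family_sequences)
    freqs = (counts + pseudocount) / (n + 20 * pseudocount)
    scores = np.log2(freqs / background)
    return PSSMProfile(name=name, scores=scores, background=background)


def encode_protein(seq: str) -> np.ndarray:
    """Residues as indices 0..19; unknown letters (X etc.) as 20."""
    return np.fromiter((_AA_INDEX.get(aa, 20) for aa in seq), dtype=np.int64, count=len(seq))


def scan_best_window(profile: PSSMProfile, seq: str) -> tuple[float, int, int]:
    """Best ungapped placement of the profile on the sequence.

    Returns (score, query_start_0based, profile_columns_used). Sequences
    shorter than the profile are scored at their best offset inside the
    profile, using len(seq) columns. Unknown residues score 0.
    """
    L = profile.length
    codes = encode_protein(seq)
    padded = np.hstack([profile.scores, np.zeros((L, 1))])  # col 20 = unknown -> 0
    if len(seq) >= L:
        n_win = len(seq) - L + 1
        total = np.zeros(n_win)
        for j in range(L):
            total += padded[j, codes[j : j + n_win]]
        best = int(np.argmax(total))
        return float(total[best]), best, L
    # short sequence: slide it along the profile
    n_off = L - len(seq) + 1
    total = np.zeros(n_off)
    col_scores = padded[:, codes]  # (L, len(seq)) via fancy indexing per column
    for j in range(len(seq)):
        total += col_scores[j : j + n_off, j]
    best = int(np.argmax(total))
    return float(total[best]), 0, len(seq)


def calibrate(
    profile: PSSMProfile,
    seed: int,
    n_decoys: int = 1000,
    decoy_length: int = DECOY_LENGTH,
) -> PSSMProfile:
    """Fit Gumbel parameters to best-window scores of shuffled decoys.

    One decoy source sequence of ``decoy_length`` residues is drawn from the
    profile background; the decoys are independent shuffles of it, so all
    decoys share one composition. The fit is stored on the profile.
    """
    rng = np.random.default_rng(seed)
    source = rng.choice(20, size=decoy_length, p=profile.background / profile.background.sum())
    scores = np.empty(n_decoys)
    padded = np.hstack([profile.scores, np.zeros((profile.length, 1))])
    L = profile.length
    for i in range(n_decoys):
        codes = rng.permutation(source)
        if decoy_length >= L:
            n_win = decoy_length - L + 1
            total = np.zeros(n_win)
            for j in range(L):
                total += padded[j, codes[j : j + n_win]]
            scores[i] = total.max()
        else:
            s, _, _ = scan_best_window(profile, "".join(PROTEIN_ALPHABET[c] for c in codes))
            scores[i] = s
    mu, beta = stats.gumbel_r.fit(scores)
    profile.mu = float(mu)
    profile.beta = float(beta)
    profile.calibration_seed = int(seed)
    return profile


def domain_evalue(profile: PSSMProfile, score: float, n_targets: int) -> float:
    """E-value of a window score over a search of ``n_targets`` proteins."""
    if not profile.calibrated:
        raise UncalibratedProfileError(
            f"profile {profile.name!r} has no decoy calibration"
        )
    p = float(stats.gumbel_r.sf(score, loc=profile.mu, scale=profile.beta))
    return n_targets * p


# ---------------------------------------------------------------------------
# Plain-text serialisation
#
# One profile:
#   >name length=L mu=... beta=... calib_seed=...      (mu/beta/seed optional)
#   # background: 20 whitespace-separated frequencies
#   L lines of 20 tab-separated bit scores
# ---------------------------------------------------------------------------


def write_profiles(profiles: list[PSSMProfile], path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            header = f">{p.name} length={p.length}"
            if p.calibrated:
                header += f" mu={p.mu:.6f} beta={p.beta:.6f} calib_seed={p.calibration_seed}"
            fh.write(header + "\n")
            fh.write("# background: " + " ".join(f"{b:.6f}" for b in p.background) + "\n")
            for row in p.scores:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_profiles(path) -> list[PSSMProfile]:
    profiles: list[PSSMProfile] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}: line {i + 1}: expected profile header")
        fields = line[1:].split()
        name = fields[0]
        meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        length = int(meta["length"])
        bg_line = lines[i + 1]
        if not bg_line.startswith("# background:"):
            raise ValueError(f"{path}: line {i + 2}: expected background line")
        background = np.array([float(x) for x in bg_line.split(":", 1)[1].split()])
        rows = [
            [float(x) for x in lines[i + 2 + j].split("\t")] for j in range(length)
        ]
        prof = PSSMProfile(name=name, scores=np.array(rows), background=background)
        if "mu" in meta and "beta" in meta:
            prof.mu = float(meta["mu"])
            prof.beta = float(meta["beta"])
            prof.calibration_seed = int(meta.get("calib_seed", -1))
        profiles.append(prof)
        i += 2 + length
    return profiles
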