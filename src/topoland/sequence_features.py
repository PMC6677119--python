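"""Primary-sequence features of mature proteins.

Residue-set composition fractions, GRAVY (grand average of hydropathy on the
Kyte–Doolittle scale), isoelectric point (Henderson–Hasselbalch net charge
with the EMBOSS pKa set, solved by bisection), mean biosynthetic cost in
ATP equivalents, continuous hydrophobic patches and their flanking peptides.

All functions operate on mature sequences (signal peptide removed) and skip
``X`` residues in both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_annotation import Segment

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Akashi–Gojobori biosynthetic cost per residue, in high-energy phosphate
#: bond (~ATP) equivalents.
BIOSYNTHETIC_COST: Mapping[str, float] = {
    "A": 11.7, "R": 27.3, "N": 14.7, "D": 12.7, "C": 24.7, "Q": 16.3, "E": 15.3,
    "G": 11.7, "H": 38.3, "I": 32.3, "L": 27.3, "K": 30.3, "M": 34.3, "F": 52.0,
    "P": 20.3, "S": 11.7, "T": 21.3, "W": 74.3, "Y": 50.0, "V": 23.3,
}

#: EMBOSS pKa constants for the ionizable groups.
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")

#: Named residue sets used for composition fractions.  ``polar``,
#: ``hydrophobic`` and ``small`` follow a published composition convention in
#: which a residue may belong to several sets (G is both small and
#: hydrophobic; H, K, T, C appear in the broad hydrophobic set).  The
#: remaining sets are standard groupings; ``disorder_promoting`` is
#: TOP-IDP-style.  All are overridable through config.
DEFAULT_RESIDUE_SETS: Mapping[str, frozenset] = {
    "polar": frozenset("DEKHRQNSCTYW"),
    "hydrophobic": frozenset("ILVFYWHTCGAMK"),
    "small": frozenset("GSAC"),
    "charged": frozenset("DEHKR"),
    "aromatic": frozenset("FWY"),
    "aliphatic": frozenset("AILV"),
    "disorder_promoting": frozenset("ARGQSPEK"),
}

#: Residue set defining *continuous hydrophobic patches*: the Kyte–Doolittle
#: positive core plus tryptophan.  Deliberately stricter than the broad
#: composition "hydrophobic" set above, which is a composition bookkeeping
#: category, not a patch definition.
PATCH_RESIDUES: frozenset = frozenset("ACFILMVW")


@dataclass(frozen=True)
class CompositionProfile:
    """Per-protein composition summary; fractions over non-X residues."""

    fractions: Mapping[str, float]
    length: int
    gravy: float
    pI: float
    cost: float


def _non_x(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    stripped = sequence.replace("X", "")
    if not stripped:
        raise ValueError("sequence contains no scorable (non-X) residues")
    return stripped


def composition_profile(
    sequence: str, residue_sets: Mapping[str, frozenset] | None = None
) -> CompositionProfile:
    """Compute residue-set fractions, GRAVY, pI and biosynthetic cost."""
    sets = residue_sets or DEFAULT_RESIDUE_SETS
    body = _non_x(sequence)
    n = len(body)
    fractions = {name: sum(1 for aa in body if aa in members) / n for name, members in sets.items()}
    return CompositionProfile(
        fractions=fractions,
        length=len(sequence),
        gravy=gravy(sequence),
        pI=isoelectric_point(sequence),
        cost=biosynthetic_cost(sequence),
    )


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle score over non-X residues."""
    body = _non_x(sequence)
    return float(np.mean([KYTE_DOOLITTLE[aa] for aa in body]))


def net_charge(sequence: str, ph) -> np.ndarray | float:
    """Henderson–Hasselbalch net charge of the chain at pH value(s) ``ph``.

    Positive groups (N-terminus, K, R, H) contribute ``1/(1+10^(pH−pKa))``;
    negative groups (C-terminus, D, E, C, Y) contribute ``−1/(1+10^(pKa−pH))``.
    """
    body = sequence.replace("X", "")
    ph = np.asarray(ph, dtype=float)
    charge = 1.0 / (1.0 + 10.0 ** (ph - EMBOSS_PKA["Nterm"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA["Cterm"] - ph))
    for aa in _BASIC:
        k = body.count(aa)
        if k:
            charge = charge + k / (1.0 + 10.0 ** (ph - EMBOSS_PKA[aa]))
    for aa in _ACIDIC:
        k = body.count(aa)
        if k:
            charge = charge - k / (1.0 + 10.0 ** (EMBOSS_PKA[aa] - ph))
    return charge if charge.shape else float(charge)


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the zero crossing is
    unique; bisection runs until ``|charge| < tol``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def biosynthetic_cost(sequence: str, cost_table: Mapping[str, float] | None = None) -> float:
    """Mean biosynthetic cost per residue (ATP equivalents) over non-X residues."""
    table = cost_table or BIOSYNTHETIC_COST
    body = _non_x(sequence)
    try:
        return float(np.mean([table[aa] for aa in body]))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from cost table") from exc


def hydrophobic_patches(
    sequence: str, min_len: int = 5, patch_residues: frozenset | None = None
) -> list[Segment]:
    """Maximal runs of patch residues of length >= ``min_len``, left to right.

    Each segment carries the mean Kyte–Doolittle score of its residues.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if not sequence:
        raise ValueError("empty sequence")
    members = patch_residues or PATCH_RESIDUES
    segments = []
    start = None
    for i, aa in enumerate(sequence + "\x00", start=1):  # sentinel terminates last run
        if aa in members:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                run = sequence[start - 1 : i - 1]
                segments.append(
                    Segment(
                        start=start,
                        end=i - 1,
                        kind="hydrophobic_patch",
                        mean_score=float(np.mean([KYTE_DOOLITTLE[a] for a in run])),
                    )
                )
            start = None
    return segments


@dataclass(frozen=True)
class PatchSummary:
    segments: tuple = field(default_factory=tuple)
    patches_per_100: float = 0.0
    mean_length: float = float("nan")
    mean_kd_score: float = float("nan")


def patch_summary(sequence: str, min_len: int = 5, patch_residues: frozenset | None = None) -> PatchSummary:
    """Patch count per 100 residues, mean patch length and mean patch K&D score."""
    segments = hydrophobic_patches(sequence, min_len=min_len, patch_residues=patch_residues)
    n = len(segments)
    return PatchSummary(
        segments=tuple(segments),
        patches_per_100=100.0 * n / len(sequence),
        mean_length=float(np.mean([s.length for s in segments])) if n else float("nan"),
        mean_kd_score=float(np.mean([s.mean_score for s in segments])) if n else float("nan"),
    )


def flanking_peptides(segment: Segment, sequence: str, width: int = 5) -> tuple[str, str]:
    """Residues immediately flanking a segment, up to ``width`` per side.

    Truncated at the sequence termini; either side may be empty.
    """
    L = len(sequence)
    if segment.start < 1 or segment.end > L:
        raise ValueError(f"segment ({segment.start}, {segment.end}) out of bounds for L={L}")
    left = sequence[max(0, segment.start - 1 - width) : segment.start - 1]
    right = sequence[segment.end : segment.end + width]
    return left, right
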