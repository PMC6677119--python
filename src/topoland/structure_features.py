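"""Structure-derived scalar features.

Contact maps, absolute and relative contact order, N–C termini distance and
secondary-structure content from annotation segments.

Contact order (CO) is the mean sequence separation |i − j| over residue
pairs in spatial contact; relative contact order rCO = CO / L normalises by
the modeled chain length.  Low rCO (contacts mostly local in sequence)
correlates with fast folding; high rCO with slow folding.  The default
contact definition — any heavy-atom pair within 6 Å, sequence separation
>= 1 — is the original contact-order convention; a CA-only mode is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_annotation import Segment, StructureModel
from .track_segmentation import merge_segments

CONTACT_CUTOFF = 6.0  # Å, heavy-atom pair distance
MIN_SEPARATION = 1  # residues, |i - j| >= min_sep


@dataclass(frozen=True)
class StructureFeatures:
    rco: float
    co_abs: float
    n_contacts: int
    modeled_length: int
    termini_distance: float = float("nan")
    helix_fraction: float = float("nan")
    strand_fraction: float = float("nan")


def contact_pairs(
    structure: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    min_sep: int = MIN_SEPARATION,
    ca_only: bool = False,
) -> set[tuple[int, int]]:
    """Residue index pairs (i < j) with any heavy-atom pair within ``cutoff`` Å.

    Unresolved residues carry no atoms and therefore contribute no contacts.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    residues = structure.resolved_residues
    if len(residues) < 2:
        return set()
    coords, index = [], []
    for res in residues:
        atoms = res.atoms
        if ca_only:
            # First carbon in record order is the CA in standard PDB files
            # (and the sole atom of a CA trace).
            carbons = [a for a in atoms if a[0] == "C"]
            atoms = carbons[:1]
        for element, x, y, z in atoms:
            coords.append((x, y, z))
            index.append(res.sequence_index)
    if not coords:
        return set()
    coords = np.asarray(coords)
    index = np.asarray(index)
    dist = cdist(coords, coords)
    ai, aj = np.nonzero(dist <= cutoff)
    ri, rj = index[ai], index[aj]
    keep = rj - ri >= min_sep
    return set(zip(ri[keep].tolist(), rj[keep].tolist()))


def relative_contact_order(
    structure: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    min_sep: int = MIN_SEPARATION,
    ca_only: bool = False,
) -> StructureFeatures:
    """Absolute CO = mean |i − j| over contacts; rCO = CO / modeled length L.

    L spans the first to last resolved residue inclusive, so unresolved
    interior gaps count toward the normalisation but add no contacts.
    """
    pairs = contact_pairs(structure, cutoff=cutoff, min_sep=min_sep, ca_only=ca_only)
    if not pairs:
        raise ValueError(f"{structure.accession}: no contacts, rCO undefined")
    seps = np.array([j - i for i, j in pairs], dtype=float)
    co_abs = float(seps.mean())
    L = structure.L
    return StructureFeatures(
        rco=co_abs / L,
        co_abs=co_abs,
        n_contacts=len(pairs),
        modeled_length=L,
    )


def termini_distance(structure: StructureModel) -> float:
    """Euclidean CA–CA distance between the first and last resolved residues."""
    residues = structure.resolved_residues
    if not residues:
        raise ValueError(f"{structure.accession}: no resolved residues")

    def _ca(res):
        # CA atoms are carbon; in CA-only traces the single atom is the CA.
        carbons = [a for a in res.atoms if a[0] == "C"]
        if not carbons:
            raise ValueError(
                f"{structure.accession}: residue {res.sequence_index} has no CA/carbon atom"
            )
        return np.array(carbons[0][1:], dtype=float)

    return float(np.linalg.norm(_ca(residues[0]) - _ca(residues[-1])))


def ss_content(ss_segments, L: int) -> tuple[float, float]:
    """Helix and strand fractions of the chain from annotation segments.

    Segments are (start, end, label) triples or :class:`Segment` objects with
    label in ``kind``; overlapping segments of the same label are merged,
    conflicting labels at one position are an error.
    """
    by_label: dict[str, list[Segment]] = {"helix": [], "strand": []}
    for seg in ss_segments:
        if isinstance(seg, Segment):
            start, end, label = seg.start, seg.end, seg.kind
        else:
            start, end, label = seg
        if label not in by_label:
            raise ValueError(f"unknown secondary-structure label {label!r}")
        if start < 1 or end > L:
            raise ValueError(f"segment ({start}, {end}) out of bounds for L={L}")
        by_label[label].append(Segment(start=start, end=end, kind=label))

    positions = {}
    fractions = {}
    for label, segs in by_label.items():
        merged = merge_segments(segs)
        covered = set()
        for s in merged:
            covered.update(range(s.start, s.end + 1))
        fractions[label] = len(covered) / L
        positions[label] = covered
    clash = positions["helix"] & positions["strand"]
    if clash:
        raise ValueError(f"conflicting helix/strand labels at positions {sorted(clash)[:5]}")
    return fractions["helix"], fractions["strand"]
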