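"""Input/output and shared domain types for subcellular topology analysis.

This module holds the data model shared by every analysis stage — protein
records with topology annotations, per-residue score tracks, called segments,
structure models — together with readers/writers for the plain-text formats
they travel in (FASTA, TSV tables, PDB ATOM records).

Conventions
-----------
* All residue coordinates are 1-based inclusive and refer to the *mature*
  sequence, i.e. the protein after removal of its cleavable N-terminal signal
  peptide.  Cytoplasmic proteins have no signal peptide and their mature
  sequence is the full chain.
* ``X`` residues (unknown) are tolerated in sequences but excluded from both
  numerators and denominators of composition statistics; score tracks must
  still cover them positionally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("topoland")

#: Single-letter subcellular topology classes.  A cytoplasmic,
#: B inner-membrane embedded, C colicin-like imported, E/I lipoproteins,
#: F1 peripheral IM (cytoplasmic face), F2/F3 peripheral IM/OM (periplasmic
#: face), G periplasmic, H outer-membrane β-barrel, N nucleoid-associated,
#: X extracellular/surface, r ribosome-associated.
TOPOLOGY_CLASSES = frozenset({"A", "B", "C", "E", "F1", "F2", "F3", "G", "H", "I", "N", "X", "r"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Score-track kinds understood by the segmentation stage.
TRACK_KINDS = frozenset(
    {
        "disorder",
        "backbone_dynamics",
        "early_folding",
        "aggregation",
        "helix_propensity",
        "sheet_propensity",
        "hydropathy",
    }
)

SCOP_CLASSES = frozenset({"a", "b", "c", "d", "f", "other"})


class FormatError(ValueError):
    """A structured input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of the proteome with its topology annotation.

    ``sp_length`` is the length of the cleavable signal peptide (0 when the
    protein has none); it is an annotation input, never predicted here.
    """

    accession: str
    sequence: str
    sp_length: int = 0
    topology_class: str = "A"
    essential: bool = False
    experimental_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be uppercase")
        if not 0 <= self.sp_length < len(self.sequence):
            raise ValueError(
                f"{self.accession}: sp_length {self.sp_length} out of range "
                f"for length {len(self.sequence)}"
            )
        if self.topology_class not in TOPOLOGY_CLASSES:
            raise ValueError(
                f"{self.accession}: unknown topology class {self.topology_class!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.sp_length :]


@dataclass(frozen=True)
class TopologyGroupMap:
    """Mapping from topology class letters to named analysis groups.

    The defaults follow the standard partition of a Gram-negative proteome:
    the *cytoplasmome* (soluble cytoplasmic, nucleoid-, ribosome- and
    peripherally IM-associated proteins), the *membranome* (inner-membrane
    embedded), and the *secretome* (everything translocated across the inner
    membrane: periplasmic, lipoproteins, OMPs, surface/extracellular).  The
    *exportome* is membranome ∪ secretome.
    """

    groups: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "cytoplasmome": frozenset({"A", "N", "r", "F1"}),
            "membranome": frozenset({"B"}),
            "secretome": frozenset({"C", "E", "F2", "F3", "G", "H", "I", "X"}),
            "secretome_no_OMP": frozenset({"C", "E", "F2", "F3", "G", "I", "X"}),
            "OMP": frozenset({"H"}),
            "exportome": frozenset({"B", "C", "E", "F2", "F3", "G", "H", "I", "X"}),
            "peripheral_IM": frozenset({"F1"}),
        }
    )

    def __post_init__(self):
        covered = set().union(*self.groups.values())
        missing = TOPOLOGY_CLASSES - covered
        if missing:
            raise ValueError(f"topology classes mapped to no group: {sorted(missing)}")
        if not self.groups["OMP"] <= self.groups["secretome"]:
            raise ValueError("OMP classes must be a subset of the secretome")
        if self.groups["exportome"] != self.groups["membranome"] | self.groups["secretome"]:
            raise ValueError("exportome must equal membranome ∪ secretome")

    def group_of(self, topology_class: str, primary=("cytoplasmome", "membranome", "secretome")):
        """Return the first primary group containing the class letter."""
        for name in primary:
            if topology_class in self.groups[name]:
                return name
        raise KeyError(topology_class)

    def members(self, group: str, records: Iterable[ProteinRecord]):
        letters = self.groups[group]
        return [r for r in records if r.topology_class in letters]


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue numeric track (disorder, aggregation …) on the mature sequence."""

    accession: str
    kind: str
    values: tuple
    provenance: str = ""

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"{self.accession}: track must be a nonempty vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{self.accession}: non-finite track values")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class Segment:
    """A called region (IDR / foldon / hydrophobic patch / APR), 1-based inclusive."""

    start: int
    end: int
    kind: str = "IDR"
    mean_score: float = float("nan")
    length_class: str = "na"
    position_class: str = "na"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment bounds ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ResidueModel:
    """One residue of a structure model; unresolved residues carry no atoms."""

    sequence_index: int
    resolved: bool
    atoms: tuple  # of (element, x, y, z) in Å


@dataclass(frozen=True)
class StructureModel:
    """Ordered single-chain structure; L spans first to last modeled residue."""

    accession: str
    residues: tuple

    def __post_init__(self):
        idx = [r.sequence_index for r in self.residues]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"{self.accession}: residue indices must strictly increase")
        for r in self.residues:
            if r.resolved and not r.atoms:
                raise ValueError(f"{self.accession}: resolved residue {r.sequence_index} has no atoms")
            for _, x, y, z in r.atoms:
                if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                    raise ValueError(f"{self.accession}: non-finite coordinates")

    @property
    def L(self) -> int:
        """Modeled chain length: first to last residue index, inclusive."""
        res = [r.sequence_index for r in self.residues if r.resolved]
        if not res:
            return 0
        return res[-1] - res[0] + 1

    @property
    def resolved_residues(self):
        return tuple(r for r in self.residues if r.resolved)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into sequence-only :class:`ProteinRecord` objects.

    Annotations (topology class, signal-peptide length, essentiality) are
    joined later from the topology table.  Sequences are uppercased; entry
    order is preserved.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for entry {entry.id!r}")
        records.append(ProteinRecord(accession=entry.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Topology table


def read_topology_table(path) -> dict:
    """Read the per-protein topology annotation TSV.

    Expected header columns: ``accession``, ``topology_class``, ``sp_length``,
    ``essential``.  Returns ``{accession: (topology_class, sp_length,
    essential)}``.  Duplicate accessions and unknown class letters are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "topology_class", "sp_length", "essential"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dupes = df["accession"][df["accession"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate accessions {sorted(set(dupes))}")
    bad = sorted(set(df["topology_class"]) - TOPOLOGY_CLASSES)
    if bad:
        raise FormatError(f"{path}: unknown topology classes {bad}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.accession] = (row.topology_class, int(row.sp_length), bool(int(row.essential)))
    return out


def write_topology_table(records: Iterable[ProteinRecord], path) -> None:
    rows = [
        {
            "accession": r.accession,
            "topology_class": r.topology_class,
            "sp_length": r.sp_length,
            "essential": int(r.essential),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def join_annotations(records: Sequence[ProteinRecord], annotations: Mapping) -> list[ProteinRecord]:
    """Attach topology-table annotations to FASTA-derived records."""
    out = []
    for rec in records:
        if rec.accession in annotations:
            cls, sp, ess = annotations[rec.accession]
            out.append(replace(rec, topology_class=cls, sp_length=sp, essential=ess))
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Mature-domain derivation and redundancy reduction


def trim_to_mature(record: ProteinRecord) -> ProteinRecord:
    """Remove the signal peptide; downstream coordinates refer to the result.

    The record invariant already guarantees ``sp_length < L``; a record whose
    annotation violates that cannot be constructed.
    """
    if record.sp_length == 0:
        return record
    return replace(record, sequence=record.sequence[record.sp_length :], sp_length=0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global sequence identity = matches / alignment length (gapped columns count)."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def reduce_redundancy(records: Sequence[ProteinRecord], identity_threshold: float = 0.90) -> list[ProteinRecord]:
    """Greedy longest-first redundancy reduction at a global-identity threshold.

    Records are visited longest first (ties keep input order); a record joins
    the first existing cluster whose representative it matches at
    ``identity >= identity_threshold``, otherwise it founds a new cluster.
    Representatives are returned longest first.  This mirrors the greedy
    incremental clustering convention of CD-HIT and is fully deterministic.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    if not records:
        raise ValueError("no records to cluster")
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: -len(r.sequence))
    representatives: list[ProteinRecord] = []
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(rec.sequence, rep.sequence, aligner) >= identity_threshold:
                break
        else:
            representatives.append(rec)
    return representatives


# ---------------------------------------------------------------------------
# Score tracks


def read_score_tracks(path, kind: str) -> list[ScoreTrack]:
    """Read per-residue score tracks from a TSV of (accession, position, residue, score).

    Positions must be 1-based and contiguous per accession.  Track/sequence
    length agreement is checked at join time by :func:`validate_tracks`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "position": int, "score": float})
    required = {"accession", "position", "score"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    tracks = []
    for acc, sub in df.groupby("accession", sort=False):
        pos = sub["position"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            raise FormatError(f"{path}: non-contiguous positions for {acc}")
        tracks.append(ScoreTrack(accession=acc, kind=kind, values=tuple(sub["score"]), provenance=str(path)))
    return tracks


def write_score_tracks(tracks: Iterable[ScoreTrack], path, sequences: Mapping[str, str] | None = None) -> None:
    """Write tracks as TSV; scores at 6 decimals so round trips preserve them."""
    rows = []
    for t in tracks:
        seq = sequences.get(t.accession) if sequences else None
        for i, v in enumerate(t.values, start=1):
            rows.append(
                {
                    "accession": t.accession,
                    "position": i,
                    "residue": seq[i - 1] if seq else "X",
                    "score": f"{v:.6f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_tracks_json(path, kind: str) -> list[ScoreTrack]:
    """Per-protein JSON alternative: ``{accession: [scores…], …}``."""
    data = json.loads(Path(path).read_text())
    return [
        ScoreTrack(accession=acc, kind=kind, values=tuple(vals), provenance=str(path))
        for acc, vals in data.items()
    ]


def validate_tracks(tracks: Iterable[ScoreTrack], records: Sequence[ProteinRecord]) -> None:
    """Check each track covers its protein's mature sequence exactly."""
    lengths = {r.accession: len(r.mature_sequence) for r in records}
    for t in tracks:
        if t.accession in lengths and len(t) != lengths[t.accession]:
            raise FormatError(
                f"track length {len(t)} != mature length {lengths[t.accession]} "
                f"for {t.accession}"
            )


# ---------------------------------------------------------------------------
# Structures (PDB ATOM records)


def read_structure(path, chain: str | None = None, accession: str | None = None) -> StructureModel:
    """Read a single chain from PDB ATOM records into a :class:`StructureModel`.

    Hydrogens and waters are dropped, the first altLoc of each atom is kept,
    only the first MODEL is used (with a warning if more exist), and gaps in
    residue numbering are represented as unresolved residues.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: no models / ATOM records")
    if len(st) > 1:
        logger.warning("%s: %d models present, using the first", path, len(st))
    model = st[0]
    chains = list(model)
    if not chains:
        raise FormatError(f"{path}: no chains with ATOM records")
    if chain is None:
        selected = chains[0]
    else:
        matches = [c for c in chains if c.name == chain]
        if not matches:
            raise FormatError(f"{path}: chain {chain!r} not found")
        selected = matches[0]

    by_index: dict[int, list] = {}
    for res in selected:
        if res.is_water():
            continue
        seen_names = set()
        atoms = []
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.name in seen_names:  # keep first altLoc only
                continue
            seen_names.add(atom.name)
            atoms.append((atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z))
        if atoms:
            by_index.setdefault(res.seqid.num, []).extend(atoms)
    if not by_index:
        raise FormatError(f"{path}: no heavy ATOM records in selected chain")

    first, last = min(by_index), max(by_index)
    residues = tuple(
        ResidueModel(sequence_index=i, resolved=i in by_index, atoms=tuple(by_index.get(i, ())))
        for i in range(first, last + 1)
    )
    return StructureModel(accession=accession or Path(path).stem, residues=residues)


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:^4s}{alt:1s}{resname:>3s} {chain:1s}{resnum:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def write_structure(model: StructureModel, path, chain: str = "A") -> None:
    """Write a structure model as minimal PDB ATOM records (CA traces and toys)."""
    serial = 0
    with open(path, "w") as fh:
        for res in model.residues:
            for element, x, y, z in res.atoms:
                serial += 1
                name = "CA" if element == "C" else element
                fh.write(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=f" {name:<3s}"[:4],
                        alt=" ",
                        resname="ALA",
                        chain=chain,
                        resnum=res.sequence_index,
                        x=x,
                        y=y,
                        z=z,
                        occ=1.0,
                        b=0.0,
                        element=element,
                    )
                )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Fold table and abundance matrix


def read_fold_table(path) -> pd.DataFrame:
    """Read fold assignments: accession, fold_id, scop_class, start, end.

    ``scop_class`` letters: a (all-α), b (all-β), c (α/β), d (α+β),
    f (membrane / cell surface), other.  Class-f folds are flagged
    non-soluble for the census' soluble-only view.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "fold_id": str, "scop_class": str})
    required = {"accession", "fold_id", "scop_class"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["fold_id"].isna().any() or (df["fold_id"] == "").any():
        raise FormatError(f"{path}: empty fold_id")
    bad = sorted(set(df["scop_class"]) - SCOP_CLASSES)
    if bad:
        raise FormatError(f"{path}: unknown SCOP classes {bad}")
    df["soluble"] = df["scop_class"] != "f"
    return df


def read_abundance(path) -> pd.DataFrame:
    """Read the abundance matrix (proteins × conditions, copies per cell)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need ≥2 conditions, got {df.shape[1]}")
    if (df.to_numpy() <= 0).any():
        raise FormatError(f"{path}: abundances must be positive")
    return df
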