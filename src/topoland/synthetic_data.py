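"""Synthetic proteome generator with known ground truth.

Generates two-group proteomes (cytoplasmome vs secretome) whose statistical
structure mirrors the contrasts the analysis is designed to detect, so every
pipeline stage has a recovery test without external datasets:

* per-group residue composition targets (secretome enriched in polar/small/
  disorder-promoting residues, cytoplasmome in hydrophobic/charged/aromatic/
  aliphatic residues, hence higher GRAVY and biosynthetic cost);
* score tracks with autocorrelated noise and planted segments (IDRs,
  foldons, APRs) at group-specific densities;
* ideal-geometry toy structures (helix / extended / hairpin) whose relative
  contact order separates the groups;
* a designed fold pool with planted unique/shared and rare/frequent folds;
* an abundance matrix with per-protein variability classes.

Every generator is deterministic under its seed, and the returned
:class:`SyntheticTruth` records what was planted, including the qualitative
effect-direction ledger the end-to-end tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_annotation import AMINO_ACIDS, ProteinRecord, ResidueModel, ScoreTrack, Segment, StructureModel

# Per-group residue composition targets.  Chosen once so that every named
# set fraction, GRAVY and biosynthetic cost differ between groups in the
# direction recorded in EFFECT_LEDGER (verified in expectation from the
# target vectors themselves; see docs/methods.md).
CYTOPLASMOME_COMPOSITION: Mapping[str, float] = {
    "A": 0.0912, "C": 0.0123, "D": 0.0503, "E": 0.0695, "F": 0.0480,
    "G": 0.0637, "H": 0.0225, "I": 0.0735, "K": 0.0491, "L": 0.1094,
    "M": 0.0307, "N": 0.0259, "P": 0.0451, "Q": 0.0350, "R": 0.0624,
    "S": 0.0373, "T": 0.0412, "V": 0.0828, "W": 0.0174, "Y": 0.0327,
}
SECRETOME_COMPOSITION: Mapping[str, float] = {
    "A": 0.0906, "C": 0.0122, "D": 0.0600, "E": 0.0511, "F": 0.0317,
    "G": 0.0894, "H": 0.0224, "I": 0.0491, "K": 0.0388, "L": 0.0827,
    "M": 0.0205, "N": 0.0517, "P": 0.0448, "Q": 0.0528, "R": 0.0500,
    "S": 0.0791, "T": 0.0670, "V": 0.0643, "W": 0.0133, "Y": 0.0285,
}

#: Direction of each programmed between-group effect: feature name -> group
#: expected to show the higher value.  This is the ground-truth ledger the
#: end-to-end comparison stage must recover.
EFFECT_LEDGER: Mapping[str, str] = {
    "polar": "secretome",
    "small": "secretome",
    "disorder_promoting": "secretome",
    "hydrophobic": "cytoplasmome",
    "charged": "cytoplasmome",
    "aromatic": "cytoplasmome",
    "aliphatic": "cytoplasmome",
    "gravy": "cytoplasmome",
    "cost": "cytoplasmome",
    "disorder_mean": "secretome",
    "idrs_per_100": "secretome",
    "backbone_dynamics_mean": "secretome",
    "early_folding_mean": "cytoplasmome",
    "foldons_per_100": "cytoplasmome",
    "aprs_per_100": "cytoplasmome",
    "patches_per_100": "cytoplasmome",
    "rco": "secretome",
    "thermostability": "secretome",
    "log_abundance_mean": "cytoplasmome",
}


@dataclass(frozen=True)
class ProteomeConfig:
    """Study-design knobs for the synthetic proteome.

    Defaults define the reference synthetic study: 400 proteins per group,
    lengths log-normal around ~250 residues, composition concentration 400
    (per-protein Dirichlet jitter around the group target), IDR planting
    densities of 1.1 (secretome) vs 0.7 (cytoplasmome) per 100 residues.
    """

    n_per_group: int = 400
    length_log_mean: float = 5.5  # exp(5.5) ~ 245 residues
    length_log_sd: float = 0.35
    min_length: int = 60
    composition_concentration: float = 400.0
    sp_length_range: tuple = (15, 30)
    # planted per-100-residue segment densities (group -> density)
    idr_density: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.7, "secretome": 1.1}
    )
    foldon_density: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 1.3, "secretome": 0.9}
    )
    apr_density: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.86, "secretome": 0.60}
    )
    # track baselines (below threshold) per group
    disorder_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.26, "secretome": 0.34}
    )
    dynamics_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.70, "secretome": 0.78}
    )
    early_folding_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.10, "secretome": 0.07}
    )
    aggregation_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 1.5, "secretome": 1.0}
    )
    track_noise_sd: float = 0.04
    # fraction of each group receiving the high-rCO (hairpin) toy structure
    hairpin_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 0.25, "secretome": 0.75}
    )
    thermostability_mean: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 50.0, "secretome": 55.0}
    )
    thermostability_sd: float = 6.0
    log2_abundance_mean: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasmome": 9.0, "secretome": 7.5}
    )
    log2_abundance_sd: float = 1.5


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything the generators planted, for recovery testing."""

    group_of: Mapping[str, str]
    composition_targets: Mapping[str, Mapping[str, float]]
    planted_segments: Mapping[str, Mapping[str, tuple]]  # accession -> kind -> segments
    structure_kind: Mapping[str, str]
    variability_class: Mapping[str, str]
    effect_ledger: Mapping[str, str] = field(default_factory=lambda: dict(EFFECT_LEDGER))
    fold_design: pd.DataFrame | None = None


def _sequence_from_composition(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_proteome(
    config: ProteomeConfig | None = None, seed: int = 0
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate annotated two-group protein records and their ground truth.

    Secretome records carry a signal peptide (``sp_length`` in the configured
    range, prepended as extra residues) and topology class G; cytoplasmic
    records are class A with no signal peptide.  Per-protein compositions are
    Dirichlet draws around the group target, so group mean compositions
    converge on the targets (within ±0.01 by n = 500).
    """
    config = config or ProteomeConfig()
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    group_of: dict[str, str] = {}
    for group, target, topo_class in (
        ("cytoplasmome", CYTOPLASMOME_COMPOSITION, "A"),
        ("secretome", SECRETOME_COMPOSITION, "G"),
    ):
        target_vec = np.array([target[aa] for aa in AMINO_ACIDS])
        if not np.isclose(target_vec.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{group} composition does not sum to 1")
        for i in range(config.n_per_group):
            acc = f"SYN_{group[:3].upper()}_{i:04d}"
            length = max(
                config.min_length,
                int(round(np.exp(rng.normal(config.length_log_mean, config.length_log_sd)))),
            )
            probs = rng.dirichlet(config.composition_concentration * target_vec)
            mature = _sequence_from_composition(rng, length, probs)
            if group == "secretome":
                sp_len = int(rng.integers(config.sp_length_range[0], config.sp_length_range[1] + 1))
                sp = _sequence_from_composition(rng, sp_len, probs)
                records.append(
                    ProteinRecord(
                        accession=acc,
                        sequence=sp + mature,
                        sp_length=sp_len,
                        topology_class=topo_class,
                    )
                )
            else:
                records.append(
                    ProteinRecord(accession=acc, sequence=mature, topology_class=topo_class)
                )
            group_of[acc] = group
    truth = SyntheticTruth(
        group_of=group_of,
        composition_targets={
            "cytoplasmome": dict(CYTOPLASMOME_COMPOSITION),
            "secretome": dict(SECRETOME_COMPOSITION),
        },
        planted_segments={},
        structure_kind={},
        variability_class={},
    )
    return records, truth


def plant_segment_coordinates(
    rng: np.random.Generator,
    length: int,
    density_per_100: float,
    seg_len_range: tuple = (6, 25),
    min_gap: int = 8,
) -> list[Segment]:
    """Draw non-overlapping planted segment coordinates at a target density.

    The number of segments is Poisson with mean ``density_per_100 × L / 100``;
    placement is rejection-sampled with a minimum gap so segments stay
    distinct after calling.
    """
    n_target = rng.poisson(density_per_100 * length / 100.0)
    segments: list[Segment] = []
    for _ in range(n_target):
        for _attempt in range(50):
            seg_len = int(rng.integers(seg_len_range[0], seg_len_range[1] + 1))
            if seg_len >= length:
                continue
            start = int(rng.integers(1, length - seg_len + 2))
            end = start + seg_len - 1
            if all(
                end < s.start - min_gap or start > s.end + min_gap for s in segments
            ):
                segments.append(Segment(start=start, end=end, kind="planted"))
                break
    return sorted(segments, key=lambda s: s.start)


def generate_track_with_segments(
    record: ProteinRecord,
    kind: str,
    baseline: float,
    noise_sd: float,
    planted_segments: Sequence[Segment],
    seed: int,
    plateau: float | None = None,
    threshold: float | None = None,
    snr: float = 3.0,
    smooth_window: int = 5,
) -> ScoreTrack:
    """Autocorrelated-noise track with plateaus at the planted coordinates.

    Noise is Gaussian smoothed with a moving-average window (mimicking the
    positional autocorrelation of per-residue predictor outputs).  The
    plateau level defaults to ``threshold + snr × noise_sd``, guaranteeing
    the planted segments sit at the requested signal-to-noise ratio above
    the calling threshold while the baseline stays below it.
    """
    L = len(record.mature_sequence)
    for a, b in zip(planted_segments, planted_segments[1:]):
        if b.start <= a.end:
            raise ValueError(f"{record.accession}: overlapping planted segments")
    if planted_segments and planted_segments[-1].end > L:
        raise ValueError(f"{record.accession}: planted segment beyond mature length {L}")
    if plateau is None:
        if threshold is None:
            raise ValueError("give either plateau or threshold")
        plateau = threshold + snr * noise_sd
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=L + smooth_window)
    kernel = np.ones(smooth_window) / smooth_window
    noise = np.convolve(noise, kernel, mode="valid")[:L] * np.sqrt(smooth_window)
    values = np.full(L, baseline) + noise
    for seg in planted_segments:
        values[seg.start - 1 : seg.end] = plateau + noise[seg.start - 1 : seg.end]
    return ScoreTrack(accession=record.accession, kind=kind, values=tuple(values), provenance="synthetic")


def generate_toy_structure(kind: str, length: int, accession: str = "TOY") -> StructureModel:
    """Ideal-geometry CA trace: ``helix``, ``extended`` or ``hairpin``.

    Helix: 1.5 Å rise, 100°/residue, 2.3 Å radius (contacts are sequence-
    local, low rCO).  Extended: 3.8 Å CA spacing along a line (adjacent
    contacts only).  Hairpin: two antiparallel extended strands ~5 Å apart
    joined by a turn (long-range cross-strand contacts, high rCO).
    """
    if length < 3:
        raise ValueError(f"length must be >= 3, got {length}")
    coords = np.zeros((length, 3))
    if kind == "helix":
        rise, turn, radius = 1.5, np.deg2rad(100.0), 2.3
        for i in range(length):
            coords[i] = (radius * np.cos(i * turn), radius * np.sin(i * turn), rise * i)
    elif kind == "extended":
        coords[:, 0] = 3.8 * np.arange(length)
    elif kind == "hairpin":
        half = length // 2
        for i in range(length):
            if i < half:
                coords[i] = (3.8 * i, 0.0, 0.0)
            else:
                coords[i] = (3.8 * (length - 1 - i), 5.0, 0.0)
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    residues = tuple(
        ResidueModel(sequence_index=i + 1, resolved=True, atoms=(("C", *coords[i]),))
        for i in range(length)
    )
    return StructureModel(accession=accession, residues=residues)


@dataclass(frozen=True)
class FoldDesign:
    """Planted fold-pool design: per-fold class letter, group and counts."""

    rows: pd.DataFrame  # fold_id, scop_class, group ('shared' or a group name), count_per_group


def default_fold_design() -> FoldDesign:
    """A small reference design with unique-β secretome folds, shared folds,
    and both rare and frequent folds in each group."""
    rows = []
    for i in range(5):  # unique-to-secretome β folds, frequent
        rows.append(("sec_b_%d" % i, "b", "secretome", 5))
    for i in range(3):  # unique-to-secretome β folds, rare
        rows.append(("sec_b_rare_%d" % i, "b", "secretome", 2))
    for i in range(6):  # unique cytoplasmic α/β folds, frequent
        rows.append(("cyt_c_%d" % i, "c", "cytoplasmome", 6))
    for i in range(4):  # unique cytoplasmic α folds, rare
        rows.append(("cyt_a_rare_%d" % i, "a", "cytoplasmome", 1))
    for i in range(4):  # shared α folds
        rows.append(("shared_a_%d" % i, "a", "shared", 4))
    for i in range(2):  # shared α+β folds, rare overall
        rows.append(("shared_d_%d" % i, "d", "shared", 1))
    rows.append(("membrane_f", "f", "secretome", 3))  # excluded by soluble-only
    return FoldDesign(
        rows=pd.DataFrame(rows, columns=["fold_id", "scop_class", "group", "count_per_group"])
    )


def generate_fold_table(
    design: FoldDesign,
    group_accessions: Mapping[str, Sequence[str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Realise a fold design as an (accession, fold_id, scop_class) table.

    ``group`` = 'shared' places ``count_per_group`` instances in *each*
    group; otherwise all instances go to the named group.  Proteins are
    drawn with replacement from the group's accession pool, so one protein
    may carry several folds (n-fold proteins).
    """
    rng = np.random.default_rng(seed)
    records = []
    for row in design.rows.itertuples(index=False):
        targets = (
            list(group_accessions) if row.group == "shared" else [row.group]
        )
        if row.count_per_group < 1:
            raise ValueError(f"fold {row.fold_id} assigned to zero proteins")
        for group in targets:
            pool = group_accessions[group]
            for acc in rng.choice(pool, size=row.count_per_group, replace=True):
                records.append({"accession": acc, "fold_id": row.fold_id, "scop_class": row.scop_class})
    df = pd.DataFrame(records)
    df["soluble"] = df["scop_class"] != "f"
    return df


def generate_abundance(
    accessions: Sequence[str],
    n_conditions: int = 13,
    class_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    base_log2_mean: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Abundance matrix (copies per cell) with per-protein variability classes.

    Each protein is assigned a variability class with the ``class_mix``
    probabilities; its row is log-normal with a class-specific log2-SD
    (very_low 0.05, low 0.3, moderate 0.7, high 1.5), so called VS values
    reproduce the planted class ordering.
    """
    class_sd = {"very_low": 0.05, "low": 0.3, "moderate": 0.7, "high": 1.5}
    mix = class_mix or {"very_low": 0.25, "low": 0.25, "moderate": 0.25, "high": 0.25}
    if not np.isclose(sum(mix.values()), 1.0):
        raise ValueError("class mix must sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    rows, assigned = [], {}
    for acc in accessions:
        cls = classes[rng.choice(len(classes), p=probs)]
        assigned[acc] = cls
        mean = base_log2_mean[acc] if base_log2_mean else 8.0
        rows.append(2.0 ** rng.normal(mean, class_sd[cls], size=n_conditions))
    matrix = pd.DataFrame(
        rows, index=list(accessions), columns=[f"condition_{i+1}" for i in range(n_conditions)]
    )
    return matrix, assigned
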