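"""Shared fixtures: toy structures, random generators, and the reference
synthetic study (session-scoped, since the full pipeline run is the most
expensive object in the suite)."""

import numpy as np
import pytest

from topoland.io_annotation import ResidueModel, StructureModel
from topoland.pipeline import run_synthetic_study


def ca_trace(coords, accession="TOY", start_index=1, resolved=None):
    """Build a CA-only StructureModel from a list of coordinates."""
    residues = []
    for i, c in enumerate(coords):
        ok = True if resolved is None else resolved[i]
        residues.append(
            ResidueModel(
                sequence_index=start_index + i,
                resolved=ok,
                atoms=(("C", *c),) if ok else (),
            )
        )
    return StructureModel(accession=accession, residues=tuple(residues))


@pytest.fixture
def collinear_trace():
    """Three CA atoms on a line, 3.8 Å apart (adjacent contacts only at 6 Å)."""
    return ca_trace([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])


@pytest.fixture
def triangle_trace():
    """Equilateral triangle with 5 Å sides: all three pairs in contact at 6 Å."""
    h = 5 * np.sqrt(3) / 2
    return ca_trace([(0, 0, 0), (5, 0, 0), (2.5, h, 0)])


@pytest.fixture(scope="session")
def reference_study():
    """The default synthetic study (400 proteins per group, fixed seed)."""
    return run_synthetic_study(seed=20240917 % 2**31)
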