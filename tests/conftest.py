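import numpy as np
import pytest

from xlquant.grouping import MergedGroup
from xlquant.proteingroups import MINUS_UV, PLUS_UV, ProteinEntry, SampleDesign


@pytest.fixture
def design4():
    """Two replicates per condition: p1, p2 (+UV) and m1, m2 (−UV)."""
    return [
        SampleDesign("p1", PLUS_UV, 1),
        SampleDesign("p2", PLUS_UV, 2),
        SampleDesign("m1", MINUS_UV, 1),
        SampleDesign("m2", MINUS_UV, 2),
    ]


def make_entry(acc, intensities, peptides=None, contaminant=False, reverse=False, only_by_site=False):
    return ProteinEntry(
        protein_ids=[acc],
        gene_symbol=acc,
        peptide_ids=frozenset(peptides or {f"{acc}_p1", f"{acc}_p2"}),
        intensities=dict(intensities),
        flag_contaminant=contaminant,
        flag_reverse=reverse,
        flag_only_by_site=only_by_site,
    )


def make_group(gid, acc, intensities, peptides=None):
    """Single-member merged group with given pooled intensities."""
    entry = make_entry(acc, intensities, peptides)
    return MergedGroup(
        group_id=gid,
        member_entries=[entry],
        representative=acc,
        pooled_peptides=entry.peptide_ids,
        pooled_intensities=dict(intensities),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
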