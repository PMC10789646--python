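"""Reading, writing and entry-level filtering of MaxQuant-style proteinGroups tables.

The dialect is the tab-separated ``proteinGroups.txt`` layout: one row per
protein group, semicolon-joined accession and peptide-ID lists, one
``iBAQ <sample_id>`` column per sample, and flag columns (``Potential
contaminant``, ``Reverse``, ``Only identified by site``) holding ``+`` or
empty.  MaxQuant encodes no experimental design, so the ±UV condition and
replicate structure is bound separately through a design table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

PLUS_UV = "plusUV"
MINUS_UV = "minusUV"
CONDITIONS = (PLUS_UV, MINUS_UV)

# canonical column headers of the dialect
COL_PROTEIN_IDS = "Protein IDs"
COL_GENE_NAMES = "Gene names"
COL_PEPTIDE_IDS = "Peptide IDs"
COL_CONTAMINANT = "Potential contaminant"
COL_REVERSE = "Reverse"
COL_ONLY_BY_SITE = "Only identified by site"
IBAQ_PREFIX = "iBAQ "


@dataclass(frozen=True)
class SampleDesign:
    """Binding of one MS run to its experimental condition.

    condition is ``plusUV`` (UV-irradiated, cross-linked) or ``minusUV``
    (control); replicate is a positive integer within the condition.
    """

    sample_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass
class ProteinEntry:
    """One protein-group row.

    ``protein_ids`` is an ordered accession list (first entry is the
    representative); ``intensities`` maps sample_id to iBAQ, with 0 meaning
    not detected.
    """

    protein_ids: list[str]
    gene_symbol: str
    peptide_ids: frozenset[str]
    intensities: dict[str, float]
    flag_contaminant: bool = False
    flag_reverse: bool = False
    flag_only_by_site: bool = False

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("protein_ids must be non-empty")
        for sid, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"negative iBAQ for sample {sid!r}")
        if not self.peptide_ids and not self.flag_reverse:
            raise ValueError("peptide_ids must be non-empty for non-decoy entries")

    @property
    def representative(self) -> str:
        return self.protein_ids[0]

    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))


RenameMap = Mapping[str, tuple[str, str]]


def check_design(design: Sequence[SampleDesign], require_replicates: bool = False) -> None:
    """Validate a sample design: unique ids; optionally ≥2 replicates per condition."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids in design are not unique")
    if require_replicates:
        for cond in CONDITIONS:
            n = sum(1 for d in design if d.condition == cond)
            if n < 2:
                raise ValueError(f"condition {cond} has {n} replicate(s); need >= 2")


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a design TSV with columns sample_id, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"design file {path} missing columns: {sorted(missing)}")
    design = [
        SampleDesign(str(r.sample_id), str(r.condition), int(r.replicate))
        for r in df.itertuples(index=False)
    ]
    check_design(design)
    return design


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "condition": [d.condition for d in design],
            "replicate": [d.replicate for d in design],
        }
    ).to_csv(path, sep="\t", index=False)


def _parse_flag(value: object) -> bool:
    if isinstance(value, str):
        return value.strip() == "+"
    return False


def read_protein_groups(path: str | Path, design: Sequence[SampleDesign]) -> list[ProteinEntry]:
    """Parse a proteinGroups-style TSV into entries, one per row.

    Column order is irrelevant; missing or empty iBAQ cells parse as 0.
    A designed sample without a matching ``iBAQ <sample_id>`` column is a
    fatal configuration error.
    """
    check_design(design)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if COL_PROTEIN_IDS not in df.columns:
        raise ValueError(f"{path}: missing required column {COL_PROTEIN_IDS!r}")
    ibaq_cols = {}
    for d in design:
        col = IBAQ_PREFIX + d.sample_id
        if col not in df.columns:
            raise ValueError(f"{path}: missing iBAQ column {col!r} for designed sample {d.sample_id!r}")
        ibaq_cols[d.sample_id] = col

    entries: list[ProteinEntry] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        intensities: dict[str, float] = {}
        for sid, col in ibaq_cols.items():
            cell = rowd[col].strip()
            if cell == "":
                intensities[sid] = 0.0
            else:
                try:
                    intensities[sid] = float(cell)
                except ValueError as exc:
                    raise ValueError(f"{path}: unparseable numeric cell at row {idx + 2}, column {col!r}: {cell!r}") from exc
        peptides = frozenset(p for p in rowd.get(COL_PEPTIDE_IDS, "").split(";") if p)
        entries.append(
            ProteinEntry(
                protein_ids=[p for p in rowd[COL_PROTEIN_IDS].split(";") if p],
                gene_symbol=rowd.get(COL_GENE_NAMES, "").strip(),
                peptide_ids=peptides,
                intensities=intensities,
                flag_contaminant=_parse_flag(rowd.get(COL_CONTAMINANT, "")),
                flag_reverse=_parse_flag(rowd.get(COL_REVERSE, "")),
                flag_only_by_site=_parse_flag(rowd.get(COL_ONLY_BY_SITE, "")),
            )
        )
    return entries


def write_protein_groups(
    entries: Iterable[ProteinEntry], path: str | Path, design: Sequence[SampleDesign]
) -> None:
    """Write entries back in the same dialect (full-precision intensities)."""
    rows = []
    for e in entries:
        row = {
            COL_PROTEIN_IDS: ";".join(e.protein_ids),
            COL_GENE_NAMES: e.gene_symbol,
            COL_PEPTIDE_IDS: ";".join(sorted(e.peptide_ids)),
            COL_CONTAMINANT: "+" if e.flag_contaminant else "",
            COL_REVERSE: "+" if e.flag_reverse else "",
            COL_ONLY_BY_SITE: "+" if e.flag_only_by_site else "",
        }
        for d in design:
            v = e.intensities.get(d.sample_id, 0.0)
            row[IBAQ_PREFIX + d.sample_id] = repr(v) if v else "0"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_rename(entries: Sequence[ProteinEntry], names: RenameMap) -> list[ProteinEntry]:
    """Replace representative accession and gene symbol where mapped.

    Unmapped entries pass through unchanged; order is preserved.  The lookup
    key is the current representative (first accession).
    """
    out: list[ProteinEntry] = []
    for e in entries:
        hit = names.get(e.representative)
        if hit is None:
            out.append(e)
        else:
            name, symbol = hit
            out.append(
                replace(e, protein_ids=[name] + e.protein_ids[1:], gene_symbol=symbol)
            )
    return out


def read_rename_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a rename TSV with columns accession, preferred_name, preferred_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"accession", "preferred_name", "preferred_symbol"}
    if not need <= set(df.columns):
        raise ValueError(f"rename map {path} must have columns {sorted(need)}")
    if df["accession"].duplicated().any():
        raise ValueError(f"rename map {path}: duplicate accession keys")
    return {
        r.accession: (r.preferred_name, r.preferred_symbol)
        for r in df.itertuples(index=False)
    }


def filter_entries(
    entries: Sequence[ProteinEntry],
) -> tuple[list[ProteinEntry], list[ProteinEntry]]:
    """Partition entries into (kept, removed).

    Contaminant- or decoy-flagged entries are removed; the
    only-identified-by-site flag alone does not remove an entry.  Order is
    preserved and the two lists partition the input.
    """
    kept, removed = [], []
    for e in entries:
        (removed if (e.flag_contaminant or e.flag_reverse) else kept).append(e)
    return kept, removed


def removal_reason(entry: ProteinEntry) -> str:
    # entries flagged both ways count once, under "reverse"
    if entry.flag_reverse:
        return "reverse"
    if entry.flag_contaminant:
        return "contaminant"
    return "kept"


def write_removal_log(removed: Sequence[ProteinEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "accession": [e.representative for e in removed],
            "reason": [removal_reason(e) for e in removed],
        }
    ).to_csv(path, sep="\t", index=False)
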