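"""End-to-end interactome pipeline: read → rename → filter → group → riBAQ →
classify → Venn/volcano, with a run manifest for provenance.

Configuration is a flat YAML mapping with optional sections; unknown keys
are rejected.  Outputs carry a comment header with the tool version and a
hash of the configuration, and contain no timestamps, so re-running with
the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import EnrichmentConfig, classify, compute_ribaq, records_to_table, venn_counts, volcano_table
from .grouping import GroupingConfig, group_proteins, groups_to_table
from .proteingroups import (
    apply_rename,
    filter_entries,
    read_design,
    read_protein_groups,
    read_rename_map,
    write_removal_log,
)

_KNOWN_KEYS = {
    "protein_groups",
    "design",
    "rename_map",
    "out_dir",
    "seed",
    "verbosity",
    "p_threshold",
    "fc_threshold",
    "share_threshold",
    "denominator_rule",
    "log_transform",
    "test",
    "bh_correction",
}


@dataclass
class PipelineConfig:
    protein_groups: str
    design: str
    out_dir: str = "xlquant_out"
    rename_map: str | None = None
    seed: int = 0
    verbosity: str = "INFO"
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    share_threshold: float = 0.30
    denominator_rule: str = "min_set"
    log_transform: bool = True
    test: str = "student"
    bh_correction: bool = False

    def enrichment_config(self) -> EnrichmentConfig:
        return EnrichmentConfig(
            p_threshold=self.p_threshold,
            fc_threshold=self.fc_threshold,
            log_transform=self.log_transform,
            test=self.test,
            bh_correction=self.bh_correction,
        )

    def grouping_config(self) -> GroupingConfig:
        return GroupingConfig(
            share_threshold=self.share_threshold,
            denominator_rule=self.denominator_rule,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return PipelineConfig(**raw)


def validate_config(raw: dict) -> list[str]:
    """Return a list of problems; empty iff the mapping is runnable."""
    problems = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown key {key!r}")
    for key in ("protein_groups", "design"):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    p = raw.get("p_threshold", 0.05)
    if not (0 < p < 1):
        problems.append("p_threshold out of (0,1)")
    fc = raw.get("fc_threshold", 2.0)
    if fc < 1:
        problems.append("fc_threshold below 1")
    share = raw.get("share_threshold", 0.30)
    if not (0 < share <= 1):
        problems.append("share_threshold out of (0,1]")
    if raw.get("denominator_rule", "min_set") not in ("min_set", "jaccard"):
        problems.append("denominator_rule must be min_set or jaccard")
    if raw.get("test", "welch") not in ("welch", "student"):
        problems.append("test must be welch or student")
    return problems


def _config_hash(cfg: PipelineConfig) -> str:
    # hash the analysis parameters only: file locations and log level do
    # not change results, so tables are byte-identical across destinations
    skip = ("protein_groups", "design", "rename_map", "out_dir", "verbosity")
    d = {k: v for k, v in asdict(cfg).items() if k not in skip}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_interactome(cfg: PipelineConfig) -> dict:
    """Execute the full proteomics chain and write all artifacts.

    Returns the run manifest (also written to ``manifest.json``): the config
    echo, stage counts and classification summary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"xlquant {__version__}", f"config_hash {_config_hash(cfg)}"]

    design = read_design(cfg.design)
    entries = read_protein_groups(cfg.protein_groups, design)
    if cfg.rename_map:
        entries = apply_rename(entries, read_rename_map(cfg.rename_map))
    kept, removed = filter_entries(entries)
    write_removal_log(removed, out / "removed_entries.tsv")

    groups = group_proteins(kept, cfg.grouping_config())
    sample_ids = [d.sample_id for d in design]
    _write_table(groups_to_table(groups, sample_ids), out / "groups.tsv", header)

    table = compute_ribaq(groups, design)
    records = classify(groups, table, cfg.enrichment_config())
    _write_table(records_to_table(records), out / "enrichment.tsv", header)
    _write_table(volcano_table(records), out / "volcano.tsv", header)

    venn = venn_counts(records)
    (out / "venn_counts.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")

    manifest = {
        "tool": "xlquant",
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "counts": {
            "entries_read": len(entries),
            "entries_removed": len(removed),
            "entries_kept": len(kept),
            "groups": len(groups),
            "groups_analyzed": int(table.values.shape[0]),
            **venn,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
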