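"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all pure functions of (config, seed):

* a proteomics table emulating a ±UV photo-cross-linking experiment —
  log-normal baseline abundances, condition-specific enrichment for spiked
  true interactors, logistic dropout on low abundance, contaminant/decoy
  entries and shared-peptide families — with per-protein truth labels;
* one-site ITC isotherms under the standard titration protocol with
  Gaussian heat noise (delegating to the forward model);
* peak sets with controlled pairwise co-occurrence via shared latent sites,
  plus bump-shaped signal tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coloc import GenomicInterval, PeakSet, SignalTrack
from .itc import Isotherm, ITCProtocol, OneSiteParams, simulate_isotherm
from .proteingroups import MINUS_UV, PLUS_UV, ProteinEntry, SampleDesign

BACKGROUND = "background"
TRUE_INTERACTOR = "true_interactor"
EXCLUSIVE_PLUS_CLASS = "exclusive_plus"
CONTAMINANT = "contaminant"
DECOY = "decoy"


@dataclass(frozen=True)
class ProteomicsSimConfig:
    """Study-scale defaults: ~800 background proteins, 50 spiked interactors
    at 8× enrichment, 40 +UV-exclusive proteins, two replicates per
    condition, 25% replicate CV."""

    n_background: int = 800
    n_true_interactors: int = 50
    n_exclusive_plus: int = 40
    n_contaminants: int = 20
    n_decoys: int = 10
    enrichment_factor: float = 8.0
    abundance_log_mean: float = 14.0   # natural-log iBAQ scale (~1.2e6 median)
    abundance_log_sd: float = 1.5
    noise_cv: float = 0.25
    dropout: bool = True
    dropout_midpoint: float = 10.5     # log-abundance of 50% dropout
    dropout_slope: float = 1.5
    peptides_per_protein: tuple[int, int] = (4, 20)
    shared_family_prob: float = 0.05
    shared_fraction: float = 0.5
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_true_interactors, self.n_exclusive_plus,
               self.n_contaminants, self.n_decoys) < 0:
            raise ValueError("counts must be non-negative")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass
class TruthLabels:
    labels: dict[str, str]          # accession -> class
    true_fold: dict[str, float]     # accession -> condition fold applied in +UV

    def of_class(self, cls: str) -> set[str]:
        return {acc for acc, c in self.labels.items() if c == cls}


def _make_design(n_replicates: int) -> list[SampleDesign]:
    design = []
    for r in range(1, n_replicates + 1):
        design.append(SampleDesign(f"p{r}", PLUS_UV, r))
    for r in range(1, n_replicates + 1):
        design.append(SampleDesign(f"m{r}", MINUS_UV, r))
    return design


def generate_proteomics(
    cfg: ProteomicsSimConfig,
) -> tuple[list[ProteinEntry], list[SampleDesign], TruthLabels]:
    """Generate a proteinGroups-style cohort with ground-truth classes.

    Baseline abundance a_p ~ LogNormal(μ, σ); observed
    iBAQ(p, s) = a_p · f(p, condition(s)) · LogNormal(0, σ_cv), where f is
    the enrichment factor for true interactors in +UV and 1 otherwise.
    Dropout zeroes a measurement with logistic probability decreasing in log
    abundance; +UV-exclusive proteins are forced to 0 in all −UV samples;
    contaminants and decoys carry the corresponding flags and are class-
    labelled.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg.n_replicates)
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))

    specs: list[tuple[str, str]] = []
    specs += [(f"BG{i:04d}", BACKGROUND) for i in range(cfg.n_background)]
    specs += [(f"TI{i:04d}", TRUE_INTERACTOR) for i in range(cfg.n_true_interactors)]
    specs += [(f"EX{i:04d}", EXCLUSIVE_PLUS_CLASS) for i in range(cfg.n_exclusive_plus)]
    specs += [(f"CON{i:04d}", CONTAMINANT) for i in range(cfg.n_contaminants)]
    specs += [(f"REV{i:04d}", DECOY) for i in range(cfg.n_decoys)]

    # peptide catalogues; sharing families pair consecutive background
    # proteins so that the designated pairs exceed the 30% grouping threshold
    lo, hi = cfg.peptides_per_protein
    peptide_sets: list[frozenset[str]] = []
    share_next: frozenset[str] | None = None
    for k, (acc, cls) in enumerate(specs):
        n_pep = int(rng.integers(lo, hi + 1))
        own = frozenset(f"{acc}_pep{j}" for j in range(n_pep))
        if share_next is not None:
            n_shared = max(int(math.ceil(cfg.shared_fraction * min(len(own), len(share_next)))), 1)
            own = frozenset(sorted(own)[: len(own) - n_shared]) | frozenset(sorted(share_next)[:n_shared])
            share_next = None
        elif cls == BACKGROUND and rng.random() < cfg.shared_family_prob:
            share_next = own
        peptide_sets.append(own)

    labels: dict[str, str] = {}
    fold: dict[str, float] = {}
    entries: list[ProteinEntry] = []
    for (acc, cls), peptides in zip(specs, peptide_sets):
        base = float(rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd))
        f_plus = cfg.enrichment_factor if cls in (TRUE_INTERACTOR, EXCLUSIVE_PLUS_CLASS) else 1.0
        intensities: dict[str, float] = {}
        for d in design:
            f = f_plus if d.condition == PLUS_UV else 1.0
            v = base * f * float(rng.lognormal(0.0, sigma))
            if cfg.dropout:
                p_drop = 1.0 / (1.0 + math.exp(cfg.dropout_slope * (math.log(max(v, 1e-300)) - cfg.dropout_midpoint)))
                if rng.random() < p_drop:
                    v = 0.0
            intensities[d.sample_id] = v
        if cls == EXCLUSIVE_PLUS_CLASS:
            for d in design:
                if d.condition == MINUS_UV:
                    intensities[d.sample_id] = 0.0
        entries.append(
            ProteinEntry(
                protein_ids=[acc],
                gene_symbol=acc,
                peptide_ids=peptides,
                intensities=intensities,
                flag_contaminant=(cls == CONTAMINANT),
                flag_reverse=(cls == DECOY),
                flag_only_by_site=False,
            )
        )
        labels[acc] = cls
        fold[acc] = f_plus
    return entries, design, TruthLabels(labels=labels, true_fold=fold)


def generate_itc(
    params: OneSiteParams,
    protocol: ITCProtocol | None = None,
    noise_sd_ucal: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Simulate an ITC experiment (thin wrapper over the forward model)."""
    return simulate_isotherm(params, protocol or ITCProtocol(), noise_sd_ucal, seed)


def generate_peak_sets(
    chrom_lengths: dict[str, int],
    n_latent_sites: int = 200,
    n_private_peaks: int = 20,
    peak_width: tuple[int, int] = (200, 500),
    co_occurrence: Sequence[float] = (1.0, 1.0, 1.0),
    set_names: Sequence[str] | None = None,
    signal_bin_size: int = 50,
    signal_height: float = 10.0,
    signal_noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[list[PeakSet], list[SignalTrack]]:
    """Peak sets with controlled co-occurrence, plus matching signal tracks.

    A latent site list is drawn uniformly over the genome; set *k* includes
    each latent site with probability ``co_occurrence[k]`` and adds
    ``n_private_peaks`` private peaks.  Tracks are sums of rectangular bumps
    of height ``signal_height`` at the set's peaks with Gaussian bin noise.
    Peaks that would exceed chromosome bounds are clipped.
    """
    if any(not (0 <= p <= 1) for p in co_occurrence):
        raise ValueError("co_occurrence probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(set_names) if set_names else [f"set{k + 1}" for k in range(len(co_occurrence))]
    if len(names) != len(co_occurrence):
        raise ValueError("set_names and co_occurrence lengths differ")
    chroms = sorted(chrom_lengths)
    total = sum(chrom_lengths.values())
    wlo, whi = peak_width

    def draw_peak() -> GenomicInterval:
        pos = int(rng.integers(0, total))
        for c in chroms:
            if pos < chrom_lengths[c]:
                width = int(rng.integers(wlo, whi + 1))
                start = max(0, min(pos, chrom_lengths[c] - 1))
                end = min(start + width, chrom_lengths[c])
                if end <= start:
                    start, end = max(0, end - 1), end  # clip to >= 1 bp
                return GenomicInterval(c, start, end)
            pos -= chrom_lengths[c]
        raise AssertionError("unreachable")

    latent = [draw_peak() for _ in range(n_latent_sites)]
    peak_sets: list[PeakSet] = []
    for name, p in zip(names, co_occurrence):
        include = rng.random(n_latent_sites) < p
        ivs = [latent[i] for i in range(n_latent_sites) if include[i]]
        ivs += [draw_peak() for _ in range(n_private_peaks)]
        peak_sets.append(PeakSet(name, ivs))

    tracks: list[SignalTrack] = []
    for ps in peak_sets:
        values = {c: np.zeros(-(-chrom_lengths[c] // signal_bin_size)) for c in chroms}
        for iv in ps.intervals:
            b0 = iv.start // signal_bin_size
            b1 = -(-iv.end // signal_bin_size)
            values[iv.chrom][b0:b1] += signal_height
        if signal_noise_sd > 0:
            for c in chroms:
                values[c] += rng.normal(0.0, signal_noise_sd, size=values[c].shape)
        tracks.append(SignalTrack(ps.name, signal_bin_size, dict(chrom_lengths), values))
    return peak_sets, tracks
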