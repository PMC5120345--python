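"""Seeded generator of synthetic market-survey datasets.

Produces a reference haplotype panel (two markers) with a controlled
intra-/inter-specific divergence structure, plus specimen tables (filament
lengths, categorical traits, prices, localities) and per-specimen query
sequences mutated from conspecific references. Every draw flows from a
single seed, so identical configs give byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .barcode_core import (
    ReferencePanel,
    SequenceRecord,
    UNKNOWN,
    decode,
    distance_matrix,
    encode,
    write_fasta,
)
from .morphology import GillSpecimen, write_specimen_csv
from .profiles import (
    LENGTH_PARAMS,
    MARKER_LENGTHS,
    PRICE_PARAMS,
    SPECIES_COUNTS,
    TRAIT_FREQS,
)

#: Sampling localities with rough market weights (majority-market city first).
CITIES = ("Guangzhou", "Zhanjiang", "Beihai", "Zhapo", "Shanwei")
CITY_WEIGHTS = (0.60, 0.15, 0.10, 0.05, 0.10)


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int
    n_specimens: int | None = None
    species_counts: Mapping[str, int] | None = None
    markers: Mapping[str, int] = field(default_factory=lambda: dict(MARKER_LENGTHS))
    intra_divergence: float = 0.006
    inter_divergence: tuple[float, float] = (0.04, 0.13)
    ts_tv_ratio: float = 2.0
    length_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LENGTH_PARAMS)
    )
    trait_freqs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {sp: dict(v) for sp, v in TRAIT_FREQS.items()}
    )
    price_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRICE_PARAMS)
    )
    dropout_rate: float = 0.16
    haplotypes_per_species: int = 3

    def __post_init__(self) -> None:
        if self.species_counts is None:
            if self.n_specimens is None:
                self.species_counts = dict(SPECIES_COUNTS)
            else:
                self.species_counts = _scale_counts(SPECIES_COUNTS, self.n_specimens)
        self.species_counts = dict(self.species_counts)
        if any(c < 0 for c in self.species_counts.values()):
            raise GeneratorError("species counts must be >= 0")
        self.n_specimens = sum(self.species_counts.values())
        if not (0.0 <= self.intra_divergence < 1.0):
            raise GeneratorError("intra_divergence must be in [0, 1)")
        lo, hi = self.inter_divergence
        if not (0.0 < lo <= hi < 1.0):
            raise GeneratorError("inter_divergence range must satisfy 0 < lo <= hi < 1")
        if lo <= self.intra_divergence:
            raise GeneratorError("inter_divergence must exceed intra_divergence")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise GeneratorError("dropout_rate must be in [0, 1]")
        if self.ts_tv_ratio < 0:
            raise GeneratorError("ts_tv_ratio must be >= 0 (or inf)")
        if self.haplotypes_per_species < 2:
            raise GeneratorError("need at least 2 haplotypes per species")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_counts)


def _scale_counts(base: Mapping[str, int], n: int) -> dict[str, int]:
    """Largest-remainder scaling of the default species mix to n specimens."""
    total = sum(base.values())
    raw = {sp: n * c / total for sp, c in base.items()}
    out = {sp: int(math.floor(v)) for sp, v in raw.items()}
    short = n - sum(out.values())
    for sp in sorted(raw, key=lambda s: raw[s] - out[s], reverse=True)[:short]:
        out[sp] += 1
    return out


def _mutate(codes: np.ndarray, sites: np.ndarray, rng: np.random.Generator, ts_tv: float) -> np.ndarray:
    """Substitute bases at the given sites; transition prob = k/(k+1)."""
    out = codes.copy()
    if len(sites) == 0:
        return out
    p_ts = 1.0 if math.isinf(ts_tv) else ts_tv / (ts_tv + 1.0)
    is_ts = rng.random(len(sites)) < p_ts
    for site, ts in zip(sites, is_ts):
        base = out[site]
        if ts:
            out[site] = base ^ 1  # A<->G (0/1), C<->T (2/3)
        else:
            choices = (2, 3) if base < 2 else (0, 1)
            out[site] = choices[rng.integers(0, 2)]
    return out


def generate_reference_sequences(cfg: GeneratorConfig) -> ReferencePanel:
    """Reference haplotype panel with controlled divergence structure.

    Per marker: one random ancestral sequence; each species consensus is the
    ancestor mutated at its own disjoint block of random sites, sized so the
    pairwise raw divergences land inside the configured inter-species range;
    haplotypes are the consensus plus copies carrying up to
    ``intra_divergence x length`` further substitutions. Realised pairwise
    K2P distances between consensus sequences are verified within +-25% of
    their design targets.
    """
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species
    k = len(species)
    lo, hi = cfg.inter_divergence
    offsets = np.linspace(lo / 2.0, hi / 2.0, k) if k > 1 else np.array([lo / 2.0])
    records: list[SequenceRecord] = []
    for marker, L in cfg.markers.items():
        site_counts = [int(round(e * L)) for e in offsets]
        if sum(site_counts) > L:
            raise GeneratorError(
                f"unattainable divergence targets for {marker} length {L}"
            )
        anc = rng.integers(0, 4, size=L).astype(np.uint8)
        perm = rng.permutation(L)
        consensus: dict[str, np.ndarray] = {}
        pos = 0
        for sp, n_sites in zip(species, site_counts):
            sites = perm[pos : pos + n_sites]
            pos += n_sites
            consensus[sp] = _mutate(anc, sites, rng, cfg.ts_tv_ratio)
        m_intra = int(cfg.intra_divergence * L)
        for sp in species:
            for h in range(cfg.haplotypes_per_species):
                if h == 0 or m_intra == 0:
                    seq = consensus[sp]
                else:
                    n_mut = int(rng.integers(1, m_intra + 1))
                    sites = rng.choice(L, size=n_mut, replace=False)
                    seq = _mutate(consensus[sp], sites, rng, cfg.ts_tv_ratio)
                records.append(
                    SequenceRecord(f"ref_{sp}_h{h}_{marker}", marker, sp, decode(seq))
                )
        if k > 1:
            _verify_inter_distances(consensus, species, offsets, marker)
    return ReferencePanel(records)


def _verify_inter_distances(consensus, species, offsets, marker) -> None:
    recs = [
        SequenceRecord(f"__cons_{sp}", marker, sp, decode(consensus[sp]))
        for sp in species
    ]
    dm = distance_matrix(recs)
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            target = offsets[i] + offsets[j]
            realized = dm.d[i, j]
            if not (0.75 * target <= realized <= 1.25 * target):
                raise GeneratorError(
                    f"realized {marker} divergence {species[i]}-{species[j]} "
                    f"({realized:.4f}) outside +-25% of target {target:.4f}"
                )


@dataclass
class SpecimenSet:
    specimens: list[GillSpecimen]
    sequences: dict[str, list[SequenceRecord]]  # marker -> query records
    truth: dict[str, str]  # specimen id -> true species

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write specimen CSV, per-marker query FASTA and the truth table."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        csv_path = out_dir / "specimens.csv"
        write_specimen_csv(self.specimens, csv_path)
        paths["specimens"] = csv_path
        for marker, recs in self.sequences.items():
            p = out_dir / f"queries_{marker}.fasta"
            write_fasta(recs, p)
            paths[f"queries_{marker}"] = p
        truth_path = out_dir / "truth.csv"
        pd.DataFrame(
            sorted(self.truth.items()), columns=["id", "true_species"]
        ).to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


def _truncated_normal(rng, mu, sd, lower, size=None):
    a = (lower - mu) / sd
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def generate_specimen_set(
    cfg: GeneratorConfig, panel: ReferencePanel | None = None
) -> SpecimenSet:
    """Synthetic market specimens with traits, prices and query sequences.

    Species are assigned exactly per ``species_counts`` (order shuffled);
    filament plate means are truncated normals (lower bound 2 mm) with 5
    per-plate measurement points jittered at 5% of the plate mean; traits are
    drawn independently from the per-species frequency rows; prices are
    truncated normals (lower bound 10 US$). A ``dropout_rate`` fraction of
    specimens carries no sequence; the rest get one query sequence per marker,
    mutated from a random conspecific reference haplotype.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    from .morphology import CATEGORICAL_TRAITS

    norm_freqs: dict[str, dict[str, dict[str, float]]] = {}
    for sp in cfg.species:
        if sp not in cfg.trait_freqs or sp not in cfg.length_params:
            raise GeneratorError(f"species {sp!r} missing from trait/length tables")
        norm_freqs[sp] = {}
        for trait, levels in CATEGORICAL_TRAITS.items():
            row = cfg.trait_freqs[sp][trait]
            total = sum(row[l] for l in levels)
            if total <= 0:
                raise GeneratorError(f"{sp}/{trait}: frequencies sum to 0")
            norm_freqs[sp][trait] = {l: row[l] / total for l in levels}

    species_seq: list[str] = []
    for sp in cfg.species:
        species_seq.extend([sp] * cfg.species_counts[sp])
    order = rng.permutation(len(species_seq))
    species_seq = [species_seq[i] for i in order]
    n = len(species_seq)

    specimens: list[GillSpecimen] = []
    truth: dict[str, str] = {}
    n_drop = int(round(cfg.dropout_rate * n))
    drop_idx = set(rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()
    if panel is None:
        drop_idx = set(range(n))

    ref_by_species: dict[str, dict[str, list[SequenceRecord]]] = {}
    if panel is not None:
        for marker in cfg.markers:
            for rec in panel.records(marker):
                ref_by_species.setdefault(rec.species_label, {}).setdefault(
                    marker, []
                ).append(rec)

    sequences: dict[str, list[SequenceRecord]] = {m: [] for m in cfg.markers}
    width = max(4, len(str(n)))
    for idx, sp in enumerate(species_seq):
        sid = f"GR{idx + 1:0{width}d}"
        truth[sid] = sp
        mu, sd = cfg.length_params[sp]
        plate_mean = float(_truncated_normal(rng, mu, sd, lower=2.0))
        points = plate_mean + rng.normal(0.0, 0.05 * plate_mean, size=5)
        while np.any(points <= 0):  # ~20 sigma event; guards invariant
            bad = points <= 0
            points[bad] = plate_mean + rng.normal(0.0, 0.05 * plate_mean, size=int(bad.sum()))
        traits = {
            trait: str(
                rng.choice(list(levels), p=[norm_freqs[sp][trait][l] for l in levels])
            )
            for trait, levels in CATEGORICAL_TRAITS.items()
        }
        pmu, psd = cfg.price_params[sp]
        price = float(_truncated_normal(rng, pmu, psd, lower=10.0))
        city = str(rng.choice(CITIES, p=CITY_WEIGHTS))
        seq_ids: dict[str, str] = {}
        if idx not in drop_idx and panel is not None:
            for marker, L in cfg.markers.items():
                haps = ref_by_species.get(sp, {}).get(marker)
                if not haps:
                    raise GeneratorError(f"panel lacks {marker} references for {sp!r}")
                ref = haps[rng.integers(0, len(haps))]
                codes = encode(ref.residues)
                m_intra = int(cfg.intra_divergence * L)
                n_mut = int(rng.integers(0, m_intra + 1)) if m_intra else 0
                if n_mut:
                    sites = rng.choice(L, size=n_mut, replace=False)
                    codes = _mutate(codes, sites, rng, cfg.ts_tv_ratio)
                sequences[marker].append(
                    SequenceRecord(sid, marker, UNKNOWN, decode(codes))
                )
                seq_ids[marker] = sid
        specimens.append(
            GillSpecimen(
                id=sid,
                filament_points=tuple(round(p, 3) for p in points),
                price=round(price, 2),
                city=city,
                true_species=sp,
                sequence_ids=seq_ids,
                **traits,
            )
        )
    return SpecimenSet(specimens=specimens, sequences=sequences, truth=truth)


def generate_dataset(cfg: GeneratorConfig) -> tuple[ReferencePanel, SpecimenSet]:
    """Convenience wrapper: reference panel plus a matching specimen set."""
    panel = generate_reference_sequences(cfg)
    return panel, generate_specimen_set(cfg, panel)
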