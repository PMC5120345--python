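"""Market composition and price summaries, plus end-to-end orchestration.

Composition percentages and the count-weighted mean price mirror the
market-survey bookkeeping; ``run_pipeline`` wires the molecular channel
(identity assignment + cluster cross-check) and the morphological channel
(three-step rule + trait Bayes) into one per-specimen report.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .barcode_core import (
    BarcodeError,
    ReferencePanel,
    SequenceRecord,
    UNKNOWN,
    distance_matrix,
    read_fasta,
)
from .morphology import (
    GillSpecimen,
    TraitProfileTable,
    mean_filament_length,
    read_specimen_csv,
    size_screen,
    three_step_classify,
    trait_bayes_classify,
)
from .profiles import default_profile_table
from .tree_cluster import (
    GapSummary,
    TreeError,
    UNASSIGNED,
    assign_by_identity,
    barcoding_gap,
    bootstrap_support,
    extract_clusters,
)

REPORT_SCHEMA_VERSION = "1.0"
NO_SEQUENCE = "NO_SEQUENCE"


class MarketError(ValueError):
    pass


def composition_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of the identified total per species, to 1 decimal."""
    if any(c < 0 for c in counts.values()):
        raise MarketError("counts must be >= 0")
    total = sum(counts.values())
    if total == 0:
        raise MarketError("total count is zero")
    return {sp: round(100.0 * c / total, 1) for sp, c in counts.items()}


def weighted_mean_price(per_species: Mapping[str, tuple[int, float]]) -> float:
    """Count-weighted mean of per-species mean prices (US$/kg)."""
    if not per_species:
        raise MarketError("empty per-species price map")
    num = 0.0
    den = 0
    for sp, (count, mean_price) in per_species.items():
        if count <= 0:
            raise MarketError(f"{sp}: count must be > 0")
        if mean_price <= 0:
            raise MarketError(f"{sp}: mean price must be > 0")
        num += count * mean_price
        den += count
    return num / den


def length_price_fit(specimens: Sequence[GillSpecimen]) -> tuple[float, float]:
    """OLS fit of price on mean filament length; returns (slope, intercept)."""
    pts = [
        (mean_filament_length(s), s.price)
        for s in specimens
        if s.price is not None
    ]
    if len(pts) < 3:
        raise MarketError("need >= 3 specimens with both price and length")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise MarketError("zero length variance; fit undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass(frozen=True)
class MarketSummary:
    per_species: Mapping[str, dict]  # count, percentage, mean_price, sd_price
    overall_weighted_mean_price: float
    overall_pooled_sd: float
    per_city_mean_price: Mapping[str, float]
    n_identified: int

    def to_dict(self) -> dict:
        return {
            "per_species": {sp: dict(v) for sp, v in self.per_species.items()},
            "overall_weighted_mean_price": self.overall_weighted_mean_price,
            "overall_pooled_sd": self.overall_pooled_sd,
            "per_city_mean_price": dict(self.per_city_mean_price),
            "n_identified": self.n_identified,
        }


def summarise_market(
    calls: Mapping[str, str], specimens: Sequence[GillSpecimen]
) -> MarketSummary:
    """Market summary from per-specimen species calls and price data.

    Specimens whose call is a species name (not UNASSIGNED/UNRESOLVED/
    NO_SEQUENCE sentinels) count as identified.
    """
    sentinels = {UNASSIGNED, NO_SEQUENCE, UNKNOWN, "UNRESOLVED"}
    by_species: dict[str, list[GillSpecimen]] = {}
    for s in specimens:
        call = calls.get(s.id)
        if call and call not in sentinels:
            by_species.setdefault(call, []).append(s)
    if not by_species:
        raise MarketError("no identified specimens to summarise")
    counts = {sp: len(v) for sp, v in by_species.items()}
    pcts = composition_percentages(counts)
    per_species: dict[str, dict] = {}
    weighted: dict[str, tuple[int, float]] = {}
    for sp, group in sorted(by_species.items()):
        prices = [s.price for s in group if s.price is not None]
        mean_p = float(np.mean(prices)) if prices else float("nan")
        sd_p = float(np.std(prices, ddof=1)) if len(prices) > 1 else 0.0
        per_species[sp] = {
            "count": counts[sp],
            "percentage": pcts[sp],
            "mean_price": mean_p,
            "sd_price": sd_p,
        }
        if prices:
            weighted[sp] = (len(prices), mean_p)
    overall = weighted_mean_price(weighted) if weighted else float("nan")
    # pooled sd across species groups around the weighted mean
    num = 0.0
    den = 0
    for sp, (c, m) in weighted.items():
        sd = per_species[sp]["sd_price"]
        num += c * (sd**2 + (m - overall) ** 2)
        den += c
    pooled = math.sqrt(num / den) if den else float("nan")
    city_prices: dict[str, list[float]] = {}
    for s in specimens:
        if s.city and s.price is not None:
            city_prices.setdefault(s.city, []).append(s.price)
    per_city = {c: float(np.mean(v)) for c, v in sorted(city_prices.items())}
    return MarketSummary(
        per_species=per_species,
        overall_weighted_mean_price=overall,
        overall_pooled_sd=pooled,
        per_city_mean_price=per_city,
        n_identified=sum(counts.values()),
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    min_identity: float = 0.99
    min_support: float = 99.0
    bootstrap_replicates: int = 100
    smoothing: float = 0.5
    profile: TraitProfileTable | None = None


@dataclass
class SpecimenCall:
    id: str
    molecular_call: str
    molecular_identity: float | None
    cluster_call: str | None
    three_step_call: str
    three_step_low_confidence: bool
    bayes_call: str
    bayes_posterior: Mapping[str, float]
    size_flag: str
    final_call: str
    final_channel: str  # "molecular" | "morphological"
    low_confidence: bool
    agreement: bool | None  # molecular vs cluster cross-check
    complex_caveat: bool = False
    errors: tuple[str, ...] = ()


@dataclass
class IdentificationReport:
    calls: list[SpecimenCall]
    market: MarketSummary
    gaps: Mapping[str, GapSummary]
    trees: Mapping[str, str]  # marker -> newick with supports
    clusters: Mapping[str, list]
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "n_specimens": len(self.calls),
            "calls": [
                {
                    "id": c.id,
                    "molecular_call": c.molecular_call,
                    "molecular_identity": c.molecular_identity,
                    "cluster_call": c.cluster_call,
                    "three_step_call": c.three_step_call,
                    "three_step_low_confidence": c.three_step_low_confidence,
                    "bayes_call": c.bayes_call,
                    "bayes_posterior": dict(c.bayes_posterior),
                    "size_flag": c.size_flag,
                    "final_call": c.final_call,
                    "final_channel": c.final_channel,
                    "low_confidence": c.low_confidence,
                    "agreement": c.agreement,
                    "complex_caveat": c.complex_caveat,
                    "errors": list(c.errors),
                }
                for c in self.calls
            ],
            "market": self.market.to_dict(),
            "gaps": {
                m: {
                    "intra_min": g.intra_min,
                    "intra_max": g.intra_max,
                    "inter_min": g.inter_min,
                    "inter_max": g.inter_max,
                }
                for m, g in self.gaps.items()
            },
            "trees": dict(self.trees),
            "clusters": {
                m: [
                    {
                        "cluster_id": c.cluster_id,
                        "species_call": c.species_call,
                        "support": c.support,
                        "n_members": len(c.members),
                    }
                    for c in cl
                ]
                for m, cl in self.clusters.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_pipeline(
    specimens: Sequence[GillSpecimen] | str | Path,
    query_seqs: Mapping[str, Sequence[SequenceRecord] | str | Path],
    panel: ReferencePanel,
    config: PipelineConfig | None = None,
) -> IdentificationReport:
    """Molecular + morphological identification of a specimen batch.

    Molecular calls come from best-identity assignment, cross-checked against
    monophyletic clusters on the bootstrap-annotated NJ tree of the first
    marker. The final call is the molecular one when available; otherwise the
    Bayes morphological call, flagged low-confidence. Per-specimen failures
    are recorded on the call rather than aborting the run.
    """
    cfg = config or PipelineConfig()
    profile = cfg.profile or default_profile_table()
    if isinstance(specimens, (str, Path)):
        specimens = read_specimen_csv(specimens)
    specimens = list(specimens)
    if not specimens:
        raise MarketError("no specimens supplied")
    seqs: dict[str, list[SequenceRecord]] = {}
    for marker, src in query_seqs.items():
        seqs[marker] = (
            read_fasta(src, marker) if isinstance(src, (str, Path)) else list(src)
        )

    # molecular channel: per-marker identity assignment
    identity_calls: dict[str, dict[str, object]] = {}
    for marker, records in seqs.items():
        for rec in records:
            entry = identity_calls.setdefault(
                rec.id, {"species": UNASSIGNED, "identity": None, "caveat": False}
            )
            try:
                res = assign_by_identity(rec, panel, cfg.min_identity)
            except BarcodeError as exc:
                entry.setdefault("errors", []).append(f"{marker}: {exc}")  # type: ignore[attr-defined]
                continue
            if res.species != UNASSIGNED and entry["species"] == UNASSIGNED:
                entry["species"] = res.species
                entry["identity"] = res.identity
                entry["caveat"] = res.complex_caveat
            elif entry["identity"] is None:
                entry["identity"] = res.identity

    # tree channel + gap summaries, one per marker with enough sequences
    trees: dict[str, str] = {}
    gaps: dict[str, GapSummary] = {}
    clusters_by_marker: dict[str, list] = {}
    cluster_call: dict[str, str] = {}
    for marker, records in seqs.items():
        try:
            panel_records = panel.records(marker)
        except BarcodeError:
            continue
        combined = panel_records + records
        if len(combined) < 3:
            continue
        try:
            tree = bootstrap_support(
                combined, replicates=cfg.bootstrap_replicates, seed=cfg.seed
            )
            clusters = extract_clusters(tree, panel, cfg.min_support)
        except (BarcodeError, TreeError):
            continue
        trees[marker] = tree.to_newick()
        clusters_by_marker[marker] = clusters
        if marker == next(iter(seqs)):  # first marker drives the cluster cross-check
            for cl in clusters:
                for member in cl.members:
                    if member not in panel.species_map():
                        cluster_call[member] = cl.species_call
        labels = dict(panel.species_map())
        for rec in records:
            call = identity_calls.get(rec.id, {}).get("species", UNASSIGNED)
            if call not in (UNASSIGNED,):
                labels[rec.id] = str(call)
        try:
            gaps[marker] = barcoding_gap(distance_matrix(combined), labels)
        except (BarcodeError, TreeError):
            pass

    calls: list[SpecimenCall] = []
    final_by_id: dict[str, str] = {}
    for s in specimens:
        errors: list[str] = []
        mol_entry = identity_calls.get(s.id)
        if mol_entry is None:
            mol_call, mol_ident, caveat = NO_SEQUENCE, None, False
        else:
            mol_call = str(mol_entry["species"])
            mol_ident = mol_entry["identity"]  # type: ignore[assignment]
            caveat = bool(mol_entry["caveat"])
            errors.extend(mol_entry.get("errors", []))  # type: ignore[arg-type]
        cl_call = cluster_call.get(s.id)
        try:
            step = three_step_classify(s)
            posterior = trait_bayes_classify(s, profile, cfg.smoothing)
            bayes_call = max(posterior, key=posterior.get)
            flag = size_screen(mean_filament_length(s))
        except Exception as exc:  # morphology should not abort the batch
            errors.append(str(exc))
            step = None
            posterior = {}
            bayes_call = UNKNOWN
            flag = "NOT_FLAGGED"
        if mol_call not in (UNASSIGNED, NO_SEQUENCE):
            final, channel, low_conf = mol_call, "molecular", False
        else:
            final, channel, low_conf = bayes_call, "morphological", True
        agreement = None
        if cl_call is not None and mol_call not in (UNASSIGNED, NO_SEQUENCE):
            agreement = cl_call == mol_call
        calls.append(
            SpecimenCall(
                id=s.id,
                molecular_call=mol_call,
                molecular_identity=mol_ident,
                cluster_call=cl_call,
                three_step_call=step.call if step else UNKNOWN,
                three_step_low_confidence=step.low_confidence if step else True,
                bayes_call=bayes_call,
                bayes_posterior=posterior,
                size_flag=flag,
                final_call=final,
                final_channel=channel,
                low_confidence=low_conf,
                agreement=agreement,
                complex_caveat=caveat,
                errors=tuple(errors),
            )
        )
        final_by_id[s.id] = final
    market = summarise_market(final_by_id, specimens)
    return IdentificationReport(
        calls=calls,
        market=market,
        gaps=gaps,
        trees=trees,
        clusters=clusters_by_marker,
    )
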