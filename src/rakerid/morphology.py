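"""Trait coding and classification of dried gill-raker plates.

Three classification routes over the same five features (mean filament
length plus four categorical traits):

* ``three_step_classify`` — the frontline enforcement decision rule
  (fused terminal lobes -> variegated screen -> finger-like projections).
* ``trait_bayes_classify`` — a transparent naive-Bayes counterpart driven
  directly by the per-species trait frequency table.
* ``ensemble_classify`` — a random-forest classifier with out-of-bag error
  estimation and per-feature variable importance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier

MA_BIROSTRIS = "Manta_birostris"
MO_JAPANICA = "Mobula_japanica"
MO_TARAPACANA = "Mobula_tarapacana"
MO_KUHLII = "Mobula_kuhlii"
MO_THURSTONI = "Mobula_thurstoni"
SPECIES = (MO_JAPANICA, MO_KUHLII, MO_TARAPACANA, MO_THURSTONI, MA_BIROSTRIS)

ARRANGEMENTS = ("loose", "general", "tight")
COLORS = ("light_end", "light_base", "whole_light", "whole_dark")
MIDDLE_LOBES = ("finger_like", "veins", "oval", "cilia", "none_obvious")
TERMINAL_LOBES = ("large_fused", "oval", "sharp_apex")

CATEGORICAL_TRAITS = {
    "arrangement": ARRANGEMENTS,
    "color": COLORS,
    "middle_lobe": MIDDLE_LOBES,
    "terminal_lobe": TERMINAL_LOBES,
}
FEATURES = ("filament_length", "arrangement", "color", "middle_lobe", "terminal_lobe")

# three-step outcomes
MANTA = "MANTA"
MOBULA_TARAPACANA = "MOBULA_TARAPACANA"
OTHER_MOBULA = "OTHER_MOBULA"

# size screen outcomes
MANTA_LIKELY = "MANTA_LIKELY"
NOT_FLAGGED = "NOT_FLAGGED"


class MorphologyError(ValueError):
    pass


@dataclass(frozen=True)
class GillSpecimen:
    """One dried gill-raker plate with 5 filament-length points and 4 traits."""

    id: str
    filament_points: tuple[float, float, float, float, float]
    arrangement: str
    color: str
    middle_lobe: str
    terminal_lobe: str
    price: float | None = None
    city: str | None = None
    true_species: str | None = None
    sequence_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.filament_points) != 5:
            raise MorphologyError(f"specimen {self.id!r}: need exactly 5 filament points")
        if any(p <= 0 for p in self.filament_points):
            raise MorphologyError(f"specimen {self.id!r}: filament points must be > 0")
        for trait, allowed in CATEGORICAL_TRAITS.items():
            val = getattr(self, trait)
            if val not in allowed:
                raise MorphologyError(
                    f"specimen {self.id!r}: {trait}={val!r} not in {allowed}"
                )


def mean_filament_length(s: GillSpecimen) -> float:
    """Arithmetic mean of the five filament-length points (mm)."""
    return float(sum(s.filament_points) / 5.0)


def size_screen(length_mm: float) -> str:
    """Flag plates whose filaments exceed 70 mm (strictly) as likely Manta."""
    if length_mm <= 0:
        raise MorphologyError("length must be > 0")
    return MANTA_LIKELY if length_mm > 70.0 else NOT_FLAGGED


@dataclass(frozen=True)
class ThreeStepResult:
    call: str
    low_confidence: bool = False


def three_step_classify(s: GillSpecimen) -> ThreeStepResult:
    """Three-step enforcement rule; total over the whole trait space.

    1. Terminal lobes not enlarged-and-fused -> OTHER_MOBULA.
    2. Variegated plates (light-base colour with visible cilia) ->
       MOBULA_TARAPACANA.
    3. Finger-like projections -> MANTA. Plates with no visible projection
       structure still get a class, flagged low-confidence: uniformly
       coloured ones lean MANTA, the rest lean MOBULA_TARAPACANA.
    """
    if s.terminal_lobe != "large_fused":
        return ThreeStepResult(OTHER_MOBULA)
    if s.color == "light_base" and s.middle_lobe == "cilia":
        return ThreeStepResult(MOBULA_TARAPACANA)
    if s.middle_lobe == "finger_like":
        return ThreeStepResult(MANTA)
    if s.color in ("whole_light", "whole_dark") and s.middle_lobe == "none_obvious":
        return ThreeStepResult(MANTA, low_confidence=True)
    return ThreeStepResult(MOBULA_TARAPACANA, low_confidence=True)


@dataclass(frozen=True)
class SpeciesProfile:
    length_mean: float
    length_sd: float
    trait_freqs: Mapping[str, Mapping[str, float]]
    prior_count: float


class TraitProfileTable:
    """Per-species length parameters, trait frequencies and prior counts.

    Raw frequency rows may under-sum (published tables are rounded and
    sometimes truncated); rows are renormalised on construction, preserving
    zeros. Rows summing outside [0.8, 1.01] are rejected.
    """

    def __init__(self, profiles: Mapping[str, SpeciesProfile]):
        if not profiles:
            raise MorphologyError("profile table is empty")
        normed: dict[str, SpeciesProfile] = {}
        for sp, prof in profiles.items():
            if prof.prior_count <= 0:
                raise MorphologyError(f"{sp}: prior count must be > 0")
            if prof.length_sd <= 0 or prof.length_mean <= 0:
                raise MorphologyError(f"{sp}: length parameters must be > 0")
            freqs: dict[str, dict[str, float]] = {}
            for trait, levels in CATEGORICAL_TRAITS.items():
                row = dict(prof.trait_freqs[trait])
                missing = set(levels) - set(row)
                if missing:
                    raise MorphologyError(f"{sp}/{trait}: missing levels {sorted(missing)}")
                total = sum(row[l] for l in levels)
                if not (0.8 <= total <= 1.01):
                    raise MorphologyError(
                        f"{sp}/{trait}: frequencies sum to {total:.3f}, outside [0.8, 1.01]"
                    )
                freqs[trait] = {l: row[l] / total for l in levels}
            normed[sp] = SpeciesProfile(prof.length_mean, prof.length_sd, freqs, prof.prior_count)
        self._profiles = normed

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._profiles)

    def __getitem__(self, sp: str) -> SpeciesProfile:
        return self._profiles[sp]

    def priors(self) -> dict[str, float]:
        total = sum(p.prior_count for p in self._profiles.values())
        return {sp: p.prior_count / total for sp, p in self._profiles.items()}


def trait_posterior(
    profile: TraitProfileTable,
    *,
    length: float | None = None,
    arrangement: str | None = None,
    color: str | None = None,
    middle_lobe: str | None = None,
    terminal_lobe: str | None = None,
    smoothing: float = 0.5,
) -> dict[str, float]:
    """Posterior over species from whatever evidence is supplied.

    Posterior ∝ prior × Π smoothed categorical likelihoods × Gaussian
    length density. Smoothing is an additive pseudo-count applied against
    the per-species prior count, so zero table frequencies stay decisive
    only when smoothing is 0.
    """
    if smoothing < 0:
        raise MorphologyError("smoothing pseudo-count must be >= 0")
    observed = {
        "arrangement": arrangement,
        "color": color,
        "middle_lobe": middle_lobe,
        "terminal_lobe": terminal_lobe,
    }
    log_post: dict[str, float] = {}
    priors = profile.priors()
    for sp in profile.species:
        prof = profile[sp]
        lp = math.log(priors[sp])
        for trait, value in observed.items():
            if value is None:
                continue
            levels = CATEGORICAL_TRAITS[trait]
            if value not in levels:
                raise MorphologyError(f"{trait}={value!r} not in {levels}")
            f = prof.trait_freqs[trait][value]
            n = prof.prior_count
            p = (f * n + smoothing) / (n + smoothing * len(levels))
            if p == 0.0:
                lp = -math.inf
                break
            lp += math.log(p)
        if length is not None and math.isfinite(lp):
            lp += norm.logpdf(length, loc=prof.length_mean, scale=prof.length_sd)
        log_post[sp] = lp
    mx = max(log_post.values())
    if mx == -math.inf:
        raise MorphologyError("all species have zero likelihood for this evidence")
    weights = {sp: math.exp(lp - mx) for sp, lp in log_post.items()}
    z = sum(weights.values())
    return {sp: w / z for sp, w in weights.items()}


def trait_bayes_classify(
    s: GillSpecimen, profile: TraitProfileTable, smoothing: float = 0.5
) -> dict[str, float]:
    """Posterior over species for a fully coded specimen."""
    return trait_posterior(
        profile,
        length=mean_filament_length(s),
        arrangement=s.arrangement,
        color=s.color,
        middle_lobe=s.middle_lobe,
        terminal_lobe=s.terminal_lobe,
        smoothing=smoothing,
    )


@dataclass(frozen=True)
class ClassificationReport:
    species: tuple[str, ...]
    per_species_error: Mapping[str, float]
    total_error: float
    confusion: pd.DataFrame
    per_feature_error: Mapping[str, float]
    variable_importance: Mapping[str, float]
    importance_ranking: tuple[tuple[str, ...], ...]
    n_trees: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "per_species_error": dict(self.per_species_error),
            "total_error": self.total_error,
            "confusion": {
                sp: {c: int(v) for c, v in row.items()}
                for sp, row in self.confusion.to_dict(orient="index").items()
            },
            "per_feature_error": dict(self.per_feature_error),
            "variable_importance": dict(self.variable_importance),
            "importance_ranking": [list(g) for g in self.importance_ranking],
            "n_trees": self.n_trees,
            "seed": self.seed,
        }


def _one_hot(specimens: Sequence[GillSpecimen], features: Sequence[str]):
    """Design matrix with one-hot categoricals; returns (X, column feature map)."""
    cols: list[np.ndarray] = []
    owner: list[str] = []
    for feat in features:
        if feat == "filament_length":
            cols.append(np.array([mean_filament_length(s) for s in specimens], float))
            owner.append(feat)
        else:
            levels = CATEGORICAL_TRAITS[feat]
            vals = [getattr(s, feat) for s in specimens]
            for lev in levels:
                cols.append(np.array([1.0 if v == lev else 0.0 for v in vals]))
                owner.append(feat)
    return np.column_stack(cols), owner


def _rank_with_ties(importance: Mapping[str, float], tol: float = 1e-12):
    items = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[tuple[str, ...]] = []
    current: list[str] = []
    last: float | None = None
    for name, val in items:
        if last is None or abs(val - last) <= tol:
            current.append(name)
        else:
            groups.append(tuple(current))
            current = [name]
        last = val
    if current:
        groups.append(tuple(current))
    return tuple(groups)


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int):
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # few-OOB warnings on tiny forests
        clf.fit(X, y)
    votes = clf.oob_decision_function_
    voted = ~np.isnan(votes).any(axis=1) & (votes.sum(axis=1) > 0)
    pred = np.array(clf.classes_)[
        np.argmax(np.where(np.isnan(votes), -1.0, votes), axis=1)
    ]
    return pred, voted


def ensemble_classify(
    train: Sequence[GillSpecimen],
    features: Sequence[str] = FEATURES,
    n_trees: int = 1000,
    seed: int = 0,
) -> ClassificationReport:
    """Random-forest classification with out-of-bag (OOB) error estimation.

    Categorical traits are one-hot encoded. Per-species and total errors are
    OOB errors of the all-features forest; samples never out of bag
    (possible for very small forests) are excluded from the error tallies.

    Variable usefulness is measured the way the per-characteristic error
    rates of the survey table behave: each feature's standalone OOB
    classification error (a forest trained on that feature alone). Lower
    standalone error = more useful; ``variable_importance`` stores the
    complementary standalone accuracy so that higher = more important.
    """
    if n_trees < 1:
        raise MorphologyError("n_trees must be >= 1")
    labels = [s.true_species for s in train]
    if any(l is None for l in labels):
        raise MorphologyError("all training specimens need true_species")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise MorphologyError("need at least 2 species in the training data")
    y = np.array(labels)
    X, owner = _one_hot(train, features)
    pred, voted = _fit_forest(X, y, n_trees, seed)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for truth, p, ok in zip(y, pred, voted):
        if ok:
            confusion.loc[truth, p] += 1
    per_err: dict[str, float] = {}
    for sp in classes:
        n_sp = int(confusion.loc[sp].sum())
        per_err[sp] = 1.0 - (confusion.loc[sp, sp] / n_sp) if n_sp else float("nan")
    n_voted = int(voted.sum())
    total_err = float((pred[voted] != y[voted]).mean()) if n_voted else float("nan")
    feat_err: dict[str, float] = {}
    for feat in features:
        Xf, _ = _one_hot(train, [feat])
        pf, vf = _fit_forest(Xf, y, n_trees, seed)
        feat_err[feat] = float((pf[vf] != y[vf]).mean()) if vf.any() else float("nan")
    importance = {f: 1.0 - e for f, e in feat_err.items()}
    return ClassificationReport(
        species=tuple(classes),
        per_species_error=per_err,
        total_error=total_err,
        confusion=confusion,
        per_feature_error=feat_err,
        variable_importance=importance,
        importance_ranking=_rank_with_ties(importance, tol=1e-9),
        n_trees=n_trees,
        seed=seed,
    )


def variable_importance_check(report: ClassificationReport) -> tuple[tuple[str, ...], ...]:
    """Feature ranking from a classification report, ties kept as groups."""
    return report.importance_ranking


CSV_COLUMNS = [
    "id", "fl1", "fl2", "fl3", "fl4", "fl5",
    "arrangement", "color", "middle_lobe", "terminal_lobe",
    "price_usd_kg", "city", "true_species",
]


def write_specimen_csv(specimens: Sequence[GillSpecimen], path) -> None:
    rows = []
    for s in specimens:
        row = {"id": s.id}
        for k, p in enumerate(s.filament_points, start=1):
            row[f"fl{k}"] = f"{p:.3f}"
        row.update(
            arrangement=s.arrangement,
            color=s.color,
            middle_lobe=s.middle_lobe,
            terminal_lobe=s.terminal_lobe,
            price_usd_kg="" if s.price is None else f"{s.price:.2f}",
            city=s.city or "",
            true_species=s.true_species or "",
        )
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_specimen_csv(path) -> list[GillSpecimen]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise MorphologyError(f"specimen CSV missing columns: {missing}")
    if df.empty:
        raise MorphologyError(f"specimen CSV {path} contains no rows")
    specimens = []
    for _, r in df.iterrows():
        specimens.append(
            GillSpecimen(
                id=r["id"],
                filament_points=tuple(float(r[f"fl{k}"]) for k in range(1, 6)),
                arrangement=r["arrangement"],
                color=r["color"],
                middle_lobe=r["middle_lobe"],
                terminal_lobe=r["terminal_lobe"],
                price=float(r["price_usd_kg"]) if r.get("price_usd_kg", "") else None,
                city=r.get("city", "") or None,
                true_species=r.get("true_species", "") or None,
            )
        )
    return specimens
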