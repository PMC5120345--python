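"""Aligned marker sequence I/O and Kimura two-parameter (K2P) distances.

Sequences are assumed pre-aligned and of equal length per marker. Gap ('-')
and ambiguity ('N') sites are handled by pairwise deletion: a site is dropped
from a comparison if either sequence carries one of those symbols.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

UNKNOWN = "UNKNOWN"
MARKERS = ("COI", "NADH2")

# Base codes: purines < 2, pyrimidines in {2, 3}; codes >= 4 are excluded
# from comparisons (pairwise deletion).
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4, "-": 5}
_LETTER = "AGCT"
_ALPHABET = frozenset(_CODE)
_SPECIES_TOKEN = re.compile(r"species=(\S+)")


class BarcodeError(ValueError):
    """Malformed sequence input or an invalid pairwise comparison."""


class SaturationError(BarcodeError):
    """Substitution proportions outside the domain of the K2P log terms."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned marker sequence with an optional species label."""

    id: str
    marker: str
    species_label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise BarcodeError("sequence id must be non-empty")
        if self.marker not in MARKERS:
            raise BarcodeError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not self.residues:
            raise BarcodeError(f"record {self.id!r}: residues must be non-empty")
        for pos, ch in enumerate(self.residues):
            if ch not in _ALPHABET:
                raise BarcodeError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseSubstitution:
    """Site counts for one aligned pair after pairwise deletion.

    P and Q are the transition (A<->G, C<->T) and transversion proportions
    over the ``n_sites`` compared sites.
    """

    n_sites: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise BarcodeError("n_sites must be >= 1")
        if not (0.0 <= self.P <= 1.0 and 0.0 <= self.Q <= 1.0):
            raise BarcodeError("P and Q must lie in [0, 1]")
        if self.P + self.Q > 1.0 + 1e-12:
            raise BarcodeError("P + Q must not exceed 1")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix (substitutions/site).

    Also retains the per-pair comparable-site counts and the transition /
    transversion proportions so the long-format export can reproduce every
    intermediate quantity.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    n_sites: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise BarcodeError("distance matrix dimension must match labels")
        if not np.allclose(self.d, self.d.T):
            raise BarcodeError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise BarcodeError("distances must be finite and non-negative")
        if not np.allclose(np.diag(self.d), 0.0):
            raise BarcodeError("distance matrix diagonal must be zero")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_phylip(self) -> str:
        """Square PHYLIP-style distance matrix."""
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.d[i])
            lines.append(f"{lab}  {row}")
        return "\n".join(lines) + "\n"

    def to_long(self) -> pd.DataFrame:
        """Long-format table (id1, id2, n_sites, P, Q, d) over i < j pairs."""
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.labels[i],
                        "id2": self.labels[j],
                        "n_sites": int(self.n_sites[i, j]),
                        "P": self.P[i, j],
                        "Q": self.Q[i, j],
                        "d": self.d[i, j],
                    }
                )
        return pd.DataFrame(rows, columns=["id1", "id2", "n_sites", "P", "Q", "d"])


class ReferencePanel:
    """Reference sequences with known species labels, grouped by marker."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self._by_marker: dict[str, list[SequenceRecord]] = {}
        self._species: dict[str, str] = {}
        for rec in records:
            if rec.species_label == UNKNOWN:
                raise BarcodeError(f"reference record {rec.id!r} lacks a species label")
            self._by_marker.setdefault(rec.marker, []).append(rec)
            prev = self._species.get(rec.id)
            if prev is not None and prev != rec.species_label:
                raise BarcodeError(f"conflicting species labels for reference {rec.id!r}")
            self._species[rec.id] = rec.species_label
        if not self._species:
            raise BarcodeError("reference panel is empty")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self._by_marker)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._species.values())))

    def records(self, marker: str) -> list[SequenceRecord]:
        try:
            return list(self._by_marker[marker])
        except KeyError:
            raise BarcodeError(f"panel has no records for marker {marker!r}") from None

    def species_of(self, ref_id: str) -> str:
        return self._species[ref_id]

    def species_map(self) -> dict[str, str]:
        return dict(self._species)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_marker.values())


def read_fasta(path: str | Path, marker: str) -> list[SequenceRecord]:
    """Read aligned records from FASTA.

    The species label is parsed from a ``species=<name>`` token in the header
    when present; records without one are labelled UNKNOWN. Residues are
    uppercased on input.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise BarcodeError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        m = _SPECIES_TOKEN.search(rec.description)
        species = m.group(1) if m else UNKNOWN
        residues = str(rec.seq).upper()
        if "U" in residues:
            raise BarcodeError(f"record {rec.id!r}: 'U' not allowed (DNA only)")
        records.append(SequenceRecord(rec.id, marker, species, residues))
    if not records:
        raise BarcodeError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species_label != UNKNOWN:
                header += f" species={rec.species_label}"
            fh.write(f">{header}\n{rec.residues}\n")


_CODE_LUT = np.full(128, 255, dtype=np.uint8)
for _ch, _code in _CODE.items():
    _CODE_LUT[ord(_ch)] = _code


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8 codes (purines < 2; >= 4 excluded)."""
    return _CODE_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_LETTER[c] for c in codes)


def encode_panel(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Stack records into an (n, L) uint8 code matrix; lengths must agree."""
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise BarcodeError(f"records have unequal aligned lengths: {sorted(lengths)}")
    return np.vstack([encode(r.residues) for r in records])


def pairwise_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Comparable-site, transition and transversion count matrices.

    Vectorised over one row at a time against all later rows; fine for the
    panel sizes this pipeline handles (hundreds of sequences).
    """
    n = codes.shape[0]
    valid = codes < 4
    purine = codes < 2
    n_sites = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & v
        same_class = purine[i] == purine[i + 1 :]
        ts_i = (diff & same_class).sum(axis=1)
        diff_i = diff.sum(axis=1)
        n_sites[i, i + 1 :] = v.sum(axis=1)
        ts[i, i + 1 :] = ts_i
        tv[i, i + 1 :] = diff_i - ts_i
    n_sites += n_sites.T
    ts += ts.T
    tv += tv.T
    return n_sites, ts, tv


def count_substitutions(a: SequenceRecord, b: SequenceRecord) -> PairwiseSubstitution:
    """Tally transition/transversion proportions for one aligned pair."""
    if a.marker != b.marker:
        raise BarcodeError(f"marker mismatch: {a.id!r} is {a.marker}, {b.id!r} is {b.marker}")
    if len(a) != len(b):
        raise BarcodeError(
            f"unequal aligned lengths for {a.id!r} ({len(a)}) and {b.id!r} ({len(b)})"
        )
    ca, cb = encode(a.residues), encode(b.residues)
    v = (ca < 4) & (cb < 4)
    n = int(v.sum())
    if n == 0:
        raise BarcodeError(f"no comparable sites between {a.id!r} and {b.id!r}")
    diff = (ca != cb) & v
    ts = int((diff & ((ca < 2) == (cb < 2))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseSubstitution(n_sites=n, P=ts / n, Q=tv / n)


def k2p_distance(sub: PairwiseSubstitution) -> float:
    """K2P distance: d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)."""
    w1 = 1.0 - 2.0 * sub.P - sub.Q
    w2 = 1.0 - 2.0 * sub.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError("K2P distance undefined (saturation)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All-pairs K2P distance matrix over aligned same-marker records."""
    if len(records) < 2:
        raise BarcodeError("need at least 2 records for a distance matrix")
    markers = {r.marker for r in records}
    if len(markers) != 1:
        raise BarcodeError(f"mixed markers in one matrix: {sorted(markers)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise BarcodeError(f"duplicate sequence id {dup!r}")
    codes = encode_panel(records)
    n_sites, ts, tv = pairwise_counts(codes)
    n = len(records)
    off = ~np.eye(n, dtype=bool)
    if np.any(n_sites[off] == 0):
        i, j = np.argwhere((n_sites == 0) & off)[0]
        raise BarcodeError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(off, ts / np.where(n_sites == 0, 1, n_sites), 0.0)
        Q = np.where(off, tv / np.where(n_sites == 0, 1, n_sites), 0.0)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    bad = (w1 <= 0.0) | (w2 <= 0.0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise SaturationError(
            f"K2P distance undefined (saturation) for pair ({ids[i]!r}, {ids[j]!r})"
        )
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d, n_sites, P, Q)


def identity_fraction(a: SequenceRecord, b: SequenceRecord) -> float:
    """Matching sites / compared sites under pairwise deletion."""
    sub = count_substitutions(a, b)
    return 1.0 - sub.P - sub.Q
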