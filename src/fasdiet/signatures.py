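"""Compositional fatty-acid signatures: data model, I/O and summaries.

A fatty-acid (FA) signature is the vector of proportional masses of each FA
bin in a tissue lipid extract — a composition: non-negative entries that sum
to one (closure). Signatures are stored internally as fractions; all reports
and summaries use percent by mass, the convention of GC-FID FA tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FABinSet",
    "FASignature",
    "SignatureLibrary",
    "GroupSummary",
    "InvalidCompositionError",
    "SignatureParseError",
    "normalize",
    "replace_zeros",
    "group_summary",
    "predominant_fraction",
    "read_signature_csv",
    "write_signature_csv",
]

#: Default floor used before log-ratio distances (KL needs strictly positive
#: entries). Far below the 0.1% resolution of printed FA tables.
DEFAULT_EPS = 1e-5

_CLOSURE_TOL = 1e-9
_META_COLUMNS = ("sample_id", "group", "species", "deposit")


class InvalidCompositionError(ValueError):
    """Raised for vectors that cannot be interpreted as a composition."""


class SignatureParseError(ValueError):
    """Raised when a signature CSV fails validation; names the row/column."""


@dataclass(frozen=True)
class FABinSet:
    """An ordered, fixed set of FA bin labels for a study.

    Bins may be single FA ("16:0"), combined chromatographic bins
    ("22:6n4+24:1"), or a pooled remainder ("other").
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 2:
            raise ValueError("a bin set needs at least 2 bins")
        if len(set(self.names)) != len(self.names):
            raise ValueError("bin labels must be unique")

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        pos = {name: i for i, name in enumerate(self.names)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"bin {exc.args[0]!r} not in bin set") from None


@dataclass(frozen=True)
class FASignature:
    """One sample's FA composition over a fixed bin set.

    Proportions are fractions summing to one within 1e-9.
    """

    sample_id: str
    proportions: np.ndarray
    bin_set: FABinSet
    group: str = ""
    species: str = ""
    deposit: str = "none"
    season: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if p.ndim != 1 or p.size != self.bin_set.size:
            raise ValueError(
                f"proportions have length {p.size}, bin set has {self.bin_set.size}"
            )
        if np.any(p < 0):
            raise InvalidCompositionError(f"negative proportion in {self.sample_id!r}")
        if abs(p.sum() - 1.0) > _CLOSURE_TOL:
            raise InvalidCompositionError(
                f"proportions of {self.sample_id!r} sum to {p.sum():.12g}, not 1"
            )


@dataclass
class SignatureLibrary:
    """A collection of FA signatures sharing one bin set."""

    signatures: list[FASignature]
    bin_set: FABinSet

    def __post_init__(self) -> None:
        for sig in self.signatures:
            if sig.bin_set != self.bin_set:
                raise ValueError(f"signature {sig.sample_id!r} uses a different bin set")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def matrix(self) -> np.ndarray:
        """Samples × bins matrix of fractions."""
        return np.array([s.proportions for s in self.signatures], dtype=float)

    def labels(self, key: str = "group") -> list[str]:
        if key not in ("group", "species", "deposit", "season"):
            raise KeyError(f"unknown label key {key!r}")
        return [getattr(s, key) or "" for s in self.signatures]

    def subset(self, **criteria: str) -> "SignatureLibrary":
        """Signatures matching all ``label=value`` criteria, e.g. group='otter'."""
        keep = [
            s
            for s in self.signatures
            if all(getattr(s, k) == v for k, v in criteria.items())
        ]
        return SignatureLibrary(keep, self.bin_set)

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.signatures],
                "group": [s.group for s in self.signatures],
                "species": [s.species for s in self.signatures],
                "deposit": [s.deposit for s in self.signatures],
            }
        )
        props = pd.DataFrame(self.matrix(), columns=list(self.bin_set.names))
        return pd.concat([meta, props], axis=1)

    @classmethod
    def from_arrays(
        cls,
        matrix: np.ndarray,
        bin_set: FABinSet,
        sample_ids: Sequence[str] | None = None,
        group: str | Sequence[str] = "",
        species: str | Sequence[str] = "",
        deposit: str | Sequence[str] = "none",
    ) -> "SignatureLibrary":
        matrix = np.asarray(matrix, dtype=float)
        n = matrix.shape[0]
        if sample_ids is None:
            sample_ids = [f"s{i:04d}" for i in range(n)]

        def _bcast(v):
            return [v] * n if isinstance(v, str) else list(v)

        groups, specs, deps = _bcast(group), _bcast(species), _bcast(deposit)
        sigs = [
            FASignature(sample_ids[i], matrix[i], bin_set, groups[i], specs[i], deps[i])
            for i in range(n)
        ]
        return cls(sigs, bin_set)


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sd of a group's signatures, in percent by mass."""

    group: str
    n: int
    mean: np.ndarray  # percent
    sd: np.ndarray  # percent, n-1 denominator, 0 when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must be non-empty")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be non-negative")


def normalize(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Close a non-negative vector to a composition summing to one.

    Accepts raw peak areas or percentages; rejects negative entries and the
    all-zero vector.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise InvalidCompositionError("need at least 2 entries")
    if np.any(raw < 0):
        raise InvalidCompositionError("negative entry in raw composition")
    total = raw.sum()
    if total <= 0:
        raise InvalidCompositionError("all-zero composition cannot be normalized")
    return raw / total


def replace_zeros(sig: FASignature | np.ndarray, eps: float = DEFAULT_EPS):
    """Floor near-zero parts at ``eps`` and re-close, so log ratios are finite.

    Entries below ``eps`` are raised to ``eps``; the vector is then
    renormalized, so entries already above the floor change only through
    closure. Accepts either a signature (returns a signature) or a bare
    fraction vector (returns a vector).
    """
    if not 0 < eps <= 1e-3:
        raise ValueError("eps must be in (0, 1e-3]")
    if isinstance(sig, FASignature):
        p = sig.proportions
    else:
        p = np.asarray(sig, dtype=float)
    floored = np.maximum(p, eps)
    out = floored / floored.sum()
    if isinstance(sig, FASignature):
        return replace(sig, proportions=out)
    return out


def group_summary(lib: SignatureLibrary, by: str = "group") -> list[GroupSummary]:
    """Per-group mean and sample sd of signatures, in percent.

    ``by`` is one of group/species/deposit. Groups appear in order of first
    occurrence, matching how a signature table is usually laid out.
    """
    labels = lib.labels(by)
    matrix = lib.matrix() * 100.0
    out: list[GroupSummary] = []
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        idx = [i for i, l in enumerate(labels) if l == lab]
        sub = matrix[idx]
        n = len(idx)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if n > 1 else np.zeros(matrix.shape[1])
        out.append(GroupSummary(lab, n, mean, sd))
    return out


def predominant_fraction(
    summaries: Sequence[GroupSummary],
    fa_set: Sequence[str],
    bin_set: FABinSet,
    weights: Sequence[float] | None = None,
) -> float:
    """n-weighted grand mean (percent) of the within-group sums over ``fa_set``.

    With weights equal to the group sample sizes this equals the all-samples
    mean of the summed proportions of the chosen FA — e.g. the share of total
    FA contributed by the four predominant acids 16:0, 16:1, 18:0 and 18:1.
    """
    idx = bin_set.index_of(fa_set)
    if weights is None:
        weights = [s.n for s in summaries]
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if w.size != len(summaries):
        raise ValueError("one weight per group summary required")
    sums = np.array([np.asarray(s.mean)[idx].sum() for s in summaries])
    return float(np.average(sums, weights=w))


def write_signature_csv(lib: SignatureLibrary, path: str | Path) -> None:
    """Write a library as CSV: sample_id, group, species, deposit, then bins.

    Proportions are written as fractions with 10 significant digits so a
    write→read round trip is lossless at that precision.
    """
    df = lib.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def read_signature_csv(
    path: str | Path, renormalize: bool = False, tol: float = 1e-6
) -> SignatureLibrary:
    """Read a signature CSV written by :func:`write_signature_csv`.

    Rows must close to 1 within ``tol`` unless ``renormalize`` is set (which
    also accepts percent rows summing to 100). Negative or non-numeric cells
    are rejected with the offending row and column named.
    """
    df = pd.read_csv(path, dtype={c: str for c in _META_COLUMNS})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SignatureParseError(f"missing required columns: {missing}")
    bin_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if len(bin_cols) < 2:
        raise SignatureParseError("fewer than 2 FA bin columns")
    bin_set = FABinSet(tuple(bin_cols))

    sigs: list[FASignature] = []
    for i, row in df.iterrows():
        vals = np.empty(len(bin_cols))
        for j, col in enumerate(bin_cols):
            try:
                vals[j] = float(row[col])
            except (TypeError, ValueError):
                raise SignatureParseError(
                    f"row {i + 2}, column {col!r}: non-numeric value {row[col]!r}"
                ) from None
            if vals[j] < 0:
                raise SignatureParseError(
                    f"row {i + 2}, column {col!r}: negative value {vals[j]}"
                )
        if renormalize:
            vals = normalize(vals)
        elif abs(vals.sum() - 1.0) > tol:
            raise SignatureParseError(
                f"row {i + 2} ({row['sample_id']!r}): proportions sum to "
                f"{vals.sum():.8g}, not 1 (pass renormalize=True to close)"
            )
        else:
            vals = vals / vals.sum()
        sigs.append(
            FASignature(
                str(row["sample_id"]),
                vals,
                bin_set,
                group=str(row["group"]),
                species=str(row["species"]),
                deposit=str(row["deposit"]),
            )
        )
    return SignatureLibrary(sigs, bin_set)
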