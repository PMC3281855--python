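"""Pairwise nucleotide distances: p-distance and Kimura 2-parameter (K2P).

The K2P correction treats transitions (A<->G, C<->T) and transversions
separately:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the proportions of sites showing a transition and a
transversion, respectively, among sites compared. Sites where either
sequence carries a gap or an IUPAC ambiguity code are excluded per pair
(pairwise deletion). Saturated pairs (log argument <= 0) raise
:class:`~barcodekit.errors.SaturationError` from the scalar function and are
masked -- never silently dropped -- in matrix computation.

Distances are proportions internally; reports render them as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ComputationError, SaturationError, ValidationError
from .seqio import Dataset

__all__ = [
    "SiteComparison",
    "DistanceMatrix",
    "compare_sites",
    "k2p",
    "k2p_from_counts",
    "p_distance",
    "pairwise_matrix",
    "encode",
]

# A=0, C=1, G=2, T=3; anything else (gaps, N, ambiguity codes) = -1 and is
# excluded by pairwise deletion. With this encoding a substitution is a
# transition iff |a - b| == 2.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0, C=1, G=2, T=3, other=-1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteComparison:
    """Substitution counts over the sites comparable in one sequence pair."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValidationError("substitution counts exceed compared sites")
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValidationError("negative site counts")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


def compare_sites(seq_a: str, seq_b: str) -> SiteComparison:
    """Count compared sites, transitions and transversions for one pair.

    Sites where either sequence has a gap or ambiguity code are excluded
    (pairwise deletion). Raises on length mismatch or zero comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = encode(seq_a), encode(seq_b)
    valid = (a >= 0) & (b >= 0)
    n_compared = int(valid.sum())
    if n_compared == 0:
        raise ComputationError("no comparable sites in pair (all gaps/ambiguous)")
    diff = valid & (a != b)
    ts = int((diff & (np.abs(a - b) == 2)).sum())
    tv = int(diff.sum()) - ts
    return SiteComparison(n_compared, ts, tv)


def k2p_from_counts(counts: SiteComparison) -> float:
    """Evaluate the K2P closed form on substitution counts."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f}: saturated pair"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalizes -0.0


def k2p(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences."""
    return k2p_from_counts(compare_sites(seq_a, seq_b))


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    c = compare_sites(seq_a, seq_b)
    return (c.n_transitions + c.n_transversions) / c.n_compared


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an explicit undefined-cell mask.

    ``values`` holds proportions; undefined (saturated) cells are NaN and
    flagged True in ``mask``. The diagonal is zero and never masked.
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.mask is None:
            self.mask = np.zeros((n, n), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        finite = self.values[~self.mask]
        if finite.size and (not np.allclose(np.diag(self.values), 0.0)):
            raise ValidationError("distance matrix diagonal must be zero")
        if finite.size and (finite < 0).any():
            raise ValidationError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_undefined(self) -> int:
        """Number of unordered pairs whose distance is undefined (saturated)."""
        return int(self.mask[np.triu_indices(len(self.labels), k=1)].sum())

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.labels.index(id_a), self.labels.index(id_b)
        if self.mask[i, j]:
            raise SaturationError(f"distance undefined for pair ({id_a}, {id_b})")
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (NaN where masked), row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        vals = self.values * 100.0 if percent else self.values
        return pd.DataFrame(vals, index=self.labels, columns=self.labels)

    def reordered(self, new_labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in new_labels]
        return DistanceMatrix(
            list(new_labels),
            self.values[np.ix_(idx, idx)],
            self.mask[np.ix_(idx, idx)],
        )

    def to_phylip(self, path: str | Path) -> None:
        """Write PHYLIP square distance format (undefined cells as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = [
                    "-1" if self.mask[i, j] else f"{self.values[i, j]:.6f}"
                    for j in range(len(self.labels))
                ]
                fh.write(f"{lab:<10s} " + " ".join(row) + "\n")

    def to_lower_triangle(self, path: str | Path) -> None:
        """Write tab-delimited lower-triangular matrix with a label column."""
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                cells = [
                    "NA" if self.mask[i, j] else f"{self.values[i, j]:.6f}"
                    for j in range(i)
                ]
                fh.write("\t".join([lab] + cells) + "\n")


Metric = Literal["k2p", "p"]


def pairwise_matrix(dataset: Dataset, metric: Metric = "k2p") -> DistanceMatrix:
    """Full pairwise distance matrix over an aligned dataset.

    Saturated pairs (K2P undefined) are masked and counted via
    :attr:`DistanceMatrix.n_undefined`; a pair with zero comparable sites is
    an error naming the pair.
    """
    if metric not in ("k2p", "p"):
        raise ValidationError(f"unknown metric {metric!r}")
    if dataset.alignment_length is None:
        raise ValidationError("pairwise_matrix requires an aligned dataset")
    ids = dataset.ids
    enc = np.stack([encode(r.sequence) for r in dataset.records])
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    mask = np.zeros((n, n), dtype=bool)
    ok = enc >= 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = ok[i] & ok[j]
            n_comp = int(valid.sum())
            if n_comp == 0:
                raise ComputationError(
                    f"no comparable sites for pair ({ids[i]}, {ids[j]})"
                )
            diff = valid & (enc[i] != enc[j])
            n_diff = int(diff.sum())
            if metric == "p":
                d = n_diff / n_comp
            else:
                ts = int((diff & (np.abs(enc[i] - enc[j]) == 2)).sum())
                try:
                    d = k2p_from_counts(SiteComparison(n_comp, ts, n_diff - ts))
                except SaturationError:
                    values[i, j] = values[j, i] = np.nan
                    mask[i, j] = mask[j, i] = True
                    continue
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, mask)
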