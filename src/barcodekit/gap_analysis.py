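"""Barcode-gap analysis: divergences partitioned by taxonomic comparison class.

Every unordered specimen pair is assigned to exactly one comparison class by
the most specific rank the two specimens share: same species; same genus but
different species; same family but different genus; same order but different
family; same class but different order. Per-class summary statistics
(mean/min/max/SE over pairwise distances, expressed in percent) reproduce
the classic rank-summary table of barcoding studies; congeneric
interspecific distances are further banded (<5%, 5-10%, >10%) per family.

Nearest-neighbor distance (NND) is computed per species: the minimum
distance between any of its specimens and any heterospecific specimen.
Species are flagged when their maximum intraspecific distance exceeds the
barcode filter (default 1%) or when their NND falls below it — the two
failure modes that erode the barcode gap.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import ComputationError, ValidationError

__all__ = [
    "ComparisonClass",
    "RankSummary",
    "NNDResult",
    "BoxplotStats",
    "classify_pair",
    "rank_summaries",
    "band_counts",
    "threshold_fraction",
    "nearest_neighbor_distances",
    "fold_ratio",
    "boxplot_stats",
    "barcode_gap_flags",
    "summaries_to_tsv",
    "nnd_to_tsv",
    "round2",
]


class ComparisonClass(enum.IntEnum):
    """Most specific rank shared by a specimen pair (mutually exclusive)."""

    within_species = 0
    within_genus = 1
    within_family = 2
    within_order = 3
    within_class = 4


# rank column checked at each level, from most to least specific
_RANK_ORDER = ["species", "genus", "family", "order", "class_"]


def round2(x: float) -> float:
    """Round to 2 decimals, half-to-even (used only at reporting)."""
    return float(np.round(x, 2))


def classify_pair(taxonomy: pd.DataFrame, id_a: str, id_b: str) -> ComparisonClass | None:
    """Comparison class of one pair; None if the pair shares no class rank."""
    try:
        ta, tb = taxonomy.loc[id_a], taxonomy.loc[id_b]
    except KeyError as e:
        raise ValidationError(f"specimen id not in taxonomy: {e.args[0]}") from e
    for cls, rank in zip(ComparisonClass, _RANK_ORDER):
        if ta[rank] == tb[rank]:
            return cls
    return None


def _pair_class_codes(matrix: DistanceMatrix, taxonomy: pd.DataFrame) -> np.ndarray:
    """n x n matrix of ComparisonClass codes (-1 = no shared class rank)."""
    missing = [l for l in matrix.labels if l not in taxonomy.index]
    if missing:
        raise ValidationError(f"matrix labels absent from taxonomy: {missing}")
    tax = taxonomy.loc[matrix.labels]
    codes = np.full((len(matrix), len(matrix)), -1, dtype=np.int8)
    # assign from least to most specific so specific ranks overwrite
    for cls, rank in reversed(list(zip(ComparisonClass, _RANK_ORDER))):
        vals = pd.factorize(tax[rank])[0]
        same = vals[:, None] == vals[None, :]
        codes[same] = int(cls)
    return codes


@dataclass(frozen=True)
class RankSummary:
    """One row of the per-class divergence summary (percent scale)."""

    comparison_class: ComparisonClass
    n_taxa: int
    n_comparisons: int
    mean: float
    minimum: float
    maximum: float
    se: float


def _contributing_taxa(tax: pd.DataFrame, cls: ComparisonClass) -> int:
    """Taxa at the class's rank containing >=2 distinct child taxa.

    For within_species: species with >=2 specimens; for within_genus: genera
    with >=2 species; and so on up the hierarchy.
    """
    if cls == ComparisonClass.within_species:
        return int((tax.groupby("species").size() >= 2).sum())
    rank = _RANK_ORDER[int(cls)]
    child = _RANK_ORDER[int(cls) - 1]
    return int((tax.groupby(rank)[child].nunique() >= 2).sum())


def rank_summaries(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    cumulative: bool = False,
) -> dict[ComparisonClass, RankSummary]:
    """Per-comparison-class divergence statistics (the rank-summary table).

    Classes are disjoint by default: each pair contributes to exactly one
    class. With ``cumulative=True`` a pair also contributes to every less
    specific class it is nested in (an alternative convention some studies
    use for the upper rows). Masked (saturated) cells are excluded with a
    warning; classes with zero comparisons are omitted with a warning.
    """
    codes = _pair_class_codes(matrix, taxonomy)
    iu = np.triu_indices(len(matrix), k=1)
    pair_codes = codes[iu]
    pair_vals = matrix.values[iu] * 100.0  # percent
    pair_masked = matrix.mask[iu]
    if pair_masked.any():
        warnings.warn(
            f"{int(pair_masked.sum())} saturated pair(s) excluded from summaries"
        )
    tax = taxonomy.loc[matrix.labels]
    out: dict[ComparisonClass, RankSummary] = {}
    for cls in ComparisonClass:
        if cumulative:
            sel = (pair_codes >= 0) & (pair_codes <= int(cls)) & ~pair_masked
        else:
            sel = (pair_codes == int(cls)) & ~pair_masked
        vals = pair_vals[sel]
        if vals.size == 0:
            warnings.warn(f"no comparisons in class {cls.name}; omitted")
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[cls] = RankSummary(
            comparison_class=cls,
            n_taxa=_contributing_taxa(tax, cls),
            n_comparisons=int(vals.size),
            mean=float(vals.mean()),
            minimum=float(vals.min()),
            maximum=float(vals.max()),
            se=se,
        )
    return out


def band_counts(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    bands: tuple[float, float] = (5.0, 10.0),
) -> pd.DataFrame:
    """Congeneric interspecific distances banded per family.

    Bands are half-open in percent: [0, b1), [b1, b2), [b2, inf). Rows are
    (order, family) pairs with at least one congeneric comparison; the
    column totals sum to the within_genus comparison count.
    """
    b1, b2 = bands
    if not 0 < b1 < b2:
        raise ValidationError(f"bands must be increasing positive, got {bands}")
    codes = _pair_class_codes(matrix, taxonomy)
    tax = taxonomy.loc[matrix.labels]
    fam = pd.factorize(tax["family"])[0]
    iu = np.triu_indices(len(matrix), k=1)
    sel = (codes[iu] == int(ComparisonClass.within_genus)) & ~matrix.mask[iu]
    vals = matrix.values[iu][sel] * 100.0
    fams = fam[iu[0]][sel]  # congeneric pairs share the family
    col_names = [f"<{b1:g}%", f"{b1:g}–{b2:g}%", f">{b2:g}%"]
    rows = {}
    fam_labels = pd.factorize(tax["family"])[1]
    fam_order = tax.drop_duplicates("family").set_index("family")["order"]
    for code in np.unique(fams):
        fvals = vals[fams == code]
        counts = (
            int((fvals < b1).sum()),
            int(((fvals >= b1) & (fvals < b2)).sum()),
            int((fvals >= b2).sum()),
        )
        family = fam_labels[code]
        rows[(fam_order[family], family)] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=col_names)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["order", "family"])
    return df.sort_index()


def threshold_fraction(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    comparison_class: ComparisonClass,
    threshold_pct: float,
) -> tuple[int, int, float]:
    """(count strictly below threshold, total, percent) for one class."""
    codes = _pair_class_codes(matrix, taxonomy)
    iu = np.triu_indices(len(matrix), k=1)
    sel = (codes[iu] == int(comparison_class)) & ~matrix.mask[iu]
    vals = matrix.values[iu][sel] * 100.0
    if vals.size == 0:
        raise ComputationError(f"no comparisons in class {comparison_class.name}")
    below = int((vals < threshold_pct).sum())
    return below, int(vals.size), round2(100.0 * below / vals.size)


@dataclass(frozen=True)
class NNDResult:
    """Nearest-neighbor distance of one species (percent scale)."""

    species: str
    nearest_neighbor: str
    distance: float


def nearest_neighbor_distances(
    matrix: DistanceMatrix, taxonomy: pd.DataFrame
) -> list[NNDResult]:
    """Per-species minimum distance to any heterospecific specimen.

    Every species gets a result, including singletons. Requires >=2 species.
    """
    tax = taxonomy.loc[matrix.labels]
    species = tax["species"].to_numpy()
    uniq = np.unique(species)
    if uniq.size < 2:
        raise ComputationError("nearest-neighbor distances require >=2 species")
    vals = np.where(matrix.mask, np.inf, matrix.values) * 100.0
    out = []
    for sp in uniq:
        rows = species == sp
        sub = vals[np.ix_(rows, ~rows)]
        j = int(np.argmin(sub))
        dist = float(sub.flat[j])
        if not np.isfinite(dist):
            raise ComputationError(f"all heterospecific distances saturated for {sp}")
        neighbor = species[~rows][j % sub.shape[1]]
        out.append(NNDResult(str(sp), str(neighbor), dist))
    return out


def fold_ratio(summaries: dict[ComparisonClass, RankSummary]) -> float:
    """Within-genus mean divided by within-species mean."""
    try:
        intra = summaries[ComparisonClass.within_species]
        inter = summaries[ComparisonClass.within_genus]
    except KeyError as e:
        raise ComputationError(f"missing summary for {e.args[0]}") from e
    if intra.mean == 0:
        raise ComputationError("within-species mean is zero; fold ratio undefined")
    return inter.mean / intra.mean


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot statistics (quartiles by linear interpolation)."""

    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    mild_outliers: list[float]
    extreme_outliers: list[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def boxplot_stats(values) -> BoxplotStats:
    """Tukey convention: whiskers at the most extreme points within 1.5 IQR
    of the quartiles; mild outliers beyond that, extreme beyond 3 IQR."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValidationError("boxplot_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_ext, hi_ext = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    mild = v[((v < lo_fence) & (v >= lo_ext)) | ((v > hi_fence) & (v <= hi_ext))]
    extreme = v[(v < lo_ext) | (v > hi_ext)]
    return BoxplotStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mild_outliers=[float(x) for x in mild],
        extreme_outliers=[float(x) for x in extreme],
    )


def barcode_gap_flags(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    intra_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-species barcode-gap screening at the given filter (percent).

    Flags species whose maximum intraspecific distance exceeds the filter
    (deep intraspecific divergence) and species whose nearest-neighbor
    distance falls below it (overlap with a close relative).
    """
    if intra_threshold <= 0:
        raise ValidationError("intra_threshold must be positive")
    tax = taxonomy.loc[matrix.labels]
    species = tax["species"].to_numpy()
    nnd = {r.species: r for r in nearest_neighbor_distances(matrix, taxonomy)}
    vals = matrix.values * 100.0
    rows = []
    for sp in np.unique(species):
        sel = species == sp
        n = int(sel.sum())
        if n >= 2:
            sub = vals[np.ix_(sel, sel)]
            msk = matrix.mask[np.ix_(sel, sel)]
            intra = sub[np.triu_indices(n, k=1)]
            intra = intra[~msk[np.triu_indices(n, k=1)]]
            max_intra = float(intra.max()) if intra.size else np.nan
        else:
            max_intra = np.nan
        r = nnd[str(sp)]
        rows.append(
            {
                "species": str(sp),
                "n_specimens": n,
                "max_intraspecific": max_intra,
                "nnd": r.distance,
                "nearest_neighbor": r.nearest_neighbor,
                "deep_intraspecific": bool(max_intra > intra_threshold)
                if not np.isnan(max_intra)
                else False,
                "nnd_below_threshold": r.distance < intra_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("species").sort_index()


def summaries_to_tsv(
    summaries: dict[ComparisonClass, RankSummary], path: str | Path
) -> None:
    """Write the rank-summary table with percent values at 2 decimals."""
    rows = []
    for cls in ComparisonClass:
        if cls not in summaries:
            continue
        s = summaries[cls]
        rows.append(
            {
                "comparisons_within": cls.name.removeprefix("within_"),
                "taxa": s.n_taxa,
                "n_comparisons": s.n_comparisons,
                "mean": f"{s.mean:.2f}",
                "minimum": f"{s.minimum:.2f}",
                "maximum": f"{s.maximum:.2f}",
                "se": f"{s.se:.2f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def nnd_to_tsv(results: list[NNDResult], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in results])
    df["distance"] = df["distance"].map(lambda d: f"{d:.2f}")
    df.to_csv(path, sep="\t", index=False)
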