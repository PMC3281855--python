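"""Character-based species identification: pure simple diagnostic sites.

For a target species, a diagnostic site is an alignment column where the set
of nucleotide states observed in the target is disjoint from the set
observed in all other species. Such columns identify the species even when
overall distance-based divergence is too low (as with highly conserved
markers like 18S). Only single-column ("pure simple") diagnostics are
considered; compound multi-column characters are out of scope.

Specimens carrying a gap or ambiguity code at a column are excluded from
that column's state sets, and a column is only reported when at least a
configurable fraction (default 80%) of target specimens are informative
there, preventing missing-data artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import encode
from .errors import ValidationError
from .seqio import Dataset

__all__ = ["DiagnosticSite", "DiagnosticSiteSet", "QueryAssignment",
           "pure_diagnostics", "build_library", "diagnose_query",
           "library_to_tsv", "assignments_to_tsv"]

_BASES = "ACGT"


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic alignment column (1-based position)."""

    column: int
    diagnostic_states: frozenset[str]
    background_states: frozenset[str]


@dataclass(frozen=True)
class DiagnosticSiteSet:
    """All pure simple diagnostic sites for one species."""

    species: str
    sites: tuple[DiagnosticSite, ...]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def columns(self) -> list[int]:
        return [s.column for s in self.sites]


def _presence(enc: np.ndarray) -> np.ndarray:
    """4 x L boolean: base b observed in any row at each column."""
    return np.stack([(enc == b).any(axis=0) for b in range(4)])


def pure_diagnostics(
    dataset: Dataset,
    target_species: str,
    min_informative: float = 0.8,
) -> DiagnosticSiteSet:
    """All columns whose target state set is disjoint from the background.

    Polymorphic target columns still qualify as long as no target state is
    shared with any other species. Requires an aligned dataset with at least
    one target and one non-target specimen.
    """
    if dataset.alignment_length is None:
        raise ValidationError("diagnostic sites require an aligned dataset")
    if not 0 < min_informative <= 1:
        raise ValidationError("min_informative must be in (0, 1]")
    tax = dataset.taxonomy
    in_target = (tax["species"] == target_species).to_numpy()
    if not in_target.any():
        raise ValidationError(f"no specimens of species {target_species!r}")
    if in_target.all():
        raise ValidationError("no non-target specimens to compare against")
    enc = np.stack([encode(r.sequence) for r in dataset.records])
    t_enc, b_enc = enc[in_target], enc[~in_target]
    t_pres, b_pres = _presence(t_enc), _presence(b_enc)
    t_informative = (t_enc >= 0).sum(axis=0) / t_enc.shape[0]
    disjoint = (
        t_pres.any(axis=0)
        & b_pres.any(axis=0)
        & ~(t_pres & b_pres).any(axis=0)
        & (t_informative >= min_informative)
    )
    sites = tuple(
        DiagnosticSite(
            column=int(col) + 1,
            diagnostic_states=frozenset(_BASES[b] for b in range(4) if t_pres[b, col]),
            background_states=frozenset(_BASES[b] for b in range(4) if b_pres[b, col]),
        )
        for col in np.flatnonzero(disjoint)
    )
    return DiagnosticSiteSet(target_species, sites)


def build_library(
    dataset: Dataset, min_informative: float = 0.8
) -> dict[str, DiagnosticSiteSet]:
    """Diagnostic site sets for every species in the dataset."""
    species = sorted(dataset.taxonomy["species"].unique())
    if len(species) < 2:
        raise ValidationError("a diagnostic library requires >=2 species")
    return {
        sp: pure_diagnostics(dataset, sp, min_informative=min_informative)
        for sp in species
    }


@dataclass(frozen=True)
class QueryAssignment:
    species: str
    fraction_matched: float
    n_sites: int


def diagnose_query(
    query_sequence: str,
    diagnostic_library: dict[str, DiagnosticSiteSet],
    alignment_length: int | None = None,
) -> list[QueryAssignment]:
    """Score a pre-aligned query against every species' diagnostic sites.

    For each species: the fraction of its diagnostic columns at which the
    query carries a diagnostic state. Species are ranked by fraction, then
    by number of diagnostic sites, then alphabetically. The query must span
    the library's alignment coordinates.
    """
    if alignment_length is None:
        alignment_length = max(
            (s.column for dset in diagnostic_library.values() for s in dset.sites),
            default=0,
        )
    if len(query_sequence) < alignment_length:
        raise ValidationError(
            f"query length {len(query_sequence)} shorter than alignment "
            f"coordinates ({alignment_length}); align the query first"
        )
    q = query_sequence.upper()
    out = []
    for sp, dset in diagnostic_library.items():
        if dset.sites:
            hits = sum(1 for s in dset.sites if q[s.column - 1] in s.diagnostic_states)
            frac = hits / len(dset.sites)
        else:
            frac = 0.0
        out.append(QueryAssignment(sp, frac, len(dset.sites)))
    return sorted(out, key=lambda a: (-a.fraction_matched, -a.n_sites, a.species))


def library_to_tsv(library: dict[str, DiagnosticSiteSet], path: str | Path) -> None:
    rows = [
        {
            "species": sp,
            "column": s.column,
            "diagnostic_states": "".join(sorted(s.diagnostic_states)),
            "background_states": "".join(sorted(s.background_states)),
        }
        for sp, dset in sorted(library.items())
        for s in dset.sites
    ]
    pd.DataFrame(rows, columns=["species", "column", "diagnostic_states",
                                "background_states"]).to_csv(path, sep="\t", index=False)


def assignments_to_tsv(assignments: list[QueryAssignment], path: str | Path) -> None:
    df = pd.DataFrame([vars(a) for a in assignments])
    df["fraction_matched"] = df["fraction_matched"].map(lambda f: f"{f:.4f}")
    df.to_csv(path, sep="\t", index=False)
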