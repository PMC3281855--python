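"""Synthetic barcode datasets with known truth.

Generates aligned sequence datasets with the statistical structure barcode
studies assume: a nested five-rank taxonomy, per-rank divergence targets
(defaults on the scale of fish COI surveys: ~0.2% within species, ~13.5%
among congeners, ~19.7% within families), and a transition-biased
two-parameter (Kimura) substitution process, so the K2P estimator is
correctly specified on the simulated data.

Sequences evolve down a balanced rank-structured tree whose branch lengths
are solved so the expected pairwise divergence between two specimens equals
the configured target for their comparison class. For coding markers the
root is drawn from stop-free codons and any in-frame stop codon arising
along a branch is resampled, so clean simulations always pass numt
screening; planted numts (stop codon or single-base deletion) are the only
screening positives.

All stochastic draws flow from one seeded generator; truth (true tree,
divergences, planted numts, splits and diagnostic columns) is recorded
alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import ValidationError
from .seqio import Dataset, Marker, SpecimenRecord, write_fasta, write_taxonomy

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate", "simulate_pair",
           "inject_numt", "plant_deep_split", "plant_diagnostic_columns",
           "evolve_sequence", "write_synthetic"]

_BASES = np.array(list("ACGT"))
# A=0, C=1, G=2, T=3: the transition partner (A<->G, C<->T) is (x+2)%4;
# the two transversion partners are x^1 and x^3.
_STOPS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate mitochondrial code


def _kimura_probs(branch_length: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after a branch.

    ``branch_length`` is the expected number of substitutions per site; the
    transition rate is kappa times each single transversion rate, so
    alpha*t = b*kappa/(kappa+2) and beta*t = b/(kappa+2).
    """
    at = branch_length * kappa / (kappa + 2.0)
    bt = branch_length / (kappa + 2.0)
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_same, p_ts, p_tv


def _evolve_enc(enc: np.ndarray, branch_length: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along one branch under the Kimura model."""
    if branch_length < 0:
        raise ValidationError("branch length must be non-negative")
    if branch_length == 0:
        return enc.copy()
    p_same, p_ts, p_tv = _kimura_probs(branch_length, kappa)
    u = rng.random(enc.shape[0])
    out = enc.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    out[ts] = (enc[ts] + 2) % 4
    out[tv1] = enc[tv1] ^ 1
    out[tv2] = enc[tv2] ^ 3
    return out


def _decode(enc: np.ndarray) -> str:
    return "".join(_BASES[enc])


def _encode(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate("ACGT")}
    return np.array([lut[c] for c in seq], dtype=np.int64)


def _stop_codon_starts(enc: np.ndarray) -> list[int]:
    s = _decode(enc)
    return [i for i in range(0, len(s) - 2, 3) if s[i : i + 3] in _STOPS]


def _evolve_coding(enc: np.ndarray, branch_length: float, kappa: float,
                   rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Kimura evolution conditioned on producing no in-frame stop codon.

    Codons that mutate into a stop are re-evolved from the parent codon;
    after ``max_tries`` rejections the parent codon is kept unchanged.
    """
    out = _evolve_enc(enc, branch_length, kappa, rng)
    for start in _stop_codon_starts(out):
        for _ in range(max_tries):
            cand = _evolve_enc(enc[start : start + 3], branch_length, kappa, rng)
            if _decode(cand) not in _STOPS:
                out[start : start + 3] = cand
                break
        else:
            out[start : start + 3] = enc[start : start + 3]
    return out


def _random_root(length: int, rng: np.random.Generator, coding: bool) -> np.ndarray:
    """Uniform random root sequence; stop-free in frame 0 when coding."""
    enc = rng.integers(0, 4, size=length)
    if coding:
        for start in _stop_codon_starts(enc):
            while _decode(enc[start : start + 3]) in _STOPS:
                enc[start : start + 3] = rng.integers(0, 4, size=3)
    return enc


def evolve_sequence(seq: str, branch_length: float, kappa: float,
                    rng: np.random.Generator, coding: bool = False) -> str:
    """Evolve a sequence string along one branch (public helper)."""
    fn = _evolve_coding if coding else _evolve_enc
    return _decode(fn(_encode(seq), branch_length, kappa, rng))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Divergence targets are expected substitutions per site between two
    specimens of the given comparison class and must increase strictly with
    rank. Defaults mirror the fish COI scale: 0.2% within species, 13.5%
    among congeneric species, 19.7% among confamilial genera, 24% among
    families of the same order. kappa is the transition/transversion rate
    ratio of the substitution process.
    """

    seed: int = 0
    n_families: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    specimens_per_species: int = 3
    seq_length: int = 652
    kappa: float = 2.0
    divergence_within_species: float = 0.002
    divergence_within_genus: float = 0.135
    divergence_within_family: float = 0.197
    divergence_within_order: float = 0.24
    numt_rate: float = 0.0
    marker: Marker = Marker.COI

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "specimens_per_species", "seq_length"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        if not 0 <= self.numt_rate <= 1:
            raise ValidationError("numt_rate must be in [0, 1]")
        d = (self.divergence_within_species, self.divergence_within_genus,
             self.divergence_within_family, self.divergence_within_order)
        if any(x < 0 for x in d) or not all(a < b for a, b in zip(d, d[1:])):
            raise ValidationError(
                "divergence targets must be non-negative and strictly "
                f"increasing with rank, got {d}"
            )
        object.__setattr__(self, "marker", Marker.parse(self.marker))

    @property
    def branch_lengths(self) -> dict[str, float]:
        """Per-level branch lengths solving the pairwise divergence targets."""
        return {
            "specimen": self.divergence_within_species / 2.0,
            "species": (self.divergence_within_genus - self.divergence_within_species) / 2.0,
            "genus": (self.divergence_within_family - self.divergence_within_genus) / 2.0,
            "family": (self.divergence_within_order - self.divergence_within_family) / 2.0,
        }


@dataclass
class SyntheticDataset:
    """A generated dataset together with its ground truth."""

    dataset: Dataset
    truth: dict = field(default_factory=dict)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a dataset under the configured hierarchy and divergences.

    Deterministic given ``config.seed``. All families sit under one order
    and one class; the root is the order-level ancestor.
    """
    rng = np.random.default_rng(config.seed)
    coding = config.marker.is_coding
    bl = config.branch_lengths
    root = _random_root(config.seq_length, rng, coding)
    evolve = _evolve_coding if coding else _evolve_enc

    tns = dendropy.TaxonNamespace()
    tree_root = dendropy.Node()
    records: list[SpecimenRecord] = []
    counter = 0
    for f in range(config.n_families):
        family = f"Family{f + 1}"
        fam_enc = evolve(root, bl["family"], config.kappa, rng)
        fam_node = dendropy.Node()
        tree_root.add_child(fam_node)
        fam_node.edge.length = bl["family"]
        for g in range(config.genera_per_family):
            genus = f"Genus{f + 1}{chr(65 + g)}"
            gen_enc = evolve(fam_enc, bl["genus"], config.kappa, rng)
            gen_node = dendropy.Node()
            fam_node.add_child(gen_node)
            gen_node.edge.length = bl["genus"]
            for s in range(config.species_per_genus):
                species = f"{genus}_sp{s + 1}"
                sp_enc = evolve(gen_enc, bl["species"], config.kappa, rng)
                sp_node = dendropy.Node()
                gen_node.add_child(sp_node)
                sp_node.edge.length = bl["species"]
                for k in range(config.specimens_per_species):
                    counter += 1
                    sid = f"SP{counter:04d}"
                    ind_enc = evolve(sp_enc, bl["specimen"], config.kappa, rng)
                    taxon = dendropy.Taxon(label=sid)
                    tns.add_taxon(taxon)
                    leaf = dendropy.Node(taxon=taxon)
                    sp_node.add_child(leaf)
                    leaf.edge.length = bl["specimen"]
                    records.append(SpecimenRecord(
                        specimen_id=sid,
                        sequence=_decode(ind_enc),
                        marker=config.marker,
                        species=species,
                        genus=genus,
                        family=family,
                        order="Order1",
                        class_="Actinopterygii",
                    ))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=tree_root)
    tree.is_rooted = False
    dataset = Dataset(records)
    truth = {
        "seed": config.seed,
        "config": {
            k: (v.value if isinstance(v, Marker) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "true_tree_newick": tree.as_string(schema="newick").strip(),
        "divergence_targets": {
            "within_species": config.divergence_within_species,
            "within_genus": config.divergence_within_genus,
            "within_family": config.divergence_within_family,
            "within_order": config.divergence_within_order,
        },
        "numt_ids": [],
        "deep_splits": {},
        "diagnostic_columns": {},
    }
    result = SyntheticDataset(dataset, truth)
    if config.numt_rate > 0:
        flags = rng.random(len(records)) < config.numt_rate
        for rec, hit in zip(list(dataset.records), flags):
            if hit:
                result = inject_numt(result, rec.specimen_id, seed=config.seed)
    return result


def simulate_pair(divergence: float, kappa: float, length: int,
                  rng: np.random.Generator) -> tuple[str, str]:
    """One pair of sequences at a known true divergence (no stop constraint).

    Each sequence evolves divergence/2 from a shared uniform ancestor, so the
    expected pairwise divergence is exactly ``divergence`` and the K2P
    estimator is correctly specified.
    """
    root = rng.integers(0, 4, size=length)
    a = _evolve_enc(root, divergence / 2.0, kappa, rng)
    b = _evolve_enc(root, divergence / 2.0, kappa, rng)
    return _decode(a), _decode(b)


def _record_rng(seed: int, specimen_id: str) -> np.random.Generator:
    """Deterministic per-(seed, specimen) stream, independent of call order."""
    return np.random.default_rng([seed, zlib.crc32(specimen_id.encode())])


def _replace_record(sd: SyntheticDataset, specimen_id: str, new_seq: str) -> Dataset:
    records = [
        dataclasses.replace(r, sequence=new_seq) if r.specimen_id == specimen_id else r
        for r in sd.dataset.records
    ]
    return Dataset(records)


def inject_numt(sd: SyntheticDataset, specimen_id: str, seed: int,
                mode: str | None = None) -> SyntheticDataset:
    """Replace one specimen's sequence with a detectable pseudogene copy.

    ``mode`` is "stop" (an in-frame stop codon is planted) or "deletion"
    (one base removed; in an aligned dataset it becomes an internal gap).
    Unset, the mode is drawn from the per-specimen stream, making injection
    idempotent per (specimen, seed). Only coding markers can host numts
    detectable this way.
    """
    rec = next((r for r in sd.dataset.records if r.specimen_id == specimen_id), None)
    if rec is None:
        raise ValidationError(f"specimen {specimen_id!r} not in dataset")
    if not rec.marker.is_coding:
        raise ValidationError(
            f"cannot inject a numt into non-coding marker {rec.marker.value}"
        )
    rng = _record_rng(seed, specimen_id)
    if mode is None:
        mode = "stop" if rng.random() < 0.5 else "deletion"
    elif mode not in ("stop", "deletion"):
        raise ValidationError(f"mode must be 'stop' or 'deletion', got {mode!r}")
    seq = rec.sequence
    n_codons = len(seq) // 3
    if mode == "stop":
        codon = int(rng.integers(1, max(2, n_codons - 1)))  # keep ends intact
        pos = codon * 3
        new_seq = seq[:pos] + "TAA" + seq[pos + 3:]
    else:
        pos = int(rng.integers(3, len(seq) - 3))
        if sd.dataset.alignment_length is not None:
            new_seq = seq[:pos] + "-" + seq[pos + 1:]
        else:
            new_seq = seq[:pos] + seq[pos + 1:]
    dataset = _replace_record(sd, specimen_id, new_seq)
    truth = dict(sd.truth)
    numts = list(truth.get("numt_ids", []))
    if specimen_id not in numts:
        numts.append(specimen_id)
    truth["numt_ids"] = numts
    return SyntheticDataset(dataset, truth)


def plant_deep_split(sd: SyntheticDataset, species: str, extra_divergence: float,
                     seed: int = 0, kappa: float = 2.0) -> SyntheticDataset:
    """Give half of a species' specimens extra divergence (a deep split).

    Models lineages with restricted gene flow whose maximum intraspecific
    distance breaches the barcode filter. ``extra_divergence`` 0 returns the
    dataset unchanged.
    """
    if extra_divergence < 0:
        raise ValidationError("extra_divergence must be non-negative")
    members = [r for r in sd.dataset.records if r.species == species]
    if not members:
        raise ValidationError(f"species {species!r} not in dataset")
    if len(members) < 2:
        raise ValidationError(
            f"deep split requires >=2 specimens of {species!r}, found {len(members)}"
        )
    if extra_divergence == 0:
        return sd
    half = members[: len(members) // 2]
    dataset = sd.dataset
    coding = members[0].marker.is_coding
    out = SyntheticDataset(dataset, dict(sd.truth))
    for rec in half:
        rng = _record_rng(seed, rec.specimen_id)
        new_seq = evolve_sequence(rec.sequence, extra_divergence, kappa, rng,
                                  coding=coding)
        out = SyntheticDataset(_replace_record(out, rec.specimen_id, new_seq),
                               out.truth)
    truth = dict(out.truth)
    splits = dict(truth.get("deep_splits", {}))
    splits[species] = {
        "extra_divergence": extra_divergence,
        "shifted_ids": [r.specimen_id for r in half],
    }
    truth["deep_splits"] = splits
    return SyntheticDataset(out.dataset, truth)


def plant_diagnostic_columns(sd: SyntheticDataset, species: str, n_columns: int,
                             seed: int = 0) -> SyntheticDataset:
    """Fix ``n_columns`` random columns to a state unique to one species.

    At each chosen column every target specimen receives one base and every
    other specimen a different base, making the column a pure diagnostic for
    the target by construction. Columns are recorded in truth (1-based).
    """
    if sd.dataset.alignment_length is None:
        raise ValidationError("diagnostic planting requires an aligned dataset")
    tax = sd.dataset.taxonomy
    if species not in set(tax["species"]):
        raise ValidationError(f"species {species!r} not in dataset")
    rng = np.random.default_rng([seed, zlib.crc32(species.encode())])
    L = sd.dataset.alignment_length
    if n_columns > L:
        raise ValidationError("more diagnostic columns requested than sites")
    cols = sorted(rng.choice(L, size=n_columns, replace=False).tolist())
    target_base, other_base = (str(b) for b in rng.choice(_BASES, 2, replace=False))
    records = []
    for r in sd.dataset.records:
        seq = list(r.sequence)
        base = target_base if r.species == species else other_base
        for c in cols:
            seq[c] = base
        records.append(dataclasses.replace(r, sequence="".join(seq)))
    truth = dict(sd.truth)
    diag = dict(truth.get("diagnostic_columns", {}))
    diag[species] = {
        "columns": [c + 1 for c in cols],
        "target_state": target_base,
        "background_state": other_base,
    }
    truth["diagnostic_columns"] = diag
    return SyntheticDataset(Dataset(records), truth)


def write_synthetic(sd: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + taxonomy TSV + truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(paths["fasta"], sd.dataset)
    write_taxonomy(paths["taxonomy"], sd.dataset)
    with open(paths["truth"], "w") as fh:
        json.dump(sd.truth, fh, indent=2)
    return paths
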