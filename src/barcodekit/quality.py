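"""Numt / pseudogene screening for protein-coding barcode sequences.

Nuclear copies of mitochondrial genes (numts) co-amplify with the target
locus and betray themselves through in-frame stop codons or frameshifting
indels. Screening translates each sequence with the vertebrate mitochondrial
code and flags stop codons, internal alignment gaps, and lengths not
congruent (mod 3) with the dataset mode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .errors import ValidationError
from .seqio import Dataset, SpecimenRecord

__all__ = ["QCReport", "translate", "detect_frame", "screen_numt",
           "screen_dataset", "write_qc_tsv"]

# NCBI translation table 2. Stops: TAA, TAG, AGA, AGG.
_VMT = CodonTable.unambiguous_dna_by_id[2]
_CODON_MAP: dict[str, str] = dict(_VMT.forward_table)
_CODON_MAP.update({c: "*" for c in _VMT.stop_codons})


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the vertebrate mitochondrial code.

    Codons containing a gap or ambiguity code yield 'X'; stops yield '*'.
    The trailing partial codon, if any, is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValidationError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    aa = []
    for i in range(frame, len(seq) - 2, 3):
        aa.append(_CODON_MAP.get(seq[i : i + 3], "X"))
    return "".join(aa)


def _count_stops(seq: str, frame: int) -> int:
    return translate(seq, frame).count("*")


def _degap(seq: str) -> str:
    return seq.replace("-", "")


def _has_internal_gap(seq: str) -> bool:
    core = seq.strip("-")
    return "-" in core


def detect_frame(sequences: list[str]) -> int:
    """Reading frame under which the most sequences translate stop-free.

    Ties resolve to the lowest frame. Applied dataset-wide so a frameshifted
    numt cannot pick its own convenient frame.
    """
    best_frame, best_clean = 0, -1
    for frame in (0, 1, 2):
        clean = sum(1 for s in sequences if _count_stops(_degap(s), frame) == 0)
        if clean > best_clean:
            best_frame, best_clean = frame, clean
    return best_frame


@dataclass(frozen=True)
class QCReport:
    """Per-specimen numt screen result.

    verdict is ``pass`` iff there is no stop codon, no internal gap, and the
    ungapped length is congruent mod 3 with the dataset's modal length.
    """

    specimen_id: str
    reading_frame_used: int
    has_stop_codon: bool
    has_internal_gap: bool
    length_offset_mod3: int
    verdict: str

    @staticmethod
    def evaluate(record: SpecimenRecord, frame: int, expected_length: int) -> "QCReport":
        seq = record.sequence
        ungapped = _degap(seq)
        if len(ungapped) < 3:
            raise ValidationError(
                f"{record.specimen_id}: sequence shorter than one codon"
            )
        offset = (len(ungapped) - expected_length) % 3
        stop = _count_stops(ungapped, frame) > 0
        gap = _has_internal_gap(seq)
        verdict = "pass" if not (stop or gap or offset) else "suspect_numt"
        return QCReport(record.specimen_id, frame, stop, gap, offset, verdict)


def screen_numt(record: SpecimenRecord, reference_frame: int | None = None,
                expected_length: int | None = None) -> QCReport:
    """Screen a single protein-coding record.

    Without a ``reference_frame`` the frame minimizing stop codons in this
    record is used; without an ``expected_length`` the record's own ungapped
    length is the reference (so length_offset_mod3 = 0).
    """
    if not record.marker.is_coding:
        raise ValidationError(
            f"numt screening applies to coding markers only, not {record.marker.value}"
        )
    ungapped = _degap(record.sequence)
    if len(ungapped) < 3:
        raise ValidationError(f"{record.specimen_id}: sequence shorter than one codon")
    if reference_frame is None:
        reference_frame = min((_count_stops(ungapped, f), f) for f in (0, 1, 2))[1]
    if expected_length is None:
        expected_length = len(ungapped)
    return QCReport.evaluate(record, reference_frame, expected_length)


def screen_dataset(dataset: Dataset,
                   reference_frame: int | None = None) -> tuple[list[QCReport], dict]:
    """Screen every record of a coding dataset.

    The reading frame is auto-detected dataset-wide (frame under which the
    most records are stop-free) and the modal ungapped length anchors the
    mod-3 congruence test. Returns per-record reports plus summary counts.
    """
    if not dataset.marker.is_coding:
        raise ValidationError(
            f"numt screening applies to coding markers only, not {dataset.marker.value}"
        )
    seqs = [r.sequence for r in dataset.records]
    frame = detect_frame(seqs) if reference_frame is None else reference_frame
    modal_length = Counter(len(_degap(s)) for s in seqs).most_common(1)[0][0]
    reports = [QCReport.evaluate(r, frame, modal_length) for r in dataset.records]
    n_suspect = sum(r.verdict == "suspect_numt" for r in reports)
    summary = {
        "n_records": len(reports),
        "n_pass": len(reports) - n_suspect,
        "n_suspect_numt": n_suspect,
        "reading_frame": frame,
        "modal_length": modal_length,
    }
    return reports, summary


def write_qc_tsv(reports: list[QCReport], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in reports]).to_csv(path, sep="\t", index=False)
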