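"""Composition screening of long intrinsically disordered regions.

Extracts maximal runs of high-disorder residues from per-residue score
tracks, censuses each sequence's IDR residue composition (aromatic W/F/Y,
positive K/R, negative D/E, histidine tallied separately), classifies
sequences by aromatic richness and net IDR charge, and summarizes cohort
proportions.

Classification rules and defaults mirror the published galectin-3 homolog
screen: an IDR must span strictly more than 50 consecutive residues at
disorder score >= 0.5; a sequence is aromatic-rich when the aromatic
fraction of its IDR residues strictly exceeds 9% (the summed proteome-wide
averages of W 1.5%, Y 3.5%, F 4.0%); net-negative IDRs with a D+E fraction
strictly below 3% are flagged "negative-sparse" — the composition signature
of galectin-3's own N-terminal domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_io import AlignmentError, DisorderTrack, ProteinRecord

logger = logging.getLogger(__name__)

AROMATIC = frozenset("WFY")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: Proteome-wide average aromatic residue frequencies (fractions):
#: tryptophan 1.5%, tyrosine 3.5%, phenylalanine 4.0%; their sum defines
#: the aromatic-richness cutoff.
PROTEOME_AROMATIC_FREQS = {"W": 0.015, "Y": 0.035, "F": 0.040}


class PipelineError(RuntimeError):
    """Screen-level failure (e.g. no record has a usable track)."""


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs for IDR extraction and composition classification.

    Parameters
    ----------
    disorder_threshold : residues with score >= this are called disordered.
    min_idr_length : segment qualifies when strictly longer than this.
    aromatic_rich_threshold : strict lower bound on f_aromatic.
    negative_sparse_threshold : strict upper bound on f_negative.
    """

    disorder_threshold: float = 0.5
    min_idr_length: int = 50
    aromatic_rich_threshold: float = sum(PROTEOME_AROMATIC_FREQS.values())
    negative_sparse_threshold: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 <= self.disorder_threshold <= 1.0):
            raise ValueError("disorder_threshold must be in [0, 1]")
        if self.min_idr_length < 1:
            raise ValueError("min_idr_length must be >= 1")
        for name in ("aromatic_rich_threshold", "negative_sparse_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class IDRSegment:
    """A maximal disordered run, 1-based inclusive coordinates."""

    record_id: str
    start: int
    end: int
    subsequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.subsequence) != self.end - self.start + 1:
            raise ValueError("subsequence length inconsistent with span")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-class census of a sequence region.

    ``X`` residues count toward ``n_total`` but toward no class; histidine
    is tallied separately and contributes to neither charge class.
    ``net_charge`` is the formal integer count K+R minus D+E.
    """

    n_total: int
    n_aromatic: int
    n_positive: int
    n_negative: int
    n_his: int
    f_aromatic: float
    f_positive: float
    f_negative: float
    net_charge: int


@dataclass(frozen=True)
class ScreenClassification:
    """Per-sequence category flags.

    Flags other than ``has_long_idr`` are ``None`` when the sequence has
    no qualifying IDR; ``negative_sparse`` is defined only for the
    net-negative charge class.
    """

    record_id: str
    has_long_idr: bool
    aromatic_rich: bool | None = None
    charge_class: str | None = None  # net_negative | net_positive | balanced
    negative_sparse: bool | None = None


@dataclass(frozen=True)
class ScreenSummary:
    """Cohort counts and one-decimal percentages.

    Percentages of the charge/aromatic classes use ``n_long_idr`` as the
    denominator; ``pct_negative_sparse`` uses ``n_net_negative``.  When a
    denominator is zero the corresponding percentages are ``None``.
    """

    n_screened: int
    n_long_idr: int
    n_aromatic_rich: int
    n_net_negative: int
    n_net_positive: int
    n_balanced: int
    n_negative_sparse: int
    pct_long_idr: float | None
    pct_aromatic_rich: float | None
    pct_net_negative: float | None
    pct_net_positive: float | None
    pct_balanced: float | None
    pct_negative_sparse: float | None


def round_percentage(count: int, denominator: int) -> float | None:
    """100*count/denominator rounded half-away-from-zero to one decimal."""
    if denominator == 0:
        return None
    value = 100.0 * count / denominator
    # half-away-from-zero at one decimal; counts are non-negative here but
    # keep the symmetric form for reuse
    return math.floor(value * 10 + 0.5) / 10 if value >= 0 else \
        -math.floor(-value * 10 + 0.5) / 10


def extract_idrs(track: DisorderTrack, record: ProteinRecord,
                 cfg: ScreenConfig = ScreenConfig()) -> list[IDRSegment]:
    """All maximal runs of scores >= threshold strictly longer than the cutoff.

    Segments are returned in order of their start position and never
    overlap.  Raises :class:`~galphase.core_io.AlignmentError` when the
    track length does not match the sequence.
    """
    if len(track) != len(record):
        raise AlignmentError(
            f"track length {len(track)} != sequence length {len(record)} "
            f"for record {record.id!r}"
        )
    segments: list[IDRSegment] = []
    run_start: int | None = None
    for i, score in enumerate(track.scores):
        if score >= cfg.disorder_threshold:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                _maybe_append(segments, record, run_start, i - 1, cfg)
                run_start = None
    if run_start is not None:
        _maybe_append(segments, record, run_start, len(track) - 1, cfg)
    return segments


def _maybe_append(segments: list[IDRSegment], record: ProteinRecord,
                  i0: int, i1: int, cfg: ScreenConfig) -> None:
    length = i1 - i0 + 1
    if length > cfg.min_idr_length:
        segments.append(IDRSegment(
            record_id=record.id, start=i0 + 1, end=i1 + 1,
            subsequence=record.sequence[i0:i1 + 1]))


def composition(seq: str) -> CompositionProfile:
    """Exact residue-class census of an amino-acid string."""
    if not seq:
        raise ValueError("cannot census an empty sequence")
    n_aromatic = sum(seq.count(a) for a in AROMATIC)
    n_positive = sum(seq.count(a) for a in POSITIVE)
    n_negative = sum(seq.count(a) for a in NEGATIVE)
    n_his = seq.count("H")
    n_total = len(seq)
    return CompositionProfile(
        n_total=n_total,
        n_aromatic=n_aromatic,
        n_positive=n_positive,
        n_negative=n_negative,
        n_his=n_his,
        f_aromatic=n_aromatic / n_total,
        f_positive=n_positive / n_total,
        f_negative=n_negative / n_total,
        net_charge=n_positive - n_negative,
    )


def classify(record: ProteinRecord, segments: Sequence[IDRSegment],
             cfg: ScreenConfig = ScreenConfig()) -> ScreenClassification:
    """Classify one sequence from its qualifying IDR segments.

    Composition is evaluated on the concatenation of *all* qualifying
    segments.  Thresholds are strict: f_aromatic exactly at the cutoff is
    not aromatic-rich, f_negative exactly at the cutoff is not sparse,
    and net charge 0 is the balanced class.
    """
    for seg in segments:
        if seg.record_id != record.id:
            raise ValueError(
                f"segment for {seg.record_id!r} passed with record {record.id!r}"
            )
    if not segments:
        return ScreenClassification(record_id=record.id, has_long_idr=False)
    prof = composition("".join(seg.subsequence for seg in segments))
    if prof.net_charge < 0:
        charge_class = "net_negative"
        negative_sparse = prof.f_negative < cfg.negative_sparse_threshold
    elif prof.net_charge > 0:
        charge_class = "net_positive"
        negative_sparse = None
    else:
        charge_class = "balanced"
        negative_sparse = None
    return ScreenClassification(
        record_id=record.id,
        has_long_idr=True,
        aromatic_rich=prof.f_aromatic > cfg.aromatic_rich_threshold,
        charge_class=charge_class,
        negative_sparse=negative_sparse,
    )


def summarize(classifications: Sequence[ScreenClassification]) -> ScreenSummary:
    """Cohort counts and one-decimal percentages."""
    if not classifications:
        raise ValueError("cannot summarize an empty classification list")
    n_screened = len(classifications)
    with_idr = [c for c in classifications if c.has_long_idr]
    n_long_idr = len(with_idr)
    n_aromatic_rich = sum(1 for c in with_idr if c.aromatic_rich)
    n_net_negative = sum(1 for c in with_idr if c.charge_class == "net_negative")
    n_net_positive = sum(1 for c in with_idr if c.charge_class == "net_positive")
    n_balanced = sum(1 for c in with_idr if c.charge_class == "balanced")
    n_negative_sparse = sum(1 for c in with_idr if c.negative_sparse)
    return ScreenSummary(
        n_screened=n_screened,
        n_long_idr=n_long_idr,
        n_aromatic_rich=n_aromatic_rich,
        n_net_negative=n_net_negative,
        n_net_positive=n_net_positive,
        n_balanced=n_balanced,
        n_negative_sparse=n_negative_sparse,
        pct_long_idr=round_percentage(n_long_idr, n_screened),
        pct_aromatic_rich=round_percentage(n_aromatic_rich, n_long_idr),
        pct_net_negative=round_percentage(n_net_negative, n_long_idr),
        pct_net_positive=round_percentage(n_net_positive, n_long_idr),
        pct_balanced=round_percentage(n_balanced, n_long_idr),
        pct_negative_sparse=round_percentage(n_negative_sparse, n_net_negative),
    )


def run_screen(records: Sequence[ProteinRecord],
               tracks: Mapping[str, DisorderTrack],
               cfg: ScreenConfig = ScreenConfig(),
               ) -> tuple[list[ScreenClassification], ScreenSummary,
                          list[dict]]:
    """Screen a cohort: extract IDRs, classify, summarize.

    ``tracks`` maps record id -> track; records without a track are
    skipped with a log message rather than failing the run.  Returns the
    classifications, the cohort summary, and a per-record table suitable
    for :func:`~galphase.core_io.write_table`.
    """
    classifications: list[ScreenClassification] = []
    table: list[dict] = []
    n_skipped = 0
    for record in records:
        track = tracks.get(record.id)
        if track is None:
            logger.warning("record %s has no disorder track; skipped", record.id)
            n_skipped += 1
            continue
        segments = extract_idrs(track, record, cfg)
        cls = classify(record, segments, cfg)
        classifications.append(cls)
        if segments:
            prof = composition("".join(s.subsequence for s in segments))
            row = {
                "id": record.id,
                "n_idrs": len(segments),
                "idr_spans": ";".join(f"{s.start}-{s.end}" for s in segments),
                "n_idr_residues": prof.n_total,
                "f_aromatic": prof.f_aromatic,
                "f_positive": prof.f_positive,
                "f_negative": prof.f_negative,
                "net_charge": prof.net_charge,
                "aromatic_rich": cls.aromatic_rich,
                "charge_class": cls.charge_class,
                "negative_sparse": cls.negative_sparse,
            }
        else:
            row = {
                "id": record.id, "n_idrs": 0, "idr_spans": "",
                "n_idr_residues": 0, "f_aromatic": "", "f_positive": "",
                "f_negative": "", "net_charge": "", "aromatic_rich": "",
                "charge_class": "", "negative_sparse": "",
            }
        table.append(row)
    if not classifications:
        raise PipelineError(
            f"no record has a disorder track ({n_skipped} skipped)"
        )
    return classifications, summarize(classifications), table


def summary_to_dict(summary: ScreenSummary) -> dict:
    """JSON-ready dict; undefined percentages serialize as null."""
    from dataclasses import asdict

    return asdict(summary)
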