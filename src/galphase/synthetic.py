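"""Ground-truth synthetic inputs for every pipeline stage.

Each generator forward-simulates the model its analysis stage inverts, so
the whole pipeline is testable closed-loop with no external data:

* :func:`make_cohort` builds protein sequences with one designed IDR of
  controlled composition per record, disorder tracks that call exactly
  that region disordered, and a truth table of the class every record was
  designed to land in.  Class-defining residues are placed with a strict
  margin from every threshold (at least one residue's worth) so float
  rounding can never flip a designed class.
* :func:`make_titration` draws CSPs from the ligand-depletion isotherm
  plus additive Gaussian noise.
* :func:`make_decay` draws mono-exponential relaxation decays.
* :func:`make_assay` builds Bradford standards on a designed calibration
  line and total/supernatant ratio pairs realizing chosen true levels.

All randomness flows from a single spec-level seed through named
substreams, so each output can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding_nmr import RelaxationSeries, TitrationSeries, binding_isotherm
from .core_io import DisorderTrack, ProteinRecord
from .idr_screen import ScreenConfig

#: Charge- and aromatic-neutral residues used as sequence filler.
BACKGROUND_RESIDUES = "GSAPQN"
#: Default CPMG-style relaxation delays (s).
DEFAULT_DELAYS = (0.017, 0.034, 0.051, 0.068, 0.085, 0.102)


class SpecError(ValueError):
    """A generator spec is internally inconsistent or infeasible."""


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from the spec seed and a stream name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, *name.encode()])


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic screening cohort.

    Charge-class targets must sum to ``n_sequences`` minus ``n_no_idr``;
    ``n_negative_sparse`` applies within the net-negative class and
    ``n_aromatic_rich`` within all IDR-positive records.
    """

    n_sequences: int
    n_net_negative: int
    n_net_positive: int
    n_balanced: int
    n_negative_sparse: int = 0
    n_aromatic_rich: int = 0
    n_no_idr: int = 0
    idr_length_range: tuple[int, int] = (60, 120)
    folded_length_range: tuple[int, int] = (80, 140)
    idr_score: float = 0.9
    folded_score: float = 0.1
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def __post_init__(self) -> None:
        n_with_idr = self.n_sequences - self.n_no_idr
        if n_with_idr < 0:
            raise SpecError("n_no_idr exceeds n_sequences")
        if self.n_net_negative + self.n_net_positive + self.n_balanced \
                != n_with_idr:
            raise SpecError("charge-class targets must sum to the number of "
                            "IDR-positive sequences")
        if self.n_negative_sparse > self.n_net_negative:
            raise SpecError("sparse-negative count exceeds net-negative count")
        if self.n_aromatic_rich > n_with_idr:
            raise SpecError("aromatic-rich count exceeds IDR-positive count")
        lo, hi = self.idr_length_range
        if lo <= self.screen.min_idr_length and self.n_no_idr < self.n_sequences:
            # IDR-positive designs need lengths that pass the strict cutoff
            if hi <= self.screen.min_idr_length:
                raise SpecError("idr_length_range cannot satisfy the screen's "
                                "length rule for IDR-positive sequences")
        if not (0 <= self.folded_score < self.screen.disorder_threshold
                <= self.idr_score <= 1):
            raise SpecError("score levels must bracket the disorder threshold")


def _design_idr(rng: np.random.Generator, length: int, charge_class: str,
                negative_sparse: bool, aromatic_rich: bool,
                cfg: ScreenConfig) -> str:
    """One IDR sequence hitting its designed class with strict margins."""
    f_neg_thr = cfg.negative_sparse_threshold
    f_aro_thr = cfg.aromatic_rich_threshold

    if charge_class == "net_negative":
        if negative_sparse:
            n_neg = max(1, math.floor(f_neg_thr * length) - 1)
            if not n_neg / length < f_neg_thr:
                raise SpecError(f"IDR length {length} cannot host a "
                                "sparse-negative design")
            n_pos = 0
        else:
            n_neg = math.floor(f_neg_thr * length) + 2
            n_pos = int(rng.integers(0, min(2, n_neg - 1) + 1))
            assert n_neg / length > f_neg_thr
    elif charge_class == "net_positive":
        n_pos = int(rng.integers(2, 7))
        n_neg = int(rng.integers(0, n_pos))
        negative_sparse = None
    elif charge_class == "balanced":
        n_pos = n_neg = int(rng.integers(0, 5))
        negative_sparse = None
    else:
        raise SpecError(f"unknown charge class {charge_class!r}")

    if aromatic_rich:
        n_aro = math.floor(f_aro_thr * length) + 2
        assert n_aro / length > f_aro_thr
    else:
        n_aro = max(0, math.floor(f_aro_thr * length) - 1)
        if n_aro / length >= f_aro_thr:  # tiny lengths
            n_aro = 0

    n_class = n_neg + n_pos + n_aro
    if n_class > length:
        raise SpecError(f"IDR length {length} too short for class design")

    residues = list(rng.choice(list(BACKGROUND_RESIDUES), size=length))
    positions = rng.choice(length, size=n_class, replace=False)
    it = iter(positions)
    for _ in range(n_neg):
        residues[next(it)] = rng.choice(["D", "E"])
    for _ in range(n_pos):
        residues[next(it)] = rng.choice(["K", "R"])
    for _ in range(n_aro):
        residues[next(it)] = rng.choice(["W", "F", "Y"])
    return "".join(residues)


def make_cohort(spec: CohortSpec) -> tuple[list[ProteinRecord],
                                           dict[str, DisorderTrack],
                                           list[dict]]:
    """Generate records, tracks and a truth table for a designed cohort.

    Each record is a folded filler region (scores below threshold)
    followed by one designed IDR (scores above threshold); IDR-negative
    records get an IDR too short to pass the length rule.  Output order
    is a seeded shuffle so classes are not grouped.  Deterministic for a
    given spec.
    """
    rng_seq = _substream(spec.seed, "sequence")
    cfg = spec.screen
    lo, hi = spec.idr_length_range
    lo = max(lo, cfg.min_idr_length + 1)

    designs: list[tuple[str, bool | None, bool]] = []
    designs += [("net_negative", True, False)] * spec.n_negative_sparse
    designs += [("net_negative", False, False)] * (spec.n_net_negative
                                                   - spec.n_negative_sparse)
    designs += [("net_positive", None, False)] * spec.n_net_positive
    designs += [("balanced", None, False)] * spec.n_balanced
    # distribute aromatic richness across the IDR-positive designs
    rich_idx = rng_seq.choice(len(designs), size=spec.n_aromatic_rich,
                              replace=False) if designs else []
    designs = [(cc, ns, i in set(np.asarray(rich_idx).tolist()))
               for i, (cc, ns, _) in enumerate(designs)]
    designs += [("no_idr", None, False)] * spec.n_no_idr
    order = rng_seq.permutation(len(designs))

    records: list[ProteinRecord] = []
    tracks: dict[str, DisorderTrack] = {}
    truth: list[dict] = []
    for out_i, design_i in enumerate(order):
        charge_class, sparse, rich = designs[design_i]
        rid = f"syn{out_i + 1:05d}"
        folded_len = int(rng_seq.integers(spec.folded_length_range[0],
                                          spec.folded_length_range[1] + 1))
        folded = "".join(rng_seq.choice(list(BACKGROUND_RESIDUES),
                                        size=folded_len))
        if charge_class == "no_idr":
            idr_len = max(2, cfg.min_idr_length // 2)
            idr = "".join(rng_seq.choice(list(BACKGROUND_RESIDUES),
                                         size=idr_len))
            row = {"id": rid, "has_long_idr": False, "aromatic_rich": None,
                   "charge_class": None, "negative_sparse": None}
        else:
            idr_len = int(rng_seq.integers(lo, hi + 1))
            idr = _design_idr(rng_seq, idr_len, charge_class, bool(sparse),
                              rich, cfg)
            row = {"id": rid, "has_long_idr": True, "aromatic_rich": rich,
                   "charge_class": charge_class,
                   "negative_sparse": (sparse if charge_class == "net_negative"
                                       else None)}
        seq = folded + idr
        scores = (spec.folded_score,) * folded_len + \
                 (spec.idr_score,) * len(idr)
        records.append(ProteinRecord(id=rid, sequence=seq))
        tracks[rid] = DisorderTrack(record_id=rid, scores=scores)
        truth.append(row)
    return records, tracks, truth


# ---------------------------------------------------------------------------
# titration / decay / assay generation

@dataclass(frozen=True)
class TitrationSpec:
    """True binding parameters and sampling design for one titration."""

    kd: float = 100.0
    delta_max: float = 0.2
    protein_conc: float = 50.0
    ligand_concs: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0, 200.0,
                                       400.0, 800.0, 1600.0)
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd < 0 or self.delta_max <= 0 or self.protein_conc <= 0:
            raise SpecError("kd >= 0, delta_max > 0, protein_conc > 0 required")
        if any(l < 0 for l in self.ligand_concs):
            raise SpecError("ligand concentrations must be non-negative")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def make_titration(spec: TitrationSpec) -> tuple[TitrationSeries, dict]:
    """Observed CSPs = isotherm(truth) + Gaussian noise; returns truth echo."""
    rng = _substream(spec.seed, "titration-noise")
    lig = np.asarray(spec.ligand_concs, dtype=float)
    clean = binding_isotherm(spec.kd, spec.delta_max, spec.protein_conc, lig)
    observed = clean + rng.normal(0.0, spec.noise_sd, size=lig.size) \
        if spec.noise_sd > 0 else clean
    series = TitrationSeries(protein_conc=spec.protein_conc,
                             ligand_concs=tuple(lig.tolist()),
                             observed=tuple(np.asarray(observed).tolist()))
    truth = {"kd": spec.kd, "delta_max": spec.delta_max,
             "protein_conc": spec.protein_conc, "noise_sd": spec.noise_sd,
             "seed": spec.seed}
    return series, truth


@dataclass(frozen=True)
class DecaySpec:
    """True relaxation parameters for one peak's decay series."""

    r2: float = 12.0
    i0: float = 100.0
    delays: tuple[float, ...] = DEFAULT_DELAYS
    noise_sd: float = 1.0
    seed: int = 0
    peak_id: str = "peak"

    def __post_init__(self) -> None:
        if self.r2 <= 0 or self.i0 <= 0:
            raise SpecError("r2 and i0 must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def make_decay(spec: DecaySpec) -> tuple[RelaxationSeries, dict]:
    """Intensities = i0*exp(-r2*t) + Gaussian noise; returns truth echo."""
    rng = _substream(spec.seed, "decay-noise")
    t = np.asarray(spec.delays, dtype=float)
    clean = spec.i0 * np.exp(-spec.r2 * t)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.size) \
        if spec.noise_sd > 0 else clean
    series = RelaxationSeries(
        peak_id=spec.peak_id, delays=tuple(t.tolist()),
        intensities=tuple(np.maximum(noisy, 1e-9).tolist()),
        noise_sd=max(spec.noise_sd, 1e-12))
    truth = {"r2": spec.r2, "i0": spec.i0, "noise_sd": spec.noise_sd,
             "seed": spec.seed}
    return series, truth


@dataclass(frozen=True)
class AssaySpec:
    """True sedimentation levels and Bradford calibration design.

    ``true_levels`` maps condition label -> designed level in [0, 1];
    ratios are produced through the designed calibration line with
    additive Gaussian ratio noise.
    """

    true_levels: tuple[tuple[str, float], ...] = (("WT", 0.8),)
    total_conc: float = 20.0
    n_replicates: int = 3
    slope: float = 0.05
    intercept: float = 0.40
    standard_concs: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0)
    ratio_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, lvl in self.true_levels:
            if not (0.0 <= lvl <= 1.0):
                raise SpecError(f"true level {lvl} for {label!r} outside [0, 1]")
        if self.total_conc <= 0 or self.n_replicates < 1:
            raise SpecError("total_conc > 0 and n_replicates >= 1 required")
        if self.ratio_noise_sd < 0:
            raise SpecError("ratio_noise_sd must be non-negative")


def make_assay(spec: AssaySpec) -> tuple[list[tuple[float, float]],
                                         list[dict], dict]:
    """Standards table, per-replicate measurement rows, and truth echo.

    Measurement rows carry (label, replicate, total_ratio,
    supernatant_ratio); supernatant concentration realizes
    ``total * (1 - true_level)`` before ratio noise.
    """
    rng = _substream(spec.seed, "assay-noise")
    standards = []
    for conc in spec.standard_concs:
        ratio = spec.slope * conc + spec.intercept
        if spec.ratio_noise_sd > 0:
            ratio += rng.normal(0.0, spec.ratio_noise_sd)
        standards.append((float(conc), float(ratio)))
    rows: list[dict] = []
    for label, lvl in spec.true_levels:
        sup_conc = spec.total_conc * (1.0 - lvl)
        for rep in range(1, spec.n_replicates + 1):
            tr = spec.slope * spec.total_conc + spec.intercept
            sr = spec.slope * sup_conc + spec.intercept
            if spec.ratio_noise_sd > 0:
                tr += rng.normal(0.0, spec.ratio_noise_sd)
                sr += rng.normal(0.0, spec.ratio_noise_sd)
            rows.append({"label": label, "replicate": rep,
                         "total_ratio": float(tr),
                         "supernatant_ratio": float(sr)})
    truth = {"true_levels": dict(spec.true_levels),
             "total_conc": spec.total_conc, "slope": spec.slope,
             "intercept": spec.intercept,
             "ratio_noise_sd": spec.ratio_noise_sd, "seed": spec.seed}
    return standards, rows, truth
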