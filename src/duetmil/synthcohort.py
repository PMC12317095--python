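"""Synthetic paired-modality cohorts with rule-consistent labels and outcomes.

Every downstream stage of the pipeline (tessellation, encoding, transformer
aggregation, evaluation, explainability, survival) is testable against
cohorts produced here, without any external data. A cohort consists of
:class:`PairedCase` records: an H&E embedding bag and an IHC embedding bag
with a planted class signal, a raw label-generating assay measurement
(microsatellite locus counts or PD-L1 cell counts), scanner/site covariates
applied as additive embedding shifts, and a claims-style outcome record.

Label-generating rules implemented here are the clinical scoring rules:

* MSI by altered-locus count: >=116 MSI-H, 113-115 equivocal, <=112 MSS.
* PD-L1 Combined Positive Score: 100 x positive cells / viable tumor cells
  (capped at 100), positive iff CPS >= 10.

Measurements are drawn from status-conditional over-dispersed count
distributions and rejection-sampled so the rule-derived label always equals
the latent status that drives the planted embedding signal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tileenc import EMBED_DIM, EmbeddingBag

MSI_H_MIN_LOCI = 116
MSS_MAX_LOCI = 112
CPS_POSITIVE_CUT = 10.0


class Assay(str, enum.Enum):
    MSI_LOCI = "MSI_LOCI"
    CPS = "CPS"


class MsiStatus(str, enum.Enum):
    MSI_H = "MSI_H"
    EQUIVOCAL = "EQUIVOCAL"
    MSS = "MSS"


class Pdl1Status(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


def assign_msi_label(loci_altered: int) -> MsiStatus:
    """Microsatellite call from the number of altered loci.

    116 or more altered loci is MSI-high, 113-115 equivocal, 112 or fewer
    microsatellite stable.
    """
    if loci_altered < 0:
        raise ValueError("loci_altered must be non-negative")
    if loci_altered >= MSI_H_MIN_LOCI:
        return MsiStatus.MSI_H
    if loci_altered > MSS_MAX_LOCI:
        return MsiStatus.EQUIVOCAL
    return MsiStatus.MSS


def compute_cps(pdl1_positive_cells: int, viable_tumor_cells: int) -> float:
    """Combined Positive Score: 100 x positive cells / viable tumor cells.

    The numerator counts PD-L1-positive tumor cells, lymphocytes and
    macrophages, so the raw ratio can exceed 1; the score is capped at 100,
    the clinical convention.
    """
    if viable_tumor_cells < 1:
        raise ValueError("viable_tumor_cells must be >= 1")
    if pdl1_positive_cells < 0:
        raise ValueError("pdl1_positive_cells must be non-negative")
    return min(100.0, 100.0 * pdl1_positive_cells / viable_tumor_cells)


def assign_pdl1_label(cps: float) -> Pdl1Status:
    """PD-L1 positivity: positive iff CPS >= 10."""
    if not 0.0 <= cps <= 100.0:
        raise ValueError("cps must lie in [0, 100]")
    return Pdl1Status.POSITIVE if cps >= CPS_POSITIVE_CUT else Pdl1Status.NEGATIVE


@dataclass(frozen=True)
class LabelMeasurement:
    """Raw assay measurement from which the case label is derived."""

    assay: Assay
    loci_altered: int | None = None
    pdl1_positive_cells: int | None = None
    viable_tumor_cells: int | None = None

    def label_positive(self) -> bool:
        if self.assay == Assay.MSI_LOCI:
            return assign_msi_label(self.loci_altered) == MsiStatus.MSI_H
        cps = compute_cps(self.pdl1_positive_cells, self.viable_tumor_cells)
        return assign_pdl1_label(cps) == Pdl1Status.POSITIVE

    def equivocal(self) -> bool:
        return (
            self.assay == Assay.MSI_LOCI
            and assign_msi_label(self.loci_altered) == MsiStatus.EQUIVOCAL
        )


@dataclass(frozen=True)
class OutcomeParams:
    """Exponential two-arm outcome model for the claims simulator.

    ``base_event_rate`` is the daily event hazard in the biomarker-negative
    arm; positives have hazard ``base_event_rate * exp(log_hr)``. ``log_hr``
    of ln(0.5) makes the biomarker protective. ``censor_rate`` is the daily
    hazard of administrative loss to follow-up.
    """

    base_event_rate: float = 1.0 / 300.0
    log_hr: float = float(np.log(0.5))
    censor_rate: float = 1.0 / 600.0
    death_recorded_prob: float = 0.5  # chance a death appears in the RWE feed

    def __post_init__(self) -> None:
        if self.base_event_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("event and censor rates must be positive")


@dataclass(frozen=True)
class OutcomeRecord:
    """Claims-style follow-up for one treated patient (day indices)."""

    first_admin_day: int
    last_admin_day: int
    last_claim_day: int
    refresh_day: int
    death_day: int | None = None

    def __post_init__(self) -> None:
        if not (self.first_admin_day <= self.last_admin_day <= self.last_claim_day <= self.refresh_day):
            raise ValueError("day indices must satisfy first <= last admin <= last claim <= refresh")
        if self.death_day is not None and self.death_day < self.first_admin_day:
            raise ValueError("death_day must not precede treatment start")


@dataclass
class PairedCase:
    """One patient: paired slide bags, label, measurement, covariates, outcome."""

    case_id: str
    status: int  # latent binary biomarker status (1 = positive/deficient)
    he_bag: EmbeddingBag | None
    ihc_bag: EmbeddingBag | None
    measurement: LabelMeasurement
    scanner: str
    site: str
    outcome: OutcomeRecord
    signal_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def label(self) -> int:
        return int(self.measurement.label_positive())


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the study conditions.

    The H&E and IHC signal subspaces are disjoint coordinate blocks
    (``[0, d_sig)`` and ``[d_sig, 2*d_sig)``) so each modality carries
    complementary information: a single-stain model can at best use half
    the planted separation, the duet model all of it.
    """

    n_cases: int = 300
    prevalence: float = 0.17
    tiles_per_slide_range: tuple[int, int] = (8, 32)
    signal_fraction: float = 0.35
    d_sig: int = 8
    effect_he: np.ndarray | None = None  # defaults to 1.5 per signal coordinate
    effect_ihc: np.ndarray | None = None
    embed_dim: int = EMBED_DIM
    scanner_shift: float = 0.2  # L2 norm of the per-scanner embedding offset
    site_shift: float = 0.2
    site_noise_scale: dict[str, float] = field(default_factory=dict)  # per-site noise multiplier
    assay: Assay = Assay.MSI_LOCI
    equivocal_rate: float = 0.0
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for p in (self.prevalence, self.signal_fraction, self.equivocal_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.tiles_per_slide_range
        if lo < 1 or hi < lo:
            raise ValueError("tiles_per_slide_range must be a valid interval with lower bound >= 1")
        if 2 * self.d_sig > self.embed_dim:
            raise ValueError("signal blocks exceed the embedding width")
        for eff in (self.effect_he, self.effect_ihc):
            if eff is not None:
                eff = np.asarray(eff, dtype=float)
                if eff.shape != (self.d_sig,) or not np.isfinite(eff).all():
                    raise ValueError("effect vectors must be finite with length d_sig")

    def effect(self, modality: str) -> np.ndarray:
        eff = self.effect_he if modality == "HE" else self.effect_ihc
        if eff is None:
            return np.full(self.d_sig, 1.5)
        return np.asarray(eff, dtype=float)

    def signal_block(self, modality: str) -> slice:
        return slice(0, self.d_sig) if modality == "HE" else slice(self.d_sig, 2 * self.d_sig)


SCANNERS = ("scannerA", "scannerB")
SITES = ("primary", "metastatic")


def _offset_vector(rng: np.random.Generator, dim: int, norm: float) -> np.ndarray:
    v = rng.standard_normal(dim)
    n = np.linalg.norm(v)
    return (v / n * norm) if n > 0 else v


def _draw_measurement(rng: np.random.Generator, status: int, assay: Assay,
                      equivocal: bool) -> LabelMeasurement:
    """Status-conditional over-dispersed counts, rejection-sampled onto the
    correct side of the clinical cut so rule-derived label == latent status."""
    if assay == Assay.MSI_LOCI:
        if equivocal:
            return LabelMeasurement(assay, loci_altered=int(rng.integers(113, 116)))
        # negative binomial: n dispersion, mean mu -> p = n / (n + mu)
        mu, disp = (150.0, 20.0) if status else (60.0, 10.0)
        while True:
            k = int(rng.negative_binomial(disp, disp / (disp + mu)))
            if status and k >= MSI_H_MIN_LOCI:
                return LabelMeasurement(assay, loci_altered=k)
            if not status and k <= MSS_MAX_LOCI:
                return LabelMeasurement(assay, loci_altered=k)
    viable = int(rng.poisson(200)) + 1
    rate = 0.30 if status else 0.04
    while True:
        pos = int(rng.poisson(rate * viable))
        cps = compute_cps(pos, viable)
        if (cps >= CPS_POSITIVE_CUT) == bool(status):
            return LabelMeasurement(assay, pdl1_positive_cells=pos, viable_tumor_cells=viable)


def simulate_outcomes(status: int, params: OutcomeParams,
                      rng: np.random.Generator | int) -> OutcomeRecord:
    """Simulate one patient's claims trail under an exponential two-arm model.

    The survival time T is exponential with hazard
    ``base_event_rate * exp(log_hr * status)``; an independent exponential
    censoring time C is drawn at ``censor_rate``. If the event comes first it
    is either recorded as an explicit death date or left to be inferred from
    a >100-day claims gap; if censoring comes first the claims trail stays
    within 100 days of the data refresh.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    haz = params.base_event_rate * np.exp(params.log_hr * status)
    t_event = rng.exponential(1.0 / haz)
    t_censor = rng.exponential(1.0 / params.censor_rate)
    first = 0
    t = max(1, int(round(min(t_event, t_censor))))
    last_admin = max(first, int(np.floor(t * rng.uniform(0.5, 1.0))))
    if t_event <= t_censor:  # death
        last_claim = t
        if rng.uniform() < params.death_recorded_prob:
            return OutcomeRecord(first, last_admin, last_claim,
                                 refresh_day=last_claim + int(rng.integers(0, 100)),
                                 death_day=t)
        # presumed death through the claims gap rule (> 100 days silent)
        return OutcomeRecord(first, last_admin, last_claim,
                             refresh_day=last_claim + int(rng.integers(101, 200)))
    # censored: recent contact relative to the refresh
    return OutcomeRecord(first, last_admin, t, refresh_day=t + int(rng.integers(0, 100)))


def _make_bag(rng: np.random.Generator, cfg: SynthConfig, case_id: str, modality: str,
              status: int, n_tiles: int, scanner: str, site: str,
              offsets: dict[str, np.ndarray], signal_idx: np.ndarray) -> EmbeddingBag:
    emb = rng.standard_normal((n_tiles, cfg.embed_dim))
    emb *= cfg.site_noise_scale.get(site, 1.0)
    if status and signal_idx.size:
        emb[np.ix_(signal_idx, np.arange(cfg.embed_dim)[cfg.signal_block(modality)])] += cfg.effect(modality)
    emb += offsets[f"scanner:{scanner}"] + offsets[f"site:{site}"]
    ts = 224
    side = int(np.ceil(np.sqrt(n_tiles)))
    boxes = np.array([[(i % side) * ts, (i // side) * ts, ts, ts] for i in range(n_tiles)],
                     dtype=np.int64)
    return EmbeddingBag(case_id, modality, emb.astype(np.float32), boxes,
                        scanner=scanner, site=site)


def generate_cohort(cfg: SynthConfig) -> list[PairedCase]:
    """Generate a reproducible paired-modality cohort.

    For each case a latent binary status is drawn at ``cfg.prevalence``. Both
    modality bags share the same signal-tile indices (the same tissue regions
    carry the phenotype in both stains) but the mean shift lives in disjoint
    coordinate blocks per modality. Scanner and site are assigned uniformly
    and enter as additive constant offsets; the measurement and outcome are
    drawn conditionally on status. Identical configs give byte-identical
    cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    off_rng = np.random.default_rng(cfg.seed + 1)
    offsets = {}
    for s in SCANNERS:
        offsets[f"scanner:{s}"] = _offset_vector(off_rng, cfg.embed_dim, cfg.scanner_shift)
    for s in SITES:
        offsets[f"site:{s}"] = _offset_vector(off_rng, cfg.embed_dim, cfg.site_shift)

    cases: list[PairedCase] = []
    for i in range(cfg.n_cases):
        cid = f"case{i:05d}"
        status = int(rng.uniform() < cfg.prevalence)
        equivocal = cfg.assay == Assay.MSI_LOCI and rng.uniform() < cfg.equivocal_rate
        scanner = SCANNERS[int(rng.integers(len(SCANNERS)))]
        site = SITES[int(rng.integers(len(SITES)))]
        lo, hi = cfg.tiles_per_slide_range
        n_tiles = int(rng.integers(lo, hi + 1))
        n_sig = int(round(cfg.signal_fraction * n_tiles)) if status else 0
        signal_idx = np.sort(rng.choice(n_tiles, size=n_sig, replace=False)) if n_sig else np.array([], dtype=int)
        he = _make_bag(rng, cfg, cid, "HE", status, n_tiles, scanner, site, offsets, signal_idx)
        ihc = _make_bag(rng, cfg, cid, "IHC", status, n_tiles, scanner, site, offsets, signal_idx)
        meas = _draw_measurement(rng, status, cfg.assay, equivocal)
        outcome = simulate_outcomes(status, cfg.outcome_params, rng)
        cases.append(PairedCase(cid, status, he, ihc, meas, scanner, site, outcome,
                                signal_tiles=signal_idx))
    return cases


def drop_equivocal(cases: list[PairedCase]) -> list[PairedCase]:
    """Exclude equivocal/indeterminate assay results before modeling."""
    return [c for c in cases if not c.measurement.equivocal()]


def cohort_manifest(cases: list[PairedCase]) -> pd.DataFrame:
    """Tabular cohort summary (one row per case)."""
    rows = []
    for c in cases:
        m = c.measurement
        rows.append({
            "case_id": c.case_id,
            "label": c.label,
            "status": c.status,
            "assay": m.assay.value,
            "loci_altered": m.loci_altered,
            "pdl1_positive_cells": m.pdl1_positive_cells,
            "viable_tumor_cells": m.viable_tumor_cells,
            "scanner": c.scanner,
            "site": c.site,
            "n_tiles": c.he_bag.n_tiles if c.he_bag is not None else 0,
            "first_admin_day": c.outcome.first_admin_day,
            "last_admin_day": c.outcome.last_admin_day,
            "last_claim_day": c.outcome.last_claim_day,
            "refresh_day": c.outcome.refresh_day,
            "death_day": c.outcome.death_day,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image rendering (desk-scale stand-ins for scanned slides)

HE_TISSUE = np.array([225, 160, 205], dtype=float)  # eosin pink
IHC_TISSUE = np.array([205, 170, 140], dtype=float)  # DAB-ish tan
SIGNAL_DOT = np.array([90, 60, 110], dtype=float)  # dark chromatin-like dots


def _paint_rect(img, mask, x0, y0, w, h, color_vec, rng, noise=6.0):
    h_img, w_img = img.shape[:2]
    x1, y1 = min(x0 + w, w_img), min(y0 + h, h_img)
    if x1 <= x0 or y1 <= y0:
        return
    patch = color_vec + rng.standard_normal((y1 - y0, x1 - x0, 3)) * noise
    img[y0:y1, x0:x1] = np.clip(patch, 0, 255)
    mask[y0:y1, x0:x1] = True


def render_synthetic_slide(
    case: PairedCase,
    dims: tuple[int, int] = (448, 448),
    tile_size: int = 224,
    blobs: list[dict] | None = None,
    n_blobs: int | None = None,
    seed: int | None = None,
):
    """Render a small H&E-like / IHC-like image pair plus ground-truth mask.

    Tissue is painted as rectangular blobs on a white background; positive
    cases get dark nuclear-like dots sprinkled into their tissue (a texture
    the toy encoder separates from plain stain). ``blobs`` may pin exact
    rectangles ``{"x0", "y0", "w", "h"}`` for geometry tests; otherwise
    ``n_blobs`` random tile-aligned rectangles are placed. Deterministic for
    a fixed seed; dims must fit at least one tile.
    """
    h, w = dims
    if h < tile_size or w < tile_size:
        raise ValueError("dims must fit at least one tile")
    rng = np.random.default_rng(hash(case.case_id) % (2**31) if seed is None else seed)
    he = np.full((h, w, 3), 255.0)
    ihc = np.full((h, w, 3), 255.0)
    mask = np.zeros((h, w), dtype=bool)
    if blobs is None:
        k = 2 if n_blobs is None else n_blobs
        blobs = []
        for _ in range(k):
            bw = int(rng.integers(1, max(2, w // tile_size + 1))) * tile_size
            bh = int(rng.integers(1, max(2, h // tile_size + 1))) * tile_size
            x0 = int(rng.integers(0, max(1, w - bw + 1)))
            y0 = int(rng.integers(0, max(1, h - bh + 1)))
            blobs.append({"x0": x0, "y0": y0, "w": bw, "h": bh})
    for b in blobs:
        _paint_rect(he, mask, b["x0"], b["y0"], b["w"], b["h"], HE_TISSUE, rng)
        _paint_rect(ihc, np.zeros_like(mask), b["x0"], b["y0"], b["w"], b["h"], IHC_TISSUE, rng)
    if case.status:
        ys, xs = np.where(mask)
        n_dots = ys.size // 40
        if n_dots:
            pick = rng.choice(ys.size, size=n_dots, replace=False)
            for p in pick:
                _paint_rect(he, mask, int(xs[p]), int(ys[p]), 3, 3, SIGNAL_DOT, rng, noise=2.0)
                _paint_rect(ihc, mask, int(xs[p]), int(ys[p]), 3, 3, SIGNAL_DOT, rng, noise=2.0)
    return he.astype(np.uint8), ihc.astype(np.uint8), mask
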