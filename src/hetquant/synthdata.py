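"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure its downstream analysis
assumes, so parameter recovery can be checked against the generating truth:

* mitotic-spread images — paired Gaussian centromere spots sitting on
  DNA-positive pericentric discs and dim chromosome arms, with a
  condition-dependent measurement-channel amplitude;
* FRAP traces — single-exponential recovery with a plateau (the mobile
  fraction), a bleach-depth floor, and per-frame acquisition photobleaching
  applied multiplicatively to both the ROI and the whole-nucleus signal;
* binding titrations — Hill isotherms sampled on geometric dilution series
  (probe assumed well below Kd, so free ligand ~ total);
* repeat-family count tables — multinomial read counts for a control and a
  knockout sample with a few truly enriched repeat types;
* qPCR Ct tables — cycle thresholds from the exponential-amplification
  signal model ``signal = expAmp**(-Ct)``, with optional minus-RT background
  and standard-curve dilution series.

All generators are seed-deterministic: the same spec and seed give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .imagequant import MultiChannelImage
from .frapkit import FrapTrace

__all__ = [
    "SpreadImageSpec",
    "FrapTraceSpec",
    "TitrationSpec",
    "RepeatTableSpec",
    "CtTableSpec",
    "make_spread_images",
    "make_frap_trace",
    "make_titration",
    "make_repeat_table",
    "make_ct_table",
]


# ---------------------------------------------------------------------------
# chromosome-spread images
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpreadImageSpec:
    """Parameters of a synthetic mitotic-spread image.

    Channels are rendered in the order ``dna``, ``measure``, ``marker``.
    Sister-centromere pairs are placed uniformly at random with a minimum
    inter-pair spacing; each centromere is a 2-D Gaussian spot
    (``sigma = spot_radius / 2``) in the marker channel, sitting on a
    pericentric disc that is bright in the DNA channel and carries the
    condition-dependent measurement-channel amplitude. A dim elongated
    chromosome arm through each pair makes the DNA segmentation non-trivial.
    """

    shape: tuple[int, int] = (256, 256)
    n_pairs: int = 10
    pair_dist_mean: float = 8.0
    pair_dist_sd: float = 1.0
    spot_radius: float = 3.0
    marker_amp: float = 1000.0
    peri_radius: float = 12.0
    dna_amp: float = 500.0
    measure_amp: float = 800.0
    arm_amp: float = 150.0
    noise_sd: float = 20.0
    min_pair_spacing: float = 40.0
    margin: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("marker_amp", "dna_amp", "measure_amp", "arm_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.pair_dist_mean <= 0 or self.pair_dist_sd < 0:
            raise ValueError("pair distance mean must be > 0 and sd >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spot_radius <= 0 or self.peri_radius <= 0:
            raise ValueError("spot_radius and peri_radius must be > 0")


_MAX_PLACEMENT_TRIES = 2000


def _place_pairs(spec: SpreadImageSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place pair centroids with rejection sampling on the spacing constraint."""
    h, w = spec.shape
    lo_r, hi_r = spec.margin, h - spec.margin
    lo_c, hi_c = spec.margin, w - spec.margin
    if spec.n_pairs and (lo_r >= hi_r or lo_c >= hi_c):
        raise ValueError("shape too small for the requested margin (SpreadImageSpec.shape/margin)")
    centers: list[np.ndarray] = []
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.n_pairs):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            center = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if all(np.hypot(*(center - c)) >= spec.min_pair_spacing for c in centers):
                break
        else:
            raise ValueError(
                "could not place all centromere pairs; reduce SpreadImageSpec.n_pairs "
                "or SpreadImageSpec.min_pair_spacing"
            )
        theta = rng.uniform(0, 2 * math.pi)
        d = max(rng.normal(spec.pair_dist_mean, spec.pair_dist_sd), 1.0)
        offset = 0.5 * d * np.array([math.sin(theta), math.cos(theta)])
        a, b = center - offset, center + offset
        for p in (a, b):
            p[0] = min(max(p[0], lo_r), hi_r)
            p[1] = min(max(p[1], lo_c), hi_c)
        centers.append(center)
        pairs.append((a, b))
    return pairs


def _render_spread(spec: SpreadImageSpec, pairs: Sequence[tuple[np.ndarray, np.ndarray]]):
    """Render noiseless dna/measure/marker planes plus the true pericentric masks."""
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dna = np.zeros((h, w))
    measure = np.zeros((h, w))
    marker = np.zeros((h, w))
    peri_masks: list[np.ndarray] = []
    sigma = spec.spot_radius / 2.0
    for (a, b) in pairs:
        mid = 0.5 * (a + b)
        axis = b - a
        norm = np.hypot(*axis)
        u = axis / norm if norm > 0 else np.array([0.0, 1.0])
        # pericentric disc around the pair midpoint
        d_mid = np.hypot(rr - mid[0], cc - mid[1])
        disc = d_mid <= spec.peri_radius
        peri_masks.append(disc)
        dna[disc] += spec.dna_amp
        measure[disc] += spec.measure_amp
        # chromosome arm: an elongated Gaussian ridge perpendicular to the
        # centromere axis, dim in DNA only
        along = (rr - mid[0]) * -u[1] + (cc - mid[1]) * u[0]
        across = (rr - mid[0]) * u[0] + (cc - mid[1]) * u[1]
        arm = spec.arm_amp * np.exp(-0.5 * (across / (spec.peri_radius / 2)) ** 2)
        arm[np.abs(along) > 4 * spec.peri_radius] = 0.0
        dna += arm
        for p in (a, b):
            g = np.exp(-((rr - p[0]) ** 2 + (cc - p[1]) ** 2) / (2 * sigma ** 2))
            marker += spec.marker_amp * g
    return dna, measure, marker, peri_masks


def make_spread_images(
    spec: SpreadImageSpec,
    n_images: int = 1,
) -> tuple[list[MultiChannelImage], pd.DataFrame, pd.DataFrame]:
    """Generate spread images plus ground truth.

    Returns ``(images, spots, regions)`` where ``spots`` lists every true
    centromere centroid (``image, pair, mate, row, col``) and ``regions``
    the per-pair integrated measurement-channel intensity over the true
    pericentric disc of the noiseless rendering
    (``image, pair, measure_integrated, area``).
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    rng = np.random.default_rng(spec.seed)
    roles = {"dna": 0, "measure": 1, "marker": 2}
    images: list[MultiChannelImage] = []
    spot_rows = []
    region_rows = []
    for i in range(n_images):
        pairs = _place_pairs(spec, rng)
        dna, measure, marker, peri_masks = _render_spread(spec, pairs)
        data = np.stack([dna, measure, marker])
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
        images.append(MultiChannelImage(data, roles=roles, provenance="projected"))
        for k, ((a, b), mask) in enumerate(zip(pairs, peri_masks)):
            for mate, p in enumerate((a, b)):
                spot_rows.append({"image": i, "pair": k, "mate": mate,
                                  "row": p[0], "col": p[1]})
            region_rows.append({
                "image": i,
                "pair": k,
                "measure_integrated": float(measure[mask].sum()),
                "area": int(mask.sum()),
            })
    spots = pd.DataFrame(spot_rows, columns=["image", "pair", "mate", "row", "col"])
    regions = pd.DataFrame(region_rows,
                           columns=["image", "pair", "measure_integrated", "area"])
    return images, spots, regions


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FrapTraceSpec:
    """Ground truth for one FRAP trace.

    ``t_half`` (s) and ``mobile_fraction`` parameterize the
    single-exponential recovery ``Y = Ymax * (1 - exp(-(ln 2 / t_half) * (x - x0)))``
    of the normalized intensity after the bleach at ``x0 = n_prebleach * interval``.
    ``bleach_depth`` is the fraction of pre-bleach ROI intensity remaining
    immediately after the bleach; ``acq_bleach`` is the per-frame
    multiplicative acquisition-photobleaching factor applied to both the ROI
    and the whole-nucleus signal (1.0 disables it).
    """

    t_half: float = 27.0
    mobile_fraction: float = 0.58
    bleach_depth: float = 0.2
    n_prebleach: int = 5
    acq_bleach: float = 1.0
    interval: float = 1.0
    duration: float = 120.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not 0 <= self.bleach_depth < 1:
            raise ValueError("bleach_depth must be in [0, 1)")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if not 0 < self.acq_bleach <= 1:
            raise ValueError("acq_bleach must be in (0, 1]")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_frap_trace(spec: FrapTraceSpec) -> FrapTrace:
    """Simulate ROI and whole-nucleus intensity series for one cell.

    The underlying ROI signal is 1 before the bleach and
    ``depth + (1 - depth) * Ymax * (1 - exp(-k (t - x0)))`` after it; the
    whole-nucleus signal is constant. Acquisition photobleaching multiplies
    both by ``acq_bleach**frame``, and Gaussian noise is added last.
    """
    if spec.duration < 2 * spec.interval:
        raise ValueError("duration must cover at least 2 sampling intervals")
    rng = np.random.default_rng(spec.seed)
    n_post = int(round(spec.duration / spec.interval)) + 1
    n = spec.n_prebleach + n_post
    time = np.arange(n) * spec.interval
    bleach_index = spec.n_prebleach
    x0 = time[bleach_index]

    roi = np.ones(n)
    post = time[bleach_index:] - x0
    k = math.log(2) / spec.t_half
    recovery = spec.mobile_fraction * (1.0 - np.exp(-k * post))
    roi[bleach_index:] = spec.bleach_depth + (1.0 - spec.bleach_depth) * recovery
    total = np.ones(n)

    decay = spec.acq_bleach ** np.arange(n)
    roi = roi * decay
    total = total * decay
    if spec.noise_sd > 0:
        roi = roi + rng.normal(0.0, spec.noise_sd, size=n)
        total = total + rng.normal(0.0, spec.noise_sd, size=n)
        roi = np.clip(roi, 1e-6, None)
        total = np.clip(total, 1e-6, None)

    return FrapTrace(
        time=time,
        roi=roi,
        total=total,
        reference_index=spec.n_prebleach - 1,
        bleach_index=bleach_index,
    )


# ---------------------------------------------------------------------------
# binding titrations
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TitrationSpec:
    """Hill-isotherm titration on a geometric dilution series.

    ``fraction bound = [P]**n / (Kd**n + [P]**n)`` at protein concentrations
    ``start, start/factor, ...`` (``n_points`` values). The probe is assumed
    present at a concentration well below Kd, so no depletion correction is
    applied. Concentration units are carried through unchanged.
    """

    kd: float = 0.15
    hill: float = 1.0
    start: float = 100.0
    factor: float = 2.0
    n_points: int = 9
    unit: str = "uM"
    probe_conc: float | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.start <= 0:
            raise ValueError("start concentration must be > 0")
        if self.factor <= 1:
            raise ValueError("dilution factor must be > 1")
        if self.n_points < 1:
            raise ValueError("need at least one concentration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_titration(spec: TitrationSpec):
    """Sample a titration series from the Hill model (noise clipped to [0, 1])."""
    from .bindfit import TitrationSeries, dilution_series

    rng = np.random.default_rng(spec.seed)
    conc = dilution_series(spec.start, spec.factor, spec.n_points)
    frac = conc ** spec.hill / (spec.kd ** spec.hill + conc ** spec.hill)
    if spec.noise_sd > 0:
        frac = frac + rng.normal(0.0, spec.noise_sd, size=frac.shape)
    frac = np.clip(frac, 0.0, 1.0)
    return TitrationSeries(conc=conc, fraction=frac, unit=spec.unit,
                           probe=None, probe_conc=spec.probe_conc)


# ---------------------------------------------------------------------------
# repeat-family count tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RepeatTableSpec:
    """Two-sample (control vs knockout) repeat-family read counts.

    Baseline expected proportions are drawn from a log-normal and shared by
    both samples; repeat types named in ``enriched`` have their knockout
    frequency multiplied by the stated fold (the remaining probability mass
    is rescaled uniformly over the other types, so the stated folds are
    exact in expectation). Counts are multinomial unless ``exact`` is set,
    in which case expected (fractional) counts are returned.
    """

    n_types: int = 50
    total_reads: int = 1_000_000
    enriched: Mapping[str, float] = dataclasses.field(default_factory=dict)
    lognorm_sigma: float = 1.5
    repeat_classes: tuple[str, ...] = ("Satellite", "LINE", "SINE", "LTR", "DNA")
    exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        for name, fold in self.enriched.items():
            if fold <= 1:
                raise ValueError(f"enriched fold for {name!r} must be > 1")


def make_repeat_table(spec: RepeatTableSpec) -> pd.DataFrame:
    """Generate a control/knockout repeat count table.

    Enriched types are named ``rep_<i>`` for i in 0..n_types-1; keys of
    ``spec.enriched`` must use those names. Columns:
    ``repeat_type, repeat_class, reads_control, reads_ko``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"rep_{i}" for i in range(spec.n_types)]
    unknown = set(spec.enriched) - set(names)
    if unknown:
        raise ValueError(f"enriched names not in table: {sorted(unknown)}")
    classes = [spec.repeat_classes[i % len(spec.repeat_classes)] for i in range(spec.n_types)]

    raw = rng.lognormal(mean=0.0, sigma=spec.lognorm_sigma, size=spec.n_types)
    p_control = raw / raw.sum()

    folds = np.ones(spec.n_types)
    for name, fold in spec.enriched.items():
        folds[names.index(name)] = fold
    enriched_idx = folds > 1
    enriched_mass = (p_control * folds)[enriched_idx].sum()
    if enriched_mass >= 1:
        raise ValueError("enriched folds leave no probability mass for the other types")
    scale_rest = (1.0 - enriched_mass) / p_control[~enriched_idx].sum()
    p_ko = np.where(enriched_idx, p_control * folds, p_control * scale_rest)

    if spec.exact:
        reads_control = p_control * spec.total_reads
        reads_ko = p_ko * spec.total_reads
    else:
        reads_control = rng.multinomial(spec.total_reads, p_control).astype(float)
        reads_ko = rng.multinomial(spec.total_reads, p_ko).astype(float)

    return pd.DataFrame({
        "repeat_type": names,
        "repeat_class": classes,
        "reads_control": reads_control,
        "reads_ko": reads_ko,
    })


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CtTableSpec:
    """qPCR records generated from ``signal = expAmp**(-Ct)``.

    ``abundances`` maps ``sample -> fraction -> primer -> relative
    abundance``; ``fraction`` is ``"total"``, ``"IP"`` or ``"input"``.
    Ct for an abundance ``a`` is ``ct_offset - log(a) / log(expAmp)``, so a
    doubling of abundance at expAmp 2 lowers Ct by exactly one cycle.
    ``minus_rt_fraction`` is the fraction of the +RT signal that appears in
    the matched −RT control (0 gives a no-amplification −RT record).
    """

    abundances: Mapping[str, Mapping[str, Mapping[str, float]]] = dataclasses.field(
        default_factory=dict
    )
    expamp: Mapping[str, float] | float = 2.0
    ct_offset: float = 30.0
    minus_rt_fraction: float = 0.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 1
    std_dilution_factor: float = 10.0
    std_n_points: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for sample, fractions in self.abundances.items():
            for fraction, primers in fractions.items():
                for primer, a in primers.items():
                    if a <= 0:
                        raise ValueError(
                            f"abundance must be > 0 (sample={sample!r}, "
                            f"fraction={fraction!r}, primer={primer!r})"
                        )
        for amp in (self.expamp.values() if isinstance(self.expamp, Mapping) else [self.expamp]):
            if not 1 < amp <= 2:
                raise ValueError("expAmp must be in (1, 2]")
        if not 0 <= self.minus_rt_fraction < 1:
            raise ValueError("minus_rt_fraction must be in [0, 1)")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _expamp_for(spec: CtTableSpec, primer: str) -> float:
    if isinstance(spec.expamp, Mapping):
        return float(spec.expamp[primer])
    return float(spec.expamp)


def _ct_from_abundance(a: float, expamp: float, offset: float) -> float:
    return offset - math.log(a) / math.log(expamp)


def make_ct_table(spec: CtTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate Ct records and matching standard curves.

    Returns ``(records, standards)``. ``records`` columns:
    ``sample, primer, fraction, rt_flag, replicate, ct`` — ``ct`` is NaN for
    no-amplification wells (−RT controls with zero background).
    ``standards`` columns: ``primer, dilution, ct`` with ``dilution`` the
    relative input amount (1, 1/f, 1/f², ...).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    primers_seen: set[str] = set()
    for sample, fractions in spec.abundances.items():
        for fraction, primers in fractions.items():
            for primer, a in primers.items():
                primers_seen.add(primer)
                amp = _expamp_for(spec, primer)
                for rep in range(spec.n_replicates):
                    ct = _ct_from_abundance(a, amp, spec.ct_offset)
                    if spec.ct_noise_sd > 0:
                        ct += rng.normal(0.0, spec.ct_noise_sd)
                    rows.append({"sample": sample, "primer": primer, "fraction": fraction,
                                 "rt_flag": "+RT", "replicate": rep, "ct": ct})
                    if spec.minus_rt_fraction > 0:
                        ct_bg = _ct_from_abundance(a * spec.minus_rt_fraction, amp,
                                                   spec.ct_offset)
                        if spec.ct_noise_sd > 0:
                            ct_bg += rng.normal(0.0, spec.ct_noise_sd)
                    else:
                        ct_bg = math.nan  # no amplification
                    rows.append({"sample": sample, "primer": primer, "fraction": fraction,
                                 "rt_flag": "-RT", "replicate": rep, "ct": ct_bg})
    records = pd.DataFrame(rows, columns=["sample", "primer", "fraction",
                                          "rt_flag", "replicate", "ct"])

    std_rows = []
    for primer in sorted(primers_seen):
        amp = _expamp_for(spec, primer)
        for i in range(spec.std_n_points):
            rel = spec.std_dilution_factor ** (-i)
            ct = _ct_from_abundance(rel, amp, spec.ct_offset)
            if spec.ct_noise_sd > 0:
                ct += rng.normal(0.0, spec.ct_noise_sd)
            std_rows.append({"primer": primer, "dilution": rel, "ct": ct})
    standards = pd.DataFrame(std_rows, columns=["primer", "dilution", "ct"])
    return records, standards
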