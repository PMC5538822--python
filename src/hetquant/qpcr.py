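"""qPCR quantification: standard curves, the expAmp signal model, and RIP
enrichment arithmetic.

A dilution standard curve gives the per-cycle exponential amplification
factor ``expAmp`` of each amplicon (slope of Ct against log relative
input). A well's relative abundance is then ``signal = expAmp**(-Ct)``.
For repetitive targets the reverse-transcriptase-omitted (−RT) signal is
subtracted to remove DNA-derived background, the result is divided by a
reference-gene signal, and for RNA-immunoprecipitation experiments the
normalized IP signal over the normalized input signal — optionally
renormalized to a control sample — gives the enrichment fold.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "NormalizedSignal",
    "EnrichmentValue",
    "fit_standard_curve",
    "signal",
    "subtract_minus_rt",
    "normalize_to_reference",
    "ip_enrichment",
    "analyze_rip",
]


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Fitted per-cycle amplification for one primer set."""

    primer: str
    dilutions: tuple[float, ...]    # relative input amounts (1, 1/f, 1/f^2, ...)
    cts: tuple[float, ...]
    expamp: float                   # per-cycle amplification factor, in (1, 2]
    r_squared: float


@dataclasses.dataclass(frozen=True)
class NormalizedSignal:
    sample: str
    target_primer: str
    reference_primer: str
    value: float                    # target signal / reference signal
    background_dominated: bool = False


@dataclasses.dataclass(frozen=True)
class EnrichmentValue:
    sample: str
    value: float                    # normalized IP / normalized input [/ control]
    control_normalized: bool = False


def fit_standard_curve(
    dilutions: Sequence[float],
    cts: Sequence[float],
    primer: str = "",
) -> StandardCurve:
    """Estimate expAmp from a dilution series.

    ``dilutions`` are relative input amounts (e.g. 1, 0.1, 0.01 for a
    10-fold series). The least-squares slope m of Ct against the natural
    log of input gives ``expAmp = exp(-1/m)``. Perfect doubling yields a
    Ct step of log2(10) ~ 3.32 per 10-fold dilution and expAmp = 2.
    """
    d = np.asarray(dilutions, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if d.shape != ct.shape or d.ndim != 1:
        raise ValueError("dilutions and cts must be 1-D arrays of equal length")
    if d.size < 3:
        raise ValueError("need at least 3 standard-curve points")
    if np.any(d <= 0):
        raise ValueError("dilutions must be positive relative input amounts")
    x = np.log(d)
    m, b = np.polyfit(x, ct, 1)
    if m >= 0:
        raise ValueError("standard-curve slope must be negative (Ct rises as input falls)")
    pred = m * x + b
    ss_res = float(np.sum((ct - pred) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(primer=primer, dilutions=tuple(d.tolist()), cts=tuple(ct.tolist()),
                         expamp=float(np.exp(-1.0 / m)), r_squared=r2)


def signal(expamp: float, ct: float | None) -> float:
    """Relative abundance from a cycle threshold: ``expAmp**(-Ct)``.

    A no-amplification well (``ct`` None or NaN) maps to signal 0.
    """
    if expamp <= 1:
        raise ValueError("expAmp must be > 1")
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return float(expamp) ** (-float(ct))


def subtract_minus_rt(plus_rt: float, minus_rt: float) -> tuple[float, bool]:
    """Subtract the −RT (DNA-background) signal from the +RT signal.

    Returns ``(max(plus - minus, 0), background_dominated)``; the flag is
    set when the background meets or exceeds the +RT signal.
    """
    if plus_rt < 0 or minus_rt < 0:
        raise ValueError("signals must be non-negative")
    dominated = minus_rt >= plus_rt
    return max(plus_rt - minus_rt, 0.0), dominated


def normalize_to_reference(
    target: float,
    reference: float,
    sample: str = "",
    target_primer: str = "",
    reference_primer: str = "",
    background_dominated: bool = False,
) -> NormalizedSignal:
    """Divide a target signal by the reference-gene signal of the same sample."""
    if reference <= 0:
        raise ValueError("reference signal must be positive")
    if target < 0:
        raise ValueError("target signal must be non-negative")
    return NormalizedSignal(sample=sample, target_primer=target_primer,
                            reference_primer=reference_primer,
                            value=target / reference,
                            background_dominated=background_dominated)


def ip_enrichment(
    ip: NormalizedSignal,
    input_lysate: NormalizedSignal,
    control: EnrichmentValue | None = None,
) -> EnrichmentValue:
    """IP enrichment: normalized IP signal over normalized input signal.

    With a control sample's enrichment supplied, the ratio is further
    divided by it, so the control sample itself maps to 1.
    """
    if input_lysate.value <= 0:
        raise ValueError("input normalized signal must be positive")
    value = ip.value / input_lysate.value
    if control is not None:
        if control.value <= 0:
            raise ValueError("control enrichment must be positive")
        return EnrichmentValue(sample=ip.sample, value=value / control.value,
                               control_normalized=True)
    return EnrichmentValue(sample=ip.sample, value=value, control_normalized=False)


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def _mean_signal(records: pd.DataFrame, expamp: float, sample: str, primer: str,
                 fraction: str, rt_flag: str) -> float:
    """Replicate-averaged signal for one (sample, primer, fraction, rt) cell.

    Averaging happens on the signal scale; a missing −RT cell counts as 0.
    """
    sel = records[(records["sample"] == sample) & (records["primer"] == primer)
                  & (records["fraction"] == fraction) & (records["rt_flag"] == rt_flag)]
    if sel.empty:
        if rt_flag == "-RT":
            return 0.0
        raise ValueError(f"no +RT records for sample={sample!r}, primer={primer!r}, "
                         f"fraction={fraction!r}")
    return float(np.mean([signal(expamp, ct) for ct in sel["ct"]]))


def analyze_rip(
    records: pd.DataFrame,
    standards: pd.DataFrame,
    target_primer: str,
    reference_primer: str,
    control_sample: str | None = None,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Per-sample RIP enrichment from a Ct table and standard curves.

    For each sample: the target signal in the IP and input fractions is
    background-subtracted (−RT) when requested, divided by the reference
    signal of the same fraction, and the IP/input ratio of those normalized
    signals gives the enrichment — renormalized to ``control_sample`` when
    given. Returns a table with columns
    ``sample, ip_normalized, input_normalized, enrichment``.
    """
    curves = {
        primer: fit_standard_curve(grp["dilution"], grp["ct"], primer=primer)
        for primer, grp in standards.groupby("primer")
    }
    for primer in (target_primer, reference_primer):
        if primer not in curves:
            raise ValueError(f"no standard curve for primer {primer!r}")

    def normalized(sample: str, fraction: str) -> float:
        amp_t = curves[target_primer].expamp
        amp_r = curves[reference_primer].expamp
        plus = _mean_signal(records, amp_t, sample, target_primer, fraction, "+RT")
        if subtract_background:
            minus = _mean_signal(records, amp_t, sample, target_primer, fraction, "-RT")
            target, _ = subtract_minus_rt(plus, minus)
        else:
            target = plus
        ref = _mean_signal(records, amp_r, sample, reference_primer, fraction, "+RT")
        return normalize_to_reference(target, ref, sample=sample).value

    samples = records["sample"].unique().tolist()
    rows = []
    for sample in samples:
        ipn = normalized(sample, "IP")
        inn = normalized(sample, "input")
        rows.append({"sample": sample, "ip_normalized": ipn, "input_normalized": inn,
                     "enrichment": ipn / inn})
    out = pd.DataFrame(rows)
    if control_sample is not None:
        if control_sample not in samples:
            raise ValueError(f"control sample {control_sample!r} not in the table")
        ctrl = float(out.loc[out["sample"] == control_sample, "enrichment"].iloc[0])
        if ctrl <= 0:
            raise ValueError("control enrichment must be positive")
        out["enrichment"] = out["enrichment"] / ctrl
    return out
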