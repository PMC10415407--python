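"""Amplification-curve analysis and the multiplex identification rule set.

Cq values are the linearly interpolated cycle at which a curve first crosses
a fixed RFU threshold (1000 RFU by default, the empirically set baseline
threshold).  The triplex caller combines the FAM (C. includens), HEX
(C. chalcites / C. eriosoma) and Quasar 670 (18S control) channels:

* no control signal                       -> inconclusive (low / poor DNA);
* both diagnostics positive               -> inconclusive (contamination,
  artifact, or unsampled genotype);
* one diagnostic, not lagging the control by more than the ΔCq cutoff
  (8 cycles)                              -> species verdict (HEX verdicts
  require CO1 barcoding follow-up to split the two species);
* diagnostic lagging beyond the cutoff, or no diagnostic -> negative.

ΔCq is control minus diagnostic, so positive values mean the diagnostic
channel is the more sensitive one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AmplificationCurve",
    "CqResult",
    "RuleConfig",
    "PlateCall",
    "StandardCurveFit",
    "compute_cq",
    "delta_cq",
    "classify_sample",
    "fit_standard_curve",
    "read_plate_csv",
    "write_calls",
    "call_plate",
]

CHANNELS = ("FAM", "HEX", "Q670_control")

VERDICTS = (
    "C_includens",
    "Chalcites_or_eriosoma_CO1_followup",
    "negative_not_target",
    "inconclusive_low_dna",
    "inconclusive_contamination",
)


@dataclass
class AmplificationCurve:
    well: str
    sample: str
    channel: str
    rfu: np.ndarray  # indexed by cycle 1..C

    def __post_init__(self) -> None:
        self.rfu = np.asarray(self.rfu, dtype=float)
        if len(self.rfu) < 1:
            raise ValueError("empty curve")
        if not np.all(np.isfinite(self.rfu)):
            raise ValueError("non-finite RFU values")


@dataclass
class CqResult:
    cq: float | None
    end_rfu: float
    threshold: float

    @property
    def detected(self) -> bool:
        return self.cq is not None


@dataclass
class RuleConfig:
    threshold_rfu: float = 1000.0
    max_cycles: int = 40
    delta_cq_cutoff: float = 8.0

    def __post_init__(self) -> None:
        if min(self.threshold_rfu, self.max_cycles, self.delta_cq_cutoff) <= 0:
            raise ValueError("rule parameters must be positive")


@dataclass
class PlateCall:
    sample: str
    verdict: str
    rationale: str
    cq: dict[str, float | None] = field(default_factory=dict)


@dataclass
class StandardCurveFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float | None  # None when the fit is degenerate (slope ~ 0)
    lod: float | None  # lowest concentration with all replicates detected

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "efficiency": self.efficiency,
                "lod": self.lod,
            }
        )


def compute_cq(curve: AmplificationCurve, threshold: float = 1000.0) -> CqResult:
    """First upward threshold crossing, linearly interpolated between cycles.

    A curve whose final-cycle RFU sits below the threshold counts as not
    detected even if it grazed the threshold earlier (transient artifacts).
    """
    rfu = curve.rfu
    end_rfu = float(rfu[-1])
    if end_rfu < threshold:
        return CqResult(None, end_rfu, threshold)
    above = rfu >= threshold
    if above[0]:
        return CqResult(1.0, end_rfu, threshold)
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if not len(crossings):
        return CqResult(None, end_rfu, threshold)
    i = int(crossings[0])  # cycle i+1 below, i+2 at/above
    lo, hi = rfu[i], rfu[i + 1]
    frac = (threshold - lo) / (hi - lo)
    return CqResult(float(i + 1 + frac), end_rfu, threshold)


def delta_cq(diagnostic: CqResult, control: CqResult) -> float:
    """Cq(control) - Cq(diagnostic); positive when the diagnostic channel is
    the more sensitive one."""
    if diagnostic.cq is None or control.cq is None:
        raise ValueError("delta_cq requires both Cq values present")
    return control.cq - diagnostic.cq


def classify_sample(cqs: dict[str, CqResult],
                    rules: RuleConfig | None = None,
                    sample: str = "") -> PlateCall:
    """Apply the triplex identification rule set to one sample's channels."""
    rules = rules or RuleConfig()
    missing = set(CHANNELS) - set(cqs)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    fam, hexc, ctrl = cqs["FAM"], cqs["HEX"], cqs["Q670_control"]
    cq_out = {ch: cqs[ch].cq for ch in CHANNELS}
    if not ctrl.detected:
        return PlateCall(
            sample, "inconclusive_low_dna",
            "No 18S control amplification: likely insufficient DNA quantity "
            "or poor DNA quality.", cq_out)
    diagnostics = {"FAM": fam, "HEX": hexc}
    present = {ch: r for ch, r in diagnostics.items() if r.detected}
    # a diagnostic lagging the control beyond the cutoff is a false positive
    valid = {ch: r for ch, r in present.items()
             if -(delta_cq(r, ctrl)) <= rules.delta_cq_cutoff}
    if len(valid) == 2:
        return PlateCall(
            sample, "inconclusive_contamination",
            "Both diagnostic probes amplified: likely contamination, "
            "artifacts, or an unsampled genotype.", cq_out)
    if len(valid) == 1:
        ch = next(iter(valid))
        if ch == "FAM":
            return PlateCall(sample, "C_includens",
                             "FAM (ITS2) probe positive within the ΔCq window.",
                             cq_out)
        return PlateCall(
            sample, "Chalcites_or_eriosoma_CO1_followup",
            "HEX (ITS1) probe positive within the ΔCq window; CO1 barcoding "
            "should be carried out to delineate C. chalcites from "
            "C. eriosoma.", cq_out)
    if present:
        return PlateCall(
            sample, "negative_not_target",
            f"Diagnostic amplification lagged the control by more than "
            f"{rules.delta_cq_cutoff:g} cycles (false positive).", cq_out)
    return PlateCall(sample, "negative_not_target",
                     "No diagnostic amplification.", cq_out)


def fit_standard_curve(series: list[tuple[float, CqResult]]) -> StandardCurveFit:
    """OLS of mean Cq on log10(concentration), efficiency, and LOD.

    ``series`` holds replicated (concentration, CqResult) measurements.
    Efficiency is ``10^(-1/slope) - 1``; the LOD is the lowest concentration
    at which every replicate was detected.
    """
    by_conc: dict[float, list[CqResult]] = {}
    for conc, r in series:
        by_conc.setdefault(conc, []).append(r)
    detected_means = {}
    lod_candidates = []
    for conc, rs in sorted(by_conc.items()):
        det = [r.cq for r in rs if r.detected]
        if det and len(det) == len(rs):
            lod_candidates.append(conc)
        if det:
            detected_means[conc] = float(np.mean(det))
    if len(detected_means) < 3:
        raise ValueError("need detections at >= 3 distinct concentrations")
    x = np.log10(np.array(sorted(detected_means)))
    y = np.array([detected_means[c] for c in sorted(detected_means)])
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue ** 2)
    eff = None if abs(slope) < 1e-9 else float(10.0 ** (-1.0 / slope) - 1.0)
    lod = min(lod_candidates) if lod_candidates else None
    return StandardCurveFit(slope, intercept, r2, eff, lod)


# ---------------------------------------------------------------------------
# Plate I/O and driver


def read_plate_csv(path: str | Path) -> list[AmplificationCurve]:
    """Parse a plate CSV (well, sample, channel, cycle, rfu) into curves."""
    df = pd.read_csv(path)
    required = {"well", "sample", "channel", "cycle", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    if df.duplicated(subset=["well", "channel", "cycle"]).any():
        raise ValueError("duplicate (well, channel, cycle) rows")
    curves = []
    for (well, channel), grp in df.groupby(["well", "channel"], sort=True):
        grp = grp.sort_values("cycle")
        cycles = grp["cycle"].to_numpy()
        if not np.array_equal(cycles, np.arange(1, len(cycles) + 1)):
            raise ValueError(f"well {well} channel {channel}: missing cycles")
        curves.append(AmplificationCurve(
            well=str(well), sample=str(grp["sample"].iloc[0]),
            channel=str(channel), rfu=grp["rfu"].to_numpy()))
    return curves


def call_plate(curves: list[AmplificationCurve],
               rules: RuleConfig | None = None) -> list[PlateCall]:
    """Compute Cq per (well, channel) and classify each well."""
    rules = rules or RuleConfig()
    by_well: dict[str, dict[str, CqResult]] = {}
    samples: dict[str, str] = {}
    for c in curves:
        by_well.setdefault(c.well, {})[c.channel] = compute_cq(c, rules.threshold_rfu)
        samples[c.well] = c.sample
    return [classify_sample(chans, rules, sample=samples[w])
            for w, chans in sorted(by_well.items())]


def write_calls(calls: list[PlateCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "sample": c.sample,
            "verdict": c.verdict,
            "rationale": c.rationale,
            **{f"cq_{ch}": ("" if c.cq.get(ch) is None else f"{c.cq[ch]:.2f}")
               for ch in CHANNELS},
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
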