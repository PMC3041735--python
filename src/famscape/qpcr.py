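"""Efficiency-corrected relative qPCR quantification.

The initial transcript amount behind a well with threshold cycle Ct and
per-cycle amplification factor E is Q0 = F_threshold / E^Ct, so the
target-to-reference ratio reduces to

    Q0_target / Q0_ref = E_ref^Ct_ref / E_target^Ct_target.

E is on the amplification-factor scale (2.0 = perfect doubling) and is
estimated per well from the exponential phase of the raw fluorescence
curve by the window-of-linearity approach: after baseline subtraction,
the 4-6 cycle window maximizing the r^2 of a log-linear fit gives
E = 10^slope. Per-amplicon efficiencies are plate averages of well
estimates. Replicate ratios are summarized as mean +/- SE on the ratio
scale, treatment contrasts use a two-sample Student's t test with the
conventional star thresholds (p <= 0.05 '*', p <= 0.01 '**'), and
multi-group organ comparisons use one-way ANOVA with Tukey HSD compact
letter display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class WellRecord:
    gene: str
    sample: str
    replicate: int
    ct: float
    efficiency: Optional[float] = None

    def __post_init__(self):
        if self.ct <= 0:
            raise ValueError(f"well {self.gene}/{self.sample}: ct must be > 0")
        if self.efficiency is not None and not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")


@dataclass
class AmplificationCurve:
    well_id: str
    gene: str
    sample: str
    fluorescence: np.ndarray      # readings for cycles 1..C

    def __post_init__(self):
        f = np.asarray(self.fluorescence, dtype=float)
        if len(f) < 10:
            raise ValueError("curve needs at least 10 cycles")
        if not np.isfinite(f).all():
            raise ValueError("non-finite fluorescence readings")
        self.fluorescence = f


@dataclass
class EfficiencyEstimate:
    well_id: str
    E: float
    window: tuple[int, int]       # (first cycle, last cycle), 1-based
    r2: float


@dataclass
class RelExpression:
    gene: str
    sample: str
    q_ratios: tuple[float, ...]
    mean: float
    se: Optional[float]           # None (flagged) for single replicates


@dataclass
class TestResult:
    comparison: tuple[str, str]
    p_value: float
    stars: str                    # "", "*", or "**"
    fold_change: float


# ---------------------------------------------------------------------------
# efficiency estimation


def estimate_efficiency(curve: AmplificationCurve,
                        window_range: tuple[int, int] = (4, 6),
                        n_baseline_cycles: int = 3,
                        plateau_fraction: float | None = None) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate from a raw curve.

    Baseline (mean of the first ``n_baseline_cycles`` readings) is
    subtracted. Candidate windows are contiguous 4-6 cycle stretches
    with strictly positive corrected readings; the window maximizing the
    r^2 of the log10-linear fit wins (ties: longer, then earlier);
    E = 10^slope, capped at 2.0 with a warning. Saturated stretches are
    rejected by the r^2 criterion itself; for curves with a slow, smooth
    approach to plateau an optional guard restricts candidates to below
    ``plateau_fraction`` of the maximum corrected signal (dropped again
    if no window qualifies).
    """
    lo, hi = window_range
    if not (4 <= lo <= hi <= 6):
        raise ValueError("window_range must lie within [4, 6]")
    f = curve.fluorescence
    baseline = f[:n_baseline_cycles].mean()
    corrected = f - baseline
    cycles = np.arange(1, len(f) + 1)
    cap = (plateau_fraction * corrected.max()) if plateau_fraction else None

    def fit(use_cap: bool):
        best = None   # ((r2, width, -start), E, window)
        for width in range(lo, hi + 1):
            for start in range(len(f) - width + 1):
                seg = corrected[start:start + width]
                if (seg <= 0).any():
                    continue
                if use_cap and cap is not None and seg.max() > cap:
                    continue
                x = cycles[start:start + width]
                y = np.log10(seg)
                slope, _, r, _, _ = stats.linregress(x, y)
                key = (r * r, width, -start)
                if best is None or key > best[0]:
                    best = (key, 10.0 ** slope, (start + 1, start + width))
        return best

    best = (fit(True) or fit(False)) if cap is not None else fit(False)
    if best is None:
        raise ValueError(f"well {curve.well_id}: no window with positive readings")
    _, E, window = best
    r2 = best[0][0]
    if E > 2.0:
        logger.warning("well %s: estimated E=%.3f capped at 2.0", curve.well_id, E)
        E = 2.0
    return EfficiencyEstimate(curve.well_id, E, window, r2)


def average_efficiency(estimates: Sequence[EfficiencyEstimate],
                       amplicon_of: dict[str, str]) -> dict[str, float]:
    """Arithmetic per-amplicon mean of well estimates (one plate)."""
    groups: dict[str, list[float]] = {}
    for est in estimates:
        amplicon = amplicon_of[est.well_id]
        groups.setdefault(amplicon, []).append(est.E)
    return {a: float(np.mean(v)) for a, v in groups.items()}


# ---------------------------------------------------------------------------
# relative quantification


def relative_expression(ct_target: float, ct_ref: float,
                        e_target: float, e_ref: float) -> float:
    """Efficiency-corrected ratio E_ref^Ct_ref / E_target^Ct_target,
    evaluated in log space."""
    for name, v in (("ct_target", ct_target), ("ct_ref", ct_ref)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    for name, v in (("e_target", e_target), ("e_ref", e_ref)):
        if not (1.0 < v <= 2.0):
            raise ValueError(f"{name} must be in (1, 2]")
    return math.exp(ct_ref * math.log(e_ref) - ct_target * math.log(e_target))


def aggregate_replicates(q_ratios: Sequence[float], gene: str = "",
                         sample: str = "") -> RelExpression:
    """Replicate mean and standard error on the ratio scale; a single
    replicate yields mean only with SE flagged as undefined (None)."""
    vals = [float(v) for v in q_ratios]
    if not vals:
        raise ValueError("no replicate ratios")
    if any(v <= 0 for v in vals):
        raise ValueError("q_ratios must be positive")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        logger.warning("single replicate for %s/%s: SE undefined", gene, sample)
        se = None
    else:
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    return RelExpression(gene, sample, tuple(vals), mean, se)


def quantify(wells: Sequence[WellRecord], reference_gene: str = "UBQ5",
             undetected_ct: float = 35.0) -> list[RelExpression]:
    """Per-(gene, sample) efficiency-corrected ratios vs the reference.

    Target and reference wells are paired by replicate index within each
    sample; wells at or above the detection threshold Ct are flagged
    undetected and excluded.
    """
    kept = [w for w in wells if w.ct < undetected_ct]
    dropped = len(list(wells)) - len(kept)
    if dropped:
        logger.info("%d wells at Ct >= %.1f flagged undetected and excluded",
                    dropped, undetected_ct)
    refs: dict[tuple[str, int], WellRecord] = {}
    for w in kept:
        if w.gene == reference_gene:
            refs[(w.sample, w.replicate)] = w
    groups: dict[tuple[str, str], list[WellRecord]] = {}
    for w in kept:
        if w.gene != reference_gene:
            groups.setdefault((w.gene, w.sample), []).append(w)
    out = []
    for (gene, sample), ws in sorted(groups.items()):
        ratios = []
        for w in sorted(ws, key=lambda x: x.replicate):
            ref = refs.get((sample, w.replicate))
            if ref is None:
                logger.warning("no reference well for %s/%s replicate %d",
                               gene, sample, w.replicate)
                continue
            if w.efficiency is None or ref.efficiency is None:
                raise ValueError(f"missing efficiency for {gene}/{sample}")
            ratios.append(relative_expression(w.ct, ref.ct, w.efficiency, ref.efficiency))
        if ratios:
            out.append(aggregate_replicates(ratios, gene, sample))
    return out


# ---------------------------------------------------------------------------
# significance conventions


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_treatment(control: RelExpression, treated: RelExpression) -> TestResult:
    """Two-sided two-sample Student's t test on replicate ratios."""
    a, b = np.asarray(control.q_ratios), np.asarray(treated.q_ratios)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        if math.isnan(p):
            p = 1.0
    return TestResult(
        comparison=(control.sample, treated.sample),
        p_value=p,
        stars=_stars(p),
        fold_change=treated.mean / control.mean,
    )


def tukey_groups(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> dict[str, str]:
    """One-way ANOVA then all-pairs Tukey HSD compact letter display.

    Groups not significantly different share a letter; letters are
    assigned greedily from the largest mean ('a' = largest). Unequal
    group sizes use the Tukey-Kramer generalization.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    if np.ptp(values) == 0:
        return {g: "a" for g in names}
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = res.summary().data[1:]
    differs: set[frozenset[str]] = set()
    for row in frame:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[6])
        if reject:
            differs.add(frozenset((g1, g2)))

    order = sorted(names, key=lambda g: -float(np.mean(groups[g])))
    letter_classes: list[list[str]] = []     # members of each letter, in order
    assignment: dict[str, list[int]] = {g: [] for g in names}
    for g in order:
        placed = False
        for idx, members in enumerate(letter_classes):
            if all(frozenset((g, m)) not in differs for m in members):
                members.append(g)
                assignment[g].append(idx)
                placed = True
        if not placed:
            letter_classes.append([g])
            assignment[g].append(len(letter_classes) - 1)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {g: "".join(alphabet[i] for i in sorted(assignment[g])) for g in names}
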