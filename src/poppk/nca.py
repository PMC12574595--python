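"""Non-compartmental analysis.

Exposure metrics computed without a structural model: AUC by the
linear-up/log-down trapezoid rule, Cmax/Tmax from the observed maximum, and
the terminal elimination rate constant lambda_z from the best log-linear
tail regression (automatic terminal-phase detection by maximum adjusted
R-squared over candidate tails of 3..8 points strictly after Tmax).
AUC to infinity adds the ``C_last / lambda_z`` extrapolation tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SubjectRecord
from .exceptions import InvalidInputError

logger = logging.getLogger("poppk")

__all__ = [
    "NCAResult",
    "auc_linear_up_log_down",
    "terminal_phase",
    "run_nca",
]

#: maximum number of tail points screened for lambda_z
MAX_TERMINAL_POINTS = 8


@dataclass
class NCAResult:
    """Per-subject NCA metrics (units: mg, h, L)."""

    subject_id: str
    auc_last: float = np.nan
    auc_inf: float = np.nan
    cmax: float = np.nan
    tmax: float = np.nan
    lambda_z: float = np.nan
    t_half: float = np.nan
    cl_f: float = np.nan  # Dose/AUC_inf; apparent clearance (CL/F for oral)
    n_terminal_points: int = 0
    adj_r2_terminal: float = np.nan
    success: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def auc_linear_up_log_down(times, concs) -> float:
    """Area under the curve by the linear-up/log-down trapezoid method.

    Rising or flat segments use the linear trapezoid ``(C1+C2)/2 * dt``;
    strictly falling segments with both ends positive use the log trapezoid
    ``(C1-C2) * dt / ln(C1/C2)``; falling segments touching zero fall back
    to linear (log undefined).
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    if t.size != c.size or t.size < 2:
        raise InvalidInputError("AUC needs >= 2 paired points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(c < 0):
        raise InvalidInputError("concentrations must be non-negative")
    total = 0.0
    for i in range(t.size - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c2 < c1 and c2 > 0:
            total += (c1 - c2) * dt / np.log(c1 / c2)
        else:
            total += 0.5 * (c1 + c2) * dt
    return float(total)


@dataclass
class TerminalPhase:
    lambda_z: float
    t_half: float
    n_points: int
    adj_r2: float
    success: bool


def terminal_phase(times, concs) -> TerminalPhase:
    """Automatic terminal-phase detection.

    Screens candidate tails (the last 3..m points strictly after Tmax,
    m capped at 8) by log-linear regression, keeping the candidate with the
    maximum adjusted R-squared among those with a negative slope; ties in
    adjusted R-squared resolve toward fewer points.  Returns a failure flag
    when no candidate qualifies.
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    failure = TerminalPhase(np.nan, np.nan, 0, np.nan, False)
    if t.size < 3:
        return failure
    i_max = int(np.argmax(c))
    t_tail = t[i_max + 1 :]
    c_tail = c[i_max + 1 :]
    pos = c_tail > 0
    t_tail, c_tail = t_tail[pos], c_tail[pos]
    m = min(t_tail.size, MAX_TERMINAL_POINTS)
    best: TerminalPhase | None = None
    for k in range(3, m + 1):
        tt, cc = t_tail[-k:], np.log(c_tail[-k:])
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        fitted = intercept + slope * tt
        ss_res = float(np.sum((cc - fitted) ** 2))
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if not np.isfinite(r2):
            continue
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        # strict > keeps the fewer-point candidate on ties (k ascends)
        if best is None or adj > best.adj_r2 + 1e-12:
            lz = -float(slope)
            best = TerminalPhase(lz, float(np.log(2.0) / lz), k, float(adj), True)
    return best if best is not None else failure


def _c0_backextrapolated(t: np.ndarray, c: np.ndarray) -> float | None:
    """IV-bolus C(0) by log-linear back-extrapolation from the first two
    positive concentrations (standard NCA practice); falls back to the first
    observed value on a non-declining start."""
    pos = c > 0
    if pos.sum() < 2:
        return None
    tp, cp = t[pos][:2], c[pos][:2]
    if tp[1] <= tp[0]:
        return None
    slope = (np.log(cp[1]) - np.log(cp[0])) / (tp[1] - tp[0])
    if slope >= 0:
        return float(cp[0])
    return float(np.exp(np.log(cp[0]) - slope * tp[0]))


def _analyze_subject(subject: SubjectRecord) -> NCAResult:
    order = np.argsort(subject.times, kind="stable")
    t = subject.times[order]
    c = subject.concentrations[order]
    result = NCAResult(subject_id=subject.subject_id)
    if t.size < 2:
        logger.warning("NCA failed for subject %s: fewer than 2 points", subject.subject_id)
        return result
    result.cmax = float(c.max())
    result.tmax = float(t[int(np.argmax(c))])  # earliest time attaining cmax
    if subject.dose.route == "iv_bolus" and t[0] > 0:
        c0 = _c0_backextrapolated(t, c)
        if c0 is not None:
            t = np.concatenate(([0.0], t))
            c = np.concatenate(([c0], c))
    result.auc_last = auc_linear_up_log_down(t, c)
    term = terminal_phase(t, c)
    if term.success:
        result.lambda_z = term.lambda_z
        result.t_half = term.t_half
        result.n_terminal_points = term.n_points
        result.adj_r2_terminal = term.adj_r2
        c_last = c[c > 0][-1] if np.any(c > 0) else 0.0
        result.auc_inf = result.auc_last + float(c_last) / term.lambda_z
        if result.auc_inf > 0:
            result.cl_f = subject.dose.amount / result.auc_inf
    result.success = True
    return result


_SUMMARY_METRICS = (
    "auc_last", "auc_inf", "cmax", "tmax", "lambda_z", "t_half", "cl_f",
)


def run_nca(
    population: Sequence[SubjectRecord], dose=None
) -> tuple[list[NCAResult], dict]:
    """Batch NCA with per-subject error containment.

    Returns per-subject results plus a summary of arithmetic mean and CV%
    per metric over successful subjects, and the batch success rate.
    Subject-level failures are logged, never raised.
    """
    results = []
    for subj in population:
        try:
            results.append(_analyze_subject(subj))
        except Exception as exc:
            logger.warning("NCA failed for subject %s: %s", subj.subject_id, exc)
            results.append(NCAResult(subject_id=subj.subject_id))
    ok = [r for r in results if r.success]
    summary: dict = {
        "n_subjects": len(results),
        "n_success": len(ok),
        "success_rate": len(ok) / len(results) if results else np.nan,
    }
    for metric in _SUMMARY_METRICS:
        vals = np.array([getattr(r, metric) for r in ok], float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean = float(vals.mean())
            cv = 100.0 * float(vals.std(ddof=1) / mean) if vals.size > 1 and mean else np.nan
            summary[metric] = {"mean": mean, "cv_pct": cv, "n": int(vals.size)}
    return results, summary


def nca_table(results: Sequence[NCAResult]) -> pd.DataFrame:
    """One row per subject, for CSV export."""
    return pd.DataFrame([r.to_dict() for r in results])
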