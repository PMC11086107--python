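"""Blood-pressure parameter extraction and device-grade evaluation.

From each predicted/reference ABP window the systolic (waveform maximum),
diastolic (waveform minimum) and mean pressure MBP = (SBP + 2·DBP)/3 are
extracted.  Paired series are then scored with:

* regression metrics — ME, MAE, MSE, the RMSE-style "STD" sqrt(MSE)
  (reported as ``std_eq20``), the conventional error dispersion
  (``sd_diff``), R² and Pearson's r;
* BHS grading — percentage of absolute errors within 5/10/15 mmHg, graded
  A/B/C per threshold against (60, 85, 95) / (50, 75, 90) / (40, 65, 85)
  with the overall grade the worst of the three (D below C);
* AAMI criterion — |ME| ≤ 5 mmHg and error SD ≤ 8 mmHg over ≥ 85 subjects;
* Bland–Altman limits of agreement μ ± 1.96σ of the differences.

Both "STD" variants are computed because sqrt(mean squared error) is the
RMSE of the error, not its dispersion about the mean; Bland–Altman and the
AAMI check use the conventional dispersion.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "BPTriple",
    "MetricSet",
    "BHSResult",
    "AAMIResult",
    "BlandAltman",
    "EvaluationReport",
    "extract_bp",
    "metrics",
    "bhs_grade",
    "aami_check",
    "bland_altman",
    "evaluate_run",
]


@dataclass(frozen=True)
class BPTriple:
    """(SBP, DBP, MBP) in mmHg; MBP = (SBP + 2*DBP)/3."""

    sbp: float
    dbp: float
    mbp: float

    def __post_init__(self):
        if not (self.dbp <= self.mbp <= self.sbp):
            raise ValueError(f"require dbp <= mbp <= sbp, got {self}")


def extract_bp(waveform: np.ndarray) -> BPTriple:
    """Extract the BP triple from one ABP window (global extrema)."""
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform contains non-finite values")
    sbp = float(np.max(w))
    dbp = float(np.min(w))
    return BPTriple(sbp=sbp, dbp=dbp, mbp=(sbp + 2.0 * dbp) / 3.0)


@dataclass
class MetricSet:
    me: float
    mae: float
    mse: float
    std_eq20: float      # sqrt(MSE): RMSE-style "STD"
    sd_diff: float       # dispersion of the error about its mean
    r2: float
    r: float


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """Regression metrics for paired series (literal formula transcriptions)."""
    y = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("need equally-sized series of length >= 2")
    err = y - yh
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    sd_diff = float(np.std(err))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = r = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
        n = y.size
        num = n * np.sum(y * yh) - np.sum(y) * np.sum(yh)
        den = np.sqrt(n * np.sum(y ** 2) - np.sum(y) ** 2) * np.sqrt(
            n * np.sum(yh ** 2) - np.sum(yh) ** 2
        )
        r = float(num / den) if den > 0 else float("nan")
    return MetricSet(me=me, mae=mae, mse=mse, std_eq20=float(np.sqrt(mse)),
                     sd_diff=sd_diff, r2=r2, r=r)


# BHS minimum cumulative percentages per grade at thresholds (5, 10, 15) mmHg
_BHS_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
_BHS_THRESHOLDS = (5.0, 10.0, 15.0)


@dataclass
class BHSResult:
    pct_within: tuple[float, float, float]  # at 5 / 10 / 15 mmHg
    grade: str                              # A, B, C or D (below C)
    per_threshold: tuple[str, str, str] = ("D", "D", "D")


def bhs_grade(
    abs_errors: Sequence[float] | None = None,
    pct_within: tuple[float, float, float] | None = None,
) -> BHSResult:
    """Grade a prediction series against the BHS standard.

    Pass either raw absolute errors (mmHg) or a precomputed percentage
    triple at the 5/10/15 mmHg thresholds.  The per-threshold grade is the
    best of A/B/C whose minimum percentage is met; the overall grade is the
    worst of the three, with D when any threshold falls below C.
    """
    if pct_within is None:
        if abs_errors is None:
            raise ValueError("provide abs_errors or pct_within")
        e = np.abs(np.asarray(abs_errors, dtype=float))
        if e.size == 0:
            raise ValueError("empty error sequence")
        pct_within = tuple(
            float(100.0 * np.mean(e <= thr)) for thr in _BHS_THRESHOLDS
        )
    per_threshold = []
    for i, pct in enumerate(pct_within):
        g = "D"
        for grade in ("A", "B", "C"):
            if pct >= _BHS_TABLE[grade][i]:
                g = grade
                break
        per_threshold.append(g)
    overall = max(per_threshold, key="ABCD".index)  # worst of three
    return BHSResult(pct_within=tuple(pct_within), grade=overall,
                     per_threshold=tuple(per_threshold))


@dataclass
class AAMIResult:
    me: float
    std_of_differences: float
    n_subjects: int
    passed: bool


def aami_check(me: float, sd_diff: float, n_subjects: int) -> AAMIResult:
    """AAMI device criterion (boundaries inclusive): |ME|<=5, SD<=8, n>=85."""
    passed = abs(me) <= 5.0 and sd_diff <= 8.0 and n_subjects >= 85
    return AAMIResult(me=float(me), std_of_differences=float(sd_diff),
                      n_subjects=int(n_subjects), passed=bool(passed))


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]       # mu -/+ 1.96 sigma
    frac_within_loa: float


def bland_altman(y_true: np.ndarray, y_pred: np.ndarray) -> BlandAltman:
    """Limits of agreement of the differences d = predicted - true."""
    y = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("need equally-sized series of length >= 2")
    d = yh - y
    mu = float(np.mean(d))
    sd = float(np.std(d))
    lo, hi = mu - 1.96 * sd, mu + 1.96 * sd
    frac = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean_diff=mu, sd_diff=sd, loa=(lo, hi), frac_within_loa=frac)


@dataclass
class EvaluationReport:
    """Complete evaluation for one prediction run."""

    n_segments: int
    waveform: MetricSet
    per_parameter: dict[str, MetricSet]          # sbp/dbp/mbp
    bhs: dict[str, BHSResult]
    aami: dict[str, AAMIResult]
    bland_altman: dict[str, BlandAltman]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        d = json.loads(s)
        return cls(
            n_segments=d["n_segments"],
            waveform=MetricSet(**d["waveform"]),
            per_parameter={k: MetricSet(**v) for k, v in d["per_parameter"].items()},
            bhs={
                k: BHSResult(
                    pct_within=tuple(v["pct_within"]), grade=v["grade"],
                    per_threshold=tuple(v["per_threshold"]),
                )
                for k, v in d["bhs"].items()
            },
            aami={k: AAMIResult(**v) for k, v in d["aami"].items()},
            bland_altman={
                k: BlandAltman(
                    mean_diff=v["mean_diff"], sd_diff=v["sd_diff"],
                    loa=tuple(v["loa"]), frac_within_loa=v["frac_within_loa"],
                )
                for k, v in d["bland_altman"].items()
            },
        )


def evaluate_run(
    predictions: np.ndarray,
    targets: np.ndarray,
    out_dir: str | None = None,
    make_plots: bool = True,
) -> EvaluationReport:
    """Score predicted ABP windows (mmHg) against reference windows.

    ``predictions`` and ``targets`` are [n_segments, window_len] arrays on
    the mmHg scale.  Per-segment BP triples are extracted from both and
    compared; waveform-level metrics are computed sample-wise.  When
    ``out_dir`` is given, ``report.json``, ``metrics.csv`` and (optionally)
    Bland–Altman / error-histogram / regression plots are written there.
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape or predictions.ndim != 2:
        raise ValueError(
            f"misaligned inputs: predictions {predictions.shape} vs targets {targets.shape}"
        )
    n = predictions.shape[0]
    true_bp = {p: np.empty(n) for p in ("sbp", "dbp", "mbp")}
    pred_bp = {p: np.empty(n) for p in ("sbp", "dbp", "mbp")}
    for i in range(n):
        t = extract_bp(targets[i])
        p = extract_bp(predictions[i])
        for name in ("sbp", "dbp", "mbp"):
            true_bp[name][i] = getattr(t, name)
            pred_bp[name][i] = getattr(p, name)

    per_parameter = {}
    bhs = {}
    aami = {}
    ba = {}
    for name in ("sbp", "dbp", "mbp"):
        m = metrics(true_bp[name], pred_bp[name])
        per_parameter[name] = m
        bhs[name] = bhs_grade(abs_errors=np.abs(pred_bp[name] - true_bp[name]))
        aami[name] = aami_check(m.me, m.sd_diff, n)
        ba[name] = bland_altman(true_bp[name], pred_bp[name])

    report = EvaluationReport(
        n_segments=n,
        waveform=metrics(targets.ravel(), predictions.ravel()),
        per_parameter=per_parameter,
        bhs=bhs,
        aami=aami,
        bland_altman=ba,
    )
    if out_dir is not None:
        _write_report(report, true_bp, pred_bp, out_dir, make_plots)
    return report


def _write_report(report, true_bp, pred_bp, out_dir, make_plots):
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as f:
        f.write(report.to_json(indent=2))
    rows = []
    for name, m in report.per_parameter.items():
        row = {"parameter": name, **dataclasses.asdict(m)}
        row["bhs_grade"] = report.bhs[name].grade
        row["aami_pass"] = report.aami[name].passed
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    if not make_plots:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name in ("sbp", "dbp", "mbp"):
        y, yh = true_bp[name], pred_bp[name]
        ba = report.bland_altman[name]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter((y + yh) / 2, yh - y, s=6, alpha=0.5)
        for val, style in ((ba.mean_diff, "-"), (ba.loa[0], "--"), (ba.loa[1], "--")):
            ax.axhline(val, color="r", linestyle=style, lw=1)
        ax.set_xlabel(f"mean of true/predicted {name.upper()} (mmHg)")
        ax.set_ylabel("difference (mmHg)")
        ax.set_title(f"Bland-Altman: {name.upper()}")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"bland_altman_{name}.png"), dpi=100)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in ("sbp", "dbp", "mbp"):
        ax.hist(np.abs(pred_bp[name] - true_bp[name]), bins=30, alpha=0.5,
                label=name.upper())
    ax.set_xlabel("absolute error (mmHg)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "error_hist.png"), dpi=100)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, name in zip(axes, ("sbp", "dbp", "mbp")):
        y, yh = true_bp[name], pred_bp[name]
        ax.scatter(y, yh, s=6, alpha=0.5)
        lim = (min(y.min(), yh.min()), max(y.max(), yh.max()))
        ax.plot(lim, lim, "g-", lw=1)
        if np.std(y) > 0:
            b, a = np.polyfit(y, yh, 1)
            ax.plot(lim, [b * v + a for v in lim], "r--", lw=1)
        ax.set_xlabel(f"true {name.upper()} (mmHg)")
        ax.set_ylabel(f"predicted {name.upper()} (mmHg)")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "regression_fit.png"), dpi=100)
    plt.close(fig)
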