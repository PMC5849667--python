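"""Full validation run: QC → agreement → prediction → trough summary.

`run_validation` wires the stages together for all three method
comparisons (DBS vs WB, DBS_wb vs WB, DBS vs DBS_wb), runs the
leave-one-out predictive-performance analysis on the principal pair,
and classifies extrapolated troughs against the therapeutic window.
The result serialises to JSON at full precision; the text rendering
rounds concentrations and ratios to two decimals and percentages to
one, and rounding never feeds back into computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .bland_altman import BAResult, ratio_agreement
from .passing_bablok import BiasCall, PBFit, classify_bias, fit_passing_bablok, pearson_correlation
from .prediction import PredictionMetrics, PredictionSet, loo_predict, prediction_metrics
from .samples import (
    AnalysisPair,
    PairedSample,
    build_pairs,
    flag_hematocrit,
    read_samples,
)
from .trough import (
    DEFAULT_ABSORPTION_CUTOFF_H,
    DEFAULT_HALF_LIFE_H,
    DEFAULT_TAU_H,
    WINDOW_HIGH,
    WINDOW_LOW,
    TroughEstimate,
    WindowSummary,
    cohort_window_summary,
    extrapolate_trough,
)

__all__ = [
    "ReportConfig",
    "ComparisonResult",
    "ValidationReport",
    "PipelineError",
    "run_validation",
    "write_report",
    "report_to_dict",
    "report_from_dict",
]


class PipelineError(RuntimeError):
    """An upstream stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass(frozen=True)
class ReportConfig:
    """Run configuration; every key has a documented default."""

    principal_pair: str = "dbs_vs_wb"
    level: float = 0.95
    clinical_limits: tuple[float, float] = (0.75, 1.25)
    center_clinical_on_mean: bool = False
    tau_h: float = DEFAULT_TAU_H
    half_life_h: float = DEFAULT_HALF_LIFE_H
    absorption_cutoff_h: float = DEFAULT_ABSORPTION_CUTOFF_H
    window_low: float = WINDOW_LOW
    window_high: float = WINDOW_HIGH


@dataclass(frozen=True)
class ComparisonResult:
    pair_name: str
    n: int
    pb: PBFit
    bias: BiasCall | None
    ba: BAResult
    r: float
    r_squared: float


@dataclass
class ValidationReport:
    comparisons: dict[str, ComparisonResult]
    prediction: PredictionMetrics | None
    prediction_set: PredictionSet | None
    troughs: list[TroughEstimate]
    window: WindowSummary
    qc: list[dict]
    rejections: list[dict]
    config: ReportConfig
    meta: dict
    # raw pairs kept for plotting only; not serialised
    pairs: dict[str, AnalysisPair] = field(default_factory=dict, repr=False)


def _stage(name: str):
    # context manager that re-raises stage failures with identification
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_validation(
    samples: Sequence[PairedSample] | str | Path,
    config: ReportConfig | None = None,
) -> ValidationReport:
    """Run the full cross-validation analysis.

    ``samples`` is either a list of :class:`PairedSample` or a path to
    the canonical CSV.  Deterministic given inputs and config.
    """
    config = config or ReportConfig()
    rejections: list[dict] = []
    if isinstance(samples, (str, Path)):
        with _stage("sample_io"):
            samples, rejections = read_samples(samples)
    samples = list(samples)

    with _stage("sample_io"):
        for s in samples:
            flag_hematocrit(s)
        pairs = build_pairs(samples)

    comparisons: dict[str, ComparisonResult] = {}
    for name, pair in pairs.items():
        with _stage(f"agreement:{name}"):
            fit = fit_passing_bablok(pair.x, pair.y, level=config.level)
            bias = classify_bias(fit) if fit.slope_ci is not None else None
            ba = ratio_agreement(
                pair,
                clinical_limits=config.clinical_limits,
                center_clinical_on_mean=config.center_clinical_on_mean,
            )
            r, r2 = pearson_correlation(pair.x, pair.y)
            comparisons[name] = ComparisonResult(
                pair_name=name, n=pair.n, pb=fit, bias=bias, ba=ba, r=r, r_squared=r2
            )

    principal = pairs.get(config.principal_pair)
    if principal is None:
        raise PipelineError(
            "loo_prediction", f"principal pair {config.principal_pair!r} not available"
        )
    with _stage("loo_prediction"):
        pred_set = loo_predict(principal)
        metrics = prediction_metrics(pred_set)

    with _stage("trough"):
        troughs = [
            extrapolate_trough(
                s.wb,
                s.time_after_dose_h,
                tau=config.tau_h,
                half_life=config.half_life_h,
                absorption_cutoff=config.absorption_cutoff_h,
                window=(config.window_low, config.window_high),
            )
            for s in samples
        ]
        window = cohort_window_summary([t.window_class for t in troughs])

    qc = [
        {"patient_id": s.patient_id, "flags": sorted(s.flags)}
        for s in samples
        if s.flags
    ]
    return ValidationReport(
        comparisons=comparisons,
        prediction=metrics,
        prediction_set=pred_set,
        troughs=troughs,
        window=window,
        qc=qc,
        rejections=rejections,
        config=config,
        meta={"package": "dbsval", "version": __version__},
        pairs=pairs,
    )


# -- serialisation -----------------------------------------------------


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def report_to_dict(report: ValidationReport) -> dict:
    """Full-precision JSON-ready dict (raw pairs omitted)."""
    d = {
        f.name: _to_jsonable(getattr(report, f.name))
        for f in dataclasses.fields(report)
        if f.name != "pairs"
    }
    # WindowSummary percentages are derived properties; surface them
    d["window"]["percentages"] = {
        "below": report.window.pct_below,
        "within": report.window.pct_within,
        "above": report.window.pct_above,
        "outside": report.window.pct_outside,
    }
    # verdict nested inside prediction metrics
    return d


def _tup(v):
    return tuple(v) if v is not None else None


def report_from_dict(d: dict) -> ValidationReport:
    """Rebuild a report object from :func:`report_to_dict` output."""
    from .prediction import Verdict
    from .trough import WindowSummary

    comparisons = {}
    for name, c in d["comparisons"].items():
        pb = dict(c["pb"])
        pb["slope_ci"] = _tup(pb["slope_ci"])
        pb["intercept_ci"] = _tup(pb["intercept_ci"])
        ba = dict(c["ba"])
        ba["loa"] = tuple(ba["loa"])
        ba["clinical_limits"] = tuple(ba["clinical_limits"])
        comparisons[name] = ComparisonResult(
            pair_name=c["pair_name"],
            n=c["n"],
            pb=PBFit(**pb),
            bias=BiasCall(**c["bias"]) if c["bias"] is not None else None,
            ba=BAResult(**ba),
            r=c["r"],
            r_squared=c["r_squared"],
        )
    pred = None
    if d["prediction"] is not None:
        p = dict(d["prediction"])
        v = p.pop("verdict")
        pred = PredictionMetrics(
            **p, verdict=Verdict(passed=v["passed"], reasons=tuple(v["reasons"]))
        )
    pred_set = None
    if d["prediction_set"] is not None:
        ps = dict(d["prediction_set"])
        pred_set = PredictionSet(
            labels=tuple(ps["labels"]),
            observed=np.asarray(ps["observed"], dtype=float),
            predicted=np.asarray(ps["predicted"], dtype=float),
            loo_slope=np.asarray(ps["loo_slope"], dtype=float),
            loo_intercept=np.asarray(ps["loo_intercept"], dtype=float),
            excluded=tuple(ps["excluded"]),
        )
    w = d["window"]
    window = WindowSummary(
        n=w["n"], n_below=w["n_below"], n_within=w["n_within"], n_above=w["n_above"]
    )
    cfg = dict(d["config"])
    cfg["clinical_limits"] = tuple(cfg["clinical_limits"])
    return ValidationReport(
        comparisons=comparisons,
        prediction=pred,
        prediction_set=pred_set,
        troughs=[TroughEstimate(**t) for t in d["troughs"]],
        window=window,
        qc=d["qc"],
        rejections=d["rejections"],
        config=ReportConfig(**cfg),
        meta=d["meta"],
    )


# -- rendering ---------------------------------------------------------


def _fmt2(v) -> str:
    return f"{v:.2f}"


def _fmt1p(v) -> str:
    return f"{v:.1f}%"


def render_markdown(report: ValidationReport) -> str:
    """Human-readable rendering (two decimals for concentrations/ratios,
    one for percentages)."""
    lines = ["# DBS validation report", ""]
    for name, c in report.comparisons.items():
        ci = c.pb.slope_ci
        aci = c.pb.intercept_ci
        lines += [
            f"## Agreement: {name} (n = {c.n})",
            "",
            f"- Passing-Bablok slope {_fmt2(c.pb.slope)}"
            + (f" (95% CI {_fmt2(ci[0])}–{_fmt2(ci[1])})" if ci else " (no CI)"),
            f"- Passing-Bablok intercept {_fmt2(c.pb.intercept)} µg/L"
            + (f" (95% CI {_fmt2(aci[0])}–{_fmt2(aci[1])})" if aci else " (no CI)"),
        ]
        if c.bias is not None:
            lines += [
                f"- Constant bias: {'yes' if c.bias.constant_bias else 'no'}; "
                f"proportional bias: {'yes' if c.bias.proportional_bias else 'no'}",
            ]
        lines += [
            f"- r = {_fmt2(c.r)} (r² = {_fmt2(c.r_squared)})",
            f"- Mean ratio ({c.ba.ratio_direction}) {_fmt2(c.ba.mean_ratio)} "
            f"(95% LoA {_fmt2(c.ba.loa[0])}–{_fmt2(c.ba.loa[1])})",
            f"- Outside clinical limits {_fmt2(c.ba.clinical_limits[0])}–"
            f"{_fmt2(c.ba.clinical_limits[1])}: "
            f"{c.ba.n_outside_clinical}/{c.ba.n} "
            f"({_fmt1p(100.0 * c.ba.n_outside_clinical / c.ba.n)})",
            "",
        ]
    m = report.prediction
    if m is not None:
        v = m.verdict
        lines += [
            f"## Predictive performance ({report.config.principal_pair}, n = {m.n})",
            "",
            f"- MPE {m.mpe:.3f} µg/L; MPPE {_fmt1p(m.mppe)}",
            f"- RMSE (root-median-square) {_fmt2(m.rmse_median)} µg/L; "
            f"MAPE {_fmt1p(m.mape)}",
            f"- RMSE (root-mean-square, for reference) {_fmt2(m.rmse_mean)} µg/L",
            f"- Samples with |percentage prediction error| < 20%: "
            f"{_fmt1p(m.fraction_within_20pct)}",
            f"- Cross-validation verdict: {'PASS' if v.passed else 'FAIL'}"
            + ("" if v.passed else " — " + "; ".join(v.reasons)),
            "",
        ]
    w = report.window
    lines += [
        "## Extrapolated trough concentrations",
        "",
        f"- Below {_fmt2(report.config.window_low)} µg/L: {_fmt1p(w.pct_below)}; "
        f"within window: {_fmt1p(w.pct_within)}; "
        f"above {_fmt2(report.config.window_high)} µg/L: {_fmt1p(w.pct_above)}",
        f"- Outside proposed therapeutic window: {_fmt1p(w.pct_outside)}",
        "",
    ]
    if report.qc:
        lines += ["## QC flags", ""]
        lines += [f"- {q['patient_id']}: {', '.join(q['flags'])}" for q in report.qc]
        lines += [""]
    if report.rejections:
        lines += ["## Rejected rows", ""]
        lines += [
            f"- row {r['row']} ({r['patient_id']}): {r['reason']}"
            for r in report.rejections
        ]
        lines += [""]
    return "\n".join(lines)


def _plot_comparison(c: ComparisonResult, pair: AnalysisPair, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # Bland-Altman: ratio vs mean concentration
    if c.ba.ratio_direction == "y/x":
        r = pair.y / pair.x
    else:
        r = pair.x / pair.y
    mean_conc = (pair.x + pair.y) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_conc, r, color="k", s=18)
    ax.axhline(c.ba.mean_ratio, color="b", label="mean ratio")
    for v in c.ba.loa:
        ax.axhline(v, color="b", ls="--", label=None)
    for v in c.ba.clinical_limits:
        ax.axhline(v, color="r", ls=":", label=None)
    ax.set_xlabel("mean concentration (µg/L)")
    ax.set_ylabel(f"ratio ({c.ba.ratio_direction})")
    ax.set_title(f"Bland-Altman: {c.pair_name}")
    fig.tight_layout()
    fig.savefig(outdir / f"ba_{c.pair_name}.png", dpi=150)
    plt.close(fig)

    # Passing-Bablok scatter with fitted line
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pair.x, pair.y, color="k", s=18)
    grid = np.linspace(pair.x.min(), pair.x.max(), 50)
    ax.plot(grid, c.pb.intercept + c.pb.slope * grid, "b-", label="Passing-Bablok")
    ax.plot(grid, grid, "g:", label="identity")
    ax.set_xlabel("comparator (µg/L)")
    ax.set_ylabel("reference (µg/L)")
    ax.set_title(f"Passing-Bablok: {c.pair_name}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / f"pb_{c.pair_name}.png", dpi=150)
    plt.close(fig)


def _plot_prediction(pred: PredictionSet, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = 100.0 * (pred.predicted - pred.observed) / pred.observed
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(pct)), pct, color="0.4")
    ax.axhline(20, color="r", ls="--")
    ax.axhline(-20, color="r", ls="--")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(range(len(pct)))
    ax.set_xticklabels(pred.labels, rotation=90, fontsize=7)
    ax.set_ylabel("percentage prediction error (%)")
    ax.set_title("Leave-one-out prediction error")
    fig.tight_layout()
    fig.savefig(outdir / "prediction_error.png", dpi=150)
    plt.close(fig)


def write_report(
    report: ValidationReport,
    outdir: str | Path,
    *,
    formats: tuple[str, ...] = ("json", "md"),
    plots: bool = True,
) -> list[Path]:
    """Write machine- and human-readable renderings (and plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = outdir / "report.json"
        p.write_text(json.dumps(report_to_dict(report), indent=2))
        written.append(p)
    if "md" in formats:
        p = outdir / "report.md"
        p.write_text(render_markdown(report))
        written.append(p)
    if plots and report.pairs:
        for name, c in report.comparisons.items():
            _plot_comparison(c, report.pairs[name], outdir)
            written += [outdir / f"ba_{name}.png", outdir / f"pb_{name}.png"]
        if report.prediction_set is not None:
            _plot_prediction(report.prediction_set, outdir)
            written.append(outdir / "prediction_error.png")
    return written
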