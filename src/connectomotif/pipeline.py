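"""Hypothesis pipeline (Q1-Q4) and motif reporting.

The four questions, run separately per hemisphere:

Q1  Does baseline connectivity (scan a) correlate with day-1 performance?
    SVD on the scan-a columns; Spearman of each motif's weights against
    day-1 double-embedding performance; Bonferroni family = motif count.
Q2  Does baseline connectivity correlate with the training gain
    (day 4 minus day 1)?  As Q1 with the performance change.
Q3  Does connectivity change (scan b minus scan a) correlate with the
    training gain?  SVD on scans a and b jointly; per-subject weight
    change per motif; Spearman against the performance change; family =
    motif count of that decomposition.
Q4  Are there group-level connectivity changes (b vs. a, c vs. a)?
    One Mann-Whitney U test per connection, Bonferroni over all
    connections.

Motif reports rank regions by node strength (sum of absolute motif
weights over incident connections) and connections by absolute weight
with sign preserved — the data behind chord plots and prevalence-vs-
performance regressions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .exceptions import DegenerateInputError, MissingDataError, UsageError
from .io import ConnectomeCohort, stack
from .stats import TestResult, bonferroni, connectionwise_group_test, spearman
from .svd import (
    MotifDecomposition,
    decompose,
    motif_as_matrix,
    weight_change_vector,
    weight_vector,
)


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs, serializable to the run metadata."""

    manifest: str = ""
    behavior_path: str = ""
    spans_path: str | None = None
    questions: tuple[str, ...] = ("q1", "q2", "q3", "q4")
    alpha: float = 0.05
    mode: str = "symmetric"
    sentence_type: str = "double"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise UsageError("alpha must be in (0, 1)")
        bad = [q for q in self.questions if q not in ("q1", "q2", "q3", "q4")]
        if bad:
            raise UsageError(f"unknown questions {bad}")


@dataclass
class QuestionResult:
    """One question's decomposition (if any) plus its per-motif tests."""

    question: str
    results: list[TestResult]
    decomposition: MotifDecomposition | None = None
    subjects: list[str] = field(default_factory=list)
    behavior_values: np.ndarray | None = None

    @property
    def significant(self) -> list[TestResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": [r.name for r in self.results],
                "statistic": [r.statistic for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_corrected": [r.p_corrected for r in self.results],
                "significant": [r.significant for r in self.results],
                "n": [r.n for r in self.results],
                "family_size": [r.family_size for r in self.results],
                "variable": [r.variable for r in self.results],
                "note": [r.note for r in self.results],
            }
        )


@dataclass
class MotifReport:
    """Reporting view of one motif: top regions, signed edges, regression pairs."""

    motif: int
    explained_variance: float
    top_regions: list[tuple[str, float]]
    top_connections: list[tuple[str, str, float]]
    prevalence: np.ndarray
    behavior_values: np.ndarray | None
    subjects: list[str]


def _complete_subjects(
    cohort: ConnectomeCohort, scans: list[str], question: str
) -> list[str]:
    """Subjects holding every requested scan; the rest are dropped with a warning."""
    keep = [s for s in cohort.subjects if all(cohort.has(s, sc) for sc in scans)]
    dropped = [s for s in cohort.subjects if s not in keep]
    if dropped:
        warnings.warn(
            f"{question}: dropping subjects missing scans {scans}: {dropped}",
            stacklevel=3,
        )
    if not keep:
        raise MissingDataError(f"{question}: no subject has all scans {scans}")
    return keep


def _motif_tests(
    xs: list[np.ndarray],
    y: np.ndarray,
    alpha: float,
    variable: str,
    degenerate_note: str,
) -> list[TestResult]:
    """Spearman of each motif's weight vector against y, Bonferroni over motifs."""
    family = len(xs)
    out: list[TestResult] = []
    for k, x in enumerate(xs):
        try:
            rho, p = spearman(x, y)
            note = ""
        except DegenerateInputError:
            if np.ptp(y) == 0:
                raise  # constant behavior invalidates every test in the family
            rho, p, note = math.nan, math.nan, degenerate_note
        out.append(
            TestResult(
                name=f"motif_{k + 1}",
                statistic=rho,
                p_raw=p,
                p_corrected=bonferroni(p, family) if not math.isnan(p) else math.nan,
                n=len(y),
                family_size=family,
                alpha=alpha,
                variable=variable,
                note=note,
            )
        )
    return out


def run_q1(
    cohort: ConnectomeCohort,
    behavior: beh.BehavioralTable,
    alpha: float = 0.05,
    mode: str = "symmetric",
    sentence_type: str = "double",
    scan: str = "a",
) -> QuestionResult:
    """Baseline connectivity vs. day-1 performance."""
    subjects = _complete_subjects(cohort, [scan], "Q1")
    y = beh.performance_vector(behavior, subjects, day=1, sentence_type=sentence_type)
    M, col_idx, index_map = stack(cohort, [scan], mode=mode, subjects=subjects)
    dec = decompose(M, col_idx, index_map, mode=mode)
    xs = [weight_vector(dec, k, subjects, scan) for k in range(dec.n_motifs)]
    results = _motif_tests(
        xs, y, alpha, f"day1_{sentence_type}_performance", "no weight variation"
    )
    return QuestionResult("q1", results, dec, subjects, y)


def run_q2(
    cohort: ConnectomeCohort,
    behavior: beh.BehavioralTable,
    alpha: float = 0.05,
    mode: str = "symmetric",
    sentence_type: str = "double",
    scan: str = "a",
) -> QuestionResult:
    """Baseline connectivity vs. training gain (day 4 minus day 1)."""
    subjects = _complete_subjects(cohort, [scan], "Q2")
    y = beh.performance_change_vector(behavior, subjects, sentence_type=sentence_type)
    M, col_idx, index_map = stack(cohort, [scan], mode=mode, subjects=subjects)
    dec = decompose(M, col_idx, index_map, mode=mode)
    xs = [weight_vector(dec, k, subjects, scan) for k in range(dec.n_motifs)]
    results = _motif_tests(
        xs, y, alpha, f"{sentence_type}_performance_change", "no weight variation"
    )
    return QuestionResult("q2", results, dec, subjects, y)


def run_q3(
    cohort: ConnectomeCohort,
    behavior: beh.BehavioralTable,
    alpha: float = 0.05,
    mode: str = "symmetric",
    sentence_type: str = "double",
    scans: tuple[str, str] = ("a", "b"),
) -> QuestionResult:
    """Connectivity change (scan b minus scan a) vs. training gain.

    Motifs whose weight change is constant across subjects (e.g. scan b
    identical to scan a) are reported with the note "no testable change"
    rather than a p-value.
    """
    subjects = _complete_subjects(cohort, list(scans), "Q3")
    y = beh.performance_change_vector(behavior, subjects, sentence_type=sentence_type)
    M, col_idx, index_map = stack(cohort, list(scans), mode=mode, subjects=subjects)
    dec = decompose(M, col_idx, index_map, mode=mode)
    xs = [
        weight_change_vector(dec, k, subjects, scans) for k in range(dec.n_motifs)
    ]
    # identical scans leave only floating-point residue in the weight change;
    # collapse near-constant changes so they report as untestable, not noise
    xs = [x if np.ptp(x) > 1e-10 else np.zeros_like(x) for x in xs]
    results = _motif_tests(
        xs, y, alpha, f"{sentence_type}_performance_change", "no testable change"
    )
    return QuestionResult("q3", results, dec, subjects, y)


def run_q4(
    cohort: ConnectomeCohort,
    alpha: float = 0.05,
    mode: str = "symmetric",
    baseline: str = "a",
    followups: tuple[str, ...] = ("b", "c"),
    paired: bool = False,
) -> dict[str, pd.DataFrame]:
    """Group-level per-connection change tests: each follow-up scan vs. baseline.

    Missing follow-up scans are skipped with a warning.  Returns a mapping
    like ``{"b_vs_a": table, "c_vs_a": table}``.
    """
    out: dict[str, pd.DataFrame] = {}
    for scan in followups:
        subjects = [
            s for s in cohort.subjects if cohort.has(s, baseline) and cohort.has(s, scan)
        ]
        if not subjects:
            warnings.warn(f"Q4: no subjects with scans {baseline} and {scan}; skipped",
                          stacklevel=2)
            continue
        out[f"{scan}_vs_{baseline}"] = connectionwise_group_test(
            cohort, baseline, scan, alpha=alpha, mode=mode,
            subjects=subjects, paired=paired,
        )
    if not out:
        raise MissingDataError("Q4: no comparison could be run")
    return out


def run_span_correlations(
    dec: MotifDecomposition,
    behavior: beh.BehavioralTable,
    subjects: list[str],
    scan: str = "a",
    alpha: float = 0.05,
) -> dict[str, list[TestResult]]:
    """Optional side analysis: motif weights vs. reading/digit span covariates."""
    out: dict[str, list[TestResult]] = {}
    xs = [weight_vector(dec, k, subjects, scan) for k in range(dec.n_motifs)]
    for span_type in ("reading_span", "digit_span"):
        try:
            y = beh.span_vector(behavior, subjects, span_type)
        except MissingDataError:
            continue
        out[span_type] = _motif_tests(xs, y, alpha, span_type, "no weight variation")
    return out


def report_motif(
    dec: MotifDecomposition,
    motif: int,
    behavior_values: np.ndarray | None = None,
    subjects: list[str] | None = None,
    top_k_regions: int = 9,
    edge_fraction: float = 0.5,
    edge_count: int | None = None,
    prevalence_values: np.ndarray | None = None,
) -> MotifReport:
    """Rank a motif's regions and connections for chord-plot-style reporting.

    Node strength of a region is the sum of absolute motif weights over
    its incident connections.  Edges are ranked by absolute weight; by
    default the smallest edge set covering ``edge_fraction`` of the
    motif's squared norm is reported, or exactly ``edge_count`` edges when
    given.
    """
    labels = sorted({r for pair in dec.index_map for r in pair},
                    key=lambda r: _label_order(dec, r))
    mat = motif_as_matrix(dec, motif)
    absmat = np.abs(mat)
    if dec.mode == "symmetric":
        strength = absmat.sum(axis=1)
    else:
        strength = absmat.sum(axis=1) + absmat.sum(axis=0)
    d = mat.shape[0]
    if top_k_regions > d:
        warnings.warn(f"top_k_regions={top_k_regions} exceeds {d} regions; clipped",
                      stacklevel=2)
        top_k_regions = d
    order = np.argsort(-strength, kind="stable")[:top_k_regions]
    top_regions = [(labels[i], float(strength[i])) for i in order]

    w = dec.motifs[:, motif]
    edge_order = np.argsort(-np.abs(w), kind="stable")
    if edge_count is not None:
        chosen = edge_order[: min(edge_count, len(w))]
    else:
        sq = np.cumsum(w[edge_order] ** 2)
        n_edges = int(np.searchsorted(sq, edge_fraction * sq[-1]) + 1)
        chosen = edge_order[:n_edges]
    top_connections = [
        (dec.index_map[i][0], dec.index_map[i][1], float(w[i])) for i in chosen
    ]

    if prevalence_values is not None:
        prevalence = np.asarray(prevalence_values, dtype=float)
    else:
        prevalence = dec.weights[motif, :]
    return MotifReport(
        motif=motif,
        explained_variance=float(dec.explained_variance[motif]),
        top_regions=top_regions,
        top_connections=top_connections,
        prevalence=prevalence.copy(),
        behavior_values=None if behavior_values is None else np.asarray(
            behavior_values, dtype=float),
        subjects=subjects or [s for s, _ in dec.column_index],
    )


def _label_order(dec: MotifDecomposition, label: str) -> int:
    # region order is implied by the first occurrences in the index map
    if not hasattr(dec, "_label_cache"):
        seen: dict[str, int] = {}
        for a, b in dec.index_map:
            for r in (a, b):
                if r not in seen:
                    seen[r] = len(seen)
        dec._label_cache = seen  # type: ignore[attr-defined]
    return dec._label_cache[label]  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Orchestration with file outputs
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def run_pipeline(
    cohort: ConnectomeCohort,
    behavior: beh.BehavioralTable,
    config: AnalysisConfig,
) -> dict[str, object]:
    """Run the configured questions; write deterministic result tables if
    ``config.out_dir`` is set.  Returns the in-memory results keyed by question."""
    results: dict[str, object] = {}
    if "q1" in config.questions:
        results["q1"] = run_q1(cohort, behavior, config.alpha, config.mode,
                               config.sentence_type)
    if "q2" in config.questions:
        results["q2"] = run_q2(cohort, behavior, config.alpha, config.mode,
                               config.sentence_type)
    if "q3" in config.questions:
        results["q3"] = run_q3(cohort, behavior, config.alpha, config.mode,
                               config.sentence_type)
    if "q4" in config.questions:
        results["q4"] = run_q4(cohort, config.alpha, config.mode)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta: dict[str, object] = {
            "alpha": config.alpha,
            "mode": config.mode,
            "sentence_type": config.sentence_type,
            "seed": config.seed,
            "questions": list(config.questions),
            "hemisphere": cohort.parcellation.hemisphere,
            "n_subjects": len(cohort.subjects),
            "n_regions": len(cohort.parcellation),
        }
        for q in ("q1", "q2", "q3"):
            if q not in results:
                continue
            qr: QuestionResult = results[q]  # type: ignore[assignment]
            qr.to_frame().to_csv(out / f"{q}_results.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
            meta[f"{q}_n_motifs"] = qr.decomposition.n_motifs
            meta[f"{q}_significant"] = [r.name for r in qr.significant]
            for r in qr.significant:
                k = int(r.name.split("_")[1]) - 1
                if q == "q3":
                    prev = weight_change_vector(qr.decomposition, k, qr.subjects)
                else:
                    prev = weight_vector(qr.decomposition, k, qr.subjects, "a")
                rep = report_motif(qr.decomposition, k, qr.behavior_values,
                                   qr.subjects, prevalence_values=prev)
                _write_motif_report(rep, out / f"{q}_{r.name}")
        if "q4" in results:
            q4: dict[str, pd.DataFrame] = results["q4"]  # type: ignore[assignment]
            meta["q4_significant_connections"] = {}
            for name, table in q4.items():
                table.to_csv(out / f"q4_{name}_connections.tsv", sep="\t",
                             index=False, float_format=_FLOAT_FMT)
                meta["q4_significant_connections"][name] = int(
                    table["significant"].sum()
                )
        (out / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return results


def _write_motif_report(report: MotifReport, prefix: Path) -> None:
    """Edge list, region ranking and regression pairs for one motif."""
    pd.DataFrame(report.top_connections,
                 columns=["source", "target", "weight"]).to_csv(
        f"{prefix}_edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(report.top_regions,
                 columns=["region", "node_strength"]).to_csv(
        f"{prefix}_regions.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if report.behavior_values is not None:
        n = len(report.behavior_values)
        pd.DataFrame(
            {
                "subject": report.subjects[:n],
                "prevalence": report.prevalence[:n],
                "behavior": report.behavior_values,
            }
        ).to_csv(f"{prefix}_regression.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
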