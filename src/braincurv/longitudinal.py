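"""Longitudinal statistics: curvature change ratios vs behavioral change.

The pipeline mirrors a pre/post imaging study design. Per subject, curvature
is computed at baseline and follow-up; change is the *ratio*
follow-up / baseline (curvature is unitless, so a ratio is interpretable
where a difference is not). Each edge and each node is then correlated —
Spearman, two-sided — against three behavioral change scores across
subjects. A unit is *selected* when it reaches p below the significance
threshold on at least two of the three measures; Benjamini-Hochberg FDR
q-values are computed per measure within each unit family (edges and nodes
are corrected separately).

Direction conventions: VABS-SS and EOW changes are follow-up minus baseline
(positive = improvement); CGI-I is the follow-up improvement rating itself,
where *lower* means more improvement. A unit whose robustness rises with
improvement therefore shows positive r on VABS-SS/EOW and negative r on
CGI-I.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .curvature import CurvatureResult, all_edge_curvatures
from .io import MEASURES, CohortRecord, remove_cross_hemisphere_edges

logger = logging.getLogger("braincurv")

Mode = Literal["edges", "nodes"]

#: Units with fewer paired observations than this cannot be correlated.
MIN_PAIRS = 4


class AnalysisError(ValueError):
    """Invalid input to the longitudinal pipeline."""


# ---------------------------------------------------------------------------
# Change ratios
# ---------------------------------------------------------------------------

def curvature_change(
    before: CurvatureResult,
    after: CurvatureResult,
    mode: Mode,
    epsilon: float = 1e-12,
) -> dict:
    """Per-unit curvature ratio after/before for one subject.

    A unit (edge pair or node) is excluded — not set to NaN or infinity —
    when it is absent at either timepoint or its baseline curvature is
    within ``epsilon`` of zero, where the ratio is numerically meaningless.
    Curvature can legitimately be negative, so ratios can be negative; they
    are kept as-is.
    """
    if mode == "edges":
        first = before.edge_curvature
        second = after.edge_curvature
    elif mode == "nodes":
        first = before.scalar_curvature
        second = after.scalar_curvature
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ratios = {}
    for unit, k0 in first.items():
        if unit not in second:
            logger.debug("unit %s absent at follow-up; excluded", unit)
            continue
        if abs(k0) < epsilon:
            logger.debug("unit %s has near-zero baseline curvature; excluded", unit)
            continue
        ratios[unit] = second[unit] / k0
    return ratios


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(
    changes: Sequence[float],
    behavior: Sequence[float],
    method: Literal["asymptotic", "exact"] = "asymptotic",
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks break ties; the p-value uses the t-distribution
    approximation (adequate at the cohort sizes this pipeline targets).
    ``method="exact"`` enumerates pairings instead — only sensible below
    ten subjects, where the t approximation is rough.
    """
    x = np.asarray(changes, dtype=float)
    y = np.asarray(behavior, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < MIN_PAIRS:
        raise AnalysisError(
            f"need at least {MIN_PAIRS} paired observations, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined for a constant vector")
    if method == "exact":
        if x.size > 9:
            raise AnalysisError("exact permutation p only supported for n <= 9")
        r = float(stats.spearmanr(x, y).statistic)
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        return r, float(res.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_batch(
    ratio_matrix: np.ndarray, behavior: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman r and two-sided t-approximation p for many units at once.

    ``ratio_matrix`` is (n_subjects, n_units); ``behavior`` is
    (n_subjects,). Column-wise identical to :func:`spearman` on complete
    data — used where thousands of correlations are needed (null
    calibration, permutation checks). Constant columns yield NaN.
    """
    x = np.asarray(ratio_matrix, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = x.shape[0]
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rx * ry[:, None]).sum(axis=0) / denom
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def benjamini_hochberg(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: q-values and rejection flags at level ``alpha``.

    Input order is preserved; q-values are invariant to it. NaN entries
    (undefined correlations) pass through as NaN, never rejected, and do
    not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qvals, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        q[finite] = qvals
        reject[finite] = rej
    return q, reject


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationRow:
    """Per-unit correlation results across the three behavioral measures."""

    unit_type: str                      # "edge" or "node"
    node_a: str
    node_b: str                         # empty for node units
    r: Mapping[str, float]
    p: Mapping[str, float]
    q: Mapping[str, float] = field(default_factory=dict)
    n_valid: int = 0
    mean_ratio: float = math.nan
    sd_ratio: float = math.nan
    selected: bool = False
    survives_fdr: bool = False
    unit_key: tuple = ()                # index-level key, for programmatic use


def run_analysis(cohort: Sequence[CohortRecord], config: RunConfig) -> list[CorrelationRow]:
    """Run the longitudinal curvature-behavior pipeline on a cohort.

    Steps: (1) optionally remove cross-hemisphere edges per subject;
    (2) compute edge and scalar curvature at both timepoints; (3) form
    per-unit follow-up/baseline curvature ratios; (4) keep units with at
    least ``min_valid`` defined ratios (default: the whole cohort);
    (5) Spearman-correlate ratios against each behavioral change score;
    (6) flag units significant on at least ``selection_min_measures``
    measures; (7) BH-correct per measure within each unit family.
    Undefined correlations (constant ratios) get NaN r/p and never count
    as significant.
    """
    if len(cohort) < MIN_PAIRS:
        raise AnalysisError(f"need at least {MIN_PAIRS} subjects, got {len(cohort)}")
    node_ids = cohort[0].baseline.node_ids
    for rec in cohort:
        if rec.baseline.node_ids != node_ids:
            raise AnalysisError(
                f"subject {rec.subject_id}: node ordering differs across the cohort"
            )
    min_valid = config.min_valid if config.min_valid is not None else len(cohort)

    # Per-subject curvature at both timepoints.
    ratio_tables: dict[str, list[dict]] = {"edges": [], "nodes": []}
    for rec in cohort:
        baseline, followup = rec.baseline, rec.followup
        if config.remove_cross_hemisphere:
            baseline = remove_cross_hemisphere_edges(baseline, config.keep_brainstem)
            followup = remove_cross_hemisphere_edges(followup, config.keep_brainstem)
        k0 = all_edge_curvatures(baseline, config.metric_kind)
        k1 = all_edge_curvatures(followup, config.metric_kind)
        for mode in ("edges", "nodes"):
            ratio_tables[mode].append(
                curvature_change(k0, k1, mode, config.epsilon)
            )

    behavior = {
        m: np.array([rec.behavior[m] for rec in cohort]) for m in MEASURES
    }

    rows: list[CorrelationRow] = []
    for mode in ("edges", "nodes"):
        per_subject = ratio_tables[mode]
        units = sorted({u for table in per_subject for u in table})
        unit_rows: list[CorrelationRow] = []
        n_dropped = 0
        for unit in units:
            values = np.array(
                [table.get(unit, np.nan) for table in per_subject], dtype=float
            )
            valid = np.isfinite(values)
            n_valid = int(valid.sum())
            if n_valid < max(min_valid, MIN_PAIRS):
                n_dropped += 1
                continue
            r: dict[str, float] = {}
            p: dict[str, float] = {}
            for m in MEASURES:
                try:
                    r[m], p[m] = spearman(values[valid], behavior[m][valid])
                except AnalysisError:
                    r[m], p[m] = math.nan, math.nan
            n_sig = sum(
                1 for m in MEASURES
                if np.isfinite(p[m]) and p[m] < config.selection_threshold
            )
            if mode == "edges":
                node_a, node_b = node_ids[unit[0]], node_ids[unit[1]]
            else:
                node_a, node_b = node_ids[unit], ""
            unit_rows.append(
                CorrelationRow(
                    unit_type=mode[:-1],
                    node_a=node_a,
                    node_b=node_b,
                    r=r,
                    p=p,
                    n_valid=n_valid,
                    mean_ratio=float(values[valid].mean()),
                    sd_ratio=float(values[valid].std(ddof=1)),
                    selected=n_sig >= config.selection_min_measures,
                    unit_key=unit if mode == "edges" else (unit,),
                )
            )
        logger.info(
            "%s: %d units, %d retained, %d dropped (min_valid=%d)",
            mode, len(units), len(unit_rows), n_dropped, min_valid,
        )
        # BH families: one per mode x measure.
        for m in MEASURES:
            q, _ = benjamini_hochberg([row.p[m] for row in unit_rows], config.alpha)
            for row, qm in zip(unit_rows, q):
                row.q[m] = float(qm)  # type: ignore[index]
        for row in unit_rows:
            n_q = sum(
                1 for m in MEASURES
                if np.isfinite(row.q[m]) and row.q[m] < config.alpha
            )
            object.__setattr__(
                row, "survives_fdr", n_q >= config.selection_min_measures
            )
        rows.extend(unit_rows)
    logger.info(
        "selected %d of %d units; %d survive FDR at alpha=%g",
        sum(r.selected for r in rows), len(rows),
        sum(r.survives_fdr for r in rows), config.alpha,
    )
    return rows


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

_MEASURE_TAGS = {"VABS-SS": "vabs", "EOW": "eow", "CGI-I": "cgi"}


def results_frame(rows: Sequence[CorrelationRow]) -> pd.DataFrame:
    """Flatten correlation rows into the tabular report layout."""
    out = []
    for row in rows:
        rec: dict = {
            "unit_type": row.unit_type,
            "node_a": row.node_a,
            "node_b": row.node_b,
        }
        for m in MEASURES:
            tag = _MEASURE_TAGS[m]
            rec[f"r_{tag}"] = row.r[m]
            rec[f"p_{tag}"] = row.p[m]
            rec[f"q_{tag}"] = row.q.get(m, math.nan)
        rec.update(
            n_valid=row.n_valid,
            mean_ratio=row.mean_ratio,
            sd_ratio=row.sd_ratio,
            selected=row.selected,
            survives_fdr=row.survives_fdr,
        )
        out.append(rec)
    return pd.DataFrame(out)


def write_results(rows: Sequence[CorrelationRow], path: str | Path) -> None:
    results_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    n_subjects: int = 19,
    n_units: int = 200,
    n_replicates: int = 500,
    threshold: float = 0.05,
    min_measures: int = 2,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the per-unit test and of the selection rule.

    Simulates curvature ratios independent of behavior (both i.i.d. normal),
    runs the per-unit Spearman tests and the two-of-three selection, and
    returns the observed false-positive rates. Behavior scores for the three
    measures share a latent factor, matching the generator's coupling, which
    the selection null rate inherits.
    """
    rng = np.random.default_rng(seed)
    n_tests = 0
    n_hits = 0
    n_selected = 0
    n_units_total = 0
    for _ in range(n_replicates):
        ratios = rng.standard_normal((n_subjects, n_units))
        latent = rng.standard_normal(n_subjects)
        sig_count = np.zeros(n_units, dtype=int)
        for sign in (1.0, 1.0, -1.0):  # VABS, EOW, CGI-I directions
            behavior = sign * latent + rng.standard_normal(n_subjects)
            _, p = spearman_batch(ratios, behavior)
            n_tests += n_units
            n_hits += int((p < threshold).sum())
            sig_count += p < threshold
        n_selected += int((sig_count >= min_measures).sum())
        n_units_total += n_units
    return {
        "type_i_rate": n_hits / n_tests,
        "selection_rate": n_selected / n_units_total,
        "n_tests": n_tests,
    }
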