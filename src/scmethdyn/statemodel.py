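"""Per-sample residual modeling and lineage-plot trajectory inference.

The core statistical idea: a treated cell's methylation change in a region
set is confounded by the set's starting methylation (highly methylated sets
have more room to lose) and by its CpG density.  For each sample, the
difference from the untreated-control mean is therefore regressed on the
control methylation level and the set's CpG percentage:

    diff_j = b0 + b1 * control_j + b2 * cpg_percent_j + r_j

The residual r_j is the change not explained by either covariate.  Region
sets whose residual distributions differ between endpoint and control
samples (two-sample t-test, p < alpha, up to ``max_sets`` per direction)
define two summary axes: the mean residual over positive sets (methylation
above expectation, y) and over negative sets (below expectation, x).  The
two scores position every sample — including intermediate time points not
used for selection — on the treatment-induced trajectory ("lineage plot").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ScoreMode = Literal["residual", "methylation"]


@dataclass
class ResidualTable:
    """Per-sample OLS fits of methylation difference on control level + CpG%.

    ``residuals``: samples x sets frame (NaN where a set lacked a complete
    (diff, control, cpg_percent) triple for that sample).  ``coefficients``:
    samples x (intercept, coef_control_meth, coef_cpg_percent).
    """

    residuals: pd.DataFrame
    coefficients: pd.DataFrame
    n_sets_fit: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.residuals.index)


@dataclass
class DifferentialSelection:
    """Region sets differentially methylated between treated and controls.

    Each entry is (set_name, t_statistic, p_value); positive sets have
    greater residuals in treated samples, negative the reverse.  At most
    ``max_sets`` per direction, all with p < ``alpha``.
    """

    positive_sets: list[tuple[str, float, float]]
    negative_sets: list[tuple[str, float, float]]
    alpha: float
    max_sets: int
    n_tested: int = 0
    n_skipped: int = 0

    @property
    def positive_names(self) -> list[str]:
        return [name for name, _, _ in self.positive_sets]

    @property
    def negative_names(self) -> list[str]:
        return [name for name, _, _ in self.negative_sets]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": "positive", "set_name": n, "t_statistic": t, "p_value": p}
            for n, t, p in self.positive_sets
        ] + [
            {"direction": "negative", "set_name": n, "t_statistic": t, "p_value": p}
            for n, t, p in self.negative_sets
        ]
        return pd.DataFrame(rows, columns=["direction", "set_name", "t_statistic", "p_value"])


@dataclass
class LineageScores:
    """Two summary coordinates per sample.

    ``x_neg``: mean score over the negative (below-expectation) sets;
    ``y_pos``: mean over the positive sets.  NaN when a sample lacks every
    set of a direction or a direction selected no sets.
    """

    scores: pd.DataFrame  # columns: x_neg, y_pos
    score_mode: ScoreMode

    def to_frame(self) -> pd.DataFrame:
        return self.scores.copy()


# ---------------------------------------------------------------------------
# control reference and normalization
# ---------------------------------------------------------------------------

def control_reference(matrix, control_ids: Sequence[str]) -> pd.Series:
    """Mean region-set methylation over the untreated control samples.

    Per set, the unweighted mean of the non-missing control values; a set
    with no non-missing control value is dropped from the reference.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control group is empty")
    values = matrix.values if hasattr(matrix, "values") and hasattr(matrix, "set_names") else matrix
    missing = set(control_ids) - set(values.index)
    if missing:
        raise KeyError(f"control ids absent from matrix: {sorted(missing)}")
    ref = values.loc[control_ids].mean(axis=0, skipna=True)
    return ref.dropna().rename("control_meth")


def normalize_to_control(matrix, reference: pd.Series) -> pd.DataFrame:
    """Subtract the per-set control value; sets absent from the reference
    and missing sample values propagate as NaN."""
    values = matrix.values if hasattr(matrix, "values") and hasattr(matrix, "set_names") else matrix
    return values.sub(reference.reindex(values.columns), axis=1)


# ---------------------------------------------------------------------------
# per-sample OLS residuals
# ---------------------------------------------------------------------------

def fit_residuals(
    diff_row: pd.Series,
    reference: pd.Series,
    cpg_percents: pd.Series,
) -> tuple[pd.Series, np.ndarray]:
    """OLS fit of one sample's differences on (1, control level, CpG%).

    Returns (residuals indexed like ``diff_row`` with NaN outside the fitted
    sets, coefficients [intercept, coef_control_meth, coef_cpg_percent]).
    Requires >= 3 sets with complete triples and a full-rank design.
    """
    aligned = pd.DataFrame(
        {
            "diff": diff_row,
            "ref": reference.reindex(diff_row.index),
            "cpg": cpg_percents.reindex(diff_row.index),
        }
    ).dropna()
    if len(aligned) < 3:
        raise ValueError(
            f"need >= 3 region sets with complete data to fit, got {len(aligned)}"
        )
    X = np.column_stack(
        [np.ones(len(aligned)), aligned["ref"].to_numpy(), aligned["cpg"].to_numpy()]
    )
    if np.linalg.matrix_rank(X) < 3:
        if np.ptp(X[:, 1]) == 0:
            culprit = "control_meth (constant)"
        elif np.ptp(X[:, 2]) == 0:
            culprit = "cpg_percent (constant)"
        else:
            culprit = "control_meth and cpg_percent (collinear)"
        raise ValueError(f"rank-deficient design: {culprit}")
    y = aligned["diff"].to_numpy()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    residuals = pd.Series(np.nan, index=diff_row.index, dtype=float)
    residuals.loc[aligned.index] = y - fitted
    return residuals, coef


def fit_residual_table(
    diff: pd.DataFrame,
    reference: pd.Series,
    cpg_percents: pd.Series,
) -> ResidualTable:
    """Fit the per-sample linear model for every row of the difference matrix."""
    residual_rows = {}
    coef_rows = {}
    n_fit = {}
    for sample_id, row in diff.iterrows():
        res, coef = fit_residuals(row, reference, cpg_percents)
        residual_rows[sample_id] = res
        coef_rows[sample_id] = coef
        n_fit[sample_id] = int(res.notna().sum())
    residuals = pd.DataFrame(residual_rows).T
    residuals.index.name = "sample_id"
    coefficients = pd.DataFrame(
        coef_rows, index=["intercept", "coef_control_meth", "coef_cpg_percent"]
    ).T
    return ResidualTable(
        residuals=residuals,
        coefficients=coefficients,
        n_sets_fit=pd.Series(n_fit, name="n_sets_fit"),
    )


# ---------------------------------------------------------------------------
# differential selection
# ---------------------------------------------------------------------------

def select_differential(
    residuals: pd.DataFrame,
    treated_ids: Sequence[str],
    control_ids: Sequence[str],
    alpha: float = 0.01,
    max_sets: int = 20,
    equal_var: bool = False,
    fdr: bool = False,
) -> DifferentialSelection:
    """Select up to ``max_sets`` differential region sets per direction.

    Per set, a two-sided two-sample t-test (Welch by default) compares
    treated versus control residual distributions.  Sets with p < alpha are
    split by the sign of (treated mean - control mean); within each
    direction the smallest p-values are kept, with deterministic
    tie-breaking (p ascending, |mean difference| descending, name
    ascending).  Sets with fewer than two residual values in either group
    are skipped.  With ``fdr=True``, Benjamini-Hochberg-adjusted p-values
    are thresholded instead of raw ones.
    """
    treated_ids, control_ids = list(treated_ids), list(control_ids)
    if not treated_ids or not control_ids:
        raise ValueError("treated and control groups must both be non-empty")
    records = []
    n_skipped = 0
    for set_name in residuals.columns:
        a = residuals.loc[treated_ids, set_name].dropna().to_numpy()
        b = residuals.loc[control_ids, set_name].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            n_skipped += 1
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        records.append((set_name, float(t), float(p), float(a.mean() - b.mean())))
    if n_skipped:
        logger.info("select_differential: skipped %d untestable sets", n_skipped)
    if not records:
        return DifferentialSelection([], [], alpha, max_sets, 0, n_skipped)
    pvals = np.array([r[2] for r in records])
    if fdr:
        adjusted = stats.false_discovery_control(pvals, method="bh")
        records = [
            (name, t, float(q), d)
            for (name, t, _, d), q in zip(records, adjusted)
        ]
    candidates = [r for r in records if np.isfinite(r[2]) and r[2] < alpha]

    def _top(direction: int) -> list[tuple[str, float, float]]:
        pool = [r for r in candidates if np.sign(r[3]) == direction]
        pool.sort(key=lambda r: (r[2], -abs(r[3]), r[0]))
        return [(name, t, p) for name, t, p, _ in pool[:max_sets]]

    return DifferentialSelection(
        positive_sets=_top(+1),
        negative_sets=_top(-1),
        alpha=alpha,
        max_sets=max_sets,
        n_tested=len(records),
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# lineage scores and full trajectory
# ---------------------------------------------------------------------------

def lineage_scores(
    selection: DifferentialSelection,
    scores_source: pd.DataFrame,
    score_mode: ScoreMode = "residual",
) -> LineageScores:
    """Average the selected sets into two coordinates per sample.

    ``scores_source`` is the residual table (mode "residual") or the raw
    region-set methylation matrix (mode "methylation"); y averages the
    positive sets, x the negative sets.  A direction without selected sets
    yields NaN for every sample.
    """
    if not selection.positive_sets and not selection.negative_sets:
        raise ValueError("selection is empty in both directions")
    frame = scores_source.values if hasattr(scores_source, "set_names") else scores_source

    def _axis(names: list[str]) -> pd.Series:
        present = [n for n in names if n in frame.columns]
        if not present:
            return pd.Series(np.nan, index=frame.index)
        return frame[present].mean(axis=1, skipna=True)

    out = pd.DataFrame(
        {
            "x_neg": _axis(selection.negative_names),
            "y_pos": _axis(selection.positive_names),
        }
    )
    out.index.name = "sample_id"
    return LineageScores(scores=out, score_mode=score_mode)


@dataclass
class TrajectoryResult:
    reference: pd.Series
    residual_table: ResidualTable
    selection: DifferentialSelection
    scores: LineageScores


def run_trajectory(
    matrix,
    cpg_percents: pd.Series,
    control_ids: Sequence[str],
    endpoint_ids: Sequence[str],
    alpha: float = 0.01,
    max_sets: int = 20,
    score_mode: ScoreMode = "residual",
    equal_var: bool = False,
    fdr: bool = False,
) -> TrajectoryResult:
    """Full trajectory inference over a region-set matrix.

    The differential selection is fitted on endpoint versus control samples
    only; residuals and lineage scores are computed for every sample in the
    matrix, so intermediate time points are placed on the trajectory without
    having influenced the selection.
    """
    control_ids, endpoint_ids = list(control_ids), list(endpoint_ids)
    if set(control_ids) & set(endpoint_ids):
        raise ValueError("endpoint and control groups must be disjoint")
    reference = control_reference(matrix, control_ids)
    diff = normalize_to_control(matrix, reference)
    table = fit_residual_table(diff, reference, cpg_percents)
    selection = select_differential(
        table.residuals,
        treated_ids=endpoint_ids,
        control_ids=control_ids,
        alpha=alpha,
        max_sets=max_sets,
        equal_var=equal_var,
        fdr=fdr,
    )
    source = (
        table.residuals
        if score_mode == "residual"
        else (matrix.values if hasattr(matrix, "set_names") else matrix)
    )
    scores = lineage_scores(selection, source, score_mode=score_mode)
    return TrajectoryResult(
        reference=reference, residual_table=table, selection=selection, scores=scores
    )


def plot_lineage(scores: LineageScores, groups: pd.Series | None = None, path=None):
    """Scatter the lineage plot (x = negative-set score, y = positive-set score)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    df = scores.scores
    if groups is not None:
        for label, sub in df.groupby(groups.reindex(df.index)):
            ax.scatter(sub["x_neg"], sub["y_pos"], label=str(label), s=30)
        ax.legend(frameon=False)
    else:
        ax.scatter(df["x_neg"], df["y_pos"], s=30)
    ax.set_xlabel(f"negative-set score ({scores.score_mode})")
    ax.set_ylabel(f"positive-set score ({scores.score_mode})")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
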