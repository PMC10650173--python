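"""Cross-modality group statistics and correlation analysis.

Implements the study-level statistics linking the AFM and FLIM measurements:
one-way ANOVA with a Bonferroni post hoc (pairwise pooled-variance t-tests,
used for microviscosity and lipid data), Kruskal-Wallis with Dunn's multiple
comparisons (used for the AFM map means), printed-convention significance
stars, the line-level Pearson correlation matrix across modalities
(Young's modulus, E0, eta, alpha, cell height, microviscosity), and a
deterministic study report.

Correlations are computed on per-line mean values by default — the study's
headline correlation (stiffness vs membrane microviscosity, r = 0.93) is a
line-level quantity; pooled per-cell correlation is available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODALITY_LABELS = {
    "E_hertz": "YM",
    "E0": "E0",
    "eta": "eta",
    "alpha": "alpha",
    "height": "height",
    "viscosity": "MV",
}


@dataclass
class GroupSeries:
    """Values of one modality for one group (cell line)."""

    label: str
    values: np.ndarray
    modality: str = ""
    units: str = ""

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PairwiseTable:
    """Omnibus statistic plus pairwise adjusted p-values with star labels."""

    test: str
    statistic: float
    p_value: float
    pairs: pd.DataFrame
    degenerate: bool = False


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over per-line means."""

    labels: list[str]
    r: pd.DataFrame
    n: int

    def __post_init__(self):
        vals = self.r.to_numpy(float)
        assert np.allclose(vals, vals.T), "correlation matrix must be symmetric"


def significance_stars(p: float) -> str:
    """Printed star convention: * p<=0.05, ** p<=0.01, *** p<=0.001,
    **** p<0.0001 (note the strict inequality on the last level)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _as_groups(series) -> list[GroupSeries]:
    if isinstance(series, dict):
        return [GroupSeries(label=k, values=np.asarray(v, float)) for k, v in series.items()]
    return list(series)


def group_compare_anova(series) -> PairwiseTable:
    """One-way ANOVA with Bonferroni-adjusted pairwise post hoc comparisons.

    Pairwise tests use the pooled within-group mean square from the ANOVA
    (t with N-k degrees of freedom); adjusted p is min(1, m*p) over the
    m = k*(k-1)/2 comparisons.
    """
    groups = _as_groups(series)
    if len(groups) < 2 or any(g.n < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    vals = [g.values for g in groups]
    N = sum(g.n for g in groups)
    k = len(groups)
    grand = np.concatenate(vals).mean()
    ss_between = sum(g.n * (g.values.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    degenerate = ss_within == 0 and ss_between == 0
    if ss_within == 0 and not degenerate:
        F, p = np.inf, 0.0
        mse = 0.0
    elif degenerate:
        F, p, mse = 0.0, 1.0, 0.0
        logger.warning("ANOVA degenerate: zero variance everywhere")
    else:
        mse = ss_within / (N - k)
        F = (ss_between / (k - 1)) / mse
        p = float(stats.f.sf(F, k - 1, N - k))
    m = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if mse > 0:
            t = (a.values.mean() - b.values.mean()) / np.sqrt(mse * (1 / a.n + 1 / b.n))
            praw = float(2 * stats.t.sf(abs(t), N - k))
        else:
            t = 0.0 if a.values.mean() == b.values.mean() else np.inf
            praw = 1.0 if t == 0.0 else 0.0
        padj = min(1.0, m * praw)
        rows.append(
            {
                "group_a": a.label,
                "group_b": b.label,
                "statistic": float(t),
                "p_raw": praw,
                "p_adjusted": padj,
                "stars": significance_stars(padj),
            }
        )
    return PairwiseTable(
        test="anova_bonferroni",
        statistic=float(F),
        p_value=float(p),
        pairs=pd.DataFrame(rows),
        degenerate=degenerate,
    )


def group_compare_kw(series) -> PairwiseTable:
    """Kruskal-Wallis H test with Dunn's pairwise multiple comparisons.

    Dunn's z statistics use mean ranks of the pooled sample with the standard
    tie correction; pairwise p-values are Bonferroni-adjusted.
    """
    groups = _as_groups(series)
    if len(groups) < 2 or any(g.n < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    vals = [g.values for g in groups]
    pooled = np.concatenate(vals)
    if np.ptp(pooled) == 0:
        H, p = 0.0, 1.0
        logger.warning("Kruskal-Wallis degenerate: all values identical")
    else:
        H, p = stats.kruskal(*vals)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    # mean rank per group
    mean_ranks, ns = [], []
    pos = 0
    for v in vals:
        mean_ranks.append(ranks[pos : pos + v.size].mean())
        ns.append(v.size)
        pos += v.size
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(groups), 2):
        se = np.sqrt(var_base * (1.0 / ns[ia] + 1.0 / ns[ib]))
        z = (mean_ranks[ia] - mean_ranks[ib]) / se if se > 0 else 0.0
        praw = float(2 * stats.norm.sf(abs(z)))
        padj = min(1.0, m * praw)
        rows.append(
            {
                "group_a": a.label,
                "group_b": b.label,
                "statistic": float(z),
                "p_raw": praw,
                "p_adjusted": padj,
                "stars": significance_stars(padj),
            }
        )
    return PairwiseTable(
        test="kruskal_dunn",
        statistic=float(H),
        p_value=float(p),
        pairs=pd.DataFrame(rows),
        degenerate=bool(np.ptp(pooled) == 0),
    )


def correlation_matrix(
    line_means: pd.DataFrame,
    permutation_p: bool = False,
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[CorrelationMatrix, pd.DataFrame | None]:
    """Pairwise Pearson correlations over per-line mean values.

    ``line_means`` has one row per cell line and one column per modality
    (e.g. E_hertz, E0, eta, alpha, height, viscosity).  Requires >= 3 lines.
    Because the number of lines is small, no parametric p-values are
    attached; with ``permutation_p=True`` a permutation p-value table is
    returned alongside.
    """
    if len(line_means) < 3:
        raise ValueError("need >= 3 lines for a correlation matrix")
    r = line_means.corr(method="pearson")
    cm = CorrelationMatrix(labels=list(line_means.columns), r=r, n=len(line_means))
    perm = None
    if permutation_p:
        rng = np.random.default_rng(seed)
        cols = list(line_means.columns)
        perm = pd.DataFrame(np.nan, index=cols, columns=cols)
        X = line_means.to_numpy(float)
        for i, j in itertools.combinations(range(len(cols)), 2):
            obs = abs(r.iloc[i, j])
            y = X[:, j].copy()
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(y)
                rp = np.corrcoef(X[:, i], y)[0, 1]
                count += abs(rp) >= obs - 1e-12
            pv = (count + 1) / (n_permutations + 1)
            perm.iloc[i, j] = perm.iloc[j, i] = pv
        np.fill_diagonal(perm.values, 0.0)
    return cm, perm


def pooled_cell_correlation(
    cells_a: pd.DataFrame, cells_b: pd.DataFrame, value_a: str, value_b: str
) -> float:
    """Pooled per-cell correlation across lines (flagged alternative to the
    default line-level correlation; mixes within- and between-line variance)."""
    merged = cells_a[["line", value_a]].merge(cells_b[["line", value_b]], on="line")
    return float(np.corrcoef(merged[value_a], merged[value_b])[0, 1])


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Deterministic summary of a full study analysis."""

    line_summaries: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    correlations: CorrelationMatrix | None = None
    qc: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name, df in self.line_summaries.items():
            out[f"summary_{name}"] = df
        for name, tbl in self.tests.items():
            out[f"test_{name}"] = tbl.pairs
        if self.correlations is not None:
            out["correlation_matrix"] = self.correlations.r
        return out


def report(
    viscosity_cells: pd.DataFrame | None = None,
    map_means: pd.DataFrame | None = None,
    lipid_table: pd.DataFrame | None = None,
    calib=None,
) -> StudyReport:
    """Assemble the study report from whichever modalities are available.

    ``viscosity_cells``: per-cell rows (line, tau_ns or viscosity_cP, accepted);
    ``map_means``: per-map rows (line, E_hertz_Pa, E0_Pa, alpha, eta_Pas,
    height_nm); ``lipid_table``: normalized yields.  Sections for missing
    modalities are omitted with a note.  Output is deterministic given the
    inputs.
    """
    from . import flim_viscosity as fv
    from . import lipid_profile as lp

    rep = StudyReport()
    line_means: dict[str, pd.Series] = {}

    if viscosity_cells is not None and len(viscosity_cells):
        cells = viscosity_cells.copy()
        if "viscosity_cP" not in cells:
            if calib is None:
                calib = fv.fit_fh_calibration()
            cells["viscosity_cP"] = fv.lifetime_to_viscosity(
                cells["tau_ns"].to_numpy(), calib, warn=False
            )
        if "accepted" not in cells:
            cells["accepted"] = True
        acc = cells[cells["accepted"].astype(bool)]
        summary = (
            acc.groupby("line", sort=False)["viscosity_cP"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
        rep.line_summaries["viscosity"] = summary
        rep.tests["viscosity_anova"] = group_compare_anova(
            {ln: g["viscosity_cP"].to_numpy() for ln, g in acc.groupby("line", sort=False)}
        )
        line_means["viscosity"] = acc.groupby("line", sort=False)["viscosity_cP"].mean()
        rep.qc["n_cells"] = int(len(cells))
        rep.qc["n_cells_rejected"] = int((~cells["accepted"].astype(bool)).sum())
    else:
        rep.notes.append("no FLIM microviscosity data; section omitted")

    if map_means is not None and len(map_means):
        cols = {
            "E_hertz": "E_hertz_Pa",
            "E0": "E0_Pa",
            "alpha": "alpha",
            "eta": "eta_Pas",
            "height": "height_nm",
        }
        for name, col in cols.items():
            if col not in map_means or map_means[col].dropna().empty:
                continue
            groups = {
                ln: g[col].dropna().to_numpy()
                for ln, g in map_means.groupby("line", sort=False)
            }
            summary = (
                map_means.groupby("line", sort=False)[col]
                .agg(mean="mean", sd="std", n="count")
                .reset_index()
            )
            rep.line_summaries[name] = summary
            if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                rep.tests[f"{name}_kruskal_dunn"] = group_compare_kw(groups)
            line_means[name] = map_means.groupby("line", sort=False)[col].mean()
        rep.qc["n_maps"] = int(len(map_means))
    else:
        rep.notes.append("no AFM map data; section omitted")

    if lipid_table is not None and len(lipid_table):
        norm = (
            lipid_table
            if "ion_yield" in lipid_table
            else lp.normalize_ion_yields(lipid_table)
        )
        rep.line_summaries["lipids"] = (
            norm.groupby(["line", "component"], sort=False)["ion_yield"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
        if "viscosity" in line_means:
            rep.line_summaries["lipid_viscosity_corr"] = lp.correlate_lipids_viscosity(
                norm, line_means["viscosity"]
            )
    else:
        rep.notes.append("no ToF-SIMS lipid data; section omitted")

    if len(line_means) >= 2:
        lm = pd.DataFrame(line_means).dropna()
        if len(lm) >= 3:
            rep.correlations, _ = correlation_matrix(lm)
        else:
            rep.notes.append("fewer than 3 lines with joint means; correlations omitted")
    return rep
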