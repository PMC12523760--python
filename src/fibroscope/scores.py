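"""Trait selection, normalization, and composite fibrosis scoring.

Traits that change between the peri-papillary and remote groups (absolute
group mean change above a threshold, default 20%, with a two-sided
Mann-Whitney p below alpha, default 0.05) are min-max normalized across
the cohort, oriented so that larger always means more fibrotic, and
averaged -- equi-weighted -- into four composite fibrosis scores:

* Ph-FCS: phenotype score over the union of all selected traits,
* CCS: collagen content family,
* MCS: morphometry family,
* ACS: architecture family,

each scaled to [0, scale] (default 10).  The absolute scale is a
presentation choice; only direction and significance of group differences
are meaningful.  Fine/assembled sub-scores are derived from the stratum tag
of selected morphometry traits.

Group comparisons use the unpaired two-sided Mann-Whitney U test: exact
(full enumeration of the U null) when both groups have at most 8
observations and there are no ties, otherwise a normal approximation with
tie and continuity corrections; the method used is recorded.  A paired
Wilcoxon signed-rank alternative is available but off by default.  No
multiple-testing correction is applied to per-trait selection by default;
Benjamini-Hochberg q-values are reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .qft import TraitCatalog, trait_catalog

__all__ = [
    "MWUResult",
    "SelectionResult",
    "CompositeResult",
    "SCORE_FAMILIES",
    "mann_whitney_u",
    "group_mean_change",
    "select_traits",
    "normalize_traits",
    "composite_scores",
    "score_study",
    "significance_stars",
    "report",
]

SCORE_FAMILIES = {"Ph-FCS": None, "CCS": "content", "MCS": "morphometry", "ACS": "architecture"}
REGIONS = ("peri_papillary", "remote")


@dataclass
class MWUResult:
    U: float  # U statistic for the first sample
    p: float  # two-sided
    method: str  # "exact" | "asymptotic"


@lru_cache(maxsize=256)
def _null_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of the C(m+n, m) group assignments yielding each U value.

    Classic recurrence on the largest observation: if it belongs to the
    first sample it contributes n exceedances, N(u; m, n) =
    N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    table: dict[tuple[int, int], np.ndarray] = {}
    for a in range(m + 1):
        for b in range(n + 1):
            if a == 0 or b == 0:
                arr = np.zeros(1, dtype=np.int64)
                arr[0] = 1
            else:
                arr = np.zeros(a * b + 1, dtype=np.int64)
                prev1 = table[a - 1, b]
                arr[b : b + len(prev1)] += prev1
                prev2 = table[a, b - 1]
                arr[: len(prev2)] += prev2
            table[a, b] = arr
    return tuple(int(v) for v in table[m, n])


def mann_whitney_u(x, y, method: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test; U is reported for ``x``.

    ``method='auto'`` uses the exact null distribution (enumeration over
    all C(n1+n2, n1) group assignments) when n1, n2 <= 8 and there are no
    ties, and the tie- and continuity-corrected normal approximation
    otherwise.  Degenerate all-identical input gives U = n1*n2/2, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if method == "auto":
        method = "exact" if (n1 <= 8 and n2 <= 8 and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        counts = np.asarray(_null_counts(n1, n2), dtype=float)
        total = counts.sum()
        u_int = int(round(u1))
        cdf_le = counts[: u_int + 1].sum() / total
        cdf_ge = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
        return MWUResult(u1, p, "exact")

    n = n1 + n2
    mean = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MWUResult(u1, 1.0, "asymptotic")
    z = (abs(u1 - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MWUResult(u1, p, "asymptotic")


def group_mean_change(x, y, nonnegative: bool = False) -> float:
    """Percent group mean change, 100 * (mean_x - mean_y) / |mean_y|.

    A zero reference mean with a non-zero contrast mean is flagged as
    infinite change; both zero gives 0.  ``nonnegative=True`` enforces the
    non-negative domain of content/count-like traits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if nonnegative and (np.any(x < 0) or np.any(y < 0)):
        raise ValueError("trait values must be non-negative")
    mx, my = float(x.mean()), float(y.mean())
    if my == 0.0:
        return 0.0 if mx == 0.0 else float("inf") * np.sign(mx)
    return 100.0 * (mx - my) / abs(my)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


@dataclass
class SelectionResult:
    """Per-trait group statistics and the selected flag."""

    table: pd.DataFrame  # index: trait name
    alpha: float
    change_min: float
    p_direction: str  # "less" (standard) or "greater" (literal printed rule)

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def select_traits(
    traits: pd.DataFrame,
    study: pd.DataFrame,
    catalog: TraitCatalog | None = None,
    alpha: float = 0.05,
    change_min: float = 20.0,
    p_direction: str = "less",
    max_missing_fraction: float = 0.5,
) -> SelectionResult:
    """Flag traits with |group mean change| > ``change_min`` and a
    Mann-Whitney p on the selected side of ``alpha``.

    ``traits`` is the wide sample x trait matrix; ``study`` maps sample_id
    to region.  Traits missing in more than ``max_missing_fraction`` of
    samples are dropped from selection (logged in the table); otherwise
    pairwise-complete values are used.  ``p_direction='greater'`` runs the
    literal p > alpha reading of the selection rule.
    """
    if catalog is None:
        catalog = trait_catalog()
    study = study.set_index("sample_id") if "sample_id" in study.columns else study
    region = study.loc[traits.index, "region"]
    peri = traits.index[region == "peri_papillary"]
    remote = traits.index[region == "remote"]
    if len(peri) == 0 or len(remote) == 0:
        raise ValueError("both regions must be present in the study table")

    rows = []
    for name in traits.columns:
        tdef = catalog.by_name.get(name)
        col = traits[name]
        xs = col.loc[peri].to_numpy(dtype=float)
        ys = col.loc[remote].to_numpy(dtype=float)
        missing_frac = float(np.isnan(col.to_numpy(dtype=float)).mean())
        xs_ok, ys_ok = xs[~np.isnan(xs)], ys[~np.isnan(ys)]
        row = {
            "trait": name,
            "family": tdef.family if tdef else "unknown",
            "compartment": tdef.compartment if tdef else "unknown",
            "stratum": (tdef.stratum or "") if tdef else "",
            "direction": tdef.direction if tdef else 1,
            "n_peri": len(xs_ok),
            "n_remote": len(ys_ok),
            "missing_fraction": missing_frac,
            "mean_peri": float(np.nan),
            "mean_remote": float(np.nan),
            "delta_pct": float(np.nan),
            "U": float(np.nan),
            "p": float(np.nan),
            "method": "",
            "selected": False,
            "excluded_reason": "",
        }
        if missing_frac > max_missing_fraction:
            row["excluded_reason"] = "missing_gt_50pct"
        elif len(xs_ok) == 0 or len(ys_ok) == 0:
            row["excluded_reason"] = "group_missing"
        else:
            row["mean_peri"] = float(xs_ok.mean())
            row["mean_remote"] = float(ys_ok.mean())
            row["delta_pct"] = group_mean_change(xs_ok, ys_ok)
            res = mann_whitney_u(xs_ok, ys_ok)
            row["U"], row["p"], row["method"] = res.U, res.p, res.method
            change_ok = abs(row["delta_pct"]) > change_min
            sig_ok = (row["p"] < alpha) if p_direction == "less" else (row["p"] > alpha)
            row["selected"] = bool(change_ok and sig_ok)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("trait")
    table["q_bh"] = _bh_qvalues(table["p"].to_numpy(dtype=float))
    return SelectionResult(table, alpha, change_min, p_direction)


def normalize_traits(
    traits: pd.DataFrame, catalog: TraitCatalog | None = None
) -> pd.DataFrame:
    """Orient by catalog direction, then min-max scale each trait to [0, 1].

    Constant traits (zero range across the cohort) are dropped.  Min-max
    scaling is invariant to positive affine rescaling of the raw values.
    """
    if catalog is None:
        catalog = trait_catalog()
    out = {}
    for name in traits.columns:
        col = traits[name].to_numpy(dtype=float)
        tdef = catalog.by_name.get(name)
        direction = tdef.direction if tdef else 1
        finite = col[np.isfinite(col)]
        if finite.size < 2 or np.ptp(finite) == 0:
            continue  # constant or degenerate trait carries no contrast
        lo, hi = float(finite.min()), float(finite.max())
        z = (col - lo) / (hi - lo)
        if direction < 0:
            z = 1.0 - z
        out[name] = z
    return pd.DataFrame(out, index=traits.index)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CompositeResult:
    """Per-sample composite scores plus group statistics for one compartment."""

    compartment: str
    scores: pd.DataFrame  # index: sample_id; columns: score names
    stats: pd.DataFrame  # index: score name
    selection: SelectionResult
    boxplot: pd.DataFrame
    empty_selection: bool = False
    scale: float = 10.0
    trait_ledger: dict[str, list[str]] = field(default_factory=dict)


def _box_stats(v: np.ndarray) -> dict[str, float]:
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    return {
        "min": float(v.min()),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "max": float(v.max()),
    }


def composite_scores(
    normalized: pd.DataFrame,
    study: pd.DataFrame,
    selection: SelectionResult,
    catalog: TraitCatalog | None = None,
    scale: float = 10.0,
    compartment: str = "whole",
    test: str = "unpaired",
) -> CompositeResult:
    """Equi-weighted composite scores and their group comparison.

    Each family score is ``scale`` times the unweighted mean of that
    family's selected, normalized traits; the phenotype score (Ph-FCS)
    averages the union of all selected traits.  All four families are
    always reported; an empty family yields NaN scores.  ``test='paired'``
    compares groups with the Wilcoxon signed-rank test on within-patient
    pairs instead of the default unpaired Mann-Whitney U.
    """
    if catalog is None:
        catalog = trait_catalog()
    study = study.set_index("sample_id") if "sample_id" in study.columns else study
    sel_names = [n for n in selection.selected if n in normalized.columns]
    families = {
        score: (
            sel_names
            if fam is None
            else [n for n in sel_names if catalog.by_name[n].family == fam]
        )
        for score, fam in SCORE_FAMILIES.items()
    }
    # stratum-tagged sub-scores over selected morphometry/architecture traits
    for stratum in ("fine", "assembled"):
        families[f"FCS_{stratum}"] = [
            n for n in sel_names if catalog.by_name[n].stratum == stratum
        ]

    scores = pd.DataFrame(index=normalized.index)
    for score, names in families.items():
        if names:
            scores[score] = scale * normalized[names].mean(axis=1, skipna=True)
        else:
            scores[score] = float("nan")

    region = study.loc[scores.index, "region"]
    peri_idx = scores.index[region == "peri_papillary"]
    remote_idx = scores.index[region == "remote"]
    stat_rows, box_rows = [], []
    for score in scores.columns:
        xs = scores.loc[peri_idx, score].to_numpy(dtype=float)
        ys = scores.loc[remote_idx, score].to_numpy(dtype=float)
        xs_ok, ys_ok = xs[np.isfinite(xs)], ys[np.isfinite(ys)]
        row = {
            "score": score,
            "n_traits": len(families[score]),
            "mean_peri": float(xs_ok.mean()) if xs_ok.size else float("nan"),
            "sd_peri": float(xs_ok.std(ddof=1)) if xs_ok.size > 1 else float("nan"),
            "mean_remote": float(ys_ok.mean()) if ys_ok.size else float("nan"),
            "sd_remote": float(ys_ok.std(ddof=1)) if ys_ok.size > 1 else float("nan"),
            "median_peri": float(np.median(xs_ok)) if xs_ok.size else float("nan"),
            "median_remote": float(np.median(ys_ok)) if ys_ok.size else float("nan"),
            "U": float("nan"),
            "p": float("nan"),
            "method": "",
        }
        if xs_ok.size and ys_ok.size:
            if test == "paired":
                patients = study.loc[scores.index, "patient_id"]
                merged = pd.DataFrame(
                    {"score": scores[score], "region": region, "patient": patients}
                ).pivot_table(index="patient", columns="region", values="score")
                merged = merged.dropna()
                diffs = (merged["peri_papillary"] - merged["remote"]).to_numpy()
                if np.all(diffs == 0) or diffs.size == 0:
                    row["p"] = 1.0
                else:
                    row["p"] = float(stats.wilcoxon(diffs).pvalue)
                row["method"] = "wilcoxon_signed_rank"
            else:
                if np.ptp(np.concatenate([xs_ok, ys_ok])) == 0:
                    row["U"], row["p"], row["method"] = (
                        xs_ok.size * ys_ok.size / 2.0,
                        1.0,
                        "degenerate",
                    )
                else:
                    res = mann_whitney_u(xs_ok, ys_ok)
                    row["U"], row["p"], row["method"] = res.U, res.p, res.method
        row["stars"] = significance_stars(row["p"])
        stat_rows.append(row)
        for reg, vals in (("peri_papillary", xs), ("remote", ys)):
            box_rows.append({"score": score, "region": reg, **_box_stats(vals)})
    return CompositeResult(
        compartment=compartment,
        scores=scores,
        stats=pd.DataFrame(stat_rows).set_index("score"),
        selection=selection,
        boxplot=pd.DataFrame(box_rows),
        empty_selection=(len(sel_names) == 0),
        scale=scale,
        trait_ledger=families,
    )


def score_study(
    traits: pd.DataFrame,
    study: pd.DataFrame,
    catalog: TraitCatalog | None = None,
    compartments: tuple[str, ...] = ("whole", "myocardium", "endocardium"),
    alpha: float = 0.05,
    change_min: float = 20.0,
    scale: float = 10.0,
    p_direction: str = "less",
    test: str = "unpaired",
) -> dict[str, CompositeResult]:
    """Select, normalize, and score traits independently per compartment."""
    if catalog is None:
        catalog = trait_catalog()
    results: dict[str, CompositeResult] = {}
    for comp in compartments:
        cols = [c for c in traits.columns if c.split(".", 1)[0] == comp]
        if not cols:
            continue
        sub = traits[cols]
        selection = select_traits(
            sub, study, catalog, alpha=alpha, change_min=change_min, p_direction=p_direction
        )
        normalized = normalize_traits(sub[list(selection.selected)], catalog)
        results[comp] = composite_scores(
            normalized, study, selection, catalog, scale=scale, compartment=comp, test=test
        )
    return results


def report(results: dict[str, CompositeResult], params: dict | None = None) -> dict:
    """Machine-readable study report: per-compartment score tables and stats."""
    out: dict = {"parameters": params or {}, "compartments": {}}
    for comp, res in results.items():
        out["compartments"][comp] = {
            "empty_selection": res.empty_selection,
            "n_selected_traits": int(res.selection.table["selected"].sum()),
            "scores": res.scores.round(6).to_dict(orient="index"),
            "stats": res.stats.replace({np.nan: None}).to_dict(orient="index"),
            "boxplot": res.boxplot.replace({np.nan: None}).to_dict(orient="records"),
            "selected_traits": {k: list(v) for k, v in res.trait_ledger.items()},
        }
    return out
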