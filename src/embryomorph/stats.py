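"""Inferential machinery for organ-volume and voxel-level phenotyping.

Organ volumes are analysed with the linear model

    organ volume / WEV ~ genotype + WEV

where WEV (whole-embryo volume, mm³) acts as a surrogate for developmental
substage: normalising by WEV removes overall size, and the WEV fixed effect
absorbs substage-dependent differential organ growth. Voxel-level fields use
the same model per voxel. Multiple testing is controlled either by
Benjamini-Hochberg (voxel maps, and organ tables when permutation is
impossible) or by a permutation scheme that samples synthetic mutant lines
from the baselines, matching the observed line-size distribution, and then
searches for a per-organ p-value threshold at which the estimated false
discovery rate falls below the target (5% at gene level, 20% at specimen
level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DesignError, ParameterError

log = logging.getLogger(__name__)

MIN_UNIQUE_PERMUTATIONS = 500  # guard below which the null is flagged unreliable


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """OLS fit summary for one response."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    dof: int
    degenerate: bool = False

    def term(self, name: str) -> int:
        return self.terms.index(name)


def _ols_multi(X: np.ndarray, Y: np.ndarray):
    """Vectorised OLS of many responses on one design.

    Returns ``(beta, se, t, p, dof, degenerate)`` with shapes ``(P, K)`` for
    the first four; ``degenerate`` marks responses with (numerically) zero
    residual variance, whose p-values are set to 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    scale = float(np.sqrt(np.mean(Y**2))) if Y.size else 1.0
    degenerate = sigma2 <= (1e-10 * max(scale, 1.0)) ** 2
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * sstats.t.sf(np.abs(t), dof)
    pvals[:, degenerate] = 1.0
    return beta, se, t, pvals, dof, degenerate


def _design_matrix(group: np.ndarray, wev: np.ndarray | None, include_wev: bool):
    cols = [np.ones_like(np.asarray(group, dtype=float))]
    terms = ["intercept"]
    cols.append(np.asarray(group, dtype=float))
    terms.append("genotype")
    if include_wev:
        if wev is None:
            raise DesignError("include_wev=True but no WEV values supplied")
        cols.append(np.asarray(wev, dtype=float))
        terms.append("wev")
    return np.column_stack(cols), terms


def fit_linear_model(
    y: np.ndarray,
    group: np.ndarray,
    wev: np.ndarray | None = None,
    include_wev: bool = True,
) -> LinearFit:
    """Fit ``y ~ genotype (+ WEV)`` by ordinary least squares.

    ``group`` is 0 for baseline and 1 for the test group (genotype or sex);
    two-sided p-values come from the t distribution on the residual dof.
    """
    X, terms = _design_matrix(group, wev, include_wev)
    beta, se, t, p, dof, degenerate = _ols_multi(X, np.asarray(y, dtype=float))
    return LinearFit(
        terms, beta[:, 0], se[:, 0], t[:, 0], p[:, 0], dof, bool(degenerate[0])
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p.reshape(-1), method="fdr_bh")[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# organ tables
# ---------------------------------------------------------------------------


def organ_table_wide(table: pd.DataFrame):
    """Pivot a long organ-volume table to (specimen × organ) normalised
    volumes, plus per-specimen WEV and metadata."""
    needed = {"specimen", "line", "genotype", "label", "normalized_volume", "wev_mm3"}
    missing = needed - set(table.columns)
    if missing:
        raise ParameterError(f"organ table missing columns {sorted(missing)}")
    wide = table.pivot_table(
        index="specimen", columns="label", values="normalized_volume"
    )
    meta = table.groupby("specimen")[["line", "genotype", "wev_mm3"]].first()
    meta = meta.loc[wide.index]
    return wide, meta


# ---------------------------------------------------------------------------
# permutation null distributions and threshold search
# ---------------------------------------------------------------------------


@dataclass
class NullAltDistributions:
    """Per-organ null (synthetic-line) and alternative (real-line) p-values."""

    null_p: pd.DataFrame  # n_perms × organs
    alt_p: pd.DataFrame  # lines/specimens × organs
    line_sizes: list[int] = field(default_factory=list)
    n_perms: int = 0
    seed: int = 0
    n_unique_possible: float = math.inf


def _allocate_sizes(line_sizes, n_perms: int, rng: np.random.Generator):
    """Allocate synthetic-line sizes across permutations in the empirical
    proportions of the observed line sizes (largest-remainder rounding)."""
    sizes, counts = np.unique(np.asarray(list(line_sizes), dtype=int), return_counts=True)
    frac = counts / counts.sum()
    alloc = np.floor(frac * n_perms).astype(int)
    remainder = n_perms - alloc.sum()
    order = np.argsort(-(frac * n_perms - alloc))
    for i in range(remainder):
        alloc[order[i % len(sizes)]] += 1
    out = np.repeat(sizes, alloc)
    rng.shuffle(out)
    return out


def build_null_distributions(
    baseline_table: pd.DataFrame,
    line_sizes,
    n_perms: int = 1000,
    seed: int = 0,
    include_wev: bool = True,
) -> pd.DataFrame:
    """Organ-specific null p-values from synthetic mutant lines.

    Each permutation draws a synthetic line size (matching the empirical
    line-size proportions), samples that many baseline specimens without
    replacement, relabels them as mutant — removing them from the baseline
    side — and records the genotype-effect p-value per organ. A warning is
    logged when fewer than 500 distinct synthetic lines are possible.
    """
    if n_perms < 1:
        raise ParameterError("n_perms must be >= 1")
    sizes_list = [int(s) for s in line_sizes]
    if not sizes_list:
        raise ParameterError("line_sizes must be non-empty")
    wide, meta = organ_table_wide(baseline_table)
    n_base = len(wide)
    if max(sizes_list) >= n_base:
        raise DesignError(
            f"largest line size {max(sizes_list)} must be below the baseline "
            f"count {n_base}"
        )
    n_unique = float(sum(math.comb(n_base, s) for s in sorted(set(sizes_list))))
    if n_unique < MIN_UNIQUE_PERMUTATIONS:
        log.warning(
            "only %.0f unique synthetic lines possible (< %d); null may be coarse",
            n_unique,
            MIN_UNIQUE_PERMUTATIONS,
        )
    rng = np.random.default_rng(seed)
    draw_sizes = _allocate_sizes(sizes_list, n_perms, rng)
    Y = wide.to_numpy()
    wev = meta["wev_mm3"].to_numpy(dtype=float)
    pvals = np.empty((n_perms, Y.shape[1]))
    group = np.zeros(n_base)
    for i, m in enumerate(draw_sizes):
        pick = rng.choice(n_base, size=int(m), replace=False)
        group[:] = 0.0
        group[pick] = 1.0
        X, terms = _design_matrix(group, wev if include_wev else None, include_wev)
        _, _, _, p, _, _ = _ols_multi(X, Y)
        pvals[i] = p[terms.index("genotype")]
    out = pd.DataFrame(pvals, columns=wide.columns)
    out.attrs.update(
        line_sizes=sizes_list, n_perms=n_perms, seed=int(seed),
        n_unique_possible=n_unique,
    )
    return out


def _line_pvalues(
    table: pd.DataFrame,
    units: list[tuple[str, list[str]]],
    include_wev: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype p-values and effect summaries for test units (lines or single
    specimens) against all baseline specimens."""
    from .phantom import WT

    wide, meta = organ_table_wide(table)
    base_ids = meta.index[meta["genotype"] == WT]
    if len(base_ids) < 2:
        raise DesignError("need at least 2 baseline specimens")
    rows_p, rows_eff = [], []
    for unit_id, members in units:
        ids = list(base_ids) + [m for m in members if m not in set(base_ids)]
        sub = wide.loc[ids]
        group = np.asarray([1.0 if s in set(members) else 0.0 for s in ids])
        wev = meta.loc[ids, "wev_mm3"].to_numpy(dtype=float)
        X, terms = _design_matrix(group, wev if include_wev else None, include_wev)
        beta, _, _, p, _, _ = _ols_multi(X, sub.to_numpy())
        gi = terms.index("genotype")
        rows_p.append(pd.Series(p[gi], index=wide.columns, name=unit_id))
        mut_mean = wide.loc[list(members)].mean(axis=0)
        base_mean = wide.loc[base_ids].mean(axis=0)
        rows_eff.append(
            pd.DataFrame(
                {
                    "unit": unit_id,
                    "label": wide.columns,
                    "coef": beta[gi],
                    "mean_norm_diff": (mut_mean - base_mean).to_numpy(),
                }
            )
        )
    return pd.DataFrame(rows_p), pd.concat(rows_eff, ignore_index=True)


def permutation_threshold_search(
    null_p: pd.DataFrame,
    alt_p: pd.DataFrame,
    start: float = 0.05,
    target: float = 0.05,
    literal_ratio: bool = False,
) -> pd.DataFrame:
    """Descending per-organ p-value threshold search.

    Candidate thresholds are the observed (pooled null + alternative)
    p-values at or below ``start``, scanned in descending order; the first
    threshold whose estimated FDR — the fraction of null p-values at or
    below it divided by the fraction of alternative p-values at or below it
    — is below ``target`` is returned. ``literal_ratio`` flips the ratio to
    alternative/null, the direction the source text prints.
    """
    if null_p.empty or alt_p.empty:
        raise ParameterError("null and alternative distributions must be non-empty")
    rows = []
    for organ in null_p.columns:
        nulls = null_p[organ].to_numpy(dtype=float)
        alts = alt_p[organ].to_numpy(dtype=float)
        pooled = np.concatenate([nulls, alts])
        cands = np.unique(pooled[pooled <= start])[::-1]
        thr, ratio_at = np.nan, np.nan
        for c in cands:
            fn = float(np.mean(nulls <= c))
            fa = float(np.mean(alts <= c))
            num, den = (fa, fn) if literal_ratio else (fn, fa)
            if den == 0.0:
                continue
            ratio = num / den
            if ratio < target:
                thr, ratio_at = float(c), ratio
                break
        rows.append({"label": organ, "threshold": thr, "ratio": ratio_at})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene- and specimen-level calls
# ---------------------------------------------------------------------------


def _calls_from_units(
    table, units, thresholds: pd.DataFrame, include_wev: bool, level: str
) -> pd.DataFrame:
    alt_p, effects = _line_pvalues(table, units, include_wev)
    thr = thresholds.set_index("label")["threshold"]
    rows = []
    for unit_id in alt_p.index:
        for organ in alt_p.columns:
            p = float(alt_p.loc[unit_id, organ])
            t = float(thr.get(organ, np.nan))
            eff = effects[(effects["unit"] == unit_id) & (effects["label"] == organ)]
            coef = float(eff["coef"].iloc[0])
            rows.append(
                {
                    "unit": unit_id,
                    "level": level,
                    "label": organ,
                    "p": p,
                    "threshold": t,
                    # candidates are observed p-values, so the unit whose
                    # p-value IS the threshold is called (at-or-below)
                    "significant": bool(np.isfinite(t) and p <= t),
                    "direction": "smaller" if coef < 0 else "larger",
                    "mean_norm_diff": float(eff["mean_norm_diff"].iloc[0]),
                }
            )
    return pd.DataFrame(rows)


def _line_units(table: pd.DataFrame) -> list[tuple[str, list[str]]]:
    from .phantom import WT

    mut = table[table["genotype"] != WT]
    units = []
    for line_id, grp in mut.groupby("line"):
        members = sorted(grp["specimen"].unique())
        if not members:
            log.warning("line %s has no specimens; skipped", line_id)
            continue
        units.append((str(line_id), members))
    return units


def gene_level_calls(
    table: pd.DataFrame,
    n_perms: int = 1000,
    seed: int = 0,
    fdr_target: float = 0.05,
    include_wev: bool = True,
    literal_ratio: bool = False,
):
    """Per-line organ-volume phenotype calls with permutation FDR thresholds.

    Returns ``(calls, thresholds, distributions)``; an empty mutant set
    yields an empty calls table.
    """
    from .phantom import WT

    units = _line_units(table)
    if not units:
        return pd.DataFrame(), pd.DataFrame(), None
    baseline = table[table["genotype"] == WT]
    sizes = [len(m) for _, m in units]
    null_p = build_null_distributions(baseline, sizes, n_perms, seed, include_wev)
    alt_p, _ = _line_pvalues(table, units, include_wev)
    thresholds = permutation_threshold_search(
        null_p, alt_p, target=fdr_target, literal_ratio=literal_ratio
    )
    calls = _calls_from_units(table, units, thresholds, include_wev, "gene")
    dists = NullAltDistributions(
        null_p, alt_p, sizes, n_perms, seed,
        null_p.attrs.get("n_unique_possible", math.inf),
    )
    return calls, thresholds, dists


def specimen_level_calls(
    table: pd.DataFrame,
    n_perms: int = 1000,
    seed: int = 0,
    fdr_target: float = 0.20,
    include_wev: bool = True,
):
    """Each mutant specimen analysed singly against the baselines, with
    permutation thresholds recomputed at line size 1 and the specimen-level
    FDR target (20% by default, reflecting the reduced power of single-
    specimen tests)."""
    from .phantom import WT

    mut = table[table["genotype"] != WT]
    specs = sorted(mut["specimen"].unique())
    if not specs:
        return pd.DataFrame(), pd.DataFrame(), None
    units = [(s, [s]) for s in specs]
    baseline = table[table["genotype"] == WT]
    null_p = build_null_distributions(
        baseline, [1] * len(specs), n_perms, seed, include_wev
    )
    alt_p, _ = _line_pvalues(table, units, include_wev)
    thresholds = permutation_threshold_search(null_p, alt_p, target=fdr_target)
    calls = _calls_from_units(table, units, thresholds, include_wev, "specimen")
    dists = NullAltDistributions(
        null_p, alt_p, [1] * len(specs), n_perms, seed,
        null_p.attrs.get("n_unique_possible", math.inf),
    )
    return calls, thresholds, dists


def organ_bh_calls(
    table: pd.DataFrame,
    group_col: str = "genotype",
    test_value: str | None = None,
    alpha: float = 0.05,
    include_wev: bool = True,
) -> pd.DataFrame:
    """BH-corrected organ tests for designs where permutation is impossible
    because every specimen enters the single comparison (e.g. a whole-cohort
    sex contrast). ``group_col`` may be ``genotype`` or ``sex``."""
    from .phantom import WT

    wide, meta = organ_table_wide(table)
    if group_col == "sex":
        meta = meta.join(
            table.groupby("specimen")["sex"].first(), how="left"
        )
        values = meta["sex"].astype(str)
        test_value = test_value or "F"
        group = (values.str.upper().str.startswith(test_value.upper())).astype(float)
    else:
        group = (meta["genotype"] != WT).astype(float)
    if group.nunique() < 2:
        raise DesignError("both groups must be present")
    X, terms = _design_matrix(
        group.to_numpy(), meta["wev_mm3"].to_numpy(dtype=float) if include_wev else None,
        include_wev,
    )
    beta, _, t, p, _, _ = _ols_multi(X, wide.to_numpy())
    gi = terms.index("genotype")
    q = bh_fdr(p[gi])
    return pd.DataFrame(
        {
            "label": wide.columns,
            "coef": beta[gi],
            "t": t[gi],
            "p": p[gi],
            "q": q,
            "significant": q < alpha,
        }
    )


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------


def staging_report(
    baseline_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-organ substage effect in the baselines: ``organ volume/WEV ~ WEV``.

    BH across organs; the sign of the WEV coefficient classifies organs as
    proportionally larger or smaller later in development.
    """
    wide, meta = organ_table_wide(baseline_table)
    if len(wide) < 4:
        raise DesignError("staging needs at least 4 baseline specimens")
    wev = meta["wev_mm3"].to_numpy(dtype=float)
    if np.ptp(wev) == 0:
        raise DegenerateDataError("constant WEV across baselines")
    X = np.column_stack([np.ones_like(wev), wev])
    beta, _, t, p, _, _ = _ols_multi(X, wide.to_numpy())
    q = bh_fdr(p[1])
    return pd.DataFrame(
        {
            "label": wide.columns,
            "wev_coef": beta[1],
            "t": t[1],
            "p": p[1],
            "q": q,
            "significant": q < alpha,
            "trend": np.where(beta[1] > 0, "proportionally_larger", "proportionally_smaller"),
        }
    )


# ---------------------------------------------------------------------------
# voxel-level statistics
# ---------------------------------------------------------------------------


@dataclass
class VoxelStatsResult:
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    thresholded_t: np.ndarray
    mask: np.ndarray
    n_significant: int


def voxel_level_stats(
    stack: np.ndarray,
    group: np.ndarray,
    wev: np.ndarray | None,
    mask: np.ndarray,
    alpha: float = 0.05,
    include_wev: bool = True,
) -> VoxelStatsResult:
    """Per-voxel ``value ~ genotype (+ WEV)`` with BH across masked voxels.

    ``stack`` is ``(n_specimens, nz, ny, nx)``; the thresholded t map keeps
    voxels with ``q < alpha``. Degenerate (constant) voxels get p = 1.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 4:
        raise ParameterError("stack must be (n, nz, ny, nx)")
    if stack.shape[0] < 3:
        raise DesignError("need at least 3 specimens")
    if mask.shape != stack.shape[1:]:
        raise ParameterError("mask shape must match the volume shape")
    if not mask.any():
        raise DegenerateDataError("mask selects no voxels")
    Y = stack[:, mask]
    X, terms = _design_matrix(group, wev if include_wev else None, include_wev)
    _, _, t, p, _, _ = _ols_multi(X, Y)
    gi = terms.index("genotype")
    q = bh_fdr(p[gi])
    shape = stack.shape[1:]
    t_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    q_map = np.full(shape, np.nan)
    t_map[mask], p_map[mask], q_map[mask] = t[gi], p[gi], q
    thresh = np.zeros(shape)
    sig = mask.copy()
    sig[mask] = q < alpha
    thresh[sig] = t_map[sig]
    return VoxelStatsResult(t_map, p_map, q_map, thresh, mask, int(sig.sum()))


__all__ = [
    "LinearFit",
    "NullAltDistributions",
    "VoxelStatsResult",
    "fit_linear_model",
    "bh_fdr",
    "organ_table_wide",
    "build_null_distributions",
    "permutation_threshold_search",
    "gene_level_calls",
    "specimen_level_calls",
    "organ_bh_calls",
    "staging_report",
    "voxel_level_stats",
    "MIN_UNIQUE_PERMUTATIONS",
]
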