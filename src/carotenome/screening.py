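"""Per-protein association screen with q-value FDR control.

For one carotenoid analyte, every protein surviving the global detection
filter is fit with the random-intercept model on its complete cases, the
slope is tested against zero, and the resulting p-value vector is converted
to q-values (Storey-style FDR).  Records below the q threshold form the
analyte's "proteome" table; the full unfiltered table is kept for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix, CarotenoidTable, prepare_response
from .errors import (
    InsufficientDataError,
    InsufficientGroupsError,
    InvalidPValueError,
    NoSlopeVarianceError,
)
from .lme import association_stats, fit_random_intercept, percent_change, wald_p

log = logging.getLogger(__name__)

#: Tuning grid for the pi0 smoother (Storey & Tibshirani's default range).
PI0_GRID = np.arange(0.0, 0.91, 0.05)

AUDIT_COLUMNS = [
    "protein_id", "gene_name", "gene_symbol", "accession",
    "n", "n_groups", "r", "R2", "p", "q", "b1_raw", "b1_pct",
    "sigma_B2", "sigma_e2", "converged",
]


def estimate_pi0(p: np.ndarray, grid: np.ndarray = PI0_GRID) -> float:
    """Smoother estimate of the null proportion pi0.

    Computes pi0(t) = #{p > t} / (m (1 - t)) over the tuning grid, fits a
    cubic least-squares polynomial (a df-3 smoother) and evaluates it at
    the largest grid point.  Falls back to 1 (Benjamini–Hochberg
    equivalence) when the smoothed value leaves (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    raw = np.array([(p > t).sum() / (m * (1.0 - t)) for t in grid])
    coef = np.polyfit(grid, raw, deg=3)
    val = float(np.polyval(coef, grid[-1]))
    if not np.isfinite(val) or val <= 0.0 or val > 1.0:
        return 1.0
    return val


def qvalues(p, *, pi0: float | None = None, pi0_method: str = "smoother") -> np.ndarray:
    """q-values for a vector of p-values.

    q_(i) = pi0 * min_{j >= i} ( m * p_(j) / j ) on the sorted scale,
    clipped to [0, 1] and mapped back to the input order.  pi0 comes from
    the smoother (see :func:`estimate_pi0`) when ``pi0_method='smoother'``
    and m >= 100; otherwise pi0 = 1, which reduces the procedure exactly
    to the Benjamini–Hochberg step-up.  Ranking by q never contradicts
    ranking by p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidPValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if pi0_method == "smoother" and m >= 100:
            pi0 = estimate_pi0(p)
        elif pi0_method in ("smoother", "bh"):
            pi0 = 1.0
        else:
            raise ValueError(f"unknown pi0_method {pi0_method!r}")
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q_sorted = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


@dataclass
class ScreenResult:
    """Outcome of the per-protein screen for one analyte."""

    analyte: str
    records: pd.DataFrame          # q < threshold, sorted by (q, p)
    audit: pd.DataFrame            # every tested protein, same columns
    skipped: pd.DataFrame          # protein_id, reason
    excluded_samples: list = field(default_factory=list)
    pi0: float = 1.0


def _meta_row(m: AbundanceMatrix, protein: str) -> tuple[str, str, str]:
    if m.protein_meta is not None and protein in m.protein_meta.index:
        row = m.protein_meta.loc[protein]
        return (
            str(row.get("gene_name", protein)),
            str(row.get("gene_symbol", protein)),
            str(row.get("accession", protein)),
        )
    return (protein, protein, protein)


def screen(
    analyte: str,
    abundance: AbundanceMatrix,
    carotenoids: CarotenoidTable,
    *,
    q_threshold: float = 0.10,
    min_obs: int = 10,
    min_groups: int = 2,
    pi0_method: str = "smoother",
) -> ScreenResult:
    """Screen every protein in ``abundance`` against one carotenoid.

    ``abundance`` is expected to be median-centered and detection-filtered
    already.  Each protein is fit on its complete cases (samples with both
    the protein detected and the analyte detectable); proteins below the
    observation or plex floors are skipped with a logged reason.  q-values
    are computed over the full per-analyte p-value vector.
    """
    resp = prepare_response(carotenoids, analyte)
    empty_audit = pd.DataFrame(columns=AUDIT_COLUMNS)
    if len(resp) == 0:
        log.warning("analyte %s: no detectable samples; screen skipped", analyte)
        return ScreenResult(
            analyte=analyte,
            records=empty_audit.copy(),
            audit=empty_audit.copy(),
            skipped=pd.DataFrame(columns=["protein_id", "reason"]),
            excluded_samples=resp.excluded,
        )

    values = abundance.analytic_values.loc[
        abundance.analytic_index.intersection(resp.values.index)
    ]
    y_all = resp.values.loc[values.index].to_numpy()
    plex = abundance.plex_of.loc[values.index].to_numpy()

    rows, skipped = [], []
    for protein in values.columns:
        col = values[protein].to_numpy()
        mask = ~np.isnan(col)
        n = int(mask.sum())
        try:
            fit = fit_random_intercept(
                y_all[mask], col[mask], plex[mask], min_obs=min_obs
            )
            if fit.n_groups < min_groups:
                raise InsufficientGroupsError("below plex floor")
        except (InsufficientDataError, InsufficientGroupsError,
                NoSlopeVarianceError) as exc:
            skipped.append((protein, f"{type(exc).__name__}: {exc}"))
            log.info("analyte %s: skipped %s (%s)", analyte, protein, exc)
            continue
        p = wald_p(fit)
        r, r2 = association_stats(fit, y_all[mask], col[mask], plex[mask])
        gene_name, gene_symbol, accession = _meta_row(abundance, protein)
        rows.append({
            "protein_id": protein, "gene_name": gene_name,
            "gene_symbol": gene_symbol, "accession": accession,
            "n": n, "n_groups": fit.n_groups,
            "r": r, "R2": r2, "p": p, "q": np.nan,
            "b1_raw": fit.b1_raw, "b1_pct": float(percent_change(fit.b1_raw)),
            "sigma_B2": fit.sigma_B2, "sigma_e2": fit.sigma_e2,
            "converged": fit.converged,
        })

    skipped_df = pd.DataFrame(skipped, columns=["protein_id", "reason"])
    if not rows:
        return ScreenResult(
            analyte=analyte, records=empty_audit.copy(), audit=empty_audit.copy(),
            skipped=skipped_df, excluded_samples=resp.excluded,
        )
    audit = pd.DataFrame(rows, columns=AUDIT_COLUMNS)
    pvec = audit["p"].to_numpy()
    pi0 = (estimate_pi0(pvec)
           if pi0_method == "smoother" and pvec.size >= 100 else 1.0)
    audit["q"] = qvalues(pvec, pi0=pi0)
    audit = audit.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    records = audit[audit["q"] < q_threshold].reset_index(drop=True)
    return ScreenResult(
        analyte=analyte, records=records, audit=audit,
        skipped=skipped_df, excluded_samples=resp.excluded, pi0=pi0,
    )


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with per-pair n and p."""

    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame


def _fisher_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via the Fisher-z normal approximation."""
    if n < 4 or not np.isfinite(r) or abs(r) >= 1.0:
        return np.nan if (n < 4 or not np.isfinite(r)) else 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def carotenoid_correlations(
    t: CarotenoidTable, min_pairs: int = 3
) -> CorrelationMatrix:
    """Analyte × analyte correlations of log2 concentration.

    Uses all pairwise-complete detectable samples (below-LOD and
    unmeasured samples are masked per analyte).  Pairs with fewer than
    ``min_pairs`` shared samples are flagged missing (NaN).
    """
    if len(t.analytes) < 2:
        raise ValueError("need at least two analytes")
    masked = t.concentrations.where(~t.below_lod)
    logc = np.log2(masked.where(masked > 0))
    r = logc.corr(method="pearson", min_periods=min_pairs)
    notna = logc.notna().astype(int)
    n = pd.DataFrame(
        notna.T.to_numpy() @ notna.to_numpy(),
        index=logc.columns, columns=logc.columns,
    )
    p = pd.DataFrame(
        [[_fisher_p(r.iat[i, j], int(n.iat[i, j]))
          for j in range(len(r))] for i in range(len(r))],
        index=r.index, columns=r.columns,
    )
    np.fill_diagonal(p.values, 0.0)
    return CorrelationMatrix(r=r, n=n, p=p)


def proteome_correlation_matrix(
    records: pd.DataFrame,
    abundance: AbundanceMatrix,
    q_cut: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Protein × protein abundance correlations for one analyte's hits.

    Restricted to records with q < ``q_cut``; rows are ordered positive
    correlates first (ascending q), then negative correlates (ascending
    q).  Correlations are Pearson over shared non-missing samples; pairs
    sharing fewer than ``min_pairs`` samples are NaN.
    """
    sel = records[records["q"] < q_cut]
    pos = sel[sel["r"] >= 0].sort_values(["q", "p"], kind="mergesort")
    neg = sel[sel["r"] < 0].sort_values(["q", "p"], kind="mergesort")
    order = list(pos["protein_id"]) + list(neg["protein_id"])
    mat = abundance.analytic_values.loc[:, order]
    return mat.corr(method="pearson", min_periods=min_pairs)
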