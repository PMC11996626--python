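"""Abundance, lanthanide-fraction, logistic and ordination statistics.

Implements the downstream numerics of the pipeline: RPKM normalisation and
percent-of-total abundances; the per-sample lanthanide fraction fLn (the
share of complete-domain PQQ-DH abundance carried by lanthanide-motif genes);
a quasi-binomial logistic regression of fLn on phosphate fitted by IRLS; and
unconstrained correspondence analysis of a samples x gene-group table with
optional environmental arrows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

COMPLETE_CALLS = ("lanthanide", "calcium", "unknown")


@dataclass
class AbundanceTable:
    """Genes x samples abundance matrix with per-gene lengths and library sizes.

    ``kind`` flags whether values are raw mapped-read counts or RPKM.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series       # bp
    library_sizes: pd.Series      # mapped reads
    kind: str = "counts"          # "counts" | "rpkm"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "rpkm"):
            raise ValueError("kind must be 'counts' or 'rpkm'")
        self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        if self.gene_lengths.isna().any():
            raise ValueError("gene_lengths missing for some genes")
        if self.library_sizes.isna().any():
            raise ValueError("library_sizes missing for some samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")


def compute_rpkm(table: AbundanceTable) -> AbundanceTable:
    """Reads per kilobase of gene per million mapped reads.

    RPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * library_size[s]).
    """
    if table.kind != "counts":
        raise ValueError("compute_rpkm expects a counts table")
    if (table.gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (table.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = (
        table.values * 1e9
    ).div(table.gene_lengths, axis=0).div(table.library_sizes, axis=1)
    return AbundanceTable(values=rpkm, gene_lengths=table.gene_lengths,
                          library_sizes=table.library_sizes, kind="rpkm")


def relative_abundance_percent(table: AbundanceTable,
                               gene_subset: Sequence[str] | None = None
                               ) -> pd.DataFrame:
    """Percent of total abundance within ``gene_subset`` per sample.

    Columns sum to 100 where the subset total is positive; all-zero samples
    are reported missing (NaN), not zero.
    """
    if table.kind != "rpkm":
        raise ValueError("relative_abundance_percent expects an RPKM table")
    sub = table.values if gene_subset is None else table.values.loc[list(gene_subset)]
    totals = sub.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * sub.div(totals.where(totals > 0), axis=1)
    return percent


@dataclass
class FLnSeries:
    """Per-sample lanthanide fraction with its numerator and denominator."""

    table: pd.DataFrame  # columns: fln, numerator, denominator
    mode: str            # "abundance_weighted" | "count_based"
    include_unknown: bool

    @property
    def fln(self) -> pd.Series:
        return self.table["fln"]


def compute_fln(table: AbundanceTable, calls: Mapping[str, str],
                mode: str = "abundance_weighted",
                include_unknown: bool = True) -> FLnSeries:
    """Fraction of complete-domain PQQ-DH abundance with the Ln-binding motif.

    Genes called 'incomplete' are excluded entirely.  The numerator sums
    abundance over lanthanide-call genes; the denominator over lanthanide,
    calcium and (by default) unknown calls.  In count_based mode abundance is
    replaced by a presence indicator (abundance > 0).  fLn is missing where
    the denominator is zero.
    """
    if mode not in ("abundance_weighted", "count_based"):
        raise ValueError("mode must be 'abundance_weighted' or 'count_based'")
    missing = [g for g in table.values.index if g not in calls]
    if missing:
        raise ValueError(f"no motif call for genes: {missing[:5]}...")
    call_series = pd.Series({g: calls[g] for g in table.values.index})
    denom_calls = COMPLETE_CALLS if include_unknown else ("lanthanide", "calcium")

    abundance = table.values
    if mode == "count_based":
        abundance = (abundance > 0).astype(float)
    num = abundance.loc[call_series == "lanthanide"].sum(axis=0)
    den = abundance.loc[call_series.isin(denom_calls)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fln = num / den.where(den > 0)
    out = pd.DataFrame({"fln": fln, "numerator": num, "denominator": den})
    return FLnSeries(table=out, mode=mode, include_unknown=include_unknown)


@dataclass
class LogisticFit:
    """Quasi-binomial logistic fit of a fractional response on one covariate."""

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    z_b1: float
    p_b1: float | None
    dispersion: float
    n: int
    converged: bool
    iterations: int
    identifiable: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.b0 + self.b1 * np.asarray(x, float))))


def fit_fractional_logistic(y: Sequence[float] | pd.Series,
                            x: Sequence[float] | pd.Series,
                            tol: float = 1e-10,
                            max_iter: int = 100) -> LogisticFit:
    """IRLS fit of E[y] = logistic(b0 + b1 x) for fractional responses.

    Uses the quasi-binomial score (working weights mu(1-mu)); Wald standard
    errors come from the inverse information scaled by the Pearson dispersion.
    Convergence: max coefficient change < ``tol`` within ``max_iter``
    iterations.
    """
    y = np.asarray(pd.Series(y).dropna(), dtype=float) if isinstance(y, pd.Series) \
        else np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 samples with defined response")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1]")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # Non-identifiable slope: report the intercept-only solution, no p.
        mu = float(np.mean(y))
        mu = min(max(mu, 1e-12), 1 - 1e-12)
        b0 = float(np.log(mu / (1 - mu)))
        return LogisticFit(b0=b0, b1=0.0, se_b0=np.nan, se_b1=np.nan,
                           z_b1=np.nan, p_b1=None, dispersion=np.nan, n=n,
                           converged=True, iterations=0, identifiable=False)

    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    mu0 = min(max(float(np.mean(y)), 1e-6), 1 - 1e-6)
    beta[0] = np.log(mu0 / (1 - mu0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        xtw = X.T * w
        info = xtw @ X
        beta_new = np.linalg.solve(info, xtw @ z)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1.0 - mu)
    pearson = float(np.sum((y - mu) ** 2 / w))
    dof = max(n - 2, 1)
    dispersion = pearson / dof
    info = (X.T * w) @ X
    cov = dispersion * np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z_b1 = beta[1] / se[1] if se[1] > 0 else np.nan
    p_b1 = float(2.0 * stats.norm.sf(abs(z_b1))) if np.isfinite(z_b1) else None
    return LogisticFit(b0=float(beta[0]), b1=float(beta[1]),
                       se_b0=float(se[0]), se_b1=float(se[1]),
                       z_b1=float(z_b1), p_b1=p_b1, dispersion=dispersion,
                       n=n, converged=converged, iterations=it)


@dataclass
class CAResult:
    """Correspondence analysis of a nonnegative samples x groups table."""

    row_scores: pd.DataFrame      # principal coordinates per axis
    col_scores: pd.DataFrame
    singular_values: np.ndarray
    inertia: np.ndarray           # sigma^2 per axis
    inertia_fraction: np.ndarray
    total_inertia: float
    env_arrows: pd.DataFrame | None = None


def correspondence_analysis(matrix: pd.DataFrame,
                            env: pd.DataFrame | None = None,
                            exclude_env: Sequence[str] = ("nitrate",),
                            tol: float = 1e-12) -> CAResult:
    """Unconstrained correspondence analysis via SVD of the standardised
    residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}.

    Total inertia equals chi-square / n.  Axis signs are fixed so the first
    nonzero column loading of each axis is positive.  Environmental arrows
    are mass-weighted correlations of standardised variables with the row
    scores; a variable named in ``exclude_env`` (nitrate by default, owing to
    its collinearity with phosphate) is dropped.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be nonnegative")
    total = X.sum()
    if total <= 0:
        raise ValueError("matrix grand total must be positive")

    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping all-zero rows/columns from correspondence analysis")
        matrix = matrix.loc[row_ok, col_ok]
        X = matrix.to_numpy(dtype=float)
        total = X.sum()

    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sig > tol
    U, sig, Vt = U[:, keep], sig[keep], Vt[keep, :]

    # reproducible sign convention: first nonzero column loading positive
    for k in range(sig.size):
        v = Vt[k]
        nz = np.flatnonzero(np.abs(v) > tol)
        if nz.size and v[nz[0]] < 0:
            Vt[k] = -v
            U[:, k] = -U[:, k]

    F = (U * sig) / np.sqrt(r)[:, None]
    G = (Vt.T * sig) / np.sqrt(c)[:, None]
    axes = [f"CA{k + 1}" for k in range(sig.size)]
    row_scores = pd.DataFrame(F, index=matrix.index, columns=axes)
    col_scores = pd.DataFrame(G, index=matrix.columns, columns=axes)
    inertia = sig ** 2
    total_inertia = float(inertia.sum())
    fractions = inertia / total_inertia if total_inertia > 0 else inertia

    arrows = None
    if env is not None and sig.size:
        env = env.loc[matrix.index, [col for col in env.columns
                                     if col not in exclude_env]]
        numeric = env.select_dtypes(include=[np.number])
        arr = {}
        for name, series in numeric.items():
            vals = series.to_numpy(dtype=float)
            mean = np.sum(r * vals)
            sd = np.sqrt(np.sum(r * (vals - mean) ** 2))
            if sd == 0:
                continue
            std = (vals - mean) / sd
            # mass-weighted correlation with standardised row scores
            fs = F / np.sqrt(inertia)  # standard coordinates have unit weighted var
            arr[name] = np.array([np.sum(r * std * fs[:, k])
                                  for k in range(sig.size)])
        if arr:
            arrows = pd.DataFrame(arr, index=axes).T
    return CAResult(row_scores=row_scores, col_scores=col_scores,
                    singular_values=sig, inertia=inertia,
                    inertia_fraction=fractions, total_inertia=total_inertia,
                    env_arrows=arrows)


def nearest_grid_join(points: pd.DataFrame, grid: pd.DataFrame,
                      value_columns: Sequence[str],
                      radius: float = 1.0,
                      coord_columns: tuple[str, str] = ("lat", "lon")
                      ) -> pd.DataFrame:
    """Average gridded values within ``radius`` (same units as coordinates)
    of each point; NaN where no grid cell falls inside the radius."""
    lat, lon = coord_columns
    tree = cKDTree(grid[[lat, lon]].to_numpy(dtype=float))
    out = {}
    pts = points[[lat, lon]].to_numpy(dtype=float)
    neighbours = tree.query_ball_point(pts, r=radius)
    for col in value_columns:
        vals = grid[col].to_numpy(dtype=float)
        out[col] = [float(np.mean(vals[idx])) if idx else np.nan
                    for idx in neighbours]
    return pd.DataFrame(out, index=points.index)
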