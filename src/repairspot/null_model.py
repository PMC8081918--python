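"""Cross-sample Poisson log-linear null model for bin counts.

The null for bin i, sample j is

    Y_ij ~ Poisson(lambda_ij),   lambda_ij = N_j * beta_i * f_j(TC_i)

with N_j the sample's total mapped reads (fixed after depth equalization),
beta_i a bin-specific propensity capturing library-preparation and
sequencing bias (sum of beta over unmasked bins = 1 per strand), and f_j a
smooth sample-specific function of the bin's T+C content (normalized to
beta-weighted mean 1 per sample for identifiability). Fitting alternates a
closed-form beta update with a stratified robust estimate of f, trimming
bins with large Pearson residuals so that genuinely enriched bins do not
contaminate the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import ReferenceGenome
from .spots import BinCountMatrix, BinIndex

logger = logging.getLogger(__name__)


def compute_tc_content(bins: BinIndex, genome: ReferenceGenome, strand: str = "+") -> np.ndarray:
    """Per-bin T+C fraction on the requested strand.

    For the minus strand the content is computed on the reverse complement,
    i.e. T+C on "-" equals A+G on the forward sequence. Ns are excluded from
    numerator and denominator; all-N bins get NaN (callers should mask them).
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    out = np.full(bins.n_bins, np.nan)
    pyr = ("T", "C") if strand == "+" else ("A", "G")
    for chrom in bins.chroms:
        seq = genome.sequences[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_pyr = (arr == pyr[0].encode()) | (arr == pyr[1].encode())
        is_n = arr == b"N"
        cum_p = np.concatenate([[0], np.cumsum(is_pyr)])
        cum_n = np.concatenate([[0], np.cumsum(is_n)])
        sel = bins.chrom_codes == bins.chroms.index(chrom)
        s, e = bins.starts[sel], bins.ends[sel]
        n_pyr = cum_p[e] - cum_p[s]
        n_valid = (e - s) - (cum_n[e] - cum_n[s])
        vals = np.full(len(s), np.nan)
        ok = n_valid > 0
        vals[ok] = n_pyr[ok] / n_valid[ok]
        out[bins.offsets[chrom] : bins.offsets[chrom] + len(s)] = vals
    return out


@dataclass
class NullModelFit:
    """Fitted null-model parameters for one strand.

    ``scale`` is a fitted global factor absorbing the read mass that the
    fixed library sizes N count but the unmasked rows do not carry (reads on
    blacklisted bins); expected counts are N_j * scale * beta_i * f_j(TC_i).
    """

    beta: np.ndarray              # per-bin propensity; NaN for masked bins
    f_grid_tc: np.ndarray         # stratum-midpoint TC values (per sample row)
    f_grid_values: np.ndarray     # (n_samples, n_strata) f at the grid points
    f_bins: np.ndarray            # (n_bins, n_samples) f evaluated per bin
    N: np.ndarray                 # per-sample library sizes
    tc: np.ndarray                # per-bin TC fraction used in the fit
    strand: str
    n_iter: int
    loglik_trace: np.ndarray
    trimmed: np.ndarray           # per-bin trimmed-from-updates flag
    converged: bool
    scale: float = 1.0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def trimmed_fraction(self) -> float:
        valid = ~np.isnan(self.beta)
        return float(self.trimmed[valid].mean()) if valid.any() else 0.0


def _poisson_loglik(Y: np.ndarray, lam: np.ndarray) -> float:
    lam = np.maximum(lam, 1e-300)
    return float(np.sum(Y * np.log(lam) - lam - gammaln(Y + 1)))


def fit_null_model(
    Y: BinCountMatrix,
    max_iter: int = 50,
    tol: float = 1e-6,
    resid_cut: float = 3.0,
    n_strata: int = 20,
) -> NullModelFit:
    """Robust alternating fit of the Poisson log-linear null.

    Each iteration: (1) flag bins whose standardized Pearson residual exceeds
    ``resid_cut`` in any sample and exclude them from the updates (they are
    retained for testing; their beta is imputed from the median beta of kept
    bins in the same TC stratum); (2) closed-form beta update
    beta_i = sum_j Y_ij / sum_j N_j f_j(TC_i), renormalized to sum 1;
    (3) per-sample f from the 10%-trimmed mean of Y_ij/(N_j beta_i) within
    TC-quantile strata, linearly interpolated between stratum midpoints and
    renormalized to beta-weighted mean 1. Iterations stop on relative
    log-likelihood change < ``tol`` or if an update fails to improve the
    penalized objective (safeguard keeping the recorded trace non-decreasing).
    """
    if Y.n_samples < 2:
        raise ValueError("null model needs >= 2 samples")
    tc = np.asarray(Y.tc, dtype=float) if Y.tc is not None else None
    if tc is None:
        raise ValueError("BinCountMatrix.tc must be set before fitting (compute_tc_content)")
    valid = ~Y.bins.masked & ~np.isnan(tc)
    if valid.sum() < 100:
        raise ValueError(f"only {int(valid.sum())} unmasked bins; need >= 100")
    if (Y.Y[valid].sum(axis=0) == 0).any():
        raise ValueError("a sample has zero counts on unmasked bins")

    Yv = Y.Y[valid].astype(float)
    tcv = tc[valid]
    N = np.asarray(Y.N, dtype=float)
    nb, ns = Yv.shape

    # TC-quantile strata (shared across samples)
    qs = np.quantile(tcv, np.linspace(0, 1, n_strata + 1))
    qs[0] -= 1e-9
    stratum = np.clip(np.searchsorted(qs, tcv, side="right") - 1, 0, n_strata - 1)
    grid_tc = np.array([
        tcv[stratum == s].mean() if (stratum == s).any() else np.nan
        for s in range(n_strata)
    ])

    # Initialization: median across samples is robust to bins enriched in a
    # subset of time points, so such bins show up in the residuals and get
    # trimmed instead of being absorbed into beta.
    beta = np.median(Yv / N[None, :], axis=1)
    if beta.sum() <= 0:
        beta = Yv.sum(axis=1)
    beta /= beta.sum()
    beta = np.maximum(beta, 0.1 / nb)
    beta /= beta.sum()
    F = np.ones((nb, ns))
    grid_f = np.ones((ns, n_strata))
    scale = float(Yv.sum() / N.sum())

    keep = np.ones(nb, dtype=bool)
    ll_trace = [_poisson_loglik(Yv, scale * N[None, :] * beta[:, None] * F)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            # first pass untrimmed: residuals from the rough initialization
            # would flag far too many ordinary bins
            keep = np.ones(nb, dtype=bool)
        elif it == 2:
            # trim once, from the stabilized first-pass fit, then freeze the
            # kept set: re-trimming every iteration makes the objective drift
            lam = scale * N[None, :] * beta[:, None] * F
            resid = (Yv - lam) / np.sqrt(np.maximum(lam, 1e-12))
            keep = (np.abs(resid) <= resid_cut).all(axis=1)
            if keep.sum() < max(50, nb // 10):
                logger.warning("null fit: trimming removed too many bins; relaxing to keep all")
                keep = np.ones(nb, dtype=bool)
        lam_old = scale * N[None, :] * beta[:, None] * F

        new_beta = beta.copy()
        new_beta[keep] = Yv[keep].sum(axis=1) / (F[keep] * N[None, :]).sum(axis=1)
        # impute trimmed bins from their stratum's median propensity
        for s in np.unique(stratum[~keep]):
            donor = keep & (stratum == s)
            if donor.any():
                new_beta[~keep & (stratum == s)] = np.median(new_beta[donor])
        new_beta /= new_beta.sum()
        new_beta = np.maximum(new_beta, 1e-12)
        new_beta /= new_beta.sum()

        new_grid = np.ones((ns, n_strata))
        ratio = Yv / (N[None, :] * new_beta[:, None])
        for s in range(n_strata):
            sel = keep & (stratum == s)
            if sel.sum() >= 5:
                # symmetric 10%-trimmed mean: robust to residual enriched
                # bins, far less noisy than a median of quantized ratios
                new_grid[:, s] = stats.trim_mean(ratio[sel], 0.1, axis=0)
        new_grid = np.maximum(new_grid, 1e-6)
        # f is smooth in TC by model assumption: a size-weighted 3-point
        # window on the stratum grid trades negligible bias for variance
        sizes = np.array([(keep & (stratum == s)).sum() for s in range(n_strata)], dtype=float)
        sm = np.ones_like(new_grid)
        for s in range(n_strata):
            lo_s, hi_s = max(0, s - 1), min(n_strata, s + 2)
            w = sizes[lo_s:hi_s] * np.where(np.arange(lo_s, hi_s) == s, 1.0, 0.5)
            w = np.where(np.isnan(grid_tc[lo_s:hi_s]), 0.0, w)
            if w.sum() > 0:
                sm[:, s] = (new_grid[:, lo_s:hi_s] * w[None, :]).sum(axis=1) / w.sum()
        new_grid = sm
        ok_grid = ~np.isnan(grid_tc)
        new_F = np.column_stack([
            np.interp(tcv, grid_tc[ok_grid], new_grid[j, ok_grid]) for j in range(ns)
        ])
        # identifiability: beta-weighted mean of f equals 1 per sample
        w = (new_beta[:, None] * new_F).sum(axis=0)
        new_F /= w[None, :]
        new_grid /= w[:, None]
        # global scale is the exact MLE given (beta, f) on the kept bins
        base = N[None, :] * new_beta[:, None] * new_F
        new_scale = float(Yv[keep].sum() / base[keep].sum())

        new_lam = new_scale * base
        ll = _poisson_loglik(Yv[keep], new_lam[keep])
        ll_prev = _poisson_loglik(Yv[keep], lam_old[keep])
        # iterations 1-2 restructure the problem (first full update, then
        # trimming with imputation), so the ascent safeguard and the
        # convergence check only apply to the refinement iterations
        if it > 2 and ll < ll_prev - 1e-9 * abs(ll_prev):
            logger.info("null fit: update did not improve log-likelihood; stopping at iter %d", it)
            break
        beta, F, grid_f, scale = new_beta, new_F, new_grid, new_scale
        ll_trace.append(ll)
        if it > 2 and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
    if not converged:
        logger.warning("null model did not converge in %d iterations (tol %.1e)", it, tol)

    full_beta = np.full(Y.bins.n_bins, np.nan)
    full_beta[valid] = beta
    full_F = np.full((Y.bins.n_bins, ns), np.nan)
    full_F[valid] = F
    full_trim = np.zeros(Y.bins.n_bins, dtype=bool)
    full_trim[valid] = ~keep
    return NullModelFit(
        beta=full_beta,
        f_grid_tc=grid_tc,
        f_grid_values=grid_f,
        f_bins=full_F,
        N=N,
        tc=tc,
        strand=Y.strand,
        n_iter=it,
        loglik_trace=np.asarray(ll_trace),
        trimmed=full_trim,
        converged=converged,
        scale=scale,
    )


def expected_counts(fit: NullModelFit) -> np.ndarray:
    """Expected counts Lambda_ij = N_j * scale * beta_i * f_j(TC_i).

    NaN for masked bins. ``scale`` corrects for read mass on masked bins
    that the fixed N counts but the unmasked rows do not carry.
    """
    return fit.scale * fit.N[None, :] * fit.beta[:, None] * fit.f_bins


def save_fit(fit: NullModelFit, beta_tsv: str, meta_json: str) -> None:
    """Serialize a fit: per-bin beta/TC/trim table (TSV) + model metadata (JSON)."""
    import json

    pd.DataFrame({
        "beta": fit.beta, "tc": fit.tc, "trimmed": fit.trimmed.astype(int),
    }).to_csv(beta_tsv, sep="\t", index=False)
    meta = {
        "strand": fit.strand,
        "N": fit.N.tolist(),
        "scale": fit.scale,
        "f_grid_tc": fit.f_grid_tc.tolist(),
        "f_grid_values": fit.f_grid_values.tolist(),
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "loglik_trace": fit.loglik_trace.tolist(),
    }
    with open(meta_json, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fit(beta_tsv: str, meta_json: str) -> NullModelFit:
    """Inverse of :func:`save_fit`; per-bin f is re-interpolated from the grid."""
    import json

    table = pd.read_csv(beta_tsv, sep="\t")
    with open(meta_json) as fh:
        meta = json.load(fh)
    grid_tc = np.asarray(meta["f_grid_tc"])
    grid_f = np.asarray(meta["f_grid_values"])
    tc = table["tc"].to_numpy()
    ok = ~np.isnan(grid_tc)
    f_bins = np.column_stack([
        np.interp(tc, grid_tc[ok], grid_f[j, ok]) for j in range(grid_f.shape[0])
    ])
    f_bins[np.isnan(table["beta"].to_numpy())] = np.nan
    return NullModelFit(
        beta=table["beta"].to_numpy(),
        f_grid_tc=grid_tc,
        f_grid_values=grid_f,
        f_bins=f_bins,
        N=np.asarray(meta["N"], dtype=float),
        tc=tc,
        strand=meta["strand"],
        n_iter=int(meta["n_iter"]),
        loglik_trace=np.asarray(meta["loglik_trace"]),
        trimmed=table["trimmed"].to_numpy().astype(bool),
        converged=bool(meta["converged"]),
        scale=float(meta["scale"]),
    )


def test_enrichment(
    Y: BinCountMatrix,
    fit: NullModelFit,
    spots: pd.DataFrame,
    group: list[str],
    tail: str = "by_category",
    randomize: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-spot Poisson tail test of the summed group counts against the null.

    Counts are summed over the ``group`` samples (Poisson additivity), and
    compared with the summed expected counts: upper tail for hotspots
    (enrichment at early times), lower tail for coldspots (depletion).
    ``randomize=True`` breaks the discreteness of the exact tail with the
    standard uniform tie-split, giving p-values exactly Uniform(0,1) under
    the null — useful for calibration checks; the default exact p is
    conservative and is what is reported on spot calls. q-values are
    Benjamini-Hochberg over the tested bins.
    """
    if not group:
        raise ValueError("group must name at least one sample")
    gi = Y.sample_index(group)
    lam = expected_counts(fit)
    idx = spots["bin_index"].to_numpy()
    lam_g = lam[idx][:, gi].sum(axis=1)
    y_g = Y.Y[idx][:, gi].sum(axis=1)

    if tail == "by_category":
        upper = spots["category"].to_numpy() == "hotspot"
    elif tail in ("upper", "lower"):
        upper = np.full(len(spots), tail == "upper")
    else:
        raise ValueError(f"unknown tail {tail!r}")

    if randomize:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.random(len(y_g))
        p_up = stats.poisson.sf(y_g, lam_g) + u * stats.poisson.pmf(y_g, lam_g)
        p_lo = stats.poisson.cdf(y_g - 1, lam_g) + u * stats.poisson.pmf(y_g, lam_g)
    else:
        p_up = stats.poisson.sf(y_g - 1, lam_g)
        p_lo = stats.poisson.cdf(y_g, lam_g)
    p = np.where(upper, p_up, p_lo)
    p = np.clip(p, 0.0, 1.0)

    out = spots.copy()
    out["group_count"] = y_g
    out["group_expected"] = lam_g
    out["pvalue"] = p
    out["qvalue"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return out
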