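"""Statistical core: position filtering, TMM normalization, NB dispersion
estimation, per-position likelihood-ratio testing, FDR control, and site calling.

The model is the standard one for overdispersed count data: the 5'-end count
y_pl of position p in library l is NB(mu_pl, phi) with log mu_pl = beta_p,g(l)
+ o_l, where o_l = log(N_l * f_l) is the offset built from the library size
N_l and its TMM scaling factor f_l, and g(l) indexes the two-level condition
(targeting vs nontargeting, or RppH-treated vs untreated for the TSS
contrast).  Per position, the likelihood-ratio statistic compares the
two-mean model against the one-mean null and is referred to chi-square(1);
p-values are Benjamini-Hochberg corrected over all retained positions.
Cleavage sites are the top-N positions by FDR that exceed the log2
fold-change threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .end_counting import AXIS_NAMES, EndCountTable, cpm_normalize

logger = logging.getLogger(__name__)

LOG2FC_INF = 20.0  # stand-in for +/-inf fold changes (one group all zero)
MIN_DISPERSION = 1e-6


@dataclass
class ModelConfig:
    """Tunable parameters of the cleavage-site analysis."""

    min_cpm: float = 10.0          # CPM filter threshold
    min_replicates: int = 3        # ... required in this many targeting libraries
    top_n: int = 100               # candidate sites taken by ascending FDR
    lfc_threshold: float = 4.0     # log2 fold-change cutoff (strict >)
    dispersion_mode: str = "common"  # "common" or "per-position-moment"
    prior_count: float = 0.0       # fold-change shrinkage pseudo-mean

    def __post_init__(self) -> None:
        if self.min_cpm < 0:
            raise ValueError("min_cpm must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not np.isfinite(self.lfc_threshold):
            raise ValueError("lfc_threshold must be finite")
        if self.dispersion_mode not in ("common", "per-position-moment"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_positions(
    table: EndCountTable,
    config: ModelConfig,
    positive_libs: Sequence[str] | None = None,
) -> EndCountTable:
    """Drop positions without >= ``min_cpm`` CPM in >= ``min_replicates`` of the
    signal-bearing ("targeting"-role) libraries.

    CPM here uses raw library sizes (the filter precedes normalization).  The
    criterion looks only at the positive-role libraries; control columns do
    not influence retention.
    """
    if positive_libs is None:
        positive_libs = table.libraries_where(condition="targeting")
    positive_libs = list(positive_libs)
    if len(positive_libs) < config.min_replicates:
        raise ValueError(
            f"need >= {config.min_replicates} targeting-role libraries, "
            f"got {len(positive_libs)}"
        )
    cpm = cpm_normalize(table.counts[positive_libs],
                        table.library_sizes[positive_libs])
    keep = (cpm >= config.min_cpm).sum(axis=1) >= config.min_replicates
    out = table.subset_positions(table.counts.index[keep])
    logger.info("filter_positions: retained %d of %d positions",
                out.n_positions, table.n_positions)
    return out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts,
    library_sizes,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors.

    Per library, the factor is 2**(precision-weighted mean of per-position
    log2 ratios M against a reference library), after discarding the most
    extreme ``trim_m`` fraction of M-values and ``trim_a`` fraction of
    average log-abundances A on each side.  The reference library is the one
    whose 75th-percentile count fraction is closest to the mean of those;
    weights are inverse delta-method variances; factors are rescaled so their
    geometric mean is 1.  Libraries with no positive overlap with the
    reference get factor 1 with a warning.
    """
    y = np.asarray(counts, dtype=float)
    if isinstance(counts, pd.DataFrame):
        pass
    N = np.asarray(library_sizes, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a positions x libraries matrix with >= 2 libraries")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")

    frac = y / N
    f75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        both = (y[:, j] > 0) & (y[:, ref] > 0)
        if not both.any():
            warnings.warn(
                f"library column {j} shares no expressed positions with the "
                "TMM reference; factor set to 1"
            )
            continue
        yj, yr = y[both, j], y[both, ref]
        pj, pr = yj / N[j], yr / N[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        # delta-method variance of M
        v = (N[j] - yj) / (N[j] * yj) + (N[ref] - yr) / (N[ref] * yr)

        n = M.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(M)
        ra = rankdata(A)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        with np.errstate(divide="ignore"):
            w = 1.0 / v[keep]
        f = np.sum(M[keep] * w) / np.sum(w)
        if not np.isfinite(f) or abs(f) < 1e-6:
            f = 0.0
        log_factors[j] = f

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized over positions)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion) -> np.ndarray:
    """Elementwise NB (or Poisson when dispersion == 0) log-likelihood.

    ``dispersion`` may be a scalar or a per-position vector (one value per
    row of ``y``).
    """
    if np.ndim(dispersion) == 0 and dispersion == 0.0:
        return xlogy(y, mu) - mu - gammaln(y + 1)
    r = 1.0 / np.atleast_1d(np.asarray(dispersion, dtype=float))
    if r.size > 1 or y.ndim > 1:
        r = r.reshape(-1, *([1] * (y.ndim - 1)))
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + xlogy(y, mu / (r + mu))
    )


def _fit_means(
    y: np.ndarray,
    offsets: np.ndarray,
    dispersion: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-mean intercepts beta_p for mu_pl = exp(beta_p + o_l).

    Vectorized Fisher-scoring over positions (a one-parameter NB GLM per
    position).  Rows with all-zero counts get beta = -inf / mu = 0, which is
    the boundary MLE.  Returns (beta, mu, converged).
    """
    y = np.asarray(y, dtype=float)
    e = np.exp(np.asarray(offsets, dtype=float))
    tot = y.sum(axis=1)
    zero = tot == 0
    with np.errstate(divide="ignore"):
        beta = np.log(np.where(zero, 1.0, tot) / e.sum())
    converged = np.zeros(y.shape[0], dtype=bool)
    converged[zero] = True
    scalar_zero = np.ndim(dispersion) == 0 and dispersion == 0.0
    if scalar_zero:
        # Poisson MLE is closed-form
        beta[zero] = -np.inf
        mu = np.exp(beta[:, None] + np.log(e)[None, :])
        mu[zero] = 0.0
        return beta, mu, np.ones_like(converged)
    phi = np.broadcast_to(
        np.atleast_1d(np.asarray(dispersion, dtype=float)), (y.shape[0],)
    )
    active = ~zero
    b = beta[active]
    ya = y[active]
    pa = phi[active, None]
    for _ in range(max_iter):
        mu = np.exp(b[:, None]) * e[None, :]
        denom = 1.0 + pa * mu
        score = ((ya - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
        b = b + step
        done = np.abs(step) < tol
        if done.all():
            converged[active] = True
            break
    else:
        idx = np.where(active)[0]
        converged[idx] = np.abs(step) < tol
    beta[active] = b
    beta[zero] = -np.inf
    mu = np.exp(beta[:, None] + np.log(e)[None, :])
    mu[zero] = 0.0
    return beta, mu, converged


def estimate_dispersion(
    counts,
    group_labels: Sequence,
    offsets: Sequence[float],
    mode: str = "common",
    grid: tuple[float, float, int] = (1e-6, 10.0, 19),
) -> float | np.ndarray:
    """Estimate the NB dispersion.

    ``common`` mode maximizes the Cox-Reid adjusted profile likelihood summed
    over positions on a log-spaced grid refined by golden-section search;
    ``per-position-moment`` returns a per-position method-of-moments estimate
    (for sensitivity analysis).  Requires replication in at least one group.
    """
    y = np.asarray(counts, dtype=float)
    groups = np.asarray(group_labels)
    offsets = np.asarray(offsets, dtype=float)
    levels = [groups == g for g in pd.unique(groups)]
    if max(m.sum() for m in levels) < 2:
        raise ValueError("dispersion is not estimable without replication")

    if mode == "per-position-moment":
        # moment estimator on offset-normalized counts, pooled within groups
        z = y / np.exp(offsets)[None, :]
        num = np.zeros(y.shape[0])
        den = np.zeros(y.shape[0])
        for m in levels:
            if m.sum() < 2:
                continue
            zm = z[:, m]
            mean = zm.mean(axis=1)
            var = zm.var(axis=1, ddof=1)
            num += var - mean
            den += mean ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = num / den
        return np.clip(np.nan_to_num(phi, nan=MIN_DISPERSION), MIN_DISPERSION, None)

    if mode != "common":
        raise ValueError(f"unknown dispersion mode {mode!r}")

    def apl(phi: float) -> float:
        total = 0.0
        for m in levels:
            _, mu, _ = _fit_means(y[:, m], offsets[m], phi)
            total += _nb_loglik(y[:, m], mu, phi).sum()
            w = mu / (1.0 + phi * mu)
            # Cox-Reid adjustment: -0.5 log det(X'WX); one-way design =>
            # the information is the within-group weight sum
            total -= 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-12)).sum()
        return total

    lo, hi, n = grid
    candidates = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    values = np.array([apl(p) for p in candidates])
    best = int(np.argmax(values))
    a = np.log(candidates[max(best - 1, 0)])
    b = np.log(candidates[min(best + 1, n - 1)])
    # golden-section refinement on the log scale
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = apl(np.exp(c)), apl(np.exp(d))
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = apl(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = apl(np.exp(d))
    phi = float(np.exp((a + b) / 2.0))
    return max(phi, MIN_DISPERSION)


def nb_lrt(
    counts,
    group_labels: Sequence,
    offsets: Sequence[float],
    dispersion: float | np.ndarray,
    prior_count: float = 0.0,
    positive_level=None,
) -> pd.DataFrame:
    """Per-position likelihood-ratio test of the two-level condition effect.

    Fits the NB log-link GLM with known dispersion under the full (one mean
    per group) and null (single mean) models and refers
    ``2 * (ll_full - ll_null)`` to chi-square with 1 df.  ``log2fc`` is the
    difference of the group log-mean intercepts in log2 units (positive =
    enriched in the positive-role group); with one group at zero counts it is
    reported as +/-20.  ``prior_count`` > 0 shrinks the fold change by adding
    a pseudo-mean to both normalized group means before the ratio.

    Returns a DataFrame with columns log2fc, lrt_stat, pvalue, converged
    (FDR is added by :func:`bh_adjust` downstream).
    """
    if isinstance(counts, pd.DataFrame):
        index = counts.index
        y = counts.to_numpy(dtype=float)
    else:
        y = np.asarray(counts, dtype=float)
        index = pd.RangeIndex(y.shape[0])
    groups = np.asarray(group_labels)
    offsets = np.asarray(offsets, dtype=float)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    if positive_level is None:
        positive_level = "targeting" if "targeting" in set(uniq) else uniq[0]
    pos_mask = groups == positive_level
    neg_mask = ~pos_mask

    phi = (float(dispersion) if np.ndim(dispersion) == 0
           else np.asarray(dispersion, dtype=float))

    beta_pos, mu_pos, conv_p = _fit_means(y[:, pos_mask], offsets[pos_mask], phi)
    beta_neg, mu_neg, conv_n = _fit_means(y[:, neg_mask], offsets[neg_mask], phi)
    beta_null, mu_null, conv_0 = _fit_means(y, offsets, phi)

    ll_full = (
        _nb_loglik(y[:, pos_mask], mu_pos, phi).sum(axis=1)
        + _nb_loglik(y[:, neg_mask], mu_neg, phi).sum(axis=1)
    )
    ll_null = _nb_loglik(y, mu_null, phi).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    converged = conv_p & conv_n & conv_0
    pvalue = chi2.sf(lrt, df=1)
    pvalue[~converged] = np.nan

    if prior_count > 0:
        scale = np.exp(offsets).mean()
        m_pos = np.exp(beta_pos) * scale + prior_count
        m_neg = np.exp(beta_neg) * scale + prior_count
        log2fc = np.log2(m_pos / m_neg)
    else:
        with np.errstate(invalid="ignore"):
            log2fc = (beta_pos - beta_neg) / np.log(2.0)
        log2fc = np.where(np.isposinf(log2fc), LOG2FC_INF, log2fc)
        log2fc = np.where(np.isneginf(log2fc), -LOG2FC_INF, log2fc)
        log2fc = np.where(np.isnan(log2fc), 0.0, log2fc)  # both groups zero

    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("nb_lrt: %d positions did not converge (p set to NA)", n_bad)
    return pd.DataFrame(
        {"log2fc": log2fc, "lrt_stat": lrt, "pvalue": pvalue,
         "converged": converged},
        index=index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NA entries are ignored (returned as NA); values outside [0, 1] are an
    error.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# contrasts and site calling
# ---------------------------------------------------------------------------

def _site_sort(frame: pd.DataFrame) -> pd.DataFrame:
    """Order by FDR ascending with the deterministic tie-break:
    |log2fc| descending, then reference/strand/position lexicographic."""
    key = frame.assign(_neg_abs_lfc=-frame["log2fc"].abs()).reset_index()
    key = key.sort_values(
        ["fdr", "_neg_abs_lfc", *AXIS_NAMES],
        kind="mergesort",
    ).drop(columns="_neg_abs_lfc")
    return key.set_index(list(AXIS_NAMES))


def call_sites(
    diff_result: pd.DataFrame,
    config: ModelConfig,
    site_type: str = "cleavage",
) -> pd.DataFrame:
    """Call sites: top ``top_n`` positions by ascending FDR, then keep those
    with log2fc strictly above ``lfc_threshold`` (possibly none).

    The result keeps the FDR ordering and records ``site_type`` in
    ``DataFrame.attrs``.
    """
    if diff_result.empty:
        raise ValueError("empty differential result")
    d = diff_result.dropna(subset=["pvalue"])
    ranked = _site_sort(d)
    top = ranked.head(config.top_n)
    sites = top[top["log2fc"] > config.lfc_threshold].copy()
    sites.attrs["site_type"] = site_type
    logger.info("call_sites: %d of top-%d candidates pass log2FC > %g",
                len(sites), config.top_n, config.lfc_threshold)
    return sites


def run_contrast(
    table: EndCountTable,
    config: ModelConfig,
    positive_libs: Sequence[str],
    negative_libs: Sequence[str],
    site_type: str = "cleavage",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full per-contrast pipeline: filter -> TMM -> dispersion -> LRT -> BH -> call.

    Returns (diff_result, site_set, info) where ``info`` records library
    roles, TMM factors and the dispersion estimate.
    """
    positive_libs, negative_libs = list(positive_libs), list(negative_libs)
    if not positive_libs or not negative_libs:
        raise ValueError("both contrast groups need at least one library")
    sub = table.subset_libraries(positive_libs + negative_libs)
    filtered = filter_positions(sub, config, positive_libs=positive_libs)
    if filtered.n_positions == 0:
        raise ValueError("no positions left after the CPM filter")
    y = filtered.counts
    sizes = filtered.library_sizes.to_numpy()
    factors = tmm_factors(y, sizes)
    offsets = np.log(sizes * factors)
    groups = np.array(
        ["pos"] * len(positive_libs) + ["neg"] * len(negative_libs)
    )
    dispersion = estimate_dispersion(
        y, groups, offsets, mode=config.dispersion_mode
    )
    diff = nb_lrt(y, groups, offsets, dispersion,
                  prior_count=config.prior_count, positive_level="pos")
    diff["fdr"] = bh_adjust(diff["pvalue"].to_numpy())
    sites = call_sites(diff, config, site_type=site_type)
    info = {
        "positive_libraries": positive_libs,
        "negative_libraries": negative_libs,
        "tmm_factors": dict(zip(y.columns, map(float, factors))),
        "dispersion": (float(dispersion) if np.ndim(dispersion) == 0
                       else float(np.median(dispersion))),
        "n_filtered": int(filtered.n_positions),
        "n_tested": int(diff["pvalue"].notna().sum()),
        "n_called": int(len(sites)),
    }
    return diff, sites, info


def run_cleavage_contrast(
    table: EndCountTable, config: ModelConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Targeting vs nontargeting contrast on a count table.

    When both RppH treatments are present, only the treated libraries enter
    the cleavage contrast (the untreated ones exist for the TSS contrast;
    mixing treatments would fold TSS-driven variance into the replicates).
    """
    pos = table.libraries_where(condition="targeting", rpph_treated=True)
    neg = table.libraries_where(condition="nontargeting", rpph_treated=True)
    if not pos or not neg:
        pos = table.libraries_where(condition="targeting")
        neg = table.libraries_where(condition="nontargeting")
    return run_contrast(table, config, pos, neg, site_type="cleavage")


def call_tss(
    table: EndCountTable, config: ModelConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """TSS detection: RppH-treated vs untreated libraries, same machinery.

    RppH converts 5'-triphosphate (primary, TSS-derived) transcript ends to
    ligatable monophosphates, so positions enriched in treated over untreated
    libraries mark transcription starts rather than processed/cleaved ends.
    """
    pos = table.libraries_where(rpph_treated=True)
    neg = table.libraries_where(rpph_treated=False)
    if not neg:
        raise ValueError("no RppH-untreated libraries: TSS contrast impossible")
    if not pos:
        raise ValueError("no RppH-treated libraries: TSS contrast impossible")
    return run_contrast(table, config, pos, neg, site_type="tss")


def crosscheck_tss_vs_cleavage(
    tss_sites: pd.DataFrame,
    cleavage_sites: pd.DataFrame,
    k: int = 1000,
) -> tuple[int, list[tuple]]:
    """Intersect the top-k (by FDR) strand-specific positions of the TSS and
    cleavage site sets; returns (count, sorted shared positions)."""
    out = []
    for sites, label in ((tss_sites, "tss"), (cleavage_sites, "cleavage")):
        if k > len(sites):
            warnings.warn(
                f"k={k} exceeds the {label} set size {len(sites)}; using all"
            )
        top = _site_sort(sites).head(k)
        out.append(set(top.index))
    shared = sorted(out[0] & out[1])
    return len(shared), shared
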