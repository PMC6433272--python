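"""Array-based differential methylation: filtering, QC, M-values, eBayes.

The workflow starts from a probes x samples beta matrix with paired
detection-p and bead-count matrices (the tables a scanner pipeline exports)
and proceeds:

1. remove probes failing detection (p > 0.05) or bead count (< 3) in at
   least 5% of samples;
2. keep only probes detected in *every* sample — on a human array hybridised
   to canine DNA this is the cross-species usable subset;
3. QC: per-sample beta densities (a global mode near 0.3 flags a failed
   sample) and classical multidimensional scaling of the samples;
4. transform beta to M-values, M = log2(beta / (1 - beta));
5. per-CpG two-group fit and empirical-Bayes variance moderation, yielding
   a moderated t and p per probe;
6. report methylation-variable positions (MVPs) below a p threshold with a
   hyper/hypo direction in the case group.

Sign convention: logFC = mean M in the case (lymphoma) group minus mean M in
the control group, so logFC > 0 means hypermethylated in lymphoma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

DEFAULT_P_MAX = 0.05
DEFAULT_MIN_BEADS = 3
DEFAULT_MAX_BAD_FRAC = 0.05


@dataclass
class BetaExperiment:
    """Beta / detection-p / bead-count matrices plus the sample sheet.

    All three matrices are probes x samples DataFrames sharing index and
    columns; ``samples`` has columns ``sample`` and ``group``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        for name, mat in (("detection_p", self.detection_p), ("bead_count", self.bead_count)):
            if not mat.index.equals(self.beta.index) or not mat.columns.equals(self.beta.columns):
                raise ValueError(f"{name} matrix is not aligned with the beta matrix")
        b = self.beta.to_numpy()
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if not set(self.beta.columns) == set(self.samples["sample"]):
            raise ValueError("sample sheet does not match matrix columns")

    def groups(self) -> pd.Series:
        """Group label per matrix column, in column order."""
        lut = self.samples.set_index("sample")["group"]
        return lut.loc[list(self.beta.columns)]


# ------------------------------------------------------------------ filtering

def filter_probes(
    exp: BetaExperiment,
    p_max: float = DEFAULT_P_MAX,
    min_beads: int = DEFAULT_MIN_BEADS,
    max_bad_frac: float = DEFAULT_MAX_BAD_FRAC,
) -> tuple[pd.Index, pd.DataFrame]:
    """Remove unreliable probes; return (retained index, removal log).

    A probe is removed when the fraction of samples with detection
    p > ``p_max`` is >= ``max_bad_frac``, or the fraction with bead count
    < ``min_beads`` is >= ``max_bad_frac``. The removal log has one row per
    removed probe with the reason(s).
    """
    n = exp.beta.shape[1]
    frac_det = (exp.detection_p.to_numpy() > p_max).sum(axis=1) / n
    frac_bead = (exp.bead_count.to_numpy() < min_beads).sum(axis=1) / n
    bad_det = frac_det >= max_bad_frac
    bad_bead = frac_bead >= max_bad_frac
    removed = bad_det | bad_bead
    reasons = np.where(
        bad_det & bad_bead, "detection+beads", np.where(bad_det, "detection", "beads")
    )
    log = pd.DataFrame(
        {
            "probe_id": exp.beta.index[removed],
            "reason": reasons[removed],
            "frac_failed_detection": frac_det[removed],
            "frac_low_beads": frac_bead[removed],
        }
    )
    retained = exp.beta.index[~removed]
    if len(retained) == 0:
        raise ValueError("probe filter removed every probe")
    return retained, log


def subset_common(
    exp: BetaExperiment, retained: pd.Index, p_max: float = DEFAULT_P_MAX
) -> pd.Index:
    """Probes detected (p <= p_max) in *all* samples, within ``retained``."""
    detp = exp.detection_p.loc[retained]
    ok = (detp.to_numpy() <= p_max).all(axis=1)
    return retained[ok]


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization of the beta matrix (optional).

    Each sample's sorted values are replaced by the across-sample mean of the
    order statistics. Off by default in the workflow; provided for parity
    with array pipelines that normalize before testing.
    """
    arr = beta.to_numpy(float)
    order = np.argsort(arr, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ------------------------------------------------------------------------- QC

def beta_density_qc(
    exp: BetaExperiment,
    subset: pd.Index | None = None,
    grid: np.ndarray | None = None,
    flag_mode_range: tuple[float, float] = (0.25, 0.45),
) -> dict:
    """Per-sample beta kernel densities with a failed-sample flag.

    A sample whose global density mode falls inside ``flag_mode_range``
    (default [0.25, 0.45]) resembles a failed hybridisation, whose betas
    collapse to an intermediate unimodal pile-up instead of the expected
    bimodal (unmethylated/methylated) shape.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    beta = exp.beta if subset is None else exp.beta.loc[subset]
    if beta.shape[0] < 100:
        raise ValueError("density QC needs >= 100 probes")
    out: dict = {"grid": grid, "density": {}, "mode": {}, "flagged": []}
    for col in beta.columns:
        kde = sps.gaussian_kde(beta[col].to_numpy(float))
        dens = kde(grid)
        mode = float(grid[np.argmax(dens)])
        out["density"][col] = dens
        out["mode"][col] = mode
        if flag_mode_range[0] <= mode <= flag_mode_range[1]:
            out["flagged"].append(col)
    return out


def mds_qc(M: pd.DataFrame, top_k: int = 1000) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on the most variable probes.

    Euclidean distances are computed over the ``top_k`` highest-variance
    probes, double-centered, and eigendecomposed; the first two principal
    coordinates are returned, centered at zero, with a deterministic sign
    convention (largest-magnitude loading positive).
    """
    if M.shape[1] < 3:
        raise ValueError("MDS needs >= 3 samples")
    if M.shape[0] < top_k:
        warnings.warn(
            f"only {M.shape[0]} probes available; using all instead of top {top_k}"
        )
        top_k = M.shape[0]
    var = M.var(axis=1, ddof=1)
    top = var.nlargest(top_k).index
    X = M.loc[top].to_numpy(float).T  # samples x probes
    d2 = np.square(X[:, None, :] - X[None, :, :]).sum(axis=2)
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1.0
    return pd.DataFrame(coords, index=M.columns, columns=["dim1", "dim2"])


# --------------------------------------------------------------------- M-values

def beta_to_m(beta: pd.DataFrame | np.ndarray, epsilon: float = 1e-6):
    """M = log2(beta' / (1 - beta')) with beta clipped to [eps, 1 - eps]."""
    arr = np.asarray(beta, dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse logit2 transform: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


# --------------------------------------------------------------- two-group fit

@dataclass
class DMFit:
    """Per-probe two-group fit plus empirical-Bayes hyperparameters."""

    probe_ids: pd.Index
    logfc: np.ndarray          # case mean M - control mean M
    s2: np.ndarray             # pooled residual variance per probe
    df_resid: float            # n1 + n2 - 2
    n_case: int
    n_control: int
    d0: float | None = None          # prior df (may be inf)
    s02: float | None = None         # prior variance
    s2_post: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def fit_two_group(
    M: pd.DataFrame, groups: pd.Series, case: str = "lymphoma", control: str = "control"
) -> DMFit:
    """Per-probe difference of group mean M-values with pooled residual variance."""
    g = pd.Series(groups)
    g.index = list(M.columns) if len(g) == M.shape[1] else g.index
    case_cols = [c for c in M.columns if g[c] == case]
    ctrl_cols = [c for c in M.columns if g[c] == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    Xc = M[case_cols].to_numpy(float)
    Xk = M[ctrl_cols].to_numpy(float)
    n1, n2 = Xc.shape[1], Xk.shape[1]
    logfc = Xc.mean(axis=1) - Xk.mean(axis=1)
    ss = ((Xc - Xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (Xk - Xk.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return DMFit(M.index, logfc, ss / df, float(df), n1, n2)


# -------------------------------------------------------------- eBayes moderation

def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by a monotonically convergent Newton step.

    Uses the update on the reciprocal scale (trigamma is convex and
    decreasing, behaving like 1/y for large y), which converges from the
    starting value y = 0.5 + 1/x for any x > 0.
    """
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def ebayes_moderate(fit: DMFit) -> pd.DataFrame:
    """Empirical-Bayes variance moderation and per-probe moderated t-test.

    The per-probe residual variances s^2 (each on d residual df) are modelled
    as scaled-F draws around a prior variance s0^2 with prior df d0. On the
    log scale z = log s^2, E[z] = log(s^2 true) + digamma(d/2) - log(d/2) and
    Var[z] adds trigamma(d/2); the method-of-moments estimates are

        trigamma(d0/2) = var(e) - trigamma(d/2),  e = z - digamma(d/2) + log(d/2)
        s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))

    with d0 = inf (pure shrinkage to s0^2) when var(e) <= trigamma(d/2).
    The posterior variance is the df-weighted blend

        s~^2 = (d0 s0^2 + d s^2) / (d0 + d)

    and the moderated t = logFC / (s~ sqrt(1/n1 + 1/n2)) is referred to a t
    distribution on d0 + d degrees of freedom.
    """
    s2 = np.asarray(fit.s2, dtype=float)
    d = fit.df_resid
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("eBayes needs >= 10 probes with positive residual variance")
    z = np.log(s2[ok])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2.0))
    emean = float(np.mean(e))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
    fit.d0, fit.s02, fit.s2_post = d0, s02, s2_post

    se = np.sqrt(s2_post * (1.0 / fit.n_case + 1.0 / fit.n_control))
    t = fit.logfc / se
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    res = pd.DataFrame(
        {
            "probe_id": fit.probe_ids,
            "logFC": fit.logfc,
            "t": t,
            "p_value": p,
            "df_total": df_total,
            "direction": np.where(fit.logfc > 0, "hyper", "hypo"),
        }
    ).set_index("probe_id")
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ MVP table

def mvp_table(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Methylation-variable positions: probes with p below threshold.

    Sorted by ascending p; ``direction`` is 'hyper' when the case group has
    the higher mean M-value. If a manifest is given, the human gene symbol
    is attached per probe.
    """
    sig = results[results["p_value"] < p_threshold].sort_values("p_value").copy()
    if manifest is not None:
        genes = manifest.set_index("probe_id")["gene"]
        sig["gene"] = genes.reindex(sig.index)
    return sig
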