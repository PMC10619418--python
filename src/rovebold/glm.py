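"""First- and second-level GLMs, contrasts and conjunction for region-level BOLD.

Two first-level designs are supported: the *modulator* variant (one
all-trials onset regressor plus nine parametric modulators, three per
modality, mean-centered and not serially orthogonalized) and the *trainbins*
variant (one regressor per train-length bin per modality for deviants plus
one regressor for all remaining events).  Runs are concatenated with per-run
intercept and polynomial-drift blocks; AR(1) prewhitening with a single
pooled coefficient per run is optional (default on).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rovebold.annotate import TRAIN_BINS
from rovebold.bold import (
    HRFSpec,
    BoldDataset,
    MICROTIME_DT,
    N_VOLUMES,
    TR_SECONDS,
    canonical_hrf,
    convolve_and_sample,
    _microtime_length,
    _onset_bins,
)
from rovebold.markov import MODALITIES

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "ContrastResult",
    "ConjunctionResult",
    "build_design_matrix",
    "fit_glm",
    "t_contrast",
    "train_length_contrast",
    "second_level",
    "repeated_measures_anova",
    "conjunction_global_null",
    "multiple_comparison_adjust",
    "permutation_max_t",
]

MODULATOR_CODES = ("intensity", "mismatch", "predictability")


@dataclass
class DesignMatrix:
    """Concatenated-run design with named columns."""

    matrix: np.ndarray
    names: list[str]
    task_names: list[str]
    run_slices: list[slice]
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def _task_columns_modulator(ev: pd.DataFrame) -> tuple[list[str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    names = ["onset"]
    onsets_all = ev.drop_duplicates("trial")["onset"].to_numpy(float)
    cols = {"onset": (onsets_all, np.ones(onsets_all.shape[0]))}
    for m in MODALITIES:
        sub = ev[ev["modality"] == m.name]
        onsets = sub["onset"].to_numpy(float)
        for code in MODULATOR_CODES:
            vals = sub[f"mod_{code}"].to_numpy(float)
            name = f"{code}_{m.name}"
            names.append(name)
            cols[name] = (onsets, vals)
    return names, cols


def _task_columns_trainbins(ev: pd.DataFrame) -> tuple[list[str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    names: list[str] = []
    cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    binned_mask = pd.Series(False, index=ev.index)
    for m in MODALITIES:
        for b in TRAIN_BINS:
            mask = (
                (ev["modality"] == m.name)
                & (ev["role"] == "deviant")
                & (ev["train_bin"] == b)
            )
            binned_mask |= mask
            onsets = ev.loc[mask, "onset"].to_numpy(float)
            name = f"dev_{m.name}_{b}"
            names.append(name)
            cols[name] = (onsets, np.ones(onsets.shape[0]))
    # everything not covered by a bin regressor, with per-trial multiplicity
    rest = ev.loc[~binned_mask]
    counts = rest.groupby("trial", sort=True).agg(
        onset=("onset", "first"), k=("modality", "size")
    )
    names.append("remaining")
    cols["remaining"] = (counts["onset"].to_numpy(float), counts["k"].to_numpy(float))
    return names, cols


def build_design_matrix(
    run_events: list[pd.DataFrame],
    variant: str = "modulator",
    hrf: HRFSpec | None = None,
    drift_order: int = 2,
    motion: list[np.ndarray] | None = None,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
    on_empty: str = "error",
) -> DesignMatrix:
    """Assemble the concatenated-run design matrix for one subject.

    Task regressors are built as microtime impulse trains, convolved with the
    canonical HRF and sampled at volume times; they occupy shared columns
    across runs.  Each run contributes its own intercept and Legendre drift
    columns (plus optional motion columns).

    ``on_empty`` controls what happens to an all-zero task column (for
    example the predictability modulator of a C3-only session): ``"error"``
    raises, ``"drop"`` removes it with a warning.
    """
    if variant not in ("modulator", "trainbins"):
        raise ValueError("variant must be 'modulator' or 'trainbins'")
    hrf = HRFSpec() if hrf is None else hrf
    kernel = canonical_hrf(hrf)
    n_micro = _microtime_length(n_volumes, tr, dt)
    n_runs = len(run_events)

    build = _task_columns_modulator if variant == "modulator" else _task_columns_trainbins
    task_names: list[str] | None = None
    per_run_cols: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for ev in run_events:
        names, cols = build(ev)
        if task_names is None:
            task_names = names
        elif names != task_names:
            raise ValueError("runs produced inconsistent task columns")
        per_run_cols.append(cols)
    assert task_names is not None

    # modulators are mean-centered with the session-wide mean so the centering
    # offset is absorbed by the single shared onset regressor across runs
    if variant == "modulator":
        for name in task_names:
            if name == "onset":
                continue
            all_vals = np.concatenate([c[name][1] for c in per_run_cols])
            mu = all_vals.mean()
            for c in per_run_cols:
                onsets, vals = c[name]
                c[name] = (onsets, vals - mu)

    task_blocks: list[np.ndarray] = []
    for cols in per_run_cols:
        block = np.empty((n_volumes, len(task_names)))
        for j, name in enumerate(task_names):
            onsets, vals = cols[name]
            sig = np.zeros(n_micro)
            if onsets.size:
                bins = _onset_bins(onsets, dt)
                keep = bins < n_micro
                np.add.at(sig, bins[keep], vals[keep])
            block[:, j] = convolve_and_sample(sig, kernel, n_volumes, tr, dt)
        task_blocks.append(block)
    task = np.vstack(task_blocks)

    zero = [
        task_names[j]
        for j in range(task.shape[1])
        if not np.any(np.abs(task[:, j]) > 1e-12)
    ]
    if zero:
        if on_empty == "error":
            raise ValueError(
                f"all-zero task regressors: {zero}; use on_empty='drop' to exclude"
            )
        warnings.warn(f"dropping all-zero task regressors: {zero}")
        keep_idx = [j for j, n in enumerate(task_names) if n not in zero]
        task = task[:, keep_idx]
        task_names = [task_names[j] for j in keep_idx]

    # per-run nuisance blocks: intercept + Legendre drift + motion
    x_run = np.linspace(-1.0, 1.0, n_volumes)
    nuis_cols: list[np.ndarray] = []
    nuis_names: list[str] = []
    total = n_runs * n_volumes
    for r in range(n_runs):
        rows = slice(r * n_volumes, (r + 1) * n_volumes)
        base = [np.ones(n_volumes)]
        base_names = [f"run{r + 1}_intercept"]
        for k in range(1, drift_order + 1):
            base.append(np.polynomial.legendre.Legendre.basis(k)(x_run))
            base_names.append(f"run{r + 1}_drift{k}")
        if motion is not None:
            mot = np.asarray(motion[r], dtype=float)
            for k in range(mot.shape[1]):
                base.append(mot[:, k] - mot[:, k].mean())
                base_names.append(f"run{r + 1}_motion{k + 1}")
        for col, name in zip(base, base_names):
            full = np.zeros(total)
            full[rows] = col
            nuis_cols.append(full)
            nuis_names.append(name)

    X = np.column_stack([task] + nuis_cols)
    names = list(task_names) + nuis_names
    _check_rank(X, names)
    run_slices = [slice(r * n_volumes, (r + 1) * n_volumes) for r in range(n_runs)]
    meta = {
        "variant": variant,
        "hrf": hrf,
        "dt": dt,
        "tr": tr,
        "drift_order": drift_order,
        "n_volumes": n_volumes,
    }
    return DesignMatrix(X, names, list(task_names), run_slices, meta)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise on rank deficiency, naming the offending columns via pivoted QR."""
    from scipy.linalg import qr

    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * diag.max()
    if bad.any():
        offenders = [names[piv[j]] for j in np.nonzero(bad)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {offenders}")


@dataclass
class GLMResult:
    """Per-region OLS/prewhitened estimates for one subject."""

    betas: np.ndarray  # (n_regions, p)
    sigma2: np.ndarray  # (n_regions,)
    df: int
    names: list[str]
    xtx_inv: np.ndarray  # (p, p), of the (whitened) design
    whitening: str
    rho: list[float] = field(default_factory=list)
    region_names: list[str] | None = None

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def _whiten_block(A: np.ndarray, rho: float) -> np.ndarray:
    out = A.astype(float).copy()
    out[1:] = A[1:] - rho * A[:-1]
    out[0] = A[0] * np.sqrt(1.0 - rho**2)
    return out


_AR1_RHO_GRID = np.array([-0.2, 0.0, 0.2, 0.4, 0.6, 0.8])


def _ar1_calibration(design: DesignMatrix, n_sim: int = 150) -> np.ndarray:
    """Expected OLS-residual lag-1 autocorrelation per generating AR(1) rho.

    Projecting autocorrelated noise on an HRF design absorbs a large part of
    the serial correlation, so the residual autocorrelation is biased toward
    zero by a design-dependent amount.  This maps generating rho ->
    E[residual r1] by Monte-Carlo through the residual-forming matrix (cached
    on the design), so the observed r1 can be inverted to an unbiased rho.
    """
    cached = design.meta.get("_ar1_calibration")
    if cached is not None:
        return cached
    X = design.matrix
    n = X.shape[0]
    P = np.eye(n) - X @ np.linalg.pinv(X)
    rng = np.random.default_rng(61_803_398)
    curve = np.empty_like(_AR1_RHO_GRID)
    from scipy.signal import lfilter

    for i, rho in enumerate(_AR1_RHO_GRID):
        eps = rng.normal(size=(n, n_sim))
        noise = np.empty_like(eps)
        for sl in design.run_slices:
            noise[sl] = lfilter([1.0], [1.0, -rho], eps[sl], axis=0)
        e = P @ noise
        num = den = 0.0
        for sl in design.run_slices:
            er = e[sl]
            num += float(np.sum(er[1:] * er[:-1]))
            den += float(np.sum(er[:-1] ** 2))
        curve[i] = num / den
    design.meta["_ar1_calibration"] = curve
    return curve


def _estimate_rho(design: DesignMatrix, r1_observed: float) -> float:
    """Invert the calibration curve at the observed residual autocorrelation."""
    curve = _ar1_calibration(design)
    rho = float(np.interp(r1_observed, curve, _AR1_RHO_GRID))
    return float(np.clip(rho, -0.95, 0.95))


def fit_glm(
    data: BoldDataset | list[np.ndarray],
    design: DesignMatrix,
    whitening: str = "ar1",
) -> GLMResult:
    """Fit the GLM to every region's concatenated time series.

    ``whitening="ar1"`` estimates a single AR(1) coefficient per run from the
    OLS residuals pooled over regions, then refits on the whitened model;
    ``"none"`` is plain OLS.
    """
    if whitening not in ("none", "ar1"):
        raise ValueError("whitening must be 'none' or 'ar1'")
    runs = data.data if isinstance(data, BoldDataset) else data
    region_names = data.region_names if isinstance(data, BoldDataset) else None
    Y = np.hstack(runs).T  # (total_volumes, n_regions)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in BOLD data")
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"data rows ({Y.shape[0]}) do not match design rows ({X.shape[0]})"
        )

    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # (p, n_regions)
    rho_per_run: list[float] = []
    if whitening == "ar1":
        E = Y - X @ B
        Xw = X.copy()
        Yw = Y.copy()
        for sl in design.run_slices:
            e = E[sl]
            num = float(np.sum(e[1:] * e[:-1]))
            den = float(np.sum(e[:-1] ** 2))
            rho = 0.0 if den == 0 else _estimate_rho(design, num / den)
            rho_per_run.append(rho)
            Xw[sl] = _whiten_block(X[sl], rho)
            Yw[sl] = _whiten_block(Y[sl], rho)
        X, Y = Xw, Yw
        pinv = np.linalg.pinv(X)
        B = pinv @ Y

    resid = Y - X @ B
    rank = np.linalg.matrix_rank(X)
    df = X.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    return GLMResult(
        betas=B.T,
        sigma2=sigma2,
        df=df,
        names=list(design.names),
        xtx_inv=xtx_inv,
        whitening=whitening,
        rho=rho_per_run,
        region_names=region_names,
    )


@dataclass
class ContrastResult:
    """Contrast estimate, SE, t and p per region."""

    estimate: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: float
    alternative: str = "two-sided"
    region_names: list[str] | None = None
    degenerate: np.ndarray | None = None
    per_bin: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.region_names or list(range(self.estimate.shape[0]))
        return pd.DataFrame(
            {
                "region": idx,
                "estimate": self.estimate,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


def _p_from_t(t: np.ndarray, df: float, alternative: str) -> np.ndarray:
    if alternative == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    if alternative == "greater":
        return stats.t.sf(t, df)
    if alternative == "less":
        return stats.t.cdf(t, df)
    raise ValueError(f"unknown alternative {alternative!r}")


def t_contrast(
    result: GLMResult,
    weights: np.ndarray | dict[str, float],
    alternative: str = "two-sided",
) -> ContrastResult:
    """t test of ``c' beta`` per region."""
    p_cols = len(result.names)
    if isinstance(weights, dict):
        c = np.zeros(p_cols)
        for name, w in weights.items():
            c[result.names.index(name)] = w
    else:
        c = np.asarray(weights, dtype=float)
        if c.shape[0] != p_cols:
            raise ValueError(f"weights length {c.shape[0]} != {p_cols} regressors")
    est = result.betas @ c
    var_c = float(c @ result.xtx_inv @ c)
    se = np.sqrt(result.sigma2 * var_c)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.where(est == 0, 0.0, np.inf * np.sign(est)), est / np.where(se == 0, 1.0, se))
    p = np.where(degenerate, np.nan, _p_from_t(t, result.df, alternative))
    if np.all(c == 0):
        t = np.zeros_like(est)
        p = np.ones_like(est) if alternative != "two-sided" else np.ones_like(est)
    return ContrastResult(
        est, se, t, p, result.df, alternative, result.region_names, degenerate
    )


def linear_ramp_weights(n: int = 6) -> np.ndarray:
    """Centered linear ramp over bin indices; sums to zero exactly."""
    w = np.arange(n, dtype=float)
    return w - w.mean()


def train_length_contrast(
    result: GLMResult, modality: str, alternative: str = "two-sided"
) -> ContrastResult:
    """Linear train-length contrast over the six bin regressors of a modality.

    If a bin regressor was dropped (no deviants in that bin), the ramp is
    rebuilt over the present bins and re-centered, with a warning.  The
    per-bin estimates are attached for Fig-4-style plotting.
    """
    bin_names = [f"dev_{modality}_{b}" for b in TRAIN_BINS]
    present = [n for n in bin_names if n in result.names]
    if not present:
        raise ValueError(f"no train-bin regressors for modality {modality}")
    if len(present) < len(bin_names):
        warnings.warn(
            f"missing train bins {sorted(set(bin_names) - set(present))}; "
            "ramp weights renormalized over present bins"
        )
    idx = np.array([bin_names.index(n) for n in present], dtype=float)
    w = idx - idx.mean()
    weights = dict(zip(present, w))
    res = t_contrast(result, weights, alternative)
    res.per_bin = pd.DataFrame(
        {n.split("_")[-1]: result.beta(n) for n in present},
        index=result.region_names or range(result.betas.shape[0]),
    )
    return res


def second_level(
    estimates: np.ndarray, alternative: str = "two-sided"
) -> ContrastResult:
    """One-sample t across subjects, per region.

    ``estimates`` is (n_subjects, n_regions).  Regions with zero
    between-subject variance are flagged degenerate (infinite t, NaN p).
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    n = est.shape[0]
    if n < 2:
        raise ValueError("second level needs at least 2 subjects")
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            degenerate,
            np.where(mean == 0, 0.0, np.inf * np.sign(mean)),
            mean / np.where(se == 0, 1.0, se),
        )
    df = n - 1
    p = np.where(degenerate, np.nan, _p_from_t(t, df, alternative))
    return ContrastResult(mean, se, t, p, df, alternative, degenerate=degenerate)


def repeated_measures_anova(estimates: np.ndarray) -> pd.DataFrame:
    """One-way repeated-measures ANOVA over a within-subject factor.

    ``estimates`` is (n_subjects, n_levels, n_regions); returns F, df and p
    per region for the level factor.
    """
    y = np.asarray(estimates, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    n, k, n_regions = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 factor levels")
    grand = y.mean(axis=(0, 1))
    subj_mean = y.mean(axis=1)
    level_mean = y.mean(axis=0)
    ss_level = n * ((level_mean - grand) ** 2).sum(axis=0)
    ss_err = (
        (y - subj_mean[:, None, :] - level_mean[None, :, :] + grand) ** 2
    ).sum(axis=(0, 1))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_level / df1) / (ss_err / df2)
    p = stats.f.sf(F, df1, df2)
    return pd.DataFrame({"F": F, "df1": df1, "df2": df2, "p": p})


@dataclass
class ConjunctionResult:
    """Minimum-statistic conjunction across k contrast maps.

    ``p_global`` tests the global null (all k effects null): under
    independence ``p = sf(min_t)**k``, exactly calibrated.  ``p_conjnull`` is
    the conservative conjunction-null p (``sf(min_t)`` = max component p),
    which is >= every component p.
    """

    component_t: np.ndarray  # (k, n_regions)
    min_t: np.ndarray
    p_global: np.ndarray
    p_conjnull: np.ndarray
    df: float

    @property
    def p(self) -> np.ndarray:
        return self.p_global


def conjunction_global_null(results: list[ContrastResult]) -> ConjunctionResult:
    """Conjunction of k one-sided (positive) contrasts against the global null."""
    if len(results) < 1:
        raise ValueError("need at least one component contrast")
    dfs = {r.df for r in results}
    if len(dfs) != 1:
        raise ValueError(f"component contrasts have mismatched df: {sorted(dfs)}")
    df = results[0].df
    T = np.vstack([r.t for r in results])
    min_t = T.min(axis=0)
    k = T.shape[0]
    p_one = stats.t.sf(min_t, df)
    return ConjunctionResult(T, min_t, p_one**k, p_one, df)


def multiple_comparison_adjust(
    p: np.ndarray, method: str = "bonferroni", m: int | None = None
) -> np.ndarray:
    """Family-wise adjustment of per-region p values."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        m = p.shape[0] if m is None else m
        return np.minimum(1.0, m * p)
    raise ValueError(
        "method must be 'bonferroni'; use permutation_max_t for the "
        "permutation alternative (needs subject-level estimates)"
    )


def permutation_max_t(
    subject_estimates: np.ndarray,
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> np.ndarray:
    """FWE-adjusted p values via the sign-flip max-statistic null.

    ``subject_estimates`` is (n_subjects, n_regions); the observed one-sample
    t per region is compared with the permutation distribution of the maximum
    (absolute) t over regions.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(subject_estimates, dtype=float)
    n = y.shape[0]

    def tstat(z: np.ndarray) -> np.ndarray:
        se = z.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se == 0, 0.0, z.mean(axis=0) / np.where(se == 0, 1.0, se))

    obs = tstat(y)
    stat = np.abs(obs) if alternative == "two-sided" else obs
    count = np.zeros_like(stat)
    for _ in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n, 1))
        t_perm = tstat(y * flips)
        m = np.abs(t_perm).max() if alternative == "two-sided" else t_perm.max()
        count += m >= stat
    return (count + 1.0) / (n_perm + 1.0)
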