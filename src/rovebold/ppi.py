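"""Psychophysiological-interaction (PPI) estimation from region-level BOLD.

The interaction regressor couples a seed region's activity with the
deviant/standard psychological vector of one modality.  Two constructions
are available: ``bold_product`` multiplies the (centered) seed BOLD with the
convolved psychological regressor, and ``deconvolved`` (default) estimates
the seed's neural signal by ridge-regularized inversion of the HRF
convolution operator, forms the product with the trial-level psychological
impulses, and re-convolves — the closer analogue of SPM's implementation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from rovebold.bold import (
    BoldDataset,
    HRFSpec,
    MICROTIME_DT,
    N_VOLUMES,
    TR_SECONDS,
    canonical_hrf,
    convolve_and_sample,
    mismatch_psych_impulses,
    _onset_bins,
)
from rovebold.glm import (
    ContrastResult,
    DesignMatrix,
    GLMResult,
    build_design_matrix,
    fit_glm,
    t_contrast,
)

__all__ = [
    "PPIRegressors",
    "PPIResult",
    "extract_seed_timeseries",
    "build_ppi_regressors",
    "deconvolve_series",
    "fit_ppi",
]

#: neural grid for deconvolution — coarse enough for a dense operator, and a
#: common multiple of the TR (1.5 s) and ISI (1.75 s) grids
DECONV_DT = 0.25


def extract_seed_timeseries(
    dataset: BoldDataset,
    region: str | list[str],
    run: int | None = None,
    normalize: bool = False,
) -> np.ndarray | list[np.ndarray]:
    """Mean time series over one or more regions (the 'sphere' analogue).

    Returns one array per run (or a single array when ``run`` is given).
    ``normalize`` divides each run's series by its standard deviation.
    """
    names = [region] if isinstance(region, str) else list(region)
    idx = [dataset.region_index(n) for n in names]
    out = []
    for mat in dataset.data:
        series = mat[idx].mean(axis=0)
        if normalize:
            sd = series.std()
            if sd > 0:
                series = series / sd
        out.append(series)
    if run is not None:
        return out[run]
    return out


@lru_cache(maxsize=8)
def _conv_operator(
    n_volumes: int, tr: float, dt: float, hrf_key: tuple
) -> np.ndarray:
    """Dense operator mapping a neural series on the dt grid to volume BOLD."""
    hrf = HRFSpec(*hrf_key[:-1], dt=dt)
    kernel = canonical_hrf(hrf)
    n_grid = int(round(n_volumes * tr / dt))
    step = int(round(tr / dt))
    C = np.zeros((n_volumes, n_grid))
    for k in range(n_volumes):
        row_t = k * step
        lo = max(0, row_t - kernel.shape[0] + 1)
        seg = kernel[row_t - np.arange(lo, row_t + 1)]
        C[k, lo : row_t + 1] = seg
    return C


def _hrf_key(hrf: HRFSpec) -> tuple:
    return (
        hrf.peak_delay,
        hrf.undershoot_delay,
        hrf.peak_dispersion,
        hrf.undershoot_dispersion,
        hrf.ratio,
        hrf.duration,
        hrf.dt,
    )


@lru_cache(maxsize=8)
def _conv_svd(n_volumes: int, tr: float, dt: float, hrf_key: tuple):
    C = _conv_operator(n_volumes, tr, dt, hrf_key)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    return C, U, s, Vt


def deconvolve_series(
    series: np.ndarray,
    hrf: HRFSpec | None = None,
    tr: float = TR_SECONDS,
    dt: float = DECONV_DT,
    ridge: float | None = None,
) -> tuple[np.ndarray, float]:
    """Ridge-regularized deconvolution of a volume series to the neural grid.

    The ridge parameter is chosen by generalized cross-validation over a log
    grid unless given.  Returns ``(neural_estimate, lambda)``.
    """
    hrf = HRFSpec() if hrf is None else hrf
    y = np.asarray(series, dtype=float)
    y = y - y.mean()
    n = y.shape[0]
    _, U, s, Vt = _conv_svd(n, tr, dt, _hrf_key(hrf))
    uty = U.T @ y
    if ridge is None:
        lams = np.logspace(-6, 2, 33) * float(s.max() ** 2)
        best, ridge = np.inf, float(lams[0])
        for lam in lams:
            f = s**2 / (s**2 + lam)
            resid = np.sum(((1.0 - f) * uty) ** 2)
            denom = (n - f.sum()) ** 2
            gcv = n * resid / denom
            if gcv < best:
                best, ridge = gcv, float(lam)
    f = s / (s**2 + ridge)
    z = Vt.T @ (f * uty)
    return z, ridge


@dataclass
class PPIRegressors:
    """Per-run physiological, psychological and interaction regressors."""

    physiological: list[np.ndarray]
    psychological: list[np.ndarray]
    interaction: list[np.ndarray]
    mode: str
    modality: str
    ridge: list[float] | None = None


def build_ppi_regressors(
    seed_series: list[np.ndarray],
    run_events: list[pd.DataFrame],
    modality: str,
    mode: str = "deconvolved",
    hrf: HRFSpec | None = None,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
) -> PPIRegressors:
    """Build the three PPI regressors for each run.

    The psychological regressor is the +/-1 deviant/standard impulse train of
    ``modality`` convolved to the volume grid and mean-centered.  The
    interaction is either the product of centered seed BOLD and psychological
    regressor (``bold_product``) or the re-convolved product of the
    deconvolved seed and the trial-level psychological impulses
    (``deconvolved``).
    """
    if mode not in ("bold_product", "deconvolved"):
        raise ValueError("mode must be 'bold_product' or 'deconvolved'")
    hrf = HRFSpec() if hrf is None else hrf
    kernel = canonical_hrf(hrf)
    phys, psych, inter = [], [], []
    ridges: list[float] = []
    for seed, ev in zip(seed_series, run_events, strict=True):
        n_vol = seed.shape[0]
        codes = ev.loc[ev["modality"] == modality, "mod_mismatch"].to_numpy(float)
        if not np.any(codes > 0):
            raise ValueError(
                f"no deviants for modality {modality}: degenerate psychological vector"
            )
        psy_micro = mismatch_psych_impulses(ev, modality, n_vol, tr, dt)
        psy_vol = convolve_and_sample(psy_micro, kernel, n_vol, tr, dt)
        psy_vol = psy_vol - psy_vol.mean()
        seed_c = seed - seed.mean()
        if mode == "bold_product":
            ia = seed_c * psy_vol
            ridges.append(0.0)
        else:
            z, lam = deconvolve_series(seed, hrf, tr, DECONV_DT)
            ridges.append(lam)
            # trial-level psych impulses on the deconvolution grid
            sub = ev[ev["modality"] == modality]
            bins = _onset_bins(sub["onset"].to_numpy(float), DECONV_DT)
            psy_grid = np.zeros(z.shape[0])
            keep = bins < z.shape[0]
            np.add.at(psy_grid, bins[keep], sub["mod_mismatch"].to_numpy(float)[keep])
            kernel_grid = canonical_hrf(dataclasses.replace(hrf, dt=DECONV_DT))
            ia = convolve_and_sample(z * psy_grid, kernel_grid, n_vol, tr, DECONV_DT)
        ia = ia - ia.mean()
        phys.append(seed_c)
        psych.append(psy_vol)
        inter.append(ia)
    return PPIRegressors(phys, psych, inter, mode, modality, ridges)


@dataclass
class PPIResult:
    """Interaction coupling estimates from seed to every target region."""

    seed: str
    modality: str
    mode: str
    contrast: ContrastResult
    glm: GLMResult
    design: DesignMatrix

    def to_frame(self) -> pd.DataFrame:
        df = self.contrast.to_frame()
        df.insert(0, "seed", self.seed)
        df.insert(1, "modality", self.modality)
        return df.rename(columns={"estimate": "beta_ppi"})


def fit_ppi(
    dataset: BoldDataset,
    seed: str,
    modality: str,
    mode: str = "deconvolved",
    targets: list[str] | None = None,
    hrf: HRFSpec | None = None,
    whitening: str = "ar1",
    include_task: bool = True,
    drift_order: int = 2,
    omit: tuple[str, ...] = (),
) -> PPIResult:
    """First-level PPI: regress every target on the interaction regressor.

    The model contains the interaction, the seed's physiological regressor
    and (when ``include_task``) the full modulator-variant task set — the
    psychological main effect is the seed modality's mismatch modulator — plus
    per-run intercept/drift columns.  ``omit`` may list ``"phys"`` and/or
    ``"psych"`` to deliberately drop a main effect (misspecification checks
    only).
    """
    bad = set(omit) - {"phys", "psych"}
    if bad:
        raise ValueError(f"omit accepts 'phys'/'psych', got {sorted(bad)}")
    n_vol = dataset.n_volumes
    seed_series = extract_seed_timeseries(dataset, seed)
    regs = build_ppi_regressors(
        seed_series, dataset.events, modality, mode, hrf, dataset.tr
    )
    base = build_design_matrix(
        dataset.events,
        variant="modulator",
        hrf=hrf,
        drift_order=drift_order,
        n_volumes=n_vol,
        tr=dataset.tr,
        on_empty="drop",
    )
    ppi_blocks = [np.concatenate(regs.interaction)[:, None]]
    ppi_names = [f"ppi_{seed}_{modality}"]
    if "phys" not in omit:
        ppi_blocks.append(np.concatenate(regs.physiological)[:, None])
        ppi_names.append(f"phys_{seed}")
    ppi_cols = np.hstack(ppi_blocks)
    if include_task:
        keep = [
            i
            for i, n in enumerate(base.names)
            if not ("psych" in omit and n == f"mismatch_{modality}")
        ]
        X = np.column_stack([ppi_cols, base.matrix[:, keep]])
        names = ppi_names + [base.names[i] for i in keep]
        task_names = ppi_names + [n for n in base.task_names if n in names]
    else:
        cols = [ppi_cols]
        names = list(ppi_names)
        if "psych" not in omit:
            cols.append(np.concatenate(regs.psychological)[:, None])
            names.append("psych")
        nuis_idx = [i for i, n in enumerate(base.names) if n not in base.task_names]
        cols.append(base.matrix[:, nuis_idx])
        names = names + [base.names[i] for i in nuis_idx]
        task_names = [n for n in names if not n.startswith("run")]
        X = np.hstack(cols)
    design = DesignMatrix(X, names, task_names, base.run_slices, dict(base.meta))

    if targets is None:
        target_idx = [i for i, n in enumerate(dataset.region_names) if n != seed]
    else:
        target_idx = [dataset.region_index(t) for t in targets]
    runs = [mat[target_idx] for mat in dataset.data]
    result = fit_glm(runs, design, whitening=whitening)
    result.region_names = [dataset.region_names[i] for i in target_idx]
    contrast = t_contrast(result, {ppi_names[0]: 1.0})
    contrast.region_names = result.region_names
    return PPIResult(seed, modality, mode, contrast, result, design)
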