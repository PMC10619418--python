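"""Synthetic region-level BOLD generation with configurable ground-truth effects.

Each region's neural signal is an impulse train on a fine microtime grid:
one impulse per trial whose height is a linear combination of the trial's
annotation codes (intensity, mismatch, train-length bin, predictability) plus
a baseline.  The train is convolved with a canonical double-gamma HRF,
sampled at volume times, and corrupted with polynomial drift and AR(1) noise.
Seed-coupled targets additionally receive a neural-level interaction term
(seed signal times the mismatch psychological vector) before convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal, stats

from rovebold.markov import MODALITIES

__all__ = [
    "TR_SECONDS",
    "N_VOLUMES",
    "MICROTIME_DT",
    "HRFSpec",
    "NoiseSpec",
    "PPICoupling",
    "RegionEffectSpec",
    "BoldDataset",
    "canonical_hrf",
    "build_neural_signal",
    "mismatch_psych_impulses",
    "generate_run_bold",
    "generate_dataset",
    "default_region_specs",
]

TR_SECONDS = 1.5
N_VOLUMES = 475
MICROTIME_DT = 0.05

_BIN_CENTER = 2.5  # centre of the six train-length bin indices 0..5


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM-style defaults)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    duration: float = 32.0
    dt: float = MICROTIME_DT


def canonical_hrf(spec: HRFSpec | None = None) -> np.ndarray:
    """Sample the double-gamma kernel on the microtime grid, peak-normalized.

    The positive lobe is a gamma density with shape ``peak_delay /
    peak_dispersion`` (mode 5 s for the defaults), minus a scaled undershoot
    gamma; the kernel is normalized to maximum 1.
    """
    spec = HRFSpec() if spec is None else spec
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = stats.gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    h = peak - under / spec.ratio
    return h / h.max()


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1) + polynomial drift noise model for one region's run."""

    rho: float = 0.3
    sigma: float = 0.5
    drift_order: int = 2
    drift_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
        if self.sigma < 0:
            raise ValueError("innovation sd must be >= 0")


@dataclass(frozen=True)
class PPICoupling:
    """Seed-to-target coupling injected at the neural level."""

    seed: str
    base: float = 0.0
    mismatch: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per modality A, S, V


def _as_triple(v) -> tuple[float, float, float]:
    if np.isscalar(v):
        return (float(v),) * 3
    v = tuple(float(x) for x in v)
    if len(v) != 3:
        raise ValueError("per-modality amplitude needs 3 values (A, S, V)")
    return v


@dataclass
class RegionEffectSpec:
    """Ground-truth response amplitudes of one region (arbitrary units).

    Per-modality amplitudes accept a scalar (broadcast to A, S, V) or a
    3-tuple.  ``trainlength_slope`` multiplies the centered train-bin index
    of binned deviants.
    """

    name: str
    baseline_response: float = 0.0
    intensity_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mismatch_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)
    trainlength_slope: tuple[float, float, float] = (0.0, 0.0, 0.0)
    misprediction_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ppi_target: PPICoupling | None = None

    def __post_init__(self) -> None:
        self.intensity_effect = _as_triple(self.intensity_effect)
        self.mismatch_effect = _as_triple(self.mismatch_effect)
        self.trainlength_slope = _as_triple(self.trainlength_slope)
        self.misprediction_effect = _as_triple(self.misprediction_effect)

    @property
    def is_null(self) -> bool:
        return (
            self.baseline_response == 0
            and not any(self.intensity_effect)
            and not any(self.mismatch_effect)
            and not any(self.trainlength_slope)
            and not any(self.misprediction_effect)
            and self.ppi_target is None
        )


@dataclass
class BoldDataset:
    """Region x volume series per run, with the generating ground truth."""

    data: list[np.ndarray]  # one (n_regions, n_volumes) array per run
    region_names: list[str]
    effect_specs: list[RegionEffectSpec]
    events: list[pd.DataFrame]  # annotated event table per run
    noise: NoiseSpec
    tr: float = TR_SECONDS
    seed: int | None = None

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def n_volumes(self) -> int:
        return int(self.data[0].shape[1])

    def region_index(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def write_tsv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for r, mat in enumerate(self.data, start=1):
            df = pd.DataFrame(mat.T, columns=self.region_names)
            df.to_csv(out_dir / f"bold_run-{r}.tsv", sep="\t", index=False)
        meta = {
            "regions": self.region_names,
            "tr": self.tr,
            "n_volumes": self.n_volumes,
            "seed": self.seed,
        }
        (out_dir / "regions.json").write_text(json.dumps(meta, indent=2) + "\n")


def _microtime_length(n_volumes: int, tr: float, dt: float) -> int:
    return int(round(n_volumes * tr / dt))


def _onset_bins(onsets: np.ndarray, dt: float) -> np.ndarray:
    bins = onsets / dt
    rounded = np.rint(bins)
    if np.any(np.abs(bins - rounded) > 1e-6):
        raise ValueError("trial onsets must lie on the microtime grid")
    return rounded.astype(int)


def trial_impulse_heights(events: pd.DataFrame, spec: RegionEffectSpec) -> pd.Series:
    """Per-trial neural impulse height implied by an effect spec.

    Linear in all amplitudes: baseline once per trial plus, per modality, the
    intensity/mismatch/predictability codes times their amplitudes and the
    centered train-bin index (binned deviants only) times the slope.
    """
    heights: dict[int, float] = {}
    mod_of = {m.name: m.value for m in MODALITIES}
    for row in events.itertuples(index=False):
        k = mod_of[row.modality]
        h = heights.get(row.trial, spec.baseline_response)
        h += row.mod_intensity * spec.intensity_effect[k]
        h += row.mod_mismatch * spec.mismatch_effect[k]
        h += row.mod_predictability * spec.misprediction_effect[k]
        if row.train_bin != "n/a" and row.role == "deviant":
            from rovebold.annotate import train_bin_index

            h += (train_bin_index(int(row.train_length)) - _BIN_CENTER) * spec.trainlength_slope[k]
        heights[row.trial] = h
    return pd.Series(heights).sort_index()


def build_neural_signal(
    events: pd.DataFrame,
    spec: RegionEffectSpec,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """Microtime impulse series for one run and one region."""
    n = _microtime_length(n_volumes, tr, dt)
    sig = np.zeros(n)
    heights = trial_impulse_heights(events, spec)
    onsets = events.drop_duplicates("trial").set_index("trial")["onset"]
    bins = _onset_bins(onsets.loc[heights.index].to_numpy(float), dt)
    keep = bins < n
    np.add.at(sig, bins[keep], heights.to_numpy(float)[keep])
    return sig


def mismatch_psych_impulses(
    events: pd.DataFrame,
    modality: str,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """Microtime +/-1 deviant/standard impulse train for one modality."""
    n = _microtime_length(n_volumes, tr, dt)
    sig = np.zeros(n)
    sub = events[events["modality"] == modality]
    bins = _onset_bins(sub["onset"].to_numpy(float), dt)
    keep = bins < n
    np.add.at(sig, bins[keep], sub["mod_mismatch"].to_numpy(float)[keep])
    return sig


def convolve_and_sample(
    neural: np.ndarray,
    kernel: np.ndarray,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """Convolve a microtime series with the HRF and sample at volume times."""
    step = int(round(tr / dt))
    if abs(step * dt - tr) > 1e-9:
        raise ValueError("TR must be a multiple of the microtime step")
    conv = signal.fftconvolve(neural, kernel)[: neural.shape[0]]
    return conv[::step][:n_volumes]


def ar1_noise(
    n: int, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series with coefficient rho and innovation sd sigma."""
    eps = rng.normal(0.0, noise.sigma, size=n)
    x = signal.lfilter([1.0], [1.0, -noise.rho], eps)
    if noise.rho != 0.0 and n > 0:
        # stationary initial condition
        x0 = rng.normal(0.0, noise.sigma / np.sqrt(1.0 - noise.rho**2))
        decay = noise.rho ** np.arange(1, n + 1)
        x = x + x0 * decay
    return x


def polynomial_drift(
    n: int, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Random Legendre-polynomial drift of the configured order."""
    if noise.drift_order < 1 or noise.drift_amplitude == 0.0:
        return np.zeros(n)
    x = np.linspace(-1.0, 1.0, n)
    drift = np.zeros(n)
    for k in range(1, noise.drift_order + 1):
        coef = rng.normal(0.0, noise.drift_amplitude)
        drift += coef * np.polynomial.legendre.Legendre.basis(k)(x)
    return drift


def generate_run_bold(
    events: pd.DataFrame,
    specs: list[RegionEffectSpec],
    noise: NoiseSpec,
    rng: np.random.Generator,
    hrf: HRFSpec | None = None,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """One run's (n_regions, n_volumes) matrix from annotated events.

    Seed-coupled targets receive ``base * seed_neural + sum_m mismatch_m *
    (seed_neural x psych_m)`` added to their neural signal *before*
    convolution, so BOLD-level interaction estimators recover the coupling
    only approximately (the known deconvolution caveat).
    """
    hrf = HRFSpec() if hrf is None else hrf
    kernel = canonical_hrf(hrf)
    names = [s.name for s in specs]
    neural = {
        s.name: build_neural_signal(events, s, n_volumes, tr, dt) for s in specs
    }
    psych = {
        m.name: mismatch_psych_impulses(events, m.name, n_volumes, tr, dt)
        for m in MODALITIES
    }
    out = np.empty((len(specs), n_volumes))
    for i, s in enumerate(specs):
        sig = neural[s.name]
        if s.ppi_target is not None:
            cp = s.ppi_target
            if cp.seed not in neural:
                raise ValueError(
                    f"region {s.name!r}: ppi seed {cp.seed!r} not in dataset"
                )
            seed_sig = neural[cp.seed]
            sig = sig + cp.base * seed_sig
            for m in MODALITIES:
                w = _as_triple(cp.mismatch)[m.value]
                if w:
                    sig = sig + w * seed_sig * psych[m.name]
        bold = convolve_and_sample(sig, kernel, n_volumes, tr, dt)
        bold = bold + polynomial_drift(n_volumes, noise, rng)
        if noise.sigma > 0:
            bold = bold + ar1_noise(n_volumes, noise, rng)
        out[i] = bold
    return out


def generate_dataset(
    run_events: list[pd.DataFrame],
    specs: list[RegionEffectSpec],
    noise: NoiseSpec,
    rng: np.random.Generator,
    hrf: HRFSpec | None = None,
    n_volumes: int = N_VOLUMES,
    tr: float = TR_SECONDS,
    dt: float = MICROTIME_DT,
    seed: int | None = None,
) -> BoldDataset:
    """Generate a full dataset (all runs) from annotated event tables."""
    data = [
        generate_run_bold(ev, specs, noise, rng, hrf, n_volumes, tr, dt)
        for ev in run_events
    ]
    return BoldDataset(
        data=data,
        region_names=[s.name for s in specs],
        effect_specs=specs,
        events=run_events,
        noise=noise,
        tr=tr,
        seed=seed,
    )


def default_region_specs(
    amp: float = 1.0, coupling: float = 2.0
) -> list[RegionEffectSpec]:
    """The default 20-region map: sensory, fronto-parietal, IPS-like, PPI, null.

    Six sensory regions carry intensity + modality-specific mismatch, four
    shared regions carry mismatch in all modalities plus a train-length
    slope, one parietal-like region carries the misprediction effect, three
    targets receive mismatch-modulated coupling from the auditory seed, and
    six regions are null (type-I checks).
    """
    def per_mod(m: int, value: float) -> tuple[float, float, float]:
        v = [0.0, 0.0, 0.0]
        v[m] = value
        return tuple(v)

    specs: list[RegionEffectSpec] = []
    for m, mod in enumerate(["aud", "som", "vis"]):
        for side in ("l", "r"):
            specs.append(
                RegionEffectSpec(
                    name=f"{mod}_{side}",
                    baseline_response=amp,
                    intensity_effect=per_mod(m, amp),
                    mismatch_effect=per_mod(m, amp),
                )
            )
    for name in ("ifg_l", "ifg_r", "preSMA", "insula_r"):
        specs.append(
            RegionEffectSpec(
                name=name,
                baseline_response=amp,
                mismatch_effect=(amp, amp, amp),
                trainlength_slope=(0.3 * amp,) * 3,
            )
        )
    specs.append(
        RegionEffectSpec(
            name="ips_r",
            baseline_response=amp,
            mismatch_effect=(0.5 * amp,) * 3,
            misprediction_effect=(amp, amp, amp),
        )
    )
    for i, m in enumerate(["A", "S", "V"]):
        w = [0.0, 0.0, 0.0]
        w[i] = coupling
        specs.append(
            RegionEffectSpec(
                name=f"ppi_target_{m}",
                baseline_response=0.5 * amp,
                ppi_target=PPICoupling(seed="aud_l", base=0.2, mismatch=tuple(w)),
            )
        )
    for i in range(1, 7):
        specs.append(RegionEffectSpec(name=f"null_{i}"))
    return specs
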