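"""Seed-controlled synthetic DDA runs built from a catalog.

Every catalog record becomes one MS/MS spectrum carrying its published
fragment ions with Gaussian m/z jitter, log-uniform intensities above a
relative-abundance floor, and uniform decoy noise peaks.  Decoy features
(non-betalain spectra) avoid the diagnostic-ion windows so the screen's
false-positive rate has expectation zero; an adversarial mode places decoy
peaks exactly on the core ions instead, to probe the screen's specificity
limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import BetalainRecord, Catalog
from .fingerprint import CoreIonSet, MsmsSpectrum
from .mgf import write_mgf

__all__ = ["SimConfig", "simulate_spectrum", "simulate_run", "TRUTH_PREFIX", "DECOY_PREFIX"]

TRUTH_PREFIX = "truth:"
DECOY_PREFIX = "decoy:"

#: Half-width in Da of the exclusion window placed around true fragments
#: and diagnostic ions when sampling noise peaks.
AVOID_HALF_WINDOW = 0.05


@dataclass(frozen=True)
class SimConfig:
    ppm_jitter_sd: float = 2.0          # precursor m/z jitter (ppm)
    fragment_mz_jitter_sd: float = 0.003  # fragment m/z jitter (Da)
    n_noise_peaks_per_spectrum: int = 10
    noise_mz_range: tuple[float, float] = (100.0, 600.0)
    n_decoy_features: int = 0
    rt_jitter_sd: float = 0.05          # minutes
    base_peak_intensity: float = 1e6
    min_fragment_rel_intensity: float = 0.05
    adversarial_decoys: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_jitter_sd", "fragment_mz_jitter_sd", "rt_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _sample_avoiding(
    rng: np.random.Generator,
    n: int,
    mz_range: tuple[float, float],
    avoid: np.ndarray,
    half_window: float = AVOID_HALF_WINDOW,
) -> np.ndarray:
    """Uniform m/z samples that stay clear of every window in *avoid*."""
    out: list[float] = []
    lo, hi = mz_range
    while len(out) < n:
        draw = rng.uniform(lo, hi, size=2 * (n - len(out)) + 4)
        if avoid.size:
            keep = np.min(np.abs(draw[:, None] - avoid[None, :]), axis=1) > half_window
            draw = draw[keep]
        out.extend(draw[: n - len(out)].tolist())
    return np.asarray(out)


def _log_uniform(rng: np.random.Generator, n: int, floor: float, top: float) -> np.ndarray:
    return np.exp(rng.uniform(np.log(floor), np.log(top), size=n))


def simulate_spectrum(
    record: BetalainRecord,
    cfg: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
    ions: CoreIonSet = CoreIonSet(),
) -> MsmsSpectrum:
    """One synthetic MS/MS spectrum for a catalog record.

    The precursor is the record's theoretical m/z scaled by a Normal ppm
    error; each published fragment becomes one peak with Gaussian m/z
    jitter; the strongest fragment is pinned at the base-peak intensity and
    the rest are log-uniform above the relative-abundance floor.  Noise
    peaks avoid the true fragments and the diagnostic-ion windows.
    """
    if not record.fragments:
        raise ValueError(f"record {record.name!r} has no fragment list")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    precursor = record.theoretical_mz * (1.0 + rng.normal(0.0, cfg.ppm_jitter_sd) * 1e-6)
    rt = record.rt + rng.normal(0.0, cfg.rt_jitter_sd)

    fragments = np.asarray(sorted(set(record.fragments)))
    frag_mz = fragments + rng.normal(0.0, cfg.fragment_mz_jitter_sd, size=fragments.size)
    frag_intensity = _log_uniform(
        rng, fragments.size, cfg.min_fragment_rel_intensity, 1.0
    )
    frag_intensity[rng.integers(fragments.size)] = 1.0
    frag_intensity *= cfg.base_peak_intensity

    n_noise = cfg.n_noise_peaks_per_spectrum
    peaks = list(zip(frag_mz.tolist(), frag_intensity.tolist()))
    if n_noise:
        avoid = np.concatenate([fragments, np.asarray(ions.all_diagnostic)])
        noise_mz = _sample_avoiding(rng, n_noise, cfg.noise_mz_range, avoid)
        noise_intensity = (
            _log_uniform(rng, n_noise, 1e-3, 0.5) * cfg.base_peak_intensity
        )
        peaks.extend(zip(noise_mz.tolist(), noise_intensity.tolist()))

    return MsmsSpectrum(
        precursor_mz=precursor,
        rt=rt,
        peaks=tuple(peaks),
        title=f"{TRUTH_PREFIX}{record.name}",
    )


def _simulate_decoy(
    index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    ions: CoreIonSet,
) -> MsmsSpectrum:
    n_peaks = int(rng.integers(8, 25))
    if cfg.adversarial_decoys:
        # Place peaks exactly on the diagnostic ions to probe the screen.
        diagnostic = np.asarray(ions.all_diagnostic)
        mz = rng.choice(diagnostic, size=min(n_peaks, diagnostic.size), replace=False)
    else:
        mz = _sample_avoiding(
            rng, n_peaks, cfg.noise_mz_range, np.asarray(ions.all_diagnostic)
        )
    intensity = _log_uniform(rng, mz.size, 0.01, 1.0) * cfg.base_peak_intensity
    return MsmsSpectrum(
        precursor_mz=float(rng.uniform(250.0, 900.0)),
        rt=float(rng.uniform(0.5, 12.5)),
        peaks=tuple(zip(mz.tolist(), intensity.tolist())),
        title=f"{DECOY_PREFIX}{index}",
    )


def simulate_run(
    catalog: Catalog,
    cfg: SimConfig = SimConfig(),
    ions: CoreIonSet = CoreIonSet(),
    out: str | Path | None = None,
) -> list[MsmsSpectrum]:
    """Simulate a full DDA run: one spectrum per record plus decoys.

    Fully determined by ``cfg.seed``.  When *out* is given the run is also
    written as MGF with titles encoding the ground truth.
    """
    if not len(catalog):
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(cfg.seed)
    spectra = [simulate_spectrum(r, cfg, rng, ions) for r in catalog]
    spectra.extend(
        _simulate_decoy(i, cfg, rng, ions) for i in range(cfg.n_decoy_features)
    )
    if out is not None:
        write_mgf(spectra, out)
    return spectra
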