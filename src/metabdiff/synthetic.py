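"""Synthetic cohorts with the statistical structure of a dMRS aging study.

The generator emulates a 25-subject cross-sectional cohort (ages 25-80)
measured in two gray-matter regions (cerebellar cortex and posterior
cingulate cortex, PCC) on a 6-b-value tetrahedral protocol:

* ground-truth decay curves from any forward model, defaulting to the
  stick model with region/metabolite-typical intra-stick diffusivities
  (e.g. cerebellar tNAA Dintra = 0.346 um^2/ms);
* area-level Gaussian noise whose relative size interpolates in b
  between a low-b CRLB of ~3 % and metabolite/region-specific high-b
  CRLBs of 4-10 %, applied per direction before direction averaging;
* voxel tissue fractions with region-typical means/SDs and a linear
  gray-matter decline across the age range (~17 % cerebellum, ~4 % PCC);
* optional per-parameter linear age trends in the ground truth (zero by
  default: the null hypothesis of no aging effect);
* optional transient-level complex spectra (Lorentzian peaks + complex
  Gaussian noise, phase jitter, frequency drift, amplitude corruption)
  for exercising the QC chain, with spectral SNR ~18-24 at b~0.

Everything is reproducible: the master seed spawns independent,
deterministic substreams per subject, region and curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import DecayCurve, METABOLITES, REGIONS, SubjectRecord
from .models import (
    AstroSticksParams,
    KurtosisParams,
    ModAstroSticksParams,
    MonoexpParams,
    signal_for,
)
from .protocol import DiffusionProtocol
from .transient_qc import TransientSet

__all__ = [
    "AreaNoiseSpec",
    "TransientSpec",
    "TissueSpec",
    "CohortConfig",
    "DecayCurve",
    "SubjectRecord",
    "generate_cohort",
    "generate_decay",
    "generate_transients",
    "DEFAULT_GROUND_TRUTH",
    "DEFAULT_CRLB_BMAX",
]

# cohort-average intra-stick diffusivities (um^2/ms) used as ground truth
DEFAULT_GROUND_TRUTH = {
    ("cerebellum", "tNAA"): AstroSticksParams(0.346),
    ("cerebellum", "tCho"): AstroSticksParams(0.325),
    ("cerebellum", "tCr"): AstroSticksParams(0.287),
    ("PCC", "tNAA"): AstroSticksParams(0.440),
    ("PCC", "tCho"): AstroSticksParams(0.407),
    ("PCC", "tCr"): AstroSticksParams(0.440),
}

# relative area uncertainty (CRLB) at the highest b, per region/metabolite
DEFAULT_CRLB_BMAX = {
    ("cerebellum", "tNAA"): 0.04,
    ("cerebellum", "tCho"): 0.06,
    ("cerebellum", "tCr"): 0.04,
    ("PCC", "tNAA"): 0.07,
    ("PCC", "tCho"): 0.10,
    ("PCC", "tCr"): 0.05,
}


@dataclass(frozen=True)
class AreaNoiseSpec:
    """Relative Gaussian noise on per-direction peak areas.

    The SD interpolates linearly in b from ``crlb_b0`` at the lowest
    b-value to ``crlb_bmax`` at the highest, mimicking how spectral-fit
    uncertainty grows as diffusion weighting attenuates the signal.
    """

    crlb_b0: float = 0.03
    crlb_bmax: float = 0.05

    def sd_at(self, b: np.ndarray, b_lo: float, b_hi: float) -> np.ndarray:
        frac = (np.asarray(b, float) - b_lo) / (b_hi - b_lo)
        return self.crlb_b0 + frac * (self.crlb_bmax - self.crlb_b0)


@dataclass(frozen=True)
class TransientSpec:
    """Transient-level simulation: peaks, noise and corruption."""

    snr_b0: float = 20.0
    linewidth_hz: float = 4.5
    phase_jitter_sd: float = 0.3       # rad
    drift_sd_hz: float = 1.5
    corrupt_fraction: float = 0.05
    corrupt_scale: float = 0.5
    n_points: int = 2048
    bandwidth_hz: float = 3000.0
    # (ppm center, relative amplitude); well-separated singlets
    peaks: tuple = (("tNAA", 2.01, 1.0), ("tCr", 3.03, 0.8),
                    ("tCho", 3.22, 0.6))


@dataclass(frozen=True)
class TissueSpec:
    """Voxel tissue-composition distribution for one region."""

    fgm_mean: float
    fgm_sd: float
    fwm_mean: float
    fwm_sd: float
    fcsf_mean: float
    fcsf_sd: float
    # fractional decline of fGM across the full age range
    fgm_decline: float


DEFAULT_TISSUE = {
    "cerebellum": TissueSpec(0.82, 0.05, 0.12, 0.05, 0.06, 0.03,
                             fgm_decline=0.17),
    "PCC": TissueSpec(0.69, 0.07, 0.14, 0.03, 0.17, 0.08,
                      fgm_decline=0.04),
}


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort."""

    n_subjects: int = 25
    age_range: tuple = (25.0, 80.0)
    regions: tuple = REGIONS
    metabolites: tuple = METABOLITES
    ground_truth: dict = field(default_factory=lambda: dict(DEFAULT_GROUND_TRUTH))
    # (region, metabolite, parameter) -> slope per year of age
    age_slopes: dict = field(default_factory=dict)
    reference_age: float = 50.0
    tissue: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE))
    crlb_b0: float = 0.03
    crlb_bmax: dict = field(default_factory=lambda: dict(DEFAULT_CRLB_BMAX))
    include_transients: bool = False
    transient_spec: TransientSpec = TransientSpec()
    protocol: DiffusionProtocol = DiffusionProtocol()
    seed: int = 42

    def noise_for(self, region: str, metabolite: str) -> AreaNoiseSpec:
        return AreaNoiseSpec(self.crlb_b0,
                             self.crlb_bmax.get((region, metabolite), 0.05))


def _aged_params(params, slopes: dict, age: float, reference_age: float,
                 key_prefix: tuple):
    """Apply linear age trends to ground-truth parameters, clipped to bounds."""
    updates = {}
    for name in vars(params):
        slope = slopes.get(key_prefix + (name,), 0.0)
        if slope == 0.0:
            continue
        value = getattr(params, name) + slope * (age - reference_age)
        hi = 1.0 if name in ("ADC", "Dintra") else 3.0
        updates[name] = float(np.clip(value, 1e-4, hi))
    return replace(params, **updates) if updates else params


def generate_decay(params, protocol: DiffusionProtocol,
                   noise: AreaNoiseSpec, seed: int, s0: float = 1.0,
                   metabolite: str = "tNAA",
                   region: str = "cerebellum") -> DecayCurve:
    """Simulate one direction-averaged decay curve.

    Per-direction areas are S0 * S(b) * (1 + eps) with eps Gaussian at
    the b-interpolated CRLB fraction, then averaged over directions;
    amplitudes are floored just above zero so downstream log/positivity
    assumptions hold.
    """
    rng = np.random.default_rng(seed)
    b = protocol.b_array()
    clean = s0 * np.asarray(signal_for(params, b), dtype=float)
    sd = noise.sd_at(b, b[0], b[-1])
    n_dir = protocol.n_directions
    per_dir = clean[:, None] * (1.0 + rng.normal(0.0, 1.0, (b.size, n_dir))
                                * sd[:, None])
    per_dir = np.maximum(per_dir, 1e-9 * s0)
    amp = per_dir.mean(axis=1)
    amp_sd = clean * sd / np.sqrt(n_dir)
    return DecayCurve(metabolite, region, b, amp, amp_sd)


def generate_transients(params, protocol: DiffusionProtocol,
                        spec: TransientSpec, seed: int) -> TransientSet:
    """Simulate transient-level complex spectra for one condition set.

    Each transient is a sum of Lorentzian singlets whose amplitudes are
    attenuated by the forward model at that transient's b-value, plus
    complex Gaussian noise scaled so the reference peak height over the
    noise SD equals ``snr_b0`` at the lowest b. Random zero-order phase,
    frequency drift and (for a configured fraction) amplitude corruption
    emulate physiological motion.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_points
    bw = spec.bandwidth_hz
    t = np.arange(n) / bw
    carrier_mhz = 127.7
    center_ppm = 2.6
    b = protocol.b_array()
    atten = np.asarray(signal_for(params, b), dtype=float)

    def clean_fid(scale: float) -> np.ndarray:
        fid = np.zeros(n, dtype=complex)
        for _, ppm, rel in spec.peaks:
            f_hz = (ppm - center_ppm) * carrier_mhz
            fid += rel * scale * np.exp(2j * np.pi * f_hz * t) \
                * np.exp(-np.pi * spec.linewidth_hz * t)
        return fid

    # calibrate the noise floor against the b~0 reference peak height
    ref_spec = np.fft.fftshift(np.fft.fft(clean_fid(atten[0])))
    noise_sd = float(np.max(np.abs(ref_spec))) / spec.snr_b0

    nt = protocol.transients_per_condition
    spectra = np.empty((b.size, protocol.n_directions, nt, n), dtype=complex)
    for ib in range(b.size):
        for idir in range(protocol.n_directions):
            for it in range(nt):
                scale = atten[ib]
                if rng.uniform() < spec.corrupt_fraction:
                    scale *= spec.corrupt_scale
                fid = clean_fid(scale)
                drift = rng.normal(0.0, spec.drift_sd_hz)
                fid *= np.exp(2j * np.pi * drift * t)
                spec_f = np.fft.fftshift(np.fft.fft(fid))
                spec_f *= np.exp(1j * rng.normal(0.0, spec.phase_jitter_sd))
                spec_f += noise_sd * (rng.normal(size=n)
                                      + 1j * rng.normal(size=n))
                spectra[ib, idir, it] = spec_f
    return TransientSet(spectra, protocol, bandwidth_hz=bw,
                        carrier_mhz=carrier_mhz, center_ppm=center_ppm)


def _lognormal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Moment-matched lognormal draw: strictly positive, no floor pile-up."""
    var = np.log1p((sd / mean) ** 2)
    return float(rng.lognormal(np.log(mean) - var / 2.0, np.sqrt(var)))


def _tissue_fractions(tspec: TissueSpec, age: float, age_range: tuple,
                      rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw (fGM, fWM, fCSF) with an age-declining fGM, renormalized to 1.

    Fractions are moment-matched lognormal (a voxel never contains a
    vanishing or negative tissue class), so the fGM/fWM covariate stays
    bounded; the configured gray-matter decline is linear across the age
    range with the cohort mean preserved.
    """
    lo, hi = age_range
    rel = (age - lo) / (hi - lo)           # 0 at youngest, 1 at oldest
    trend = 1.0 + tspec.fgm_decline * (0.5 - rel)  # cohort mean preserved
    fgm = _lognormal(tspec.fgm_mean * trend, tspec.fgm_sd, rng)
    fwm = _lognormal(tspec.fwm_mean, tspec.fwm_sd, rng)
    fcsf = _lognormal(tspec.fcsf_mean, tspec.fcsf_sd, rng)
    fr = np.array([fgm, fwm, fcsf])
    fr /= fr.sum()
    return float(fr[0]), float(fr[1]), float(fr[2])


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate one synthetic cohort, one record per (subject, region).

    Deterministic under ``config.seed``: subject attributes and every
    curve/transient draw come from independent spawned substreams.
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    lo, hi = config.age_range
    ages = master.uniform(lo, hi, config.n_subjects)
    sexes = master.choice(["F", "M"], config.n_subjects)
    subject_seeds = ss.spawn(config.n_subjects)

    records = []
    for i in range(config.n_subjects):
        sub_ss = subject_seeds[i]
        region_seeds = sub_ss.spawn(len(config.regions))
        for ir, region in enumerate(config.regions):
            rng = np.random.default_rng(region_seeds[ir])
            tspec = config.tissue[region]
            fgm, fwm, fcsf = _tissue_fractions(tspec, ages[i],
                                               config.age_range, rng)
            curves, truth, transients = {}, {}, {}
            for metab in config.metabolites:
                base = config.ground_truth[(region, metab)]
                params = _aged_params(base, config.age_slopes, ages[i],
                                      config.reference_age, (region, metab))
                truth[metab] = params
                curve_seed = int(rng.integers(0, 2**31 - 1))
                curves[metab] = generate_decay(
                    params, config.protocol,
                    config.noise_for(region, metab), curve_seed,
                    metabolite=metab, region=region)
                if config.include_transients:
                    tseed = int(rng.integers(0, 2**31 - 1))
                    transients[metab] = generate_transients(
                        params, config.protocol, config.transient_spec,
                        tseed)
            records.append(SubjectRecord(
                subject_id=f"sub-{i + 1:03d}", age=float(ages[i]),
                sex=str(sexes[i]), region=region, fgm=fgm, fwm=fwm,
                fcsf=fcsf, curves=curves,
                transients=transients if config.include_transients else None,
                ground_truth=truth))
    return records
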