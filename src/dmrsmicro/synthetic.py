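"""Synthetic-study generator emulating the developmental dMRS design.

Produces (i) metabolite-level powder-averaged decays and two-point ADC
series for a cohort of pups scanned longitudinally in cerebellum and
thalamus, with signal-dependent Gaussian noise, pup-level parameter
variability and injectable missing data; and (ii) raw-like complex
transient sets (repetition × direction × b, optionally multi-coil) with
frequency/phase jitter and motion-corrupted transients, for exercising
the preprocessing pipeline. All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import SphereSticksParams, sphere_sticks_signal
from .scheme import DiffusionScheme, make_scheme_table
from .transients import TransientSet

__all__ = [
    "StudyDesign",
    "TruthTrajectory",
    "default_truth",
    "simulate_study",
    "simulate_transients",
    "table_repetitions",
]

AGES = (5.0, 10.0, 15.0, 20.0, 30.0)
REGIONS = ("cerebellum", "thalamus")
METABOLITES = ("tNAA", "Glu", "tCr", "Tau", "tCho", "Ins")

# repetitions per b-value index, times the direction count, per mixing time
_REPS = {100.0: (4, 4, 6, 6, 8, 8), 500.0: (8, 8), 750.0: (10, 10), 1000.0: (12, 12)}


def table_repetitions(tm: float) -> tuple[int, ...]:
    """Per-b repetition counts for one mixing time (× 16 directions)."""
    return _REPS[float(tm)]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and acquisition structure of the developmental study."""

    ages: tuple = AGES
    regions: tuple = REGIONS
    n_pups_per_region: int = 9
    metabolites: tuple = METABOLITES
    schemes: dict[float, DiffusionScheme] = field(default_factory=make_scheme_table)


# Piecewise-linear sphere-fraction trajectories per (metabolite, region),
# anchored at the study ages. Shapes emulate the developmental trends of
# the real cohort (e.g. declining cerebellar Tau/tCr sphere fraction).
_F_TRUTH = {
    ("tNAA", "cerebellum"): (0.47, 0.45, 0.42, 0.42, 0.33),
    ("tNAA", "thalamus"): (0.46, 0.24, 0.27, 0.26, 0.17),
    ("Glu", "cerebellum"): (0.47, 0.50, 0.51, 0.48, 0.47),
    ("Glu", "thalamus"): (0.23, 0.17, 0.27, 0.28, 0.24),
    ("tCr", "cerebellum"): (0.59, 0.63, 0.53, 0.39, 0.41),
    ("tCr", "thalamus"): (0.35, 0.36, 0.34, 0.31, 0.32),
    ("Tau", "cerebellum"): (0.42, 0.43, 0.38, 0.31, 0.29),
    ("Tau", "thalamus"): (0.18, 0.15, 0.18, 0.25, 0.33),
    ("tCho", "cerebellum"): (0.80, 0.82, 0.67, 0.50, 0.55),
    ("tCho", "thalamus"): (0.62, 0.47, 0.50, 0.44, 0.50),
    ("Ins", "cerebellum"): (0.83, 0.87, 0.83, 0.67, 0.65),
    ("Ins", "thalamus"): (0.82, 0.92, 0.85, 0.81, 0.76),
}
# Sphere radii decline mildly with age (soma maturation); µm.
_R_TRUTH = {
    "cerebellum": (8.0, 7.5, 6.5, 5.5, 5.0),
    "thalamus": (7.5, 7.0, 6.5, 6.0, 5.5),
}


@dataclass(frozen=True)
class TruthTrajectory:
    """Ground-truth mixture parameters versus age, per metabolite × region.

    ``f_anchor``/``R_anchor`` hold values at the design ages; parameters at
    arbitrary age follow by linear interpolation. D_intra is age-constant.
    """

    f_anchor: dict = field(default_factory=lambda: dict(_F_TRUTH))
    R_anchor: dict = field(default_factory=lambda: dict(_R_TRUTH))
    D_intra: float = 0.5
    ages: tuple = AGES

    def params(self, metabolite: str, region: str, age: float) -> SphereSticksParams:
        f = float(np.interp(age, self.ages, self.f_anchor[(metabolite, region)]))
        R = float(np.interp(age, self.ages, self.R_anchor[region]))
        return SphereSticksParams(f_sphere=f, R_sphere=R, D_intra=self.D_intra)


def default_truth() -> TruthTrajectory:
    return TruthTrajectory()


def simulate_study(
    design: StudyDesign | None = None,
    truth: TruthTrajectory | None = None,
    noise_sd: float = 0.02,
    missing_rate: float = 0.0,
    pup_sd_f: float = 0.04,
    pup_sd_R: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort's decays and ADC series.

    Per pup the truth parameters receive a random perturbation (SD
    ``pup_sd_f`` on the sphere fraction, ``pup_sd_R`` µm on the radius,
    clipped to valid ranges); signals then acquire Gaussian noise with SD
    ``noise_sd``·E (signal-dependent). ADCs are recomputed from the noisy
    two-point signals, so negative ADCs occur naturally at low SNR and are
    retained for downstream filtering. Each non-reference decay point and
    each ADC value goes missing (NaN) independently at ``missing_rate``.

    Returns (decay_table, adc_table, truth_table) in long format.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    design = design or StudyDesign()
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    schemes = design.schemes
    tms = sorted(schemes)
    sch100 = schemes[100.0]

    decay_rows, adc_rows, truth_rows = [], [], []
    for region in design.regions:
        for p in range(design.n_pups_per_region):
            pup = f"{region[:2]}{p + 1:02d}"
            for met in design.metabolites:
                df_jit = rng.normal(0.0, pup_sd_f)
                dR_jit = rng.normal(0.0, pup_sd_R)
                for age in design.ages:
                    base = truth.params(met, region, age)
                    par = SphereSticksParams(
                        f_sphere=float(np.clip(base.f_sphere + df_jit, 0.0, 1.0)),
                        R_sphere=float(np.clip(base.R_sphere + dR_jit, 1.0, 15.0)),
                        D_intra=base.D_intra,
                    )
                    truth_rows.append({
                        "pup_id": pup, "region": region, "age": age, "metabolite": met,
                        "f_sphere": par.f_sphere, "R_sphere": par.R_sphere,
                        "D_intra": par.D_intra,
                    })
                    # high-b decay at the shortest mixing time
                    E = sphere_sticks_signal(par, sch100)
                    E_noisy = E + rng.normal(0.0, noise_sd * E)
                    E_norm = E_noisy / E_noisy[0]
                    for i, b in enumerate(sch100.b_values):
                        val = E_norm[i]
                        if i > 0 and missing_rate > 0 and rng.random() < missing_rate:
                            val = np.nan
                        decay_rows.append({
                            "pup_id": pup, "region": region, "age": age,
                            "metabolite": met, "TM": 100.0, "b": float(b), "E": val,
                        })
                    # two-point ADC per mixing time from noisy signals
                    for tm in tms:
                        sch = schemes[tm]
                        b0, b1 = sch.b_pair
                        Epair = sphere_sticks_signal(par, sch, np.array([b0, b1]))
                        Ep = Epair + rng.normal(0.0, noise_sd * Epair)
                        adc = float(-np.log(Ep[1] / Ep[0]) / (b1 - b0))
                        if missing_rate > 0 and rng.random() < missing_rate:
                            adc = np.nan
                        adc_rows.append({
                            "pup_id": pup, "region": region, "age": age,
                            "metabolite": met, "TM": tm, "t_d": sch.t_d, "adc": adc,
                        })
    return pd.DataFrame(decay_rows), pd.DataFrame(adc_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# raw-like transients

# Metabolite singlet positions (ppm) for the synthetic spectra.
_PPM = {"tNAA": 2.01, "Glu": 2.35, "tCr": 3.03, "tCho": 3.22, "Tau": 3.42, "Ins": 3.56}
# Broad macromolecule-like background components.
_MM_PPM = (0.9, 1.4, 2.1, 3.0)


def _fid_from_peaks(peaks, t, f0, ref_ppm):
    """Complex FID from (ppm, amplitude, linewidth Hz) damped sinusoids."""
    fid = np.zeros(len(t), dtype=complex)
    for ppm, amp, lw in peaks:
        f_hz = (ppm - ref_ppm) * f0
        fid += amp * np.exp((1j * 2 * np.pi * f_hz - np.pi * lw) * t)
    return fid


def simulate_transients(
    tm: float = 100.0,
    b_values: np.ndarray | None = None,
    n_directions: int = 16,
    reps_per_b: tuple[int, ...] | None = None,
    metabolite_amps: dict[str, float] | None = None,
    mm_amp: float = 0.15,
    water_amp: float = 0.0,
    linewidth: float = 5.0,
    adc_per_met: float = 0.12,
    freq_jitter_sd: float = 3.0,
    phase_jitter_sd: float = 10.0,
    amp_jitter_sd: float = 0.03,
    noise_sd: float = 0.3,
    corrupt: dict[int, float] | None = None,
    n_coils: int = 0,
    coil_phases: np.ndarray | None = None,
    coil_amps: np.ndarray | None = None,
    n_points: int = 2048,
    sw: float = 5000.0,
    f0: float = 500.0,
    seed: int = 0,
) -> tuple[TransientSet, dict]:
    """Build a raw-like transient set with a known ground-truth ledger.

    Spectra are sums of metabolite singlets (linewidth ~5 Hz), broad
    macromolecule-like components and an optional water residual at
    4.7 ppm. Signal amplitude decays monoexponentially with b at
    ``adc_per_met`` (so SNR drops with b), each transient gets frequency
    jitter (SD ``freq_jitter_sd`` Hz), zero-order phase jitter (SD
    ``phase_jitter_sd`` degrees) and complex Gaussian noise. ``corrupt``
    maps transient indices to motion attenuation factors applied to the
    metabolite signal (a 0.4 factor drops M_up to ≈40% of the median).
    With ``n_coils`` > 0 the output carries a coil axis with the given (or
    random) complex sensitivities plus a matching water reference set.

    Returns (transients, truth) where ``truth`` records every injected
    quantity for injection/recovery tests.
    """
    rng = np.random.default_rng(seed)
    if b_values is None:
        b_values = np.asarray(make_scheme_table()[tm].b_values)
    b_values = np.asarray(b_values, dtype=float)
    if reps_per_b is None:
        reps_per_b = table_repetitions(tm)[: len(b_values)]
    if metabolite_amps is None:
        metabolite_amps = {m: 1.0 for m in _PPM}
    corrupt = corrupt or {}

    t = np.arange(n_points) / sw
    ref_ppm = 4.7

    idx = []
    for bi, b in enumerate(b_values):
        for d in range(n_directions):
            for r in range(reps_per_b[bi]):
                idx.append((b, d, r))
    n_tr = len(idx)

    freq_shifts = rng.normal(0.0, freq_jitter_sd, n_tr)
    phases = np.deg2rad(rng.normal(0.0, phase_jitter_sd, n_tr))
    # physiological scan-to-scan amplitude variability (breathing, B0 drift)
    amp_jitter = 1.0 + rng.normal(0.0, amp_jitter_sd, n_tr)

    if n_coils > 0:
        if coil_phases is None:
            coil_phases = rng.uniform(-np.pi, np.pi, n_coils)
        if coil_amps is None:
            coil_amps = rng.uniform(0.5, 1.5, n_coils)
        fids = np.zeros((n_tr, n_coils, n_points), dtype=complex)
    else:
        fids = np.zeros((n_tr, n_points), dtype=complex)

    for i, (b, d, r) in enumerate(idx):
        decay = np.exp(-b * adc_per_met) * amp_jitter[i]
        factor = corrupt.get(i, 1.0)
        peaks = [(_PPM[m], a * decay * factor, linewidth) for m, a in metabolite_amps.items()]
        # macromolecule background attenuates only weakly with b
        peaks += [(p, mm_amp * factor * amp_jitter[i] * np.exp(-b * 0.005), 80.0) for p in _MM_PPM]
        if water_amp:
            peaks.append((ref_ppm, water_amp, 12.0))
        fid = _fid_from_peaks(peaks, t, f0, ref_ppm)
        fid *= np.exp(1j * (2 * np.pi * freq_shifts[i] * t + phases[i]))
        if n_coils > 0:
            for c in range(n_coils):
                noise = rng.normal(0, noise_sd, n_points) + 1j * rng.normal(0, noise_sd, n_points)
                fids[i, c] = coil_amps[c] * np.exp(1j * coil_phases[c]) * fid + noise
        else:
            noise = rng.normal(0, noise_sd, n_points) + 1j * rng.normal(0, noise_sd, n_points)
            fids[i] = fid + noise

    ts = TransientSet(
        fids=fids,
        b=np.array([b for b, _, _ in idx]),
        direction=np.array([d for _, d, _ in idx], dtype=int),
        repetition=np.array([r for _, _, r in idx], dtype=int),
        sw=sw, f0=f0, ref_ppm=ref_ppm, tm=tm,
    )

    truth = {
        "freq_shifts": freq_shifts,
        "phases": phases,
        "amp_jitter": amp_jitter,
        "corrupt": dict(corrupt),
        "metabolite_amps": dict(metabolite_amps),
        "adc_per_met": adc_per_met,
        "water_amp": water_amp,
        "coil_phases": None if n_coils == 0 else np.asarray(coil_phases),
        "coil_amps": None if n_coils == 0 else np.asarray(coil_amps),
    }

    if n_coils > 0:
        # water reference at the lowest b: strong water, no jitter
        wref_fids = np.zeros((2, n_coils, n_points), dtype=complex)
        wfid = _fid_from_peaks([(ref_ppm, 50.0, 12.0)], t, f0, ref_ppm)
        for j in range(2):
            for c in range(n_coils):
                noise = rng.normal(0, noise_sd, n_points) + 1j * rng.normal(0, noise_sd, n_points)
                wref_fids[j, c] = coil_amps[c] * np.exp(1j * coil_phases[c]) * wfid + noise
        truth["water_ref"] = TransientSet(
            fids=wref_fids, b=np.full(2, b_values.min()),
            direction=np.zeros(2, dtype=int), repetition=np.arange(2),
            sw=sw, f0=f0, ref_ppm=ref_ppm, tm=tm,
        )
    return ts, truth
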