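"""Synthetic ATR-FTIR cohorts with planted band-position and survival structure.

The generator emulates the study conditions the pipeline is built for: a
paediatric bone-sarcoma cohort where each patient contributes triplicate
ATR-FTIR spectra of tumour at biopsy (t_b), tumour after neoadjuvant
chemotherapy (t_t) and — for most but not all patients — normal bone (t_n),
plus progression-free and overall survival outcomes whose hazard depends on
a latent risk class expressed in the position of the dominant
carbohydrate/phosphate band near 1030 cm^-1.

Generative model
----------------
Each spectrum is a sum of Gaussian bands on the 800-3500 cm^-1 grid at
2 cm^-1 spacing, a random linear baseline a + b*nu, and white absorbance
noise.  The centre of the ~1030 cm^-1 band carries the signal:

* tumour at biopsy:    c_b = c0 + delta * r + eps,   eps ~ N(0, sigma_c^2)
* tumour post-chemo:   c_t = c_b + shift(r) + eps_t  (responders shift right)
* normal bone:         c_n = c_b + offset(r) + eps_n

with latent risk indicator r ~ Bernoulli(p_risk).  Each replicate jitters
the centre by N(0, sigma_rep^2).  Progression times are exponential with
hazard lambda0 * exp(beta_true * r); death follows progression after an
exponential delay; both are right-censored administratively with a uniform
early-censoring fraction.

``PlantedTruth`` carries the latent quantities for oracle checks; the
analysis pipeline never reads it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import PatientRecord, Spectrum, write_csv

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "paper_like_config",
    "generate_spectrum",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Wavenumbers in cm^-1, times in months.  Defaults describe the emulated
    cohort: 27 patients, roughly half high-risk, a ~7.5 cm^-1 band-centre
    separation between risk classes against ~4.6 cm^-1 of total centre
    spread, seven patients without normal-bone spectra, and an exponential
    progression hazard ratio of 10 between risk classes.
    """

    n_patients: int = 27
    seed: int = 0

    # wavenumber grid
    grid_min: float = 800.0
    grid_max: float = 3500.0
    grid_step: float = 2.0

    # fixed background bands: (centre, sigma, amplitude)
    band_library: tuple[tuple[float, float, float], ...] = (
        (1080.0, 12.0, 0.35),
        (1240.0, 15.0, 0.50),
        (1400.0, 12.0, 0.45),
        (1545.0, 12.0, 0.60),
        (1655.0, 14.0, 0.90),
        (2852.0, 10.0, 0.25),
        (2925.0, 12.0, 0.35),
        (3290.0, 80.0, 0.50),
    )
    # the signal-carrying band near 1030 cm^-1
    main_band_sigma: float = 5.0
    main_band_amplitude: float = 1.0

    # band-centre model
    risk_prob: float = 14.0 / 27.0
    centre_low: float = 1024.0  # c0: low-risk tumour-at-biopsy centre
    centre_effect: float = 7.5  # delta: added for high-risk patients
    centre_sd: float = 4.5  # per-patient centre noise
    replicate_centre_jitter: float = 1.5
    tt_shift_low_risk: float = 7.0  # responders' post-chemo shift
    tt_shift_high_risk: float = -0.5
    tn_offset_low_risk: float = 16.0  # normal bone sits right of tumour
    tn_offset_high_risk: float = 1.0
    tissue_centre_sd: float = 4.0  # extra noise on t_t / t_n centres

    # per-spectrum nuisance
    tissues: tuple[str, ...] = ("t_b", "t_t", "t_n")  # which tissues to render
    n_replicates: int = 3
    absorbance_noise_sd: float = 0.01
    baseline_intercept_range: tuple[float, float] = (0.0, 0.05)
    baseline_slope_range: tuple[float, float] = (0.0, 2e-4)

    # missingness
    missing_tn_prob: float = 7.0 / 27.0
    exact_missing_tn: int | None = None  # overrides the probability if set

    # survival model
    baseline_hazard: float = 0.0055  # per month; low-risk 36-month PFS ~ 0.82
    log_hr: float = float(np.log(10.0))  # beta_true on the risk indicator
    death_delay_hazard: float = 1.0 / 12.0  # post-progression death delay
    censor_time: float = 74.0
    early_censor_frac: float = 0.7
    early_censor_min: float = 12.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.grid_step <= 0 or self.grid_min >= self.grid_max:
            raise ValueError("invalid wavenumber grid")
        for c, s, a in self.band_library:
            if s <= 0 or a <= 0:
                raise ValueError("band widths and amplitudes must be positive")
        if self.main_band_sigma <= 0 or self.main_band_amplitude <= 0:
            raise ValueError("main band width and amplitude must be positive")
        if self.baseline_hazard <= 0 or self.death_delay_hazard <= 0:
            raise ValueError("hazards must be positive")
        for p in (self.risk_prob, self.missing_tn_prob, self.early_censor_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


def paper_like_config(seed: int = 0) -> SyntheticConfig:
    """The 27-patient preset: exactly 7 patients without normal-bone spectra.

    Centre levels put the low/high-risk tumour-at-biopsy medians near
    1024 / 1031.5 cm^-1.  Intended for smoke tests and examples.
    """
    return SyntheticConfig(n_patients=27, exact_missing_tn=7, seed=seed)


@dataclass(frozen=True)
class PatientState:
    """Latent per-patient quantities driving spectrum and outcome generation."""

    patient_id: str
    risk: int
    centre_tb: float
    centre_tt: float
    centre_tn: float | None  # None when t_n is missing for this patient
    progression_time: float
    death_time: float
    censoring_time: float


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for oracle checks; never read by the analysis pipeline."""

    states: tuple[PatientState, ...]
    config: SyntheticConfig

    @property
    def risk(self) -> np.ndarray:
        return np.array([s.risk for s in self.states], dtype=int)

    @property
    def centres_tb(self) -> np.ndarray:
        return np.array([s.centre_tb for s in self.states])

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "patients": [asdict(s) for s in self.states],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["band_library"] = [list(b) for b in config.band_library]
    return d


def generate_spectrum(
    config: SyntheticConfig,
    state: PatientState,
    tissue_type: str,
    replicate_index: int,
    rng: np.random.Generator,
) -> Spectrum:
    """Render one replicate spectrum for a patient and tissue.

    absorbance(nu) = sum_k A_k exp(-(nu - c_k)^2 / (2 sigma_k^2))
                     + a + b*nu + N(0, sigma_a^2) noise,
    with the ~1030 cm^-1 band centred at the tissue-specific centre plus
    replicate jitter.
    """
    centre = {"t_b": state.centre_tb, "t_t": state.centre_tt, "t_n": state.centre_tn}[
        tissue_type
    ]
    if centre is None:
        raise ValueError(f"patient {state.patient_id} has no {tissue_type} tissue")
    nu = config.grid
    centre_jittered = centre + rng.normal(0.0, config.replicate_centre_jitter)
    y = config.main_band_amplitude * np.exp(
        -((nu - centre_jittered) ** 2) / (2 * config.main_band_sigma**2)
    )
    for c, s, a in config.band_library:
        y += a * np.exp(-((nu - c) ** 2) / (2 * s**2))
    a0 = rng.uniform(*config.baseline_intercept_range)
    b0 = rng.uniform(*config.baseline_slope_range)
    y += a0 + b0 * nu
    if config.absorbance_noise_sd > 0:
        y += rng.normal(0.0, config.absorbance_noise_sd, size=nu.size)
    return Spectrum(
        wavenumbers=nu,
        absorbance=y,
        patient_id=state.patient_id,
        tissue_type=tissue_type,
        replicate_index=replicate_index,
    )


def _draw_states(config: SyntheticConfig, rng: np.random.Generator) -> list[PatientState]:
    n = config.n_patients
    risk = (rng.random(n) < config.risk_prob).astype(int)

    if config.exact_missing_tn is not None:
        k = min(config.exact_missing_tn, n)
        missing_tn = np.zeros(n, dtype=bool)
        missing_tn[rng.choice(n, size=k, replace=False)] = True
    else:
        missing_tn = rng.random(n) < config.missing_tn_prob

    states = []
    for i in range(n):
        r = int(risk[i])
        c_b = config.centre_low + config.centre_effect * r + rng.normal(0, config.centre_sd)
        tt_shift = config.tt_shift_high_risk if r else config.tt_shift_low_risk
        tn_off = config.tn_offset_high_risk if r else config.tn_offset_low_risk
        c_t = c_b + tt_shift + rng.normal(0, config.tissue_centre_sd)
        c_n = c_b + tn_off + rng.normal(0, config.tissue_centre_sd)

        hazard = config.baseline_hazard * np.exp(config.log_hr * r)
        t_prog = rng.exponential(1.0 / hazard)
        t_death = t_prog + rng.exponential(1.0 / config.death_delay_hazard)
        if rng.random() < config.early_censor_frac:
            c_time = rng.uniform(config.early_censor_min, config.censor_time)
        else:
            c_time = config.censor_time

        states.append(
            PatientState(
                patient_id=f"P{i + 1:03d}",
                risk=r,
                centre_tb=float(c_b),
                centre_tt=float(c_t),
                centre_tn=None if missing_tn[i] else float(c_n),
                progression_time=float(t_prog),
                death_time=float(t_death),
                censoring_time=float(c_time),
            )
        )
    return states


def _clinical_record(
    state: PatientState, config: SyntheticConfig, rng: np.random.Generator
) -> PatientRecord:
    # clinical covariates are drawn independently of the latent risk class:
    # the planted prognostic signal is purely spectral
    necrosis_good = rng.random() < 20.0 / 27.0
    pfs = min(state.progression_time, state.censoring_time)
    os_ = min(state.death_time, state.censoring_time)
    return PatientRecord(
        patient_id=state.patient_id,
        gender="male" if rng.random() < 12.0 / 27.0 else "female",
        age_years=float(np.round(rng.uniform(5, 20), 1)),
        disease_extent="metastatic" if rng.random() < 16.0 / 27.0 else "local",
        site="axial" if rng.random() < 7.0 / 27.0 else "peripheral",
        necrosis_pct=float(
            np.round(rng.uniform(90, 100) if necrosis_good else rng.uniform(20, 90), 0)
        ),
        radiotherapy=int(rng.random() < 17.0 / 27.0),
        auto_hsct=int(rng.random() < 8.0 / 27.0),
        adjuvant_ctx="VAI" if rng.random() < 0.75 else "VAC",
        pfs_months=float(round(pfs, 2)),
        pfs_event=int(state.progression_time <= state.censoring_time),
        os_months=float(round(os_, 2)),
        os_event=int(state.death_time <= state.censoring_time),
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[PatientRecord], list[Spectrum], PlantedTruth]:
    """Generate a full cohort: clinical records, all spectra, planted truth.

    Deterministic: the same config (including its seed) reproduces the
    cohort bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    states = _draw_states(config, rng)
    records = [_clinical_record(s, config, rng) for s in states]
    spectra: list[Spectrum] = []
    for s in states:
        tissues = [
            t
            for t in config.tissues
            if not (t == "t_n" and s.centre_tn is None)
        ]
        for tissue in tissues:
            for rep in range(1, config.n_replicates + 1):
                spectra.append(generate_spectrum(config, s, tissue, rep, rng))
    return records, spectra, PlantedTruth(states=tuple(states), config=config)


def write_cohort(
    records: Sequence[PatientRecord],
    spectra: Sequence[Spectrum],
    truth: PlantedTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a cohort directory: spectra CSVs, manifest, clinical table, truth.

    Returns the paths of the manifest, clinical table and truth JSON.
    """
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for s in spectra:
        fname = f"spectra/{s.patient_id}_{s.tissue_type}_r{s.replicate_index}.csv"
        write_csv(s, out / fname)
        manifest_rows.append((s.patient_id, s.tissue_type, s.replicate_index, fname))

    manifest_path = out / "manifest.csv"
    with open(manifest_path, "w") as fh:
        fh.write("patient_id,tissue_type,replicate,path\n")
        for pid, tissue, rep, path in manifest_rows:
            fh.write(f"{pid},{tissue},{rep},{path}\n")

    clinical_path = out / "clinical.csv"
    cols = [
        "patient_id", "gender", "age_years", "disease_extent", "site",
        "necrosis_pct", "radiotherapy", "auto_hsct", "adjuvant_ctx",
        "pfs_months", "pfs_event", "os_months", "os_event",
    ]
    with open(clinical_path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for r in records:
            vals = [getattr(r, c) for c in cols]
            fh.write(",".join("" if v is None else str(v) for v in vals) + "\n")

    truth_path = out / "planted_truth.json"
    truth_path.write_text(truth.to_json())
    return {"manifest": manifest_path, "clinical": clinical_path, "truth": truth_path}
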